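"""Assay-panel cascade: individual stages, conservation, nesting, idempotence."""

import numpy as np
import pandas as pd
import pytest

from peamap import design
from peamap.config import SimulationConfig, ThresholdConfig
from peamap.simulate import simulate_study
from oracles import brute_force_flank_keep

ACCS = ["cv1", "cv2", "cv3", "w1", "w2"]
CULT, WILD = ACCS[:3], ACCS[3:]


def merged_row(contig="c1", pos=300, ref="A", alt="G", states=None,
               triallelic=False, annotated=True):
    states = states or {}
    row = {"contig": contig, "pos": pos, "ref": ref, "alt": alt,
           "triallelic": triallelic, "annotated": annotated,
           "n_accessions_with_data": len(ACCS), "maf": 0.4,
           "subst_class": "transition"}
    for a in ACCS:
        row[a] = states.get(a, "ref")
    return row


def build(merged_rows, lengths=None, splice=None, scores=None, ortho=None):
    merged = pd.DataFrame(merged_rows)
    contigs = merged["contig"].unique()
    lengths = lengths or {c: 1000 for c in contigs}
    splice = splice if splice is not None else pd.DataFrame(
        columns=["contig", "pos0"])
    if scores is None:
        scores = pd.DataFrame({"contig": merged["contig"],
                               "pos": merged["pos"],
                               "design_score": 0.9})
    if ortho is None:
        ortho = pd.DataFrame({"contig": contigs, "model_chrom": 1,
                              "model_start": 0, "model_end": 1500,
                              "strand": "+", "annotated": 0})
    return design.build_candidates(merged, lengths, splice, scores, ortho,
                                   CULT, WILD)


class TestStages:
    def test_flanking_pair_both_removed(self):
        cand = build([merged_row(pos=300, states={"cv1": "alt"}),
                      merged_row(pos=310, alt="C", states={"cv2": "alt"})])
        out = design.filter_flanking_variation(cand)
        assert out.empty

    def test_lone_snp_kept(self):
        cand = build([merged_row(pos=500, states={"cv1": "alt"})])
        assert len(design.filter_flanking_variation(cand)) == 1

    def test_flanking_matches_pairwise_oracle(self, rng):
        positions = np.sort(rng.choice(5000, size=100, replace=False))
        rows = [merged_row(pos=int(p), states={"cv1": "alt"})
                for p in positions]
        cand = build(rows, lengths={"c1": 6000})
        out = design.filter_flanking_variation(cand, window_bp=60)
        got = set(zip(out["contig"], out["pos"].astype(int)))
        expected = brute_force_flank_keep({"c1": positions.tolist()}, 60)
        assert got == expected

    def test_heterozygous_removed(self):
        cand = build([merged_row(states={"cv1": "alt", "cv2": "het_suspect"}),
                      merged_row(contig="c2", states={"cv1": "alt"})])
        out = design.filter_heterozygous(cand)
        assert out["contig"].tolist() == ["c2"]

    def test_clearance_rule_and_boundaries(self):
        rows = [merged_row(contig="c1", pos=59, states={"cv1": "alt"}),
                merged_row(contig="c2", pos=500, states={"cv1": "alt"}),
                merged_row(contig="c3", pos=500, states={"cv1": "alt"})]
        splice = pd.DataFrame({"contig": ["c3"], "pos0": [560]})
        cand = build(rows, splice=splice)
        out = design.filter_clearance(cand, min_bp=60)
        # pos 59: left clearance 59 < 60 removed; splice exactly 60 bp: kept
        assert set(out["contig"]) == {"c2", "c3"}

    def test_missing_contig_length_raises(self):
        merged = pd.DataFrame([merged_row()])
        with pytest.raises(KeyError):
            design.build_candidates(
                merged, {}, pd.DataFrame(columns=["contig", "pos0"]),
                pd.DataFrame({"contig": ["c1"], "pos": [300],
                              "design_score": [0.9]}),
                pd.DataFrame({"contig": ["c1"], "model_chrom": [1],
                              "model_start": [0], "model_end": [10],
                              "strand": ["+"], "annotated": [1]}),
                CULT, WILD)

    def test_per_contig_keeps_highest_score(self):
        rows = [merged_row(pos=200, states={"cv1": "alt"}),
                merged_row(pos=700, alt="C", states={"cv2": "alt"})]
        scores = pd.DataFrame({"contig": ["c1", "c1"], "pos": [200, 700],
                               "design_score": [0.7, 0.9]})
        cand = build(rows, scores=scores)
        out = design.select_per_contig(cand)
        assert out["pos"].tolist() == [700]

    def test_per_contig_matches_sort_and_group_oracle(self, rng):
        rows, score_rows = [], []
        for i in range(500):
            contig = f"c{rng.integers(0, 60)}"
            pos = int(rng.integers(0, 1000))
            rows.append(merged_row(contig=contig, pos=pos,
                                   states={"cv1": "alt"}))
            score_rows.append({"contig": contig, "pos": pos,
                               "design_score": float(rng.random())})
        merged = pd.DataFrame(rows).drop_duplicates(["contig", "pos"])
        scores = pd.DataFrame(score_rows).drop_duplicates(["contig", "pos"])
        lengths = {c: 1200 for c in merged["contig"].unique()}
        cand = build(merged.to_dict("records"), lengths=lengths, scores=scores)
        out = design.select_per_contig(cand)
        # oracle: python max per group with the documented tie-break
        best = {}
        for r in cand.itertuples(index=False):
            key = r.contig
            cur = best.get(key)
            rank = (-r.design_score, r.pos, "ACGT".index(r.alt))
            if cur is None or rank < cur[0]:
                best[key] = (rank, r.snp_id)
        assert set(out["snp_id"]) == {v[1] for v in best.values()}

    def test_dedup_shared_gene_interval(self):
        rows = [merged_row(contig="c1", states={"cv1": "alt"}),
                merged_row(contig="c2", states={"cv1": "alt"}),
                merged_row(contig="c3", states={"cv1": "alt"})]
        ortho = pd.DataFrame({
            "contig": ["c1", "c2", "c3"],
            "model_chrom": [2, 2, 0], "model_start": [100, 100, -1],
            "model_end": [400, 400, -1], "strand": ["+", "+", "."],
            "annotated": [1, 1, 0]})
        scores = pd.DataFrame({"contig": ["c1", "c2", "c3"],
                               "pos": [300] * 3,
                               "design_score": [0.5, 0.8, 0.1]})
        cand = build(rows, scores=scores, ortho=ortho)
        out = design.dedup_positions(cand)
        # c2 wins the shared interval; unannotated c3 never collides
        assert set(out["contig"]) == {"c2", "c3"}

    def test_score_filter_boundaries(self):
        rows = [merged_row(contig=c, states={"cv1": "alt"})
                for c in ("c1", "c2", "c3")]
        scores = pd.DataFrame({"contig": ["c1", "c2", "c3"], "pos": [300] * 3,
                               "design_score": [0.39, 0.4, 0.65]})
        cand = build(rows, scores=scores)
        out = design.filter_score(cand)
        assert set(out["contig"]) == {"c2", "c3"}
        assert out.set_index("contig")["preferred"].to_dict() == {
            "c2": False, "c3": True}

    def test_score_filter_uniform_retention(self, rng):
        rows = [merged_row(contig=f"c{i}", states={"cv1": "alt"})
                for i in range(10_000)]
        scores = pd.DataFrame({"contig": [f"c{i}" for i in range(10_000)],
                               "pos": [300] * 10_000,
                               "design_score": rng.uniform(0, 1, 10_000)})
        cand = build(rows, lengths={f"c{i}": 1000 for i in range(10_000)},
                     scores=scores)
        frac = len(design.filter_score(cand)) / len(cand)
        se = np.sqrt(0.6 * 0.4 / 10_000)
        assert abs(frac - 0.6) < 3 * se


class TestPanelAssembly:
    def test_fill_order_prefers_fewer_missing(self):
        rows = [
            merged_row(contig="c1", states={"cv1": "alt", "cv2": "ref"}),
            merged_row(contig="c2",
                       states={a: "ref" for a in CULT} | {"w1": "alt"}),
            merged_row(contig="c3",
                       states={a: "ref" for a in CULT} | {"w2": "alt"}),
        ]
        rows[1]["w2"] = "missing"
        rows[2]["cv3"] = "missing"
        rows[2]["cv2"] = "missing"
        rows[2]["w1"] = "missing"
        cand = build(rows)
        cand = design.filter_score(cand)
        panel = design.assemble_panel(cand, panel_size=2, max_missing=4)
        # core = c1; one supplement slot: c2 (1 missing) beats c3 (3 missing)
        assert set(panel["contig"]) == {"c1", "c2"}
        assert panel.set_index("contig")["panel_set"].to_dict() == {
            "c1": "core", "c2": "supplement"}

    def test_shortfall_warns_and_returns_partial_panel(self):
        cand = build([merged_row(states={"cv1": "alt"})])
        cand = design.filter_score(cand)
        with pytest.warns(UserWarning, match="unattainable"):
            panel = design.assemble_panel(cand, panel_size=10)
        assert len(panel) == 1


@pytest.fixture(scope="module")
def study_candidates():
    out = []
    for seed in range(3):
        cfg = SimulationConfig(seed=100 + seed, n_contigs=40,
                               n_markers_per_lg=4, ril_pop_sizes=(30,))
        s = simulate_study(cfg)
        from peamap import snp
        obs = snp.call_accession_snps(s.pileups, s.contigs)
        merged = snp.merge_accessions(obs, cfg.accessions, s.ortho,
                                      pileups=s.pileups)
        cand = design.build_candidates(
            merged, {c: len(x) for c, x in s.contigs.items()}, s.splice,
            s.scores, s.ortho, cfg.cultivar_names, cfg.wild_names)
        out.append(cand)
    return out


class TestCascade:
    def test_conservation_nesting_idempotence(self, study_candidates):
        thr = ThresholdConfig(panel_size=30)
        for cand in study_candidates:
            with pytest.warns(UserWarning):
                panel, report = design.run_cascade(cand, thr)
            prev_out = None
            for st in report.stages:
                assert st.n_input - st.n_removed == st.n_output
                if prev_out is not None and st.name not in (
                        "cultivar_missing_filter", "wild_supplement_fill"):
                    assert st.n_input == prev_out
                prev_out = st.n_output
            # nesting: every stage output is a subset of the stage input
            df = cand
            for name, rule, fn in design._STAGES:
                out = fn(df, thr)
                assert set(out["snp_id"]) <= set(df["snp_id"])
                # idempotence per stage
                again = fn(out, thr)
                assert set(again["snp_id"]) == set(out["snp_id"])
                df = out
            # full second pass over the filter stages is a no-op
            df2 = df
            for name, rule, fn in design._STAGES:
                df2 = fn(df2, thr)
            assert set(df2["snp_id"]) == set(df["snp_id"])

    def test_clean_truth_only_survivorship_filters_remove(self, rng):
        """Sparse clean candidates: only per-contig/dedup survivorship acts."""
        rows, score_rows = [], []
        for i in range(40):
            c = f"c{i}"
            rows.append(merged_row(contig=c, pos=400,
                                   states={"cv1": "alt", "cv2": "ref"},
                                   annotated=False))
            score_rows.append({"contig": c, "pos": 400,
                               "design_score": 0.5 + 0.5 * rng.random()})
        ortho = pd.DataFrame({"contig": [f"c{i}" for i in range(40)],
                              "model_chrom": 0, "model_start": -1,
                              "model_end": -1, "strand": ".", "annotated": 0})
        cand = build(rows, scores=pd.DataFrame(score_rows), ortho=ortho)
        thr = ThresholdConfig(panel_size=40, max_missing=4)
        panel, report = design.run_cascade(cand, thr)
        for st in report.stages:
            if st.name not in ("per_contig", "dedup_positions",
                               "wild_supplement_fill"):
                assert st.n_removed == 0, st.name
        assert len(panel) == 40
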