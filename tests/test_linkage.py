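"""Marker QC, two-point linkage, Kosambi conversion, grouping and ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2 as chi2_dist

from peamap import linkage
from peamap.config import SimulationConfig
from peamap.simulate import simulate_ril_population


def geno_frame(rows, lines=None):
    markers = list(rows)
    n = len(next(iter(rows.values())))
    lines = lines or [f"L{i}" for i in range(n)]
    return pd.DataFrame({ln: [rows[m][j] for m in markers]
                         for j, ln in enumerate(lines)}, index=markers)


def parents_frame(markers, p1="A", p2="B"):
    return pd.DataFrame({"p1": p1, "p2": p2}, index=list(markers))


class TestKosambi:
    def test_round_trip_identity(self):
        r = np.linspace(0.0, 0.49, 200)
        back = linkage.kosambi_inverse(linkage.kosambi(r))
        assert np.max(np.abs(back - r)) < 1e-12

    def test_zero_and_monotone(self):
        assert linkage.kosambi(0.0) == 0.0
        d = linkage.kosambi(np.linspace(0.0, 0.49, 100))
        assert np.all(np.diff(d) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            linkage.kosambi(0.5)
        with pytest.raises(ValueError):
            linkage.kosambi_inverse(-1.0)


class TestClassify:
    def test_classes_partition(self):
        g = geno_frame({
            "poly": ["A", "B", "A", "B"],
            "mono": ["A", "A", "A", "A"],
            "fail": ["U", "U", "U", "U"],
            "dom": ["A", "A", "A", "U"],
        })
        parents = parents_frame(g.index)
        parents.loc["mono"] = ["A", "A"]
        parents.loc["fail"] = ["U", "U"]
        parents.loc["dom"] = ["A", "U"]
        qc = {q.marker: q for q in linkage.classify_markers(g, parents)}
        assert qc["poly"].marker_class == "polymorphic"
        assert qc["mono"].marker_class == "monomorphic"
        assert qc["fail"].marker_class == "failed"
        assert qc["dom"].marker_class == "dominant"

    def test_balanced_chi2_zero(self):
        calls = ["A"] * 45 + ["B"] * 45
        g = geno_frame({"m": calls})
        qc = linkage.classify_markers(g, parents_frame(["m"]))[0]
        assert qc.chi2 == 0.0
        assert qc.distortion_class == "balanced"

    def test_chi2_formula_and_filter(self):
        calls = ["A"] * 70 + ["B"] * 20
        g = geno_frame({"m": calls})
        qc = linkage.classify_markers(g, parents_frame(["m"]))[0]
        assert qc.chi2 == pytest.approx(2500 / 90)
        assert linkage.filter_for_linkage([qc]) == []

    def test_extreme_dropped_even_with_override(self):
        calls = ["A"] * 95 + ["B"] * 5
        g = geno_frame({"m": calls})
        qc = linkage.classify_markers(g, parents_frame(["m"]))[0]
        assert qc.distortion_class == "extreme"
        assert linkage.filter_for_linkage([qc], chi2_override=True) == []

    def test_override_waives_chi2_only(self):
        calls = ["A"] * 70 + ["B"] * 20  # freq 0.22: distorted, chi2 ~ 27.8
        g = geno_frame({"m": calls})
        qc = linkage.classify_markers(g, parents_frame(["m"]))[0]
        assert linkage.filter_for_linkage([qc], chi2_override=True) == ["m"]

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            linkage.classify_markers(pd.DataFrame(), pd.DataFrame())

    def test_chi2_retention_matches_distribution(self, rng):
        """Balanced 1:1 markers are retained at ~P(chi2_1 <= 5)."""
        n_markers, n_lines = 10_000, 90
        calls = np.where(rng.random((n_markers, n_lines)) < 0.5, "A", "B")
        g = pd.DataFrame(calls, index=[f"m{i}" for i in range(n_markers)],
                         columns=[f"L{i}" for i in range(n_lines)])
        qc = linkage.classify_markers(g, parents_frame(g.index))
        kept = linkage.filter_for_linkage(qc, chi2_max=5.0)
        p = chi2_dist.cdf(5.0, df=1)
        se = np.sqrt(p * (1 - p) / n_markers)
        assert abs(len(kept) / n_markers - p) < 3 * se


class TestTwoPoint:
    def test_perfect_linkage(self):
        calls = ["A"] * 20 + ["B"] * 20
        g = geno_frame({"m1": calls, "m2": calls})
        est = linkage.two_point(g, ("m1", "m2"))
        assert est.R_hat == 0.0 and est.r_hat == 0.0
        assert est.lod == pytest.approx(40 * np.log10(2))

    def test_het_and_missing_excluded_pairwise(self):
        g = geno_frame({"m1": ["A", "A", "H", "B"] * 10,
                        "m2": ["A", "U", "A", "B"] * 10})
        est = linkage.two_point(g, ("m1", "m2"))
        assert est.n_informative == 20

    def test_insufficient_lines_raise(self):
        g = geno_frame({"m1": ["A"] * 5, "m2": ["A"] * 5})
        with pytest.raises(ValueError):
            linkage.two_point(g, ("m1", "m2"))

    def test_r_hat_capped_at_half(self):
        g = geno_frame({"m1": ["A", "B"] * 20, "m2": ["B", "A"] * 20})
        est = linkage.two_point(g, ("m1", "m2"))
        assert est.r_hat == 0.5

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=40, max_value=200), st.data())
    def test_lod_decreases_with_R(self, n, data):
        k1 = data.draw(st.integers(min_value=1, max_value=n // 2 - 1))
        k2 = data.draw(st.integers(min_value=0, max_value=k1 - 1))
        assert linkage._lod(k2, n) > linkage._lod(k1, n)

    def test_all_pairs_table_matches_single_pairs(self, rng):
        calls = np.where(rng.random((6, 60)) < 0.5, "A", "B")
        calls[rng.random(calls.shape) < 0.05] = "H"
        calls[rng.random(calls.shape) < 0.05] = "U"
        g = pd.DataFrame(calls, index=[f"m{i}" for i in range(6)],
                         columns=[f"L{i}" for i in range(60)])
        tab = linkage.two_point_all(g, min_informative=20)
        for row in tab.itertuples(index=False):
            est = linkage.two_point(g, (row.marker_a, row.marker_b))
            assert est.n_informative == row.n
            assert est.n_recombinant == row.k
            assert est.lod == pytest.approx(row.lod)

    def test_parameter_recovery_r01(self, rng):
        """Mean |r_hat - 0.1| over replicates stays within 0.03."""
        cfg = SimulationConfig(seed=0, ril_het_rate=0, missing_rate=0,
                               failure_rate=0)
        gap = linkage.kosambi(0.1)
        tmap = pd.DataFrame({"group": ["LG1", "LG1"], "marker": ["m1", "m2"],
                             "cM": [0.0, gap]})
        errs = []
        for _ in range(300):
            obs, _ = simulate_ril_population(tmap, 150, cfg, rng)
            est = linkage.two_point(obs, ("m1", "m2"))
            errs.append(abs(est.r_hat - 0.1))
        assert np.mean(errs) <= 0.03


class TestGroupingOrdering:
    def make_genome(self, rng, n_groups=3, n_markers=12, n_lines=150,
                    length_cM=60.0):
        cfg = SimulationConfig(seed=0, ril_het_rate=0, missing_rate=0,
                               failure_rate=0)
        tmap = pd.DataFrame([
            {"group": f"LG{g + 1}", "marker": f"g{g + 1}m{i:02d}",
             "cM": i * length_cM / (n_markers - 1)}
            for g in range(n_groups) for i in range(n_markers)])
        obs, _ = simulate_ril_population(tmap, n_lines, cfg, rng)
        return tmap, obs

    def test_two_clusters_two_groups(self, rng):
        tmap, obs = self.make_genome(rng, n_groups=2)
        tab = linkage.two_point_all(obs)
        groups = linkage.group_markers(tab, lod_min=5.0)
        assert len([g for g in groups if len(g) > 1]) == 2

    def test_infinite_lod_threshold_isolates_markers(self, rng):
        _, obs = self.make_genome(rng, n_groups=1, n_markers=5)
        tab = linkage.two_point_all(obs)
        groups = linkage.group_markers(tab, lod_min=np.inf,
                                       markers=obs.index)
        assert all(len(g) == 1 for g in groups)

    def test_order_recovery_up_to_reversal(self, rng):
        tmap, obs = self.make_genome(rng, n_groups=1, n_markers=15,
                                     n_lines=200)
        tab = linkage.two_point_all(obs)
        ordered = linkage.order_group(obs.index.tolist(), tab)
        truth = tmap["marker"].tolist()
        got = ordered["marker"].tolist()
        assert got == truth or got == truth[::-1]
        assert (np.diff(ordered["cM"]) >= 0).all()

    def test_three_marker_additivity(self):
        tab = pd.DataFrame({
            "marker_a": ["m1", "m2", "m1"], "marker_b": ["m2", "m3", "m3"],
            "n": [100] * 3, "k": [5, 5, 10],
            "R_hat": [0.05, 0.05, 0.10],
            "r_hat": [0.026, 0.026, 0.056], "lod": [20.0, 20.0, 15.0]})
        ordered = linkage.order_group(["m1", "m2", "m3"], tab)
        assert ordered["marker"].tolist() in (["m1", "m2", "m3"],
                                              ["m3", "m2", "m1"])

    def test_zero_r_pair_zero_gap(self):
        tab = pd.DataFrame({"marker_a": ["m1"], "marker_b": ["m2"],
                            "n": [50], "k": [0], "R_hat": [0.0],
                            "r_hat": [0.0], "lod": [15.0]})
        ordered = linkage.order_group(["m1", "m2"], tab)
        assert ordered["cM"].tolist() == [0.0, 0.0]

    def test_map_length_grows_with_inserted_marker(self, rng):
        """On a consistent (noise-free) two-point table, Kosambi distances
        are additive, so inserting a marker between its flanks never
        shortens the group."""
        pos = {f"m{i}": float(p)
               for i, p in enumerate(np.sort(rng.uniform(0, 80, size=9)))}
        markers = list(pos)
        rows = []
        for i, a in enumerate(markers):
            for b in markers[i + 1:]:
                r = linkage.kosambi_inverse(abs(pos[a] - pos[b]))
                rows.append({"marker_a": a, "marker_b": b, "n": 1000,
                             "k": int(round(1000 * r)), "R_hat": r,
                             "r_hat": min(r, 0.4999), "lod": 50.0})
        tab = pd.DataFrame(rows)
        mid = markers[4]
        without = [m for m in markers if m != mid]
        len_without = linkage.order_group(without, tab)["cM"].iloc[-1]
        len_with = linkage.order_group(markers, tab)["cM"].iloc[-1]
        assert len_with >= len_without - 1e-9
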