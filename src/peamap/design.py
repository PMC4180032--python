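"""GoldenGate assay-panel selection cascade.

Candidates flow through the published filter order: flanking variation ->
heterozygosity -> 60 bp clearance (contig ends and splice sites) -> best
scoring SNP per contig -> orthologous-position de-duplication -> ADT-score
floor -> polymorphism/missing-data panel assembly (cultivar-polymorphic core
plus a wild-only supplement filled in order of least missing data). Every
stage records input, removed and output sets in a CascadeReport whose
accounting always reconciles.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}

__all__ = [
    "CascadeStage", "CascadeReport", "build_candidates",
    "filter_flanking_variation", "filter_heterozygous", "filter_clearance",
    "select_per_contig", "dedup_positions", "filter_score", "assemble_panel",
    "run_cascade",
]


@dataclass
class CascadeStage:
    name: str
    rule: str
    n_input: int
    n_removed: int
    n_output: int
    removed_ids: list[str]


@dataclass
class CascadeReport:
    stages: list[CascadeStage] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, name: str, rule: str, before: pd.DataFrame, after: pd.DataFrame):
        removed = sorted(set(before["snp_id"]) - set(after["snp_id"]))
        self.stages.append(CascadeStage(
            name=name, rule=rule, n_input=len(before),
            n_removed=len(removed), n_output=len(after), removed_ids=removed))

    def to_json(self, path=None) -> str:
        text = json.dumps({"stages": [asdict(s) for s in self.stages],
                           "warnings": self.warnings}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _snp_id(contig, pos) -> str:
    return f"{contig}:{int(pos)}"


def build_candidates(
    merged: pd.DataFrame,
    contig_lengths: dict[str, int],
    splice: pd.DataFrame,
    scores: pd.DataFrame,
    orthologue_table: pd.DataFrame,
    cultivars: list[str],
    wild: list[str],
) -> pd.DataFrame:
    """Annotate merged SNPs into assay candidates.

    Tri-allelic sites are dropped here (never eligible for design). Each
    candidate carries flanking distances (to the nearest other called SNP —
    tri-allelic ones included as neighbours — to both contig ends and to the
    nearest splice boundary), the ADT-surrogate ``design_score`` joined from
    ``scores``, a ``dup_key`` from the orthologue gene interval, the
    polymorphism class over the accession panel and missing/heterozygosity
    flags. Missing contig lengths raise.
    """
    missing_len = set(merged["contig"]) - set(contig_lengths)
    if missing_len:
        raise KeyError(f"no contig length for: {sorted(missing_len)[:5]}")
    cand = merged.loc[~merged["triallelic"].astype(bool)].copy()
    cand["snp_id"] = [_snp_id(c, p) for c, p in zip(cand["contig"], cand["pos"])]

    # nearest other called SNP (use the full merged table as neighbour set)
    nearest = np.full(len(cand), np.inf)
    all_sites = merged.groupby("contig")["pos"].apply(
        lambda s: np.sort(s.to_numpy()))
    for i, (c, p) in enumerate(zip(cand["contig"], cand["pos"])):
        sites = all_sites[c]
        others = sites[sites != p]
        if len(others):
            nearest[i] = np.abs(others - p).min()
    cand["nearest_snp_bp"] = nearest

    splice_by_contig = {c: np.sort(g["pos0"].to_numpy())
                        for c, g in splice.groupby("contig")} if len(splice) else {}
    left = cand["pos"].to_numpy(dtype=float)
    length = np.array([contig_lengths[c] for c in cand["contig"]], dtype=float)
    right = length - 1 - left
    sp_dist = np.full(len(cand), np.inf)
    for i, (c, p) in enumerate(zip(cand["contig"], cand["pos"])):
        sp = splice_by_contig.get(c)
        if sp is not None and len(sp):
            sp_dist[i] = np.abs(sp - p).min()
    cand["end_clearance_bp"] = np.minimum(left, right)
    cand["splice_clearance_bp"] = sp_dist
    cand["clearance_bp"] = np.minimum(cand["end_clearance_bp"],
                                      cand["splice_clearance_bp"])

    score_map = {(c, int(p)): s for c, p, s in
                 zip(scores["contig"], scores["pos"], scores["design_score"])}
    cand["design_score"] = [score_map.get((c, int(p)), np.nan)
                            for c, p in zip(cand["contig"], cand["pos"])]
    if cand["design_score"].isna().any():
        raise KeyError("design score missing for some candidates")

    ann = orthologue_table.set_index("contig")
    dup_keys = []
    for c in cand["contig"]:
        row = ann.loc[c]
        if int(row["annotated"]):
            dup_keys.append(f"{int(row['model_chrom'])}:"
                            f"{int(row['model_start'])}-{int(row['model_end'])}")
        else:
            dup_keys.append(None)
    cand["dup_key"] = dup_keys

    cult_states = cand[list(cultivars)].to_numpy(dtype="U16")
    wild_states = cand[list(wild)].to_numpy(dtype="U16") if wild else \
        np.empty((len(cand), 0), dtype="U16")
    all_states = cand[list(cultivars) + list(wild)].to_numpy(dtype="U16")
    cand["het_flagged"] = (all_states == "het_suspect").any(axis=1)
    cand["n_missing"] = (all_states == "missing").sum(axis=1)
    cult_alt = (cult_states == "alt").any(axis=1)
    cult_ref = (cult_states == "ref").any(axis=1)
    scored = np.isin(cult_states, ("ref", "alt"))
    uniform = np.array([
        len(set(row[s])) <= 1 for row, s in zip(cult_states, scored)])
    wild_alt = (wild_states == "alt").any(axis=1)
    poly = np.where(cult_alt & cult_ref, "cultivar_polymorphic",
                    np.where(uniform & wild_alt, "wild_only", "monomorphic"))
    cand["poly_class"] = poly
    return cand.reset_index(drop=True)


# --- individual stages ------------------------------------------------------

def filter_flanking_variation(candidates: pd.DataFrame,
                              window_bp: int = 60) -> pd.DataFrame:
    """Keep candidates with no other called SNP within ``window_bp`` either side."""
    return candidates.loc[candidates["nearest_snp_bp"] > window_bp]


def filter_heterozygous(candidates: pd.DataFrame) -> pd.DataFrame:
    """Drop candidates where any accession shows a mixed ref/alt read profile."""
    return candidates.loc[~candidates["het_flagged"]]


def filter_clearance(candidates: pd.DataFrame, min_bp: int = 60) -> pd.DataFrame:
    """Keep candidates >= ``min_bp`` from both contig ends and any splice site."""
    return candidates.loc[candidates["clearance_bp"] >= min_bp]


def select_per_contig(candidates: pd.DataFrame) -> pd.DataFrame:
    """Retain the highest-scoring candidate per contig.

    Deterministic tie-break: smaller position, then alternate-base order
    A<C<G<T.
    """
    key = candidates.assign(
        _alt_ord=[_BASE_ORDER[a] for a in candidates["alt"]])
    key = key.sort_values(["contig", "design_score", "pos", "_alt_ord"],
                          ascending=[True, False, True, True], kind="mergesort")
    best = key.drop_duplicates("contig", keep="first")
    return candidates.loc[candidates["snp_id"].isin(best["snp_id"])]


def dedup_positions(candidates: pd.DataFrame) -> pd.DataFrame:
    """Among candidates sharing an orthologous gene interval, keep the best score.

    Candidates without a ``dup_key`` (unannotated contigs) never collide.
    """
    keyed = candidates.loc[candidates["dup_key"].notna()]
    free = candidates.loc[candidates["dup_key"].isna()]
    if keyed.empty:
        return candidates
    key = keyed.assign(_alt_ord=[_BASE_ORDER[a] for a in keyed["alt"]])
    key = key.sort_values(["dup_key", "design_score", "pos", "_alt_ord"],
                          ascending=[True, False, True, True], kind="mergesort")
    best = key.drop_duplicates("dup_key", keep="first")
    keep = set(best["snp_id"]) | set(free["snp_id"])
    return candidates.loc[candidates["snp_id"].isin(keep)]


def filter_score(candidates: pd.DataFrame, min_score: float = 0.4,
                 preferred_score: float = 0.6) -> pd.DataFrame:
    """Keep design_score >= ``min_score``; flag >= ``preferred_score`` as preferred."""
    out = candidates.loc[candidates["design_score"] >= min_score].copy()
    out["preferred"] = out["design_score"] >= preferred_score
    return out


def assemble_panel(
    candidates: pd.DataFrame,
    panel_size: int = 1536,
    max_missing: int = 4,
    report: CascadeReport | None = None,
) -> pd.DataFrame:
    """Assemble the final panel: cultivar-polymorphic core + wild-only supplement.

    Core: cultivar-polymorphic candidates with at most ``max_missing``
    accessions lacking data. Supplement: wild-only candidates ranked by
    fewest missing genotypes then highest design score (missing counts from
    one up to ``max_missing``), filled until ``panel_size``. A shortfall
    emits a warning and a partial panel, never a silent truncation.
    """
    report = report if report is not None else CascadeReport()
    cult = candidates.loc[candidates["poly_class"] == "cultivar_polymorphic"]
    core = cult.loc[cult["n_missing"] <= max_missing]
    report.add("cultivar_missing_filter",
               f"cultivar-polymorphic SNPs with n_missing <= {max_missing}",
               cult, core)
    core = core.copy()
    core["panel_set"] = "core"

    n_needed = max(panel_size - len(core), 0)
    wild_only = candidates.loc[(candidates["poly_class"] == "wild_only")
                               & (candidates["n_missing"] <= max_missing)]
    ranked = wild_only.sort_values(
        ["n_missing", "design_score", "contig", "pos"],
        ascending=[True, False, True, True], kind="mergesort")
    supplement = ranked.head(n_needed).copy()
    supplement["panel_set"] = "supplement"
    report.add("wild_supplement_fill",
               "wild-only SNPs ranked by (n_missing asc, design_score desc) "
               f"filled to panel size {panel_size}", wild_only, supplement)
    panel = pd.concat([core, supplement], ignore_index=True)
    if len(panel) > panel_size:
        # core alone exceeds the array: trim lowest scores, loudly
        panel = panel.sort_values(["design_score", "contig", "pos"],
                                  ascending=[False, True, True],
                                  kind="mergesort").head(panel_size)
        msg = f"core set exceeds panel size; trimmed to {panel_size}"
        report.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    if len(panel) < panel_size:
        msg = (f"panel size {panel_size} unattainable: only {len(panel)} "
               "candidates available")
        report.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    return panel.reset_index(drop=True)


_STAGES = (
    ("flanking_variation", "no other called SNP within the flanking window",
     lambda df, thr: filter_flanking_variation(df, thr.flank_window_bp)),
    ("heterozygous", "drop SNPs with any mixed ref/alt accession profile",
     lambda df, thr: filter_heterozygous(df)),
    ("clearance", "min bp to contig end or splice site",
     lambda df, thr: filter_clearance(df, thr.min_clearance_bp)),
    ("per_contig", "highest design score per contig",
     lambda df, thr: select_per_contig(df)),
    ("dedup_positions", "highest score per orthologous gene interval",
     lambda df, thr: dedup_positions(df)),
    ("design_score", "design score floor",
     lambda df, thr: filter_score(df, thr.min_design_score,
                                  thr.preferred_design_score)),
)


def run_cascade(candidates: pd.DataFrame, thresholds,
                assemble: bool = True) -> tuple[pd.DataFrame, CascadeReport]:
    """Run the full selection cascade in the published stage order.

    ``thresholds`` is a :class:`peamap.config.ThresholdConfig`. Returns the
    final panel (or the filtered candidate set when ``assemble`` is False)
    and the stage-by-stage report.
    """
    report = CascadeReport()
    df = candidates
    for name, rule, fn in _STAGES:
        out = fn(df, thresholds)
        report.add(name, rule, df, out)
        df = out
    if assemble:
        df = assemble_panel(df, panel_size=thresholds.panel_size,
                            max_missing=thresholds.max_missing, report=report)
    return df, report
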