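"""RIL genotype QC, two-point linkage, grouping, ordering and map distances.

Genotype matrices are pandas DataFrames with markers as the index, RIL line
ids as columns and calls in {A, B, H, U}: the two parental homozygotes,
residual heterozygotes, and unknown/failed calls.

Two-point analysis on selfed RILs uses the standard correction from the
observed recombinant fraction R between inbred lines to the per-meiosis
fraction r, r = R / (2 (1 - R)), before Kosambi conversion to centimorgans.
Ordering within a linkage group is a deterministic greedy nearest-neighbour
chain refined by 2-opt, minimising the sum of adjacent recombination
fractions — a reproducible stand-in for interactive ML/regression ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

CALLS = ("A", "B", "H", "U")

__all__ = [
    "kosambi", "kosambi_inverse", "MarkerQC", "classify_markers",
    "filter_for_linkage", "TwoPointEstimate", "two_point", "two_point_all",
    "group_markers", "order_group", "build_map",
]


# ---------------------------------------------------------------------------
# map functions

def kosambi(r):
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in cM, for r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    out = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(out) if out.ndim == 0 else out


def kosambi_inverse(d):
    """Inverse Kosambi: r = tanh(d / 50) / 2 for a distance d >= 0 in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * np.tanh(d / 50.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# per-population marker QC

@dataclass
class MarkerQC:
    """Per-population QC record for one marker (GoldenGate-style classes)."""

    marker: str
    population: str
    marker_class: str  # polymorphic | monomorphic | dominant | failed
    n_a: int
    n_b: int
    chi2: float  # (nA-nB)^2/(nA+nB) against 1:1, homozygous calls only
    parental_allele_freq: float  # min(fA, fB); nan when no scored calls
    distortion_class: str  # balanced | distorted | extreme | unscored


def _distortion_class(freq: float, distorted_freq: float, extreme_freq: float) -> str:
    if np.isnan(freq):
        return "unscored"
    if freq < extreme_freq:
        return "extreme"
    if freq < distorted_freq:
        return "distorted"
    return "balanced"


def classify_markers(
    genotypes: pd.DataFrame,
    parents: pd.DataFrame,
    population: str = "pop",
    max_missing_rate: float = 0.9,
    distorted_freq: float = 0.3,
    extreme_freq: float = 0.1,
) -> list[MarkerQC]:
    """Classify every marker into exactly one QC class and score distortion.

    ``parents`` has the same marker index and columns ``p1``/``p2`` with the
    parental calls (A/B/U). Classes:

    * failed — missing-call rate above ``max_missing_rate`` or both parents U;
    * dominant — parents differ with one parent unscored, and only one
      homozygous allele is seen in the progeny;
    * monomorphic — parents carry the same scored allele and the progeny are
      uniform for it;
    * polymorphic — everything else.
    """
    if genotypes.empty:
        raise ValueError("empty genotype matrix")
    if not genotypes.index.equals(parents.index):
        parents = parents.reindex(genotypes.index)
    arr = genotypes.to_numpy(dtype="U1")
    out: list[MarkerQC] = []
    n_lines = arr.shape[1]
    for i, marker in enumerate(genotypes.index):
        calls = arr[i]
        n_a = int(np.sum(calls == "A"))
        n_b = int(np.sum(calls == "B"))
        n_u = int(np.sum(calls == "U"))
        p1, p2 = parents.iloc[i]["p1"], parents.iloc[i]["p2"]
        scored = n_a + n_b
        chi2 = (n_a - n_b) ** 2 / scored if scored else 0.0
        freq = min(n_a, n_b) / scored if scored else float("nan")
        if n_u / n_lines > max_missing_rate or (p1 == "U" and p2 == "U"):
            cls = "failed"
        elif (p1 == "U") != (p2 == "U") and (n_a == 0 or n_b == 0):
            cls = "dominant"
        elif p1 == p2 and (n_a == 0 or n_b == 0):
            cls = "monomorphic"
        else:
            cls = "polymorphic"
        out.append(MarkerQC(
            marker=str(marker), population=population, marker_class=cls,
            n_a=n_a, n_b=n_b, chi2=float(chi2), parental_allele_freq=freq,
            distortion_class=_distortion_class(freq, distorted_freq, extreme_freq),
        ))
    return out


def filter_for_linkage(
    qc: list[MarkerQC],
    chi2_max: float = 5.0,
    extreme_cut: float = 0.1,
    chi2_override: bool = False,
) -> list[str]:
    """Markers retained for linkage analysis.

    Drops non-polymorphic markers, markers with chi2 > ``chi2_max`` (waived
    when ``chi2_override`` is set for a highly distorted cross), and always
    drops extreme distortion (parental allele frequency < ``extreme_cut``),
    override or not.
    """
    keep = []
    for rec in qc:
        if rec.marker_class != "polymorphic":
            continue
        if np.isnan(rec.parental_allele_freq) or rec.parental_allele_freq < extreme_cut:
            continue
        if not chi2_override and rec.chi2 > chi2_max:
            continue
        keep.append(rec.marker)
    return keep


# ---------------------------------------------------------------------------
# two-point linkage

@dataclass
class TwoPointEstimate:
    marker_a: str
    marker_b: str
    n_informative: int
    n_recombinant: int
    R_hat: float  # observed RIL recombinant fraction k/n
    r_hat: float  # meiotic fraction R/(2(1-R)), capped at 0.5
    lod: float  # log10 likelihood ratio vs R = 0.5


def _lod(k: int, n: int) -> float:
    # 0*log(0) == 0 convention; LOD of the MLE R_hat=k/n against R=0.5
    if n == 0:
        return 0.0
    R = k / n
    ll = 0.0
    if k:
        ll += k * np.log10(R)
    if n - k:
        ll += (n - k) * np.log10(1.0 - R)
    return float(ll + n * np.log10(2.0))


def _r_from_R(R: float) -> float:
    if R >= 0.5:
        return 0.5
    return R / (2.0 * (1.0 - R))


def two_point(genotypes: pd.DataFrame, pair: tuple[str, str],
              min_informative: int = 20) -> TwoPointEstimate:
    """Two-point estimate for one marker pair.

    Lines are informative when both calls are homozygous (A or B);
    heterozygous and unknown calls are excluded pairwise.
    """
    a, b = pair
    ca = genotypes.loc[a].to_numpy(dtype="U1")
    cb = genotypes.loc[b].to_numpy(dtype="U1")
    ok = np.isin(ca, ("A", "B")) & np.isin(cb, ("A", "B"))
    n = int(ok.sum())
    if n < min_informative:
        raise ValueError(f"only {n} informative lines for pair {pair}")
    k = int(np.sum(ca[ok] != cb[ok]))
    R = k / n
    return TwoPointEstimate(str(a), str(b), n, k, R, _r_from_R(R), _lod(k, n))


def two_point_all(genotypes: pd.DataFrame, min_informative: int = 20) -> pd.DataFrame:
    """All-pairs two-point table, vectorised.

    Returns a DataFrame with columns marker_a, marker_b, n, k, R_hat, r_hat,
    lod for every unordered pair with at least ``min_informative`` doubly
    homozygous lines.
    """
    arr = genotypes.to_numpy(dtype="U1")
    valid = np.isin(arr, ("A", "B")).astype(np.int64)
    is_b = (arr == "B").astype(np.int64) * valid
    n_mat = valid @ valid.T
    # recombinants: one call A, the other B
    k_mat = is_b @ (valid - is_b).T + (valid - is_b) @ is_b.T
    markers = genotypes.index.to_numpy()
    iu = np.triu_indices(len(markers), k=1)
    n = n_mat[iu]
    k = k_mat[iu]
    keep = n >= min_informative
    n, k = n[keep], k[keep]
    ia, ib = iu[0][keep], iu[1][keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(n > 0, k / n, np.nan)
        r = np.where(R >= 0.5, 0.5, R / (2.0 * (1.0 - R)))
        term_k = np.where(k > 0, k * np.log10(np.where(R > 0, R, 1.0)), 0.0)
        term_nk = np.where(n - k > 0, (n - k) * np.log10(np.where(R < 1, 1.0 - R, 1.0)), 0.0)
        lod = term_k + term_nk + n * np.log10(2.0)
    return pd.DataFrame({
        "marker_a": markers[ia], "marker_b": markers[ib],
        "n": n, "k": k, "R_hat": R, "r_hat": r, "lod": lod,
    })


# ---------------------------------------------------------------------------
# grouping and ordering

def group_markers(two_point_table: pd.DataFrame, lod_min: float = 5.0,
                  markers=None) -> list[list[str]]:
    """Linkage groups = connected components of the lod >= lod_min graph.

    Edges additionally require r_hat < 0.5 (coupling evidence). Groups are
    numbered by decreasing size, ties broken by the lexically smallest
    member; singletons from ``markers`` (if given) are appended.
    """
    g = nx.Graph()
    if markers is not None:
        g.add_nodes_from(str(m) for m in markers)
    tab = two_point_table
    sel = (tab["lod"] >= lod_min) & (tab["r_hat"] < 0.5)
    for a, b in tab.loc[sel, ["marker_a", "marker_b"]].itertuples(index=False):
        g.add_edge(str(a), str(b))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def _distance_matrix(group: list[str], two_point_table: pd.DataFrame) -> np.ndarray:
    idx = {m: i for i, m in enumerate(group)}
    n = len(group)
    dist = np.full((n, n), 0.5)
    np.fill_diagonal(dist, 0.0)
    tab = two_point_table
    sel = tab["marker_a"].isin(idx) & tab["marker_b"].isin(idx)
    for a, b, r in tab.loc[sel, ["marker_a", "marker_b", "r_hat"]].itertuples(index=False):
        i, j = idx[str(a)], idx[str(b)]
        dist[i, j] = dist[j, i] = r
    return dist


def _chain_cost(order: np.ndarray, dist: np.ndarray) -> float:
    return float(dist[order[:-1], order[1:]].sum())


def order_group(group: list[str], two_point_table: pd.DataFrame) -> pd.DataFrame:
    """Order a linkage group and assign cumulative Kosambi cM positions.

    Greedy chain: seed with the closest pair (ties by marker id), repeatedly
    append the unplaced marker closest to either chain end. Refinement:
    deterministic 2-opt (segment reversals, first-improvement scan) until no
    reversal lowers the total adjacent r_hat. The returned orientation is
    canonicalised so the lexically smaller terminal marker comes first.
    """
    group = [str(m) for m in group]
    if len(group) == 1:
        return pd.DataFrame({"marker": group, "cM": [0.0]})
    dist = _distance_matrix(group, two_point_table)
    n = len(group)
    if n == 2:
        order = np.array([0, 1])
    else:
        iu = np.triu_indices(n, k=1)
        flat = dist[iu]
        best = np.lexsort((iu[1], iu[0], flat))[0]
        chain = [int(iu[0][best]), int(iu[1][best])]
        free = set(range(n)) - set(chain)
        while free:
            cand = sorted(free)
            d_head = dist[chain[0], cand]
            d_tail = dist[chain[-1], cand]
            ih, it = int(np.argmin(d_head)), int(np.argmin(d_tail))
            if d_head[ih] < d_tail[it]:
                chain.insert(0, cand[ih])
                free.remove(cand[ih])
            else:
                chain.append(cand[it])
                free.remove(cand[it])
        order = np.array(chain)
        # 2-opt: reverse internal segments while it shortens the chain
        improved = True
        while improved:
            improved = False
            cost = _chain_cost(order, dist)
            for i in range(n - 1):
                for j in range(i + 1, n):
                    cand = order.copy()
                    cand[i:j + 1] = cand[i:j + 1][::-1]
                    c = _chain_cost(cand, dist)
                    if c < cost - 1e-12:
                        order, cost = cand, c
                        improved = True
        if group[order[0]] > group[order[-1]]:
            order = order[::-1]
    r_adj = np.clip(dist[order[:-1], order[1:]], 0.0, 0.5 - 1e-12)
    cm = np.concatenate([[0.0], np.cumsum(kosambi(r_adj))])
    return pd.DataFrame({"marker": [group[i] for i in order], "cM": cm})


def build_map(genotypes: pd.DataFrame, lod_min: float = 5.0,
              min_informative: int = 20, min_group: int = 2) -> pd.DataFrame:
    """Full per-population map: two-point -> group -> order.

    Returns a tidy map DataFrame (group, marker, cM); groups smaller than
    ``min_group`` are dropped (unlinked singletons).
    """
    tab = two_point_all(genotypes, min_informative=min_informative)
    groups = group_markers(tab, lod_min=lod_min, markers=genotypes.index)
    parts = []
    gid = 0
    for grp in groups:
        if len(grp) < min_group:
            continue
        gid += 1
        ordered = order_group(grp, tab)
        ordered.insert(0, "group", f"LG{gid}")
        parts.append(ordered)
    if not parts:
        return pd.DataFrame(columns=["group", "marker", "cM"])
    return pd.concat(parts, ignore_index=True)
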