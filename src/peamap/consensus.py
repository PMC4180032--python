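"""Multi-population consensus map integration and recombination binning.

The reference frame is the population map that carries the anchor
(framework) markers. Every other map's groups are matched to reference
groups by shared markers (at least two required), oriented by the sign of
the rank correlation over shared markers, and projected into the reference
frame by piecewise-linear interpolation between shared markers
(extrapolation continues the terminal segment's slope). A marker mapped in
several populations takes the mean projected position. Final group
coordinates are shifted to start at zero and partitioned into fixed-width
recombination bins, bin = floor(position / width).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["build_consensus", "assign_bins"]


def _pick_reference(maps: dict[str, pd.DataFrame], anchors: list[str]) -> str:
    anchor_set = set(anchors)
    counts = {pop: len(anchor_set & set(m["marker"])) for pop, m in maps.items()}
    best = max(sorted(counts), key=lambda p: counts[p])
    if counts[best] == 0:
        raise ValueError("no population map carries any anchor marker")
    return best


def _project(sub: pd.DataFrame, ref_pos: dict[str, float]) -> pd.Series | None:
    """Project one non-reference group into the reference frame.

    Returns projected positions indexed by marker, or None when fewer than
    two shared markers exist.
    """
    shared = [m for m in sub["marker"] if m in ref_pos]
    if len(shared) < 2:
        return None
    x_all = sub.set_index("marker")["cM"]
    xs = x_all.loc[shared].to_numpy(dtype=float)
    ys = np.array([ref_pos[m] for m in shared], dtype=float)
    rho = stats.spearmanr(xs, ys).statistic if len(shared) > 2 else \
        np.sign((ys[-1] - ys[0]) * (xs[-1] - xs[0]) or 1.0)
    x = x_all.to_numpy(dtype=float)
    if np.isnan(rho):
        rho = 1.0
    if rho < 0:
        x = x.max() - x
        xs = x_all.loc[shared].to_numpy(dtype=float)
        xs = x_all.to_numpy(dtype=float).max() - xs
    order = np.argsort(xs, kind="mergesort")
    xs, ys = xs[order], ys[order]
    # collapse duplicate control-point abscissae
    xs_u, idx = np.unique(xs, return_index=True)
    ys_u = np.array([ys[xs == v].mean() for v in xs_u])
    if len(xs_u) < 2:
        return None
    proj = np.interp(x, xs_u, ys_u)
    # linear extrapolation with the terminal segment slopes
    lo_slope = (ys_u[1] - ys_u[0]) / (xs_u[1] - xs_u[0])
    hi_slope = (ys_u[-1] - ys_u[-2]) / (xs_u[-1] - xs_u[-2])
    below = x < xs_u[0]
    above = x > xs_u[-1]
    proj[below] = ys_u[0] + (x[below] - xs_u[0]) * lo_slope
    proj[above] = ys_u[-1] + (x[above] - xs_u[-1]) * hi_slope
    return pd.Series(proj, index=x_all.index)


def build_consensus(
    maps: dict[str, pd.DataFrame],
    anchors: list[str],
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Integrate per-population maps into one consensus map.

    ``maps`` holds tidy per-population maps (columns group, marker, cM).
    Returns ``(consensus, unplaced)``: a tidy consensus (group, marker, cM,
    populations) ordered within groups, plus the (population, group) pairs
    that could not be placed for lack of two shared markers.
    """
    if len(maps) < 2:
        raise ValueError("consensus integration needs at least two maps")
    ref_pop = _pick_reference(maps, anchors)
    ref_map = maps[ref_pop]
    ref_groups = {g: dict(zip(sub["marker"], sub["cM"]))
                  for g, sub in ref_map.groupby("group")}

    # projected positions per marker: list of (pop, position, ref_group)
    proj_records: list[tuple[str, str, str, float]] = []
    for g, sub in ref_map.groupby("group"):
        for m, cm in zip(sub["marker"], sub["cM"]):
            proj_records.append((ref_pop, g, m, float(cm)))

    unplaced: list[tuple[str, str]] = []
    for pop, pmap in maps.items():
        if pop == ref_pop:
            continue
        for g, sub in pmap.groupby("group"):
            markers = set(sub["marker"])
            match, best = None, 0
            for rg in sorted(ref_groups):
                n_shared = len(markers & set(ref_groups[rg]))
                if n_shared > best:
                    match, best = rg, n_shared
            if match is None or best < 2:
                unplaced.append((pop, str(g)))
                logger.info("group %s of %s left unplaced (<2 shared markers)",
                            g, pop)
                continue
            proj = _project(sub, ref_groups[match])
            if proj is None:
                unplaced.append((pop, str(g)))
                continue
            for m, p in proj.items():
                proj_records.append((pop, match, m, float(p)))

    df = pd.DataFrame(proj_records, columns=["population", "group", "marker", "cM"])
    agg = (df.groupby(["group", "marker"])
             .agg(cM=("cM", "mean"),
                  populations=("population", lambda s: ",".join(sorted(set(s)))))
             .reset_index())
    # rescale each group to start at 0, deterministic ordering
    parts = []
    for g, sub in agg.groupby("group"):
        sub = sub.sort_values(["cM", "marker"], kind="mergesort").copy()
        sub["cM"] = sub["cM"] - sub["cM"].min()
        parts.append(sub)
    out = pd.concat(parts, ignore_index=True)
    return out[["group", "marker", "cM", "populations"]], unplaced


def assign_bins(consensus: pd.DataFrame, bin_cM: float = 20.0) -> pd.DataFrame:
    """Assign each marker to a half-open recombination bin per group.

    bin = floor(position / bin_cM); bin boundaries are multiples of the bin
    width from the group origin.
    """
    out = consensus.copy()
    out["bin"] = np.floor(out["cM"].to_numpy(dtype=float) / bin_cM).astype(int)
    return out
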