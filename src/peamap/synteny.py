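"""Macrosynteny block detection between a genetic map and a model genome.

Markers on each linkage group are scanned left-to-right in map order; a
block extends while the next orthologue hit lands on the same model
chromosome with a position consistent with the block's running orientation.
Up to ``max_interlopers`` inconsistent markers per block are skipped when
the pattern resumes immediately after; otherwise the block is closed and a
new one started. Blocks smaller than ``min_block`` markers are discarded.
Orientation is the sign of the Spearman correlation between map order and
model positions within the block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["SyntenyBlock", "detect_blocks", "blocks_to_frame",
           "correspondence_table", "export_circos", "parse_circos",
           "transitive_correspondence"]


@dataclass
class SyntenyBlock:
    group: str
    cm_start: float
    cm_end: float
    model_chrom: int
    bp_start: int
    bp_end: int
    orientation: str  # same | inverted
    n_markers: int
    n_interlopers: int
    markers: list[str] = field(default_factory=list)


def _consistent(positions: list[int], nxt: int) -> bool:
    if len(positions) < 2:
        return True
    direction = np.sign(positions[-1] - positions[0])
    if direction == 0:
        return True
    step = np.sign(nxt - positions[-1])
    return step == 0 or step == direction


def _close(group, rows, interlopers, min_block, blocks):
    if len(rows) >= min_block:
        cms = [r[1] for r in rows]
        pos = [r[3] for r in rows]
        rho = stats.spearmanr(np.arange(len(rows)), pos).statistic \
            if len(set(pos)) > 1 else 1.0
        blocks.append(SyntenyBlock(
            group=group, cm_start=float(min(cms)), cm_end=float(max(cms)),
            model_chrom=int(rows[0][2]), bp_start=int(min(pos)),
            bp_end=int(max(pos)), orientation="inverted" if rho < 0 else "same",
            n_markers=len(rows), n_interlopers=interlopers,
            markers=[r[0] for r in rows]))


def detect_blocks(
    consensus_map: pd.DataFrame,
    orthologue_table: pd.DataFrame,
    marker_to_contig: dict[str, str] | None = None,
    min_block: int = 3,
    max_interlopers: int = 1,
) -> list[SyntenyBlock]:
    """Detect macrosyntenic blocks along each linkage group.

    ``consensus_map`` is a tidy map (group, marker, cM); orthologue hits are
    joined through ``marker_to_contig`` (identity by default) and restricted
    to annotated contigs. Groups without hits yield no blocks (logged).
    """
    ann = orthologue_table.loc[orthologue_table["annotated"].astype(bool)]
    hit = {c: (int(ch), (int(s) + int(e)) // 2) for c, ch, s, e in
           zip(ann["contig"], ann["model_chrom"], ann["model_start"],
               ann["model_end"])}
    blocks: list[SyntenyBlock] = []
    for group, sub in consensus_map.groupby("group", sort=True):
        sub = sub.sort_values(["cM", "marker"], kind="mergesort")
        hits = []
        for m, cm in zip(sub["marker"], sub["cM"]):
            contig = marker_to_contig.get(m, m) if marker_to_contig else m
            if contig in hit:
                ch, pos = hit[contig]
                hits.append((str(m), float(cm), ch, pos))
        if not hits:
            logger.info("group %s has no orthologue hits", group)
            continue
        rows: list[tuple] = []
        interlopers = 0
        i = 0
        while i < len(hits):
            h = hits[i]
            if not rows:
                rows = [h]
                interlopers = 0
                i += 1
                continue
            chrom = rows[0][2]
            pos_list = [r[3] for r in rows]
            ok = h[2] == chrom and _consistent(pos_list, h[3])
            if ok:
                rows.append(h)
                i += 1
                continue
            nxt = hits[i + 1] if i + 1 < len(hits) else None
            resumes = (nxt is not None and nxt[2] == chrom
                       and _consistent(pos_list, nxt[3]))
            if interlopers < max_interlopers and resumes:
                interlopers += 1
                i += 1
                continue
            _close(group, rows, interlopers, min_block, blocks)
            rows = [h]
            interlopers = 0
            i += 1
        _close(group, rows, interlopers, min_block, blocks)
    return blocks


def blocks_to_frame(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    cols = ["group", "cm_start", "cm_end", "model_chrom", "bp_start",
            "bp_end", "orientation", "n_markers", "n_interlopers"]
    return pd.DataFrame([{c: getattr(b, c) for c in cols} for b in blocks],
                        columns=cols)


def correspondence_table(blocks: list[SyntenyBlock],
                         min_share: float = 0.2) -> pd.DataFrame:
    """Group-to-chromosome correspondence summary.

    For each linkage group, model chromosomes carrying at least
    ``min_share`` of the group's block markers are listed, supporting
    multi-chromosome rows. Empty input yields an empty table.
    """
    if not blocks:
        return pd.DataFrame(columns=["group", "model_chrom", "n_markers", "share"])
    df = blocks_to_frame(blocks)
    rows = []
    for group, sub in df.groupby("group"):
        total = sub["n_markers"].sum()
        per_chrom = sub.groupby("model_chrom")["n_markers"].sum()
        for chrom, n in per_chrom.items():
            share = n / total
            if share >= min_share:
                rows.append({"group": group, "model_chrom": int(chrom),
                             "n_markers": int(n), "share": float(share)})
    out = pd.DataFrame(rows, columns=["group", "model_chrom", "n_markers", "share"])
    return out.sort_values(["group", "share"], ascending=[True, False],
                           kind="mergesort").reset_index(drop=True)


def export_circos(blocks: list[SyntenyBlock], path=None) -> list[str]:
    """Emit Circos-style link lines: map-side then model-side coordinates.

    Inverted blocks are written with the model coordinates end-before-start
    so the twist is visible in the ribbon. cM coordinates are scaled by 1e6
    to integer 'bp' as Circos expects integers.
    """
    lines = []
    for b in blocks:
        s1 = int(round(b.cm_start * 1_000_000))
        e1 = int(round(b.cm_end * 1_000_000))
        if b.orientation == "inverted":
            m_a, m_b = b.bp_end, b.bp_start
        else:
            m_a, m_b = b.bp_start, b.bp_end
        lines.append(f"ps{b.group} {s1} {e1} mt{b.model_chrom} {m_a} {m_b}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    return lines


def parse_circos(lines: list[str]) -> pd.DataFrame:
    """Parse lines written by :func:`export_circos` back into block fields."""
    rows = []
    for ln in lines:
        if not ln.strip():
            continue
        g, s1, e1, c, m_a, m_b = ln.split()
        m_a, m_b = int(m_a), int(m_b)
        rows.append({
            "group": g[2:], "cm_start": int(s1) / 1_000_000,
            "cm_end": int(e1) / 1_000_000, "model_chrom": int(c[2:]),
            "bp_start": min(m_a, m_b), "bp_end": max(m_a, m_b),
            "orientation": "inverted" if m_a > m_b else "same",
        })
    return pd.DataFrame(rows)


def transitive_correspondence(
    blocks_a: list[SyntenyBlock],
    blocks_b: list[SyntenyBlock],
) -> pd.DataFrame:
    """Infer shared synteny between two mapped species via the model genome.

    Joins both species' blocks on the model chromosome and intersects their
    model bp intervals; each overlap row links a group of species A to a
    group of species B.
    """
    rows = []
    for a in blocks_a:
        for b in blocks_b:
            if a.model_chrom != b.model_chrom:
                continue
            lo = max(a.bp_start, b.bp_start)
            hi = min(a.bp_end, b.bp_end)
            if lo < hi:
                rows.append({
                    "group_a": a.group, "group_b": b.group,
                    "model_chrom": a.model_chrom,
                    "overlap_start": lo, "overlap_end": hi,
                    "overlap_bp": hi - lo,
                })
    return pd.DataFrame(rows, columns=["group_a", "group_b", "model_chrom",
                                       "overlap_start", "overlap_end",
                                       "overlap_bp"])
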