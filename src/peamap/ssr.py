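"""Perfect microsatellite (SSR) detection and polymorphism assessment.

Detects maximal perfect tandem repeats of primitive 2-6 bp units with a
configurable minimum copy number (default 5), reports non-overlapping loci
(longest total length first, then smallest unit, then leftmost), and flags
loci as polymorphic when independent per-accession copy estimates disagree.
Homopolymer runs are excluded: the unit floor is 2 bp and non-primitive
units (powers of a shorter unit) are rejected. Ns never contribute to a
reported locus because a unit containing N is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = ["SSRLocus", "canonical_motif", "find_ssrs", "find_ssrs_all",
           "assess_ssr_polymorphism"]


@dataclass
class SSRLocus:
    contig: str
    start: int  # 0-based half-open
    end: int
    unit: str  # observed leading repeat unit
    motif: str  # canonical unit (min over rotations and their revcomps)
    copies: int


def canonical_motif(unit: str) -> str:
    """Lexicographically least rotation of the unit or its reverse complement."""
    rc = unit.translate(_COMPLEMENT)[::-1]
    rots = [unit[i:] + unit[:i] for i in range(len(unit))]
    rots += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rots)


def _is_primitive(unit: str) -> bool:
    # a string is primitive iff it is not a rotation of itself at a shorter
    # period: unit not contained in (unit+unit) minus its endpoints
    return unit not in (unit + unit)[1:-1]


def _candidates(seq: str, min_unit: int, max_unit: int, min_copies: int):
    """All left-maximal perfect integer-copy runs, one per (unit size, phase)."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out = []
    for u in range(min_unit, max_unit + 1):
        if n < 2 * u:
            continue
        eq = (arr[:-u] == arr[u:]).astype(np.int64)
        cs = np.concatenate([[0], np.cumsum(eq)])
        match = (cs[u:] - cs[:-u]) == u  # match[i]: seq[i:i+u] == seq[i+u:i+2u]
        m_len = len(match)
        for phase in range(u):
            idx = np.arange(phase, m_len, u)
            if not len(idx):
                continue
            m = match[idx]
            # run-length encode the True stretches
            padded = np.concatenate([[False], m, [False]])
            d = np.diff(padded.astype(np.int8))
            starts = np.nonzero(d == 1)[0]
            ends = np.nonzero(d == -1)[0]
            for s, e in zip(starts, ends):
                copies = int(e - s) + 1
                if copies < min_copies:
                    continue
                start = int(idx[s])
                unit = seq[start:start + u]
                if "N" in unit or not _is_primitive(unit):
                    continue
                out.append((start, start + copies * u, unit, copies))
    return out


def find_ssrs(
    contig_seq: str,
    min_unit: int = 2,
    max_unit: int = 6,
    min_copies: int = 5,
    contig: str = "contig",
) -> list[SSRLocus]:
    """Detect non-overlapping perfect SSR loci in one sequence.

    Overlapping candidate runs are resolved greedily: longer total length
    first, then smaller unit, then leftmost start.
    """
    cands = _candidates(contig_seq.upper(), min_unit, max_unit, min_copies)
    cands.sort(key=lambda c: (-(c[1] - c[0]), len(c[2]), c[0]))
    occupied = np.zeros(len(contig_seq), dtype=bool)
    loci = []
    for start, end, unit, copies in cands:
        if occupied[start:end].any():
            continue
        occupied[start:end] = True
        loci.append(SSRLocus(contig=contig, start=start, end=end, unit=unit,
                             motif=canonical_motif(unit), copies=copies))
    loci.sort(key=lambda l: l.start)
    return loci


def find_ssrs_all(contigs: dict[str, str], **kwargs) -> pd.DataFrame:
    """SSR scan over a contig dict; returns a tidy locus table."""
    rows = []
    for cid, seq in contigs.items():
        for loc in find_ssrs(seq, contig=cid, **kwargs):
            rows.append({"contig": loc.contig, "start": loc.start,
                         "end": loc.end, "unit": loc.unit, "motif": loc.motif,
                         "copies": loc.copies})
    return pd.DataFrame(rows, columns=["contig", "start", "end", "unit",
                                       "motif", "copies"])


def assess_ssr_polymorphism(
    loci: pd.DataFrame,
    evidence: pd.DataFrame,
) -> pd.DataFrame:
    """Flag loci with putative copy-number polymorphism across accessions.

    ``evidence`` columns: contig, accession, copies (per-accession copy
    estimate; absent/NaN rows mean no data). A locus is polymorphic when at
    least two accessions with data disagree; with fewer than two informative
    accessions the flag is left missing (pd.NA), never False.
    """
    out = loci.copy()
    flags = []
    ev = evidence.dropna(subset=["copies"])
    by_contig = dict(tuple(ev.groupby("contig"))) if len(ev) else {}
    for row in out.itertuples(index=False):
        sub = by_contig.get(row.contig)
        if sub is None or len(sub) < 2:
            flags.append(pd.NA)
            continue
        vals = sub["copies"].astype(int)
        flags.append(bool(vals.nunique() > 1))
    out["polymorphic"] = pd.array(flags, dtype="boolean")
    return out
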