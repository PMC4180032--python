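"""Independent brute-force oracles used by the test suite.

Each function re-derives a result with the most literal possible algorithm
(plain loops, regex, exhaustive enumeration), sharing no code with the
implementation it checks.
"""

import re

import numpy as np

BASES = "ACGT"


def brute_force_call(pileup_df, reference, min_reads=3, min_concordance=0.8):
    """Literal re-scan of a pileup table: returns a set of observation tuples
    (accession, contig, pos, ref, alt, confidence, het_suspect)."""
    out = set()
    for row in pileup_df.itertuples(index=False):
        ref = reference[row.contig][row.pos0]
        if ref not in BASES:
            continue
        counts = {"A": row.countA, "C": row.countC, "G": row.countG,
                  "T": row.countT}
        nonref = {b: c for b, c in counts.items() if b != ref}
        best = max(nonref.values())
        if best < 1:
            continue
        alt = min(b for b, c in nonref.items() if c == best)
        total = sum(counts.values())
        conf = "high" if total >= min_reads and best / total >= min_concordance \
            else "low"
        het = best > 0 and counts[ref] > 0
        out.add((row.accession, row.contig, int(row.pos0), ref, alt, conf, het))
    return out


def brute_force_flank_keep(positions_by_contig, window):
    """Keep set of (contig, pos) with no other site within ``window`` bp."""
    keep = set()
    for contig, positions in positions_by_contig.items():
        for p in positions:
            if all(abs(p - q) > window for q in positions if q != p):
                keep.add((contig, int(p)))
    return keep


def regex_ssr_candidates(seq, min_unit=2, max_unit=6, min_copies=5):
    """All left-maximal perfect integer-copy repeat runs via regex."""
    cands = []
    for u in range(min_unit, max_unit + 1):
        for m in re.finditer(rf"(?=((.{{{u}}})\2{{{min_copies - 1},}}))", seq):
            start = m.start()
            unit = m.group(2)
            run = m.group(1)
            copies = len(run) // u
            # left-maximal only: previous u bases must differ
            if start >= u and seq[start - u:start] == unit:
                continue
            if "N" in unit:
                continue
            if unit in (unit + unit)[1:-1]:  # non-primitive
                continue
            cands.append((start, start + copies * u, unit, copies))
    return cands


def select_nonoverlapping(cands, seq_len):
    """Same published resolution rule, applied to oracle candidates."""
    cands = sorted(cands, key=lambda c: (-(c[1] - c[0]), len(c[2]), c[0]))
    taken = np.zeros(seq_len, dtype=bool)
    out = []
    for s, e, unit, copies in cands:
        if taken[s:e].any():
            continue
        taken[s:e] = True
        out.append((s, e, unit, copies))
    return sorted(out)
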