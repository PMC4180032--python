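"""SNP calling from per-accession pileups and cross-accession merging.

The caller applies count-threshold rules, not genotype likelihoods: a site
is reported for an accession when at least one non-reference read is seen;
the call is *high* confidence when the site has at least ``min_reads``
aligned reads and at least ``min_concordance`` of them carry the called
allele, and *low* otherwise. Only substitutions are considered; indel
evidence in the input dialect is parsed and discarded.

Merging produces one non-redundant record per (contig, position) with a
per-accession state in {ref, alt, het_suspect, missing, below_threshold}.
Sites whose accessions disagree on the alternate base are flagged
tri-allelic and excluded from assay design downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_COUNT_COLS = ["countA", "countC", "countG", "countT"]
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

OBSERVATION_COLUMNS = [
    "accession", "contig", "pos", "ref", "alt", "alt_reads", "total_reads",
    "concordance", "confidence", "het_suspect", "subst_class",
]

__all__ = [
    "classify_substitution", "call_accession_snps", "merge_accessions",
    "snp_summary_stats", "OBSERVATION_COLUMNS",
]


def classify_substitution(ref: str, alt: str) -> str:
    """'transition' for A<->G / C<->T, 'transversion' for the other pairs."""
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"alleles must be ACGT, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    return "transition" if (ref, alt) in _TRANSITIONS else "transversion"


def call_accession_snps(
    pileup: pd.DataFrame,
    reference: dict[str, str],
    min_reads: int = 3,
    min_concordance: float = 0.80,
) -> pd.DataFrame:
    """Call per-accession SNP observations from a pileup table.

    ``pileup`` columns: accession, contig, pos0, countA..countT, depth.
    Rows with a truthy ``is_indel`` column (if present) are discarded.
    The alternate allele at a site is the modal non-reference base, ties
    broken in base order A<C<G<T. Unknown contigs raise; non-ACGT reference
    bases are skipped with a warning.

    Returns one row per (accession, site) with at least one non-reference
    read, with columns ``OBSERVATION_COLUMNS``.
    """
    if "is_indel" in pileup.columns:
        pileup = pileup.loc[~pileup["is_indel"].astype(bool)]
    unknown = set(pileup["contig"].unique()) - set(reference)
    if unknown:
        raise KeyError(f"pileup refers to unknown contigs: {sorted(unknown)[:5]}")

    ref_base = np.empty(len(pileup), dtype="U1")
    pos = pileup["pos0"].to_numpy()
    for cid, idx in pileup.groupby("contig", sort=False).indices.items():
        seq = reference[cid]
        p = pos[idx]
        if np.any(p >= len(seq)) or np.any(p < 0):
            raise IndexError(f"pileup position outside contig {cid}")
        ref_base[idx] = [seq[i] for i in p]

    valid_ref = np.isin(ref_base, BASES)
    if not valid_ref.all():
        n_bad = int((~valid_ref).sum())
        logger.warning("skipping %d pileup rows with non-ACGT reference base", n_bad)

    counts = pileup[_COUNT_COLS].to_numpy(dtype=np.int64)
    total = counts.sum(axis=1)
    base_idx = {b: i for i, b in enumerate(BASES)}
    ref_i = np.array([base_idx.get(b, -1) for b in ref_base])
    nonref = counts.copy()
    rows = np.arange(len(pileup))
    ok = valid_ref
    nonref[rows[ok], ref_i[ok]] = -1  # mask the reference column
    alt_i = nonref.argmax(axis=1)  # first max -> A<C<G<T tie-break
    alt_reads = counts[rows, alt_i]
    ref_reads = np.where(ok, counts[rows, np.where(ref_i >= 0, ref_i, 0)], 0)

    emit = ok & (alt_reads >= 1)
    sub = pileup.loc[emit]
    alt_reads_e = alt_reads[emit]
    total_e = total[emit]
    conc = alt_reads_e / total_e
    confident = (total_e >= min_reads) & (conc >= min_concordance)
    alts = np.array(BASES)[alt_i[emit]]
    refs = ref_base[emit]
    return pd.DataFrame({
        "accession": sub["accession"].to_numpy(),
        "contig": sub["contig"].to_numpy(),
        "pos": sub["pos0"].to_numpy(),
        "ref": refs,
        "alt": alts,
        "alt_reads": alt_reads_e,
        "total_reads": total_e,
        "concordance": conc,
        "confidence": np.where(confident, "high", "low"),
        "het_suspect": (alt_reads_e > 0) & (ref_reads[emit] > 0),
        "subst_class": [classify_substitution(r, a) for r, a in zip(refs, alts)],
    })


def _site_coverage(pileups: pd.DataFrame | None, sites: set[tuple]):
    """Set of (accession, contig, pos) with depth >= 1 at ``sites``, or None."""
    if pileups is None:
        return None
    key = list(zip(pileups["contig"], pileups["pos0"]))
    at_sites = pd.Series([k in sites for k in key], index=pileups.index) \
        if len(sites) < 10_000 else pd.Series(True, index=pileups.index)
    cov = pileups.loc[at_sites & (pileups["depth"] >= 1),
                      ["accession", "contig", "pos0"]]
    return set(zip(cov["accession"], cov["contig"], cov["pos0"]))


def merge_accessions(
    observations: pd.DataFrame,
    accession_panel: list[str],
    orthologue_table: pd.DataFrame | None = None,
    pileups: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge per-accession observations into a non-redundant SNP table.

    One row per (contig, pos) with at least one accession in state ``alt``
    (a high-confidence, non-heterozygous call). Per-accession state columns:

    * ``alt`` — high-confidence call of the site's alternate allele;
    * ``het_suspect`` — reads neither 100 % ref nor 100 % alt;
    * ``below_threshold`` — observation failing the depth/concordance rule;
    * ``ref`` — covered (needs ``pileups``) with no non-reference reads;
    * ``missing`` — no read data at the site.

    Sites where accessions report different alternate bases are kept but
    flagged ``triallelic`` (excluded from design downstream). Conflicting
    reference alleles raise (corrupt input). ``maf`` is the minor allele
    frequency over accessions in state ref/alt.
    """
    if observations.empty:
        raise ValueError("no observations to merge")
    # only sites with at least one confident, non-heterozygous call can yield
    # a merged record; restrict the scan to those up front
    support = observations.loc[
        (observations["confidence"] == "high") & ~observations["het_suspect"]]
    site_keys = set(zip(support["contig"], support["pos"]))
    obs_key = pd.Series(list(zip(observations["contig"], observations["pos"])),
                        index=observations.index)
    observations = observations.loc[obs_key.isin(site_keys)]
    if observations.empty:
        return pd.DataFrame(columns=[
            "contig", "pos", "ref", "alt", "triallelic", "annotated",
            "n_accessions_with_data", "maf", "subst_class"] + list(accession_panel))
    coverage = _site_coverage(pileups, site_keys)
    annot = {}
    if orthologue_table is not None:
        annot = dict(zip(orthologue_table["contig"],
                         orthologue_table["annotated"].astype(bool)))
    rows = []
    for (contig, pos), grp in observations.groupby(["contig", "pos"], sort=True):
        refs = grp["ref"].unique()
        if len(refs) > 1:
            raise ValueError(
                f"conflicting reference alleles at {contig}:{pos}: {sorted(refs)}")
        ref = refs[0]
        high = grp.loc[grp["confidence"] == "high"]
        alt_alleles = sorted(high["alt"].unique()) or sorted(grp["alt"].unique())
        triallelic = len(alt_alleles) > 1
        # site alt = best-supported allele among confident calls
        alt = (high if len(high) else grp).groupby("alt")["alt_reads"].sum().idxmax()
        states = {}
        for acc in accession_panel:
            sub = grp.loc[grp["accession"] == acc]
            if len(sub):
                ob = sub.iloc[0]
                if ob["het_suspect"]:
                    states[acc] = "het_suspect"
                elif ob["confidence"] == "high" and ob["alt"] == alt:
                    states[acc] = "alt"
                else:
                    states[acc] = "below_threshold"
            elif coverage is None or (acc, contig, pos) in coverage:
                states[acc] = "ref"
            else:
                states[acc] = "missing"
        if not any(v == "alt" for v in states.values()):
            continue  # no confident support anywhere: below thresholds only
        n_alt = sum(v == "alt" for v in states.values())
        n_ref = sum(v == "ref" for v in states.values())
        scored = n_alt + n_ref
        maf = min(n_alt, n_ref) / scored if scored else float("nan")
        row = {
            "contig": contig, "pos": pos, "ref": ref, "alt": alt,
            "triallelic": triallelic,
            "annotated": annot.get(contig, False),
            "n_accessions_with_data": sum(v != "missing" for v in states.values()),
            "maf": maf,
            "subst_class": classify_substitution(ref, alt),
        }
        row.update(states)
        rows.append(row)
    cols = ["contig", "pos", "ref", "alt", "triallelic", "annotated",
            "n_accessions_with_data", "maf", "subst_class"] + list(accession_panel)
    return pd.DataFrame(rows, columns=cols)


def snp_summary_stats(
    merged: pd.DataFrame,
    reference: dict[str, str],
    subsets: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-subset SNP summary: count, assayable bp, bp per SNP, MAF, Ts/Tv.

    A SNP belongs to a subset when at least one subset accession is in state
    ``alt``. ``bp_per_snp`` is inf when the subset has no SNPs. ``mean_maf``
    is the panel-wide MAF averaged over the subset's sites.
    """
    if not reference:
        raise ValueError("empty reference")
    total_bp = sum(len(s) for s in reference.values())
    out = []
    for name, accs in subsets.items():
        accs = [a for a in accs if a in merged.columns]
        in_subset = (merged[accs] == "alt").any(axis=1) if accs else \
            pd.Series(False, index=merged.index)
        sub = merged.loc[in_subset]
        n = len(sub)
        ts = int((sub["subst_class"] == "transition").sum())
        tv = n - ts
        out.append({
            "subset": name,
            "n_snps": n,
            "total_bp": total_bp,
            "bp_per_snp": total_bp / n if n else float("inf"),
            "mean_maf": float(sub["maf"].mean()) if n else float("nan"),
            "ts": ts, "tv": tv,
            "ts_tv_ratio": ts / tv if tv else float("inf"),
        })
    return pd.DataFrame(out).set_index("subset")
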