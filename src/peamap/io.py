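"""Readers and writers for the pipeline's file formats.

Plain tab/comma-separated tables go through pandas; FASTA through
Biopython; the merged SNP table is additionally exported as VCF through
pysam (one ALT per record, per-accession GT/DP/AD, tri-allelic sites
flagged in FILTER).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_fasta", "read_fasta", "write_table", "read_table",
    "write_genotypes", "read_genotypes", "write_truth_json", "write_vcf",
]


def write_fasta(contigs: dict[str, str], path) -> None:
    records = (SeqRecord(Seq(seq), id=cid, description="")
               for cid, seq in contigs.items())
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    """Marker x line call matrix (A/B/H/U), markers as the index column."""
    genotypes.to_csv(path, index_label="marker")


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="marker", dtype=str)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_truth_json(truth, path) -> None:
    """Compact truth record: variant sites, marker map, layout, anchors."""
    payload = {
        "variant_sites": truth.variant_sites,
        "marker_map": truth.marker_map,
        "synteny_layout": truth.synteny_layout,
        "distorted_markers": truth.distorted_markers,
        "anchors": truth.anchors,
        "pop_markers": truth.pop_markers,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, default=_jsonable)


_STATE_TO_GT = {
    "ref": (0, 0), "alt": (1, 1), "het_suspect": (0, 1),
    "missing": (None, None), "below_threshold": (None, None),
}


def write_vcf(
    merged: pd.DataFrame,
    reference: dict[str, str],
    accessions: list[str],
    path,
    pileups: pd.DataFrame | None = None,
) -> None:
    """Write the merged SNP table as an uncompressed VCF.

    Per-accession genotypes encode the merged state (ref, alt, suspected
    heterozygote; missing and below-threshold states are ./. with the state
    in the ST field). DP/AD are filled from ``pileups`` when provided.
    Tri-allelic sites carry the TRIALLELIC filter.
    """
    header = pysam.VariantHeader()
    for cid, seq in reference.items():
        header.contigs.add(cid, length=len(seq))
    header.filters.add("TRIALLELIC", None, None,
                       "accessions disagree on the alternate base")
    header.info.add("MAF", 1, "Float", "minor allele frequency over scored accessions")
    header.info.add("ANN", 0, "Flag", "contig has a model-genome orthologue")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("ST", 1, "String", "Merged per-accession state")
    for acc in accessions:
        header.add_sample(acc)

    depth_lookup = {}
    if pileups is not None:
        sites = set(zip(merged["contig"], merged["pos"]))
        key = list(zip(pileups["contig"], pileups["pos0"]))
        mask = [k in sites for k in key]
        for row in pileups.loc[mask].itertuples(index=False):
            depth_lookup[(row.accession, row.contig, row.pos0)] = row

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in merged.sort_values(["contig", "pos"]).itertuples(index=False):
            rec = vcf.new_record(
                contig=row.contig, start=int(row.pos),
                stop=int(row.pos) + 1, alleles=(row.ref, row.alt))
            rec.info["MAF"] = float(row.maf)
            if bool(row.annotated):
                rec.info["ANN"] = True
            if bool(row.triallelic):
                rec.filter.add("TRIALLELIC")
            else:
                rec.filter.add("PASS")
            for acc in accessions:
                state = getattr(row, acc)
                rec.samples[acc]["GT"] = _STATE_TO_GT.get(state, (None, None))
                rec.samples[acc]["ST"] = state
                pr = depth_lookup.get((acc, row.contig, row.pos))
                if pr is not None:
                    rec.samples[acc]["DP"] = int(pr.depth)
                    ref_n = int(getattr(pr, f"count{row.ref}"))
                    alt_n = int(getattr(pr, f"count{row.alt}"))
                    rec.samples[acc]["AD"] = (ref_n, alt_n)
            vcf.write(rec)
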