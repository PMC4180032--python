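"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages run in a fixed order (simulate -> discover -> design -> ssr ->
qcmap -> consensus -> synteny); any stage failure aborts the run naming the
failing stage. The manifest records the config hash, seed, per-stage output
checksums and timings; re-running with the same config and seed reproduces
every checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from . import design, io, linkage, snp, ssr, synteny as syn
from .config import PipelineConfig, load_config
from .consensus import assign_bins, build_consensus
from .simulate import simulate_study

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    text = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()


def run_pipeline(config: PipelineConfig | str | Path, out_dir) -> dict:
    """Run every stage, write all products under ``out_dir``, return the manifest."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    sim = config.simulation
    manifest = {
        "tool": "peamap", "version": __version__,
        "seed": sim.seed, "config_hash": _config_hash(config),
        "stages": {},
    }
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            files = fn() or []
        except Exception as exc:
            logger.error("stage %s failed", name)
            raise StageError(name, exc) from exc
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {Path(f).name: _sha256(Path(f)) for f in files},
        }
        logger.info("stage %s done (%.2fs)", name,
                    manifest["stages"][name]["seconds"])

    def _simulate():
        study = simulate_study(sim)
        state["study"] = study
        files = []
        p = out / "contigs.fasta"
        io.write_fasta(study.contigs, p); files.append(p)
        for name, df in (("pileups.tsv", study.pileups),
                         ("ortho.tsv", study.ortho),
                         ("splice.tsv", study.splice),
                         ("scores.tsv", study.scores),
                         ("ssr_evidence.tsv", study.ssr_evidence)):
            p = out / name
            io.write_table(df, p); files.append(p)
        for pop, g in study.genotypes.items():
            p = out / f"genotypes_{pop}.csv"
            io.write_genotypes(g, p); files.append(p)
            p2 = out / f"parents_{pop}.csv"
            study.parents[pop].to_csv(p2, index_label="marker"); files.append(p2)
        p = out / "anchors.txt"
        p.write_text("\n".join(study.truth.anchors) + "\n"); files.append(p)
        p = out / "truth.json"
        io.write_truth_json(study.truth, p); files.append(p)
        return files

    def _discover():
        study = state["study"]
        obs = snp.call_accession_snps(
            study.pileups, study.contigs,
            min_reads=thr.min_reads, min_concordance=thr.min_concordance)
        merged = snp.merge_accessions(obs, sim.accessions, study.ortho,
                                      pileups=study.pileups)
        state["merged"] = merged
        summary = snp.snp_summary_stats(
            merged, study.contigs,
            {"all": sim.accessions, "cultivars": sim.cultivar_names})
        files = []
        p = out / "snp_table.tsv"
        io.write_table(merged, p); files.append(p)
        p = out / "snp_summary.tsv"
        summary.reset_index().to_csv(p, sep="\t", index=False); files.append(p)
        p = out / "snps.vcf"
        io.write_vcf(merged, study.contigs, sim.accessions, p,
                     pileups=study.pileups)
        files.append(p)
        return files

    def _design():
        study = state["study"]
        lengths = {c: len(s) for c, s in study.contigs.items()}
        cand = design.build_candidates(
            state["merged"], lengths, study.splice, study.scores, study.ortho,
            sim.cultivar_names, sim.wild_names)
        panel, report = design.run_cascade(cand, thr)
        state["panel"] = panel
        files = []
        p = out / "panel.tsv"
        cols = ["snp_id", "contig", "pos", "ref", "alt", "design_score",
                "poly_class", "n_missing", "panel_set"]
        io.write_table(panel[cols], p); files.append(p)
        p = out / "cascade_report.json"
        report.to_json(p); files.append(p)
        return files

    def _ssr():
        study = state["study"]
        loci = ssr.find_ssrs_all(study.contigs)
        loci = ssr.assess_ssr_polymorphism(loci, study.ssr_evidence)
        p = out / "ssrs.tsv"
        io.write_table(loci, p)
        return [p]

    def _qcmap():
        study = state["study"]
        files = []
        maps = {}
        for pop, g in study.genotypes.items():
            qc = linkage.classify_markers(
                g, study.parents[pop], population=pop,
                distorted_freq=thr.distorted_freq, extreme_freq=thr.extreme_freq)
            keep = linkage.filter_for_linkage(
                qc, chi2_max=thr.chi2_max, extreme_cut=thr.extreme_freq,
                chi2_override=pop in config.chi2_override_pops)
            qc_df = pd.DataFrame([vars(q) for q in qc])
            p = out / f"qc_{pop}.tsv"
            io.write_table(qc_df, p); files.append(p)
            pmap = linkage.build_map(g.loc[keep], lod_min=thr.lod_min)
            maps[pop] = pmap
            p = out / f"map_{pop}.tsv"
            io.write_table(pmap, p); files.append(p)
        state["maps"] = maps
        return files

    def _consensus():
        study = state["study"]
        cons, unplaced = build_consensus(state["maps"], study.truth.anchors)
        cons = assign_bins(cons, bin_cM=thr.bin_cM)
        state["consensus"] = cons
        files = []
        p = out / "consensus.tsv"
        io.write_table(cons, p); files.append(p)
        cmap = cons.rename(columns={"group": "map_acc", "cM": "position"})
        p = out / "cmap_export.tsv"
        io.write_table(cmap[["map_acc", "marker", "position"]], p)
        files.append(p)
        p = out / "unplaced_groups.tsv"
        io.write_table(pd.DataFrame(unplaced, columns=["population", "group"]), p)
        files.append(p)
        return files

    def _synteny():
        study = state["study"]
        blocks = syn.detect_blocks(
            state["consensus"], study.ortho,
            min_block=thr.min_block, max_interlopers=thr.max_interlopers)
        files = []
        p = out / "blocks.tsv"
        io.write_table(syn.blocks_to_frame(blocks), p); files.append(p)
        p = out / "correspondence.tsv"
        io.write_table(syn.correspondence_table(blocks, thr.min_chrom_share), p)
        files.append(p)
        p = out / "circos_links.txt"
        syn.export_circos(blocks, p); files.append(p)
        return files

    for name, fn in (("simulate", _simulate), ("discover", _discover),
                     ("design", _design), ("ssr", _ssr), ("qcmap", _qcmap),
                     ("consensus", _consensus), ("synteny", _synteny)):
        stage(name, fn)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
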