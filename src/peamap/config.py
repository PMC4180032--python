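"""Configuration objects for the simulator and the pipeline.

All thresholds used by the analysis stages (read-depth/concordance confidence
rule, flanking clearance, ADT score cut-offs, chi-square and allele-frequency
filters, LOD grouping threshold, bin width) are named keys with the study's
published defaults, so a run is fully described by one YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import Any, Mapping, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration file fails validation; lists offending keys."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the real experiment scaled to desk size: eight *Pisum*
    accessions (reference cultivar + 5 cultivars + 2 wild relatives), 3'-end
    transcript contigs of 200-1500 bp, per-accession SNP density of 1/667 bp
    for cultivars and 1/99 bp for the wild accessions, ~6x read depth, and
    five F7 RIL populations of ~90-144 lines mapped over 7 linkage groups.
    """

    seed: int = 0
    # reference transcriptome
    n_contigs: int = 120
    contig_length_range: tuple[int, int] = (200, 1500)
    splice_boundary_rate: float = 1.0  # Poisson mean per contig
    unannotated_prob: float = 0.24  # contig has no model-genome orthologue
    # accession panel and variants
    n_cultivars: int = 5  # non-reference cultivars
    n_wild: int = 2
    cultivar_snp_rate: float = 1.0 / 667.0  # per accession vs reference, per bp
    wild_snp_rate: float = 1.0 / 99.0
    het_rate: float = 0.02  # residual heterozygosity per variant site, per accession
    mean_depth: float = 6.0
    read_error_rate: float = 0.01
    # genetic map / RIL populations
    n_lgs: int = 7
    n_markers_per_lg: int = 30
    lg_length_cM: float = 110.0
    n_anchors_per_lg: int = 3
    ril_pop_sizes: tuple[int, ...] = (124, 90, 134, 94, 144)
    pop_polymorphic_fraction: float = 0.4  # share of markers segregating per cross
    reference_pop_polymorphic_fraction: float = 0.8  # anchor-carrying population
    ril_het_rate: float = 0.5 ** 6  # residual heterozygosity at F7
    distortion_fraction: float = 0.02
    selection_coefficient: float = 0.5  # viability of the B allele is 1 - s
    missing_rate: float = 0.03
    failure_rate: float = 0.07  # whole-assay failure, within the 6-9 % observed
    ssr_contig_fraction: float = 0.014  # contigs carrying a microsatellite

    def __post_init__(self) -> None:
        probs = {
            "unannotated_prob": self.unannotated_prob,
            "cultivar_snp_rate": self.cultivar_snp_rate,
            "wild_snp_rate": self.wild_snp_rate,
            "het_rate": self.het_rate,
            "read_error_rate": self.read_error_rate,
            "pop_polymorphic_fraction": self.pop_polymorphic_fraction,
            "reference_pop_polymorphic_fraction": self.reference_pop_polymorphic_fraction,
            "ril_het_rate": self.ril_het_rate,
            "distortion_fraction": self.distortion_fraction,
            "selection_coefficient": self.selection_coefficient,
            "missing_rate": self.missing_rate,
            "failure_rate": self.failure_rate,
            "ssr_contig_fraction": self.ssr_contig_fraction,
        }
        bad = [k for k, v in probs.items() if not 0.0 <= float(v) <= 1.0]
        if bad:
            raise ConfigError(f"probabilities outside [0, 1]: {bad}")
        counts = {
            "n_contigs": self.n_contigs,
            "n_cultivars": self.n_cultivars,
            "n_wild": self.n_wild,
            "n_lgs": self.n_lgs,
            "n_markers_per_lg": self.n_markers_per_lg,
        }
        bad = [k for k, v in counts.items() if int(v) <= 0]
        if bad:
            raise ConfigError(f"counts must be positive: {bad}")
        lo, hi = self.contig_length_range
        if lo <= 0 or hi < lo:
            raise ConfigError("contig_length_range must be a positive (lo, hi) with hi >= lo")
        if self.lg_length_cM <= 0 or self.mean_depth <= 0:
            raise ConfigError("lg_length_cM and mean_depth must be positive")
        if not self.ril_pop_sizes or any(int(n) <= 0 for n in self.ril_pop_sizes):
            raise ConfigError("ril_pop_sizes must be non-empty positive counts")

    @property
    def accessions(self) -> list[str]:
        """Non-reference accession names, cultivars first."""
        cult = [f"cv{i + 1}" for i in range(self.n_cultivars)]
        wild = [f"wild{i + 1}" for i in range(self.n_wild)]
        return cult + wild

    @property
    def cultivar_names(self) -> list[str]:
        return self.accessions[: self.n_cultivars]

    @property
    def wild_names(self) -> list[str]:
        return self.accessions[self.n_cultivars:]


@dataclass
class ThresholdConfig:
    """Published analysis thresholds, exposed as named knobs."""

    min_reads: int = 3  # confident call needs >= 3 aligned reads ...
    min_concordance: float = 0.80  # ... with >= 80 % carrying the allele
    flank_window_bp: int = 60  # no other SNP within this window
    min_clearance_bp: int = 60  # contig end / splice-site clearance
    min_design_score: float = 0.4  # ADT acceptance floor
    preferred_design_score: float = 0.6
    panel_size: int = 1536
    max_missing: int = 4  # missing-genotype cap during panel fill
    chi2_max: float = 5.0  # segregation-distortion drop rule
    extreme_freq: float = 0.1  # extreme-distortion allele-frequency cut
    distorted_freq: float = 0.3  # balanced/distorted class boundary
    lod_min: float = 5.0  # two-point grouping threshold
    bin_cM: float = 20.0
    min_block: int = 3  # synteny block size
    max_interlopers: int = 1
    min_chrom_share: float = 0.2  # correspondence-table marker share

    def __post_init__(self) -> None:
        if self.min_reads < 1 or not 0 < self.min_concordance <= 1:
            raise ConfigError("invalid confidence thresholds")
        if self.panel_size < 1 or self.bin_cM <= 0 or self.lod_min < 0:
            raise ConfigError("invalid panel/bin/lod settings")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    # populations exempt from the chi-square drop rule (highly distorted
    # interspecific crosses)
    chi2_override_pops: tuple[str, ...] = ()

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


_REQUIRED_THRESHOLD_KEYS = ("panel_size",)


def _build(cls, section: Mapping[str, Any], where: str):
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(section) - known)
    if unknown:
        raise ConfigError(f"unknown keys in '{where}': {unknown}")
    coerced = dict(section)
    for key in ("contig_length_range", "ril_pop_sizes", "chi2_override_pops"):
        if key in coerced and isinstance(coerced[key], list):
            coerced[key] = tuple(coerced[key])
    try:
        return cls(**coerced)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"bad section '{where}': {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML file.

    The file must contain a ``thresholds`` section naming ``panel_size``
    explicitly; everything else has defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    unknown = sorted(set(raw) - {"simulation", "thresholds", "chi2_override_pops"})
    if unknown:
        raise ConfigError(f"unknown top-level keys: {unknown}")
    thr_section = raw.get("thresholds", {}) or {}
    missing = [k for k in _REQUIRED_THRESHOLD_KEYS if k not in thr_section]
    if missing:
        raise ConfigError(f"missing required keys in 'thresholds': {missing}")
    sim = _build(SimulationConfig, raw.get("simulation", {}) or {}, "simulation")
    thr = _build(ThresholdConfig, thr_section, "thresholds")
    override = raw.get("chi2_override_pops", []) or []
    if not isinstance(override, Sequence) or isinstance(override, str):
        raise ConfigError("chi2_override_pops must be a list of population names")
    return PipelineConfig(simulation=sim, thresholds=thr,
                          chi2_override_pops=tuple(override))
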