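"""Synthetic study generator.

Produces every input the pipeline consumes — reference contigs, per-accession
pileups, orthologue and splice tables, ADT-style design scores, and F7 RIL
genotype matrices — together with the generating truth, under one seeded
NumPy random stream.  The generator emulates the statistical structure of a
3'-anchored transcriptome SNP study in pea:

* ~200-1500 bp contigs with uniform base composition;
* per-accession SNP density vs the reference of ~1/667 bp for cultivars and
  ~1/99 bp for wild accessions, with residual heterozygosity;
* Poisson read depth (mean ~6) with uniform base-miscall errors;
* seven linkage groups carried by designated marker contigs, each linkage
  group collinear with one model-genome chromosome (random orientation);
* RIL genotypes drawn directly from the selfed-RIL mapping function
  R = 2r / (1 + 2r), with per-marker viability selection for segregation
  distortion, residual F7 heterozygosity, missing calls and whole-assay
  failures overlaid last.

Genotypes are simulated marker-to-marker as a Markov chain along each group
(no residual interference beyond the Kosambi distance convention), so
linkage groups are mutually independent and distortion-induced hitchhiking
arises naturally within a group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig, ConfigError
from .linkage import kosambi_inverse

BASES = np.array(["A", "C", "G", "T"])
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_TRANSITION_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T
#: share of simulated substitutions that are transitions (observed mix in
#: comparable 454 transcriptome studies is ~64/36)
TRANSITION_PROB = 0.64
#: model-genome chromosome count and uniform pseudo-length (bp)
N_MODEL_CHROMS = 8
MODEL_CHROM_LEN = 50_000_000

__all__ = [
    "TruthSet", "Study", "simulate_reference", "simulate_truth_variants",
    "simulate_accession_pileups", "simulate_ril_population", "simulate_study",
    "simulate_ssr_truth",
]


@dataclass
class TruthSet:
    """Generating truth emitted alongside the data for recovery tests."""

    variant_sites: pd.DataFrame  # contig,pos,ref,alt,is_marker_site,<accession codes>
    marker_map: pd.DataFrame  # group, marker, cM, contig
    synteny_layout: pd.DataFrame  # group, model_chrom, orientation
    distorted_markers: list[str]
    anchors: list[str]
    pop_markers: dict[str, list[str]] = field(default_factory=dict)
    ril_true: dict[str, pd.DataFrame] = field(default_factory=dict)
    ssr_loci: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class Study:
    """Complete simulated data set (inputs + truth) for one seed."""

    config: SimulationConfig
    contigs: dict[str, str]
    ortho: pd.DataFrame
    splice: pd.DataFrame
    pileups: pd.DataFrame
    scores: pd.DataFrame
    genotypes: dict[str, pd.DataFrame]
    parents: dict[str, pd.DataFrame]
    ssr_evidence: pd.DataFrame
    truth: TruthSet


# ---------------------------------------------------------------------------
# reference, truth map and synteny layout

def _make_truth_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Marker map truth: near-regular spacing with mild jitter per group."""
    rows = []
    m = config.n_markers_per_lg
    for g in range(config.n_lgs):
        base = np.linspace(0.0, config.lg_length_cM, m)
        jitter = rng.uniform(-0.3, 0.3, size=m) * (config.lg_length_cM / max(m - 1, 1))
        pos = np.sort(np.clip(base + jitter, 0.0, config.lg_length_cM))
        for i in range(m):
            idx = g * m + i
            rows.append({"group": f"LG{g + 1}", "marker": f"ctg{idx:05d}",
                         "cM": float(pos[i]), "contig": f"ctg{idx:05d}"})
    return pd.DataFrame(rows)


def simulate_reference(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    truth_map: pd.DataFrame | None = None,
    synteny_layout: pd.DataFrame | None = None,
):
    """Simulate reference contigs plus orthologue and splice-boundary tables.

    Marker contigs (those carrying the truth map, when given) are always
    annotated and placed on the model genome according to the synteny layout;
    the rest are annotated with probability ``1 - unannotated_prob`` at
    random model positions. Splice boundaries are Poisson per contig.

    Returns ``(contigs, ortho, splice)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_contigs
    if n <= 0:
        raise ConfigError("n_contigs must be positive")
    lo, hi = config.contig_length_range
    if hi < lo or lo <= 0:
        raise ConfigError("degenerate contig_length_range")
    lengths = rng.integers(lo, hi + 1, size=n)
    contigs = {
        f"ctg{i:05d}": "".join(BASES[rng.integers(0, 4, size=int(lengths[i]))])
        for i in range(n)
    }
    marker_contig_group: dict[str, tuple[str, float]] = {}
    if truth_map is not None:
        for row in truth_map.itertuples(index=False):
            marker_contig_group[row.contig] = (row.group, row.cM)
    layout = {}
    if synteny_layout is not None:
        layout = {r.group: (int(r.model_chrom), int(r.orientation))
                  for r in synteny_layout.itertuples(index=False)}

    ortho_rows = []
    lg_len = config.lg_length_cM
    for cid in contigs:
        if cid in marker_contig_group and layout:
            group, cm = marker_contig_group[cid]
            chrom, orient = layout[group]
            frac = cm / lg_len
            if orient < 0:
                frac = 1.0 - frac
            start = int(frac * (MODEL_CHROM_LEN - 2000))
            ortho_rows.append((cid, chrom, start, start + 1500, "+", 1))
        elif rng.random() >= config.unannotated_prob:
            chrom = int(rng.integers(1, N_MODEL_CHROMS + 1))
            start = int(rng.integers(0, MODEL_CHROM_LEN - 2000))
            strand = "+" if rng.random() < 0.5 else "-"
            ortho_rows.append((cid, chrom, start, start + 1500, strand, 1))
        else:
            ortho_rows.append((cid, 0, -1, -1, ".", 0))
    ortho = pd.DataFrame(ortho_rows, columns=[
        "contig", "model_chrom", "model_start", "model_end", "strand", "annotated"])

    splice_rows = []
    for cid, seq in contigs.items():
        k = rng.poisson(config.splice_boundary_rate)
        if k:
            for p in sorted(rng.integers(0, len(seq), size=k)):
                splice_rows.append((cid, int(p)))
    splice = pd.DataFrame(splice_rows, columns=["contig", "pos0"])
    return contigs, ortho, splice


def _make_synteny_layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = rng.permutation(np.arange(1, N_MODEL_CHROMS + 1))[: config.n_lgs]
    orient = rng.choice([1, -1], size=config.n_lgs)
    return pd.DataFrame({
        "group": [f"LG{g + 1}" for g in range(config.n_lgs)],
        "model_chrom": chroms.astype(int),
        "orientation": orient.astype(int),
    })


#: per-accession probability that an SSR copy number deviates from the
#: reference by one unit (gives roughly the observed ~16 % polymorphic share
#: over an 7-accession panel)
SSR_DEVIATION_PROB = 0.03


def _inject_ssrs(contigs: dict[str, str], config: SimulationConfig,
                 rng: np.random.Generator):
    """Overwrite a segment of some contigs with a perfect microsatellite.

    Mutates ``contigs`` in place; returns (truth loci, per-accession copy
    evidence). Runs before variant placement so pileups reflect the edited
    sequence.
    """
    loci_rows, ev_rows = [], []
    for cid in list(contigs):
        if rng.random() >= config.ssr_contig_fraction:
            continue
        seq = contigs[cid]
        u = int(rng.integers(2, 5))
        motif = "".join(BASES[rng.integers(0, 4, size=u)])
        if len(set(motif)) == 1:
            motif = motif[:-1] + ("C" if motif[0] != "C" else "G")
        copies = int(rng.integers(5, 11))
        need = u * copies
        if len(seq) < need + 20:
            continue
        start = int(rng.integers(10, len(seq) - need - 10))
        contigs[cid] = seq[:start] + motif * copies + seq[start + need:]
        loci_rows.append({"contig": cid, "start": start, "end": start + need,
                          "motif": motif, "copies": copies})
        for acc in config.accessions:
            delta = int(rng.choice([-1, 1])) \
                if rng.random() < SSR_DEVIATION_PROB else 0
            ev_rows.append({"contig": cid, "accession": acc,
                            "copies": copies + delta})
    cols_l = ["contig", "start", "end", "motif", "copies"]
    cols_e = ["contig", "accession", "copies"]
    return (pd.DataFrame(loci_rows, columns=cols_l),
            pd.DataFrame(ev_rows, columns=cols_e))


# ---------------------------------------------------------------------------
# variant truth

def _draw_alt(ref_codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Alt base codes with a fixed transition share of TRANSITION_PROB."""
    n = len(ref_codes)
    alt = np.empty(n, dtype=np.int64)
    is_ts = rng.random(n) < TRANSITION_PROB
    partner = np.array([_TRANSITION_PARTNER[b] for b in range(4)])
    alt[is_ts] = partner[ref_codes[is_ts]]
    # transversion: pick one of the two pyrimidines (for purine ref) etc.
    tv = ~is_ts
    for b in range(4):
        sel = tv & (ref_codes == b)
        choices = [c for c in range(4) if c != b and c != _TRANSITION_PARTNER[b]]
        alt[sel] = rng.choice(choices, size=int(sel.sum()))
    return alt


def simulate_truth_variants(
    contigs: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
    marker_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """True variant sites with per-accession genotype codes (0 ref / 1 alt / 2 het).

    Two site classes: shared sites at which every non-reference accession
    carries the alternate allele with probability 1/2 (giving the configured
    per-cultivar density), and wild-only sites at which only wild accessions
    carry the alternate (probability 0.8), making up the wild excess density.
    Marker contigs (from ``marker_map``) additionally receive one guaranteed
    clean cultivar-polymorphic site near the contig centre.
    """
    accs = config.accessions
    n_acc = len(accs)
    n_cult = config.n_cultivars
    rate_shared = 2.0 * config.cultivar_snp_rate
    extra = max(config.wild_snp_rate - config.cultivar_snp_rate, 0.0)
    rate_wild_only = extra / 0.8 if extra > 0 else 0.0

    marker_site_contigs = set()
    if marker_map is not None:
        marker_site_contigs = set(marker_map["contig"])

    rows_contig, rows_pos = [], []
    geno_blocks = []
    is_marker_site = []
    for cid, seq in contigs.items():
        L = len(seq)
        n_shared = rng.binomial(L, min(rate_shared, 1.0))
        n_wild = rng.binomial(L, min(rate_wild_only, 1.0)) if rate_wild_only else 0
        taken: set[int] = set()
        marker_pos = -1
        if cid in marker_site_contigs:
            marker_pos = L // 2
            taken.add(marker_pos)
            g = np.zeros(n_acc, dtype=np.int8)
            k = int(rng.integers(1, n_cult)) if n_cult > 1 else 1
            g[rng.permutation(n_cult)[:k]] = 1
            g[n_cult:] = (rng.random(config.n_wild) < 0.5).astype(np.int8)
            rows_contig.append(cid)
            rows_pos.append(marker_pos)
            geno_blocks.append(g)
            is_marker_site.append(True)
        for n_sites, carrier_p, wild_only in ((n_shared, 0.5, False),
                                              (n_wild, 0.8, True)):
            placed = 0
            while placed < n_sites:
                p = int(rng.integers(0, L))
                if p in taken:
                    continue
                taken.add(p)
                placed += 1
                g = np.zeros(n_acc, dtype=np.int8)
                if wild_only:
                    g[n_cult:] = (rng.random(config.n_wild) < carrier_p).astype(np.int8)
                else:
                    g[:] = (rng.random(n_acc) < carrier_p).astype(np.int8)
                if not g.any():
                    g[int(rng.integers(0, n_acc))] = 1
                het = (g == 1) & (rng.random(n_acc) < config.het_rate)
                g[het] = 2
                rows_contig.append(cid)
                rows_pos.append(p)
                geno_blocks.append(g)
                is_marker_site.append(False)
    if not rows_contig:
        cols = ["contig", "pos", "ref", "alt", "is_marker_site"] + list(accs)
        return pd.DataFrame(columns=cols)
    geno = np.vstack(geno_blocks)
    ref_codes = np.array([_BASE_IDX[contigs[c][p]]
                          for c, p in zip(rows_contig, rows_pos)])
    alt_codes = _draw_alt(ref_codes, rng)
    df = pd.DataFrame({
        "contig": rows_contig,
        "pos": np.asarray(rows_pos, dtype=np.int64),
        "ref": BASES[ref_codes],
        "alt": BASES[alt_codes],
        "is_marker_site": is_marker_site,
    })
    for j, a in enumerate(accs):
        df[a] = geno[:, j]
    df = df.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# pileups

def _scatter_reads(counts: np.ndarray, idx: np.ndarray, base_codes: np.ndarray,
                   n_reads: np.ndarray, error_rate: float,
                   rng: np.random.Generator) -> None:
    """Add ``n_reads`` reads of true base ``base_codes`` at rows ``idx``,
    miscalling each read to a uniform other base with ``error_rate``."""
    n_err = rng.binomial(n_reads, error_rate) if error_rate > 0 else np.zeros_like(n_reads)
    correct = n_reads - n_err
    for b in range(4):
        sel = base_codes == b
        if not sel.any():
            continue
        rows = idx[sel]
        np.add.at(counts[:, b], rows, correct[sel])
        ne = n_err[sel]
        if ne.sum():
            others = [c for c in range(4) if c != b]
            err3 = rng.multinomial(ne, [1 / 3] * 3)
            for k, c in enumerate(others):
                np.add.at(counts[:, c], rows, err3[:, k])


def simulate_accession_pileups(
    contigs: dict[str, str],
    truth_variants: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-accession, per-site base counts.

    Site depth is Poisson(``mean_depth``); each read reports the accession's
    haplotype allele at the site (heterozygous sites draw each read's
    haplotype fairly), miscalled to a uniformly random other base with
    probability ``read_error_rate``.
    """
    order = list(contigs)
    lengths = np.array([len(contigs[c]) for c in order])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    ref_codes = np.frombuffer(
        "".join(contigs[c] for c in order).encode(), dtype="S1")
    ref_idx = np.zeros(total, dtype=np.int8)
    for b, i in _BASE_IDX.items():
        ref_idx[ref_codes == b.encode()] = i
    contig_of = np.repeat(np.arange(len(order)), lengths)
    pos_of = np.arange(total) - offsets[contig_of]

    # global index of each truth site
    cidx = {c: i for i, c in enumerate(order)}
    if len(truth_variants):
        bad = set(truth_variants["contig"]) - set(order)
        if bad:
            raise ValueError(f"truth sites on unknown contigs: {sorted(bad)[:3]}")
        tv_gidx = (offsets[[cidx[c] for c in truth_variants["contig"]]]
                   + truth_variants["pos"].to_numpy())
        tv_alt = np.array([_BASE_IDX[b] for b in truth_variants["alt"]])
    else:
        tv_gidx = np.array([], dtype=np.int64)
        tv_alt = np.array([], dtype=np.int64)

    frames = []
    for acc in config.accessions:
        geno = np.zeros(total, dtype=np.int8)  # 0 ref / 1 alt / 2 het
        alt_at = ref_idx.astype(np.int64).copy()
        if len(tv_gidx):
            geno[tv_gidx] = truth_variants[acc].to_numpy(dtype=np.int8)
            alt_at[tv_gidx] = tv_alt
        depth = rng.poisson(config.mean_depth, size=total)
        counts = np.zeros((total, 4), dtype=np.int64)
        e = config.read_error_rate
        hom = geno != 2
        idx_hom = np.nonzero(hom)[0]
        base_hom = np.where(geno[idx_hom] == 1, alt_at[idx_hom],
                            ref_idx[idx_hom].astype(np.int64))
        _scatter_reads(counts, idx_hom, base_hom, depth[idx_hom], e, rng)
        idx_het = np.nonzero(~hom)[0]
        if len(idx_het):
            n_alt = rng.binomial(depth[idx_het], 0.5)
            _scatter_reads(counts, idx_het, alt_at[idx_het], n_alt, e, rng)
            _scatter_reads(counts, idx_het, ref_idx[idx_het].astype(np.int64),
                           depth[idx_het] - n_alt, e, rng)
        frames.append(pd.DataFrame({
            "accession": acc,
            "contig": np.array(order)[contig_of],
            "pos0": pos_of,
            "countA": counts[:, 0], "countC": counts[:, 1],
            "countG": counts[:, 2], "countT": counts[:, 3],
            "depth": counts.sum(axis=1),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# RIL populations

def simulate_ril_population(
    true_map: pd.DataFrame,
    n_lines: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    distorted: set[str] | None = None,
    line_prefix: str = "L",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an F7 RIL genotype matrix from a truth map.

    Returns ``(observed, true)`` marker x line DataFrames with calls in
    {A, B, H, U}; ``true`` is the pre-overlay homozygous matrix. Adjacent
    markers recombine on inbred lines with R = 2r/(1+2r), r from the inverse
    Kosambi of the cM gap. Distorted markers retain the B allele with
    relative viability 1 - ``selection_coefficient`` (rejection sampling per
    linkage group, which hitchhikes linked markers). Residual heterozygosity,
    missing calls and whole-marker assay failures are overlaid last.
    """
    distorted = distorted or set()
    s = config.selection_coefficient
    blocks, names = [], []
    for group in pd.unique(true_map["group"]):
        sub = true_map.loc[true_map["group"] == group]  # caller's row order
        cm = sub["cM"].to_numpy()
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"non-monotone cM in group {group}")
        markers = sub["marker"].tolist()
        gaps = np.diff(cm)
        r = kosambi_inverse(gaps)
        R = 2.0 * r / (1.0 + 2.0 * r)
        m = len(markers)
        dist_idx = np.array([i for i, mk in enumerate(markers) if mk in distorted],
                            dtype=np.int64)
        geno = np.zeros((m, n_lines), dtype=np.int8)
        todo = np.arange(n_lines)
        while len(todo):
            k = len(todo)
            draw = np.zeros((m, k), dtype=np.int8)
            draw[0] = rng.random(k) < 0.5
            flips = rng.random((m - 1, k)) < R[:, None] if m > 1 else np.empty((0, k))
            for i in range(1, m):
                draw[i] = draw[i - 1] ^ flips[i - 1]
            if len(dist_idx) and s > 0:
                n_b = draw[dist_idx].sum(axis=0)
                accept = rng.random(k) < (1.0 - s) ** n_b
            else:
                accept = np.ones(k, dtype=bool)
            geno[:, todo[accept]] = draw[:, accept]
            todo = todo[~accept]
        blocks.append(geno)
        names.extend(markers)
    geno = np.vstack(blocks)
    lines = [f"{line_prefix}{i + 1:03d}" for i in range(n_lines)]
    true_calls = np.where(geno == 1, "B", "A")
    true_df = pd.DataFrame(true_calls, index=names, columns=lines)
    obs = true_calls.copy()
    obs[rng.random(obs.shape) < config.ril_het_rate] = "H"
    obs[rng.random(obs.shape) < config.missing_rate] = "U"
    failed = rng.random(len(names)) < config.failure_rate
    obs[failed, :] = "U"
    obs_df = pd.DataFrame(obs, index=names, columns=lines)
    return obs_df, true_df


# ---------------------------------------------------------------------------
# full study

def simulate_study(config: SimulationConfig) -> Study:
    """Generate the complete synthetic study for one seed."""
    rng = np.random.default_rng(config.seed)
    truth_map = _make_truth_map(config, rng)
    layout = _make_synteny_layout(config, rng)
    n_markers_total = config.n_lgs * config.n_markers_per_lg
    if config.n_contigs < n_markers_total:
        raise ConfigError(
            f"n_contigs={config.n_contigs} < markers required ({n_markers_total})")
    contigs, ortho, splice = simulate_reference(config, rng, truth_map, layout)
    ssr_loci, ssr_evidence = _inject_ssrs(contigs, config, rng)
    variants = simulate_truth_variants(contigs, config, rng, truth_map)
    pileups = simulate_accession_pileups(contigs, variants, config, rng)
    scores = pd.DataFrame({
        "contig": variants["contig"],
        "pos": variants["pos"],
        "design_score": rng.uniform(0.0, 1.0, size=len(variants)),
    })

    all_markers = truth_map["marker"].tolist()
    n_dist = int(round(config.distortion_fraction * len(all_markers)))
    distorted = set(rng.permutation(all_markers)[:n_dist].tolist()) if n_dist else set()
    anchors = []
    for _, sub in truth_map.groupby("group", sort=True):
        ordered = sub.sort_values("cM")["marker"].tolist()
        pick = np.linspace(0, len(ordered) - 1, config.n_anchors_per_lg).astype(int)
        anchors.extend(ordered[i] for i in sorted(set(pick)))

    genotypes: dict[str, pd.DataFrame] = {}
    parents: dict[str, pd.DataFrame] = {}
    pop_markers: dict[str, list[str]] = {}
    ril_true: dict[str, pd.DataFrame] = {}
    for p, n_lines in enumerate(config.ril_pop_sizes):
        pop = f"pop{p + 1}"
        frac = (config.reference_pop_polymorphic_fraction if p == 0
                else config.pop_polymorphic_fraction)
        mask = rng.random(len(all_markers)) < frac
        poly = {m for m, keep in zip(all_markers, mask) if keep}
        if p == 0:
            poly |= set(anchors)
        obs, true_df = simulate_ril_population(
            truth_map, int(n_lines), config, rng, distorted=distorted,
            line_prefix=f"{pop}_L")
        mono = [m for m in all_markers if m not in poly]
        obs.loc[mono, :] = "A"
        par = pd.DataFrame({"p1": "A", "p2": "B"}, index=obs.index)
        par.loc[mono, "p2"] = "A"
        genotypes[pop] = obs
        parents[pop] = par
        pop_markers[pop] = sorted(poly)
        ril_true[pop] = true_df

    truth = TruthSet(
        variant_sites=variants, marker_map=truth_map, synteny_layout=layout,
        distorted_markers=sorted(distorted), anchors=anchors,
        pop_markers=pop_markers, ril_true=ril_true, ssr_loci=ssr_loci,
    )
    return Study(config=config, contigs=contigs, ortho=ortho, splice=splice,
                 pileups=pileups, scores=scores, genotypes=genotypes,
                 parents=parents, ssr_evidence=ssr_evidence, truth=truth)


# ---------------------------------------------------------------------------
# SSR truth (for the repeat detector's recovery tests)

def simulate_ssr_truth(
    n_contigs: int,
    rng: np.random.Generator,
    n_accessions: int = 4,
    flank: int = 120,
    unit_range: tuple[int, int] = (2, 4),
    copy_range: tuple[int, int] = (6, 12),
    expansion_prob: float = 0.4,
):
    """Contigs with one injected perfect microsatellite each, plus truth.

    Returns ``(contigs, truth, copy_estimates)`` where ``truth`` records the
    injected locus per contig and ``copy_estimates`` holds per-accession copy
    numbers (reference copies, expanded/contracted by one unit with
    probability ``expansion_prob`` per accession).
    """
    contigs: dict[str, str] = {}
    rows = []
    est_rows = []
    accs = [f"acc{i + 1}" for i in range(n_accessions)]
    for i in range(n_contigs):
        cid = f"ssr_ctg{i:04d}"
        u = int(rng.integers(unit_range[0], unit_range[1] + 1))
        while True:
            motif = "".join(BASES[rng.integers(0, 4, size=u)])
            if len(set(motif)) > 1:  # primitive enough: not a homopolymer
                break
        copies = int(rng.integers(copy_range[0], copy_range[1] + 1))
        left = "".join(BASES[rng.integers(0, 4, size=flank)])
        right = "".join(BASES[rng.integers(0, 4, size=flank)])
        contigs[cid] = left + motif * copies + right
        rows.append({"contig": cid, "start": flank,
                     "end": flank + u * copies, "motif": motif, "copies": copies})
        for a in accs:
            delta = 0
            if rng.random() < expansion_prob:
                delta = int(rng.choice([-1, 1]))
            est_rows.append({"contig": cid, "accession": a,
                             "copies": copies + delta})
    return contigs, pd.DataFrame(rows), pd.DataFrame(est_rows)
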