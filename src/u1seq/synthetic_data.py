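"""Synthetic six-strain larval RNA-seq dataset generator.

Emulates the statistical structure the downstream analyses assume, for a
wild-type strain plus five single-U1-gene deletion strains:

* gene models with a configurable intron-count mixture (intronless, 1-2
  introns, >=3 introns) and annotated 3'-UTRs;
* negative-binomial gene counts in which knockout down-regulation is
  enriched among 1-2-intron genes;
* two-polyA-site 3'-UTR coverage whose proximal/distal usage shifts in the
  knockouts are coupled to planted U1-binding (5'SS-like) motifs: a motif
  in the proximal window only marks a gene whose knockout response is a
  distal shift, a motif in both windows marks a proximal-shifting gene;
* isoform-specific splice-junction counts for trans-spliced genes.

Every generator records its ground truth so parameter recovery, enrichment
detection and direction classification are checkable without real data.
All randomness flows from one master seed through independent child
streams (genome, expression, coverage, junctions), so regenerating one
output does not perturb the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .apa import MotifConfig, scan_u1_sites
from .core_io import (
    KO_STRAINS,
    STRAINS,
    CountMatrix,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    revcomp,
    write_annotation,
    write_bedgraph,
    write_counts,
    write_fasta,
    write_junctions,
)

logger = logging.getLogger(__name__)

_CHROMS = ("sim2L", "sim2R", "sim3L", "sim3R")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimConfigError(ValueError):
    """Raised when a simulation configuration is internally infeasible."""


@dataclass(frozen=True)
class DEConfig:
    """Knockout expression effects.

    ``fraction_affected`` is per deletion strain, mirroring the observed
    regimes in which some deletions perturb many genes and others few.
    Down-regulated genes are drawn so that the 1-2-intron stratum reaches
    ``intron12_enrichment`` times its background share.
    """

    fraction_affected: Mapping[str, float] = field(
        default_factory=lambda: {
            "21Ddel": 0.04,
            "82Ebdel": 0.10,
            "95Cadel": 0.05,
            "95Cbdel": 0.09,
            "95Ccdel": 0.05,
        }
    )
    log2fc_magnitude: float = 2.0
    down_fraction: float = 0.8
    intron12_enrichment: float = 2.0


@dataclass(frozen=True)
class APAConfig:
    """Two-polyA-site 3'-UTR coverage structure.

    ``class_probs`` splits APA genes into knockout response classes:
    ``distal_shift`` (PDUI rises by ``pdui_shift`` in ``shift_strains``),
    ``proximal_shift`` (falls by the same amount) and ``null``.
    """

    fraction_apa: float = 0.4
    utr_length_range: tuple[int, int] = (300, 600)
    pdui_shift: float = 0.5
    shift_strains: tuple[str, ...] = ("82Ebdel", "95Cadel", "95Cbdel")
    class_probs: Mapping[str, float] = field(
        default_factory=lambda: {"distal_shift": 0.35, "proximal_shift": 0.35, "null": 0.30}
    )
    utr_depth: float = 50.0
    min_utr_length: int = 100
    proximal_position: float = 0.45  # proximal site, as fraction of UTR length


@dataclass(frozen=True)
class MotifPlantConfig:
    """How U1-binding motifs are planted around the two polyA sites.

    ``rules`` maps an APA response class to a planting rule in
    {proximal_only, distal_only, both, none}.  Offsets are genomic
    distances (nt) from the polyA site to the planted 9-mer.  Windows of
    every APA gene are scrubbed of chance motif matches so planted hits
    are exactly the recorded truth.
    """

    motif: MotifConfig = field(default_factory=MotifConfig)
    window: int = 200
    proximal_offset: int = 150
    distal_offset: int = 50
    rules: Mapping[str, str] = field(
        default_factory=lambda: {
            "distal_shift": "proximal_only",
            "proximal_shift": "both",
            "null": "none",
        }
    )


@dataclass(frozen=True)
class TransConfig:
    """Trans-spliced genes with isoform-specific junctions.

    ``activity`` is the ratio of total isoform-specific junction reads to
    common-exon reads per strain; strains in which trans-splicing activity
    is mildly increased get a higher value.
    """

    n_genes: int = 2
    proportions: tuple[float, ...] = (0.5, 0.3, 0.2)
    activity: Mapping[str, float] = field(
        default_factory=lambda: {
            "WT": 0.8,
            "21Ddel": 0.85,
            "82Ebdel": 1.2,
            "95Cadel": 1.2,
            "95Cbdel": 1.2,
            "95Ccdel": 0.85,
        }
    )
    common_depth: float = 1000.0


@dataclass(frozen=True)
class SimConfig:
    """Full study-design configuration; ``seed`` is mandatory."""

    seed: int
    n_genes: int = 300
    # probabilities of {0 introns, 1-2 introns (uniform), >=3 introns (3..8 uniform)}
    intron_count_probs: tuple[float, float, float] = (0.29, 0.36, 0.35)
    gene_length_range: tuple[int, int] = (1000, 6000)
    intron_length_range: tuple[int, int] = (60, 800)
    gc_target: float = 0.43
    n_replicates: int = 3
    library_size_mean: float = 2e6
    nb_dispersion: float = 0.05
    baseline_mean: float = 150.0
    baseline_sigma: float = 1.0
    de: DEConfig = field(default_factory=DEConfig)
    apa: APAConfig = field(default_factory=APAConfig)
    motif: MotifPlantConfig = field(default_factory=MotifPlantConfig)
    trans: TransConfig = field(default_factory=TransConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimConfigError("seed is mandatory")
        if abs(sum(self.intron_count_probs) - 1.0) > 1e-9:
            raise SimConfigError("intron_count_probs must sum to 1")
        if abs(sum(self.apa.class_probs.values()) - 1.0) > 1e-9:
            raise SimConfigError("apa class_probs must sum to 1")
        if abs(sum(self.trans.proportions) - 1.0) > 1e-9:
            raise SimConfigError("trans proportions must sum to 1")
        for frac in (self.apa.fraction_apa, *self.de.fraction_affected.values()):
            if not 0.0 <= frac <= 1.0:
                raise SimConfigError(f"fraction {frac} outside [0, 1]")
        if self.n_replicates < 2:
            raise SimConfigError("need >=2 replicates per strain")

    def streams(self) -> dict[str, np.random.Generator]:
        """One independent generator per sub-generator."""
        names = ("genome", "expression", "coverage", "junctions")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


DEFAULT_CONFIG = SimConfig(seed=20231102)
"""Canonical fixture: 300 genes, 3 replicates x 6 strains."""


@dataclass
class SimTruth:
    """Ground truth emitted by the generators.

    ``genes``: per-gene structure and APA class (indexed by gene_id);
    ``expression``: true log2 fold change, gene x deletion strain;
    ``apa``: true PDUI per gene x strain;
    ``trans``: true isoform proportions and activity per gene x strain.
    """

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    expression: pd.DataFrame = field(default_factory=pd.DataFrame)
    apa: pd.DataFrame = field(default_factory=pd.DataFrame)
    trans: pd.DataFrame = field(default_factory=pd.DataFrame)

    def planted_motifs(self, gene_id: str) -> dict[str, Optional[int]]:
        row = self.genes.loc[gene_id]
        out = {}
        for key in ("motif_proximal_pos", "motif_distal_pos"):
            v = row[key]
            out[key] = None if pd.isna(v) else int(v)
        return out


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _sample_intron_count(rng: np.random.Generator, probs) -> int:
    cat = rng.choice(3, p=probs)
    if cat == 0:
        return 0
    if cat == 1:
        return int(rng.integers(1, 3))
    return int(rng.integers(3, 9))


def _gene_geometry(rng: np.random.Generator, cfg: SimConfig):
    """Sample (intron lengths, exon lengths in transcript order, utr_len)."""
    lo, hi = cfg.gene_length_range
    ilo, ihi = cfg.intron_length_range
    k = _sample_intron_count(rng, cfg.intron_count_probs)
    utr_len = int(rng.integers(*cfg.apa.utr_length_range))
    last_exon = utr_len + int(rng.integers(60, 200))
    min_len = last_exon + k * (80 + ilo) + 120
    if min_len > hi:
        raise SimConfigError(
            f"infeasible geometry: {k} introns of >= {ilo} nt cannot fit a "
            f"gene of <= {hi} nt"
        )
    total = int(rng.integers(max(lo, min_len), hi + 1))
    if k == 0:
        return [], [total], utr_len
    introns = rng.integers(ilo, ihi + 1, size=k)
    budget = total - last_exon - k * 80 - 40
    if introns.sum() > budget:
        introns = np.maximum(ilo, (introns * (budget / introns.sum())).astype(int))
    exon_budget = total - int(introns.sum()) - last_exon
    extra = exon_budget - k * 80
    split = rng.multinomial(extra, np.full(k, 1.0 / k)) if extra > 0 else np.zeros(k, int)
    exons = [80 + int(s) for s in split] + [last_exon]
    return [int(x) for x in introns], exons, utr_len


def _assemble_model(
    gene_id: str,
    chrom: str,
    start: int,
    strand: str,
    introns: Sequence[int],
    exons_tx: Sequence[int],
    utr_len: int,
    apa_cfg: APAConfig,
    is_apa: bool,
) -> tuple[GeneModel, dict]:
    """Lay the transcript-ordered lengths onto the genome."""
    if strand == "+":
        exon_lens = list(exons_tx)
        intron_lens = list(introns)
    else:
        exon_lens = list(exons_tx[::-1])
        intron_lens = list(introns[::-1])
    pieces = []
    pos = start
    iv_exons = []
    for i, el in enumerate(exon_lens):
        iv_exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    end = pos
    span = GenomicInterval(chrom, start, end, strand)
    exon_ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in iv_exons)
    if strand == "+":
        utr = GenomicInterval(chrom, end - utr_len, end, strand)
    else:
        utr = GenomicInterval(chrom, start, start + utr_len, strand)
    info: dict = {"utr_length": utr_len}
    kwargs = {}
    if is_apa:
        prox_offset = int(apa_cfg.proximal_position * utr_len)
        if strand == "+":
            prox = utr.start + prox_offset
            dist = utr.end - 1
        else:
            prox = utr.end - 1 - prox_offset
            dist = utr.start
        kwargs = {"polya_proximal": prox, "polya_distal": dist}
        info["proximal_offset"] = prox_offset
    model = GeneModel(gene_id=gene_id, span=span, exons=exon_ivs, utr3=utr, **kwargs)
    return model, info


def _plant(seq: np.ndarray, sense_start: int, strand: str, consensus: str) -> None:
    """Write the motif so its sense-strand start is ``sense_start``."""
    if strand == "+":
        lo = sense_start
        word = consensus
    else:
        lo = sense_start - len(consensus) + 1
        word = revcomp(consensus)
    seq[lo : lo + len(word)] = np.frombuffer(word.encode(), dtype=np.uint8)


def _sense_starts_in(seq: np.ndarray, lo: int, hi: int, strand: str, motif: MotifConfig):
    """Genomic sense-strand start positions of motif hits in [lo, hi)."""
    raw = seq[lo:hi].tobytes().decode()
    sense = raw if strand == "+" else revcomp(raw)
    hits = scan_u1_sites(sense, motif)
    if strand == "+":
        return [lo + h.position for h in hits]
    return [hi - 1 - h.position for h in hits]


def _scrub_window(
    seq: np.ndarray,
    site: int,
    strand: str,
    planted: set[int],
    plant_footprints: list[tuple[int, int]],
    cfg: MotifPlantConfig,
    rng: np.random.Generator,
) -> None:
    """Remove chance motif matches from one +/-window around a polyA site.

    Any hit whose sense start is inside the window but was not planted is
    destroyed by rewriting its bases that fall outside every planted
    footprint; planted hits are never touched.
    """
    m = len(cfg.motif.consensus)
    lo = max(0, site - cfg.window - m)
    hi = min(len(seq), site + cfg.window + m + 1)
    cons = cfg.motif.consensus.encode()
    for _ in range(10):
        starts = [
            s
            for s in _sense_starts_in(seq, lo, hi, strand, cfg.motif)
            if site - cfg.window <= s <= site + cfg.window and s not in planted
        ]
        if not starts:
            return
        for s in starts:
            footprint = range(s, s + m) if strand == "+" else range(s - m + 1, s + 1)
            mutated = 0
            for offset, gpos in enumerate(footprint):
                if any(a <= gpos < b for a, b in plant_footprints):
                    continue
                motif_idx = offset if strand == "+" else m - 1 - offset
                want_mismatch = cons[motif_idx : motif_idx + 1].decode()
                base = "C" if want_mismatch != "C" else "A"
                if strand == "-":
                    base = revcomp(base)
                seq[gpos] = ord(base)
                mutated += 1
                if mutated >= 3:
                    break
    raise RuntimeError("failed to scrub chance motif hits near a polyA site")


def build_synthetic_genome(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], list[GeneModel], SimTruth]:
    """Generate genome sequences, gene models and the structural truth table.

    APA genes (two polyA sites) are assigned a knockout response class and
    get U1-binding motifs planted per the class's planting rule; the
    +/-window around each polyA site of every APA gene is scrubbed of
    chance matches, so window hit counts equal the recorded truth exactly.
    """
    rng = rng if rng is not None else config.streams()["genome"]
    n = config.n_genes
    apa_classes = list(config.apa.class_probs)
    class_p = np.array([config.apa.class_probs[c] for c in apa_classes])

    # pass 1: structures
    per_chrom_cursor = {c: 300 for c in _CHROMS}
    models: list[GeneModel] = []
    rows = []
    for i in range(n):
        gene_id = f"g{i + 1:04d}"
        chrom = _CHROMS[i % len(_CHROMS)]
        strand = "+" if rng.random() < 0.5 else "-"
        is_apa = rng.random() < config.apa.fraction_apa
        apa_class = str(rng.choice(apa_classes, p=class_p)) if is_apa else ""
        introns, exons_tx, utr_len = _gene_geometry(rng, config)
        start = per_chrom_cursor[chrom]
        model, info = _assemble_model(
            gene_id, chrom, start, strand, introns, exons_tx, utr_len,
            config.apa, is_apa,
        )
        per_chrom_cursor[chrom] = model.span.end + int(rng.integers(300, 800))
        models.append(model)
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "strand": strand,
                "length": model.length,
                "n_introns": model.n_introns,
                "apa_class": apa_class,
                "utr_length": info["utr_length"],
                "proximal_offset": info.get("proximal_offset", np.nan),
                "motif_proximal_pos": np.nan,
                "motif_distal_pos": np.nan,
            }
        )

    # pass 2: sequences
    gc = config.gc_target
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arrays: dict[str, np.ndarray] = {}
    for chrom in _CHROMS:
        length = per_chrom_cursor[chrom] + 300
        arrays[chrom] = _BASES[rng.choice(4, size=length, p=probs)].copy()

    # pass 3: plant motifs, then scrub chance hits from every APA window
    genes = pd.DataFrame(rows).set_index("gene_id")
    plant_footprints: dict[str, list[tuple[int, int]]] = {c: [] for c in _CHROMS}
    m = len(config.motif.motif.consensus)
    for model in models:
        if not model.has_apa_sites:
            continue
        apa_class = genes.at[model.gene_id, "apa_class"]
        rule = config.motif.rules.get(apa_class, "none")
        seq = arrays[model.chrom]
        sign = 1 if model.strand == "+" else -1
        if rule in ("proximal_only", "both"):
            s = model.polya_proximal - sign * config.motif.proximal_offset
            _plant(seq, s, model.strand, config.motif.motif.consensus)
            genes.at[model.gene_id, "motif_proximal_pos"] = s
            fp = (s, s + m) if model.strand == "+" else (s - m + 1, s + 1)
            plant_footprints[model.chrom].append(fp)
        if rule in ("distal_only", "both"):
            s = model.polya_distal + sign * config.motif.distal_offset
            _plant(seq, s, model.strand, config.motif.motif.consensus)
            genes.at[model.gene_id, "motif_distal_pos"] = s
            fp = (s, s + m) if model.strand == "+" else (s - m + 1, s + 1)
            plant_footprints[model.chrom].append(fp)
    for model in models:
        if not model.has_apa_sites:
            continue
        planted = {
            int(v)
            for v in (
                genes.at[model.gene_id, "motif_proximal_pos"],
                genes.at[model.gene_id, "motif_distal_pos"],
            )
            if not pd.isna(v)
        }
        for site in (model.polya_proximal, model.polya_distal):
            _scrub_window(
                arrays[model.chrom], site, model.strand, planted,
                plant_footprints[model.chrom], config.motif, rng,
            )

    genome = {c: arrays[c].tobytes().decode() for c in _CHROMS}
    for model in models:
        seq = genome[model.chrom][model.span.start : model.span.end].upper()
        model.gc_fraction = (seq.count("G") + seq.count("C")) / len(seq)
    truth = SimTruth(genes=genes)
    return genome, models, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimConfig,
    models: Sequence[GeneModel],
    truth: SimTruth,
    rng: Optional[np.random.Generator] = None,
) -> CountMatrix:
    """Draw NB gene counts for all six strains and record true log2FCs.

    Counts are NB(mean = baseline x 2^log2FC x size factor) with variance
    mean + dispersion x mean^2; dispersion -> 0 degenerates to Poisson.
    Down-regulated genes are oversampled from the 1-2-intron stratum so
    that their in-stratum share is ``intron12_enrichment`` times the
    background share (capped by availability).
    """
    rng = rng if rng is not None else config.streams()["expression"]
    if config.n_replicates < 2:
        raise SimConfigError("need >=2 replicates per strain")
    gene_ids = [m.gene_id for m in models]
    n = len(gene_ids)
    n_introns = np.array([m.n_introns for m in models])
    in12 = (n_introns >= 1) & (n_introns <= 2)
    idx12 = np.flatnonzero(in12)
    idx_other = np.flatnonzero(~in12)
    f12 = len(idx12) / n if n else 0.0

    baseline = rng.lognormal(np.log(config.baseline_mean), config.baseline_sigma, n)
    lfc = pd.DataFrame(0.0, index=gene_ids, columns=list(KO_STRAINS))
    de = config.de
    for strain in KO_STRAINS:
        frac = de.fraction_affected.get(strain, 0.0)
        n_aff = int(round(frac * n))
        if n_aff == 0:
            continue
        n_down = int(round(de.down_fraction * n_aff))
        n_up = n_aff - n_down
        target12 = min(
            int(round(de.intron12_enrichment * f12 * n_down)), len(idx12), n_down
        )
        down = list(rng.choice(idx12, size=target12, replace=False)) if target12 else []
        n_rest = n_down - target12
        pool = idx_other if n_rest <= len(idx_other) else np.flatnonzero(
            ~np.isin(np.arange(n), down)
        )
        down += list(rng.choice(pool, size=n_rest, replace=False))
        remaining = np.setdiff1d(np.arange(n), np.array(down, dtype=int))
        up = rng.choice(remaining, size=min(n_up, len(remaining)), replace=False)
        lfc.iloc[np.array(down, dtype=int), lfc.columns.get_loc(strain)] = (
            -de.log2fc_magnitude
        )
        lfc.iloc[np.asarray(up, dtype=int), lfc.columns.get_loc(strain)] = (
            de.log2fc_magnitude
        )

    sample_ids, strains, reps = [], [], []
    for strain in STRAINS:
        for r in range(config.n_replicates):
            sample_ids.append(f"{strain}_{r + 1}")
            strains.append(strain)
            reps.append(r + 1)
    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    alpha = config.nb_dispersion
    for j, (sid, strain) in enumerate(zip(sample_ids, strains)):
        sf = rng.lognormal(0.0, 0.12)
        mu = baseline * (
            2.0 ** lfc[strain].values if strain != "WT" else 1.0
        ) * sf
        if alpha < 1e-8:
            counts[:, j] = rng.poisson(mu)
        else:
            counts[:, j] = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=sample_ids)
    samples = pd.DataFrame(
        {"strain": strains, "replicate": reps,
         "library_size": counts_df.sum(axis=0).values},
        index=pd.Index(sample_ids, name="sample"),
    )
    truth.expression = lfc
    truth.genes["baseline_mean"] = baseline
    return CountMatrix(counts=counts_df, samples=samples)


# ---------------------------------------------------------------------------
# 3'-UTR coverage
# ---------------------------------------------------------------------------

def simulate_utr_coverage(
    config: SimConfig,
    models: Sequence[GeneModel],
    truth: SimTruth,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, list[CoverageTrack]]:
    """Per-sample Poisson coverage over each APA gene's 3'-UTR.

    Expected depth is flat at D up to the proximal site and PDUI x D
    beyond it, where PDUI is the true distal-site usage.  Response-class
    genes shift by ``pdui_shift`` in the configured strains: distal_shift
    genes start low (PDUI rises on knockout), proximal_shift genes start
    high (PDUI falls).
    """
    rng = rng if rng is not None else config.streams()["coverage"]
    apa = config.apa
    eligible = []
    for m in models:
        if not m.has_apa_sites:
            continue
        if m.utr3 is None or len(m.utr3) < apa.min_utr_length:
            logger.warning("%s: 3'-UTR shorter than %d nt, skipped",
                           m.gene_id, apa.min_utr_length)
            continue
        eligible.append(m)

    base_pdui = {}
    for m in eligible:
        cls = truth.genes.at[m.gene_id, "apa_class"]
        if cls == "distal_shift":
            base = rng.uniform(0.10, 1.0 - apa.pdui_shift - 0.05)
        elif cls == "proximal_shift":
            base = rng.uniform(apa.pdui_shift + 0.05, 0.90)
        else:
            base = rng.uniform(0.10, 0.90)
        base_pdui[m.gene_id] = base

    apa_rows = []
    for m in eligible:
        cls = truth.genes.at[m.gene_id, "apa_class"]
        for strain in STRAINS:
            p = base_pdui[m.gene_id]
            if strain in apa.shift_strains:
                if cls == "distal_shift":
                    p = p + apa.pdui_shift
                elif cls == "proximal_shift":
                    p = p - apa.pdui_shift
            apa_rows.append({"gene_id": m.gene_id, "strain": strain,
                             "true_pdui": float(np.clip(p, 0.0, 1.0))})
    truth.apa = pd.DataFrame(apa_rows)
    pdui_of = truth.apa.set_index(["gene_id", "strain"])["true_pdui"]

    tracks: dict[str, list[CoverageTrack]] = {}
    for strain in STRAINS:
        for r in range(config.n_replicates):
            sid = f"{strain}_{r + 1}"
            out = []
            for m in eligible:
                p = pdui_of[(m.gene_id, strain)]
                depth_scale = apa.utr_depth * rng.uniform(0.85, 1.15)
                L = len(m.utr3)
                cut = int(truth.genes.at[m.gene_id, "proximal_offset"])
                expect = np.full(L, depth_scale)
                expect[cut:] = p * depth_scale
                tx = rng.poisson(expect).astype(float)
                depth = tx[::-1] if m.strand == "-" else tx
                out.append(CoverageTrack(region=m.utr3, depth=depth,
                                         sample=sid, gene_id=m.gene_id))
            tracks[sid] = out
    return tracks


# ---------------------------------------------------------------------------
# trans-splicing junctions
# ---------------------------------------------------------------------------

def simulate_junctions(
    config: SimConfig,
    models: Sequence[GeneModel],
    truth: SimTruth,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Isoform-specific and common junction counts for trans-spliced genes.

    Common-exon reads are Poisson around ``common_depth``; total
    isoform-specific reads are Poisson around activity x common_depth and
    split multinomially by the true usage proportions.
    """
    rng = rng if rng is not None else config.streams()["junctions"]
    tc = config.trans
    candidates = [m for m in models if m.n_introns >= 1]
    if len(candidates) < tc.n_genes:
        raise SimConfigError("not enough intron-containing genes for trans-splicing")
    chosen = candidates[: tc.n_genes]
    props = np.asarray(tc.proportions, dtype=float)
    rows = []
    truth_rows = []
    for m in chosen:
        donor = m.exons[0].end
        acceptor0 = m.exons[1].start
        for strain in STRAINS:
            activity = tc.activity.get(strain, 1.0)
            for iso_i, prop in enumerate(props):
                truth_rows.append(
                    {"gene_id": m.gene_id, "strain": strain,
                     "isoform": f"{m.gene_id}.iso{iso_i + 1}",
                     "proportion": prop, "activity": activity}
                )
            for r in range(config.n_replicates):
                sid = f"{strain}_{r + 1}"
                common = int(rng.poisson(tc.common_depth))
                total_specific = int(rng.poisson(activity * tc.common_depth))
                specific = rng.multinomial(total_specific, props)
                rows.append({"gene_id": m.gene_id, "sample": sid, "chrom": m.chrom,
                             "donor": donor, "acceptor": acceptor0, "strand": m.strand,
                             "count": common, "label": "common"})
                for iso_i, cnt in enumerate(specific):
                    rows.append(
                        {"gene_id": m.gene_id, "sample": sid, "chrom": m.chrom,
                         "donor": donor, "acceptor": acceptor0 + 10 * (iso_i + 1),
                         "strand": m.strand, "count": int(cnt),
                         "label": f"isoform-specific:{m.gene_id}.iso{iso_i + 1}"}
                    )
    truth.trans = pd.DataFrame(truth_rows)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SimDataset:
    config: SimConfig
    genome: dict[str, str]
    models: list[GeneModel]
    counts: CountMatrix
    coverage: dict[str, list[CoverageTrack]]
    junctions: pd.DataFrame
    truth: SimTruth


def simulate_dataset(config: SimConfig = DEFAULT_CONFIG) -> SimDataset:
    """Run all four generators under one master seed."""
    streams = config.streams()
    genome, models, truth = build_synthetic_genome(config, streams["genome"])
    counts = simulate_expression(config, models, truth, streams["expression"])
    coverage = simulate_utr_coverage(config, models, truth, streams["coverage"])
    junctions = simulate_junctions(config, models, truth, streams["junctions"])
    return SimDataset(config, genome, models, counts, coverage, junctions, truth)


def write_dataset(ds: SimDataset, outdir: str) -> None:
    """Serialize a simulated dataset in the pipeline's on-disk layout."""
    import os

    os.makedirs(os.path.join(outdir, "coverage"), exist_ok=True)
    write_fasta(ds.genome, os.path.join(outdir, "genome.fa"))
    write_annotation(ds.models, os.path.join(outdir, "annotation.gtf"),
                     os.path.join(outdir, "polya.bed"))
    write_counts(ds.counts, os.path.join(outdir, "counts.tsv"),
                 os.path.join(outdir, "samples.tsv"))
    write_junctions(ds.junctions, os.path.join(outdir, "junctions.tsv"))
    for sid, tracks in ds.coverage.items():
        write_bedgraph(tracks, os.path.join(outdir, "coverage", f"{sid}.bedGraph"))
    t = ds.truth
    t.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t")
    t.expression.to_csv(os.path.join(outdir, "truth_expression.tsv"), sep="\t",
                        index_label="gene_id")
    t.apa.to_csv(os.path.join(outdir, "truth_apa.tsv"), sep="\t", index=False)
    t.trans.to_csv(os.path.join(outdir, "truth_trans.tsv"), sep="\t", index=False)
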