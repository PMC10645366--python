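"""Domain types, coordinate conventions, and readers/writers.

All interval arithmetic is 0-based half-open internally.  At the file
boundary the standard dialects apply: GTF is 1-based inclusive, BED and
bedGraph are 0-based half-open.  Minus-strand coverage vectors are stored
in genomic orientation; consumers reverse them when a transcript-oriented
view is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STRAINS = ("WT", "21Ddel", "82Ebdel", "95Cadel", "95Cbdel", "95Ccdel")
"""The six larval RNA-seq conditions: wild type plus five single-U1-gene
deletion strains, named after the deleted locus."""

KO_STRAINS = STRAINS[1:]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# intervals and gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """Exon/intron structure of one gene with optional 3'-UTR and polyA sites.

    ``polya_proximal``/``polya_distal`` are single-base positions; proximal
    means nearer the stop codon, so on the minus strand the proximal
    coordinate is the larger one.  ``gc_fraction`` is filled lazily from the
    genome sequence.
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    utr3: Optional[GenomicInterval] = None
    polya_proximal: Optional[int] = None
    polya_distal: Optional[int] = None
    gc_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not exons:
            raise ValueError(f"{self.gene_id}: gene must have >=1 exon")
        for e in exons:
            if not self.span.contains_interval(e):
                raise ValueError(f"{self.gene_id}: exon {e} outside span {self.span}")
            if e.strand != self.span.strand:
                raise ValueError(f"{self.gene_id}: exon strand mismatch")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons {a} / {b}")
        self.exons = exons
        if self.utr3 is not None and not self.span.contains_interval(self.utr3):
            raise ValueError(f"{self.gene_id}: utr3 outside span")
        self._validate_polya()

    def _validate_polya(self) -> None:
        prox, dist = self.polya_proximal, self.polya_distal
        if (prox is None) != (dist is None):
            raise ValueError(f"{self.gene_id}: need both polyA sites or neither")
        if prox is None:
            return
        if self.utr3 is None:
            raise ValueError(f"{self.gene_id}: polyA sites supplied without a 3'-UTR")
        for name, pos in (("proximal", prox), ("distal", dist)):
            if not self.utr3.contains(pos):
                raise ValueError(
                    f"{self.gene_id}: {name} polyA site {pos} outside 3'-UTR "
                    f"{self.utr3.start}-{self.utr3.end}"
                )
        if self.strand == "+" and not prox < dist:
            raise ValueError(f"{self.gene_id}: expect proximal < distal on + strand")
        if self.strand == "-" and not prox > dist:
            raise ValueError(f"{self.gene_id}: expect proximal > distal on - strand")

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Inter-exon gaps, derived from the exon chain."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def length(self) -> int:
        return len(self.span)

    @property
    def has_apa_sites(self) -> bool:
        return self.polya_proximal is not None


# ---------------------------------------------------------------------------
# U1 locus registry
# ---------------------------------------------------------------------------

U1_LENGTH = 164
"""Length of the mature U1 snRNA in nucleotides."""


@dataclass(frozen=True)
class U1Variant:
    """Single-base difference from the canonical U1 snRNA (1-based position)."""

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= U1_LENGTH:
            raise ValueError("variant position outside the 164-nt U1 snRNA")


@dataclass(frozen=True)
class U1Locus:
    name: str
    chrom: str
    variant: Optional[U1Variant] = None


def u1_registry() -> tuple[U1Locus, ...]:
    """The five Drosophila melanogaster U1 snRNA genes.

    21D sits on chromosome arm 2L; the other four loci cluster on 3R.  The
    snRNAs transcribed from 21D, 95Ca and 95Cb are identical (the canonical
    U1); 95Cc carries a U-to-C change at position 123 and 82Eb a G-to-U
    change at position 134, both in or near the Sm-protein binding site.
    """
    return (
        U1Locus("21D", "2L"),
        U1Locus("82Eb", "3R", U1Variant(134, "G", "U")),
        U1Locus("95Ca", "3R"),
        U1Locus("95Cb", "3R"),
        U1Locus("95Cc", "3R", U1Variant(123, "U", "C")),
    )


def u1_locus(name: str) -> U1Locus:
    for locus in u1_registry():
        if locus.name == name:
            return locus
    raise KeyError(f"unknown U1 locus {name!r}")


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene x sample integer counts plus a sample sheet.

    ``counts`` is indexed by gene_id with one column per sample id;
    ``samples`` is indexed by sample id with columns ``strain`` and
    ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample sheet rows disagree")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.samples["strain"].isna().any():
            raise ValueError("every sample needs a strain label")

    def samples_for(self, strain: str) -> list[str]:
        hits = list(self.samples.index[self.samples["strain"] == strain])
        if not hits:
            raise KeyError(f"strain {strain!r} absent from sample sheet")
        return hits

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.samples["strain"]))


def write_counts(cm: CountMatrix, counts_path: str, samples_path: str) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_counts(counts_path: str, samples_path: str) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    samples.index = samples.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountMatrix(counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Per-base depth over one region for one sample, genomic orientation."""

    region: GenomicInterval
    depth: np.ndarray
    sample: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if len(self.depth) != len(self.region):
            raise ValueError("depth vector length != region length")
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def transcript_oriented(self) -> np.ndarray:
        """Depth vector running 5'->3' along the transcript."""
        return self.depth[::-1] if self.region.strand == "-" else self.depth


def write_bedgraph(tracks: Iterable[CoverageTrack], path: str) -> None:
    """Run-length encode tracks to bedGraph (zero runs are omitted)."""
    rows = []
    for t in sorted(tracks, key=lambda t: (t.region.chrom, t.region.start)):
        d = t.depth
        # boundaries of constant runs
        changes = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate([[0], changes])
        ends = np.concatenate([changes, [len(d)]])
        for s, e in zip(starts, ends):
            v = d[s]
            if v != 0:
                rows.append(
                    (t.region.chrom, t.region.start + s, t.region.start + e, v)
                )
    with open(path, "w") as fh:
        for chrom, s, e, v in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def load_coverage(
    bedgraph_path: str,
    regions: Sequence[GenomicInterval],
    samples: Optional[Sequence[str]] = None,
    sample: str = "",
    gene_ids: Optional[Sequence[str]] = None,
) -> list[CoverageTrack]:
    """Expand a bedGraph to per-base tracks over the requested regions.

    Bases absent from the bedGraph get depth 0.  Overlapping bedGraph
    intervals and regions on chromosomes the file knows nothing about (when
    the file is non-empty for that chromosome) are rejected.
    """
    try:
        bg = pd.read_csv(
            bedgraph_path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        bg = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, grp in bg.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
            raise ValueError(f"overlapping bedGraph intervals on {chrom}")
        by_chrom[str(chrom)] = grp
    tracks = []
    for i, region in enumerate(regions):
        depth = np.zeros(len(region), dtype=float)
        grp = by_chrom.get(region.chrom)
        if grp is not None:
            sel = grp[(grp["end"] > region.start) & (grp["start"] < region.end)]
            for s, e, v in sel[["start", "end", "value"]].itertuples(index=False):
                lo = max(int(s), region.start) - region.start
                hi = min(int(e), region.end) - region.start
                depth[lo:hi] += v
        tracks.append(
            CoverageTrack(
                region=region,
                depth=depth,
                sample=sample,
                gene_id=gene_ids[i] if gene_ids is not None else None,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(genome[name]), id=name, description="") for name in genome
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    """Whole-genome read into memory (synthetic genomes are small)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def get_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Slice [start, end) out of a dict genome or a pyfaidx.Fasta."""
    if isinstance(genome, Mapping):
        seq = genome[chrom]
        if end > len(seq):
            raise ValueError(f"{chrom}: requested {end} beyond length {len(seq)}")
        return seq[start:end]
    rec = genome[chrom]
    if end > len(rec):
        raise ValueError(f"{chrom}: requested {end} beyond length {len(rec)}")
    return str(rec[start:end])


def gc_fraction(genome, model: GeneModel) -> float:
    """G+C fraction over the full gene span (TSS to TES)."""
    seq = get_sequence(genome, model.chrom, model.span.start, model.span.end).upper()
    if not seq:
        raise ValueError(f"{model.gene_id}: empty sequence")
    gc = seq.count("G") + seq.count("C")
    return gc / len(seq)


# ---------------------------------------------------------------------------
# GTF + polyA BED annotation
# ---------------------------------------------------------------------------

def write_annotation(models: Iterable[GeneModel], gtf_path: str, bed_path: str) -> None:
    """Write gene models as GTF 2.2 plus a BED6 of polyA sites.

    The BED name field tags each site as ``<gene_id>|proximal`` or
    ``<gene_id>|distal``.
    """
    with open(gtf_path, "w") as gtf:
        for m in sorted(models, key=lambda m: (m.chrom, m.span.start)):
            attrs = f'gene_id "{m.gene_id}";'
            tattrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
            gtf.write(
                f"{m.chrom}\tu1seq\tgene\t{m.span.start + 1}\t{m.span.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            for e in m.exons:
                gtf.write(
                    f"{m.chrom}\tu1seq\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{m.strand}\t.\t{tattrs}\n"
                )
            if m.utr3 is not None:
                gtf.write(
                    f"{m.chrom}\tu1seq\tthree_prime_utr\t{m.utr3.start + 1}\t"
                    f"{m.utr3.end}\t.\t{m.strand}\t.\t{tattrs}\n"
                )
    with open(bed_path, "w") as bed:
        for m in sorted(models, key=lambda m: (m.chrom, m.span.start)):
            if not m.has_apa_sites:
                continue
            for tag, pos in (("proximal", m.polya_proximal), ("distal", m.polya_distal)):
                bed.write(
                    f"{m.chrom}\t{pos}\t{pos + 1}\t{m.gene_id}|{tag}\t0\t{m.strand}\n"
                )


def read_polya_bed(bed_path: str) -> dict[str, dict[str, int]]:
    """BED6 -> {gene_id: {"proximal": pos, "distal": pos}}."""
    sites: dict[str, dict[str, int]] = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"polyA BED needs 6 columns, got {len(fields)}")
            name = fields[3]
            try:
                gene_id, tag = name.rsplit("|", 1)
            except ValueError:
                raise ValueError(f"polyA BED name {name!r} not <gene>|proximal/distal")
            if tag not in ("proximal", "distal"):
                raise ValueError(f"polyA BED tag {tag!r} not proximal/distal")
            sites.setdefault(gene_id, {})[tag] = int(fields[1])
    return sites


def load_annotation(
    gtf_path: str, polya_bed_path: Optional[str] = None, genome=None
) -> list[GeneModel]:
    """Read gene models from GTF, attach polyA sites from BED6.

    Genes with overlapping exons are rejected with a logged diagnostic; a
    polyA site outside the gene's 3'-UTR raises.  If ``genome`` is given,
    gc_fraction is filled in.  Genes lacking an annotated three_prime_utr
    that also have polyA sites get the UTR inferred as the terminal stretch
    of the last exon covering both sites; without polyA sites they are
    simply left UTR-less (and are skipped by APA analysis).
    """
    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    polya = read_polya_bed(polya_bed_path) if polya_bed_path else {}
    models: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = g.attributes["gene_id"][0]
        span = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        exons = []
        utr = None
        for child in db.region(seqid=g.seqid, start=g.start, end=g.end):
            if child.attributes.get("gene_id", [None])[0] != gene_id:
                continue
            iv = GenomicInterval(child.seqid, child.start - 1, child.end, child.strand)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "three_prime_utr":
                utr = iv
        sites = polya.get(gene_id, {})
        kwargs = {}
        if sites:
            if set(sites) != {"proximal", "distal"}:
                raise ValueError(f"{gene_id}: polyA BED must tag proximal and distal")
            if utr is None:
                utr = _infer_utr3(span, exons, sites)
            kwargs = dict(
                polya_proximal=sites["proximal"], polya_distal=sites["distal"]
            )
        try:
            model = GeneModel(
                gene_id=gene_id, span=span, exons=tuple(exons), utr3=utr, **kwargs
            )
        except ValueError as err:
            if "overlapping exons" in str(err):
                logger.warning("rejecting gene %s: %s", gene_id, err)
                continue
            raise
        if genome is not None:
            model.gc_fraction = gc_fraction(genome, model)
        models.append(model)
    return models


def _infer_utr3(
    span: GenomicInterval, exons: Sequence[GenomicInterval], sites: Mapping[str, int]
) -> GenomicInterval:
    """Fallback 3'-UTR: terminal stretch of the last exon covering both sites."""
    exons = sorted(exons, key=lambda e: e.start)
    if span.strand == "+":
        last = exons[-1]
        start = min(sites.values())
        return GenomicInterval(span.chrom, min(start, last.end - 1), last.end, "+")
    last = exons[0]
    end = max(sites.values()) + 1
    return GenomicInterval(span.chrom, last.start, max(end, last.start + 1), "-")


# ---------------------------------------------------------------------------
# junctions and qPCR tables
# ---------------------------------------------------------------------------

JUNCTION_COLUMNS = [
    "gene_id", "sample", "chrom", "donor", "acceptor", "strand", "count", "label",
]


def validate_junctions(df: pd.DataFrame) -> pd.DataFrame:
    """Check the junction-table contract; returns the validated frame."""
    missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"junction table missing columns {missing}")
    if (df["count"] < 0).any():
        raise ValueError("negative junction counts")
    if (df["donor"] == df["acceptor"]).any():
        raise ValueError("junction with donor == acceptor")
    ok = df["label"].eq("common") | df["label"].str.startswith("isoform-specific:")
    if not ok.all():
        bad = df.loc[~ok, "label"].iloc[0]
        raise ValueError(f"bad junction label {bad!r}")
    return df


def write_junctions(df: pd.DataFrame, path: str) -> None:
    validate_junctions(df)[JUNCTION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_junctions(path: str) -> pd.DataFrame:
    return validate_junctions(pd.read_csv(path, sep="\t", dtype={"sample": str}))


MAX_CT = 40.0


def read_ct_table(path: str) -> pd.DataFrame:
    """TSV of qPCR cycle-threshold values: sample, target, ct (all ct < 40)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "target": str})
    missing = [c for c in ("sample", "target", "ct") if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    if (df["ct"] >= MAX_CT).any():
        bad = df[df["ct"] >= MAX_CT].iloc[0]
        raise ValueError(
            f"Ct {bad['ct']} for {bad['target']}/{bad['sample']} is >= "
            f"{MAX_CT:g} cycles"
        )
    return df
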