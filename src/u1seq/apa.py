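"""3'-UTR alternative polyadenylation from per-base coverage.

The percentage of distal polyA-site usage (PDUI) is estimated per sample
from 3'-UTR coverage with an exhaustive two-mean change-point fit: reads
upstream of the proximal cleavage site come from both the short and the
long isoform, reads downstream only from the long one, so the ratio of the
downstream to the upstream segment mean is the distal-usage fraction.
DeltaPDUI (knockout minus wild type) events are screened at
|DeltaPDUI| > 0.25 and FDR < 0.05; DeltaPDUI > 0 favors the distal site,
DeltaPDUI < 0 the proximal site.

U1-binding sites are modelled as 5' splice-site-like 9-mers (three exonic
bases followed by a six-base intron start with the invariant GT) and
counted in +/-200-nt windows around both polyA sites of each event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, welch_t_p
from .core_io import CoverageTrack, GeneModel, get_sequence, revcomp

logger = logging.getLogger(__name__)

DELTA_PDUI_THRESHOLD = 0.25
APA_FDR_THRESHOLD = 0.05
U1_WINDOW = 200  # nt either side of a polyA site


# ---------------------------------------------------------------------------
# PDUI estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PduiEstimate:
    """Two-segment fit of one 3'-UTR coverage track.

    ``breakpoint`` is transcript-oriented (nt from the UTR 5' end);
    ``pdui`` = clamp(mean_after / mean_before, 0, 1).  ``degenerate`` marks
    flat tracks where the fit found no drop (pdui forced to 1).
    """

    gene_id: str
    sample: str
    breakpoint: int
    pdui: float
    mean_before: float
    mean_after: float
    degenerate: bool = False


def two_mean_breakpoint(depth: np.ndarray) -> tuple[int, float, float]:
    """Exhaustive RSS minimization of a two-mean piecewise-constant fit.

    Returns (breakpoint, mean_before, mean_after) over interior breakpoints
    1..L-1; ties break toward the most proximal (smallest) breakpoint.
    """
    d = np.asarray(depth, dtype=float)
    L = len(d)
    if L < 2:
        raise ValueError("need at least 2 bases to fit a breakpoint")
    csum = np.cumsum(d)
    csq = np.cumsum(d * d)
    b = np.arange(1, L)
    s1, q1 = csum[b - 1], csq[b - 1]
    s2, q2 = csum[-1] - s1, csq[-1] - q1
    rss = (q1 - s1 * s1 / b) + (q2 - s2 * s2 / (L - b))
    i = int(np.argmin(rss))  # argmin takes the first minimum: proximal tie-break
    bp = int(b[i])
    return bp, float(s1[i] / bp), float(s2[i] / (L - bp))


def estimate_pdui(
    track: CoverageTrack,
    min_mean_depth: float = 5.0,
    min_utr_length: int = 100,
) -> Optional[PduiEstimate]:
    """Estimate PDUI for one sample's 3'-UTR track.

    Tracks below the mean-depth floor, shorter than the UTR length floor,
    or all zero are skipped (None).  The fit runs on the transcript-
    oriented depth vector, so minus-strand tracks are reversed first.
    """
    d = track.transcript_oriented()
    if len(d) < min_utr_length:
        logger.warning("%s/%s: UTR shorter than %d nt, skipped",
                       track.gene_id, track.sample, min_utr_length)
        return None
    if not d.any():
        logger.warning("%s/%s: all-zero coverage, skipped",
                       track.gene_id, track.sample)
        return None
    if d.mean() < min_mean_depth:
        logger.warning("%s/%s: mean depth %.2f below floor %.2f, skipped",
                       track.gene_id, track.sample, d.mean(), min_mean_depth)
        return None
    bp, before, after = two_mean_breakpoint(d)
    degenerate = after >= before
    pdui = 1.0 if degenerate else float(np.clip(after / before, 0.0, 1.0))
    return PduiEstimate(
        gene_id=track.gene_id or "", sample=track.sample, breakpoint=bp,
        pdui=pdui, mean_before=before, mean_after=after, degenerate=degenerate,
    )


def estimates_frame(estimates: Iterable[Optional[PduiEstimate]]) -> pd.DataFrame:
    rows = [
        {"gene_id": e.gene_id, "sample": e.sample, "breakpoint": e.breakpoint,
         "pdui": e.pdui, "mean_before": e.mean_before, "mean_after": e.mean_after,
         "degenerate": e.degenerate}
        for e in estimates if e is not None
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "sample", "breakpoint", "pdui",
                       "mean_before", "mean_after", "degenerate"],
    )


# ---------------------------------------------------------------------------
# event calling
# ---------------------------------------------------------------------------

def call_apa_events(
    estimates: pd.DataFrame,
    samples: pd.DataFrame,
    strain: str,
    reference: str = "WT",
    delta_threshold: float = DELTA_PDUI_THRESHOLD,
    fdr_threshold: float = APA_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene DeltaPDUI events for one deletion strain against wild type.

    DeltaPDUI is the difference of replicate-mean PDUIs (KO - WT); the
    p-value is a two-sided Welch t-test on replicate PDUIs, BH-adjusted
    across genes.  direction: distal iff DeltaPDUI > threshold and
    FDR < fdr_threshold, proximal iff DeltaPDUI < -threshold and FDR <
    fdr_threshold, else ns.  Genes with fewer than two replicate estimates
    in either group are skipped.
    """
    strain_of = samples["strain"]
    est = estimates.merge(
        strain_of.rename("strain"), left_on="sample", right_index=True
    )
    rows = []
    for gene_id, grp in est.groupby("gene_id", sort=True):
        wt = grp.loc[grp["strain"] == reference, "pdui"].values
        ko = grp.loc[grp["strain"] == strain, "pdui"].values
        if len(wt) < 2 or len(ko) < 2:
            logger.warning("%s: <2 replicate PDUI estimates, skipped", gene_id)
            continue
        delta = float(ko.mean() - wt.mean())
        rows.append({"gene_id": gene_id, "pdui_wt": float(wt.mean()),
                     "pdui_ko": float(ko.mean()), "delta_pdui": delta,
                     "p": welch_t_p(ko, wt)})
    events = pd.DataFrame(
        rows, columns=["gene_id", "pdui_wt", "pdui_ko", "delta_pdui", "p"]
    )
    events["fdr"] = bh_adjust(events["p"]) if len(events) else []
    sig = events["fdr"] < fdr_threshold
    events["direction"] = "ns"
    events.loc[sig & (events["delta_pdui"] > delta_threshold), "direction"] = "distal"
    events.loc[sig & (events["delta_pdui"] < -delta_threshold), "direction"] = "proximal"
    events["strain"] = strain
    return events


def classify_event_region(event_gene: str, model: Optional[GeneModel]) -> str:
    """three_prime_utr if both polyA sites fall inside the annotated 3'-UTR,
    else terminal_exon_intron (also used when the UTR is missing)."""
    if model is None or model.utr3 is None or not model.has_apa_sites:
        logger.warning("%s: missing 3'-UTR or polyA sites; classifying as "
                       "terminal_exon_intron", event_gene)
        return "terminal_exon_intron"
    if model.utr3.contains(model.polya_proximal) and model.utr3.contains(
        model.polya_distal
    ):
        return "three_prime_utr"
    return "terminal_exon_intron"


# ---------------------------------------------------------------------------
# U1-binding-site scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifConfig:
    """U1-binding-site (5'SS-like) motif definition.

    ``consensus`` is the 9-mer exon(-3..-1)|intron(+1..+6) consensus with
    the invariant GT at intron positions +1/+2 (string indices
    ``gt_start``, ``gt_start+1``).  In the default consensus mode a hit
    requires the GT exactly and at most ``max_mismatch`` mismatches over
    the remaining positions.  In ``pwm`` mode hits are windows whose
    log-odds score meets ``pwm_threshold``.
    """

    consensus: str = "CAGGTAAGT"
    gt_start: int = 3
    max_mismatch: int = 1
    mode: str = "consensus"  # or "pwm"
    pwm: Optional[tuple[tuple[float, ...], ...]] = None  # len x 4 (ACGT) log-odds
    pwm_threshold: float = 0.0

    def __post_init__(self) -> None:
        c = self.consensus.upper()
        if self.mode == "consensus" and c[self.gt_start : self.gt_start + 2] != "GT":
            raise ValueError("consensus must carry GT at the invariant positions")
        if self.mode not in ("consensus", "pwm"):
            raise ValueError(f"unknown motif mode {self.mode!r}")
        if self.mode == "pwm" and self.pwm is None:
            raise ValueError("pwm mode needs a matrix")


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based start on the sense strand
    mismatches: int
    score: float


_PWM_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def scan_u1_sites(sequence: str, motif_config: MotifConfig) -> list[MotifHit]:
    """Scan a sense-strand sequence for U1-binding sites, left to right."""
    seq = sequence.upper()
    cfg = motif_config
    m = len(cfg.consensus) if cfg.mode == "consensus" else len(cfg.pwm)
    n = len(seq) - m + 1
    if n <= 0:
        return []
    a = np.frombuffer(seq.encode(), dtype="S1")
    if cfg.mode == "pwm":
        score = np.zeros(n)
        for i, col in enumerate(cfg.pwm):
            window = a[i : i + n]
            col_scores = np.full(len(window), -np.inf)
            for base, j in _PWM_INDEX.items():
                col_scores[window == base.encode()] = col[j]
            score += col_scores
        return [
            MotifHit(int(p), 0, float(score[p]))
            for p in np.flatnonzero(score >= cfg.pwm_threshold)
        ]
    cons = cfg.consensus.upper()
    gt = cfg.gt_start
    mm = np.zeros(n, dtype=int)
    for i, base in enumerate(cons):
        if i in (gt, gt + 1):
            continue
        mm += a[i : i + n] != base.encode()
    gt_ok = (a[gt : gt + n] == b"G") & (a[gt + 1 : gt + 1 + n] == b"T")
    hits = np.flatnonzero(gt_ok & (mm <= cfg.max_mismatch))
    n_free = m - 2
    return [MotifHit(int(p), int(mm[p]), float(n_free - mm[p])) for p in hits]


@dataclass(frozen=True)
class U1WindowCounts:
    gene_id: str
    n_proximal_window: int
    n_distal_window: int


def sense_hit_positions(
    genome, chrom: str, lo: int, hi: int, strand: str, motif_config: MotifConfig,
    chrom_length: Optional[int] = None,
) -> list[int]:
    """Genomic sense-strand start positions of motif hits within [lo, hi)."""
    lo = max(0, lo)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    raw = get_sequence(genome, chrom, lo, hi)
    sense = raw if strand == "+" else revcomp(raw)
    hits = scan_u1_sites(sense, motif_config)
    if strand == "+":
        return [lo + h.position for h in hits]
    return [hi - 1 - h.position for h in hits]


def window_site_counts(
    gene_id: str,
    genome,
    model: GeneModel,
    window: int = U1_WINDOW,
    motif_config: MotifConfig = MotifConfig(),
) -> U1WindowCounts:
    """Count motif hits whose sense start lies within +/-window of each
    polyA site.  Windows are truncated at chromosome ends; a hit inside
    both windows (sites closer than 2 x window) is counted in both."""
    chrom_len = len(genome[model.chrom])
    m = len(motif_config.consensus) if motif_config.mode == "consensus" else len(
        motif_config.pwm
    )
    counts = []
    for site in (model.polya_proximal, model.polya_distal):
        starts = sense_hit_positions(
            genome, model.chrom, site - window - m, site + window + m + 1,
            model.strand, motif_config, chrom_length=chrom_len,
        )
        counts.append(sum(site - window <= s <= site + window for s in starts))
    return U1WindowCounts(gene_id, counts[0], counts[1])


def compare_site_ratios(
    events: pd.DataFrame, window_counts: Mapping[str, U1WindowCounts],
    min_group: int = 5,
) -> pd.DataFrame:
    """Proximal- vs distal-window U1-site load per event direction group.

    For each group (distal-activated: direction == distal; proximal-
    activated: direction == proximal) reports the aggregate hit ratio
    sum(proximal window) / sum(distal window), a Haldane-smoothed version
    (+0.5 to both sums, finite when a side is empty), and a Wilcoxon
    signed-rank test on the per-event (proximal - distal) differences.
    Groups below ``min_group`` events are flagged low-n without a p-value.
    """
    rows = []
    for group, direction in (("distal_activated", "distal"),
                             ("proximal_activated", "proximal")):
        genes = events.loc[events["direction"] == direction, "gene_id"]
        wc = [window_counts[g] for g in genes if g in window_counts]
        n = len(wc)
        prox = np.array([w.n_proximal_window for w in wc], dtype=float)
        dist = np.array([w.n_distal_window for w in wc], dtype=float)
        sum_p, sum_d = prox.sum(), dist.sum()
        ratio = sum_p / sum_d if sum_d > 0 else np.inf if sum_p > 0 else np.nan
        smoothed = (sum_p + 0.5) / (sum_d + 0.5)
        diffs = prox - dist
        low_n = n < min_group
        p = np.nan
        if not low_n and np.any(diffs != 0):
            p = float(stats.wilcoxon(diffs, zero_method="wilcox",
                                     method="approx").pvalue)
        elif not low_n:
            p = 1.0  # all paired differences zero: no asymmetry
        rows.append({"group": group, "n_events": n,
                     "sum_proximal": int(sum_p), "sum_distal": int(sum_d),
                     "ratio": ratio, "ratio_smoothed": smoothed,
                     "mean_paired_diff": float(diffs.mean()) if n else np.nan,
                     "wilcoxon_p": p, "low_n": low_n})
    return pd.DataFrame(rows)


def distal_common_ratio(
    expr_distal: float, expr_common: float, wt_distal: float, wt_common: float
) -> float:
    """Relative distal-site selection: (KO distal/common) / (WT distal/common).

    The distal amplicon covers only the long 3'-UTR isoform; the common
    amplicon covers both isoforms, so the double ratio is the WT-normalized
    distal selection.
    """
    if min(expr_common, wt_common, wt_distal) <= 0:
        raise ValueError("distal/common ratio undefined: zero denominator")
    return (expr_distal / expr_common) / (wt_distal / wt_common)
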