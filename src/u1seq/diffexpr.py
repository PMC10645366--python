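"""Differential expression screening of knockout vs wild-type counts.

Counts are normalized by median-of-ratios size factors.  The per-gene test
is a simplified negative-binomial contrast: method-of-moments dispersions
are pooled across replicate groups and then across genes (median within
mean-quantile bins, so a noisy 3-replicate estimate borrows strength from
genes of similar expression), and feed a Wald statistic on the log ratio
of normalized group means with a delta-method standard error.  When the
sample variance does not exceed the mean the dispersion estimate collapses
to zero, i.e. the Poisson limit.  This is not a reimplementation of any
published DE package; the downstream screen is the published rule: fold
change > 2 and FDR < 0.05.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .core_io import CountMatrix

FC_THRESHOLD = 2.0
DE_FDR_THRESHOLD = 0.05
PSEUDOCOUNT = 0.5
MIN_BASE_MEAN = 1.0  # normalized mean floor defining the "transcribed" background


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    The reference is the per-gene geometric mean across samples; genes with
    a zero in any sample are excluded from the reference set.
    """
    log_counts = np.log(counts.where(counts > 0))
    log_geo = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo) & log_counts.notna().all(axis=1)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = counts.loc[usable].div(np.exp(log_geo[usable]), axis=0)
    return ratios.median(axis=0).rename("size_factor")


def normalized_counts(cm: CountMatrix) -> pd.DataFrame:
    return cm.counts.div(size_factors(cm.counts), axis=1)


def pooled_dispersion(
    per_gene_alpha: np.ndarray, base_mean: np.ndarray, n_bins: int = 20,
    min_genes_per_bin: int = 5,
) -> np.ndarray:
    """Pool method-of-moments dispersions across genes.

    Genes are split into ``n_bins`` mean-quantile bins and each gene gets
    the median raw dispersion of its bin (a trended estimate); with too few
    genes for binning a single global median is used.
    """
    n = len(per_gene_alpha)
    if n >= n_bins * min_genes_per_bin:
        alpha = np.empty(n)
        for idx in np.array_split(np.argsort(base_mean, kind="stable"), n_bins):
            alpha[idx] = np.median(per_gene_alpha[idx])
        return alpha
    return np.full(n, np.median(per_gene_alpha) if n else 0.0)


def test_de(
    cm: CountMatrix,
    strain: str,
    reference: str = "WT",
    min_base_mean: float = MIN_BASE_MEAN,
) -> pd.DataFrame:
    """Per-gene knockout-vs-wild-type NB test for one strain.

    Returns a frame (gene_id index) with base_mean, log2fc
    (log2((KO+0.5)/(WT+0.5)) on normalized means), p and BH fdr.  Genes
    whose normalized base mean falls below ``min_base_mean`` are excluded
    from testing (tested=False, p NaN, fdr 1).
    """
    ko_cols = cm.samples_for(strain)
    wt_cols = cm.samples_for(reference)
    if len(ko_cols) < 2 or len(wt_cols) < 2:
        raise ValueError("need >=2 replicates per group")
    norm = cm.counts[wt_cols + ko_cols].div(
        size_factors(cm.counts)[wt_cols + ko_cols], axis=1
    )
    wt = norm[wt_cols].values
    ko = norm[ko_cols].values
    n1, n2 = wt.shape[1], ko.shape[1]
    m1, m2 = wt.mean(1), ko.mean(1)
    v1, v2 = wt.var(1, ddof=1), ko.var(1, ddof=1)
    base_mean = norm.mean(1).values

    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(m1 > 0, np.maximum(0.0, (v1 - m1) / m1**2), 0.0)
        a2 = np.where(m2 > 0, np.maximum(0.0, (v2 - m2) / m2**2), 0.0)
    raw_alpha = ((n1 - 1) * a1 + (n2 - 1) * a2) / (n1 + n2 - 2)
    alpha = pooled_dispersion(raw_alpha, base_mean)

    log_ratio = np.log(m2 + PSEUDOCOUNT) - np.log(m1 + PSEUDOCOUNT)
    se = np.sqrt(
        1.0 / (n1 * (m1 + PSEUDOCOUNT)) + alpha / n1
        + 1.0 / (n2 * (m2 + PSEUDOCOUNT)) + alpha / n2
    )
    z = log_ratio / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    tested = base_mean >= min_base_mean
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log_ratio / np.log(2.0),
            "p": np.where(tested, p, np.nan),
            "tested": tested,
        },
        index=cm.counts.index,
    )
    out["fdr"] = bh_adjust(out["p"])
    out.loc[~tested, "fdr"] = 1.0
    return out


def screen_degs(
    results: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    fdr_threshold: float = DE_FDR_THRESHOLD,
) -> dict[str, set[str]]:
    """Apply the DEG screen: fold change > fc_threshold and FDR < fdr_threshold.

    Returns {"down": set of gene ids, "up": set of gene ids}.
    """
    lfc_cut = np.log2(fc_threshold)
    sig = results["fdr"] < fdr_threshold
    down = set(results.index[sig & (results["log2fc"] < -lfc_cut)])
    up = set(results.index[sig & (results["log2fc"] > lfc_cut)])
    return {"down": down, "up": up}


def add_calls(results: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Annotate a DE results frame with a call column in {down, up, ns}."""
    sets = screen_degs(results, **kwargs)
    out = results.copy()
    out["call"] = "ns"
    out.loc[list(sets["down"]), "call"] = "down"
    out.loc[list(sets["up"]), "call"] = "up"
    return out


def overlap_sets(deg_sets: Mapping[str, set[str]]) -> dict:
    """Partition the union of per-strain DEG sets by membership multiplicity.

    Returns ``common`` (in every strain's set), ``unique`` (per strain: in
    exactly that one), and ``by_multiplicity`` ({k: genes in exactly k
    sets}).  Every gene in the union lands in exactly one multiplicity
    class.
    """
    strains = list(deg_sets)
    union = set().union(*deg_sets.values()) if deg_sets else set()
    multiplicity = {
        g: sum(g in deg_sets[s] for s in strains) for g in union
    }
    by_mult: dict[int, set[str]] = {}
    for g, k in multiplicity.items():
        by_mult.setdefault(k, set()).add(g)
    common = by_mult.get(len(strains), set()) if strains else set()
    unique = {
        s: {g for g in deg_sets[s] if multiplicity[g] == 1} for s in strains
    }
    return {"common": common, "unique": unique, "by_multiplicity": by_mult}
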