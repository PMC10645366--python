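"""Gene-feature stratification and DEG enrichment tests.

Genes are binned by intron count (0, 1-2, >=3), gene length (< 2 kb vs
>= 2 kb), mean intron length (< 0.5 kb vs >= 0.5 kb, intronless apart) and
GC content (quantile bins, default quartiles).  Each DEG set is tested per
bin against the transcribed-gene background with a two-sided Fisher exact
test on the 2x2 table (in-bin vs out-of-bin x DEG vs non-DEG background),
BH-adjusted within a feature.  Down- and up-regulated sets are analyzed
separately.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .core_io import GeneModel

INTRON_BINS = ("0", "1-2", ">=3")
LENGTH_BINS = ("<2kb", ">=2kb")
INTRON_LENGTH_BINS = ("<0.5kb", ">=0.5kb", "no-intron")
GENE_LENGTH_CUT = 2000  # nt
INTRON_LENGTH_CUT = 500  # nt, applied to the mean intron length of a gene
FEATURES = ("intron_count", "gene_length", "intron_length", "gc")


def _intron_bin(k: int) -> str:
    if k == 0:
        return "0"
    return "1-2" if k <= 2 else ">=3"


def stratify_genes(
    models: Iterable[GeneModel], gc_quantiles: int = 4
) -> pd.DataFrame:
    """One row per gene with its bin for every feature.

    Gene length is the span (TSS to TES); the intron-length feature uses
    the mean intron length of the gene.  GC bins are quantile bins over the
    genes with a known gc_fraction ("na" otherwise).
    """
    rows = []
    for m in models:
        mean_intron = (
            float(np.mean([len(i) for i in m.introns])) if m.n_introns else np.nan
        )
        rows.append(
            {
                "gene_id": m.gene_id,
                "n_introns": m.n_introns,
                "length": m.length,
                "mean_intron_length": mean_intron,
                "gc_fraction": m.gc_fraction,
                "intron_count": _intron_bin(m.n_introns),
                "gene_length": "<2kb" if m.length < GENE_LENGTH_CUT else ">=2kb",
                "intron_length": (
                    "no-intron"
                    if m.n_introns == 0
                    else "<0.5kb" if mean_intron < INTRON_LENGTH_CUT else ">=0.5kb"
                ),
            }
        )
    strata = pd.DataFrame(rows).set_index("gene_id")
    gc = strata["gc_fraction"]
    strata["gc"] = "na"
    known = gc.notna()
    if known.sum() >= gc_quantiles:
        codes = pd.Series(
            pd.qcut(gc[known], gc_quantiles, labels=False, duplicates="drop"),
            index=gc[known].index,
        ).fillna(0)  # all-identical values collapse to a single bin
        strata.loc[known, "gc"] = "q" + (codes + 1).astype(int).astype(str)
    return strata


def enrichment_test(
    deg_set: set[str],
    background: set[str],
    strata: pd.DataFrame,
    feature: str,
) -> pd.DataFrame:
    """Fisher exact enrichment of a DEG set per bin of one feature.

    ``deg_set`` must be a subset of ``background``.  The odds ratio uses a
    Haldane correction (+0.5 per cell) whenever a cell is zero; with an
    empty DEG set every row gets p = 1 and a flagged undefined OR.
    """
    if not deg_set <= background:
        raise ValueError("deg_set must be a subset of the background")
    bins = strata.loc[sorted(background), feature]
    deg_bins = bins.loc[sorted(deg_set)]
    n_bg, n_deg = len(background), len(deg_set)
    rows = []
    for bin_label in bins.unique():
        n_bg_in = int((bins == bin_label).sum())
        n_deg_in = int((deg_bins == bin_label).sum())
        table = np.array(
            [
                [n_deg_in, n_deg - n_deg_in],
                [n_bg_in - n_deg_in, (n_bg - n_deg) - (n_bg_in - n_deg_in)],
            ]
        )
        if n_deg == 0:
            p, odds = 1.0, np.nan
        elif n_deg == n_bg:
            # the DEG set is the whole background: trivially unenriched
            p, odds = 1.0, 1.0
        else:
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            if (table == 0).any():
                t = table + 0.5
                odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
            else:
                odds = float(
                    table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0])
                )
        rows.append(
            {
                "feature": feature,
                "bin": bin_label,
                "n_deg_in_bin": n_deg_in,
                "n_deg": n_deg,
                "n_bg_in_bin": n_bg_in,
                "n_bg": n_bg,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).sort_values("bin").reset_index(drop=True)
    out["fdr"] = bh_adjust(out["p"])
    return out


def enrichment_report(
    deg_sets: dict[str, set[str]],
    background: set[str],
    strata: pd.DataFrame,
    features: Sequence[str] = FEATURES,
) -> pd.DataFrame:
    """All features x directions for one strain's down/up DEG sets."""
    frames = []
    for direction, genes in deg_sets.items():
        for feature in features:
            t = enrichment_test(genes & background, background, strata, feature)
            t.insert(0, "direction", direction)
            frames.append(t)
    return pd.concat(frames, ignore_index=True)


def density_table(
    strata: pd.DataFrame, genes: set[str], column: str, bins: int = 30
) -> pd.DataFrame:
    """Histogram-density export of a numeric gene feature for plotting."""
    values = strata.loc[sorted(genes & set(strata.index)), column].dropna()
    hist, edges = np.histogram(values, bins=bins, density=True)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": hist}
    )
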