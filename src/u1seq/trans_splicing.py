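"""Trans-splicing isoform usage from isoform-specific junction reads.

Usage of isoform i is its specific junction count divided by the gene's
common-exon junction count; per-million sequencing depth cancels in that
ratio, so CPM of the specific reads is reported alongside purely for
cross-sample context.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from ._stats import bh_adjust, welch_t_p
from .core_io import validate_junctions


def quantify_isoform_usage(
    junctions: pd.DataFrame, library_sizes: Mapping[str, float]
) -> pd.DataFrame:
    """Per gene x sample x isoform usage (J_i / common) and CPM.

    ``junctions`` follows the junction-table contract (one row per
    junction with a ``label`` of "common" or "isoform-specific:<id>").
    Samples lacking common-exon reads for a gene get NaN usage and a
    ``flagged`` marker rather than a division by zero.
    """
    junctions = validate_junctions(junctions)
    rows = []
    for (gene, sample), grp in junctions.groupby(["gene_id", "sample"], sort=True):
        common = int(grp.loc[grp["label"] == "common", "count"].sum())
        lib = float(library_sizes[sample])
        spec = grp[grp["label"] != "common"]
        for label, cnt in (
            spec.groupby("label")["count"].sum().items()
        ):
            isoform = label.split(":", 1)[1]
            usage = cnt / common if common > 0 else np.nan
            rows.append(
                {
                    "gene_id": gene,
                    "sample": sample,
                    "isoform": isoform,
                    "usage": usage,
                    "cpm": 1e6 * cnt / lib,
                    "common_reads": common,
                    "library_size": lib,
                    "flagged": common == 0,
                }
            )
    return pd.DataFrame(rows)


def compare_usage(
    usage: pd.DataFrame,
    samples: pd.DataFrame,
    strain: str,
    reference: str = "WT",
) -> pd.DataFrame:
    """Per-isoform knockout/wild-type usage ratio with Welch t-tests.

    p-values are BH-adjusted across isoforms within each gene.  An isoform
    missing replicate usage in either group gets a NaN ratio and a flag.
    """
    strain_of = samples["strain"]
    u = usage.merge(strain_of.rename("strain"), left_on="sample", right_index=True)
    rows = []
    for (gene, isoform), grp in u.groupby(["gene_id", "isoform"], sort=True):
        wt = grp.loc[grp["strain"] == reference, "usage"].dropna().values
        ko = grp.loc[grp["strain"] == strain, "usage"].dropna().values
        if len(wt) < 2 or len(ko) < 2:
            rows.append({"gene_id": gene, "isoform": isoform, "usage_wt": np.nan,
                         "usage_ko": np.nan, "ratio": np.nan, "p": np.nan,
                         "flagged": True})
            continue
        ratio = ko.mean() / wt.mean() if wt.mean() > 0 else np.nan
        rows.append({"gene_id": gene, "isoform": isoform,
                     "usage_wt": float(wt.mean()), "usage_ko": float(ko.mean()),
                     "ratio": ratio, "p": welch_t_p(ko, wt), "flagged": False})
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for gene, grp in out.groupby("gene_id"):
        out.loc[grp.index, "fdr"] = bh_adjust(grp["p"])
    out["strain"] = strain
    return out
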