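"""Small shared statistics helpers."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through as NaN."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def welch_t_p(a, b) -> float:
    """Two-sided Welch t-test p, defined for degenerate zero-variance groups.

    With both groups constant the test statistic is undefined; we return 1
    for equal means (no evidence of difference) and 0 otherwise (the groups
    separate perfectly, replicates carry no noise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    with warnings.catch_warnings():
        # near-identical replicates trip scipy's precision-loss warning;
        # the resulting large t is the intended answer here
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0
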