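"""Thin, uniform front door to the standard statistical tests used here.

Every analysis in this package reports raw two-sided p-values from the
classical tests (paired/independent t, Wilcoxon signed-rank, chi-squared,
McNemar); this module only validates shapes and delegates to
scipy.stats / statsmodels.  No multiple-testing correction is applied by
default; ``benjamini_hochberg`` is available as an explicit opt-in.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

TEST_KINDS = ("paired-t", "wilcoxon-signed-rank", "independent-t",
              "chi-squared", "mcnemar")


def stat_tests(samples, kind: str) -> tuple[float, float]:
    """Run one named test; returns (statistic, two-sided p).

    samples: (x, y) paired equal-length vectors for 'paired-t' and
    'wilcoxon-signed-rank'; (x, y) independent vectors for 'independent-t';
    a 2-d contingency table for 'chi-squared'; a 2x2 table for 'mcnemar'.
    """
    if kind in ("paired-t", "wilcoxon-signed-rank", "independent-t"):
        try:
            x, y = samples
        except (TypeError, ValueError):
            raise ValueError(f"{kind} expects a pair of sample vectors") from None
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if kind == "independent-t":
            res = stats.ttest_ind(x, y)
        else:
            if x.shape != y.shape:
                raise ValueError(f"{kind} requires paired equal-length samples")
            if kind == "paired-t":
                if np.array_equal(x, y):
                    return 0.0, 1.0  # zero difference: no evidence by convention
                res = stats.ttest_rel(x, y)
            else:
                if np.array_equal(x, y):
                    return 0.0, 1.0
                res = stats.wilcoxon(x, y)
        return float(res.statistic), float(res.pvalue)

    table = np.asarray(samples, dtype=float)
    if kind == "chi-squared":
        if table.ndim != 2:
            raise ValueError("chi-squared expects a 2-d contingency table")
        res = stats.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    if kind == "mcnemar":
        if table.shape != (2, 2):
            raise ValueError("mcnemar expects a 2x2 table of paired outcomes")
        from statsmodels.stats.contingency_tables import mcnemar

        res = mcnemar(table, exact=False, correction=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}; choose from {TEST_KINDS}")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (explicit opt-in; analyses report raw p by default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
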