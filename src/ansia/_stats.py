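"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats

# significance thresholds and symbols used on all comparison outputs
_STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def significance_stars(p_value: float) -> str:
    """Map a p-value onto the conventional star annotation ('n.s.' above 0.05)."""
    if not np.isfinite(p_value):
        return "n.s."
    for threshold, stars in _STAR_LEVELS:
        if p_value < threshold:
            return stars
    return "n.s."


def welch_ttest(a, b) -> tuple[float, float]:
    """Welch (unequal-variance) two-sample t-test; returns (statistic, p)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                          equal_var=False)
    return float(res.statistic), float(res.pvalue)


def sem(values) -> float:
    """Standard error of the mean (sample sd / sqrt(n))."""
    values = np.asarray(values, float)
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))
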