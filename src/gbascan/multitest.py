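"""Benjamini-Hochberg FDR adjustment (thin wrapper around statsmodels)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone in the input order statistics, each in (0, 1]. NaN inputs
    propagate as NaN and do not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] <= 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
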