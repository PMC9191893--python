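"""Benjamini-Hochberg adjustment (thin wrapper around statsmodels)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_values) -> np.ndarray:
    """BH step-up adjusted p-values; empty input passes through."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
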