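"""Small shared statistical helpers: Z tests and BH-FDR."""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests


def z_to_p(z: float) -> float:
    """Two-sided normal p-value, p = 2*Phi(-|z|)."""
    return float(2.0 * ndtr(-abs(z)))


def z_test(empirical: float, null_values) -> tuple[float, float, float, float]:
    """Z test of an empirical statistic against simulated null values.

    Returns (null_mean, null_sd, z, p) with sd computed with one delta
    degree of freedom. A degenerate null (sd == 0) yields z = 0 if the
    empirical value equals the null mean, else an infinite z with p = 0.
    """
    null_values = np.asarray(null_values, dtype=float)
    m = float(np.mean(null_values))
    s = float(np.std(null_values, ddof=1)) if null_values.size > 1 else 0.0
    if s > 0:
        z = (empirical - m) / s
        return m, s, z, z_to_p(z)
    if empirical == m:
        return m, s, 0.0, 1.0
    return m, s, float(np.sign(empirical - m)) * np.inf, 0.0


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def format_p(p: float, digits: int = 3) -> str:
    """Render a p-value the way result tables print it ('<.001' floor)."""
    floor = 10.0 ** (-digits)
    if p < floor:
        return f"<{floor:.3f}".replace("0.", ".")
    return f"{p:.{digits}f}".replace("0.", ".", 1) if p < 1 else f"{p:.{digits}f}"
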