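"""Method-agreement statistics for paired velocity measurements.

Implements the validation toolkit used when a new velocity measurement
technique is compared against an established one on the same subjects:

* Bland–Altman analysis — mean difference (bias) with 95% limits of
  agreement ``bias ± 1.96·sd`` and a t-based confidence interval on the
  bias; differences are taken as ``method_a − method_b`` (reference minus
  new method).
* Spearman rank correlation with a 95% confidence interval via the Fisher
  z-transform (``sd = 1/sqrt(n − 3)``), or optionally a seeded bootstrap.
* Wilcoxon signed-rank test for a systematic shift between the paired
  medians (exact null distribution for n ≤ 25 after dropping zero
  differences, normal approximation with continuity correction beyond).
* Repeatability coefficient of variation by the logarithmic method:
  within-subject variance of the paired log-differences,
  ``s² = Σ dᵢ²/(2n)`` with ``dᵢ = ln r₁ᵢ − ln r₂ᵢ``, reported as
  ``CoV = sqrt(exp(s²) − 1) × 100``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AgreementReport",
    "bland_altman",
    "spearman_ci",
    "wilcoxon_paired",
    "cov_log",
    "agreement_report",
    "bland_altman_plot",
]


@dataclass
class AgreementReport:
    """Full agreement summary between two measurement methods."""

    n: int
    bias: float
    loa_low: float
    loa_high: float
    bias_ci_low: float
    bias_ci_high: float
    spearman_r: float
    r_ci_low: float
    r_ci_high: float
    wilcoxon_stat: float
    wilcoxon_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def _as_pair_arrays(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be 1-D arrays of equal length")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("paired inputs must be finite")
    return a, b


def bland_altman(method_a, method_b) -> dict:
    """Bias, 95% limits of agreement and t-based CI on the bias.

    Differences are ``method_a − method_b``.  Returns a dict with keys
    ``n, bias, sd, loa_low, loa_high, bias_ci_low, bias_ci_high``.
    """
    a, b = _as_pair_arrays(method_a, method_b)
    n = len(a)
    if n < 3:
        raise ValueError("Bland–Altman needs at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    tcrit = stats.t.ppf(0.975, n - 1)
    se = sd / np.sqrt(n)
    return {
        "n": n,
        "bias": bias,
        "sd": sd,
        "loa_low": bias - half,
        "loa_high": bias + half,
        "bias_ci_low": bias - tcrit * se,
        "bias_ci_high": bias + tcrit * se,
    }


def spearman_ci(
    method_a,
    method_b,
    bootstrap: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Spearman rank correlation (midranks on ties) with a 95% CI.

    The default CI uses the Fisher z-transform with standard deviation
    ``1/sqrt(n − 3)``; ``bootstrap=True`` replaces it with a seeded
    percentile bootstrap over subjects.
    """
    a, b = _as_pair_arrays(method_a, method_b)
    n = len(a)
    if n < 4:
        raise ValueError("Spearman CI needs at least 4 pairs")
    r = float(stats.spearmanr(a, b).statistic)
    if bootstrap:
        rng = np.random.default_rng(seed)
        rs = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(a[idx])) < 2 or len(np.unique(b[idx])) < 2:
                continue
            rs.append(stats.spearmanr(a[idx], b[idx]).statistic)
        lo, hi = np.percentile(rs, [2.5, 97.5])
    elif abs(r) >= 1.0:
        lo, hi = r, r  # Fisher z degenerate at |r| = 1
    else:
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    return {"n": n, "r": r, "ci_low": float(lo), "ci_high": float(hi)}


def wilcoxon_paired(method_a, method_b) -> dict:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original rule, logged); the
    exact null distribution is used for n ≤ 25 remaining pairs, otherwise
    the normal approximation with continuity correction.  All differences
    zero is degenerate and reported as ``p = 1`` with a warning.
    """
    a, b = _as_pair_arrays(method_a, method_b)
    d = a - b
    n_zero = int((d == 0).sum())
    if n_zero:
        logger.info("wilcoxon: dropping %d zero difference(s)", n_zero)
    d = d[d != 0]
    if len(d) == 0:
        logger.warning("wilcoxon: all differences zero — degenerate, p = 1")
        return {"n": 0, "statistic": 0.0, "p": 1.0}
    if len(d) < 5:
        raise ValueError("Wilcoxon needs at least 5 nonzero differences")
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(d, correction=(method == "approx"), method=method)
    return {"n": int(len(d)), "statistic": float(res.statistic), "p": float(res.pvalue)}


def cov_log(reading_1, reading_2) -> float:
    """Repeatability CoV (%) by the logarithmic method.

    With paired replicate readings, the within-subject variance on the log
    scale is estimated as ``s² = Σ dᵢ² / (2n)`` where
    ``dᵢ = ln r₁ᵢ − ln r₂ᵢ``; the coefficient of variation is
    ``sqrt(exp(s²) − 1) × 100``.  Scale-invariant by construction.
    """
    r1, r2 = _as_pair_arrays(reading_1, reading_2)
    if (r1 <= 0).any() or (r2 <= 0).any():
        raise ValueError("log-method CoV requires strictly positive readings")
    d = np.log(r1) - np.log(r2)
    s2 = float((d**2).sum() / (2 * len(d)))
    return float(np.sqrt(np.expm1(s2)) * 100.0)


def agreement_report(
    pairs: pd.DataFrame,
    col_a: str = "tte_m_s",
    col_b: str = "cmr_m_s",
    group: str = "all",
) -> AgreementReport:
    """All agreement statistics for one cohort table.

    ``pairs`` must carry the two measurement columns and, when ``group``
    is ``"sinus"`` or ``"af"``, a ``rhythm`` column to filter on.
    """
    if group not in ("all", "sinus", "af"):
        raise ValueError("group must be 'all', 'sinus' or 'af'")
    if group != "all":
        pairs = pairs[pairs["rhythm"] == group]
    a = pairs[col_a].to_numpy(dtype=np.float64)
    b = pairs[col_b].to_numpy(dtype=np.float64)
    ba = bland_altman(a, b)
    sp = spearman_ci(a, b)
    wx = wilcoxon_paired(a, b)
    return AgreementReport(
        n=ba["n"],
        bias=ba["bias"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        bias_ci_low=ba["bias_ci_low"],
        bias_ci_high=ba["bias_ci_high"],
        spearman_r=sp["r"],
        r_ci_low=sp["ci_low"],
        r_ci_high=sp["ci_high"],
        wilcoxon_stat=wx["statistic"],
        wilcoxon_p=wx["p"],
    )


def bland_altman_plot(method_a, method_b, ax=None, label_a="method A", label_b="method B"):
    """Standard Bland–Altman scatter: mean vs difference with bias/LoA lines."""
    import matplotlib.pyplot as plt

    a, b = _as_pair_arrays(method_a, method_b)
    res = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mean = (a + b) / 2.0
    ax.scatter(mean, a - b, s=18, alpha=0.7, edgecolor="none")
    for y, style in ((res["bias"], "-"), (res["loa_low"], "--"), (res["loa_high"], "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean of {label_a} and {label_b} (m/s)")
    ax.set_ylabel(f"{label_a} − {label_b} (m/s)")
    return ax
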