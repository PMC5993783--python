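"""Quantile-quantile enrichment comparison of association p-value sets.

Compares the -log10(p) quantiles of the candidate-region associations under
the composite neuroanatomical score against a reference set (e.g., the same
SNPs tested against a single ROI volume), with pointwise order-statistic
confidence envelopes: under the uniform null the i-th smallest of n p-values
is Beta(i, n - i + 1), so the envelope at level 1 - alpha is the pair of
Beta quantiles at alpha/2 and 1 - alpha/2 mapped through -log10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["QqComparison", "qq_envelope", "compare_sets", "plot_qq"]


@dataclass
class QqComparison:
    quantiles_ours: np.ndarray       # sorted ascending -log10 p
    quantiles_reference: np.ndarray  # matched to the same ranks
    expected: np.ndarray             # null expectation -log10(i/(n+1))
    envelope_lower: np.ndarray
    envelope_upper: np.ndarray
    alpha: float
    tail_shift: float                # mean top-decile difference (ours - ref)
    enriched: bool


def qq_envelope(n: int, alpha: float = 0.05):
    """Expected null quantiles and 1-alpha pointwise envelope for n p-values.

    Returns ``(expected, lower, upper)`` on the -log10 scale, ordered from the
    largest p (rank n) to the smallest (rank 1) so the arrays are ascending.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    i = np.arange(n, 0, -1)                       # rank of the p order statistic
    expected = -np.log10(i / (n + 1.0))
    lower = -np.log10(stats.beta.ppf(1.0 - alpha / 2.0, i, n - i + 1))
    upper = -np.log10(stats.beta.ppf(alpha / 2.0, i, n - i + 1))
    return expected, lower, upper


def _neglog_quantiles(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.sort(-np.log10(p))                  # ascending


def compare_sets(p_ours, p_reference, alpha: float = 0.05) -> QqComparison:
    """Paired QQ comparison with tail-shift statistic and enrichment flag.

    When the two sets differ in size, the reference quantile function is
    interpolated at the plotting ranks of our set.  The tail-shift statistic
    is the mean difference of the top decile of quantiles; enrichment is
    flagged when the mean of our top-decile quantiles exceeds the mean of the
    null envelope's upper bound at those ranks.
    """
    q_ours = _neglog_quantiles(p_ours)
    q_ref = _neglog_quantiles(p_reference)
    n = len(q_ours)
    if len(q_ref) != n:
        grid = (np.arange(1, n + 1) - 0.5) / n
        ref_grid = (np.arange(1, len(q_ref) + 1) - 0.5) / len(q_ref)
        q_ref = np.interp(grid, ref_grid, q_ref)
    expected, lower, upper = qq_envelope(n, alpha)

    n_tail = max(1, int(np.ceil(n / 10.0)))
    tail = slice(n - n_tail, n)
    tail_shift = float(np.mean(q_ours[tail] - q_ref[tail]))
    enriched = bool(np.mean(q_ours[tail]) > np.mean(upper[tail]))
    return QqComparison(q_ours, q_ref, expected, lower, upper, alpha,
                        tail_shift, enriched)


def plot_qq(comparison: QqComparison, path) -> None:
    """Write the enrichment QQ plot (observed vs reference, null envelope)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.fill_between(comparison.expected, comparison.envelope_lower,
                    comparison.envelope_upper, color="#9ecae1", alpha=0.6,
                    label=f"null envelope (1-{comparison.alpha:g})")
    ax.plot(comparison.expected, comparison.expected, "k-", lw=1,
            label="expected null")
    ax.plot(comparison.expected, comparison.quantiles_reference, "o",
            ms=3, color="#636363", label="reference (ROI)")
    ax.plot(comparison.expected, comparison.quantiles_ours, "o", ms=3,
            color="#de2d26", label="composite score")
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
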