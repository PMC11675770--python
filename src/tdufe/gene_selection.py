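"""Gene selection from a gene-mode singular vector under an optimized Gaussian null.

The null hypothesis is that gene loadings ``u_i`` on the chosen gene-mode
singular vector are Gaussian with mean zero and unknown standard deviation
``sigma``. Each gene gets a two-tailed p-value

    P_i = P[chi2_1 > (u_i / sigma)^2],

i.e. the upper tail of a 1-df chi-squared distribution at the squared
standardized loading (equivalently the two-sided Gaussian tail of |u_i|/sigma).
``sigma`` is not estimated by sd(u) — signal genes would inflate it — but
chosen so that the bulk of the p-values looks uniform: we minimize the
"flatness" objective, the dispersion of the 1−p histogram bin counts with the
smallest-p bins excluded so genuine signal does not penalize the fit.
P-values are then Benjamini–Hochberg adjusted and genes below the adjusted
threshold are selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSelectionResult",
    "chi2_pvalues",
    "bh_adjust",
    "flatness_objective",
    "optimize_sigma",
    "select_genes",
]


@dataclass
class GeneSelectionResult:
    """Optimized null scale, p-values and the selection mask.

    ``flatness_profile`` tabulates the flatness objective over the sigma search
    grid (columns ``sigma``, ``objective``); ``histogram_raw`` /
    ``histogram_adjusted`` hold the (counts, bin_edges) of the 1−p histograms
    backing the usual calibration plot.
    """

    sigma: float
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    selected: np.ndarray
    threshold: float
    flatness_profile: pd.DataFrame
    histogram_raw: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)  # type: ignore[assignment]
    histogram_adjusted: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def to_frame(self, feature_ids=None, u=None) -> pd.DataFrame:
        """Per-gene table: feature_id, u_value, p_raw, p_adjusted, selected."""
        data = {
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "selected": self.selected,
        }
        if u is not None:
            data = {"u_value": np.asarray(u), **data}
        df = pd.DataFrame(data)
        if feature_ids is not None:
            df.insert(0, "feature_id", list(feature_ids))
        return df


def chi2_pvalues(u: np.ndarray, sigma: float) -> np.ndarray:
    """Two-tailed Gaussian test via the 1-df chi-squared upper tail."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    u = np.asarray(u, dtype=float)
    if not np.isfinite(u).all():
        raise ValueError("u contains NaN or Inf")
    # The chi2_1 upper tail at (u/sigma)^2 equals the two-sided Gaussian tail
    # erfc(|u|/(sigma*sqrt(2))); erfc is the cheapest stable form inside the
    # sigma grid search (chi2.sf and chdtrc agree to ~1e-14 but cost far more).
    return special.erfc(np.abs(u) / (sigma * np.sqrt(2.0)))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flatness_objective(
    p: np.ndarray, n_bins: int = 100, exclude_low_p_bins: int = 1
) -> float:
    """Dispersion of the 1−p histogram; lower means a flatter (more uniform) bulk.

    The histogram uses ``n_bins`` equal-width bins on [0, 1]. The topmost
    ``exclude_low_p_bins`` bins — the ones holding the smallest p-values —
    are dropped before taking the standard deviation of the counts, so that
    true signal concentrated at small p does not bias the null fit.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    if not 0 <= exclude_low_p_bins < n_bins:
        raise ValueError("exclude_low_p_bins must be in [0, n_bins)")
    counts, _ = np.histogram(1.0 - p, bins=n_bins, range=(0.0, 1.0))
    kept = counts[: n_bins - exclude_low_p_bins] if exclude_low_p_bins else counts
    return float(np.std(kept))


def _golden_section(f, lo: float, hi: float, rel_tol: float = 1e-4):
    """Deterministic golden-section minimizer; returns the best point evaluated."""
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = f(c), f(d)
    best_x, best_f = (c, fc) if fc <= fd else (d, fd)
    while (b - a) > rel_tol * max(abs(a), abs(b)):
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = f(d)
        for x, fx in ((c, fc), (d, fd)):
            if fx < best_f:
                best_x, best_f = x, fx
    return best_x, best_f


def optimize_sigma(
    u: np.ndarray,
    n_bins: int = 100,
    exclude_low_p_bins: int = 1,
    n_grid: int = 101,
    span: float = 10.0,
) -> tuple[float, pd.DataFrame]:
    """Find the null scale sigma whose p-values have the flattest bulk histogram.

    Evaluates the flatness objective of ``chi2_pvalues(u, sigma)`` on a
    log-spaced grid of ``n_grid`` points spanning ``[sd(u)/span, sd(u)*span]``,
    then refines around the grid minimum by golden section to relative
    tolerance 1e-4. Returns the minimizing sigma and the full grid profile.
    """
    u = np.asarray(u, dtype=float)
    if u.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} entries to fit sigma")
    scale = float(np.std(u))
    if scale == 0:
        raise ValueError("u is constant; sigma optimization is undefined")

    sigmas = np.geomspace(scale / span, scale * span, n_grid)

    def objective(s: float) -> float:
        return flatness_objective(chi2_pvalues(u, s), n_bins, exclude_low_p_bins)

    values = np.array([objective(s) for s in sigmas])
    if not np.isfinite(values).any():
        raise ValueError("flatness objective non-finite over the entire grid")
    profile = pd.DataFrame({"sigma": sigmas, "objective": values})

    i = int(np.argmin(values))
    lo = sigmas[max(i - 1, 0)]
    hi = sigmas[min(i + 1, n_grid - 1)]
    best_x, best_f = _golden_section(objective, lo, hi)
    if values[i] <= best_f:
        best_x = float(sigmas[i])
    return float(best_x), profile


def select_genes(
    u: np.ndarray,
    threshold: float = 0.01,
    n_bins: int = 100,
    exclude_low_p_bins: int = 1,
    sigma: float | None = None,
) -> GeneSelectionResult:
    """Full gene-selection stage: optimize sigma, test, adjust, threshold.

    ``sigma`` may be fixed to bypass the optimization (e.g. for calibration
    studies); otherwise it is fitted by :func:`optimize_sigma`. Selection is
    ``p_adjusted < threshold``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    u = np.asarray(u, dtype=float)
    if sigma is None:
        sigma, profile = optimize_sigma(u, n_bins, exclude_low_p_bins)
    else:
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        profile = pd.DataFrame({"sigma": [sigma], "objective": [np.nan]})
    p_raw = chi2_pvalues(u, sigma)
    p_adj = bh_adjust(p_raw)
    selected = p_adj < threshold
    hist_raw = np.histogram(1.0 - p_raw, bins=n_bins, range=(0.0, 1.0))
    hist_adj = np.histogram(1.0 - p_adj, bins=n_bins, range=(0.0, 1.0))
    return GeneSelectionResult(
        sigma=float(sigma),
        p_raw=p_raw,
        p_adjusted=p_adj,
        selected=selected,
        threshold=float(threshold),
        flatness_profile=profile,
        histogram_raw=hist_raw,
        histogram_adjusted=hist_adj,
    )
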