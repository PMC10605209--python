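"""Degree-based network structure: hubs, degree-distribution fits, log-rank.

Hubs are nodes whose degree exceeds the across-node mean by more than 1.5
sample standard deviations. Degree distributions of brain covariance
networks are well described by an exponentially truncated power law
``P(d) = scale · d^(1/k) · exp(−d/dc)`` — a power rise/decay with
exponent 1/k truncated by an exponential cutoff at degree dc — fitted
here by nonlinear least squares to the empirical degree relative
frequencies. Two degree samples are compared by the two-group log-rank
test, treating nodal degrees as uncensored event times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class HubSet:
    """Regions whose degree summary strictly exceeds mean + 1.5·SD."""

    hub_regions: tuple[str, ...]
    hub_degrees: np.ndarray
    threshold: float
    degree_basis: np.ndarray

    def __len__(self) -> int:
        return len(self.hub_regions)


def identify_hubs(degree_summary, region_labels) -> HubSet:
    """Apply the mean + 1.5·SD degree rule.

    ``degree_summary`` may be integer degrees at one density or degrees
    averaged across the density grid. The sample standard deviation uses
    the n−1 denominator. Returned hubs are sorted by degree, descending;
    an all-equal degree vector yields an empty hub set (SD 0, nothing
    strictly above the mean).
    """
    deg = np.asarray(degree_summary, dtype=float)
    labels = tuple(region_labels)
    if deg.shape != (len(labels),):
        raise ValueError("one degree summary per region required")
    if deg.size < 2:
        raise ValueError("need at least 2 regions")
    thr = float(deg.mean() + 1.5 * deg.std(ddof=1))
    idx = np.flatnonzero(deg > thr)
    idx = idx[np.argsort(-deg[idx], kind="stable")]
    return HubSet(tuple(labels[i] for i in idx), deg[idx], thr, deg)


@dataclass
class DegreeDistributionFit:
    """Result of the truncated power-law fit."""

    k: float              #: power exponent
    dc: float             #: cutoff degree
    scale: float          #: fitted normalization constant
    r2: float             #: 1 − SS_res/SS_tot on the fitted scale
    fitted_support: tuple[int, int]
    success: bool
    form: str = "pmf"

    def predict(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return self.scale * d ** (1.0 / self.k) * np.exp(-d / self.dc)


def _model(d, scale, k, dc):
    return scale * d ** (1.0 / k) * np.exp(-d / dc)


def _model_alt(d, scale, k, dc):
    # alternative reading of the printed exponent: d^(k-1)
    return scale * d ** (k - 1.0) * np.exp(-d / dc)


def fit_frequency_table(d, y, form: str = "pmf",
                        exponent: str = "inverse_k"
                        ) -> DegreeDistributionFit:
    """Fit ``scale·d^(1/k)·exp(−d/dc)`` to a (degree, value) table.

    Multi-start bounded nonlinear least squares; if no start converges
    the result is flagged unsuccessful rather than raising. r2 is
    computed on the fitted scale.
    """
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    model = {"inverse_k": _model, "k_minus_1": _model_alt}[exponent]
    d_max = float(d.max())
    best = None
    bounds = ([1e-12, 0.05, 0.1], [10.0, 50.0, 50.0 * d_max])
    mean_d = float(np.average(d, weights=np.maximum(y, 0) + 1e-12))
    for k0 in (0.5, 1.0, 1.5, 3.0):
        for dc0 in (mean_d, d_max / 3.0, d_max):
            try:
                popt, _ = optimize.curve_fit(
                    model, d, y, p0=[max(y.max(), 1e-6), k0, dc0],
                    bounds=bounds, maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            ss_res = float(np.sum((y - model(d, *popt)) ** 2))
            if best is None or ss_res < best[0]:
                best = (ss_res, popt)
    if best is None:
        return DegreeDistributionFit(np.nan, np.nan, np.nan, np.nan,
                                     (int(d.min()), int(d_max)), False,
                                     form)
    ss_res, (scale, k, dc) = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return DegreeDistributionFit(float(k), float(dc), float(scale),
                                 float(r2), (int(d.min()), int(d_max)),
                                 True, form)


def fit_truncated_powerlaw(degrees, form: str = "pmf",
                           exponent: str = "inverse_k"
                           ) -> DegreeDistributionFit:
    """Least-squares fit of ``scale·d^(1/k)·exp(−d/dc)`` to a degree sample.

    Fits the empirical degree relative-frequency table over the full
    support 1..max(degrees) (zero-count degrees included, which anchors
    the tail). ``form='ccdf'`` fits the model's survival curve to the
    empirical complementary CDF instead. ``exponent='k_minus_1'`` swaps
    the power term for d^(k−1). Degenerate supports (< 3 distinct
    degrees) yield a flagged failure, not an exception.
    """
    degrees = np.asarray(degrees)
    if degrees.size == 0 or (degrees < 1).any():
        raise ValueError("degrees must be positive integers")
    d_max = int(degrees.max())
    if np.unique(degrees).size < 3:
        return DegreeDistributionFit(np.nan, np.nan, np.nan, np.nan,
                                     (1, d_max), False, form)
    d = np.arange(1, d_max + 1, dtype=float)
    counts = np.bincount(degrees.astype(int), minlength=d_max + 1)[1:]
    freq = counts / counts.sum()
    if form == "pmf":
        y = freq
    elif form == "ccdf":
        y = 1.0 - np.cumsum(freq) + freq   # P(D >= d)
    else:
        raise ValueError("form must be 'pmf' or 'ccdf'")
    return fit_frequency_table(d, y, form, exponent)


def logrank_degree_test(degrees_a, degrees_b) -> tuple[float, float]:
    """Two-group log-rank chi-square on nodal degrees.

    Degrees are treated as uncensored event times; at each distinct
    pooled degree the observed minus expected events in group A
    accumulate with hypergeometric variance, giving a 1-df chi-square.
    Returns ``(statistic, p)``; identical samples give (0, 1).
    """
    a = np.asarray(degrees_a, dtype=float)
    b = np.asarray(degrees_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both degree samples must be non-empty")
    times = np.unique(np.concatenate([a, b]))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n1 = float((a >= t).sum())
        n2 = float((b >= t).sum())
        n = n1 + n2
        d1 = float((a == t).sum())
        d = d1 + float((b == t).sum())
        if n <= 1 or d == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def pairwise_logrank(degree_samples: dict[str, np.ndarray]
                     ) -> dict[tuple[str, str], tuple[float, float]]:
    """All pairwise log-rank comparisons between named degree samples."""
    names = list(degree_samples)
    out = {}
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            out[(x, y)] = logrank_degree_test(degree_samples[x],
                                              degree_samples[y])
    return out


def grid_averaged_degrees(graphs) -> np.ndarray:
    """Per-region degree averaged across the density grid."""
    from .metrics import degrees as _deg
    if not graphs:
        raise ValueError("no graphs given")
    return np.mean([_deg(g) for g in graphs], axis=0)
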