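"""Heavy-tailed distribution fits for coupling strengths and spectra.

Two complementary descriptions are fitted: the Lomax (shifted-Pareto)
distribution p(x) = (α/s)(1 + x/s)^−(α+1) over the full positive sample,
and a pure power-law tail p(x) ∝ x^−γ above a lower cutoff x_min, with the
continuous (Hill) maximum-likelihood exponent γ = 1 + n / Σ ln(x/x_min).
When x_min is not given it is chosen by minimising the Kolmogorov–Smirnov
distance between the tail sample and the fitted power law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class TailFit:
    """Result of a heavy-tail fit.

    ``gamma`` is the density exponent (for the Lomax family the implied tail
    exponent is shape + 1); ``x_min`` is the lower cutoff for power-law fits
    (0 for the full-sample Lomax fit).
    """

    family: str                 # "lomax" | "powerlaw"
    shape: float | None = None  # Lomax shape α
    scale: float | None = None  # Lomax scale s
    gamma: float | None = None  # power-law density exponent
    x_min: float = 0.0
    n: int = 0
    loglik: float = np.nan
    ks_distance: float = np.nan
    converged: bool = True


def _check_positive(samples: np.ndarray) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("samples must be positive and finite")
    return x


def empirical_pdf_logbins(samples, bins_per_decade: int = 10
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Log-binned probability density: Σ density·bin_width = 1 exactly.

    Returns (geometric bin centers, densities).  Densities are per unit x
    (linear measure), so they can be overlaid on analytic pdfs directly.
    """
    x = _check_positive(samples)
    lo, hi = x.min(), x.max()
    if lo == hi:
        half = 10 ** (0.5 / bins_per_decade)
        edges = np.array([lo / half, lo * half])
    else:
        n_bins = max(1, int(np.ceil(np.log10(hi / lo) * bins_per_decade)))
        edges = np.geomspace(lo, hi, n_bins + 1)
        edges[-1] = np.nextafter(edges[-1], np.inf)  # include the max sample
    counts, edges = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    density = counts / (x.size * widths)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return centers, density


def fit_lomax(samples, min_n: int = 50) -> TailFit:
    """Maximum-likelihood Lomax fit via the profile likelihood in the scale.

    For a fixed scale s the shape MLE is closed-form, α(s) = n / Σ ln(1+x/s),
    leaving a 1-D optimisation over log s.  Exponential-like data push the
    scale to the upper bound and the shape to large values; that outcome is
    returned as converged rather than an error.
    """
    x = _check_positive(samples)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values equal")
    n = x.size
    mean = x.mean()

    def negloglik_logs(log_s: float) -> float:
        s = np.exp(log_s)
        t = np.log1p(x / s).sum()
        a = n / t
        # -loglik up to constants: -(n ln a - n ln s - (a+1) t)
        return -(n * np.log(a) - n * np.log(s) - (a + 1.0) * t)

    lo, hi = np.log(mean) - 12.0, np.log(mean) + 12.0
    res = optimize.minimize_scalar(negloglik_logs, bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    s = float(np.exp(res.x))
    shape = float(n / np.log1p(x / s).sum())
    loglik = float(-res.fun)
    ks = float(stats.kstest(x, stats.lomax(shape, loc=0, scale=s).cdf).statistic)
    return TailFit("lomax", shape=shape, scale=s, gamma=shape + 1.0,
                   x_min=0.0, n=n, loglik=loglik, ks_distance=ks,
                   converged=bool(res.success))


def _hill(x_tail: np.ndarray, x_min: float) -> float:
    return 1.0 + x_tail.size / np.log(x_tail / x_min).sum()


def _power_ks(x_tail: np.ndarray, x_min: float, gamma: float) -> float:
    xs = np.sort(x_tail)
    cdf = 1.0 - (xs / x_min) ** (1.0 - gamma)
    ecdf_hi = np.arange(1, xs.size + 1) / xs.size
    ecdf_lo = np.arange(0, xs.size) / xs.size
    return float(max(np.max(np.abs(cdf - ecdf_hi)), np.max(np.abs(cdf - ecdf_lo))))


def fit_powerlaw_tail(samples, x_min: float | None = None,
                      min_tail: int = 20) -> TailFit:
    """Continuous MLE power-law exponent of the upper tail.

    With an explicit ``x_min`` the Hill estimator is applied to the samples
    at or above it.  Otherwise ``x_min`` is scanned over the unique sample
    values between the 50th and 95th percentiles (keeping at least
    ``min_tail`` tail points) and the value minimising the KS distance is
    selected, Clauset-style.
    """
    x = _check_positive(samples)
    if x_min is not None:
        tail = x[x >= x_min]
        if tail.size < 2 or np.all(tail == x_min):
            raise ValueError("too few tail samples above x_min")
        gamma = _hill(tail, x_min)
        return TailFit("powerlaw", gamma=float(gamma), x_min=float(x_min),
                       n=int(tail.size),
                       loglik=float(tail.size * np.log((gamma - 1) / x_min)
                                    - gamma * np.log(tail / x_min).sum()),
                       ks_distance=_power_ks(tail, x_min, gamma))
    q50, q95 = np.quantile(x, [0.50, 0.95])
    grid = np.unique(x[(x >= q50) & (x <= q95)])
    grid = np.array([g for g in grid if np.sum(x >= g) >= min_tail])
    if grid.size == 0:
        raise ValueError(f"cannot keep {min_tail} tail samples; sample too small")
    best = None
    for g in grid:
        tail = x[x >= g]
        if np.all(tail == g):
            continue
        gamma = _hill(tail, g)
        ks = _power_ks(tail, g, gamma)
        if best is None or ks < best.ks_distance:
            best = TailFit(
                "powerlaw", gamma=float(gamma), x_min=float(g),
                n=int(tail.size),
                loglik=float(tail.size * np.log((gamma - 1) / g)
                             - gamma * np.log(tail / g).sum()),
                ks_distance=ks,
            )
    if best is None:
        raise ValueError("degenerate tail: no usable x_min candidate")
    return best
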