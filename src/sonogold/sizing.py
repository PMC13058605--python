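"""Log-normal size-distribution analysis for particle diameter data.

Nanoparticle tracking analysis (NTA) and cluster-size measurements both
report diameter distributions that are well described by a log-normal law.
This module bins raw diameter samples and fits an amplitude-scaled
log-normal probability density to the binned values by damped least squares
(Levenberg-Marquardt), the convention NTA software uses, rather than a raw
maximum-likelihood fit.  The headline statistic is the modal diameter
``exp(mu - sigma^2)`` of the fitted density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DiameterSample",
    "SizeHistogram",
    "LogNormalFit",
    "histogram_diameters",
    "fit_lognormal",
    "modal_diameter",
    "lognormal_pdf",
]


class UnderdeterminedFitError(ValueError):
    """Raised when a histogram has too few occupied bins to fit 3 parameters."""


@dataclass(frozen=True)
class DiameterSample:
    """A flat list of particle diameters (nm or um) with a free-text source tag."""

    diameters: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("diameters must be a nonempty 1-D array")
        if not np.all(d > 0):
            raise ValueError("all diameters must be positive")
        object.__setattr__(self, "diameters", d)


@dataclass(frozen=True)
class SizeHistogram:
    """Binned diameters: ``len(bin_edges) == len(values) + 1``, edges ascending."""

    bin_edges: np.ndarray
    values: np.ndarray
    is_density: bool = False

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if e.size != v.size + 1:
            raise ValueError("need len(edges) == len(values) + 1")
        if not np.all(np.diff(e) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("bin values must be nonnegative")
        object.__setattr__(self, "bin_edges", e)
        object.__setattr__(self, "values", v)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.values))


@dataclass(frozen=True)
class LogNormalFit:
    """Result of an amplitude-scaled log-normal least-squares fit.

    ``log_mu`` and ``log_sigma`` are the location and shape on the log scale
    (natural log of the diameter unit); ``amplitude`` carries the units of the
    fitted histogram values.  ``mode`` is ``exp(log_mu - log_sigma**2)``, the
    peak of the density.
    """

    log_mu: float
    log_sigma: float
    amplitude: float
    mode: float = field(default=float("nan"))
    sse: float = float("nan")
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be positive")
        if math.isnan(self.mode):
            object.__setattr__(self, "mode", math.exp(self.log_mu - self.log_sigma**2))

    @property
    def mean(self) -> float:
        """Arithmetic mean of the fitted log-normal distribution."""
        return math.exp(self.log_mu + 0.5 * self.log_sigma**2)

    @property
    def sd(self) -> float:
        """Arithmetic standard deviation of the fitted distribution."""
        return self.mean * math.sqrt(math.expm1(self.log_sigma**2))


def lognormal_pdf(x: np.ndarray, log_mu: float, log_sigma: float) -> np.ndarray:
    """Log-normal probability density in the diameter's own units."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    z = (np.log(x[pos]) - log_mu) / log_sigma
    out[pos] = np.exp(-0.5 * z**2) / (x[pos] * log_sigma * math.sqrt(2 * math.pi))
    return out


def histogram_diameters(sample: DiameterSample, bin_width: float) -> SizeHistogram:
    """Bin a diameter sample into right-open bins of fixed width covering its range.

    The last bin is closed on the right (numpy convention) so the total count
    is preserved exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = sample.diameters
    lo, hi = float(d.min()), float(d.max())
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width))) if hi > lo else 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    return SizeHistogram(bin_edges=edges, values=counts.astype(float))


def _initial_guess(hist: SizeHistogram) -> tuple[float, float, float]:
    # log-moments of the histogram-weighted bin centers: deterministic and
    # close enough for LM to converge from.
    c, w = hist.centers, hist.values
    mask = (w > 0) & (c > 0)
    c, w = c[mask], w[mask]
    logs = np.log(c)
    mu = float(np.average(logs, weights=w))
    var = float(np.average((logs - mu) ** 2, weights=w))
    sigma = math.sqrt(max(var, 1e-4))
    peak_density = lognormal_pdf(np.array([math.exp(mu - sigma**2)]), mu, sigma)[0]
    amp = float(w.max() / peak_density) if peak_density > 0 else float(w.max())
    return mu, sigma, amp


def fit_lognormal(
    hist: SizeHistogram,
    init: LogNormalFit | None = None,
    max_iterations: int = 200,
) -> LogNormalFit:
    """Fit ``amplitude * lognormal_pdf(x; log_mu, log_sigma)`` to a histogram.

    Minimizes the sum of squared residuals against the bin centers with the
    Levenberg-Marquardt algorithm.  Positivity of ``log_sigma`` and
    ``amplitude`` is enforced by optimizing their logarithms.

    Raises
    ------
    UnderdeterminedFitError
        If fewer than 3 bins are occupied (3 free parameters).
    """
    if hist.n_occupied < 3:
        raise UnderdeterminedFitError(
            f"log-normal fit needs >= 3 occupied bins, got {hist.n_occupied}"
        )
    x, y = hist.centers, hist.values
    if init is not None:
        p0 = (init.log_mu, init.log_sigma, init.amplitude)
    else:
        p0 = _initial_guess(hist)
    theta0 = np.array([p0[0], math.log(p0[1]), math.log(max(p0[2], 1e-300))])

    def residuals(theta: np.ndarray) -> np.ndarray:
        # clamp the exponentials so divergent steps yield large finite
        # residuals instead of overflow
        mu = theta[0]
        sigma = math.exp(min(theta[1], 50.0))
        amp = math.exp(min(theta[2], 500.0))
        return amp * lognormal_pdf(x, mu, sigma) - y

    res = least_squares(
        residuals, theta0, method="lm", max_nfev=max_iterations * 10,
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    mu, sigma, amp = res.x[0], math.exp(res.x[1]), math.exp(res.x[2])
    return LogNormalFit(
        log_mu=float(mu),
        log_sigma=float(sigma),
        amplitude=float(amp),
        sse=float(2 * res.cost),
        converged=bool(res.status > 0),
        n_iterations=int(res.nfev),
    )


def modal_diameter(fit: LogNormalFit) -> float:
    """Modal (peak) diameter ``exp(log_mu - log_sigma^2)`` of a converged fit."""
    if not fit.converged:
        raise ValueError("modal diameter is undefined for an unconverged fit")
    return math.exp(fit.log_mu - fit.log_sigma**2)
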