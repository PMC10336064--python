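"""Phoneme-identification psychometrics.

Fits the four-parameter psychometric function

    psi(x) = gamma + (1 - gamma - lambda) * S((x - m) / w)

to per-step /dA/ counts on the 10-step /bA/-/dA/ continuum, with a
binomial likelihood and uniform priors: guess rate gamma in [0, 0.89],
lapse rate lambda in [0, 0.1], midpoint m and width w within broad
bounds. Estimation is a deterministic dense-grid posterior evaluation
with local refinement (no sampling, hence no seed), giving the posterior
mode as point estimate and equal-tailed 95% marginal credible intervals
for the two asymptotes. The slope of psi at the participant-specific
50% point (psi = 0.5) is the task's outcome score; participants whose
asymptote interval includes 0.5 fail quality control and are excluded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict
from scipy.special import expit, ndtr, ndtri

from .observers import IdentificationData

Family = Literal["logistic", "cumulative_normal"]


class UndefinedSlopeError(ValueError):
    """The fitted curve never attains 0.5, so the 50%-point slope is undefined."""


class PriorSpec(BaseModel):
    """Uniform prior bounds for the four psychometric parameters."""

    model_config = ConfigDict(extra="forbid")

    guess_range: tuple[float, float] = (0.0, 0.89)
    lapse_range: tuple[float, float] = (0.0, 0.1)
    midpoint_range: tuple[float, float] = (0.0, 11.0)
    width_range: tuple[float, float] = (0.25, 10.0)
    family: Family = "logistic"

    def model_post_init(self, _ctx) -> None:
        for lo, hi in (self.guess_range, self.lapse_range,
                       self.midpoint_range, self.width_range):
            if not lo < hi:
                raise ValueError("prior ranges must be non-empty intervals")
        if self.width_range[0] <= 0:
            raise ValueError("width must be positive")


def _sigmoid(z: np.ndarray, family: Family) -> np.ndarray:
    return expit(z) if family == "logistic" else ndtr(z)


@dataclass(frozen=True)
class PsychometricFit:
    """Point estimates, asymptote intervals and derived quantities."""

    midpoint_hat: float
    width_hat: float
    guess_hat: float
    lapse_hat: float
    x50: Optional[float]
    slope50: Optional[float]
    lower_asymptote_ci: tuple[float, float]  # for gamma
    upper_asymptote_ci: tuple[float, float]  # for 1 - lambda
    family: Family
    degenerate: bool
    # marginal posteriors over the full prior grid (internal evidence)
    guess_grid: np.ndarray
    guess_marginal: np.ndarray
    lapse_grid: np.ndarray
    lapse_marginal: np.ndarray

    def psi(self, x) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.midpoint_hat) / self.width_hat
        s = _sigmoid(z, self.family)
        return self.guess_hat + (1.0 - self.guess_hat - self.lapse_hat) * s


def proportion_da(data: IdentificationData) -> np.ndarray:
    """Per-step proportion of /dA/ responses (count / reps)."""
    if data.reps_per_step <= 0:
        raise ValueError("reps_per_step must be positive")
    return data.proportions


def _log_likelihood_grid(
    k: np.ndarray, n: int, x: np.ndarray,
    m: np.ndarray, w: np.ndarray, g: np.ndarray, l: np.ndarray,
    family: Family,
) -> np.ndarray:
    """Binomial log-likelihood over the 4-D parameter grid.

    Axes of the result: (midpoint, width, guess, lapse).
    """
    z = (x[None, None, :] - m[:, None, None]) / w[None, :, None]
    s = _sigmoid(z, family)  # (M, W, S)
    s = s[:, :, None, None, :]
    gg = g[None, None, :, None, None]
    ll = l[None, None, None, :, None]
    psi = gg + (1.0 - gg - ll) * s
    psi = np.clip(psi, 1e-12, 1.0 - 1e-12)
    kk = k[None, None, None, None, :]
    return np.sum(kk * np.log(psi) + (n - kk) * np.log1p(-psi), axis=-1)


def _grid(lo: float, hi: float, num: int, log: bool = False) -> np.ndarray:
    if log:
        return np.geomspace(lo, hi, num)
    return np.linspace(lo, hi, num)


def fit_psychometric(
    data: IdentificationData,
    priors: Optional[PriorSpec] = None,
    grid_size: tuple[int, int, int, int] = (25, 25, 24, 11),
    n_refine: int = 2,
    ci_level: float = 0.95,
) -> PsychometricFit:
    """Fit the 4-parameter psychometric function by dense grid search.

    The posterior mode over a full-prior coarse grid is refined by
    zooming the (midpoint, width) x (guess, lapse) box around the mode;
    asymptote credible intervals are read off the coarse-grid marginals,
    which cover the entire prior support. Deterministic for a fixed grid
    resolution.
    """
    priors = priors or PriorSpec()
    x = np.asarray(data.steps, dtype=float)
    k = np.asarray(data.da_counts, dtype=float)
    n = data.reps_per_step
    if len(np.unique(x)) < 2:
        raise ValueError("need data at >= 2 distinct steps to fit")
    degenerate = bool(np.all(k == k[0]))

    nm, nw, ng, nl = grid_size
    m_lo, m_hi = priors.midpoint_range
    w_lo, w_hi = priors.width_range
    g_lo, g_hi = priors.guess_range
    l_lo, l_hi = priors.lapse_range

    m = _grid(m_lo, m_hi, nm)
    w = _grid(w_lo, w_hi, nw, log=True)
    g = _grid(g_lo, g_hi, ng)
    l = _grid(l_lo, l_hi, nl)
    ll = _log_likelihood_grid(k, n, x, m, w, g, l, priors.family)

    # marginal posteriors over the full prior support (uniform priors:
    # posterior weight proportional to the likelihood)
    post = np.exp(ll - ll.max())
    post /= post.sum()
    g_marg = post.sum(axis=(0, 1, 3))
    l_marg = post.sum(axis=(0, 1, 2))

    def argmax4(a):
        return np.unravel_index(np.argmax(a), a.shape)

    im, iw, ig, il = argmax4(ll)
    best = (m[im], w[iw], g[ig], l[il])

    for _ in range(n_refine):
        bm, bw, bg, bl = best
        dm = (m_hi - m_lo) / (nm - 1)
        m = _grid(max(m_lo, bm - 1.5 * dm), min(m_hi, bm + 1.5 * dm), nm)
        wlo = max(w_lo, bw / 1.6)
        whi = min(w_hi, bw * 1.6)
        w = _grid(wlo, whi, nw, log=True)
        dg = (g_hi - g_lo) / (ng - 1)
        g = _grid(max(g_lo, bg - 1.5 * dg), min(g_hi, bg + 1.5 * dg), ng)
        dl = (l_hi - l_lo) / (nl - 1)
        l = _grid(max(l_lo, bl - 1.5 * dl), min(l_hi, bl + 1.5 * dl), nl)
        ll = _log_likelihood_grid(k, n, x, m, w, g, l, priors.family)
        im, iw, ig, il = argmax4(ll)
        best = (m[im], w[iw], g[ig], l[il])
        # next pass zooms relative to the narrowed box
        m_lo, m_hi = float(m[0]), float(m[-1])
        w_lo, w_hi = float(w[0]), float(w[-1])
        g_lo, g_hi = float(g[0]), float(g[-1])
        l_lo, l_hi = float(l[0]), float(l[-1])

    m_hat, w_hat, g_hat, l_hat = (float(v) for v in best)

    gamma_ci = _marginal_interval(
        _grid(*priors.guess_range, ng), g_marg, ci_level)
    lam_ci = _marginal_interval(
        _grid(*priors.lapse_range, nl), l_marg, ci_level)
    upper_ci = (1.0 - lam_ci[1], 1.0 - lam_ci[0])

    x50, slope50 = _x50_and_slope(m_hat, w_hat, g_hat, l_hat, priors.family)

    return PsychometricFit(
        midpoint_hat=m_hat, width_hat=w_hat,
        guess_hat=g_hat, lapse_hat=l_hat,
        x50=x50, slope50=slope50,
        lower_asymptote_ci=gamma_ci, upper_asymptote_ci=upper_ci,
        family=priors.family, degenerate=degenerate,
        guess_grid=_grid(*priors.guess_range, ng), guess_marginal=g_marg,
        lapse_grid=_grid(*priors.lapse_range, nl), lapse_marginal=l_marg,
    )


def _marginal_interval(grid: np.ndarray, weights: np.ndarray, level: float
                       ) -> tuple[float, float]:
    """Equal-tailed interval from a discrete marginal, by linear
    interpolation of the cumulative mass across grid points."""
    wsum = weights.sum()
    if wsum <= 0:
        return (float(grid[0]), float(grid[-1]))
    cdf = np.cumsum(weights) / wsum
    alpha = (1.0 - level) / 2.0
    lo = float(np.interp(alpha, cdf, grid, left=grid[0]))
    hi = float(np.interp(1.0 - alpha, cdf, grid, right=grid[-1]))
    return (lo, hi)


def _x50_and_slope(m: float, w: float, g: float, l: float, family: Family
                   ) -> tuple[Optional[float], Optional[float]]:
    height = 1.0 - g - l
    if height <= 0:
        return None, None
    s0 = (0.5 - g) / height
    if not (0.0 < s0 < 1.0):
        return None, None
    if family == "logistic":
        z0 = math.log(s0 / (1.0 - s0))
        dens = s0 * (1.0 - s0)
    else:
        z0 = float(ndtri(s0))
        dens = math.exp(-0.5 * z0 * z0) / math.sqrt(2.0 * math.pi)
    return m + w * z0, height * dens / w


def slope_at_midpoint(fit: PsychometricFit) -> float:
    """Slope d psi / dx at the point where psi = 0.5 (the participant's
    50% point), in proportion per continuum step."""
    if fit.slope50 is None:
        raise UndefinedSlopeError(
            "fitted curve does not cross 0.5; participant fails quality control"
        )
    return fit.slope50


def asymptote_intervals(fit: PsychometricFit) -> tuple[tuple[float, float],
                                                       tuple[float, float]]:
    """(lower-asymptote interval for gamma, upper-asymptote interval for
    1 - lambda), both 95% equal-tailed marginal credible intervals."""
    return fit.lower_asymptote_ci, fit.upper_asymptote_ci


def qc_exclude(fit: PsychometricFit) -> bool:
    """True if either asymptote's credible interval includes 0.5 (closed
    at the boundary), i.e. the fit cannot distinguish the participant's
    asymptotic performance from coin-flipping."""
    (g_lo, g_hi), (u_lo, u_hi) = asymptote_intervals(fit)
    return (g_lo <= 0.5 <= g_hi) or (u_lo <= 0.5 <= u_hi)


def brute_force_map(
    data: IdentificationData,
    priors: PriorSpec,
    m_grid: np.ndarray, w_grid: np.ndarray,
    g_grid: np.ndarray, l_grid: np.ndarray,
) -> tuple[float, float, float, float]:
    """Naive exhaustive grid search (pure-Python loops) over explicit
    grids; independent oracle for the vectorised fit at equal resolution."""
    x = np.asarray(data.steps, dtype=float)
    k = np.asarray(data.da_counts, dtype=float)
    n = data.reps_per_step
    best, best_ll = None, -np.inf
    for m, w, g, l in itertools.product(m_grid, w_grid, g_grid, l_grid):
        z = (x - m) / w
        s = _sigmoid(z, priors.family)
        psi = np.clip(g + (1 - g - l) * s, 1e-12, 1 - 1e-12)
        ll = float(np.sum(k * np.log(psi) + (n - k) * np.log1p(-psi)))
        if ll > best_ll:
            best_ll, best = ll, (float(m), float(w), float(g), float(l))
    return best
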