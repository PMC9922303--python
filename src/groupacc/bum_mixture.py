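"""Beta-uniform mixture (BUM) modeling of element p-values.

A group's empirical p-values are modeled as a mixture of U(0,1) (the
null component) and Beta(a, 1) with a in (0, 1] (an enrichment of small
p-values), with density

    f(x | a, lambda) = lambda + (1 - lambda) * a * x**(a - 1).

The statistic pi_ub = lambda + (1 - lambda) * a equals f(1) and upper
bounds the fraction of p-values generated under the null; 1 - pi_ub is
therefore a conservative lower bound on the accelerated fraction.  A
joint 95% confidence region for (a, lambda) — likelihood ratio within
the chi-square(2) cutoff of the maximum — is mapped through pi_ub to an
interval.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

_A_FLOOR = 1e-6  # open lower end of a's domain


@dataclass
class BUMFit:
    lam: float            # uniform mixing weight, lambda-hat
    a: float              # beta shape, a-hat
    log_likelihood: float
    pi_ub: float          # upper bound of the null fraction
    n: int
    ci: tuple[float, float] | None = None

    @property
    def prop_accelerated(self) -> float:
        """Conservative lower bound on the accelerated fraction."""
        return 1.0 - self.pi_ub


def bum_loglik(p_values, a: float, lam: float) -> float:
    """Log-likelihood of p-values under the beta-uniform mixture."""
    x = np.asarray(p_values, dtype=float)
    if x.size and (x.min() <= 0 or x.max() > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < a <= 1 or not 0 <= lam <= 1:
        raise ValueError("need 0 < a <= 1 and 0 <= lambda <= 1")
    dens = lam + (1.0 - lam) * a * x ** (a - 1.0)
    return float(np.sum(np.log(dens)))


def _grid_loglik(x: np.ndarray, a: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Vectorized loglik on an (a, lambda) grid; shape (len(a), len(lam)).

    Chunked over the a axis so the temporary stays modest for large n.
    """
    out = np.empty((a.size, lam.size))
    chunk = max(1, int(2e6 // max(1, lam.size * x.size)) + 1)
    for s in range(0, a.size, chunk):
        ab = a[s : s + chunk]
        xa = x[None, :] ** (ab[:, None] - 1.0) * ab[:, None]   # (A, n)
        dens = (
            lam[None, :, None]
            + (1.0 - lam[None, :, None]) * xa[:, None, :]
        )
        out[s : s + chunk] = np.log(dens).sum(axis=2)
    return out


def fit_bum(p_values, ci_level: float | None = 0.95) -> BUMFit:
    """Maximum-likelihood BUM fit with grid seeding and local refinement.

    A coarse 50x50 grid over (a, lambda) seeds bounded local
    optimization from the top grid points (the surface has a boundary
    ridge at lambda -> 1).  ``ci_level`` adds the joint-region interval
    for pi_ub; pass None to skip it.
    """
    x = np.asarray(list(p_values), dtype=float)
    if x.size < 20:
        warnings.warn(
            f"only {x.size} p-values; mixture fit will be unstable",
            RuntimeWarning,
        )
    if x.size == 0:
        raise ValueError("no p-values")
    if np.all(x == x[0]):
        warnings.warn("all p-values identical; degenerate fit", RuntimeWarning)

    a_grid = np.linspace(0.02, 1.0, 50)
    l_grid = np.linspace(0.0, 1.0, 50)
    ll = _grid_loglik(x, a_grid, l_grid)
    flat = np.argsort(ll, axis=None)[::-1][:3]
    starts = [
        (a_grid[i // len(l_grid)], l_grid[i % len(l_grid)]) for i in flat
    ]

    def nll(theta):
        a, lam = theta
        dens = lam + (1.0 - lam) * a * x ** (a - 1.0)
        return -np.sum(np.log(np.clip(dens, 1e-300, None)))

    best = None
    for a0, l0 in starts:
        res = minimize(
            nll, [np.clip(a0, _A_FLOOR, 1.0), l0],
            method="L-BFGS-B", bounds=[(_A_FLOOR, 1.0), (0.0, 1.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    a_hat, lam_hat = best.x
    fit = BUMFit(
        lam=float(lam_hat),
        a=float(a_hat),
        log_likelihood=float(-best.fun),
        pi_ub=float(lam_hat + (1.0 - lam_hat) * a_hat),
        n=int(x.size),
    )
    if ci_level is not None:
        fit.ci = bum_confidence_interval(x, fit, level=ci_level)
    return fit


def bum_confidence_interval(
    p_values, fit: BUMFit, level: float = 0.95, grid_size: int = 200
) -> tuple[float, float]:
    """Confidence interval for pi_ub from the joint (a, lambda) region.

    Retains every grid pair whose likelihood lies within the
    chi-square(2, level) cutoff of the maximum (5.991 at 95%), maps the
    retained pairs through pi_ub = lambda + (1 - lambda) a, and returns
    the min/max.  Cells on the region boundary are re-gridded at 4x
    resolution to sharpen the endpoints.
    """
    x = np.asarray(list(p_values), dtype=float)
    cutoff = chi2.ppf(level, df=2)
    a_grid = np.linspace(_A_FLOOR, 1.0, grid_size)
    l_grid = np.linspace(0.0, 1.0, grid_size)
    ll = _grid_loglik(x, a_grid, l_grid)
    keep = 2.0 * (fit.log_likelihood - ll) <= cutoff
    if not keep.any():
        raise RuntimeError(
            "no grid point falls in the confidence region; use a finer grid"
        )
    pis = l_grid[None, :] + (1.0 - l_grid[None, :]) * a_grid[:, None]
    lo = float(pis[keep].min())
    hi = float(pis[keep].max())

    # refine around boundary cells of the retained region
    boundary = keep & ~(
        np.roll(keep, 1, 0) & np.roll(keep, -1, 0)
        & np.roll(keep, 1, 1) & np.roll(keep, -1, 1)
    )
    da = (a_grid[1] - a_grid[0]) / 2.0
    dl = (l_grid[1] - l_grid[0]) / 2.0
    bi, bj = np.nonzero(boundary)
    if bi.size:
        sub_a = np.unique(np.clip(
            (a_grid[bi][:, None] + np.linspace(-da, da, 5)[None, :]).ravel(),
            _A_FLOOR, 1.0,
        ))
        sub_l = np.unique(np.clip(
            (l_grid[bj][:, None] + np.linspace(-dl, dl, 5)[None, :]).ravel(),
            0.0, 1.0,
        ))
        # cap refinement grid to keep memory bounded
        if sub_a.size * sub_l.size * x.size <= 4e8:
            ll2 = _grid_loglik(x, sub_a, sub_l)
            keep2 = 2.0 * (fit.log_likelihood - ll2) <= cutoff
            if keep2.any():
                pis2 = (
                    sub_l[None, :]
                    + (1.0 - sub_l[None, :]) * sub_a[:, None]
                )
                lo = min(lo, float(pis2[keep2].min()))
                hi = max(hi, float(pis2[keep2].max()))

    lo = min(lo, fit.pi_ub)
    hi = max(hi, fit.pi_ub)
    return lo, hi


def accelerated_count(fit: BUMFit, n_elements: int) -> float:
    """Expected number of accelerated elements, (1 - pi_ub) * n, unrounded."""
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    return (1.0 - fit.pi_ub) * n_elements
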