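"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own computational
paths: posterior quantities come from dense deterministic grid
integration (the latents are marginalized in closed form, so the
5-parameter posterior is integrable by brute force), and the default
Bayes factors come from fine-grid trapezoid quadrature in a different
parameterization than the implementation uses.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from scipy import special, stats


def grid_posterior_rho(
    x: np.ndarray,
    y: np.ndarray,
    se_x: float,
    se_y: float,
    bounds: Dict[str, Tuple[float, float]],
    n_mu: int = 25,
    n_sigma: int = 25,
    n_rho: int = 161,
) -> Dict[str, object]:
    """Brute-force posterior of rho by integrating the marginal bivariate
    normal likelihood (uniform priors) on a dense 5-d grid.

    The grid covers the prior box but concentrates on the region where
    the likelihood is non-negligible; a boundary-mass check guards
    against clipping the posterior.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx_hat = np.std(x, ddof=1)
    sy_hat = np.std(y, ddof=1)

    # locations: uniform grid over the data-supported range; scales:
    # geometric grid over the full prior tail with trapezoid weights
    def mu_axis(center, spread, lo, hi, m):
        return np.linspace(max(lo, center - spread), min(hi, center + spread), m)

    def sigma_axis(s_hat, lo, hi, m):
        return np.geomspace(max(0.2 * s_hat, lo, 1e-6), hi, m)

    def log_cell_widths(g):
        w = np.empty_like(g)
        w[1:-1] = (g[2:] - g[:-2]) / 2.0
        w[0] = (g[1] - g[0]) / 2.0
        w[-1] = (g[-1] - g[-2]) / 2.0
        return np.log(w)

    mu_x = mu_axis(x.mean(), 12 * sx_hat / np.sqrt(n), *bounds["mu_x"], n_mu)
    mu_y = mu_axis(y.mean(), 12 * sy_hat / np.sqrt(n), *bounds["mu_y"], n_mu)
    sigma_x = sigma_axis(sx_hat, *bounds["sigma_x"], n_sigma)
    sigma_y = sigma_axis(sy_hat, *bounds["sigma_y"], n_sigma)
    lw_sigma = log_cell_widths(sigma_x)[:, None] + log_cell_widths(sigma_y)[None, :]
    rho_edges = np.linspace(*bounds["rho"], n_rho + 1)
    rho = 0.5 * (rho_edges[:-1] + rho_edges[1:])

    # sufficient statistics (common covariance across observations)
    sx_ = x.sum()
    sy_ = y.sum()
    sxx = (x * x).sum()
    syy = (y * y).sum()
    sxy = (x * y).sum()

    mx = mu_x[:, None, None, None]
    my = mu_y[None, :, None, None]
    gx = sigma_x[None, None, :, None]
    gy = sigma_y[None, None, None, :]
    dxx = sxx - 2 * mx * sx_ + n * mx**2
    dyy = syy - 2 * my * sy_ + n * my**2
    dxy = sxy - mx * sy_ - my * sx_ + n * mx * my
    a = gx**2 + se_x**2
    b = gy**2 + se_y**2

    log_w = np.empty(n_rho)
    for k, r in enumerate(rho):
        c = r * gx * gy
        det = a * b - c**2
        quad = (b * dxx - 2 * c * dxy + a * dyy) / det
        ll = -0.5 * (n * np.log(4 * np.pi**2 * det) + quad) + lw_sigma[None, None, :, :]
        log_w[k] = special.logsumexp(ll)
    log_w -= log_w.max()
    w = np.exp(log_w)
    w /= w.sum()
    if w[0] + w[-1] > 1e-3:
        raise RuntimeError("grid posterior has mass at the rho boundary; widen the grid")
    mean = float(np.sum(w * rho))
    cdf = np.cumsum(w)
    ci = tuple(float(np.interp(q, cdf, rho)) for q in (0.025, 0.975))
    return {"rho_grid": rho, "weights": w, "mean": mean, "ci95": ci}


def sample_grid_rho(grid: Dict[str, object], n_draws: int, seed: int) -> np.ndarray:
    """IID draws of rho from the grid marginal (uniform jitter within cells)."""
    rng = np.random.default_rng(seed)
    rho = np.asarray(grid["rho_grid"])
    w = np.asarray(grid["weights"])
    step = rho[1] - rho[0]
    idx = rng.choice(rho.size, size=n_draws, p=w)
    return rho[idx] + rng.uniform(-0.5, 0.5, size=n_draws) * step


def bf10_pearson_quadrature(r: float, n: int, kappa: float = 1.0, m: int = 200001) -> float:
    """Trapezoid quadrature of the correlation Bayes factor integrand."""
    rho = np.linspace(-1 + 1e-9, 1 - 1e-9, m)
    log_lik = (
        0.5 * (n - 1) * np.log1p(-(rho**2))
        + (1.5 - n) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, 0.5 * (1 + rho * r)))
    )
    log_lik0 = np.log(special.hyp2f1(0.5, 0.5, n - 0.5, 0.5))
    a = 1.0 / kappa
    log_prior = (
        (a - 1.0) * np.log1p(-(rho**2)) - special.betaln(a, a) - (2 * a - 1) * np.log(2.0)
    )
    vals = np.exp(log_lik - log_lik0 + log_prior)
    return float(np.trapezoid(vals, rho))


def bf10_ttest_quadrature(
    t: float, n1: int, n2: int, scale: float = float(np.sqrt(2) / 2), m: int = 40001
) -> float:
    """JZS two-sample Bayes factor via the g-mixture parameterization
    (inverse-gamma mixture of normals), distinct from the noncentral-t
    route the implementation integrates."""
    nu = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    # integrate over u = log g for stability
    u = np.linspace(-12.0, 12.0, m)
    g = np.exp(u)
    # InverseGamma(1/2, scale^2/2) density in g, times Jacobian g
    log_ig = (
        0.5 * np.log(scale**2 / 2.0)
        - special.gammaln(0.5)
        - 1.5 * np.log(g)
        - scale**2 / (2.0 * g)
        + u  # Jacobian dg = g du
    )
    log_lik = -0.5 * np.log1p(n_eff * g) - 0.5 * (nu + 1) * np.log1p(
        t**2 / (nu * (1.0 + n_eff * g))
    )
    num = np.trapezoid(np.exp(log_lik + log_ig), u)
    den = (1.0 + t**2 / nu) ** (-0.5 * (nu + 1))
    return float(num / den)


def linear_interp_oracle(t0, v0, t1, v1, t):
    """Two-point line evaluation."""
    return v0 + (np.asarray(t) - t0) * (v1 - v0) / (t1 - t0)


def brute_force_window_mean(values: np.ndarray, i: int, half_n: int) -> float:
    lo = max(i - half_n, 0)
    hi = min(i + half_n, values.size - 1)
    return float(np.mean(values[lo : hi + 1]))


def standard_corr_posterior_draws(
    x: np.ndarray, y: np.ndarray, bounds: Dict[str, Tuple[float, float]],
    n_draws: int = 20000, seed: int = 0,
) -> np.ndarray:
    """IID rho draws from the *standard* Bayesian correlation posterior
    (no measurement error) under the same uniform priors, via the grid."""
    grid = grid_posterior_rho(x, y, 0.0, 0.0, bounds)
    return sample_grid_rho(grid, n_draws, seed)


def two_sided_from_directional(samples: np.ndarray) -> Tuple[int, int]:
    return int(np.sum(samples < 0)), int(np.sum(samples > 0))


def noncentral_t_pdf(t: float, df: int, nc: float) -> float:
    return float(stats.nct.pdf(t, df=df, nc=nc))
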