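"""Brute-force grid posteriors used as independent oracles.

Each oracle evaluates the unnormalised log posterior on a fine grid and
returns moments by direct summation — no conjugacy, no sampling — so the
closed-form full conditionals in the package can be checked against them.
"""

import numpy as np


def _grid_moments(grid: np.ndarray, logpost: np.ndarray) -> tuple[float, float]:
    w = np.exp(logpost - logpost.max())
    w = w / w.sum()
    mean = float(np.sum(w * grid))
    var = float(np.sum(w * (grid - mean) ** 2))
    return mean, var


def grid_normal_mean(x, sigma2, mu0, var0, span=8.0, n=40_001):
    """Posterior mean/var of a normal mean under a normal prior, by grid."""
    x = np.asarray(x, dtype=float)
    centre = (mu0 / var0 + x.sum() / sigma2) / (1.0 / var0 + len(x) / sigma2)
    width = span * np.sqrt(1.0 / (1.0 / var0 + len(x) / sigma2))
    grid = np.linspace(centre - width, centre + width, n)
    lp = -0.5 * (grid - mu0) ** 2 / var0
    for xi in x:
        lp = lp - 0.5 * (xi - grid) ** 2 / sigma2
    return _grid_moments(grid, lp)


def grid_variance(resid, shape, scale, hi_factor=60.0, n=200_001):
    """Posterior mean/var of a normal variance under an IG(shape, scale)
    prior, by grid on (0, hi]."""
    resid = np.asarray(resid, dtype=float)
    ss = float(np.sum(resid**2))
    post_mean_guess = (scale + ss / 2.0) / max(shape + len(resid) / 2.0 - 1.0, 0.5)
    grid = np.linspace(post_mean_guess / 1e3, post_mean_guess * hi_factor, n)
    lp = -(shape + 1.0) * np.log(grid) - scale / grid
    lp = lp - 0.5 * len(resid) * np.log(grid) - 0.5 * ss / grid
    return _grid_moments(grid, lp)


def grid_link(x, y, sigma2_r, a_mean, a_var, b_mean, b_var, span=8.0, n=501):
    """Posterior mean vector and covariance of (a, b) for the link regression
    y ~ N(a + b x, sigma2_r), by 2-D grid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    prec = X.T @ X / sigma2_r + np.diag([1.0 / a_var, 1.0 / b_var])
    cov = np.linalg.inv(prec)
    centre = cov @ (X.T @ y / sigma2_r + np.array([a_mean / a_var, b_mean / b_var]))
    sa, sb = span * np.sqrt(np.diag(cov))
    ag = np.linspace(centre[0] - sa, centre[0] + sa, n)
    bg = np.linspace(centre[1] - sb, centre[1] + sb, n)
    A, B = np.meshgrid(ag, bg, indexing="ij")
    lp = -0.5 * (A - a_mean) ** 2 / a_var - 0.5 * (B - b_mean) ** 2 / b_var
    for xi, yi in zip(x, y):
        lp = lp - 0.5 * (yi - A - B * xi) ** 2 / sigma2_r
    w = np.exp(lp - lp.max())
    w = w / w.sum()
    ma = float(np.sum(w * A))
    mb = float(np.sum(w * B))
    cov_out = np.array(
        [
            [np.sum(w * (A - ma) ** 2), np.sum(w * (A - ma) * (B - mb))],
            [np.sum(w * (A - ma) * (B - mb)), np.sum(w * (B - mb) ** 2)],
        ]
    )
    return np.array([ma, mb]), cov_out
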