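"""Population-size trajectories from growth-rate-matched Leslie matrices.

The fitted model yields posterior-predictive growth rates per year; each is
matched to the simulated vital-rate set whose matrix growth rate is nearest,
and the matched matrices drive an age-structured recursion n_{t+1} = A_t n_t.
The initial total is a Poisson draw with mean beta0 = round(mean lek count x
correction factor); the correction factor converts a male lek count into a
total population size via the proportion of males attending leks and the
female:male sex ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import VitalRates, build_matrix, growth_rate
from .integrated_model import PosteriorDraws, sample_log_lambda_d
from .lek_data import LekCountSeries

DEFAULT_CORRECTION = 4.73

__all__ = [
    "ProjectionConfig",
    "ProjectionResult",
    "correction_factor",
    "initial_mean",
    "draw_initial",
    "match_vital_rates",
    "project",
    "lek_population_index",
    "project_posterior",
]


@dataclass(frozen=True)
class ProjectionConfig:
    beta0: float
    correction: float = DEFAULT_CORRECTION
    n_trajectories: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.beta0 <= 0:
            raise ValueError("beta0 must be positive")
        if self.correction <= 0:
            raise ValueError("correction must be positive")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")


def correction_factor(prop_males_on_lek: float = 1.0 / 1.82, sex_ratio: float = 1.6) -> float:
    """Lek-count-to-population correction (1 + female:male ratio) / attendance.

    Defaults reproduce the conventional 4.73 used for sage-grouse: a 1.6:1
    female:male ratio and ~55% of males attending leks during a count.
    """
    if not 0 < prop_males_on_lek <= 1:
        raise ValueError("prop_males_on_lek must be in (0, 1]")
    if sex_ratio < 0:
        raise ValueError("sex_ratio must be non-negative")
    return (1.0 + sex_ratio) / prop_males_on_lek


def initial_mean(lek: LekCountSeries, window: tuple[int, int], correction: float) -> int:
    """beta0 = round(mean count over the year window x correction factor)."""
    if correction <= 0:
        raise ValueError("correction must be positive")
    y0, y1 = window
    mask = (lek.years >= y0) & (lek.years <= y1)
    if not mask.any():
        raise ValueError(f"window {window} outside data years")
    m = lek.males[mask]
    if np.isnan(m).any():
        raise ValueError("window contains missing counts; impute first")
    return int(round(float(m.mean()) * correction))


def draw_initial(beta0: float, rng) -> int:
    """Poisson(beta0) draw of the initial total population size."""
    if beta0 <= 0:
        raise ValueError("beta0 must be positive")
    return int(rng.poisson(beta0))


def match_vital_rates(lambda_targets: np.ndarray, table: pd.DataFrame) -> pd.DataFrame:
    """Nearest-growth-rate row of the simulated table for each target.

    Ties go to the lowest row index.  Targets outside the simulated range are
    matched to the extreme row and a coverage warning is emitted (the cue to
    increase the covariance inflation).
    """
    targets = np.atleast_1d(np.asarray(lambda_targets, dtype=float))
    if len(table) == 0:
        raise ValueError("empty vital-rate table")
    lam = table["lam"].to_numpy(dtype=float)
    idx = np.abs(lam[None, :] - targets[:, None]).argmin(axis=1)
    if targets.min() < lam.min() or targets.max() > lam.max():
        warnings.warn(
            "growth-rate target(s) outside the simulated range "
            f"[{lam.min():.3f}, {lam.max():.3f}]; consider a larger covariance inflation",
            RuntimeWarning,
        )
    return table.iloc[idx].reset_index(drop=True)


def _matrices_from_table(rows: pd.DataFrame) -> np.ndarray:
    A = np.empty((len(rows), 2, 2))
    A[:, 0, 0] = rows["f_y"]
    A[:, 0, 1] = rows["f_a"]
    A[:, 1, 0] = rows["s_yf"]
    A[:, 1, 1] = rows["s_af"]
    return A


def project(
    init: int,
    matched: pd.DataFrame,
    stable_age_init: bool = True,
    init_age: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic Leslie recursion; returns totals for each year.

    ``matched`` holds one vital-rate row per projected transition.  The
    initial total is split across age classes by the stable age distribution
    of the first matched matrix (or by ``init_age`` when given).  Output has
    length ``len(matched) + 1``, starting at the initial total.
    """
    if init < 0:
        raise ValueError("init must be non-negative")
    A = _matrices_from_table(matched)
    if init_age is not None:
        n = np.asarray(init_age, dtype=float)
    elif stable_age_init:
        gr = growth_rate(A[0])
        sa = gr.stable_age if not gr.degenerate else np.array([0.5, 0.5])
        n = init * sa
    else:
        n = np.array([init / 2.0, init / 2.0])
    totals = np.empty(len(A) + 1)
    totals[0] = n.sum()
    for t in range(len(A)):
        n = A[t] @ n
        totals[t + 1] = n.sum()
    return totals


def lek_population_index(lek: LekCountSeries, correction: float) -> pd.DataFrame:
    """Naive population estimate straight from the counts: M_t x correction."""
    if correction <= 0:
        raise ValueError("correction must be positive")
    if np.isnan(lek.males).any():
        raise ValueError("series has missing counts; impute first")
    return pd.DataFrame({"year": lek.years, "estimate": lek.males * correction})


@dataclass
class ProjectionResult:
    years: np.ndarray
    trajectories: np.ndarray  # (n_trajectories, n_years)
    summary: pd.DataFrame  # year, mean, q05, q95


def project_posterior(
    draws: PosteriorDraws,
    table: pd.DataFrame,
    config: ProjectionConfig,
    seed=None,
) -> ProjectionResult:
    """Trajectory cloud: one projection per sampled posterior draw.

    Each selected draw contributes its posterior-predictive demographic
    growth-rate sequence; every rate is matched to the nearest simulated
    vital-rate set, and the matched matrices project a Poisson(beta0) initial
    total forward.  Summaries are the per-year mean and 90% interval.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else config.seed
    )
    spec = draws.spec
    n_traj = config.n_trajectories
    pick = rng.choice(draws.n_draws, size=n_traj, replace=n_traj > draws.n_draws)
    lam_pred = np.exp(sample_log_lambda_d(draws, rng))[pick]  # (n_traj, T-1)
    lam_table = table["lam"].to_numpy(dtype=float)
    A_all = _matrices_from_table(table)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        trajectories = np.empty((n_traj, spec.n_years))
        for k in range(n_traj):
            idx = np.abs(lam_table[None, :] - lam_pred[k][:, None]).argmin(axis=1)
            init = draw_initial(config.beta0, rng)
            gr = growth_rate(A_all[idx[0]])
            n = init * (gr.stable_age if not gr.degenerate else np.array([0.5, 0.5]))
            trajectories[k, 0] = n.sum()
            for t, j in enumerate(idx):
                n = A_all[j] @ n
                trajectories[k, t + 1] = n.sum()
    cover = np.mean(
        (lam_pred >= lam_table.min()) & (lam_pred <= lam_table.max())
    )
    if cover < 0.99:
        warnings.warn(
            f"only {cover:.1%} of predicted growth rates fall inside the simulated "
            "range; consider a larger covariance inflation",
            RuntimeWarning,
        )
    q05, q95 = np.quantile(trajectories, [0.05, 0.95], axis=0)
    summary = pd.DataFrame(
        {
            "year": spec.years,
            "mean": trajectories.mean(axis=0),
            "q05": q05,
            "q95": q95,
        }
    )
    return ProjectionResult(years=spec.years.copy(), trajectories=trajectories, summary=summary)
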