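"""Posterior parameter estimation, time recalibration, and model checking.

Parameter estimation follows the Beaumont local-linear regression scheme on
the closest ``fraction`` of the chosen scenario's reference rows: each
parameter is mapped through a logit against its prior bounds, regressed on
the standardized summary statistics with Epanechnikov weights (bandwidth =
the largest accepted distance), and the weighted residuals are translated to
the fitted value at the observed point before back-transforming. Summaries
(mean, quantiles) are kernel-weighted; the mode comes from a weighted
Gaussian KDE with Silverman bandwidth on the back-transformed scale.

Divergence times are in generations; ``recalibrate_time`` converts them to
calendar years with the species' generation time (default 8, range 6-10
years).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .coalsim import GroupConfig, simulate_dataset
from .reference import ReferenceTable
from .scenarios import ParameterDraw, Scenario
from .sumstats import sumstats_from_counts

__all__ = [
    "PosteriorEstimate",
    "PosteriorRegressor",
    "estimate_parameters",
    "recalibrate_time",
    "model_check",
    "ModelCheckReport",
    "stat_split",
]

QUANTILES = (0.025, 0.05, 0.5, 0.95, 0.975)


@dataclass
class PosteriorEstimate:
    """Adjusted posterior summaries per parameter, plus the adjusted sample."""

    param_names: tuple[str, ...]
    mean: dict[str, float]
    median: dict[str, float]
    mode: dict[str, float]
    quantiles: dict[str, dict[float, float]]
    n_accepted: int
    fraction: float
    bounds: dict[str, tuple[float, float]]
    samples: np.ndarray = field(repr=False, default=None)  # (n_accepted, n_params)
    weights: np.ndarray = field(repr=False, default=None)

    def summary_frame(self):
        import pandas as pd

        rows = []
        for p in self.param_names:
            row = {"parameter": p, "mean": self.mean[p], "median": self.median[p],
                   "mode": self.mode[p]}
            row.update({f"q{q}": self.quantiles[p][q] for q in QUANTILES})
            rows.append(row)
        return pd.DataFrame(rows)


def _weighted_quantile(x: np.ndarray, w: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    cw = (cw - 0.5 * w) / w.sum()
    return np.interp(qs, cw, x)


class PosteriorRegressor(BaseEstimator, RegressorMixin):
    """Local-linear ABC posterior adjustment as a scikit-learn estimator.

    Fit on one scenario's reference rows (X = summary statistics, Y =
    parameter draws); ``estimate`` returns the full adjusted posterior for
    one observed statistic vector, ``predict`` just its posterior means.
    """

    def __init__(self, bounds: dict[str, tuple[float, float]] | None = None,
                 fraction: float = 0.01, min_accept: int = 50,
                 scale: str = "sd", adjust: str = "loclinear"):
        self.bounds = bounds
        self.fraction = fraction
        self.min_accept = min_accept
        self.scale = scale
        self.adjust = adjust

    def fit(self, X, Y, param_names=None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if param_names is None:
            param_names = tuple(f"p{i}" for i in range(Y.shape[1]))
        if self.bounds is None:
            raise ValueError("prior bounds are required for the logit transform")
        for p in param_names:
            if p not in self.bounds:
                raise ValueError(f"no prior bounds for parameter {p!r}")
        s = X.std(axis=0, ddof=1) if self.scale == "sd" else \
            np.median(np.abs(X - np.median(X, axis=0)), axis=0) * 1.4826
        keep = s > 1e-12 * np.maximum(np.abs(X).max(axis=0), 1.0)
        if not keep.any():
            raise ValueError("all statistic columns have zero variance")
        self.param_names_ = tuple(param_names)
        self.columns_kept_ = keep
        self.scale_ = s[keep]
        self.X_ = X[:, keep] / self.scale_
        self.Y_ = Y
        return self

    def estimate(self, x_obs) -> PosteriorEstimate:
        check_is_fitted(self, "X_")
        x = np.asarray(x_obs, dtype=float).ravel()
        z0 = x[self.columns_kept_] / self.scale_
        d = np.sqrt(((self.X_ - z0) ** 2).sum(axis=1))
        n_sel = int(np.ceil(self.fraction * len(d)))
        if n_sel < self.min_accept:
            raise ValueError(
                f"insufficient acceptance: fraction {self.fraction} of "
                f"{len(d)} rows yields {n_sel} < {self.min_accept}"
            )
        sel = np.argsort(d, kind="stable")[:n_sel]
        dmax = d[sel].max()
        if dmax == 0.0:  # observed coincides with reference rows
            w = np.ones(n_sel)
        else:
            t = d[sel] / (dmax * (1.0 + 1e-9))
            w = 1.0 - t * t
        w = np.maximum(w, 1e-12)

        eps = 1e-10
        bounds = [self.bounds[p] for p in self.param_names_]
        Ysel = self.Y_[sel]
        U = np.empty_like(Ysel)
        for j, (a, b) in enumerate(bounds):
            frac = np.clip((Ysel[:, j] - a) / (b - a), eps, 1.0 - eps)
            U[:, j] = logit(frac)

        if self.adjust == "loclinear":
            Z = np.column_stack([np.ones(n_sel), self.X_[sel]])
            zq = np.concatenate([[1.0], z0])
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(Z * sw[:, None], U * sw[:, None], rcond=None)
            fitted_obs = zq @ coef
            U_adj = U - Z @ coef + fitted_obs  # residuals shifted to the observed point
        elif self.adjust == "rejection":
            U_adj = U  # plain weighted rejection sampling, no regression step
        else:
            raise ValueError(f"unknown adjust mode {self.adjust!r}")

        samples = np.empty_like(U_adj)
        for j, (a, b) in enumerate(bounds):
            samples[:, j] = a + (b - a) * expit(U_adj[:, j])

        mean, median, mode, quant = {}, {}, {}, {}
        for j, p in enumerate(self.param_names_):
            xj = samples[:, j]
            mean[p] = float(np.average(xj, weights=w))
            qs = _weighted_quantile(xj, w, QUANTILES)
            quant[p] = dict(zip(QUANTILES, map(float, qs)))
            median[p] = quant[p][0.5]
            mode[p] = _kde_mode(xj, w, bounds[j])
        return PosteriorEstimate(self.param_names_, mean, median, mode, quant,
                                 n_sel, self.fraction,
                                 {p: self.bounds[p] for p in self.param_names_},
                                 samples, w)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([
            [self.estimate(row).mean[p] for p in self.param_names_] for row in X
        ])


def _kde_mode(x: np.ndarray, w: np.ndarray, bounds: tuple[float, float]) -> float:
    if np.allclose(x, x[0]):
        return float(x[0])
    try:
        kde = gaussian_kde(x, bw_method="silverman", weights=w)
    except np.linalg.LinAlgError:
        return float(np.average(x, weights=w))
    lo, hi = max(bounds[0], x.min()), min(bounds[1], x.max())
    grid = np.linspace(lo, hi, 512)
    return float(grid[int(np.argmax(kde(grid)))])


def estimate_parameters(
    ref: ReferenceTable,
    observed,
    scenario_id: int,
    fraction: float = 0.01,
    min_accept: int = 50,
    adjust: str = "loclinear",
) -> PosteriorEstimate:
    """Adjusted posterior for one scenario's parameters given observed stats."""
    from .modelchoice import _observed_vector

    scenario = ref.scenario_by_id(scenario_id)
    mask = ref.labels() == scenario_id
    if not mask.any():
        raise ValueError(f"no reference rows for scenario {scenario_id}")
    params = [p for p in scenario.parameters if p in ref.param_names]
    Y = ref.frame.loc[mask, params].to_numpy(dtype=float)
    X = ref.stats()[mask]
    bounds = {p: ref.priors.bounds_for(p) for p in params}
    reg = PosteriorRegressor(bounds=bounds, fraction=fraction,
                             min_accept=min_accept, adjust=adjust)
    reg.fit(X, Y, param_names=params)
    return reg.estimate(_observed_vector(ref, observed))


def recalibrate_time(
    t_mean, gen_time: float = 8.0, gen_range: tuple[float, float] = (6.0, 10.0)
):
    """Convert a divergence time in generations to calendar years.

    Returns ``(central, low, high)`` = t x (gen_time, gen_range[0],
    gen_range[1]); accepts scalars or arrays (e.g. posterior quantiles).
    """
    t = np.asarray(t_mean, dtype=float)
    if np.any(t < 0):
        raise ValueError("divergence times must be non-negative")
    central, low, high = t * gen_time, t * gen_range[0], t * gen_range[1]
    if np.isscalar(t_mean) or t.ndim == 0:
        return float(central), float(low), float(high)
    return central, low, high


# ---------------------------------------------------------------------------
# model checking

#: the default disjoint split of statistic families: estimation uses FST and
#: gene diversities, the "less biased" check uses Nei and admixture statistics
def stat_split(stat_names) -> tuple[tuple[str, ...], tuple[str, ...]]:
    est = tuple(s for s in stat_names if s.startswith(("fst_", "gd_")))
    chk = tuple(s for s in stat_names if s.startswith(("nei_", "adm_")))
    return est, chk


@dataclass
class ModelCheckReport:
    """Posterior-predictive goodness-of-fit in summary-statistic space."""

    stat_names: tuple[str, ...]
    pc_prior: np.ndarray
    pc_posterior: np.ndarray
    pc_observed: np.ndarray
    variance_ratios: np.ndarray
    tail_probabilities: dict[str, float]

    def observed_in_posterior_hull(self) -> bool:
        """Is the observed point inside the posterior cloud's PC1/PC2 box?"""
        lo = self.pc_posterior[:, :2].min(axis=0)
        hi = self.pc_posterior[:, :2].max(axis=0)
        return bool(np.all(self.pc_observed[:2] >= lo) and np.all(self.pc_observed[:2] <= hi))


def model_check(
    ref: ReferenceTable,
    posterior: PosteriorEstimate,
    scenario: Scenario,
    groups: GroupConfig,
    n_loci: int,
    observed,
    n_posterior_sims: int = 200,
    stat_subset=None,
    seed: int = 0,
) -> ModelCheckReport:
    """Posterior-predictive model check in PCA summary-statistic space.

    Draws parameter vectors from the adjusted posterior sample (weighted
    resampling), simulates datasets, and compares their statistics with the
    observed vector: a PCA fitted on the prior-predictive (reference)
    statistics locates the prior cloud, the posterior-predictive cloud and
    the observed point; per-statistic two-sided posterior-predictive tail
    probabilities are reported. ``stat_subset`` restricts the check to a
    disjoint statistic set for the less biased variant.
    """
    from .modelchoice import _observed_vector

    names = tuple(stat_subset) if stat_subset is not None else tuple(ref.stat_names)
    if len(names) == 0:
        raise ValueError("stat_subset must not be empty")
    unknown = set(names) - set(ref.stat_names)
    if unknown:
        raise ValueError(f"unknown statistics in subset: {sorted(unknown)}")
    cols = [ref.stat_names.index(s) for s in names]
    x_obs = _observed_vector(ref, observed)[cols]

    from .reference import draw_stats_with_retry

    rng = np.random.default_rng(np.random.SeedSequence([seed, scenario.id]))
    w = posterior.weights / posterior.weights.sum()

    def resample_draw(r):
        row = r.choice(len(posterior.samples), p=w)
        values = dict(zip(posterior.param_names, posterior.samples[row]))
        return ParameterDraw(scenario_id=scenario.id, values=values)

    sims = np.empty((n_posterior_sims, len(names)))
    for i in range(n_posterior_sims):
        _, stats, _ = draw_stats_with_retry(
            resample_draw, scenario, groups, n_loci, ref.trios, rng
        )
        sims[i] = stats.values[cols]

    prior_stats = ref.stats()[:, cols]
    # statistics live on heterogeneous scales; standardize by the reference
    # SD (the pipeline's distance convention) before the PCA
    mu = prior_stats.mean(axis=0)
    sd = prior_stats.std(axis=0, ddof=1)
    sd = np.where(sd > 1e-12 * np.maximum(np.abs(prior_stats).max(axis=0), 1.0),
                  sd, 1.0)
    pca = PCA()  # all components, so variance proportions sum to 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pc_prior = pca.fit_transform((prior_stats - mu) / sd)
    pc_post = pca.transform((sims - mu) / sd)
    pc_obs = pca.transform(((x_obs - mu) / sd)[None, :])[0]

    tails = {}
    for j, s in enumerate(names):
        lo = float((sims[:, j] <= x_obs[j]).mean())
        hi = float((sims[:, j] >= x_obs[j]).mean())
        tails[s] = min(lo, hi)
    return ModelCheckReport(names, pc_prior, pc_post, pc_obs,
                            pca.explained_variance_ratio_, tails)
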