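"""Scenario choice: direct (nearest-neighbour) and logistic-regression ABC.

Both approaches are exposed through :class:`ScenarioClassifier`, a
scikit-learn-style estimator fitted on reference-table rows (X = summary
statistics, y = scenario labels). Every statistic is standardized by its
reference-table standard deviation before Euclidean distances are computed
(zero-variance columns are dropped with a warning).

* direct — the posterior probability of each scenario is its share among the
  ``k`` nearest rows; 95% CIs are Clopper-Pearson intervals on the counts.
* logistic — the closest ``fraction`` of rows is projected onto linear
  discriminant axes; a multinomial logistic regression of scenario label on
  the discriminant scores, weighted by an Epanechnikov kernel of distance,
  is evaluated at the observed point (Beaumont-style regression adjustment
  for model choice); 95% CIs come from the asymptotic covariance of the
  regression coefficients via the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

from .coalsim import simulate_dataset
from .reference import ReferenceTable
from .scenarios import sample_prior
from .sumstats import SumStatVector, sumstats_from_counts

__all__ = [
    "ScenarioClassifier",
    "ModelChoiceResult",
    "PriorErrorResult",
    "direct_pp",
    "logistic_pp",
    "prior_error_rate",
]


@dataclass
class ModelChoiceResult:
    """Per-scenario posterior probabilities with 95% CIs."""

    method: str
    scenario_ids: tuple[int, ...]
    pp: np.ndarray
    ci: np.ndarray  # (n_scenarios, 2)
    k: int | None = None
    fraction: float | None = None
    distance: str = "euclidean/sd-standardized"
    warnings: list[str] = field(default_factory=list)

    def best(self) -> int:
        return int(self.scenario_ids[int(np.argmax(self.pp))])

    def as_dict(self) -> dict[int, float]:
        return {int(s): float(p) for s, p in zip(self.scenario_ids, self.pp)}


def _clopper_pearson(count: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = (1.0 - level) / 2.0
    lo = 0.0 if count == 0 else float(beta_dist.ppf(a, count, n - count + 1))
    hi = 1.0 if count == n else float(beta_dist.ppf(1 - a, count + 1, n - count))
    return lo, hi


def epanechnikov(d: np.ndarray, bandwidth: float) -> np.ndarray:
    """Epanechnikov kernel weights; bandwidth = the largest accepted distance."""
    t = d / bandwidth
    return np.where(t < 1.0, 1.0 - t * t, 0.0)


# ---------------------------------------------------------------------------
# weighted multinomial logistic regression (Newton-Raphson)

def _fit_multinomial_logit(Z, y_idx, w, n_classes, ridge=1.0, max_iter=200, tol=1e-10):
    """Fit a weighted multinomial logit by Newton-Raphson; baseline class 0.

    A weak L2 penalty (``ridge``, default 1) on the coefficients keeps the
    fit finite under quasi-complete separation, which is routine when the
    accepted subset holds only tens of rows per scenario; with the large
    information matrices of production-size subsets its effect is negligible.
    Returns (B, cov): coefficients of shape (n_classes-1, p) and the inverse
    penalized observed information (covariance of vec(B)), or (B, None) when
    the information matrix stays singular.
    """
    n, p = Z.shape
    C = n_classes
    B = np.zeros((C - 1, p))
    Y = np.zeros((n, C))
    Y[np.arange(n), y_idx] = 1.0
    lam = ridge
    cov = None
    for _ in range(max_iter):
        eta = Z @ B.T  # (n, C-1)
        logits = np.concatenate([np.zeros((n, 1)), eta], axis=1)
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        grad = np.empty((C - 1, p))
        for j in range(1, C):
            grad[j - 1] = (w * (Y[:, j] - P[:, j])) @ Z
        H = np.empty(((C - 1) * p, (C - 1) * p))
        for j in range(1, C):
            for k in range(1, C):
                wjk = w * P[:, j] * ((j == k) - P[:, k])
                H[(j - 1) * p:j * p, (k - 1) * p:k * p] = (Z * wjk[:, None]).T @ Z
        grad_pen = grad.ravel() - lam * B.ravel()
        H_reg = H + lam * np.eye(H.shape[0])
        try:
            step = np.linalg.solve(H_reg, grad_pen)
            cov = np.linalg.inv(H_reg)
        except np.linalg.LinAlgError:
            lam = max(lam * 100.0, 1e-3)
            continue
        B = B + step.reshape(C - 1, p)
        if np.max(np.abs(grad_pen)) < tol or np.max(np.abs(step)) < 1e-12:
            break
    return B, cov


def _multinomial_probs(B: np.ndarray, z0: np.ndarray) -> np.ndarray:
    eta = np.concatenate([[0.0], B @ z0])
    eta -= eta.max()
    p = np.exp(eta)
    return p / p.sum()


def _delta_ci(B, cov, z0, level=0.95):
    """Delta-method CIs for class probabilities at one design point."""
    from scipy.stats import norm

    C = B.shape[0] + 1
    p = B.shape[1]
    probs = _multinomial_probs(B, z0)
    zq = norm.ppf(1 - (1 - level) / 2)
    ci = np.empty((C, 2))
    for c in range(C):
        g = np.empty((C - 1) * p)
        for j in range(1, C):
            dp_deta = probs[c] * ((c == j) - probs[j])
            g[(j - 1) * p:j * p] = dp_deta * z0
        var = float(g @ cov @ g)
        half = zq * np.sqrt(max(var, 0.0))
        ci[c] = (max(0.0, probs[c] - half), min(1.0, probs[c] + half))
    return probs, ci


class ScenarioClassifier(BaseEstimator, ClassifierMixin):
    """ABC scenario choice as a scikit-learn classifier.

    Parameters
    ----------
    method : "direct" or "logistic".
    k : number of nearest reference rows used by the direct approach.
    fraction : closest fraction of rows used by the logistic approach.
    scale : "sd" (reference-table standard deviation) or "mad".
    """

    def __init__(self, method: str = "direct", k: int = 500,
                 fraction: float = 0.01, scale: str = "sd", ridge: float = 1.0):
        self.method = method
        self.k = k
        self.fraction = fraction
        self.scale = scale
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if self.method not in ("direct", "logistic"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.scale == "sd":
            s = X.std(axis=0, ddof=1)
        elif self.scale == "mad":
            s = np.median(np.abs(X - np.median(X, axis=0)), axis=0) * 1.4826
        else:
            raise ValueError(f"unknown scale {self.scale!r}")
        # constant columns leave float residue in the SD; compare relatively
        keep = s > 1e-12 * np.maximum(np.abs(X).max(axis=0), 1.0)
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance statistic column(s)"
            )
        if not keep.any():
            raise ValueError("all statistic columns have zero variance")
        self.columns_kept_ = keep
        self.scale_ = s[keep]
        self.X_ = X[:, keep] / self.scale_
        self.classes_ = np.unique(y)
        self.y_ = y
        return self

    def _distances(self, x: np.ndarray) -> np.ndarray:
        z = x[self.columns_kept_] / self.scale_
        return np.sqrt(((self.X_ - z) ** 2).sum(axis=1))

    def choose(self, x) -> ModelChoiceResult:
        """Full model-choice result (PPs and 95% CIs) for one observed vector."""
        check_is_fitted(self, "X_")
        x = np.asarray(x, dtype=float).ravel()
        d = self._distances(x)
        if self.method == "direct":
            return self._choose_direct(d)
        return self._choose_logistic(x, d)

    def _choose_direct(self, d: np.ndarray) -> ModelChoiceResult:
        k = self.k
        if k > len(d):
            raise ValueError(f"k={k} exceeds the {len(d)} reference rows")
        # stable sort: ties at the k-th distance break by row order
        nearest = np.argsort(d, kind="stable")[:k]
        labels = self.y_[nearest]
        pp = np.empty(len(self.classes_))
        ci = np.empty((len(self.classes_), 2))
        for i, c in enumerate(self.classes_):
            count = int((labels == c).sum())
            pp[i] = count / k
            ci[i] = _clopper_pearson(count, k)
        return ModelChoiceResult("direct", tuple(int(c) for c in self.classes_),
                                 pp, ci, k=k)

    def _choose_logistic(self, x: np.ndarray, d: np.ndarray) -> ModelChoiceResult:
        n_sel = max(int(np.ceil(self.fraction * len(d))), 2)
        sel = np.argsort(d, kind="stable")[:n_sel]
        msgs: list[str] = []
        labels = self.y_[sel]
        present = np.unique(labels)
        pp = np.zeros(len(self.classes_))
        ci = np.zeros((len(self.classes_), 2))
        ci[:, 1] = 1.0
        if len(present) < 2:
            msgs.append("selected subset contains a single scenario")
            warnings.warn(msgs[-1])
            pp[self.classes_ == present[0]] = 1.0
            ci[self.classes_ == present[0]] = (1.0, 1.0)
            return ModelChoiceResult("logistic", tuple(int(c) for c in self.classes_),
                                     pp, ci, fraction=self.fraction, warnings=msgs)
        Xs = self.X_[sel]
        z_obs = x[self.columns_kept_] / self.scale_
        lda = LinearDiscriminantAnalysis(solver="svd")
        try:
            scores = lda.fit_transform(Xs, labels)
            s0 = lda.transform(z_obs[None, :])[0]
        except np.linalg.LinAlgError:
            msgs.append("singular discriminant fit; ridge-regularized projection")
            warnings.warn(msgs[-1])
            lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=0.1)
            scores = lda.fit_transform(Xs, labels)
            s0 = lda.transform(z_obs[None, :])[0]
        dmax = d[sel].max() * (1.0 + 1e-9)
        w = epanechnikov(d[sel], dmax)
        w = np.maximum(w, 1e-12)
        Z = np.column_stack([np.ones(len(scores)), scores])
        z0 = np.concatenate([[1.0], s0])
        idx_map = {c: i for i, c in enumerate(present)}
        y_idx = np.array([idx_map[c] for c in labels])
        B, cov = _fit_multinomial_logit(Z, y_idx, w, len(present), ridge=self.ridge)
        if cov is None:
            msgs.append("singular information matrix; probabilities without CIs")
            warnings.warn(msgs[-1])
            probs = _multinomial_probs(B, z0)
            sub_ci = np.column_stack([np.zeros(len(present)), np.ones(len(present))])
        else:
            probs, sub_ci = _delta_ci(B, cov, z0)
        for c, prob, bounds in zip(present, probs, sub_ci):
            i = int(np.flatnonzero(self.classes_ == c)[0])
            pp[i] = prob
            ci[i] = bounds
        # absent scenarios get probability 0 with a degenerate CI
        for i, c in enumerate(self.classes_):
            if c not in idx_map:
                ci[i] = (0.0, 0.0)
        return ModelChoiceResult("logistic", tuple(int(c) for c in self.classes_),
                                 pp, ci, fraction=self.fraction, warnings=msgs)

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([self.choose(row).pp for row in X])

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# reference-table front ends

def _observed_vector(ref: ReferenceTable, observed) -> np.ndarray:
    if isinstance(observed, SumStatVector):
        if tuple(observed.names) != tuple(ref.stat_names):
            raise ValueError("observed statistic names do not match the reference table")
        return observed.values
    return np.asarray(observed, dtype=float).ravel()


def _classifier(ref: ReferenceTable, method: str, **kw) -> ScenarioClassifier:
    clf = ScenarioClassifier(method=method, **kw)
    return clf.fit(ref.stats(), ref.labels())


def direct_pp(ref: ReferenceTable, observed, k: int = 500) -> ModelChoiceResult:
    """Direct-approach scenario posterior probabilities."""
    return _classifier(ref, "direct", k=k).choose(_observed_vector(ref, observed))


def logistic_pp(ref: ReferenceTable, observed, fraction: float = 0.01) -> ModelChoiceResult:
    """Logistic-regression scenario posterior probabilities."""
    return _classifier(ref, "logistic", fraction=fraction).choose(
        _observed_vector(ref, observed)
    )


@dataclass
class PriorErrorResult:
    """Scenario-specific prior-based error (type I error) of model choice."""

    true_scenario: int
    method: str
    n_pods: int
    error_rate: float
    winner_counts: dict[int, int]

    @property
    def n_errors(self) -> int:
        return round(self.error_rate * self.n_pods)


def prior_error_rate(
    ref: ReferenceTable,
    true_scenario: int,
    n_pods: int = 1000,
    method: str = "direct",
    seed: int = 0,
    k: int = 500,
    fraction: float = 0.01,
) -> PriorErrorResult:
    """Fraction of fresh pods whose true scenario fails to win the highest PP.

    Pods are simulated anew from the prior under ``true_scenario`` (never
    resampled reference rows); ties for the highest posterior probability
    count as errors (conservative).
    """
    scenario = ref.scenario_by_id(true_scenario)
    clf = _classifier(ref, method, k=k, fraction=fraction)
    from .reference import draw_stats_with_retry

    rng = np.random.default_rng(np.random.SeedSequence([seed, true_scenario]))
    errors = 0
    winners: dict[int, int] = {}
    for _ in range(n_pods):
        _, stats, _ = draw_stats_with_retry(
            lambda r: sample_prior(scenario, ref.priors, r), scenario,
            ref.groups, ref.n_loci, ref.trios, rng,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = clf.choose(stats.values)
        top = res.pp.max()
        top_ids = [int(s) for s, p in zip(res.scenario_ids, res.pp) if p == top]
        winner = top_ids[0] if len(top_ids) == 1 else -1  # -1 marks a tie
        winners[winner] = winners.get(winner, 0) + 1
        if winner != true_scenario:
            errors += 1
    return PriorErrorResult(true_scenario, method, n_pods, errors / n_pods, winners)
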