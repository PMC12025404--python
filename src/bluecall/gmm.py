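"""Gaussian mixture modelling: EM fitting, BIC model selection, posterior-
probability feature ranking, MAP clustering and ML classification.

The mixture has full covariance matrices with a small ridge on the diagonal
for numerical stability.  EM starts from a seeded k-means partition, runs
the usual E (log-space responsibilities) and M steps until the relative
log-likelihood change falls below tolerance, and the best of several
restarts is kept.  Feature reduction ranks feature columns by the magnitude
of their mean posterior probability (MPP) statistic — the posterior-weighted
mean of each standardised feature per component — and keeps the top zeta
columns.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

_LOG2PI = float(np.log(2 * np.pi))


def _component_log_pdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate normal log-density of each row of X."""
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    z = solve_triangular(L, (X - mean).T, lower=True)
    log_det = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * _LOG2PI + log_det + np.sum(z * z, axis=0))


class GaussianMixtureModel:
    """A Gaussian mixture to be fitted to an (n x d) feature matrix.

    Parameters
    ----------
    X : array-like, shape (n, d)
        Observations (e.g. log-entropy feature rows, one per window).

    ``fit`` returns a :class:`GaussianMixtureResults` carrying the estimated
    parameters, diagnostics and prediction methods.
    """

    def __init__(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("X must be a non-empty 2-D array")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries")
        self.endog = X
        self.n_obs, self.n_features = X.shape

    # -- fitting -----------------------------------------------------------
    def fit(self, n_components: int, seed: int = 0, reg_covar: float = 1e-6,
            tol: float = 1e-6, max_iter: int = 500, n_init: int = 5
            ) -> "GaussianMixtureResults":
        """EM fit with ``n_init`` seeded k-means restarts; best kept."""
        K = int(n_components)
        n, d = self.endog.shape
        if K < 1:
            raise ValueError("n_components must be >= 1")
        if K > n:
            raise ValueError(f"n_components={K} exceeds n={n} observations")
        if n <= K * d:
            log.info("n=%d observations for K*d=%d mean parameters; "
                     "estimates may be unstable", n, K * d)
        best = None
        rng = np.random.default_rng(seed)
        for _ in range(max(1, n_init)):
            init_seed = int(rng.integers(0, 2 ** 31 - 1))
            res = self._fit_once(K, init_seed, reg_covar, tol, max_iter)
            if best is None or res.llf > best.llf:
                best = res
        best.seed = seed
        return best

    def _fit_once(self, K, init_seed, reg_covar, tol, max_iter):
        X = self.endog
        n, d = X.shape
        if K == 1:
            resp = np.ones((n, 1))
        else:
            km = KMeans(n_clusters=K, n_init=1, random_state=init_seed).fit(X)
            resp = np.zeros((n, K))
            resp[np.arange(n), km.labels_] = 1.0
        weights, means, covs = self._m_step(resp, reg_covar)
        llf = -np.inf
        history: list[float] = []
        converged = False
        for _ in range(max_iter):
            log_resp, llf_new = self._e_step(weights, means, covs)
            history.append(llf_new)
            if np.isfinite(llf) and abs(llf_new - llf) <= tol * (1.0 + abs(llf_new)):
                converged = True
                llf = llf_new
                break
            llf = llf_new
            weights, means, covs = self._m_step(np.exp(log_resp), reg_covar)
        return GaussianMixtureResults(
            model=self, weights=weights, means=means, covariances=covs,
            llf=float(llf), loglik_history=history, converged=converged,
            reg_covar=reg_covar, seed=init_seed)

    def _e_step(self, weights, means, covs):
        X = self.endog
        K = len(weights)
        log_prob = np.empty((X.shape[0], K))
        for j in range(K):
            log_prob[:, j] = np.log(weights[j]) + _component_log_pdf(
                X, means[j], covs[j])
        norm = logsumexp(log_prob, axis=1)
        return log_prob - norm[:, None], float(norm.sum())

    def _m_step(self, resp, reg_covar):
        X = self.endog
        n, d = X.shape
        nk = resp.sum(axis=0) + 10 * np.finfo(float).eps
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = np.empty((resp.shape[1], d, d))
        for j in range(resp.shape[1]):
            diff = X - means[j]
            covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j]
            covs[j].flat[:: d + 1] += reg_covar
            try:
                np.linalg.cholesky(covs[j])
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"component {j} covariance singular despite ridge "
                    f"{reg_covar}") from exc
        return weights, means, covs


@dataclass
class GaussianMixtureResults:
    """Fitted mixture parameters plus diagnostics and prediction methods."""

    model: GaussianMixtureModel
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    llf: float
    loglik_history: list[float]
    converged: bool
    reg_covar: float
    seed: int
    #: Optional component index -> class token map (attached after training).
    class_map: dict[int, str] | None = None

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def k_free_parameters(self) -> int:
        """Free parameters of a K-component full-covariance mixture in d dims."""
        K, d = self.n_components, self.n_features
        return (K - 1) + K * d + K * d * (d + 1) // 2

    # -- inference ---------------------------------------------------------
    def _check(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :] if X.shape[0] == self.n_features else X[:, None]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"data has {X.shape[1]} features, model expects {self.n_features}")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite rows in input")
        return X

    def component_log_likelihood(self, X) -> np.ndarray:
        """Per-component log density log p(x | theta_j), weight-free: (n x K)."""
        X = self._check(X)
        out = np.empty((X.shape[0], self.n_components))
        for j in range(self.n_components):
            out[:, j] = _component_log_pdf(X, self.means[j], self.covariances[j])
        return out

    def loglike(self, X) -> float:
        """Total mixture log-likelihood of the rows of X."""
        lp = self.component_log_likelihood(X) + np.log(self.weights)
        return float(logsumexp(lp, axis=1).sum())

    def posteriors(self, X) -> np.ndarray:
        """Responsibilities P(j | x_i), rows summing to 1 (log-space stabilised)."""
        lp = self.component_log_likelihood(X) + np.log(self.weights)
        return np.exp(lp - logsumexp(lp, axis=1)[:, None])

    def bic(self, X=None) -> float:
        """-2 log L + k log n with the analytic free-parameter count."""
        if X is None:
            X = self.model.endog
        X = self._check(X)
        return -2.0 * self.loglike(X) + self.k_free_parameters() * np.log(X.shape[0])

    def map_cluster(self, X) -> np.ndarray:
        """Maximum-a-posteriori component assignment (ties -> lowest index)."""
        return np.argmax(self.posteriors(X), axis=1)

    def ml_classify(self, X) -> list[str]:
        """Maximum-likelihood class labels via the component->class map.

        Each row is assigned to the component with the highest weight-free
        density p(x | theta_j) and translated to that component's class.
        """
        if self.class_map is None:
            raise ValueError("no component->class map attached; call "
                             "map_components_to_classes first")
        comps = np.argmax(self.component_log_likelihood(X), axis=1)
        try:
            return [self.class_map[int(c)] for c in comps]
        except KeyError as exc:
            raise ValueError(f"component {exc} has no class mapping") from exc

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Gaussian mixture results",
            "=" * 46,
            f"components:      {self.n_components}",
            f"features:        {self.n_features}",
            f"observations:    {self.model.n_obs}",
            f"log-likelihood:  {self.llf:.4f}",
            f"BIC:             {self.bic():.4f}",
            f"free parameters: {self.k_free_parameters()}",
            f"converged:       {self.converged} ({len(self.loglik_history)} EM steps)",
            "-" * 46,
        ]
        for j in range(self.n_components):
            mu = np.array2string(self.means[j], precision=3, separator=", ")
            cls = f" -> {self.class_map[j]}" if self.class_map else ""
            lines.append(f"comp {j}: weight={self.weights[j]:.3f} mean={mu}{cls}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "llf": self.llf,
            "converged": self.converged,
            "reg_covar": self.reg_covar,
            "seed": self.seed,
            "class_map": ({str(k): v for k, v in self.class_map.items()}
                          if self.class_map else None),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path) -> "GaussianMixtureResults":
        with open(path) as fh:
            payload = json.load(fh)
        means = np.array(payload["means"])
        model = GaussianMixtureModel(means)  # placeholder endog: the means
        cmap = payload.get("class_map")
        return cls(
            model=model,
            weights=np.array(payload["weights"]),
            means=means,
            covariances=np.array(payload["covariances"]),
            llf=payload["llf"],
            loglik_history=[],
            converged=payload["converged"],
            reg_covar=payload["reg_covar"],
            seed=payload["seed"],
            class_map={int(k): v for k, v in cmap.items()} if cmap else None,
        )


def select_k(X, k_range=range(1, 9), seed: int = 0, return_table: bool = False,
             **fit_kwargs):
    """Choose the component count minimising BIC (ties -> smallest K)."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    model = GaussianMixtureModel(X)
    table: dict[int, float] = {}
    for K in k_range:
        try:
            res = model.fit(K, seed=seed, **fit_kwargs)
        except ValueError as exc:
            log.warning("K=%d not fittable (%s); skipped", K, exc)
            continue
        table[K] = res.bic()
    if not table:
        raise ValueError("no candidate K could be fitted")
    best = min(sorted(table), key=lambda k: table[k])
    return (best, table) if return_table else best


@dataclass
class FeatureRanking:
    """MPP-based feature ranking.

    ``mpp[j, f]`` is the posterior-weighted mean of standardised feature f
    under component j; a feature's score is max_j |mpp[j, f]| and
    ``feature_order`` sorts features by descending score.  Components with a
    large |score| concentrate on features whose standardised values are far
    from the pooled mean within that component, i.e. discriminative ones.
    """

    mpp: np.ndarray
    component_scores: np.ndarray
    feature_order: np.ndarray
    feature_scores: np.ndarray
    excluded: list[int] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "feature_order": self.feature_order.tolist(),
                "feature_scores": self.feature_scores.tolist(),
                "component_scores": self.component_scores.tolist(),
                "mpp": self.mpp.tolist(),
                "excluded": self.excluded,
            }, fh, indent=2)


@dataclass
class ReducedFeatureMatrix:
    """The top-zeta feature columns, in ranked order."""

    values: np.ndarray
    selected_features: np.ndarray


def rank_features(results: GaussianMixtureResults, X, standardize: bool = True
                  ) -> FeatureRanking:
    """Rank feature columns by the magnitude of their MPP statistic.

    Features are z-scored first (unless pre-standardised): without this the
    raw MPP rewards large-magnitude features regardless of how well they
    discriminate between components.  Zero-variance features are excluded
    from the ranking.
    """
    X = np.asarray(X, dtype=float)
    n, F = X.shape
    sd = X.std(axis=0)
    # constant up to rounding noise counts as zero-variance
    tiny = 1e-10 * np.maximum(1.0, np.abs(X).max(axis=0))
    ok = sd > tiny
    excluded = [int(i) for i in np.flatnonzero(~ok)]
    if excluded:
        log.warning("zero-variance features excluded from ranking: %s", excluded)
    if standardize:
        Z = np.zeros_like(X)
        Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    else:
        Z = X
    R = results.posteriors(X)
    mpp = R.T @ Z / n  # (K x F)
    component_scores = mpp.mean(axis=1)
    feature_scores = np.abs(mpp).max(axis=0)
    feature_scores[excluded] = -np.inf
    order = np.argsort(-feature_scores, kind="stable")
    order = np.array([i for i in order if i not in excluded])
    return FeatureRanking(mpp=mpp, component_scores=component_scores,
                          feature_order=order, feature_scores=feature_scores,
                          excluded=excluded)


def reduce(X, ranking: FeatureRanking, zeta: int) -> ReducedFeatureMatrix:
    """Keep the top-zeta ranked feature columns of X, in ranked order."""
    X = np.asarray(X, dtype=float)
    if not 1 <= zeta <= X.shape[1]:
        raise ValueError(f"zeta must be in [1, {X.shape[1]}], got {zeta}")
    if zeta > len(ranking.feature_order):
        raise ValueError(
            f"zeta={zeta} exceeds the {len(ranking.feature_order)} rankable features")
    sel = ranking.feature_order[:zeta]
    return ReducedFeatureMatrix(values=X[:, sel], selected_features=sel)


def map_components_to_classes(component_labels, true_labels,
                              n_components: int | None = None) -> dict[int, str]:
    """Map each mixture component to the majority true class of its members.

    Empty components map to ``"noise"``.  Among per-component majority
    assignments this maximises training accuracy.
    """
    component_labels = np.asarray(component_labels)
    true_labels = np.asarray(true_labels)
    if len(component_labels) != len(true_labels):
        raise ValueError("label sequences must be aligned")
    if len(true_labels) == 0:
        raise ValueError("no training labels provided")
    K = n_components if n_components is not None else int(component_labels.max()) + 1
    mapping: dict[int, str] = {}
    for j in range(K):
        members = true_labels[component_labels == j]
        if len(members) == 0:
            mapping[j] = "noise"
            continue
        classes, counts = np.unique(members, return_counts=True)
        mapping[j] = str(classes[np.argmax(counts)])
    return mapping
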