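"""Finite mixture of linear regressions on cell-type composition, fit by EM.

The model for one gene: each sample i carries a latent cluster label Z_i, and
its observed log2 expression is

    y_i = sum_d p_id * beta_{Z_i, d} + eps_i,      eps_i ~ N(0, sigma^2)

where p_id are the known cell-type fractions (tumor, stroma, ...) of sample i.
The regression has no intercept: the composition fractions themselves carry the
baseline (an optional constant pseudo-cell-type column can be appended). A
subset of the cell types is allowed to have cluster-varying coefficients; the
rest are tied across clusters. The full model lets both tumor and stroma
coefficients vary; the tumor-restricted (resp. stroma-restricted) model lets
only the tumor (resp. stroma) coefficient vary, and the two restricted fits are
compared by BIC to attribute a gene's cluster signal to a cell type.

Fitting alternates E-steps (posterior cluster responsibilities, computed in log
space) and M-steps (responsibility-weighted least squares with tied columns
shared across clusters, closed-form mixture weights and pooled residual
variance). Several seeded initializations are run and the highest-likelihood
fit kept. Clusters are canonically ordered by ascending tumor coefficient so
that "cluster 1/2" is reproducible across runs.

A batched driver fits many genes simultaneously against a common composition
design; the per-gene :class:`MixtureRegression` model wraps it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from ._emkernel import em_kernel

_SIGMA_FLOOR = 1e-8
_DEGENERATE_FRAC = 1e-6


@dataclass
class MixtureSpec:
    """Configuration of the mixture-of-regressions model.

    Parameters
    ----------
    n_clusters : number of latent clusters K (default 2).
    varying_cell_types : cell types whose coefficient varies with cluster.
        Full model: ("tumor", "stroma"); tumor-restricted: ("tumor",);
        stroma-restricted: ("stroma",).
    included_cell_types : ordered covariate list (columns of the design).
    shared_variance : single residual variance pooled over clusters (default);
        if False, one variance per cluster.
    include_intercept : append a constant pseudo-cell-type column, tied across
        clusters (off by default; the composition fractions carry the baseline).
    tol : absolute log-likelihood convergence tolerance.
    n_restarts : seeded initializations (one median split + random soft starts).
    """

    n_clusters: int = 2
    varying_cell_types: tuple = ("tumor", "stroma")
    included_cell_types: tuple = ("tumor", "stroma")
    shared_variance: bool = True
    include_intercept: bool = False
    max_iter: int = 500
    tol: float = 1e-6
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        self.varying_cell_types = tuple(self.varying_cell_types)
        self.included_cell_types = tuple(self.included_cell_types)
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        extra = set(self.varying_cell_types) - set(self.included_cell_types)
        if extra:
            raise ValueError(f"varying cell types not in included list: {sorted(extra)}")

    @property
    def design_cell_types(self) -> tuple:
        return self.included_cell_types + (("const",) if self.include_intercept else ())

    @property
    def n_params(self) -> int:
        """Free-parameter count q for the BIC penalty."""
        nv = len(self.varying_cell_types)
        nt = len(self.design_cell_types) - nv
        K = self.n_clusters
        n_var = 1 if self.shared_variance else K
        return nv * K + nt + (K - 1) + n_var

    def restricted(self, cell_type: str) -> "MixtureSpec":
        """Variant where only ``cell_type``'s coefficient varies with cluster."""
        return replace(self, varying_cell_types=(cell_type,))


def tumor_restricted_spec(spec: MixtureSpec) -> MixtureSpec:
    return spec.restricted("tumor")


def stroma_restricted_spec(spec: MixtureSpec) -> MixtureSpec:
    return spec.restricted("stroma")


def _design(P: np.ndarray, spec: MixtureSpec, cell_types) -> tuple:
    """Build the per-(sample, cluster) design tensor X of shape (n, K, m).

    Row X[i, k] multiplies the stacked parameter vector
    [beta_varying(cluster 1), ..., beta_varying(cluster K), beta_tied].
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise ValueError("composition matrix must be 2-D (samples x cell types)")
    cell_types = list(cell_types)
    if len(cell_types) != P.shape[1]:
        raise ValueError("cell_types length does not match composition columns")
    cols = {}
    for ct in spec.included_cell_types:
        if ct not in cell_types:
            raise KeyError(f"cell type {ct!r} not present in composition matrix")
        cols[ct] = P[:, cell_types.index(ct)]
    if spec.include_intercept:
        cols["const"] = np.ones(P.shape[0])
    design_types = list(spec.design_cell_types)
    varying = [ct for ct in design_types if ct in spec.varying_cell_types]
    tied = [ct for ct in design_types if ct not in spec.varying_cell_types]
    Pv = np.column_stack([cols[ct] for ct in varying]) if varying else np.empty((P.shape[0], 0))
    Pt = np.column_stack([cols[ct] for ct in tied]) if tied else np.empty((P.shape[0], 0))
    full = np.column_stack([Pv, Pt]) if varying or tied else np.empty((P.shape[0], 0))
    if full.shape[1] and np.linalg.matrix_rank(full) < full.shape[1]:
        # find an offending column to name
        for j, ct in enumerate(varying + tied):
            others = np.delete(full, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(full):
                raise ValueError(
                    f"rank-deficient composition design: column {ct!r} is "
                    "linearly dependent on the others (e.g. constant)"
                )
        raise ValueError("rank-deficient composition design")
    n = P.shape[0]
    K = spec.n_clusters
    nv, nt = Pv.shape[1], Pt.shape[1]
    m = K * nv + nt
    X = np.zeros((n, K, m))
    for k in range(K):
        X[:, k, k * nv : (k + 1) * nv] = Pv
    if nt:
        X[:, :, K * nv :] = Pt[:, None, :]
    return X, varying, tied


def _theta_to_beta(theta: np.ndarray, spec: MixtureSpec, varying, tied) -> np.ndarray:
    """Unstack the WLS solution into a K x D coefficient matrix (design order)."""
    K = spec.n_clusters
    nv, nt = len(varying), len(tied)
    design_types = list(spec.design_cell_types)
    G = theta.shape[:-1]
    beta = np.zeros(G + (K, len(design_types)))
    for k in range(K):
        for j, ct in enumerate(varying):
            beta[..., k, design_types.index(ct)] = theta[..., k * nv + j]
        for j, ct in enumerate(tied):
            beta[..., k, design_types.index(ct)] = theta[..., K * nv + j]
    return beta


def _beta_to_theta(beta: np.ndarray, spec: MixtureSpec, varying, tied) -> np.ndarray:
    K = spec.n_clusters
    nv, nt = len(varying), len(tied)
    design_types = list(spec.design_cell_types)
    G = beta.shape[:-2]
    theta = np.zeros(G + (K * nv + nt,))
    for k in range(K):
        for j, ct in enumerate(varying):
            theta[..., k * nv + j] = beta[..., k, design_types.index(ct)]
    for j, ct in enumerate(tied):
        theta[..., K * nv + j] = beta[..., 0, design_types.index(ct)]
    return theta


def _flat_design(X):
    """Precompute the flattened design products reused every EM iteration."""
    n, K, m = X.shape
    Xf = X.reshape(n * K, m)
    XXf = (X[:, :, :, None] * X[:, :, None, :]).reshape(n * K, m * m)
    return Xf, XXf


def _m_step_flat(Y, Xf, XXf, R, spec: MixtureSpec):
    """Responsibility-weighted least squares with tied columns, batched over genes.

    Returns (theta, sigma2, weights, resid2) with sigma2 of shape (G, K) —
    identical across K when the variance is shared — and resid2 the squared
    residuals (G, n, K) at the new coefficients (reused by the E-step).
    """
    G, n = Y.shape
    K = R.shape[2]
    m = Xf.shape[1]
    Rf = R.reshape(G, n * K)
    A = (Rf @ XXf).reshape(G, m, m)
    b = (R * Y[:, :, None]).reshape(G, n * K) @ Xf
    try:
        theta = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # exactly symmetric or empty-cluster responsibilities make the system
        # singular; the minimum-norm solution keeps the tied structure
        theta = np.stack(
            [np.linalg.lstsq(A[g], b[g], rcond=None)[0] for g in range(G)]
        )
    mu = (theta @ Xf.T).reshape(G, n, K)
    resid2 = (Y[:, :, None] - mu) ** 2
    if spec.shared_variance:
        sigma2 = (Rf * resid2.reshape(G, n * K)).sum(axis=1) / n
        sigma2 = np.repeat(sigma2[:, None], K, axis=1)
    else:
        tot = R.sum(axis=1)  # (G, K)
        sigma2 = (R * resid2).sum(axis=1) / np.maximum(tot, 1e-300)
    sigma2 = np.maximum(sigma2, _SIGMA_FLOOR)
    weights = R.mean(axis=1)
    return theta, sigma2, weights, resid2


def _e_step_flat(resid2, sigma2, weights):
    """Log-space E-step from precomputed squared residuals; never NaN."""
    with np.errstate(divide="ignore"):
        logd = (
            (-0.5 * np.log(2 * np.pi * sigma2) + np.log(weights))[:, None, :]
            - resid2 / (2 * sigma2[:, None, :])
        )
    top = logd.max(axis=2)
    lse = top + np.log(np.exp(logd - top[:, :, None]).sum(axis=2))
    R = np.exp(logd - lse[:, :, None])
    return R, lse.sum(axis=1)


def _m_step_batch(Y, X, R, spec: MixtureSpec):
    Xf, XXf = _flat_design(X)
    theta, sigma2, weights, _ = _m_step_flat(Y, Xf, XXf, R, spec)
    return theta, sigma2, weights


def _e_step_batch(Y, X, theta, sigma2, weights):
    n, K, m = X.shape
    mu = (theta @ X.reshape(n * K, m).T).reshape(-1, n, K)
    resid2 = (Y[:, :, None] - mu) ** 2
    return _e_step_flat(resid2, sigma2, weights)


def _init_responsibilities(Y, K, restart, rng):
    """Restart 0: hard quantile split of y; others: random soft assignments."""
    G, n = Y.shape
    if restart == 0:
        R = np.zeros((G, n, K))
        qs = np.quantile(Y, np.linspace(0, 1, K + 1)[1:-1], axis=1).T  # (G, K-1)
        bins = np.zeros((G, n), dtype=int)
        for k in range(K - 1):
            bins += Y > qs[:, [k]]
        np.put_along_axis(R, bins[:, :, None], 1.0, axis=2)
        return R
    R = rng.random((G, n, K)) + 1e-3
    return R / R.sum(axis=2, keepdims=True)


def _em_batch(Y, P, spec: MixtureSpec, cell_types, keep_trace=True):
    """Fit the mixture to every row of Y (genes x samples) by restarted EM.

    All restarts of all genes run as one vectorized batch (each restart is a
    "virtual gene" sharing the common composition design); the highest-
    likelihood valid restart per gene wins. Returns a dict of per-gene arrays:
    beta (G,K,D), sigma2 (G,K), weights (G,K), responsibilities (G,n,K),
    loglik (G,), n_iter (G,), converged (G,), trace (per-gene log-likelihood
    trace of the winning restart, when kept).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if not np.all(np.isfinite(Y)):
        raise ValueError("expression values must be finite")
    X, varying, tied = _design(P, spec, cell_types)
    G, n = Y.shape
    K = spec.n_clusters
    m = X.shape[2]
    if n < 2 * K * len(spec.design_cell_types):
        warnings.warn(f"only {n} samples for {m} mixture parameters; fit may be unstable")

    rng = np.random.default_rng(spec.seed)
    Xf, XXf = _flat_design(X)
    n_restarts = max(spec.n_restarts, 1)
    B = G * n_restarts
    Yv = np.tile(Y, (n_restarts, 1))  # restart r occupies rows [r*G, (r+1)*G)
    R = np.concatenate(
        [_init_responsibilities(Y, K, r, rng) for r in range(n_restarts)], axis=0
    )
    trace_arr = np.full((B if keep_trace else 0, spec.max_iter), np.nan)
    theta, sigma2, weights, loglik, n_iter, converged, invalid = em_kernel(
        np.ascontiguousarray(Yv),
        np.ascontiguousarray(Xf),
        np.ascontiguousarray(XXf),
        R,
        len(varying),
        spec.tol,
        spec.max_iter,
        spec.shared_variance,
        _SIGMA_FLOOR,
        _DEGENERATE_FRAC,
        trace_arr,
    )

    # pick the best restart per gene
    ll_by_restart = loglik.reshape(n_restarts, G)
    winner = np.argmax(ll_by_restart, axis=0)  # ties: lowest restart index
    pick = winner * G + np.arange(G)
    best = {
        "theta": theta[pick],
        "sigma2": sigma2[pick],
        "weights": weights[pick],
        "R": R[pick],
        "loglik": loglik[pick],
        "n_iter": n_iter[pick].astype(int),
        "converged": converged[pick],
        "trace": [trace_arr[p, : n_iter[p]].copy() for p in pick]
        if keep_trace
        else [None] * G,
    }
    best["sigma2"][~np.isfinite(best["loglik"])] = np.nan

    if not np.all(np.isfinite(best["loglik"])):
        warnings.warn("EM failed to produce a valid fit for some gene(s)")
    if not np.all(best["converged"]):
        n_bad = int((~best["converged"]).sum())
        warnings.warn(f"EM did not converge for {n_bad} gene(s); results returned anyway")

    beta = _theta_to_beta(best["theta"], spec, varying, tied)
    beta, best["sigma2"], best["weights"], best["R"] = _canonical_order(
        beta, best["sigma2"], best["weights"], best["R"], spec
    )
    design_types = list(spec.design_cell_types)
    hard = np.argmax(best["R"], axis=2)  # argmax: ties break toward lower index
    return {
        "beta": beta,
        "sigma2": best["sigma2"],
        "weights": best["weights"],
        "responsibilities": best["R"],
        "hard_labels": hard,
        "loglik": best["loglik"],
        "n_iter": best["n_iter"],
        "converged": best["converged"],
        "trace": best["trace"],
        "cell_types": design_types,
    }


def _canonical_order(beta, sigma2, weights, R, spec: MixtureSpec):
    """Order clusters by ascending tumor coefficient (tie-break: first varying type)."""
    design_types = list(spec.design_cell_types)
    keys = []
    if "tumor" in design_types:
        keys.append(beta[..., design_types.index("tumor")])
    for ct in spec.varying_cell_types:
        if ct != "tumor" and ct in design_types:
            keys.append(beta[..., design_types.index(ct)])
            break
    if not keys:
        return beta, sigma2, weights, R
    # lexsort wants last key primary
    order = np.lexsort(tuple(k for k in reversed(keys)), axis=-1)
    beta = np.take_along_axis(beta, order[..., None], axis=-2)
    sigma2 = np.take_along_axis(sigma2, order, axis=-1)
    weights = np.take_along_axis(weights, order, axis=-1)
    R = np.take_along_axis(R, order[..., None, :], axis=-1)
    return beta, sigma2, weights, R


# ---------------------------------------------------------------------------
# per-gene functional surface


def e_step(y, P, beta, sigma2, weights, spec=None, cell_types=None):
    """Posterior cluster responsibilities for one gene (log-space, never NaN)."""
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    K, D = beta.shape
    P = np.asarray(P, dtype=float)
    if P.shape[1] != D:
        raise ValueError("beta columns must match composition columns")
    sigma2 = np.broadcast_to(np.asarray(sigma2, dtype=float), (K,)).copy()
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be > 0")
    mu = P @ beta.T  # (n, K)
    with np.errstate(divide="ignore"):
        logd = (
            -0.5 * np.log(2 * np.pi * sigma2)[None, :]
            - (y[:, None] - mu) ** 2 / (2 * sigma2[None, :])
            + np.log(np.asarray(weights, dtype=float))[None, :]
        )
    lse = logsumexp(logd, axis=1)
    return np.exp(logd - lse[:, None])


def m_step(y, P, responsibilities, spec: MixtureSpec, cell_types=None):
    """Weighted least squares update for one gene; returns (beta, sigma2, weights)."""
    y = np.asarray(y, dtype=float)
    P = np.asarray(P, dtype=float)
    if cell_types is None:
        cell_types = spec.included_cell_types
    X, varying, tied = _design(P, spec, cell_types)
    R = np.asarray(responsibilities, dtype=float)[None]
    theta, sigma2, weights = _m_step_batch(y[None], X, R, spec)
    beta = _theta_to_beta(theta, spec, varying, tied)[0]
    s2 = sigma2[0, 0] if spec.shared_variance else sigma2[0]
    return beta, s2, weights[0]


@dataclass
class MixtureResults:
    """EM fit of the composition-weighted mixture of regressions for one gene.

    Attributes follow the model: ``responsibilities`` are the posterior cluster
    probabilities of each sample, ``beta`` the K x D coefficient matrix (rows
    identical across clusters for tied cell types), ``weights`` the mixture
    proportions, ``sigma2`` the residual variance(s), ``loglik`` the final
    observed-data log-likelihood with its per-iteration ``loglik_trace``.
    """

    spec: MixtureSpec
    cell_types: list
    responsibilities: np.ndarray
    hard_labels: np.ndarray
    weights: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = None
    n_obs: int = 0

    @property
    def params(self) -> np.ndarray:
        return self.beta

    @property
    def llf(self) -> float:
        return self.loglik

    @property
    def bic(self) -> float:
        return bic(self, self.spec, self.n_obs)

    def summary(self) -> str:
        lines = [
            "Mixture of linear regressions (EM)",
            f"  clusters: {self.spec.n_clusters}   samples: {self.n_obs}",
            f"  varying: {', '.join(self.spec.varying_cell_types)}",
            f"  log-likelihood: {self.loglik:.4f}   BIC: {self.bic:.4f}",
            f"  converged: {self.converged} in {self.n_iter} iterations",
            f"  sigma2: {np.atleast_1d(self.sigma2)[0]:.6g}",
            "  cluster   weight  " + "  ".join(f"beta[{ct}]" for ct in self.cell_types),
        ]
        for k in range(self.spec.n_clusters):
            coefs = "  ".join(f"{self.beta[k, d]:10.4f}" for d in range(self.beta.shape[1]))
            lines.append(f"  {k + 1:7d}  {self.weights[k]:6.3f}  {coefs}")
        return "\n".join(lines)


class MixtureRegression:
    """Per-gene mixture-of-regressions model on known cell-type fractions.

    Parameters
    ----------
    endog : (n,) log2 expression values of one gene.
    exog : (n, D) composition fractions (columns named by ``cell_types``).
    spec : MixtureSpec, defaults to the full two-cluster tumor/stroma model.

    ``fit()`` returns a :class:`MixtureResults`.
    """

    def __init__(self, endog, exog, spec: MixtureSpec | None = None, cell_types=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.spec = spec if spec is not None else MixtureSpec()
        self.cell_types = (
            list(cell_types) if cell_types is not None else list(self.spec.included_cell_types)
        )
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("endog and exog must have the same number of samples")

    @classmethod
    def from_tables(cls, expr, comp, gene_id, spec: MixtureSpec | None = None):
        """Build the model for one gene from ExpressionMatrix + CompositionTable."""
        comp = comp.align(expr.sample_ids)
        y = expr.values[expr.gene_ids.index(gene_id)]
        return cls(y, comp.fractions, spec=spec, cell_types=comp.cell_types)

    def fit(self) -> MixtureResults:
        out = _em_batch(self.endog[None], self.exog, self.spec, self.cell_types)
        s2 = out["sigma2"][0]
        return MixtureResults(
            spec=self.spec,
            cell_types=out["cell_types"],
            responsibilities=out["responsibilities"][0],
            hard_labels=out["hard_labels"][0],
            weights=out["weights"][0],
            beta=out["beta"][0],
            sigma2=s2[0] if self.spec.shared_variance else s2,
            loglik=float(out["loglik"][0]),
            n_iter=int(out["n_iter"][0]),
            converged=bool(out["converged"][0]),
            loglik_trace=out["trace"][0],
            n_obs=len(self.endog),
        )


def em_fit(y, P, spec: MixtureSpec, cell_types=None) -> MixtureResults:
    """Functional alias: fit one gene's mixture by restarted EM."""
    return MixtureRegression(y, P, spec=spec, cell_types=cell_types).fit()


def fit_gene_batch(Y, P, spec: MixtureSpec, cell_types=None, keep_trace=False) -> dict:
    """Fit every row of Y (genes x samples) in one vectorized EM run.

    Returns the raw dict of batched arrays (see :func:`_em_batch`); used by the
    screening stage where thousands of genes are fit against one design.
    """
    if cell_types is None:
        cell_types = spec.included_cell_types
    return _em_batch(Y, P, spec, cell_types, keep_trace=keep_trace)


def log_likelihood(fit: MixtureResults, y, P, cell_types=None) -> float:
    """Observed-data mixture log-likelihood of ``fit``'s parameters on (y, P)."""
    y = np.asarray(y, dtype=float)
    P = np.asarray(P, dtype=float)
    spec = fit.spec
    if cell_types is None:
        cell_types = fit.cell_types if "const" not in fit.cell_types else None
    X, varying, tied = _design(P, spec, cell_types or spec.included_cell_types)
    theta = _beta_to_theta(fit.beta[None], spec, varying, tied)[0]
    K = spec.n_clusters
    sigma2 = np.broadcast_to(np.atleast_1d(fit.sigma2), (K,))
    mu = np.einsum("ika,a->ik", X, theta)
    resid2 = (y[:, None] - mu) ** 2
    if np.any(sigma2 == 0):
        if np.any(resid2[:, sigma2 == 0] > 0):
            warnings.warn("zero variance with nonzero residual: log-likelihood is -inf")
            return -np.inf
    s2 = np.maximum(sigma2, _SIGMA_FLOOR)
    with np.errstate(divide="ignore"):
        logd = (
            -0.5 * np.log(2 * np.pi * s2)[None, :]
            - resid2 / (2 * s2[None, :])
            + np.log(fit.weights)[None, :]
        )
    return float(logsumexp(logd, axis=1).sum())


def bic(fit: MixtureResults, spec: MixtureSpec, n: int) -> float:
    """Bayesian information criterion, -2*loglik + q*ln(n).

    q counts the cluster-varying coefficients (K per varying cell type), the
    tied coefficients, the K-1 free mixture weights, and the residual variance
    (1 when shared, K otherwise). Full K=2 tumor/stroma model: q=6; either
    restricted model: q=5.
    """
    if n <= 1:
        raise ValueError("BIC requires n > 1")
    if not fit.converged:
        warnings.warn("BIC computed from a non-converged fit")
    return -2.0 * fit.loglik + spec.n_params * np.log(n)
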