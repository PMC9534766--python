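"""Step 1: fit the phenotype null model (no genotype terms).

Three fitting modes are provided:

* plain GLM — logistic (IRLS) for binary traits, ordinary least squares for
  quantitative traits;
* covariates-as-offset — the covariate-only linear predictor of the fitted
  GLM is frozen as an offset, so Step 2 score tests project out only the
  intercept (a cheap approximation that is exact when genotypes are
  orthogonal to the covariates);
* sparse-GRM mixed model — a polygenic random effect with covariance
  ``tau * K`` for a sparse genetic relationship matrix K, fitted by REML
  (quantitative, via eigen-rotation) or penalized quasi-likelihood with an
  inner REML step (binary), followed by a variance-ratio calibration that
  maps naive GLM score variances to mixed-model score variances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, sparse
from scipy.special import expit

logger = logging.getLogger(__name__)

GRM_CUTOFF_DEFAULT = 0.05


@dataclass
class SparseGRM:
    """Symmetric relatedness matrix with off-diagonal entries below a cutoff
    (default 0.05) set to exactly zero; diagonal always retained."""

    matrix: sparse.csr_matrix
    cutoff: float = GRM_CUTOFF_DEFAULT
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1]:
            raise ValueError("GRM must be square")
        if (abs(m - m.T) > 1e-8).nnz:
            raise ValueError("GRM must be symmetric")
        if np.any(m.diagonal() <= 0):
            raise ValueError("GRM diagonal must be positive")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass
class NullModelFit:
    """Fitted null model handed from Step 1 to Step 2.

    ``X_proj`` is the design projected out of genotypes in Step 2: the full
    covariate design normally, the intercept column alone under offset mode.
    ``work_w`` are the IRLS working weights (``mu*(1-mu)`` for binary,
    ``1/sigma^2`` for quantitative).  ``variance_ratio`` is 1 unless a GRM
    random effect was fitted and calibrated.
    """

    trait_type: str
    mu_hat: np.ndarray
    resid: np.ndarray
    work_w: np.ndarray
    X: np.ndarray
    X_proj: np.ndarray
    beta: np.ndarray
    offset_mode: bool = False
    offset: np.ndarray | None = None
    tau: float | None = None
    sigma2: float | None = None
    variance_ratio: float = 1.0
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError("trait_type must be 'binary' or 'quantitative'")
        if self.trait_type == "binary" and not (
            np.all(self.mu_hat > 0) and np.all(self.mu_hat < 1)
        ):
            raise ValueError("binary fit requires mu_hat strictly in (0,1)")
        if (self.tau is None or self.tau == 0) and self.variance_ratio != 1.0:
            raise ValueError("variance_ratio must be 1 when no random effect is present")

    @property
    def n(self) -> int:
        return self.mu_hat.shape[0]


def _with_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    if not np.any(np.all(X == 1.0, axis=0)):
        X = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank-deficient")
    return X


def _irls_logistic(y: np.ndarray, X: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 100) -> np.ndarray:
    """Logistic MLE by iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    for _ in range(max_iter):
        eta = X @ beta
        if np.max(np.abs(eta)) > 15:
            raise ValueError(
                "separation detected (diverging linear predictor); "
                "consider penalized regression or dropping covariates"
            )
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            return beta
        H = (X * w[:, None]).T @ X
        beta = beta + np.linalg.solve(H, grad)
    eta = X @ beta
    if np.linalg.norm(X.T @ (y - expit(eta))) < 1e-4:
        return beta
    raise RuntimeError("IRLS did not converge")


def fit_null_glm(
    y: np.ndarray,
    X: np.ndarray | None,
    trait_type: str = "binary",
    offset_mode: bool = False,
    sample_ids: list[str] | None = None,
) -> NullModelFit:
    """Fit the covariate-only null GLM.

    Binary traits are fitted by IRLS to gradient norm < 1e-8; quantitative
    traits by least squares with ``sigma^2 = RSS / (N - p)``.  Under
    ``offset_mode`` the fit itself is unchanged but Step 2 will treat the
    covariate linear predictor as fixed and project out only the intercept.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples")
    Xd = _with_intercept(X, n)
    if trait_type == "binary":
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])) or uniq.size < 2:
            raise ValueError("binary trait must contain both 0 and 1")
        beta = _irls_logistic(y, Xd)
        mu = expit(Xd @ beta)
        work_w = mu * (1 - mu)
        sigma2 = None
    elif trait_type == "quantitative":
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        mu = Xd @ beta
        rss = float(np.sum((y - mu) ** 2))
        sigma2 = rss / (n - Xd.shape[1])
        work_w = np.full(n, 1.0 / sigma2)
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")

    resid = y - mu
    if offset_mode:
        X_proj = np.ones((n, 1))
        offset = Xd @ beta
    else:
        X_proj = Xd
        offset = None
    return NullModelFit(
        trait_type=trait_type, mu_hat=mu, resid=resid, work_w=work_w,
        X=Xd, X_proj=X_proj, beta=beta, offset_mode=offset_mode, offset=offset,
        sigma2=sigma2, sample_ids=sample_ids or [f"s{i}" for i in range(n)],
    )


def build_sparse_grm(
    genotypes: np.ndarray,
    cutoff: float = GRM_CUTOFF_DEFAULT,
    sample_ids: list[str] | None = None,
) -> SparseGRM:
    """Genetic relationship matrix from common markers, sparsified at a
    relatedness cutoff.

    ``genotypes`` is M_common x N (markers by samples, dosages 0..2).  Entries
    are means over markers of standardized-genotype products; off-diagonal
    values below ``cutoff`` are zeroed so only close relatives remain.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotypes must be M x N")
    p = G.mean(axis=1) / 2.0
    poly = (p > 0) & (p < 1)
    if (~poly).any():
        logger.warning("excluding %d monomorphic marker(s) from GRM", int((~poly).sum()))
        G, p = G[poly], p[poly]
    m = G.shape[0]
    if m < 100:
        raise ValueError(f"need >= 100 polymorphic common markers, got {m}")
    Z = (G - 2 * p[:, None]) / np.sqrt(2 * p * (1 - p))[:, None]
    K = (Z.T @ Z) / m
    off = K.copy()
    np.fill_diagonal(off, 0.0)
    off[off < cutoff] = 0.0
    Ksp = sparse.csr_matrix(off + np.diag(np.diag(K)))
    return SparseGRM(matrix=Ksp, cutoff=cutoff, sample_ids=sample_ids)


def _reml_quantitative(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                       tol: float = 1e-6):
    """REML for y = Xb + g + e, g ~ N(0, tau*K), e ~ N(0, sigma2*I).

    Profiles sigma2 out analytically after eigen-rotation by K, leaving a 1-D
    REML objective in delta = tau/sigma2 maximized by bounded scalar search.
    """
    n, p = X.shape
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt, Xt = U.T @ y, U.T @ X

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        v = 1.0 + delta * d
        Xv = Xt / v[:, None]
        XtVX = Xt.T @ Xv
        beta = np.linalg.solve(XtVX, Xv.T @ yt)
        r = yt - Xt @ beta
        rss = float(np.sum(r * r / v))
        sigma2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(sigma2) + np.sum(np.log(v))
            + np.linalg.slogdet(XtVX)[1] + (n - p)
        )
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=(-12.0, 8.0), method="bounded",
                                   options={"xatol": tol})
    delta = float(np.exp(res.x))
    # boundary: compare with the delta -> 0 (no random effect) limit
    if neg_reml(-30.0) <= res.fun + 1e-9:
        delta = 0.0
    v = 1.0 + delta * d
    Xv = Xt / v[:, None]
    XtVX = Xt.T @ Xv
    beta = np.linalg.solve(XtVX, Xv.T @ yt)
    r = yt - Xt @ beta
    sigma2 = float(np.sum(r * r / v)) / (n - p)
    tau = delta * sigma2
    # BLUP of the random effect on the original scale
    b = U @ (delta * d * (r / v))
    return beta, tau, sigma2, b


def fit_null_mixed(
    y: np.ndarray,
    X: np.ndarray | None,
    grm: SparseGRM,
    trait_type: str = "binary",
    offset_mode: bool = False,
    sample_ids: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> NullModelFit:
    """Fit the null model with a sparse-GRM polygenic random effect.

    Quantitative traits use REML directly.  Binary traits use penalized
    quasi-likelihood: iterate the IRLS working response ``z = eta +
    (y-mu)/w`` and re-estimate ``tau`` by REML of the working linear mixed
    model until ``tau`` moves by less than ``tol``.  ``tau >= 0`` enforced.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    Xd = _with_intercept(X, n)
    if grm.n != n:
        raise ValueError(f"GRM dimension {grm.n} does not match N={n}")
    K = grm.toarray()

    if trait_type == "quantitative":
        beta, tau, sigma2, b = _reml_quantitative(y, Xd, K, tol=tol)
        mu = Xd @ beta + b
        resid = y - mu
        work_w = np.full(n, 1.0 / sigma2)
    elif trait_type == "binary":
        glm = fit_null_glm(y, Xd, "binary", sample_ids=sample_ids)
        beta, mu = glm.beta, glm.mu_hat
        eta = Xd @ beta
        tau, tau_prev = 0.0, np.inf
        b = np.zeros(n)
        history = []
        for it in range(max_iter):
            w = mu * (1 - mu)
            z = eta + (y - mu) / w
            # REML on the working model: Var(z) = tau*K + diag(1/w)
            beta, tau, b = _pql_working_reml(z, Xd, K, w)
            history.append(tau)
            eta = Xd @ beta + b
            mu = expit(np.clip(eta, -30, 30))
            if abs(tau - tau_prev) < tol:
                break
            tau_prev = tau
        else:
            raise RuntimeError(
                f"PQL did not converge in {max_iter} iterations; tau trajectory: "
                f"{[round(t, 4) for t in history[-8:]]}"
            )
        resid = y - mu
        work_w = mu * (1 - mu)
        sigma2 = None
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")

    tau = max(float(tau), 0.0)
    if offset_mode:
        X_proj, offset = np.ones((n, 1)), Xd @ beta
    else:
        X_proj, offset = Xd, None
    return NullModelFit(
        trait_type=trait_type, mu_hat=mu, resid=resid, work_w=work_w,
        X=Xd, X_proj=X_proj, beta=beta, offset_mode=offset_mode, offset=offset,
        tau=tau, sigma2=sigma2, variance_ratio=1.0,
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
    )


def _pql_working_reml(z: np.ndarray, X: np.ndarray, K: np.ndarray, w: np.ndarray):
    """One REML step of the heteroscedastic working LMM
    z = Xb + g + e, g ~ N(0, tau*K), e ~ N(0, diag(1/w))."""
    n, p = X.shape
    sw = np.sqrt(w)
    zs, Xs = z * sw, X * sw[:, None]
    Ks = (K * sw[:, None]) * sw[None, :]
    d, U = np.linalg.eigh(Ks)
    d = np.clip(d, 0.0, None)
    zt, Xt = U.T @ zs, U.T @ Xs

    def neg_reml(log_tau: float) -> float:
        tau = np.exp(log_tau)
        v = 1.0 + tau * d
        Xv = Xt / v[:, None]
        XtVX = Xt.T @ Xv
        beta = np.linalg.solve(XtVX, Xv.T @ zt)
        r = zt - Xt @ beta
        ll = -0.5 * (np.sum(np.log(v)) + np.sum(r * r / v)
                     + np.linalg.slogdet(XtVX)[1])
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=(-12.0, 6.0), method="bounded",
                                   options={"xatol": 1e-8})
    tau = float(np.exp(res.x))
    if neg_reml(-30.0) <= res.fun + 1e-9:
        tau = 0.0
    v = 1.0 + tau * d
    Xv = Xt / v[:, None]
    beta = np.linalg.solve(Xt.T @ Xv, Xv.T @ zt)
    r = zt - Xt @ beta
    b = (U @ (tau * d * (r / v))) / sw  # BLUP back on the unweighted scale
    return beta, tau, b


def estimate_variance_ratio(
    fit: NullModelFit,
    grm: SparseGRM,
    probe_markers: np.ndarray,
    min_probes: int = 30,
) -> float:
    """Calibrate Step 2 score variances against the mixed model.

    For each probe marker g the ratio of the score variance accounting for
    the random effect, ``g' P g`` with ``P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1``
    and ``V = diag(1/w) + tau*K``, to the naive GLM variance
    ``g'(W - WX(X'WX)^-1X'W)g`` is computed; the mean ratio is stored on the
    fit and returned.  With ``tau = 0`` the two variances coincide and the
    ratio is 1.
    """
    G = np.atleast_2d(np.asarray(probe_markers, dtype=float))
    if G.shape[0] == fit.n and G.shape[1] != fit.n:
        G = G.T  # markers in rows
    if G.shape[0] < min_probes:
        logger.warning("only %d probe markers (< %d); variance ratio is best-effort",
                       G.shape[0], min_probes)
    tau = fit.tau or 0.0
    X, w = fit.X, fit.work_w
    if tau == 0.0:
        fit.variance_ratio = 1.0
        return 1.0
    K = grm.toarray()
    V = np.diag(1.0 / w) + tau * K
    Vi = np.linalg.inv(V)
    ViX = Vi @ X
    P = Vi - ViX @ np.linalg.solve(X.T @ ViX, ViX.T)
    WX = X * w[:, None]
    H = np.linalg.inv(X.T @ WX)
    ratios = []
    for g in G:
        naive = float(g @ (w * g) - (g @ WX) @ H @ (WX.T @ g))
        if naive <= 0:
            continue
        true = float(g @ P @ g)
        ratios.append(true / naive)
    if not ratios:
        raise ValueError("no usable probe markers for the variance ratio")
    ratio = float(np.mean(ratios))
    if ratio <= 0:
        raise ValueError("variance ratio must be positive")
    fit.variance_ratio = ratio
    return ratio


# ----------------------------------------------------------------------------
# model archive (Step 1 -> Step 2 hand-off)

_ARCHIVE_VERSION = 1


def save_null_model(fit: NullModelFit, path: str | Path) -> None:
    """Write the fitted null model as a versioned JSON archive."""
    payload = {
        "version": _ARCHIVE_VERSION,
        "trait_type": fit.trait_type,
        "mu_hat": fit.mu_hat.tolist(),
        "resid": fit.resid.tolist(),
        "work_w": fit.work_w.tolist(),
        "X": fit.X.tolist(),
        "X_proj": fit.X_proj.tolist(),
        "beta": fit.beta.tolist(),
        "offset_mode": fit.offset_mode,
        "offset": None if fit.offset is None else fit.offset.tolist(),
        "tau": fit.tau,
        "sigma2": fit.sigma2,
        "variance_ratio": fit.variance_ratio,
        "sample_ids": list(fit.sample_ids),
    }
    Path(path).write_text(json.dumps(payload))


def load_null_model(path: str | Path) -> NullModelFit:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != _ARCHIVE_VERSION:
        raise ValueError(f"unsupported model archive version {payload.get('version')}")
    arr = lambda k: np.asarray(payload[k], dtype=float)
    return NullModelFit(
        trait_type=payload["trait_type"], mu_hat=arr("mu_hat"), resid=arr("resid"),
        work_w=arr("work_w"), X=arr("X"), X_proj=arr("X_proj"), beta=arr("beta"),
        offset_mode=payload["offset_mode"],
        offset=None if payload["offset"] is None else arr("offset"),
        tau=payload["tau"], sigma2=payload["sigma2"],
        variance_ratio=payload["variance_ratio"], sample_ids=payload["sample_ids"],
    )
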