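"""Step 2: Burden, SKAT and SKAT-O score tests on a collapsed variant set.

All three tests are built from the same score decomposition: the per-marker
score vector ``S = w * G'(y - mu)`` with covariates projected out of ``G``
under the working-weight metric, and its null covariance ``Phi``.  The SKAT
statistic ``Q = sum S_j^2`` follows a mixture of 1-df chi-squares whose tail
is evaluated by numerical characteristic-function inversion (Davies-type),
with a Kuonen saddlepoint and then Liu moment-matching as fallbacks.  The
burden statistic ``1'S`` is normal under the null; for binary traits with a
standardized score beyond |z| > 2 the tail is replaced by a saddlepoint
approximation to the exact conditional distribution, which is what keeps the
test calibrated under severe case-control imbalance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from scipy.special import log_ndtr

from .collapsing import CollapsedSet, WeightScheme, collapse, DEFAULT_MAC_THRESHOLD
from .null_model import NullModelFit
from .variant_io import EmptySetError, GeneVariantSet, MaskSpec, apply_mask

logger = logging.getLogger(__name__)

#: SKAT-O mixing grid between the SKAT (rho=0) and burden (rho=1) kernels.
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)

#: Standardized-score threshold beyond which the saddlepoint tail replaces
#: the normal approximation for binary traits.
SPA_Z_THRESHOLD = 2.0

_GAUSS_NODES = np.polynomial.legendre.leggauss(128)


@dataclass
class ScoreDecomposition:
    """Score vector and its null covariance for one testing set."""

    S: np.ndarray
    Phi: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float).ravel()
        self.Phi = np.asarray(self.Phi, dtype=float)
        k = self.S.shape[0]
        if self.Phi.shape != (k, k):
            raise ValueError("Phi must be K x K matching S")
        if not np.allclose(self.Phi, self.Phi.T, atol=1e-8):
            raise ValueError("Phi must be symmetric")

    @property
    def k(self) -> int:
        return self.S.shape[0]


@dataclass
class SetTestResult:
    """Burden/SKAT/SKAT-O p-values for one (gene, mask) testing cell."""

    gene_id: str
    mask: MaskSpec
    p_burden: float
    p_skat: float
    p_skato: float
    q_skat: float
    score_burden: float
    m_markers_pre: int
    m_markers: int
    collapsed: bool
    spa_applied: bool
    method_tail: str
    provenance: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# mixture-of-chi-square tails


def _liu_params(lam: np.ndarray):
    c1, c2 = lam.sum(), (lam**2).sum()
    c3, c4 = (lam**3).sum(), (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        d = s1 * a**3 - a**2
        l = a**2 - 2 * d
    else:
        l = 1.0 / s2
        a = np.sqrt(l)
        d = 0.0
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x, sigma_x = l + d, np.sqrt(2) * a
    return mu_q, sigma_q, mu_x, sigma_x, l, d


def _liu_sf(q, lam: np.ndarray):
    """Liu-Tang-Zhang moment-matched tail of sum lam_j * chi2_1
    (vectorized in q)."""
    mu_q, sigma_q, mu_x, sigma_x, l, d = _liu_params(lam)
    t = (np.asarray(q, dtype=float) - mu_q) / sigma_q * sigma_x + mu_x
    t = np.clip(t, 0.0, None)
    out = stats.ncx2.sf(t, l, d) if d > 0 else special.chdtrc(l, t)
    return float(out) if np.ndim(q) == 0 else out


def _liu_quantile(p_upper: float, lam: np.ndarray) -> float:
    """Quantile q with P(sum lam_j chi2_1 > q) = p_upper, Liu-matched."""
    mu_q, sigma_q, mu_x, sigma_x, l, d = _liu_params(lam)
    t = stats.ncx2.isf(p_upper, l, d) if d > 0 else stats.chi2.isf(p_upper, l)
    return float((t - mu_x) / sigma_x * sigma_q + mu_q)


def _kuonen_sf(q: float, lam: np.ndarray) -> float | None:
    """Saddlepoint (Barndorff-Nielsen) tail for sum lam_j chi2_1; None if the
    saddlepoint equation has no usable root (q too close to the mean)."""
    lmax = lam.max()
    if q <= 0 or lmax <= 0:
        return None

    def kprime(t):
        return np.sum(lam / (1 - 2 * lam * t))

    mean = lam.sum()
    if abs(q - mean) < 1e-10 * max(mean, 1.0):
        return 0.5
    hi = 1.0 / (2 * lmax)
    try:
        t = optimize.brentq(lambda t: kprime(t) - q, -1e4, hi * (1 - 1e-12), xtol=1e-14)
    except ValueError:
        return None
    if abs(t) < 1e-12:
        return 0.5
    K = -0.5 * np.sum(np.log1p(-2 * lam * t))
    K2 = 2 * np.sum(lam**2 / (1 - 2 * lam * t) ** 2)
    w = np.sign(t) * np.sqrt(max(2 * (t * q - K), 0.0))
    v = t * np.sqrt(K2)
    if w == 0 or v == 0:
        return 0.5
    z = w + np.log(v / w) / w
    return float(np.exp(log_ndtr(-z)))


def _cf_inversion_sf(q: float, lam: np.ndarray, acc: float = 1e-9):
    """Davies-type tail by numerical inversion of the characteristic
    function (Imhof's integral), evaluated with a fixed-step trapezoid rule
    dense enough for the oscillation frequency; the error estimate is the
    Richardson difference against the half-resolution grid.
    Returns (p, abs-error-estimate)."""
    lam = np.asarray(lam, dtype=float)

    # truncation point: the envelope 1/(u*rho(u)) must fall below acc
    def envelope_log(u):
        return -np.log(u) - 0.25 * np.sum(np.log1p((lam * u) ** 2))

    # the truncated tail is corrected by the leading integration-by-parts
    # term, so U only needs envelope(U) < acc * |theta'(U)| * U
    u_hi = 1.0 / lam.max()
    for _ in range(200):
        if envelope_log(u_hi) < np.log(acc * max(q, 0.5) * u_hi * 0.25):
            break
        u_hi *= 1.4
    # oscillation rate of theta(u) is bounded by (sum lam + q) / 2
    rate = 0.5 * (lam.sum() + q)
    n = int(min(max(2000, 16 * u_hi * rate / (2 * np.pi)), 2 ** 18))
    n += n % 2
    u = np.linspace(0.0, u_hi, n + 1)[1:]
    with np.errstate(all="ignore"):
        theta = 0.5 * np.sum(np.arctan(lam[:, None] * u[None, :]), axis=0) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam[:, None] * u[None, :]) ** 2), axis=0))
        f = np.sin(theta) / (u * rho)
    f0 = 0.5 * (lam.sum() - q)  # limit of the integrand at u -> 0
    du = u_hi / n
    val = du * (0.5 * f0 + f[:-1].sum() + 0.5 * f[-1])
    half = 2 * du * (0.5 * f0 + f[1:-1:2].sum() + 0.5 * f[-1])
    # leading term of the truncated tail integral (integration by parts)
    dtheta = 0.5 * np.sum(lam / (1 + (lam * u_hi) ** 2)) - 0.5 * q
    env = np.exp(envelope_log(u_hi))
    tail_corr = np.cos(theta[-1]) * env / dtheta if abs(dtheta) > 1e-3 * rate else 0.0
    val += tail_corr
    err = abs(val - half - tail_corr) / 3.0 + abs(env / (max(abs(dtheta), 1e-12) ** 2 * u_hi)) + acc * 0.1
    return 0.5 + val / np.pi, err


def chi2_mixture_sf(q: float, lam: np.ndarray, acc: float = 1e-9):
    """P(sum_j lam_j chi2_1 > q) with the Davies -> Kuonen -> Liu ladder.

    Returns ``(p, method)`` where method records which rung produced the
    value.  Eigenvalues below ``1e-10 * max(lam)`` are dropped.
    """
    lam = np.asarray(lam, dtype=float).ravel()
    lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 0.0)] if lam.size else lam
    if lam.size == 0:
        return 1.0, "degenerate"
    if q <= 0:
        return 1.0, "exact"
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1)), "exact"
    # the inversion integral oscillates with period ~1/sum(arctan) and its
    # cost and failure rate grow with the number of eigenvalues; the
    # saddlepoint is fast and accurate in the deep tail and for wide spectra
    pk = _kuonen_sf(q, lam)
    if pk is not None and np.isfinite(pk) and 0 <= pk <= 1:
        if pk < 1e-4 or lam.size > 40:
            return float(pk), "kuonen"
    with np.errstate(all="ignore"):
        p, err = _cf_inversion_sf(q, lam, acc)
    if np.isfinite(p) and 10 * acc < p <= 1 and err < max(acc, 1e-3 * p):
        return float(min(max(p, 0.0), 1.0)), "davies"
    pk = _kuonen_sf(q, lam)
    if pk is not None and np.isfinite(pk) and 0 <= pk <= 1:
        return float(pk), "kuonen"
    return _liu_sf(q, lam), "liu"


# ---------------------------------------------------------------------------
# score construction


def score_decompose(fit: NullModelFit, cs: CollapsedSet) -> ScoreDecomposition:
    """Per-marker scores ``S = w * G'resid`` and null covariance
    ``Phi = w' (G'WG - G'WX (X'WX)^-1 X'WG) w * variance_ratio``."""
    G = cs.marker_matrix
    if G.shape[0] != fit.n:
        raise ValueError("sample mismatch between null model and collapsed set")
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite dosages in marker matrix")
    if G.shape[1] == 0:
        raise ValueError("no markers to test")
    w = cs.weights
    X, ww = fit.X_proj, fit.work_w
    WX = X * ww[:, None]
    # rare-variant matrices are overwhelmingly zero; sparse products cut the
    # dominant G'WG cost for wide sets
    if G.size > 50_000 and G.shape[1] >= 8 and np.count_nonzero(G) < 0.05 * G.size:
        from scipy import sparse as sp

        Gs = sp.csc_matrix(G)
        Gw = Gs.multiply(ww[:, None]).tocsc()
        S = w * np.asarray(Gs.T @ fit.resid).ravel()
        GtWX = np.asarray(Gw.T @ X)
        GtWG = np.asarray((Gs.T @ Gw).todense())
    else:
        S = w * (G.T @ fit.resid)
        GtWX = G.T @ WX
        GtWG = (G * ww[:, None]).T @ G
    H = np.linalg.solve(X.T @ WX, GtWX.T)
    A = GtWG - GtWX @ H
    Phi = (w[:, None] * A * w[None, :]) * fit.variance_ratio
    Phi = 0.5 * (Phi + Phi.T)
    return ScoreDecomposition(S=S, Phi=Phi)


def _projected_burden_genotype(fit: NullModelFit, cs: CollapsedSet) -> np.ndarray:
    """Weighted burden genotype with covariates projected out under W."""
    g = cs.marker_matrix @ cs.weights
    X, ww = fit.X_proj, fit.work_w
    WX = X * ww[:, None]
    coef = np.linalg.solve(X.T @ WX, WX.T @ g)
    return g - X @ coef


# ---------------------------------------------------------------------------
# tests


def spa_pvalue(score: float, g: np.ndarray, mu: np.ndarray) -> float:
    """Two-sided saddlepoint tail for the binary-trait score ``g'(y - mu)``.

    The cumulant generating function of the centered score is
    ``K(t) = sum_i log(1 - mu_i + mu_i e^{g_i t}) - t sum_i g_i mu_i``;
    ``K'(t) = s`` is solved by a safeguarded root search and each tail comes
    from the Barndorff-Nielsen formula; the two-sided value sums the mass
    beyond |s| on both sides.  Falls back to the normal approximation when
    the root-finder fails at machine bounds.
    """
    g = np.asarray(g, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("spa_pvalue requires a binary fit with mu in (0,1)")
    s = float(score)
    if s == 0:
        return 1.0
    var0 = float(np.sum(g * g * mu * (1 - mu)))
    if var0 <= 0:
        return 1.0

    # integer-valued genotype vectors put the score on a lattice; the tail
    # then gets Daniels' continuity correction (offset 1/2, sinh factor),
    # which matters for exactness at tiny N
    rounded = np.round(g)
    nz = rounded[rounded != 0]
    lattice = bool(nz.size) and np.max(np.abs(g - rounded)) < 1e-9
    span = float(np.gcd.reduce(np.abs(nz).astype(np.int64))) if lattice else 1.0

    def tail(gv: np.ndarray, s_obs: float) -> float | None:
        """Upper tail P(gv'(y - mu) >= s_obs) for s_obs > 0."""
        if lattice:
            gv, s_obs = gv / span, s_obs / span
        gm = float(gv @ mu)

        def K(t):
            return float(np.sum(np.logaddexp(np.log1p(-mu), np.log(mu) + gv * t))) - t * gm

        def K1(t):
            e = mu * np.exp(np.clip(gv * t, -700, 700))
            return float(np.sum(gv * e / (1 - mu + e))) - gm

        def K2(t):
            e = mu * np.exp(np.clip(gv * t, -700, 700))
            pi = e / (1 - mu + e)
            return float(np.sum(gv * gv * pi * (1 - pi)))

        sc = s_obs - 0.5 if lattice else s_obs
        s_max = float(np.sum(np.where(gv > 0, gv * (1 - mu), -gv * mu)))
        if sc >= s_max:
            return 0.0
        if sc <= 0:
            return 0.5
        hi = 1.0
        for _ in range(200):
            if K1(hi) > sc:
                break
            hi *= 2
            if hi > 1e8:
                return None
        try:
            t = optimize.brentq(lambda t: K1(t) - sc, 0.0, hi, xtol=1e-13)
        except ValueError:
            return None
        if abs(t) < 1e-13:
            return 0.5
        w = np.sign(t) * np.sqrt(max(2 * (t * sc - K(t)), 0.0))
        v = (2 * np.sinh(t / 2) if lattice else t) * np.sqrt(K2(t))
        if w == 0 or v <= 0:
            return None
        z = w + np.log(v / w) / w
        return float(np.exp(log_ndtr(-z)))

    p_up = tail(g, abs(s))
    # lower tail of S at -|s| equals the upper tail of -S at |s|
    p_dn = tail(-g, abs(s))
    if p_up is None or p_dn is None:
        z = abs(s) / np.sqrt(var0)
        return float(min(2 * stats.norm.sf(z), 1.0))
    # two-sided: mass beyond |s| on both sides.  For a symmetric score this
    # doubles one tail; when one side cannot reach |s| its tail is 0.
    return float(min(p_up + p_dn, 1.0))


def burden_test(sd: ScoreDecomposition, fit: NullModelFit, cs: CollapsedSet):
    """Two-sided burden p-value; returns (p, score, spa_applied).

    For binary traits the saddlepoint tail replaces the normal approximation
    when |z| exceeds :data:`SPA_Z_THRESHOLD`."""
    s = float(sd.S.sum())
    var = float(sd.Phi.sum())
    if var <= 0:
        logger.warning("burden genotype constant after projection; p = 1")
        return 1.0, s, False
    z = s / np.sqrt(var)
    if fit.trait_type == "binary" and abs(z) > SPA_Z_THRESHOLD:
        g = _projected_burden_genotype(fit, cs)
        # SPA on the raw-variance scale; rescale the observed score so that
        # the variance-ratio calibration carries over to the adjusted tail
        raw_var = float(np.sum(g * g * fit.work_w))
        if raw_var > 0:
            s_spa = z * np.sqrt(raw_var)
            return spa_pvalue(s_spa, g, fit.mu_hat), s, True
    return float(min(2 * stats.norm.sf(abs(z)), 1.0)), s, False


def skat_test(sd: ScoreDecomposition, acc: float = 1e-9):
    """SKAT variance-component test; returns (q, p, method_tail)."""
    q = float(np.sum(sd.S**2))
    lam = np.linalg.eigvalsh(sd.Phi)
    lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 0.0)]
    if lam.size == 0:
        logger.warning("null covariance numerically zero; p = 1")
        return q, 1.0, "degenerate"
    p, method = chi2_mixture_sf(q, lam, acc)
    return q, p, method


def _skato_param(Phi: np.ndarray, rho_grid: np.ndarray):
    """Moments and per-rho eigenvalues for the SKAT-O minimum-p construction."""
    k = Phi.shape[0]
    c = Phi @ np.ones(k)
    s_sum = float(c.sum())  # 1' Phi 1
    lam_rho, tau_rho = [], []
    d, U = np.linalg.eigh(Phi)
    d = np.clip(d, 0.0, None)
    sq = (U * np.sqrt(d)) @ U.T  # Phi^{1/2}
    b = sq @ np.ones(k)
    for rho in rho_grid:
        A = (1 - rho) * Phi + rho * np.outer(b, b)
        lam = np.linalg.eigvalsh(0.5 * (A + A.T))
        lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 0.0)]
        lam_rho.append(lam)
        tau_rho.append(rho * s_sum + (1 - rho) * float(c @ c) / s_sum)
    # conditional-remainder kernel: Phi minus its component along Phi*1
    Phi_c = Phi - np.outer(c, c) / s_sum
    lam_c = np.linalg.eigvalsh(0.5 * (Phi_c + Phi_c.T))
    lam_c = lam_c[lam_c > 1e-10 * max(lam_c.max(initial=0.0), 0.0)]
    mu_q = float(lam_c.sum())
    var_zeta = 4.0 * float(c @ Phi_c @ c) / s_sum
    var_q = 2.0 * float((lam_c**2).sum()) + var_zeta
    return lam_rho, np.asarray(tau_rho), lam_c, mu_q, var_q, var_zeta


def skato_test(sd: ScoreDecomposition, rho_grid=DEFAULT_RHO_GRID, acc: float = 1e-9) -> float:
    """SKAT-O: minimum p over the rho-mixture family
    ``Q_rho = (1-rho) Q_SKAT + rho Q_Burden`` combined by the one-dimensional
    integration over the shared burden component (Lee et al. construction).
    If the integration fails the Bonferroni bound ``min(min_p * |grid|, 1)``
    is returned."""
    rho_grid = np.asarray(sorted(set(float(r) for r in rho_grid)))
    if rho_grid.min() < 0 or rho_grid.max() > 1:
        raise ValueError("rho grid must lie in [0, 1]")
    q_skat = float(np.sum(sd.S**2))
    s_burden = float(sd.S.sum())
    q_burden = s_burden**2
    var_burden = float(sd.Phi.sum())

    if sd.k == 1 or var_burden <= 0:
        _, p, _ = skat_test(sd, acc)
        return p

    # degenerate single-element grids reduce exactly to the component tests
    if rho_grid.size == 1:
        rho = rho_grid[0]
        if rho == 1.0:
            return float(stats.chi2.sf(q_burden / var_burden, 1))
        if rho == 0.0:
            _, p, _ = skat_test(sd, acc)
            return p

    lam_rho, tau_rho, lam_c, mu_q, var_q, var_zeta = _skato_param(sd.Phi, rho_grid)

    # per-rho p-values: the saddlepoint tail is accurate where it matters
    # (small p) and cheap enough to evaluate across the whole grid
    p_rho = np.empty(rho_grid.size)
    q_rho = (1 - rho_grid) * q_skat + rho_grid * q_burden
    for i, rho in enumerate(rho_grid):
        if rho == 1.0:
            p_rho[i] = stats.chi2.sf(q_burden / var_burden, 1)
        elif lam_rho[i].size == 1:
            p_rho[i] = stats.chi2.sf(q_rho[i] / lam_rho[i][0], 1)
        else:
            pk = _kuonen_sf(q_rho[i], lam_rho[i])
            p_rho[i] = pk if pk is not None else _liu_sf(q_rho[i], lam_rho[i])
    t_min = float(p_rho.min())
    if t_min <= 0:
        return max(t_min, np.finfo(float).tiny)

    # per-rho quantiles of Q_rho at the minimum p
    rho_int = np.minimum(rho_grid, 0.999)  # keep (1-rho) > 0 in the integrand
    q_min = np.array([_liu_quantile(t_min, lam) for lam in lam_rho])

    sd_ratio = np.sqrt(max(var_q - var_zeta, 0.0) / var_q) if var_q > 0 else 1.0

    # p = integral over the 1-df burden component x of
    # P(kappa > min_rho (q_min(rho) - tau(rho) x) / (1 - rho)) f_chi2_1(x) dx
    # computed on the complement scale so small p suffers no cancellation;
    # substitution x = u^2 removes the chi2_1 density singularity at 0.
    x0 = float(np.min(q_min / np.maximum(tau_rho, 1e-300)))  # bound hits 0 here
    u0 = min(np.sqrt(max(x0, 0.0)), 8.2)

    def upper_tail(u: np.ndarray) -> np.ndarray:
        x = u * u
        bound = np.min(
            (q_min[:, None] - tau_rho[:, None] * x[None, :]) / (1 - rho_int[:, None]),
            axis=0,
        )
        temp = (bound - mu_q) * sd_ratio + mu_q
        out = _liu_sf(np.clip(temp, 0.0, None), lam_c)
        out[bound <= 0] = 1.0
        return out

    try:
        nodes, wts = _GAUSS_NODES
        u = 0.5 * u0 * (nodes + 1.0)
        w = 0.5 * u0 * wts
        val = float(np.sum(w * upper_tail(u) * 2.0 * stats.norm.pdf(u)))
        p = val + float(stats.chi2.sf(u0 * u0, 1))  # bound <= 0 region
    except Exception:  # pragma: no cover - integration failure path
        p = np.nan
    if not np.isfinite(p) or p <= 0 or p > 1:
        return float(min(t_min * rho_grid.size, 1.0))
    return float(min(p, 1.0))


def run_gene(
    fit: NullModelFit,
    gvs: GeneVariantSet,
    masks: list[MaskSpec],
    scheme: WeightScheme = WeightScheme(),
    mac_threshold: float = DEFAULT_MAC_THRESHOLD,
    rho_grid=DEFAULT_RHO_GRID,
) -> list[SetTestResult]:
    """Test one gene across a mask grid; the gene's dosage matrix is
    materialized once and each (annotation, max-MAF) cell is masked,
    collapsed and tested against the shared null model.  Cells with no
    qualifying variants are omitted (and logged), never reported as p = 1."""
    if not masks:
        raise ValueError("mask list must be non-empty")
    results: list[SetTestResult] = []
    for mask in masks:
        try:
            sub = apply_mask(gvs, mask)
        except EmptySetError:
            logger.info("gene %s: cell (%s, %g) has no qualifying variants; skipped",
                        gvs.gene_id, mask.label(), mask.max_maf)
            continue
        cs = collapse(sub, scheme, mac_threshold)
        sd = score_decompose(fit, cs)
        p_b, s_b, spa = burden_test(sd, fit, cs)
        q, p_s, method = skat_test(sd)
        if sd.k == 1:
            # the whole cell reduced to one (collapsed) marker: all three
            # tests are the same single-variant check, so the SPA-adjusted
            # burden tail is the p-value for each of them
            p_s = p_o = p_b
        else:
            p_o = skato_test(sd, rho_grid)
        results.append(SetTestResult(
            gene_id=gvs.gene_id, mask=mask, p_burden=p_b, p_skat=p_s, p_skato=p_o,
            q_skat=q, score_burden=s_b, m_markers_pre=sub.n_variants,
            m_markers=cs.n_markers, collapsed=cs.collapsed, spa_applied=spa,
            method_tail=method, provenance=list(cs.provenance),
        ))
    return results
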