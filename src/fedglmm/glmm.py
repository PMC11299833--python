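"""Pooled logistic mixed-model engine: PQL null fit, AI-REML, score test.

This is the non-federated reference implementation of the two-stage
association test for binary traits with a polygenic random effect:

    logit P(y_i = 1 | b) = x_i' alpha + b_i,      b ~ N(0, tau * V)

where ``V`` is an n x n relatedness (kinship) matrix.  Stage one fits the
null model (alpha, tau, b) by penalized quasi-likelihood: iterate a working
linear mixed model on the working response

    Ytilde = eta + (y - pi) / nu(pi),   nu(pi) = pi (1 - pi),  w = nu

with generalized-least-squares updates of alpha, BLUP updates of b, and an
average-information REML step for tau.  Stage two scores each variant g by

    T = g' P Ytilde,     var(T) = g' P g,      T^2 / var ~ chi^2_1,

where P = Sigma^{-1} - Omega Xi^{-1} Omega' is the projection onto the
orthocomplement of the fixed-effect design (Sigma = W^{-1} + tau V,
Omega = Sigma^{-1} X, Xi = X' Omega).  The federated protocol in
:mod:`fedglmm.federation` reproduces exactly these quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import expit
from scipy.stats import chi2

PI_EPS = 1e-10
TAU_FLOOR = 1e-8
VAR_FLOOR = 1e-10
W_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CohortData:
    """One cohort: binary outcome, fixed-covariate design, relatedness.

    ``X`` must carry an all-ones intercept as its first column; ``V`` is a
    symmetric near-PSD relationship matrix (diagonal ~ 1, i.e. twice the
    kinship coefficient) in the same sample order as ``y`` and ``X``.
    """

    sample_ids: np.ndarray
    y: np.ndarray
    X: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.y.shape[0]
        if len(np.unique(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique and match y length")
        if not np.isin(self.y, (0.0, 1.0)).all():
            bad = np.unique(self.y[~np.isin(self.y, (0.0, 1.0))])
            raise ValueError(f"outcome must be binary 0/1; found {bad}")
        if self.X.shape[0] != n or self.V.shape != (n, n):
            raise ValueError("X/V shapes inconsistent with y")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be the intercept")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is rank deficient")
        if not np.allclose(self.V, self.V.T, atol=1e-8):
            raise ValueError("V must be symmetric")
        if np.any(np.diag(self.V) <= 0):
            raise ValueError("V diagonal entries must be positive")
        lo = np.linalg.eigvalsh(self.V)[0]
        if lo < -1e-8 * max(1.0, np.abs(self.V).max()):
            raise ValueError(f"V is not near-PSD (min eigenvalue {lo:.3e})")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class WorkingState:
    """Per-iteration PQL quantities for the logistic link (w = nu)."""

    eta: np.ndarray
    pi: np.ndarray
    nu: np.ndarray
    w: np.ndarray
    ytilde: np.ndarray
    psi: np.ndarray


@dataclass
class SigmaFactors:
    """Factorization of Sigma = W^{-1} + tau V and derived projections."""

    sigma_inv: np.ndarray
    v_sigma_inv: np.ndarray | None = None
    Omega: np.ndarray | None = None
    Xi: np.ndarray | None = None
    P: np.ndarray | None = None


@dataclass
class NullModel:
    """Converged (or flagged) null-model parameters from stage one."""

    alpha: np.ndarray
    tau: float
    b: np.ndarray
    converged: bool
    n_iter: int
    loglik_trace: list = field(default_factory=list)
    # carried for stage two (scoring) and diagnostics
    working: WorkingState | None = None
    factors: SigmaFactors | None = None

    @property
    def P(self) -> np.ndarray:
        if self.factors is None or self.factors.P is None:
            raise ValueError("projection matrix not available on this model")
        return self.factors.P

    @property
    def ytilde(self) -> np.ndarray:
        if self.working is None:
            raise ValueError("working state not available on this model")
        return self.working.ytilde


@dataclass
class ScoreRow:
    """Score-test result for one variant."""

    snp_id: str
    score_T: float
    var_T: float
    pval: float | None
    n_used: int = 0
    af: float = float("nan")
    chrom: str = ""
    pos: int = 0
    ref: str = ""
    alt: str = ""
    reason: str = ""


@dataclass
class NewtonResult:
    alpha: np.ndarray
    converged: bool
    n_iter: int
    grad_norm: float


@dataclass
class FitOptions:
    tol: float = 1e-6
    max_iter: int = 100
    newton_tol: float = 1e-6
    newton_max_iter: int = 50
    fix_tau: float | None = None
    tau_floor: float = TAU_FLOOR


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def logistic_working_update(
    alpha: np.ndarray, b: np.ndarray, data: CohortData, eps: float = PI_EPS
) -> WorkingState:
    """Working response, weights and linear predictor at (alpha, b).

    For the logit link g'(pi) = 1/nu so the PQL weight reduces to
    w = 1/(nu g'^2) = nu; Ytilde = eta + (y - pi)/nu; Psi = X alpha.
    pi is clipped into [eps, 1-eps] to keep nu bounded away from zero.
    """
    alpha = np.asarray(alpha, dtype=float)
    b = np.asarray(b, dtype=float)
    eta = data.X @ alpha + b
    bad = ~np.isfinite(eta)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise FloatingPointError(f"non-finite linear predictor at sample index {idx}")
    pi = np.clip(expit(eta), eps, 1.0 - eps)
    nu = pi * (1.0 - pi)
    w = nu
    ytilde = eta + (data.y - pi) / nu
    psi = data.X @ alpha
    return WorkingState(eta=eta, pi=pi, nu=nu, w=w, ytilde=ytilde, psi=psi)


def binomial_loglik(alpha: np.ndarray, b: np.ndarray, data: CohortData) -> float:
    """Bernoulli log-likelihood at the current linear predictor (diagnostic)."""
    eta = data.X @ np.asarray(alpha, float) + np.asarray(b, float)
    pi = np.clip(expit(eta), PI_EPS, 1.0 - PI_EPS)
    return float(np.sum(data.y * np.log(pi) + (1.0 - data.y) * np.log1p(-pi)))


def newton_init_alpha(
    data: CohortData, tol: float = 1e-6, max_iter: int = 50
) -> NewtonResult:
    """Plain logistic-regression MLE of alpha (b = 0, tau = 0) by Newton.

    Gradient X'(y - pi), Hessian -X'WX; the update alpha <- alpha +
    (X'WX)^{-1} X'(y - pi) is iterated until the max-absolute change in
    alpha drops below ``tol``.
    """
    alpha = np.zeros(data.p)
    converged = False
    grad = np.full(data.p, np.nan)
    it = 0
    for it in range(1, max_iter + 1):
        pi = np.clip(expit(data.X @ alpha), PI_EPS, 1.0 - PI_EPS)
        grad = data.X.T @ (data.y - pi)
        H = (data.X * (pi * (1.0 - pi))[:, None]).T @ data.X
        if not np.all(np.isfinite(H)):
            warnings.warn("non-finite Hessian in logistic Newton; stopping")
            break
        try:
            step = linalg.solve(H, grad, assume_a="pos")
        except linalg.LinAlgError:
            warnings.warn(
                "singular Hessian in logistic Newton (possible separation)"
            )
            break
        alpha = alpha + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"logistic Newton did not converge in {it} iterations "
            f"(|grad|_inf = {np.max(np.abs(grad)):.3e})"
        )
    return NewtonResult(
        alpha=alpha, converged=converged, n_iter=it, grad_norm=float(np.max(np.abs(grad)))
    )


def assemble_sigma(
    working: WorkingState,
    tau: float,
    V: np.ndarray,
    compute_v_sigma_inv: bool = True,
) -> SigmaFactors:
    """Invert Sigma = W^{-1} + tau V (SPD for w > 0, tau >= 0, V PSD)."""
    w = working.w
    if np.any(w <= W_FLOOR):
        raise ValueError("PQL weights below floor; pi collapsed to 0/1")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    sigma = tau * V + np.diag(1.0 / w)
    try:
        c, low = linalg.cho_factor(sigma)
    except linalg.LinAlgError as err:
        cond = np.linalg.cond(sigma)
        raise linalg.LinAlgError(
            f"Sigma not positive definite (condition number {cond:.3e})"
        ) from err
    sigma_inv = linalg.cho_solve((c, low), np.eye(sigma.shape[0]))
    sigma_inv = 0.5 * (sigma_inv + sigma_inv.T)
    v_sigma_inv = V @ sigma_inv if compute_v_sigma_inv else None
    return SigmaFactors(sigma_inv=sigma_inv, v_sigma_inv=v_sigma_inv)


def gls_update_alpha(
    factors: SigmaFactors, X: np.ndarray, ytilde: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GLS solve for alpha on the working response.

    Omega = Sigma^{-1} X, Xi = X' Omega, alpha_hat = Xi^{-1} Omega' Ytilde
    (the normal equations (X' Sigma^{-1} X) alpha = X' Sigma^{-1} Ytilde).
    Results are cached on ``factors``.
    """
    Omega = factors.sigma_inv @ X
    Xi = X.T @ Omega
    try:
        alpha_hat = linalg.solve(Xi, Omega.T @ ytilde, assume_a="pos")
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError("Xi = X' Sigma^{-1} X is singular") from err
    factors.Omega, factors.Xi = Omega, Xi
    return Omega, Xi, alpha_hat


def update_random_effects(
    tau: float, v_sigma_inv: np.ndarray, ytilde: np.ndarray, psi: np.ndarray
) -> np.ndarray:
    """BLUP update b_hat = tau * V Sigma^{-1} (Ytilde - Psi)."""
    resid = np.asarray(ytilde, float) - np.asarray(psi, float)
    if v_sigma_inv.shape[1] != resid.shape[0]:
        raise ValueError("shape mismatch between V Sigma^{-1} and residual")
    return tau * (v_sigma_inv @ resid)


def projection_matrix(factors: SigmaFactors) -> np.ndarray:
    """P = Sigma^{-1} - Omega Xi^{-1} Omega'; annihilates the X-span."""
    if factors.Omega is None or factors.Xi is None:
        raise ValueError("run gls_update_alpha first to populate Omega/Xi")
    try:
        XiinvOt = linalg.solve(factors.Xi, factors.Omega.T, assume_a="pos")
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError("Xi is singular; cannot form projection") from err
    P = factors.sigma_inv - factors.Omega @ XiinvOt
    P = 0.5 * (P + P.T)
    factors.P = P
    return P


def aireml_tau_step(
    P: np.ndarray,
    V: np.ndarray,
    ytilde: np.ndarray,
    tau: float,
    tau_floor: float = TAU_FLOOR,
    prev_delta: float | None = None,
) -> float:
    """One average-information REML update of the variance component.

    score  s = (Ytilde' P V P Ytilde - tr(PV)) / 2
    AI     a = (Ytilde' P V P V P Ytilde) / 2
    tau_new = max(tau + s/a, tau_floor)

    The dependence of W on tau is ignored (standard PQL simplification).
    All quadratic forms reduce to matrix-vector products; tr(PV) uses the
    symmetry of V: tr(PV) = sum(P * V).
    """
    u = P @ ytilde
    v = V @ u
    s = 0.5 * (u @ v - np.sum(P * V))
    a = 0.5 * (v @ (P @ v))
    if a <= 0 or not np.isfinite(a):
        warnings.warn(
            f"average information nonpositive (a={a:.3e}); halving previous step"
        )
        delta = 0.5 * prev_delta if prev_delta is not None else 0.0
    else:
        delta = s / a
    return max(tau + delta, tau_floor)


def fit_null_pooled(data: CohortData, opts: FitOptions | None = None) -> NullModel:
    """Fit the null logistic mixed model on pooled data.

    Initialization: alpha from the plain logistic Newton fit, tau from the
    sample variance of y (or ``opts.fix_tau``), b = 0.  Each PQL iteration
    runs working update -> Sigma factorization -> GLS alpha -> BLUP b ->
    projection -> AI-REML tau, and converges when the max-absolute change
    over (alpha, b, tau) drops below ``opts.tol``.  On return the model
    carries the projection matrix and working response refreshed at the
    final parameters, ready for scoring.
    """
    opts = opts or FitOptions()
    init = newton_init_alpha(data, tol=opts.newton_tol, max_iter=opts.newton_max_iter)
    alpha = init.alpha
    fit_tau = opts.fix_tau is None
    tau = float(np.var(data.y)) if fit_tau else float(opts.fix_tau)
    b = np.zeros(data.n)
    trace: list[float] = []
    converged = False
    prev_delta: float | None = None
    it = 0
    for it in range(1, opts.max_iter + 1):
        ws = logistic_working_update(alpha, b, data)
        factors = assemble_sigma(ws, tau, data.V, compute_v_sigma_inv=False)
        _, _, alpha_new = gls_update_alpha(factors, data.X, ws.ytilde)
        # b_hat = tau * V Sigma^{-1} (Ytilde - Psi) via matvecs
        b_new = tau * (data.V @ (factors.sigma_inv @ (ws.ytilde - ws.psi)))
        P = projection_matrix(factors)
        if fit_tau:
            tau_new = aireml_tau_step(
                P, data.V, ws.ytilde, tau, opts.tau_floor, prev_delta
            )
            prev_delta = tau_new - tau
        else:
            tau_new = tau
        trace.append(binomial_loglik(alpha_new, b_new, data))
        delta = max(
            np.max(np.abs(alpha_new - alpha)),
            np.max(np.abs(b_new - b)),
            abs(tau_new - tau),
        )
        alpha, b, tau = alpha_new, b_new, tau_new
        if delta < opts.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"PQL did not converge in {it} iterations")
    # refresh scoring quantities at the final parameters
    ws = logistic_working_update(alpha, b, data)
    factors = assemble_sigma(ws, tau, data.V, compute_v_sigma_inv=False)
    gls_update_alpha(factors, data.X, ws.ytilde)
    projection_matrix(factors)
    return NullModel(
        alpha=alpha,
        tau=tau,
        b=b,
        converged=converged,
        n_iter=it,
        loglik_trace=trace,
        working=ws,
        factors=factors,
    )


def score_test_chunk(
    G: np.ndarray,
    P: np.ndarray,
    ytilde: np.ndarray,
    snp_ids: list[str] | None = None,
    af: np.ndarray | None = None,
    var_floor: float = VAR_FLOOR,
    quantize_gtp: bool = False,
) -> list[ScoreRow]:
    """Score a chunk of k variants (rows of ``G``, columns = samples).

    Per variant g: T = g' P Ytilde, var = g' P g, p = chi2_1 sf(T^2/var).
    ``quantize_gtp`` round-trips the G'P matrix through float32 before the
    variance step, mirroring the quantized network transfer.  Variants with
    var below ``var_floor`` (e.g. monomorphic: Pg = 0) get a missing p-value
    with a reason code.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n = ytilde.shape[0]
    if G.shape[1] != n or P.shape != (n, n):
        raise ValueError(
            f"shape mismatch: G {G.shape}, P {P.shape}, ytilde ({n},)"
        )
    k = G.shape[0]
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(k)]
    T = G @ (P @ ytilde)
    GP = G @ P
    if quantize_gtp:
        from fedglmm.secure import quantize_matrix

        GP = quantize_matrix(GP, 32)
    var = np.einsum("ij,ij->i", GP, G)
    return score_rows_from_stats(T, var, snp_ids, af=af, n_used=n, var_floor=var_floor)


def score_rows_from_stats(
    T: np.ndarray,
    var: np.ndarray,
    snp_ids: list[str],
    af: np.ndarray | None = None,
    n_used: int = 0,
    var_floor: float = VAR_FLOOR,
) -> list[ScoreRow]:
    """Assemble per-variant rows from score statistics and variances."""
    rows = []
    for i in range(len(snp_ids)):
        a = float(af[i]) if af is not None else float("nan")
        if var[i] <= var_floor:
            rows.append(
                ScoreRow(
                    snp_id=snp_ids[i],
                    score_T=float(T[i]),
                    var_T=float(var[i]),
                    pval=None,
                    n_used=n_used,
                    af=a,
                    reason="degenerate variance",
                )
            )
        else:
            pv = float(chi2.sf(T[i] ** 2 / var[i], df=1))
            rows.append(
                ScoreRow(
                    snp_id=snp_ids[i],
                    score_T=float(T[i]),
                    var_T=float(var[i]),
                    pval=pv,
                    n_used=n_used,
                    af=a,
                )
            )
    return rows


def allele_stats_and_filter(
    G_blocks: list[np.ndarray], maf_threshold: float = 0.01
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Pooled allele frequencies, MAF keep-mask, and mean-imputed blocks.

    ``G_blocks`` are per-site k x n_j dosage matrices with NaN for missing.
    af = (pooled dosage sum) / (2 * pooled non-missing count); a variant is
    kept iff min(af, 1-af) >= ``maf_threshold``; missing dosages are imputed
    to 2*af (the dosage mean).  All-missing variants are dropped.
    """
    blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in G_blocks]
    total = np.zeros(blocks[0].shape[0])
    count = np.zeros(blocks[0].shape[0])
    for b in blocks:
        if np.nanmin(b, initial=0.0) < 0 or np.nanmax(b, initial=0.0) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        total += np.nansum(b, axis=1)
        count += np.sum(~np.isnan(b), axis=1)
    af = np.divide(total, 2.0 * count, out=np.full_like(total, np.nan), where=count > 0)
    with np.errstate(invalid="ignore"):
        keep = np.minimum(af, 1.0 - af) >= maf_threshold
    keep &= count > 0
    imputed = []
    for b in blocks:
        out = b.copy()
        miss = np.isnan(out)
        if miss.any():
            fill = np.broadcast_to((2.0 * af)[:, None], out.shape)
            out[miss] = fill[miss]
        imputed.append(out)
    return af, keep, imputed
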