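"""In-process simulation of the federated null-fit and score-test protocols.

Parties are plain objects — J :class:`SiteData` holders and one
:class:`ServerState` — exchanging matrices through the secure-aggregation
primitives of :mod:`fedglmm.secure`; every transfer is recorded in the
server transcript.  The three protocol stages are:

1. **Federated Newton** — sites aggregate encrypted logistic gradients and
   Hessians; the server Newton-updates the fixed effects.
2. **Federated PQL** — per iteration the sites send weight vectors; the
   server forms Sigma^{-1} and V Sigma^{-1} and returns vertical partitions;
   sites build Omega_j, Xi_j, working responses and BLUP shares, which are
   EADP-aggregated or secure-summed; the projection matrix is assembled at
   the server from rotation-masked products; tau takes an AI-REML step.
3. **Federated score test** — the server distributes row partitions of P and
   P Ytilde once; per chunk of k variants the sites secure-sum G'PYtilde,
   EADP-aggregate G'P and secure-sum the variance G'PG.

With the OTP-like mask backend the protocol reproduces the pooled engine's
output to float-cancellation error (well below 1e-6), which is the point:
federation changes where the computation happens, not what it computes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from fedglmm import glmm
from fedglmm.glmm import (
    CohortData,
    FitOptions,
    NewtonResult,
    NullModel,
    ScoreRow,
    SigmaFactors,
    WorkingState,
    score_rows_from_stats,
)
from fedglmm.secure import (
    EncryptionBackend,
    MaskMaterial,
    PartitionPlan,
    RotationSecret,
    Transcript,
    eadp,
    get_backend,
    quantize_matrix,
    rotation_mask_products,
    round_robin_secure_sum,
)

# kinds of plaintext the server is allowed to receive (aggregate-level only)
SERVER_PLAINTEXT_ALLOWED = frozenset(
    {"w_j", "Ytilde_j", "site-metadata", "rotated-OmegaQ", "rotated-QinvXiinvOmegaT"}
)
RAW_KINDS = frozenset({"X_j", "y_j", "G_j"})


@dataclass
class SiteData:
    """One collaborating site's local data.

    ``V_block`` holds the n x n_j columns of the global kinship matrix for
    this site's subjects (global row order = concatenation of sites);
    ``G`` is an optional m x n_j dosage block (variants by local samples,
    NaN for missing).
    """

    site_id: str
    sample_ids: np.ndarray
    X: np.ndarray
    y: np.ndarray
    V_block: np.ndarray
    G: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.n or self.V_block.shape[1] != self.n:
            raise ValueError(f"site {self.site_id}: inconsistent row counts")
        if self.G is not None and np.atleast_2d(self.G).shape[1] != self.n:
            raise ValueError(f"site {self.site_id}: genotype column count != n_j")


@dataclass
class ServerState:
    """Central server: full kinship, keys, current global parameters."""

    V: np.ndarray
    backend: EncryptionBackend
    rng: np.random.Generator
    transcript: Transcript = field(default_factory=Transcript)
    keys: tuple = None
    alpha: np.ndarray | None = None
    tau: float = 0.0
    b: np.ndarray | None = None
    sigma_inv: np.ndarray | None = None
    v_sigma_inv: np.ndarray | None = None
    P: np.ndarray | None = None
    ytilde: np.ndarray | None = None
    diagnostics: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.keys is None:
            self.keys = self.backend.keygen()


def make_server(
    V: np.ndarray,
    backend: str | EncryptionBackend = "mask",
    seed: int | None = None,
) -> ServerState:
    """Set up the central server with a seeded backend and fresh transcript."""
    rng = np.random.default_rng(seed)
    if isinstance(backend, str):
        backend = get_backend(backend, rng=rng)
    return ServerState(V=np.asarray(V, dtype=float), backend=backend, rng=rng)


def split_cohort(
    data: CohortData,
    n_sites: int,
    G: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    sizes: list[int] | None = None,
) -> tuple[list[SiteData], CohortData, np.ndarray | None]:
    """Randomly split a pooled cohort into contiguous site blocks.

    Returns the sites, the pooled cohort reordered to the concatenated site
    order (so pooled and federated results are directly comparable), and
    the genotype matrix in the same sample order.
    """
    n = data.n
    perm = rng.permutation(n) if rng is not None else np.arange(n)
    if sizes is None:
        base = n // n_sites
        sizes = [base] * n_sites
        sizes[-1] += n - base * n_sites
    if sum(sizes) != n:
        raise ValueError("site sizes must sum to the cohort size")
    order = perm
    y, X, V = data.y[order], data.X[order], data.V[np.ix_(order, order)]
    ids = data.sample_ids[order]
    Gp = None if G is None else np.atleast_2d(G)[:, order]
    pooled = CohortData(sample_ids=ids, y=y, X=X, V=V)
    sites = []
    lo = 0
    for j, nj in enumerate(sizes):
        hi = lo + nj
        sites.append(
            SiteData(
                site_id=f"site{j}",
                sample_ids=ids[lo:hi],
                X=X[lo:hi],
                y=y[lo:hi],
                V_block=V[:, lo:hi],
                G=None if Gp is None else Gp[:, lo:hi],
            )
        )
        lo = hi
    return sites, pooled, Gp


def _plan(sites: list[SiteData]) -> PartitionPlan:
    return PartitionPlan(site_sizes=[s.n for s in sites])


def _site_working(site: SiteData, alpha: np.ndarray, b_j: np.ndarray) -> WorkingState:
    """Local PQL working update (same clipping as the pooled engine)."""
    from scipy.special import expit

    eta = site.X @ alpha + b_j
    pi = np.clip(expit(eta), glmm.PI_EPS, 1.0 - glmm.PI_EPS)
    nu = pi * (1.0 - pi)
    return WorkingState(
        eta=eta, pi=pi, nu=nu, w=nu, ytilde=eta + (site.y - pi) / nu, psi=site.X @ alpha
    )


# ---------------------------------------------------------------------------
# Stage 1: federated Newton initialization of the fixed effects
# ---------------------------------------------------------------------------


def algorithm1_fed_newton(
    sites: list[SiteData],
    server: ServerState,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> NewtonResult:
    """Federated logistic-regression fit of the initial fixed effects.

    Per iteration each site computes its local gradient X_j'(y_j - pi_j)
    and Hessian X_j' W_j X_j, the encrypted shares are round-robin summed,
    and the server applies the Newton step.  With a single site this is
    exactly the pooled Newton initialization.
    """
    from scipy.special import expit

    p = sites[0].X.shape[1]
    for s in sites:
        if s.X.shape[1] != p:
            raise ValueError(f"site {s.site_id} covariate schema mismatch")
    t = server.transcript
    alpha = np.zeros(p)
    converged = False
    grad = np.full(p, np.nan)
    it = 0
    for it in range(1, max_iter + 1):
        for s in sites:
            t.log("server", s.site_id, "alpha", (p,), False, "newton")
        grads, hessians = [], []
        for s in sites:
            pi = np.clip(expit(s.X @ alpha), glmm.PI_EPS, 1.0 - glmm.PI_EPS)
            grads.append(s.X.T @ (s.y - pi))
            hessians.append((s.X * (pi * (1.0 - pi))[:, None]).T @ s.X)
        grad = round_robin_secure_sum(
            grads, server.backend, keys=server.keys, transcript=t,
            kind="newton-grad", stage="newton",
        )
        H = round_robin_secure_sum(
            hessians, server.backend, keys=server.keys, transcript=t,
            kind="newton-hess", stage="newton",
        )
        try:
            step = linalg.solve(H, grad, assume_a="pos")
        except linalg.LinAlgError:
            warnings.warn("singular aggregated Hessian in federated Newton")
            break
        alpha = alpha + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"federated Newton did not converge in {it} iterations")
    server.alpha = alpha
    return NewtonResult(
        alpha=alpha, converged=converged, n_iter=it, grad_norm=float(np.max(np.abs(grad)))
    )


# ---------------------------------------------------------------------------
# Stage 2: federated PQL / AI-REML null fit
# ---------------------------------------------------------------------------


def _server_sigma_factors(
    server: ServerState,
    w: np.ndarray,
    tau: float,
    plan: PartitionPlan,
    assume_block_diagonal: bool,
) -> None:
    """Form Sigma^{-1} and V Sigma^{-1} at the server from the weight vector.

    Under the block-diagonal kinship shortcut only the within-site kinship
    blocks enter Sigma, and the inverse is assembled blockwise — the result
    coincides with the full computation whenever cross-site kinship is zero.
    """
    n = w.shape[0]
    if assume_block_diagonal:
        sigma_inv = np.zeros((n, n))
        for lo, hi in plan.row_ranges:
            blk = tau * server.V[lo:hi, lo:hi] + np.diag(1.0 / w[lo:hi])
            c = linalg.cho_factor(blk)
            inv = linalg.cho_solve(c, np.eye(hi - lo))
            sigma_inv[lo:hi, lo:hi] = 0.5 * (inv + inv.T)
    else:
        sigma = tau * server.V + np.diag(1.0 / w)
        try:
            c = linalg.cho_factor(sigma)
        except linalg.LinAlgError as err:
            raise linalg.LinAlgError(
                f"Sigma not positive definite (cond {np.linalg.cond(sigma):.3e})"
            ) from err
        sigma_inv = linalg.cho_solve(c, np.eye(n))
        sigma_inv = 0.5 * (sigma_inv + sigma_inv.T)
    server.sigma_inv = sigma_inv
    server.v_sigma_inv = server.V @ sigma_inv


def algorithm2_fed_pql(
    sites: list[SiteData],
    server: ServerState,
    tol: float = 1e-6,
    max_iter: int = 100,
    fix_tau: float | None = None,
    quantize: bool = False,
    assume_block_diagonal: bool = False,
    alpha0: np.ndarray | None = None,
) -> NullModel:
    """Federated PQL fit of the null mixed model (Stage 2).

    Mirrors the pooled engine iteration for iteration; converges when the
    max-absolute change over (alpha, b, tau) drops below ``tol``.  With
    ``quantize`` the Sigma^{-1} and V Sigma^{-1} partitions travel as
    float32.  Requires the Stage-1 estimate (``alpha0`` or ``server.alpha``).
    """
    plan = _plan(sites)
    n, p = plan.total_n, sites[0].X.shape[1]
    t = server.transcript
    alpha = np.asarray(alpha0 if alpha0 is not None else server.alpha, dtype=float)
    if alpha is None or alpha.shape != (p,):
        raise ValueError("stage-1 fixed-effect estimate unavailable")
    y_all = np.concatenate([s.y for s in sites])
    fit_tau = fix_tau is None
    tau = float(np.var(y_all)) if fit_tau else float(fix_tau)
    b = np.zeros(n)
    trace: list[float] = []
    converged = False
    prev_delta: float | None = None
    it = 0

    def one_pass(alpha, b, tau, final: bool = False):
        # (1) local working updates; weight vectors to the server (plaintext)
        wss = []
        for j, s in enumerate(sites):
            lo, hi = plan.row_ranges[j]
            ws = _site_working(s, alpha, b[lo:hi])
            wss.append(ws)
            t.log(s.site_id, "server", "w_j", (s.n,), False, "pql")
        w = np.concatenate([ws.w for ws in wss])
        if np.any(w <= glmm.W_FLOOR):
            raise ValueError("PQL weights below floor; pi collapsed to 0/1")
        # (2) server Sigma^{-1}, V Sigma^{-1}; vertical partitions to sites
        _server_sigma_factors(server, w, tau, plan, assume_block_diagonal)
        sig_parts, vsig_parts = [], []
        for j, s in enumerate(sites):
            lo, hi = plan.row_ranges[j]
            sp = server.sigma_inv[:, lo:hi]
            vp = server.v_sigma_inv[:, lo:hi]
            if quantize:
                sp, vp = quantize_matrix(sp, 32), quantize_matrix(vp, 32)
            sig_parts.append(sp)
            vsig_parts.append(vp)
            t.log("server", s.site_id, "sigma_inv_part", sp.shape, False, "pql")
            t.log("server", s.site_id, "v_sigma_inv_part", vp.shape, False, "pql")
        # (3) sites build Omega_j = Sigma^{-1}_(j) X_j; EADP -> row partitions
        Omega_j = [sig_parts[j] @ sites[j].X for j in range(plan.J)]
        res = eadp(
            Omega_j, plan, backend=server.backend, keys=server.keys,
            rng=server.rng, transcript=t, kind="Omega", stage="pql",
        )
        Omega_parts = res.partitions  # Omega_(j), n_j x p
        # (4) Xi_j = X_j' Omega_(j); secure sum -> Xi at server
        Xi = round_robin_secure_sum(
            [sites[j].X.T @ Omega_parts[j] for j in range(plan.J)],
            server.backend, keys=server.keys, transcript=t, kind="Xi", stage="pql",
        )
        # (5) BLUP shares b_hat_j = tau (V Sigma^{-1})_(j) (Ytilde_j - Psi_j)
        b_new = round_robin_secure_sum(
            [
                tau * (vsig_parts[j] @ (wss[j].ytilde - wss[j].psi))
                for j in range(plan.J)
            ],
            server.backend, keys=server.keys, transcript=t, kind="bhat", stage="pql",
        )
        # sites send Ytilde_j; server concatenates (plaintext, as specified)
        for s in sites:
            t.log(s.site_id, "server", "Ytilde_j", (s.n,), False, "pql")
        ytilde = np.concatenate([ws.ytilde for ws in wss])
        server.ytilde = ytilde
        # (6) alpha_hat = Xi^{-1} (sum_j Omega_(j)' Ytilde_j)
        q = round_robin_secure_sum(
            [Omega_parts[j].T @ wss[j].ytilde for j in range(plan.J)],
            server.backend, keys=server.keys, transcript=t, kind="OmegaTY", stage="pql",
        )
        try:
            alpha_new = linalg.solve(Xi, q, assume_a="pos")
        except linalg.LinAlgError as err:
            raise linalg.LinAlgError("aggregated Xi is singular") from err
        # (7) projection matrix via the rotation protocol
        Xi_inv = linalg.inv(Xi)
        for s in sites:
            t.log("server", s.site_id, "Xi_inv", (p, p), False, "pql")
        secret = RotationSecret.generate(p, n, server.rng)
        A_sum = np.zeros((n, p))
        B_sum = np.zeros((p, n))
        for j, s in enumerate(sites):
            A_j, B_j = rotation_mask_products(Omega_j[j], Xi_inv, secret)
            t.log(s.site_id, "server", "rotated-OmegaQ", A_j.shape, True, "pql")
            t.log(s.site_id, "server", "rotated-QinvXiinvOmegaT", B_j.shape, True, "pql")
            A_sum += A_j
            B_sum += B_j
        P = server.sigma_inv - A_sum @ B_sum
        P = 0.5 * (P + P.T)
        server.P = P
        return wss, ytilde, alpha_new, b_new, P

    for it in range(1, max_iter + 1):
        wss, ytilde, alpha_new, b_new, P = one_pass(alpha, b, tau)
        # (8) AI-REML tau update at the server
        if fit_tau:
            tau_new = glmm.aireml_tau_step(
                P, server.V, ytilde, tau, prev_delta=prev_delta
            )
            prev_delta = tau_new - tau
        else:
            tau_new = tau
        delta = max(
            np.max(np.abs(alpha_new - alpha)),
            np.max(np.abs(b_new - b)),
            abs(tau_new - tau),
        )
        for s in sites:
            t.log("server", s.site_id, "alpha", (p,), False, "pql")
            t.log("server", s.site_id, "b", (n,), False, "pql")
            t.log("server", s.site_id, "tau", (), False, "pql")
        alpha, b, tau = alpha_new, b_new, tau_new
        trace.append(float(delta))
        server.diagnostics.append({"iter": it, "delta": float(delta), "tau": tau})
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"federated PQL did not converge in {it} iterations")
    # refresh scoring quantities at the final parameters (as the pooled fit does)
    wss, ytilde, _, _, P = one_pass(alpha, b, tau, final=True)
    server.alpha, server.tau, server.b = alpha, tau, b
    factors = SigmaFactors(sigma_inv=server.sigma_inv, v_sigma_inv=server.v_sigma_inv)
    factors.P = P
    working = WorkingState(
        eta=np.concatenate([ws.eta for ws in wss]),
        pi=np.concatenate([ws.pi for ws in wss]),
        nu=np.concatenate([ws.nu for ws in wss]),
        w=np.concatenate([ws.w for ws in wss]),
        ytilde=ytilde,
        psi=np.concatenate([ws.psi for ws in wss]),
    )
    return NullModel(
        alpha=alpha, tau=tau, b=b, converged=converged, n_iter=it,
        loglik_trace=trace, working=working, factors=factors,
    )


def fit_null_federated(
    sites: list[SiteData],
    server: ServerState,
    opts: FitOptions | None = None,
    quantize: bool = False,
    assume_block_diagonal: bool = False,
) -> NullModel:
    """Run Stage 1 (Newton) then Stage 2 (PQL) across the sites."""
    opts = opts or FitOptions()
    init = algorithm1_fed_newton(
        sites, server, tol=opts.newton_tol, max_iter=opts.newton_max_iter
    )
    return algorithm2_fed_pql(
        sites,
        server,
        tol=opts.tol,
        max_iter=opts.max_iter,
        fix_tau=opts.fix_tau,
        quantize=quantize,
        assume_block_diagonal=assume_block_diagonal,
        alpha0=init.alpha,
    )


# ---------------------------------------------------------------------------
# Stage 3: federated score test
# ---------------------------------------------------------------------------


def fed_allele_stats(
    sites: list[SiteData],
    server: ServerState,
    maf_threshold: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Pooled allele frequencies via secure sums of per-site totals.

    Secure-sums (dosage sum, non-missing count) per variant, applies the
    MAF filter, and returns the mean-imputed per-site blocks.
    """
    t = server.transcript
    sums, counts = [], []
    for s in sites:
        G = np.atleast_2d(np.asarray(s.G, dtype=float))
        sums.append(np.nansum(G, axis=1))
        counts.append(np.sum(~np.isnan(G), axis=1).astype(float))
    total = round_robin_secure_sum(
        sums, server.backend, keys=server.keys, transcript=t,
        kind="af-dosage-sum", stage="score",
    )
    count = round_robin_secure_sum(
        counts, server.backend, keys=server.keys, transcript=t,
        kind="af-count", stage="score",
    )
    af = np.divide(
        total, 2.0 * count, out=np.full_like(total, np.nan), where=count > 0
    )
    with np.errstate(invalid="ignore"):
        keep = np.minimum(af, 1.0 - af) >= maf_threshold
    keep &= count > 0
    imputed = []
    for s in sites:
        G = np.atleast_2d(np.asarray(s.G, dtype=float)).copy()
        miss = np.isnan(G)
        if miss.any():
            fill = np.broadcast_to((2.0 * af)[:, None], G.shape)
            G[miss] = fill[miss]
        imputed.append(G)
    return af, keep, imputed


def algorithm3_fed_score(
    sites: list[SiteData],
    server: ServerState,
    null_model: NullModel,
    chunk_k: int = 200,
    maf_threshold: float | None = 0.01,
    quantize_gtp: bool = False,
    snp_ids: list[str] | None = None,
    var_floor: float = glmm.VAR_FLOOR,
) -> list[ScoreRow]:
    """Federated per-variant score test (Stage 3).

    The server distributes the row partitions P_(j) and (P Ytilde)_(j)
    once.  Per chunk the sites secure-sum G_j (P Ytilde)_(j) into T,
    EADP-aggregate the G'P column partitions, and secure-sum
    (G'P)_(j) G_j' into the k x k variance matrix whose diagonal is
    var(T).  p-values are chi-squared with 1 df.
    """
    plan = _plan(sites)
    t = server.transcript
    P = null_model.P
    ytilde = null_model.ytilde
    Py = P @ ytilde
    # one-time distribution of P and P*Ytilde partitions
    P_parts, Py_parts = [], []
    for j, s in enumerate(sites):
        lo, hi = plan.row_ranges[j]
        P_parts.append(P[lo:hi, :])
        Py_parts.append(Py[lo:hi])
        t.log("server", s.site_id, "P_part", (s.n, plan.total_n), False, "score")
        t.log("server", s.site_id, "PYtilde_part", (s.n,), False, "score")

    if maf_threshold is not None:
        af, keep, blocks = fed_allele_stats(sites, server, maf_threshold)
    else:
        blocks = [np.atleast_2d(np.asarray(s.G, dtype=float)) for s in sites]
        af_sum = sum(np.nansum(b, axis=1) for b in blocks)
        af_cnt = sum(np.sum(~np.isnan(b), axis=1) for b in blocks)
        af = af_sum / (2.0 * af_cnt)
        keep = np.ones(blocks[0].shape[0], dtype=bool)
    m = blocks[0].shape[0]
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(m)]
    kept_idx = np.flatnonzero(keep)
    rows: list[ScoreRow] = []
    for start in range(0, len(kept_idx), chunk_k):
        idx = kept_idx[start : start + chunk_k]
        if idx.size == 0:
            server.diagnostics.append({"stage": "score", "empty_chunk_at": int(start)})
            continue
        Gj = [blocks[j][idx] for j in range(plan.J)]  # k x n_j each
        T = round_robin_secure_sum(
            [Gj[j] @ Py_parts[j] for j in range(plan.J)],
            server.backend, keys=server.keys, transcript=t, kind="T", stage="score",
        )
        # G'P (k x n): EADP over the transposed shares, partitioned by columns
        shares = [(Gj[j] @ P_parts[j]).T for j in range(plan.J)]  # n x k
        res = eadp(
            shares, plan, backend=server.backend, keys=server.keys,
            rng=server.rng, transcript=t, kind="GtP", stage="score",
        )
        GtP_parts = [part.T for part in res.partitions]  # k x n_j column blocks
        if quantize_gtp:
            GtP_parts = [quantize_matrix(p_, 32) for p_ in GtP_parts]
        GtPG = round_robin_secure_sum(
            [GtP_parts[j] @ Gj[j].T for j in range(plan.J)],
            server.backend, keys=server.keys, transcript=t, kind="GtPG", stage="score",
        )
        var = np.diag(GtPG)
        chunk_ids = [snp_ids[i] for i in idx]
        rows.extend(
            score_rows_from_stats(
                T, var, chunk_ids, af=af[idx], n_used=plan.total_n,
                var_floor=var_floor,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# transcript audit
# ---------------------------------------------------------------------------


def audit_transcript(transcript: Transcript) -> list[str]:
    """Check the privacy surface of a protocol run.

    Returns a list of violations: any raw site matrix (X_j, y_j, G_j) sent
    anywhere, or any unprotected server-received message whose kind is not
    in the enumerated aggregate-level plaintext set.
    """
    allowed_unprotected = SERVER_PLAINTEXT_ALLOWED
    violations = []
    for msg in transcript.messages:
        if msg.kind in RAW_KINDS:
            violations.append(f"raw matrix {msg.kind} sent to {msg.receiver}")
        if msg.receiver == "server" and not msg.protected:
            if msg.kind not in allowed_unprotected:
                violations.append(
                    f"unprotected server-received message of kind {msg.kind}"
                )
    return violations
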