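"""First-order reaction-norm sire model: REML fitting and sire BLUPs.

The model for a corrected daughter yield y recorded in a standardised
environment E is

    y = mu + b*E + (s0_j + s1_j*E) + (d0_ij + d1_ij*E) + e,

with correlated random sire intercept/slope (s0, s1) per sire j,
correlated random daughter intercept/slope (d0, d1) per daughter ij
nested in sires, and residual variance heterogeneous over 10 classes of
equal size formed from the environment values.  Because environments are
centred, the sire intercept BLUP estimates general production (GP,
performance in the average environment) and the slope BLUP estimates
environmental sensitivity (ES); genetic variance in the slope is
genotype-by-environment interaction.

Two fitting modes are provided:

``heterogeneous_slope_daughter``
    the full model above (observed-scale analyses);
``homogeneous_intercept_daughter``
    daughter effect reduced to an intercept and a single residual
    variance (used on log-transformed yields, where the full model is
    poorly conditioned).

The restricted likelihood is evaluated exactly but cheaply by absorbing
the daughter effects (block-diagonal by daughter) and then the sire
effects (block-diagonal by sire) with low-rank updates, so the cost is
linear in the number of records.  Sire effects are i.i.d. across sires
by default; passing a numerator relationship matrix switches to
pedigree-correlated sire effects (used to verify that the i.i.d.
simplification is harmless when daughter groups are large).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConvergenceError, IdentifiabilityError
from .kinship import RelationshipMatrix

MODES = ("heterogeneous_slope_daughter", "homogeneous_intercept_daughter")

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# design preparation
# ---------------------------------------------------------------------------


@dataclass
class _Design:
    """Record arrays sorted by sire then daughter, with index maps."""

    y: np.ndarray
    env: np.ndarray
    cls: np.ndarray  # 0-based residual class per record
    sire_of_record: np.ndarray  # 0..q-1 per record
    daughter_of_record: np.ndarray  # 0..D-1 per record, nested in sire
    sire_of_daughter: np.ndarray  # 0..q-1 per daughter
    sire_ids: np.ndarray
    n_classes: int

    @property
    def n(self):
        return self.y.size

    @property
    def q(self):
        return self.sire_ids.size

    @property
    def n_daughters(self):
        return self.sire_of_daughter.size


def _prepare_design(records: pd.DataFrame, trait: str, n_classes_expected=None) -> _Design:
    required = {"sire_id", "daughter_id", "env", trait}
    missing = required - set(records.columns)
    if missing:
        raise KeyError(f"records table lacks columns {sorted(missing)}")
    df = records.sort_values(["sire_id", "daughter_id"], kind="stable").reset_index(drop=True)
    y = df[trait].to_numpy(dtype=float)
    env = df["env"].to_numpy(dtype=float)
    if "residual_class" in df.columns:
        cls_raw = df["residual_class"].to_numpy()
        classes = np.unique(cls_raw)
        cls = np.searchsorted(classes, cls_raw)
        n_classes = classes.size
    else:
        cls = np.zeros(len(df), dtype=int)
        n_classes = 1
    sire_codes, sire_ids = pd.factorize(df["sire_id"], sort=True)
    daughter_key = df["sire_id"].astype(str) + "\x00" + df["daughter_id"].astype(str)
    daughter_codes, daughter_ids = pd.factorize(daughter_key, sort=True)
    first_row = np.zeros(daughter_ids.size, dtype=int)
    first_row[daughter_codes[::-1]] = np.arange(len(df) - 1, -1, -1)
    sire_of_daughter = sire_codes[first_row]
    return _Design(
        y=y,
        env=env,
        cls=cls,
        sire_of_record=sire_codes,
        daughter_of_record=daughter_codes,
        sire_of_daughter=sire_of_daughter,
        sire_ids=np.asarray(sire_ids),
        n_classes=n_classes,
    )


def _check_identifiability(design: _Design, sire_slope: bool) -> None:
    q = design.q
    if q < 2:
        raise IdentifiabilityError("need at least 2 sires")
    counts = np.bincount(design.sire_of_record, minlength=q)
    if counts.min() < 2:
        bad = design.sire_ids[counts.argmin()]
        raise IdentifiabilityError(f"sire {bad!r} has fewer than 2 records")
    if sire_slope:
        # every sire needs >= 2 distinct environment values for a slope
        order = np.argsort(design.sire_of_record, kind="stable")
        env_sorted = design.env[order]
        sires_sorted = design.sire_of_record[order]
        starts = np.searchsorted(sires_sorted, np.arange(q))
        ends = np.append(starts[1:], design.n)
        for j in range(q):
            seg = env_sorted[starts[j] : ends[j]]
            if np.ptp(seg) == 0.0:
                raise IdentifiabilityError(
                    f"sire {design.sire_ids[j]!r} has records in a single environment; slope not identifiable"
                )


# ---------------------------------------------------------------------------
# parameter packing: log-Cholesky for covariance blocks, log for variances
# ---------------------------------------------------------------------------


@dataclass
class _ParamSpec:
    sire_dim: int  # 1 or 2
    daughter_dim: int  # 1 or 2
    n_classes: int

    @property
    def n_params(self):
        blocks = {1: 1, 2: 3}
        return blocks[self.sire_dim] + blocks[self.daughter_dim] + self.n_classes

    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        i = 0

        def chol(dim):
            nonlocal i
            if dim == 1:
                L = np.array([[np.exp(theta[i])]])
                i += 1
            else:
                L = np.array(
                    [[np.exp(theta[i]), 0.0], [theta[i + 1], np.exp(theta[i + 2])]]
                )
                i += 3
            return L @ L.T

        g_s = chol(self.sire_dim)
        g_d = chol(self.daughter_dim)
        sigma_e2 = np.exp(2.0 * theta[i : i + self.n_classes])
        return g_s, g_d, sigma_e2

    def pack(self, g_s, g_d, sigma_e2):
        def inv_chol(g):
            L = np.linalg.cholesky(np.asarray(g, dtype=float))
            if L.shape[0] == 1:
                return [np.log(L[0, 0])]
            return [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])]

        return np.array(inv_chol(g_s) + inv_chol(g_d) + list(0.5 * np.log(np.asarray(sigma_e2))))


# ---------------------------------------------------------------------------
# restricted log-likelihood
# ---------------------------------------------------------------------------


def _sym_inv_logdet_2x2(a, b, d):
    """Vectorised inverse and log-determinant of [[a, b], [b, d]]."""
    det = a * d - b * b
    return d / det, -b / det, a / det, np.log(det)


def _absorb(design: _Design, g_s, g_d, sigma_e2, relationship=None):
    """Daughter- and sire-absorbed sufficient statistics.

    Returns the pieces needed for the restricted likelihood and BLUPs:
    per-sire 2x2 (or 1x1) information C_j, score t_j, y-quadratic q_j in
    the daughter-absorbed metric D^-1, plus the accumulated
    log-determinant of D and per-sire design dimension handling.
    """
    y, env, cls = design.y, design.env, design.cls
    r_inv = 1.0 / sigma_e2[cls]
    logdet_r = float(np.sum(np.log(sigma_e2[cls])))

    # per-daughter cross-products of B = [1, E, y] in the R^-1 metric
    didx = design.daughter_of_record
    nd = design.n_daughters
    w = r_inv
    s11 = np.bincount(didx, weights=w, minlength=nd)
    s1e = np.bincount(didx, weights=w * env, minlength=nd)
    s1y = np.bincount(didx, weights=w * y, minlength=nd)
    see = np.bincount(didx, weights=w * env * env, minlength=nd)
    sey = np.bincount(didx, weights=w * env * y, minlength=nd)
    syy = np.bincount(didx, weights=w * y * y, minlength=nd)

    kd = g_d.shape[0]
    if kd == 1:
        gd = g_d[0, 0]
        m = 1.0 / gd + s11
        logdet_d = logdet_r + float(np.sum(np.log1p(gd * s11)))
        # corrected cross-products S* = S - u u' / m, u = first row of S
        c = 1.0 / m
        s11c = s11 - c * s11 * s11
        s1ec = s1e - c * s11 * s1e
        s1yc = s1y - c * s11 * s1y
        seec = see - c * s1e * s1e
        seyc = sey - c * s1e * s1y
        syyc = syy - c * s1y * s1y
    else:
        det_gd = g_d[0, 0] * g_d[1, 1] - g_d[0, 1] ** 2
        gi00 = g_d[1, 1] / det_gd
        gi01 = -g_d[0, 1] / det_gd
        gi11 = g_d[0, 0] / det_gd
        m00 = gi00 + s11
        m01 = gi01 + s1e
        m11 = gi11 + see
        k00, k01, k11, logdet_m = _sym_inv_logdet_2x2(m00, m01, m11)
        logdet_d = logdet_r + float(np.sum(np.log(det_gd) + logdet_m))
        # U = W_d' R^-1 B rows: u1 = (s11, s1e, s1y), u2 = (s1e, see, sey)
        # S* = S - U' M^-1 U
        def corr(ua, ub, va, vb):
            return k00 * ua * va + k01 * (ua * vb + ub * va) + k11 * ub * vb

        s11c = s11 - corr(s11, s1e, s11, s1e)
        s1ec = s1e - corr(s11, s1e, s1e, see)
        s1yc = s1y - corr(s11, s1e, s1y, sey)
        seec = see - corr(s1e, see, s1e, see)
        seyc = sey - corr(s1e, see, s1y, sey)
        syyc = syy - corr(s1y, sey, s1y, sey)

    # aggregate daughters to sires
    sidx = design.sire_of_daughter
    q = design.q
    C00 = np.bincount(sidx, weights=s11c, minlength=q)
    C01 = np.bincount(sidx, weights=s1ec, minlength=q)
    C11 = np.bincount(sidx, weights=seec, minlength=q)
    t0 = np.bincount(sidx, weights=s1yc, minlength=q)
    t1 = np.bincount(sidx, weights=seyc, minlength=q)
    qy = np.bincount(sidx, weights=syyc, minlength=q)
    return C00, C01, C11, t0, t1, qy, logdet_d


def reml_loglikelihood(
    design_or_records,
    g_s,
    g_d,
    sigma_e2,
    trait: str = "cy",
    relationship: RelationshipMatrix | None = None,
    _return_solution: bool = False,
):
    """Exact restricted log-likelihood of the reaction-norm sire model.

    ``g_s`` is the 2x2 (or 1x1, intercept-only) sire covariance, ``g_d``
    the daughter covariance block, ``sigma_e2`` the per-class residual
    variances.  Fixed effects are [1, E] and are profiled out in the
    REML sense.  With ``relationship`` given, sire effects are
    correlated across sires by the numerator relationship matrix.
    """
    if isinstance(design_or_records, _Design):
        design = design_or_records
    else:
        design = _prepare_design(design_or_records, trait)
    g_s = np.atleast_2d(np.asarray(g_s, dtype=float))
    g_d = np.atleast_2d(np.asarray(g_d, dtype=float))
    sigma_e2 = np.atleast_1d(np.asarray(sigma_e2, dtype=float))
    if sigma_e2.size != design.n_classes:
        if sigma_e2.size == 1:
            from dataclasses import replace as _dc_replace

            design = _dc_replace(design, cls=np.zeros(design.n, dtype=int), n_classes=1)
        else:
            raise ValueError(
                f"{sigma_e2.size} residual variances for {design.n_classes} residual classes"
            )
    ks = g_s.shape[0]
    n, q = design.n, design.q
    p = 2  # fixed effects: intercept + environment regression

    C00, C01, C11, t0, t1, qy, logdet_d = _absorb(design, g_s, g_d, sigma_e2)

    if relationship is None:
        if ks == 1:
            gs = g_s[0, 0]
            minv = 1.0 / gs + C00
            logdet_s = float(np.sum(np.log1p(gs * C00)))
            k00 = 1.0 / minv
            # X'V^-1X etc.; sire design is [1], fixed design is [1, E]
            # correction subtracts (W'D^-1 X)' K (W'D^-1 X) with W = [1]
            xvx00 = np.sum(C00 - k00 * C00 * C00)
            xvx01 = np.sum(C01 - k00 * C00 * C01)
            xvx11 = np.sum(C11 - k00 * C01 * C01)
            xvy0 = np.sum(t0 - k00 * C00 * t0)
            xvy1 = np.sum(t1 - k00 * C01 * t0)
            yvy = np.sum(qy - k00 * t0 * t0)
        else:
            gi00, gi01, gi11, _ = _sym_inv_logdet_2x2(
                np.array([g_s[0, 0]]), np.array([g_s[0, 1]]), np.array([g_s[1, 1]])
            )
            m00 = gi00[0] + C00
            m01 = gi01[0] + C01
            m11 = gi11[0] + C11
            k00, k01, k11, logdet_m = _sym_inv_logdet_2x2(m00, m01, m11)
            logdet_gs = np.log(g_s[0, 0] * g_s[1, 1] - g_s[0, 1] ** 2)
            logdet_s = float(np.sum(logdet_gs + logdet_m))

            def kq(ua, ub, va, vb):  # u' K v for per-sire 2-vectors
                return k00 * ua * va + k01 * (ua * vb + ub * va) + k11 * ub * vb

            xvx00 = np.sum(C00 - kq(C00, C01, C00, C01))
            xvx01 = np.sum(C01 - kq(C00, C01, C01, C11))
            xvx11 = np.sum(C11 - kq(C01, C11, C01, C11))
            xvy0 = np.sum(t0 - kq(C00, C01, t0, t1))
            xvy1 = np.sum(t1 - kq(C01, C11, t0, t1))
            yvy = np.sum(qy - kq(t0, t1, t0, t1))
        xvx = np.array([[xvx00, xvx01], [xvx01, xvx11]])
        xvy = np.array([xvy0, xvy1])
        sign, logdet_xvx = np.linalg.slogdet(xvx)
        if sign <= 0:
            return -np.inf if not _return_solution else (-np.inf, None, None)
        beta = np.linalg.solve(xvx, xvy)
        rvr = yvy - beta @ xvy
        loglik = -0.5 * ((n - p) * _LOG2PI + logdet_d + logdet_s + logdet_xvx + rvr)
        if not _return_solution:
            return float(loglik)
        # BLUPs: u_j = K_j (t_j - C_j beta)
        r0 = t0 - C00 * beta[0] - C01 * beta[1]
        if ks == 1:
            u0 = (1.0 / (1.0 / g_s[0, 0] + C00)) * r0
            u = np.column_stack([u0])
        else:
            r1 = t1 - C01 * beta[0] - C11 * beta[1]
            u0 = k00 * r0 + k01 * r1
            u1 = k01 * r0 + k11 * r1
            u = np.column_stack([u0, u1])
        return float(loglik), beta, u

    # --- pedigree-correlated sire effects -----------------------------------
    a_vals = relationship.restrict(design.sire_ids).values
    sign_a, logdet_a = np.linalg.slogdet(a_vals)
    if sign_a <= 0:
        raise np.linalg.LinAlgError("relationship matrix is not positive definite")
    a_inv = np.linalg.inv(a_vals)
    gs_inv = np.linalg.inv(g_s)
    m = np.kron(a_inv, gs_inv)
    idx = np.arange(q) * ks
    if ks == 1:
        m[idx, idx] += C00
    else:
        m[idx, idx] += C00
        m[idx, idx + 1] += C01
        m[idx + 1, idx] += C01
        m[idx + 1, idx + 1] += C11
    try:
        cho = np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        return -np.inf if not _return_solution else (-np.inf, None, None)
    logdet_m = 2.0 * float(np.sum(np.log(np.diag(cho))))
    logdet_s = ks * logdet_a + q * np.linalg.slogdet(g_s)[1] + logdet_m

    # stacked Z'D^-1 X (2q x 2) and Z'D^-1 y (2q,)
    if ks == 1:
        P = np.column_stack([C00, C01])
        tz = t0
    else:
        P = np.empty((2 * q, 2))
        P[0::2, 0] = C00
        P[0::2, 1] = C01
        P[1::2, 0] = C01
        P[1::2, 1] = C11
        tz = np.empty(2 * q)
        tz[0::2] = t0
        tz[1::2] = t1
    sol_p = np.linalg.solve(m, P)
    sol_t = np.linalg.solve(m, tz)
    xdx = np.array([[np.sum(C00), np.sum(C01)], [np.sum(C01), np.sum(C11)]])
    xvx = xdx - P.T @ sol_p
    xvy = np.array([np.sum(t0), np.sum(t1)]) - P.T @ sol_t
    yvy = np.sum(qy) - tz @ sol_t
    sign, logdet_xvx = np.linalg.slogdet(xvx)
    if sign <= 0:
        return -np.inf if not _return_solution else (-np.inf, None, None)
    beta = np.linalg.solve(xvx, xvy)
    rvr = yvy - beta @ xvy
    loglik = -0.5 * ((n - p) * _LOG2PI + logdet_d + logdet_s + logdet_xvx + rvr)
    if not _return_solution:
        return float(loglik)
    u_stack = np.linalg.solve(m, tz - P @ beta)
    u = u_stack.reshape(q, ks)
    return float(loglik), beta, u


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class ReactionNormFit:
    """Converged REML components and diagnostics for model fitting."""

    mode: str
    mu: float
    b: float
    sigma_s0_sq: float
    sigma_s0s1: float
    sigma_s1_sq: float
    rho_s0s1: float
    sigma_d0_sq: float
    sigma_d0d1: float
    sigma_d1_sq: float
    rho_d0d1: float
    residual_variances: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_records: int
    n_sires: int
    boundary: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    loglik_trace: list = field(default_factory=list)
    sire_slope: bool = True
    trait: str = "cy"

    def components(self) -> dict:
        return {
            "mu": self.mu,
            "b": self.b,
            "sigma_s0_sq": self.sigma_s0_sq,
            "sigma_s0s1": self.sigma_s0s1,
            "sigma_s1_sq": self.sigma_s1_sq,
            "rho_s0s1": self.rho_s0s1,
            "sigma_d0_sq": self.sigma_d0_sq,
            "sigma_d0d1": self.sigma_d0d1,
            "sigma_d1_sq": self.sigma_d1_sq,
            "rho_d0d1": self.rho_d0d1,
            "residual_variances": list(np.atleast_1d(self.residual_variances)),
            "loglik": self.loglik,
        }

    def covariance_blocks(self):
        ks = 2 if self.sire_slope else 1
        if ks == 2:
            g_s = np.array(
                [[self.sigma_s0_sq, self.sigma_s0s1], [self.sigma_s0s1, self.sigma_s1_sq]]
            )
        else:
            g_s = np.array([[self.sigma_s0_sq]])
        if self.mode == "heterogeneous_slope_daughter":
            g_d = np.array(
                [[self.sigma_d0_sq, self.sigma_d0d1], [self.sigma_d0d1, self.sigma_d1_sq]]
            )
        else:
            g_d = np.array([[self.sigma_d0_sq]])
        return g_s, g_d, np.atleast_1d(self.residual_variances)


def _initial_theta(design: _Design, spec: _ParamSpec) -> np.ndarray:
    y, env = design.y, design.env
    X = np.column_stack([np.ones(design.n), env])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    v = max(float(np.var(r)), 1e-8)
    q = design.q
    means = np.bincount(design.sire_of_record, weights=r, minlength=q) / np.bincount(
        design.sire_of_record, minlength=q
    )
    between = float(np.var(means, ddof=1)) if q > 1 else 0.1 * v
    s0 = min(max(between, 0.02 * v), 0.8 * v)
    s1 = 0.1 * s0
    if spec.sire_dim == 2:
        g_s = np.array([[s0, 0.0], [0.0, s1]])
    else:
        g_s = np.array([[s0]])
    within = max(v - between, 0.1 * v)
    if spec.daughter_dim == 2:
        g_d = np.array([[0.4 * within, 0.0], [0.0, 0.05 * within]])
    else:
        g_d = np.array([[0.4 * within]])
    sigma_e2 = np.full(spec.n_classes, 0.6 * within)
    return spec.pack(g_s, g_d, sigma_e2)


def fit_reaction_norm(
    records: pd.DataFrame,
    mode: str = "heterogeneous_slope_daughter",
    trait: str = "cy",
    relationship: RelationshipMatrix | None = None,
    sire_slope: bool = True,
    compute_se: bool = True,
    max_iter: int = 200,
    tol: float = 1e-10,
):
    """REML fit of the reaction-norm sire model; returns (fit, estimates).

    ``estimates`` is a DataFrame with one row per sire: ``sire_id,
    n_daughters, gp`` (intercept BLUP) and ``es`` (slope BLUP; 0 when
    the model carries no sire slope).  Non-convergence raises
    :class:`ConvergenceError` carrying the best fit found so far.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    design = _prepare_design(records, trait)
    _check_identifiability(design, sire_slope)
    n_classes = design.n_classes if mode == "heterogeneous_slope_daughter" else 1
    if mode == "homogeneous_intercept_daughter":
        design.cls = np.zeros(design.n, dtype=int)
        design.n_classes = 1
    spec = _ParamSpec(
        sire_dim=2 if sire_slope else 1,
        daughter_dim=2 if mode == "heterogeneous_slope_daughter" else 1,
        n_classes=n_classes,
    )

    var_y = max(float(np.var(design.y)), 1e-12)
    floor_var = 1e-10 * var_y
    lo_log = 0.5 * np.log(floor_var)
    hi_log = 0.5 * np.log(1e6 * var_y)

    bounds = []
    for dim in (spec.sire_dim, spec.daughter_dim):
        if dim == 1:
            bounds.append((lo_log, hi_log))
        else:
            bounds += [(lo_log, hi_log), (None, None), (lo_log, hi_log)]
    bounds += [(lo_log, hi_log)] * spec.n_classes

    trace = []
    best = {"theta": None, "loglik": -np.inf}

    def objective(theta):
        g_s, g_d, sigma_e2 = spec.unpack(theta)
        ll = reml_loglikelihood(design, g_s, g_d, sigma_e2, relationship=relationship)
        if np.isfinite(ll) and ll > best["loglik"]:
            best["loglik"] = ll
            best["theta"] = np.array(theta)
            trace.append(ll)
        return -ll if np.isfinite(ll) else 1e300

    theta0 = _initial_theta(design, spec)
    lbfgs_options = {"maxiter": max_iter, "ftol": tol, "gtol": 1e-6, "maxfun": 100 * max_iter}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            objective, theta0, method="L-BFGS-B", jac="3-point", bounds=bounds,
            options=lbfgs_options,
        )
        n_iter = int(res.nit)
        # one restart from the best point: quasi-Newton with numerical
        # gradients can stall on this surface; a fresh Hessian fixes it
        res2 = optimize.minimize(
            objective, best["theta"] if best["theta"] is not None else theta0,
            method="L-BFGS-B", jac="3-point", bounds=bounds, options=lbfgs_options,
        )
        n_iter += int(res2.nit)
        converged = bool(res.success or res2.success)
        if not converged:
            # derivative-free fallback
            res3 = optimize.minimize(
                objective,
                best["theta"] if best["theta"] is not None else theta0,
                method="Nelder-Mead",
                options={"maxiter": 400 * spec.n_params, "fatol": 1e-8, "xatol": 1e-8},
            )
            n_iter += int(res3.nit)
            converged = bool(res3.success) or (
                best["loglik"] > -np.inf and abs(res3.fun + best["loglik"]) < 1e-6
            )

    if best["theta"] is None:
        raise ConvergenceError("REML objective never evaluated to a finite value")

    fit = _assemble_fit(design, spec, best["theta"], mode, sire_slope, relationship,
                        best["loglik"], n_iter, converged, trace, floor_var, trait,
                        compute_se=compute_se)
    estimates = _blup_table(design, spec, best["theta"], relationship)
    if not converged:
        raise ConvergenceError(
            f"REML did not converge within {max_iter} iterations", best_fit=(fit, estimates)
        )
    return fit, estimates


def _assemble_fit(design, spec, theta, mode, sire_slope, relationship, loglik, n_iter,
                  converged, trace, floor_var, trait, compute_se=True):
    g_s, g_d, sigma_e2 = spec.unpack(theta)
    boundary = {}
    if g_s[0, 0] <= 10 * floor_var:
        boundary["sigma_s0_sq"] = True
    if spec.sire_dim == 2 and g_s[1, 1] <= 10 * floor_var:
        boundary["sigma_s1_sq"] = True
    if spec.daughter_dim == 2 and g_d[1, 1] <= 10 * floor_var:
        boundary["sigma_d1_sq"] = True

    def zeroed(value, key):
        return 0.0 if boundary.get(key) else float(value)

    s0 = zeroed(g_s[0, 0], "sigma_s0_sq")
    if spec.sire_dim == 2:
        s1 = zeroed(g_s[1, 1], "sigma_s1_sq")
        s01 = float(g_s[0, 1]) if not (boundary.get("sigma_s0_sq") or boundary.get("sigma_s1_sq")) else 0.0
        rho_s = s01 / np.sqrt(s0 * s1) if s0 > 0 and s1 > 0 else np.nan
    else:
        s1, s01, rho_s = 0.0, 0.0, np.nan
    d0 = float(g_d[0, 0])
    if spec.daughter_dim == 2:
        d1 = zeroed(g_d[1, 1], "sigma_d1_sq")
        d01 = float(g_d[0, 1]) if not boundary.get("sigma_d1_sq") else 0.0
        rho_d = d01 / np.sqrt(d0 * d1) if d0 > 0 and d1 > 0 else np.nan
    else:
        d1, d01, rho_d = 0.0, 0.0, np.nan

    ll, beta, _ = reml_loglikelihood(
        design, g_s, g_d, sigma_e2, relationship=relationship, _return_solution=True
    )
    se = {}
    if compute_se:
        se = _component_se(design, spec, theta, relationship)
    return ReactionNormFit(
        mode=mode,
        mu=float(beta[0]),
        b=float(beta[1]),
        sigma_s0_sq=s0,
        sigma_s0s1=s01,
        sigma_s1_sq=s1,
        rho_s0s1=float(rho_s),
        sigma_d0_sq=d0,
        sigma_d0d1=d01,
        sigma_d1_sq=d1,
        rho_d0d1=float(rho_d),
        residual_variances=sigma_e2,
        loglik=float(loglik),
        n_iter=n_iter,
        converged=converged,
        n_records=design.n,
        n_sires=design.q,
        boundary=boundary,
        se=se,
        loglik_trace=trace,
        sire_slope=sire_slope,
        trait=trait,
    )


def _blup_table(design, spec, theta, relationship):
    g_s, g_d, sigma_e2 = spec.unpack(theta)
    _, _, u = reml_loglikelihood(
        design, g_s, g_d, sigma_e2, relationship=relationship, _return_solution=True
    )
    counts = np.bincount(design.sire_of_record, minlength=design.q)
    # daughters per sire
    nd = np.bincount(design.sire_of_daughter, minlength=design.q)
    return pd.DataFrame(
        {
            "sire_id": design.sire_ids,
            "n_daughters": nd,
            "n_records": counts,
            "gp": u[:, 0],
            "es": u[:, 1] if spec.sire_dim == 2 else np.zeros(design.q),
        }
    )


def predict_sire_effects(fit: ReactionNormFit, records: pd.DataFrame,
                         relationship: RelationshipMatrix | None = None) -> pd.DataFrame:
    """BLUP sire intercept (GP) and slope (ES) at the fitted components."""
    design = _prepare_design(records, fit.trait)
    if fit.mode == "homogeneous_intercept_daughter":
        design.cls = np.zeros(design.n, dtype=int)
        design.n_classes = 1
    spec = _ParamSpec(
        sire_dim=2 if fit.sire_slope else 1,
        daughter_dim=2 if fit.mode == "heterogeneous_slope_daughter" else 1,
        n_classes=1 if fit.mode == "homogeneous_intercept_daughter" else design.n_classes,
    )
    g_s, g_d, sigma_e2 = fit.covariance_blocks()
    # guard against exact zeros reported at the boundary
    g_s = g_s + np.eye(g_s.shape[0]) * 1e-12 * max(np.trace(g_s), 1.0)
    theta = spec.pack(g_s, np.atleast_2d(g_d) + np.eye(g_d.shape[0]) * 1e-12, sigma_e2)
    return _blup_table(design, spec, theta, relationship)


# ---------------------------------------------------------------------------
# standard errors by numerical observed information
# ---------------------------------------------------------------------------


def _component_se(design, spec, theta, relationship):
    """Delta-method SEs of (sigma_s0_sq, sigma_s1_sq, rho) from the REML Hessian.

    The Hessian is approximated by central differences on the working
    (log-Cholesky) scale and pseudo-inverted, which tolerates the flat
    ridge that single-record-per-daughter designs leave between the
    daughter intercept variance and the residual levels.
    """
    k = spec.n_params

    def nll(th):
        g_s, g_d, sigma_e2 = spec.unpack(th)
        ll = reml_loglikelihood(design, g_s, g_d, sigma_e2, relationship=relationship)
        return -ll if np.isfinite(ll) else 1e300

    h = 1e-4
    hess = np.zeros((k, k))
    f0 = nll(theta)
    shifts = np.eye(k) * h
    fp = np.array([nll(theta + shifts[i]) for i in range(k)])
    fm = np.array([nll(theta - shifts[i]) for i in range(k)])
    for i in range(k):
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
        for j in range(i + 1, k):
            fpp = nll(theta + shifts[i] + shifts[j])
            fmm = nll(theta - shifts[i] - shifts[j])
            hess[i, j] = hess[j, i] = (fpp - fp[i] - fp[j] + f0 + fmm - fm[i] - fm[j] + f0) / (
                2 * h**2
            )
    cov_theta = np.linalg.pinv(hess, rcond=1e-10, hermitian=True)

    def phi(th):
        g_s, _, _ = spec.unpack(th)
        if spec.sire_dim == 2:
            rho = g_s[0, 1] / np.sqrt(g_s[0, 0] * g_s[1, 1])
            return np.array([g_s[0, 0], g_s[1, 1], rho])
        return np.array([g_s[0, 0]])

    hj = 1e-6
    base = phi(theta)
    jac = np.zeros((base.size, k))
    for i in range(k):
        jac[:, i] = (phi(theta + shifts[i] * (hj / h)) - phi(theta - shifts[i] * (hj / h))) / (2 * hj)
    cov_phi = jac @ cov_theta @ jac.T
    variances = np.clip(np.diag(cov_phi), 0.0, None)
    names = ["sigma_s0_sq", "sigma_s1_sq", "rho_s0s1"][: base.size]
    return dict(zip(names, np.sqrt(variances)))


def slope_variance_lrt(records: pd.DataFrame, mode: str = "homogeneous_intercept_daughter",
                       trait: str = "cy", full: "ReactionNormFit | None" = None) -> dict:
    """REML likelihood-ratio test of the sire slope variance against zero.

    Compares the model with a sire intercept+slope block to the nested
    intercept-only model.  Because (sigma_s1_sq, sigma_s0s1) vanish on
    the boundary of the parameter space, the LRT statistic is referred
    to a 0.5*chi2_1 + 0.5*chi2_2 mixture (conservative variant of the
    boundary mixture for one variance plus one free covariance).

    ``full`` may pass an already-fitted slope model to avoid refitting.
    Returns a dict with the two log-likelihoods, the statistic and p.
    """
    from scipy.stats import chi2

    if full is None:
        full, _ = _fit_quiet(records, mode, trait, sire_slope=True)
    null, _ = _fit_quiet(records, mode, trait, sire_slope=False)
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = 0.5 * chi2.sf(stat, 1) + 0.5 * chi2.sf(stat, 2)
    return {
        "loglik_full": full.loglik,
        "loglik_null": null.loglik,
        "statistic": stat,
        "p_value": float(p),
        "boundary": bool(full.boundary.get("sigma_s1_sq", False)),
        "sigma_s1_sq": full.sigma_s1_sq,
    }


def _fit_quiet(records, mode, trait, sire_slope):
    """Fit, accepting a best-so-far state if the optimiser stalls."""
    try:
        return fit_reaction_norm(
            records, mode=mode, trait=trait, sire_slope=sire_slope, compute_se=False
        )
    except ConvergenceError as err:
        if err.best_fit is not None:
            return err.best_fit
        raise
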