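"""Independent naive dense-matrix oracles used only by the tests.

These build the full n x n covariance matrix V and evaluate the textbook
REML expressions directly; they share no code with the package's
absorption-based likelihood, so agreement is a genuine cross-check.
"""

import numpy as np
import pandas as pd

_LOG2PI = np.log(2.0 * np.pi)


def dense_design(records: pd.DataFrame, trait="cy", sire_slope=True, daughter_slope=True):
    df = records.sort_values(["sire_id", "daughter_id"], kind="stable").reset_index(drop=True)
    y = df[trait].to_numpy(float)
    env = df["env"].to_numpy(float)
    n = len(df)
    X = np.column_stack([np.ones(n), env])

    sires = sorted(df["sire_id"].astype(str).unique())
    ks = 2 if sire_slope else 1
    Zs = np.zeros((n, ks * len(sires)))
    for i, (sid, e) in enumerate(zip(df["sire_id"].astype(str), env)):
        j = sires.index(sid)
        Zs[i, ks * j] = 1.0
        if sire_slope:
            Zs[i, ks * j + 1] = e

    daughters = list(dict.fromkeys(zip(df["sire_id"].astype(str), df["daughter_id"].astype(str))))
    kd = 2 if daughter_slope else 1
    Zd = np.zeros((n, kd * len(daughters)))
    dindex = {d: i for i, d in enumerate(daughters)}
    for i, (sid, did, e) in enumerate(zip(df["sire_id"].astype(str), df["daughter_id"].astype(str), env)):
        d = dindex[(sid, did)]
        Zd[i, kd * d] = 1.0
        if daughter_slope:
            Zd[i, kd * d + 1] = e

    if "residual_class" in df.columns:
        cls_raw = df["residual_class"].to_numpy()
        classes = np.unique(cls_raw)
        cls = np.searchsorted(classes, cls_raw)
    else:
        cls = np.zeros(n, dtype=int)
    return y, X, Zs, Zd, cls, sires, daughters


def dense_reml(records, g_s, g_d, sigma_e2, trait="cy", a_matrix=None,
               homogeneous_residual=False):
    """REML log-likelihood, GLS fixed effects and BLUPs via dense algebra."""
    g_s = np.atleast_2d(np.asarray(g_s, float))
    g_d = np.atleast_2d(np.asarray(g_d, float))
    sigma_e2 = np.atleast_1d(np.asarray(sigma_e2, float))
    y, X, Zs, Zd, cls, sires, daughters = dense_design(
        records, trait, sire_slope=g_s.shape[0] == 2, daughter_slope=g_d.shape[0] == 2
    )
    n, p = X.shape
    q = len(sires)
    if homogeneous_residual:
        cls = np.zeros(n, dtype=int)
    R = np.diag(sigma_e2[cls])
    if a_matrix is None:
        Gs_full = np.kron(np.eye(q), g_s)
    else:
        Gs_full = np.kron(a_matrix, g_s)
    Gd_full = np.kron(np.eye(len(daughters)), g_d)
    V = Zs @ Gs_full @ Zs.T + Zd @ Gd_full @ Zd.T + R
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    XtViX = XtVi @ X
    beta = np.linalg.solve(XtViX, XtVi @ y)
    r = y - X @ beta
    quad = r @ Vi @ r
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    loglik = -0.5 * ((n - p) * _LOG2PI + ld_v + ld_x + quad)
    u = Gs_full @ Zs.T @ Vi @ r
    return float(loglik), beta, u.reshape(q, g_s.shape[0]), sires


def dense_gls_snp(y, x, a_matrix, gamma_grid=None):
    """Grid-search REML for the one-SNP mixed model, fully dense.

    Maximises the restricted likelihood of y = mu + x b + u + e with
    u ~ N(0, A sg2), e ~ N(0, I se2) over a dense grid of the variance
    ratio, returning (b, se, p, loglik).
    """
    from scipy import stats

    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = y.size
    X = np.column_stack([np.ones(n), x])
    p = 2

    def evaluate(gamma):
        V = gamma * a_matrix + np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        rss = r @ Vi @ r
        sigma_e2 = rss / (n - p)
        _, ld_v = np.linalg.slogdet(V)
        _, ld_x = np.linalg.slogdet(XtViX)
        ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma_e2) + 1) + ld_v + ld_x)
        cov = sigma_e2 * np.linalg.inv(XtViX)
        return ll, beta[1], np.sqrt(cov[1, 1])

    # zooming grid search over log(gamma) in the same [-16, 16] domain the
    # implementation searches, plus the gamma = 0 boundary
    log_grid = np.linspace(-16.0, 16.0, 161) if gamma_grid is None else np.log(gamma_grid)
    best = None
    for _ in range(5):
        for lg in log_grid:
            ll, b, se = evaluate(np.exp(lg))
            if best is None or ll > best[0]:
                best = (ll, b, se, lg)
        step = log_grid[1] - log_grid[0]
        log_grid = np.clip(np.linspace(best[3] - step, best[3] + step, 41), -16.0, 16.0)
    ll0, b0, se0 = evaluate(0.0)
    if ll0 >= best[0]:
        best = (ll0, b0, se0, -np.inf)
    ll, b, se, lg = best
    gamma = float(np.exp(lg)) if np.isfinite(lg) else 0.0
    z = b / se
    return {
        "beta": float(b),
        "se": float(se),
        "p": float(2 * stats.norm.sf(abs(z))),
        "loglik": float(ll),
        "gamma": float(gamma),
    }


def bh_adjust(pvals):
    """Benjamini-Hochberg adjusted p-values, written independently."""
    pvals = np.asarray(pvals, float)
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
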