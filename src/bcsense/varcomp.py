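"""REML estimation of crossed random-effects variance components.

Camera and visual BCS data are modelled as

    y = mu * 1 + sum_i Z_i u_i + e,      u_i ~ N(0, sigma_i^2 I),

with one random term per element of the method's sampling structure: weeks
(W), days within week (D), milkings within day (M), animals (A), camera
units (C) or scorers (S), all their admissible interactions, and a
residual.  The camera model carries 15 non-residual terms, the visual model
6 (W, A, S, WA, WS, AS).  The fixed part is an intercept only.

Estimation is restricted maximum likelihood via safeguarded
average-information (AI) iterations with EM fallback steps: every iteration
is guaranteed not to decrease the restricted log-likelihood (step halving),
components are constrained to sigma^2 >= 0 with an active set so boundary
estimates are reported as exact zeros, and the whole procedure is
deterministic.  Terms whose realized levels each contain at most one
observation are aliased with the residual (their Z Z' is the identity on
the data) and are constrained to zero up front; see :func:`check_aliasing`.

The likelihood is evaluated in observation space: V = sum_i sigma_i^2 B_i
+ sigma_eps^2 I with B_i the level-match indicator of term i, assembled
from precomputed index arrays, followed by one Cholesky factorisation per
evaluation.  This is exact REML, practical for herd-scale designs (a few
thousand records).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .records import CAMERA, VISUAL, observation_times

RESIDUAL = "eps"

#: non-residual model terms per method, in the canonical order
CAMERA_TERMS = (
    "W", "A", "C", "WD", "WA", "WC", "AC", "WDM",
    "WDA", "WDC", "WAC", "WDMA", "WDMC", "WDAC", "WDMAC",
)
VISUAL_TERMS = ("W", "A", "S", "WA", "WS", "AS")

#: factor letter -> record-frame column
_FACTOR_COLUMNS = {
    "W": "week",
    "D": "day_in_week",
    "M": "milking",
    "A": "animal_id",
    "C": "device_id",
    "S": "device_id",
}


class SingularModelError(ValueError):
    """Raised when aliased terms make the requested model unidentifiable."""


class ConvergenceError(RuntimeError):
    """Raised when REML fails to converge within the iteration budget."""


@dataclass(frozen=True)
class ModelTerm:
    """One random term: a name and the factor letters it crosses."""

    name: str
    factors: tuple[str, ...]

    @classmethod
    def from_name(cls, name: str) -> "ModelTerm":
        if name == RESIDUAL:
            return cls(name=RESIDUAL, factors=())
        bad = [f for f in name if f not in _FACTOR_COLUMNS]
        if bad:
            raise ValueError(f"unknown factor letter(s) {bad} in term {name!r}")
        return cls(name=name, factors=tuple(name))

    def level_codes(self, records: pd.DataFrame) -> np.ndarray:
        """Compact integer code of each record's level of this term."""
        if not self.factors:  # residual: one level per observation
            return np.arange(len(records))
        cols = [records[_FACTOR_COLUMNS[f]].to_numpy() for f in self.factors]
        key = pd.MultiIndex.from_arrays(cols)
        return key.factorize(sort=True)[0]


def build_model_terms(method: str) -> list[ModelTerm]:
    """The random terms of one method's model, residual last."""
    if method == CAMERA:
        names = CAMERA_TERMS
    elif method == VISUAL:
        names = VISUAL_TERMS
    else:
        raise ValueError(f"unknown method {method!r}")
    return [ModelTerm.from_name(n) for n in names] + [ModelTerm.from_name(RESIDUAL)]


@dataclass(frozen=True)
class AliasingReport:
    """Identifiability diagnosis of a term set on realized data."""

    aliased_with_residual: tuple[str, ...]
    single_level: tuple[str, ...]
    duplicate_of: dict[str, str]  # term -> earlier term with identical partition

    @property
    def constrained(self) -> tuple[str, ...]:
        """All terms that must be held at zero for a well-posed fit."""
        return tuple(
            dict.fromkeys(
                list(self.aliased_with_residual)
                + list(self.single_level)
                + list(self.duplicate_of)
            )
        )


def check_aliasing(terms: list[ModelTerm], records: pd.DataFrame) -> AliasingReport:
    """Detect terms that are not separable on the realized design.

    A term whose realized levels each hold at most one observation has
    Z Z' = I and is aliased with the residual (e.g. the full five-way camera
    interaction when there is one pass per cow-milking).  A term with a
    single realized level is confounded with the intercept.  Two terms
    inducing the same partition of the observations are mutually aliased;
    the later one in model order is reported as a duplicate.
    """
    aliased, single, duplicate = [], [], {}
    partitions: dict[str, np.ndarray] = {}
    n = len(records)
    for term in terms:
        if term.name == RESIDUAL:
            continue
        codes = term.level_codes(records)
        n_levels = codes.max() + 1 if n else 0
        if n_levels <= 1:
            single.append(term.name)
            continue
        if n_levels == n:  # every level a singleton => identity partition
            aliased.append(term.name)
            continue
        for prev_name, prev_codes in partitions.items():
            if _same_partition(codes, prev_codes):
                duplicate[term.name] = prev_name
                break
        else:
            partitions[term.name] = codes
    return AliasingReport(
        aliased_with_residual=tuple(aliased),
        single_level=tuple(single),
        duplicate_of=duplicate,
    )


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    la, lb = a.max() + 1, b.max() + 1
    if la != lb:
        return False
    return len(np.unique(a.astype(np.int64) * lb + b)) == la


@dataclass
class VarianceComponents:
    """REML estimates for one method's model."""

    method: str | None
    estimates: dict[str, float]  # term -> sigma^2, residual under "eps"
    iterations: int
    loglik: float
    converged: bool
    constrained: tuple[str, ...] = ()
    loglik_trace: tuple[float, ...] = field(default_factory=tuple)

    def as_series(self) -> pd.Series:
        return pd.Series(self.estimates, name="sigma2")


# ---------------------------------------------------------------------------
# REML machinery


class _Workspace:
    """Precomputed index structures for one data set + term list.

    All dense matrices are handled in lower-triangular storage: LAPACK's
    Cholesky/inverse routines never touch the upper triangle, and every
    level-match indicator B_t has unit diagonal, so tr(M B_t) =
    tr(M) + 2 * sum of M over the strictly-lower same-level pairs.
    """

    def __init__(self, y: np.ndarray, x: np.ndarray, term_codes: dict[str, np.ndarray]):
        self.y = y
        self.x = x  # fixed-effects design matrix, full column rank
        self.n = y.size
        self.names = list(term_codes)  # free non-residual terms, model order
        self.codes = term_codes
        self.n_levels = {t: c.max() + 1 for t, c in term_codes.items()}
        dtype = np.int32 if self.n * self.n < 2**31 else np.int64
        self.flat_low: dict[str, np.ndarray] = {}
        for t, c in term_codes.items():
            self.flat_low[t] = self._lower_pair_indices(c).astype(dtype)

    def _lower_pair_indices(self, codes: np.ndarray) -> np.ndarray:
        """Flat indices row*n + col (row > col) of same-level pairs."""
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
        groups = np.split(order, boundaries)
        chunks = []
        n = self.n
        for g in groups:
            if g.size < 2:
                continue
            g64 = np.sort(g.astype(np.int64))
            r = np.repeat(g64, np.arange(g64.size))  # each member paired with all smaller
            c_idx = np.concatenate([g64[:i] for i in range(1, g64.size)])
            chunks.append(r * n + c_idx)
        return np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)

    def build_v_lower(self, sigma2: dict[str, float], eps: float) -> np.ndarray:
        """Lower triangle of V (upper left as zeros, ignored downstream)."""
        v = np.zeros(self.n * self.n)
        for t in self.names:
            s = sigma2[t]
            if s != 0.0:
                v[self.flat_low[t]] += s
        v = v.reshape(self.n, self.n)
        total = eps + sum(sigma2[t] for t in self.names)
        v[np.diag_indices(self.n)] = total
        return v

    def a_dot(self, t: str, x: np.ndarray) -> np.ndarray:
        """B_t @ x via group sums."""
        c = self.codes[t]
        return np.bincount(c, weights=x, minlength=self.n_levels[t])[c]

    def quad(self, t: str, x: np.ndarray) -> float:
        """x' B_t x = sum over levels of (group sum)^2."""
        c = self.codes[t]
        s = np.bincount(c, weights=x, minlength=self.n_levels[t])
        return float(s @ s)

    def trace_product(self, t: str, m_low_flat: np.ndarray, m_trace: float) -> float:
        """tr(M B_t) for symmetric M given by its lower triangle (raveled)."""
        return m_trace + 2.0 * float(m_low_flat[self.flat_low[t]].sum())


def _restricted_loglik(ws: _Workspace, sigma2, eps):
    """Return (loglik, context) or (None, None) if V is not SPD."""
    n = ws.n
    x = ws.x
    p = x.shape[1]
    v = ws.build_v_lower(sigma2, eps)
    chol, info = linalg.lapack.dpotrf(v, lower=1, overwrite_a=1)
    if info != 0:
        return None, None
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(chol))))
    rhs = np.column_stack([ws.y, x])
    sol = linalg.cho_solve((chol, True), rhs, check_finite=False)
    vi_y, g = sol[:, 0], sol[:, 1:]  # g = V^-1 X
    xvx = x.T @ g
    sign, logdet_xvx = np.linalg.slogdet(xvx)
    if sign <= 0:
        return None, None
    xvx_chol = linalg.cho_factor(xvx, check_finite=False)
    beta = linalg.cho_solve(xvx_chol, x.T @ vi_y, check_finite=False)
    py = vi_y - g @ beta  # P y = V^-1 (y - X beta)
    quad_form = float(ws.y @ py)  # r' V^-1 r
    loglik = -0.5 * (logdet_v + logdet_xvx + quad_form) - 0.5 * (n - p) * np.log(2 * np.pi)
    ctx = {"chol": chol, "g": g, "xvx_chol": xvx_chol, "py": py}
    return loglik, ctx


def _traces(ws: _Workspace, ctx, params):
    """tr(P B_t) and y' P B_t P y for each parameter (residual included)."""
    chol, g, xvx_chol, py = ctx["chol"], ctx["g"], ctx["xvx_chol"], ctx["py"]
    vinv, info = linalg.lapack.dpotri(chol, lower=1)
    if info != 0:
        raise ConvergenceError(f"dpotri failed with info={info}")
    vinv_trace = float(np.trace(vinv))
    vinv_flat = vinv.ravel()

    tr_p, quads, u_cols = {}, {}, {}
    for t in params:
        if t == RESIDUAL:
            tr_vi_a = vinv_trace
            ag = g
            quads[t] = float(py @ py)
            u_cols[t] = py
        else:
            tr_vi_a = ws.trace_product(t, vinv_flat, vinv_trace)
            ag = np.column_stack([ws.a_dot(t, g[:, j]) for j in range(g.shape[1])])
            quads[t] = ws.quad(t, py)
            u_cols[t] = ws.a_dot(t, py)
        # tr(P B) = tr(V^-1 B) - tr((X'V^-1X)^-1 X'V^-1 B V^-1 X)
        c = g.T @ ag
        tr_p[t] = tr_vi_a - float(np.trace(linalg.cho_solve(xvx_chol, c, check_finite=False)))
    return tr_p, quads, u_cols


def _gradient_and_ai(ws: _Workspace, ctx, free: list[str], eps_free: bool):
    """Score vector and average-information matrix for the free parameters."""
    chol, g, xvx_chol = ctx["chol"], ctx["g"], ctx["xvx_chol"]
    params = list(free) + ([RESIDUAL] if eps_free else [])
    tr_p, quads, u_cols = _traces(ws, ctx, params)
    grad = np.array([-0.5 * (tr_p[t] - quads[t]) for t in params])

    u = np.column_stack([u_cols[t] for t in params])
    vi_u = linalg.cho_solve((chol, True), u, check_finite=False)
    p_u = vi_u - g @ linalg.cho_solve(xvx_chol, g.T @ u, check_finite=False)
    ai = 0.5 * (u.T @ p_u)
    return params, grad, ai


def _em_step(ws: _Workspace, ctx, sigma2, eps, free, eps_free):
    """EM update: always feasible (>= 0), monotone, slow near the optimum."""
    params = list(free) + ([RESIDUAL] if eps_free else [])
    tr_p, quads, _ = _traces(ws, ctx, params)
    new_sigma2 = dict(sigma2)
    for t in free:
        q = ws.n_levels[t]
        s = sigma2[t]
        new_sigma2[t] = max(0.0, s + (s * s / q) * (quads[t] - tr_p[t]))
    new_eps = eps
    if eps_free:
        new_eps = max(
            1e-12, eps + (eps * eps / ws.n) * (quads[RESIDUAL] - tr_p[RESIDUAL])
        )
    return new_sigma2, new_eps


def reml_variance_components(
    records: pd.DataFrame,
    terms: list[ModelTerm] | None = None,
    method: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    drop_aliased: bool = True,
    n_em_steps: int = 1,
    fixed_trend: bool = False,
) -> VarianceComponents:
    """Fit the crossed random-effects model by REML.

    ``terms`` defaults to :func:`build_model_terms` for the frame's method
    (which must then be unique).  Terms flagged by :func:`check_aliasing`
    are constrained to zero when ``drop_aliased`` is true, otherwise their
    presence raises :class:`SingularModelError`.  Convergence is declared
    when the relative change in restricted log-likelihood falls below
    ``tol``; iterations never decrease the restricted likelihood.

    The fixed part is an intercept; with ``fixed_trend=True`` a linear
    time covariate (months from study start) is added, appropriate when the
    data carry a systematic body-condition trend that would otherwise be
    absorbed by the week variance.
    """
    if method is None:
        methods = records["method"].unique()
        if len(methods) != 1:
            raise ValueError("records mix methods; pass `method` or split first")
        method = str(methods[0])
    if terms is None:
        terms = build_model_terms(method)
    if terms[-1].name != RESIDUAL:
        raise ValueError("residual term must be present and last")

    report = check_aliasing(terms, records)
    if report.constrained and not drop_aliased:
        raise SingularModelError(
            "aliased terms present: " + ", ".join(report.constrained)
        )

    free_terms = [
        t.name for t in terms
        if t.name != RESIDUAL and t.name not in report.constrained
    ]
    y = records["value"].to_numpy(dtype=float)
    n = y.size
    if n < len(free_terms) + 2:
        raise ValueError(f"too few observations ({n}) for {len(free_terms)} terms")
    if fixed_trend:
        t_months = observation_times(records) / 30.44
        x = np.column_stack([np.ones(n), t_months - t_months.mean()])
    else:
        x = np.ones((n, 1))
    ws = _Workspace(
        y, x, {t: ModelTerm.from_name(t).level_codes(records) for t in free_terms}
    )

    var_y = float(np.var(y, ddof=1))
    if var_y <= 0:
        # degenerate constant response: all components zero
        est = {t.name: 0.0 for t in terms}
        est[RESIDUAL] = 0.0
        return VarianceComponents(method, est, 0, 0.0, True, report.constrained)

    sigma2, eps = _starting_values(records, free_terms, var_y)

    loglik, ctx = _restricted_loglik(ws, sigma2, eps)
    if loglik is None:
        raise ConvergenceError("initial covariance matrix not positive definite")
    trace = [loglik]

    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        if iteration <= n_em_steps:
            cand_sigma2, cand_eps = _em_step(ws, ctx, sigma2, eps, free_terms, True)
            new_loglik, new_ctx = _restricted_loglik(ws, cand_sigma2, cand_eps)
            if new_loglik is None or new_loglik < loglik - 1e-10:
                new_loglik, new_ctx = loglik, ctx  # keep current point
                cand_sigma2, cand_eps = sigma2, eps
        else:
            cand_sigma2, cand_eps, new_loglik, new_ctx = _ai_update(
                ws, ctx, sigma2, eps, free_terms, loglik
            )
        delta = new_loglik - loglik
        sigma2, eps, loglik, ctx = cand_sigma2, cand_eps, new_loglik, new_ctx
        trace.append(loglik)
        if iteration > n_em_steps and abs(delta) < tol * (abs(loglik) + 1.0):
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations "
            f"(last loglik {loglik:.6f}, method {method})"
        )

    estimates = {t.name: 0.0 for t in terms if t.name != RESIDUAL}
    estimates.update({t: float(s) for t, s in sigma2.items()})
    estimates[RESIDUAL] = float(eps)
    return VarianceComponents(
        method=method,
        estimates=estimates,
        iterations=iteration,
        loglik=float(loglik),
        converged=True,
        constrained=report.constrained,
        loglik_trace=tuple(trace),
    )


def _starting_values(
    records: pd.DataFrame, free_terms: list[str], var_y: float
) -> tuple[dict[str, float], float]:
    """Moment-flavoured starting values.

    Rough between-group variances of (detrended) animal and week means seed
    W, A and WA; the mean within-finest-cell variance seeds the residual;
    every other term starts at a small positive fraction of the total
    variance.  Only the iteration count depends on these, not the optimum.
    """
    floor = 1e-4 * var_y
    small = 0.02 * var_y
    df = records
    m_aw = df.groupby(["animal_id", "week"])["value"].mean().reset_index()
    t = m_aw["week"].to_numpy(dtype=float)
    y = m_aw["value"].to_numpy()
    if np.unique(t).size > 1:
        slope, intercept = np.polyfit(t, y, 1)
        m_aw["r"] = y - (intercept + slope * t)
    else:
        m_aw["r"] = y - y.mean()

    w_var = float(m_aw.groupby("week")["r"].mean().var(ddof=1)) if m_aw["week"].nunique() > 1 else small
    a_var = float(m_aw.groupby("animal_id")["r"].mean().var(ddof=1)) if m_aw["animal_id"].nunique() > 1 else small
    cw_var = float(m_aw["r"].var(ddof=1))

    fine_key = ["animal_id", "week"]
    if df["day_in_week"].nunique() > 1:
        fine_key.append("day_in_week")
    within = df.groupby(fine_key)["value"].var(ddof=1).dropna()
    eps0 = float(within.mean()) if len(within) else 0.5 * var_y
    eps0 = max(eps0, floor)

    starts: dict[str, float] = {}
    for term in free_terms:
        if term == "W":
            starts[term] = max(w_var, floor)
        elif term == "A":
            starts[term] = max(a_var, floor)
        elif term == "WA":
            starts[term] = max(cw_var - w_var - a_var, small)
        else:
            starts[term] = small
    return starts, eps0


def _ai_update(ws, ctx, sigma2, eps, free_terms, loglik):
    """One safeguarded AI step (active set on the sigma^2 >= 0 boundary)."""
    params, grad, ai = _gradient_and_ai(ws, ctx, free_terms, eps_free=True)
    # active set: parameters pinned at 0 whose gradient points outward stay put
    current = np.array([sigma2[t] if t != RESIDUAL else eps for t in params])
    active = (current <= 0.0) & (grad <= 0.0)
    live = ~active

    step = np.zeros(len(params))
    if live.any():
        try:
            step[live] = linalg.solve(
                ai[np.ix_(live, live)], grad[live], assume_a="pos"
            )
        except linalg.LinAlgError:
            step[live] = grad[live] / np.maximum(np.diag(ai)[live], 1e-12)

    scale = 1.0
    for _ in range(30):
        cand = np.maximum(current + scale * step, 0.0)
        cand_sigma2 = {
            t: float(v) for t, v in zip(params, cand) if t != RESIDUAL
        }
        cand_eps = float(cand[params.index(RESIDUAL)])
        cand_eps = max(cand_eps, 1e-12)
        new_loglik, new_ctx = _restricted_loglik(ws, cand_sigma2, cand_eps)
        if new_loglik is not None and new_loglik >= loglik - 1e-10:
            return cand_sigma2, cand_eps, new_loglik, new_ctx
        scale *= 0.5
    # no uphill AI step found: fall back to a (monotone) EM step
    cand_sigma2, cand_eps = _em_step(ws, ctx, sigma2, eps, free_terms, True)
    new_loglik, new_ctx = _restricted_loglik(ws, cand_sigma2, cand_eps)
    if new_loglik is None or new_loglik < loglik - 1e-10:
        return dict(sigma2), eps, loglik, ctx
    return cand_sigma2, cand_eps, new_loglik, new_ctx


def moment_estimates(records: pd.DataFrame) -> dict[str, float]:
    """Quick method-of-moments estimates for camera-style data.

    Returns ``W`` and ``A`` (variance of detrended week and animal means of
    the cow-by-week means) and ``obs`` — the observation-level error
    variance from paired same-day, same-camera milking differences.  ``obs``
    estimates the residual *plus* any component aliased with it.  Intended
    as an independent, assumption-light check of the generator and the REML
    fit at large design scale, not as a substitute for REML.
    """
    df = records.copy()
    means = (
        df.groupby(["animal_id", "week"])["value"].mean().reset_index(name="m")
    )
    t = (means["week"].to_numpy(dtype=float) - 1.0) * 7.0 / 30.44  # months
    slope, intercept = np.polyfit(t, means["m"].to_numpy(), 1)
    means["r"] = means["m"].to_numpy() - (intercept + slope * t)

    week_means = means.groupby("week")["r"].mean()
    animal_means = means.groupby("animal_id")["r"].mean()
    out = {
        "W": float(week_means.var(ddof=1)),
        "A": float(animal_means.var(ddof=1)),
    }

    # same-day milking pairs that used the same device
    key = ["week", "day_in_week", "animal_id"]
    am = df[df["milking"] == "AM"][key + ["device_id", "value"]]
    pm = df[df["milking"] == "PM"][key + ["device_id", "value"]]
    pairs = am.merge(pm, on=key, suffixes=("_am", "_pm"))
    pairs = pairs[pairs["device_id_am"] == pairs["device_id_pm"]]
    diffs = (pairs["value_am"] - pairs["value_pm"]).to_numpy()
    out["obs"] = float(np.var(diffs, ddof=1) / 2.0) if diffs.size >= 2 else float("nan")
    return out
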