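"""Proportional-hazards engine with a shared plot-level random effect.

The hazard for tree *i* in plot *z(i)* is modelled as

    h_i(t) = h0(t) * exp(x_i' beta + b_{z(i)})

where the baseline h0(t) is left unspecified (Cox partial likelihood) and
the plot effects b are log-normal frailties, b ~ N(0, theta).  Fixed effects
and frailties are estimated jointly by Newton–Raphson on the penalized
partial likelihood

    PPL(beta, b) = pl(beta, b) - b'b / (2 theta)

and the frailty variance theta is chosen by maximising the Laplace
approximation to the marginal likelihood,

    lm(theta) = PPL(beta^, b^) - (1/2) log det(theta * H_bb + I)

with H_bb the frailty block of the observed information.  As theta -> 0
this collapses to the ordinary partial likelihood, so theta = 0 (no plot
effect) is handled as a boundary case rather than a failure.

Ties are handled by the Efron correction by default (census data produce
heavily tied event times); Breslow is available behind a flag.  Records may
carry delayed entry (``start`` < ``time``), which supports the
counting-process representation with time-varying covariates.

AIC is −2·loglik + 2·k with k the number of fixed-effect terms, plus one
for theta when it is estimated (the marginal Laplace log-likelihood is used
in that case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "HazardFit",
    "CoxFrailtyHazard",
    "cox_partial_loglik",
    "fit_cox",
    "model_ladder",
    "table1_specs",
    "stepwise_aic",
    "vif",
    "fit_by_mode",
    "lr_tests",
    "ConvergenceError",
]

TREE_TERMS = ("rel_growth", "D", "D2")
SPECIES_TERMS = ("max_d", "mean_growth", "wood_density", "wda")


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# partial likelihood machinery


def _risk_sums(times, et_desc, w, wX, X, order):
    """Sums of w, w*x, w*xx' over subjects with ``times >= t`` per threshold.

    ``et_desc`` are the distinct event times in descending order.  Returns
    (S0, S1, S2) arrays indexed like ``et_desc``; higher orders are None
    when not requested.
    """
    d = len(et_desc)
    m = X.shape[1]
    o = np.argsort(-times, kind="stable")
    ts = times[o]
    cnt = np.searchsorted(-ts, -et_desc, side="right")
    c0 = np.concatenate([[0.0], np.cumsum(w[o])])
    S0 = c0[cnt]
    S1 = S2 = None
    if order >= 1 and m:
        c1 = np.vstack([np.zeros(m), np.cumsum(wX[o], axis=0)])
        S1 = c1[cnt]
    elif order >= 1:
        S1 = np.zeros((d, 0))
    if order >= 2:
        S2 = np.empty((d, m, m))
        acc = np.zeros((m, m))
        prev = 0
        Ew = X[o] * np.sqrt(w[o])[:, None]
        for k in range(d):
            c = cnt[k]
            if c > prev:
                seg = Ew[prev:c]
                acc = acc + seg.T @ seg
                prev = c
            S2[k] = acc
    return S0, S1, S2


def _partial_quantities(X, start, stop, event, eta, ties="efron", order=2):
    """Partial log-likelihood and, optionally, gradient and information."""
    event = event.astype(bool)
    n, m = X.shape
    if not event.any():
        z = np.zeros(m)
        return 0.0, (z if order >= 1 else None), (np.zeros((m, m)) if order >= 2 else None)
    eta = eta - eta[event].mean()  # shift-invariant; guards exp overflow
    w = np.exp(eta)
    wX = w[:, None] * X if m else np.zeros((n, 0))
    et = np.unique(stop[event])[::-1]
    d = len(et)

    S0, S1, S2 = _risk_sums(stop, et, w, wX, X, order)
    if start is not None and np.any(start >= et.min()):
        B0, B1, B2 = _risk_sums(start, et, w, wX, X, order)
        S0 = S0 - B0
        if order >= 1:
            S1 = S1 - B1
        if order >= 2:
            S2 = S2 - B2

    # per-event-time death sums
    ke = np.searchsorted(-et, -stop[event])
    dk = np.bincount(ke, minlength=d).astype(float)
    Sd0 = np.bincount(ke, weights=w[event], minlength=d)
    sum_eta_d = np.bincount(ke, weights=eta[event], minlength=d)
    if m:
        Sd1 = np.zeros((d, m))
        np.add.at(Sd1, ke, wX[event])
    else:
        Sd1 = np.zeros((d, 0))
    if order >= 2:
        Sd2 = np.zeros((d, m, m))
        Ewd = X[event] * np.sqrt(w[event])[:, None]
        oe = np.argsort(ke, kind="stable")
        bounds = np.searchsorted(ke[oe], np.arange(d + 1))
        for k in range(d):
            lo, hi = bounds[k], bounds[k + 1]
            if hi > lo:
                seg = Ewd[oe[lo:hi]]
                Sd2[k] = seg.T @ seg

    ll = 0.0
    grad = np.zeros(m) if order >= 1 else None
    info = np.zeros((m, m)) if order >= 2 else None
    if order >= 1 and m:
        grad += X[event].sum(axis=0)
    for k in range(d):
        dkk = int(dk[k])
        if ties == "efron" and dkk > 1:
            frac = np.arange(dkk) / dkk
        else:
            frac = np.zeros(dkk)
        D0 = S0[k] - frac * Sd0[k]
        if np.any(D0 <= 0):
            raise FloatingPointError("non-positive risk-set mass; check data ordering")
        ll += sum_eta_d[k] - np.log(D0).sum()
        if order >= 1 and m:
            c1 = float((1.0 / D0).sum())
            c2 = float((frac / D0).sum())
            grad -= S1[k] * c1 - Sd1[k] * c2
            if order >= 2:
                V = (S1[k][None, :] - frac[:, None] * Sd1[k][None, :]) / D0[:, None]
                info += c1 * S2[k] - c2 * Sd2[k] - V.T @ V
    return ll, grad, info


def cox_partial_loglik(
    X,
    time,
    event,
    beta=None,
    start=None,
    offset=None,
    ties: str = "efron",
) -> float:
    """Cox partial log-likelihood at ``beta`` (frailty values enter via offset).

    ``X`` may have zero columns (null model); with no events the result is
    0.0 with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    beta = np.zeros(X.shape[1]) if beta is None else np.asarray(beta, dtype=float)
    eta = X @ beta
    if offset is not None:
        eta = eta + np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(eta)):
        bad = int(np.flatnonzero(~np.isfinite(eta))[0])
        raise FloatingPointError(f"non-finite linear predictor at record {bad}")
    if not event.astype(bool).any():
        warnings.warn("all records censored; partial log-likelihood is 0", stacklevel=2)
        return 0.0
    start = None if start is None else np.asarray(start, dtype=float)
    ll, _, _ = _partial_quantities(X, start, time, event, eta, ties=ties, order=0)
    return float(ll)


def _newton(
    X, start, stop, event, penalty=None, beta0=None, ties="efron",
    max_iter=50, tol=1e-9,
):
    """Maximize pl(beta) - 0.5 beta' diag(penalty) beta by damped Newton."""
    n, m = X.shape
    beta = np.zeros(m) if beta0 is None else beta0.copy()
    pen = np.zeros(m) if penalty is None else np.asarray(penalty, dtype=float)

    def objective(b):
        ll, g, H = _partial_quantities(X, start, stop, event, X @ b, ties=ties, order=2)
        return ll - 0.5 * float(b @ (pen * b)), (None if g is None else g - pen * b), \
            (None if H is None else H + np.diag(pen))

    ll, g, H = objective(beta)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        scale = 1.0
        for _ in range(25):  # step halving on overshoot
            cand = beta + scale * step
            try:
                ll_new, g_new, H_new = objective(cand)
            except FloatingPointError:
                ll_new = -np.inf
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        delta = ll_new - ll
        beta, ll, g, H = cand, ll_new, g_new, H_new
        if abs(delta) < tol * (abs(ll) + 1.0):
            converged = True
            break
    return beta, ll, g, H, converged, n_iter


# ---------------------------------------------------------------------------
# model specification and fit container


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the risk model (the Table-1-style model ladder rows)."""

    tree_terms: tuple = TREE_TERMS
    species_terms: tuple = SPECIES_TERMS
    frailty: bool = True
    ties: str = "efron"
    description: str = ""

    def __post_init__(self):
        if "D2" in self.tree_terms and "D" not in self.tree_terms:
            raise ValueError("the quadratic size term requires the linear term")
        if self.ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")

    @property
    def terms(self) -> tuple:
        return tuple(self.tree_terms) + tuple(self.species_terms)

    def drop(self, term: str) -> "ModelSpec":
        return replace(
            self,
            tree_terms=tuple(t for t in self.tree_terms if t != term),
            species_terms=tuple(t for t in self.species_terms if t != term),
            description="",
        )

    def add(self, term: str) -> "ModelSpec":
        if term in TREE_TERMS:
            return replace(self, tree_terms=tuple(self.tree_terms) + (term,), description="")
        return replace(self, species_terms=tuple(self.species_terms) + (term,), description="")


@dataclass(frozen=True)
class HazardFit:
    terms: tuple
    coef: np.ndarray
    se: np.ndarray
    chi2: np.ndarray
    loglik: float  # partial log-likelihood at the solution
    aic: float
    theta: float  # frailty variance (0 when off)
    marginal_loglik: float | None
    frailty: pd.Series | None  # estimated log-frailty per cluster
    n: int
    n_events: int
    converged: bool
    n_iter: int
    spec: ModelSpec | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "chi2": self.chi2,
                "p": chi2_dist.sf(self.chi2, 1),
            },
            index=list(self.terms),
        )


# ---------------------------------------------------------------------------
# estimator


class CoxFrailtyHazard(BaseEstimator):
    """Cox proportional-hazards model with an optional shared log-normal frailty.

    scikit-learn-style estimator: ``fit(X, y, cluster=...)`` where ``X`` holds
    the covariate columns (DataFrame or array), ``y`` is a 2-column array or
    DataFrame of ``(time, event)`` (an optional third column / ``start``
    column gives delayed entry), and ``cluster`` labels the shared-frailty
    groups (plots).  After fitting: ``coef_``, ``se_``, ``chi2_``,
    ``loglik_``, ``aic_``, ``theta_``, ``frailty_``, ``converged_``.

    Parameters
    ----------
    frailty : include the cluster random effect (requires ``cluster``).
    theta : fix the frailty variance instead of profiling it.
    ties : 'efron' (default; census data are heavily tied) or 'breslow'.
    """

    def __init__(
        self,
        frailty: bool = True,
        theta: float | None = None,
        ties: str = "efron",
        max_iter: int = 50,
        tol: float = 1e-9,
        theta_bounds: tuple = (1e-4, 20.0),
    ):
        self.frailty = frailty
        self.theta = theta
        self.ties = ties
        self.max_iter = max_iter
        self.tol = tol
        self.theta_bounds = theta_bounds

    # -- internals ---------------------------------------------------------

    def _validate(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.coef_names_ = list(X.columns)
            Xv = X.values.astype(float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.ndim == 1:
                Xv = Xv[:, None]
            self.coef_names_ = [f"x{i}" for i in range(Xv.shape[1])]
        if isinstance(y, pd.DataFrame):
            time = y["time"].values.astype(float)
            event = y["event"].values.astype(int)
            start = y["start"].values.astype(float) if "start" in y else None
        else:
            ya = np.asarray(y, dtype=float)
            time, event = ya[:, 0], ya[:, 1].astype(int)
            start = ya[:, 2] if ya.shape[1] > 2 else None
        if not np.all(np.isfinite(Xv)):
            bad = int(np.flatnonzero(~np.isfinite(Xv).all(axis=1))[0])
            raise FloatingPointError(f"non-finite covariate at record {bad}")
        if np.any(time <= (0.0 if start is None else start)):
            raise ValueError("require time > start (and > 0)")
        zero_var = [
            self.coef_names_[j]
            for j in range(Xv.shape[1])
            if np.ptp(Xv[:, j]) == 0
        ]
        if zero_var:
            raise ValueError(f"zero-variance term(s): {zero_var}")
        self._x_sd = Xv.std(axis=0) if Xv.shape[1] else np.zeros(0)
        return Xv, time, event, start

    def fit(self, X, y, cluster=None):
        Xv, time, event, start = self._validate(X, y)
        n, p = Xv.shape
        if event.sum() < 1:
            warnings.warn("no events; returning null fit with loglik 0", stacklevel=2)
            self._set_null(p, n)
            return self
        use_frailty = self.frailty and cluster is not None
        if self.frailty and cluster is None:
            warnings.warn("frailty requested but no cluster given; fitting without", stacklevel=2)

        if not use_frailty:
            beta, ll, g, H, conv, it = _newton(
                Xv, start, time, event, ties=self.ties,
                max_iter=self.max_iter, tol=self.tol,
            )
            cov = np.linalg.pinv(H) if p else np.zeros((0, 0))
            self._store(beta, cov, ll, None, 0.0, None, n, int(event.sum()), conv, it, p)
            return self

        codes, uniques = pd.factorize(np.asarray(cluster))
        q = len(uniques)
        Z = np.zeros((n, q))
        Z[np.arange(n), codes] = 1.0
        XZ = np.hstack([Xv, Z])

        warm = {"bb": None}

        def inner(theta):
            pen = np.concatenate([np.zeros(p), np.full(q, 1.0 / theta)])
            bb, ll_pen, g, H, conv, it = _newton(
                XZ, start, time, event, penalty=pen, ties=self.ties,
                beta0=warm["bb"], max_iter=self.max_iter, tol=self.tol,
            )
            warm["bb"] = bb
            # H is penalized information; the unpenalized bb block:
            H_bb = H[p:, p:] - np.diag(np.full(q, 1.0 / theta))
            sign, logdet = np.linalg.slogdet(theta * H_bb + np.eye(q))
            lm = ll_pen - 0.5 * logdet
            return lm, bb, H, conv, it

        if self.theta is not None and self.theta > 0:
            theta = float(self.theta)
            lm, bb, H, conv, it = inner(theta)
        elif self.theta == 0:
            theta = 0.0
        else:
            lo, hi = self.theta_bounds
            res = minimize_scalar(
                lambda lt: -inner(np.exp(lt))[0],
                bounds=(np.log(lo), np.log(hi)),
                method="bounded",
                options={"xatol": 0.02},
            )
            theta = float(np.exp(res.x))
            lm_best = -res.fun
            # boundary check: no-frailty partial likelihood is the theta->0 limit
            beta0, ll0, *_ = _newton(
                Xv, start, time, event, ties=self.ties,
                max_iter=self.max_iter, tol=self.tol,
            )
            if ll0 >= lm_best - 1e-8 or theta <= lo * 1.05:
                theta = 0.0
            else:
                lm, bb, H, conv, it = inner(theta)

        if theta == 0.0:
            beta, ll, g, H, conv, it = _newton(
                Xv, start, time, event, ties=self.ties,
                max_iter=self.max_iter, tol=self.tol,
            )
            cov = np.linalg.pinv(H) if p else np.zeros((0, 0))
            # theta was still *estimated* (at the boundary): count it in k
            self._store(beta, cov, ll, float(ll), 0.0,
                        pd.Series(np.zeros(q), index=list(uniques)),
                        n, int(event.sum()), conv, it, p, theta_estimated=self.theta is None)
            return self

        beta, b = bb[:p], bb[p:]
        cov_full = np.linalg.pinv(H)
        cov = cov_full[:p, :p]
        ll = float(
            _partial_quantities(XZ, start, time, event, XZ @ bb, ties=self.ties, order=0)[0]
        )
        self._store(
            beta, cov, ll, float(lm), theta,
            pd.Series(b, index=list(uniques)), n, int(event.sum()), conv, it, p,
            theta_estimated=self.theta is None,
        )
        return self

    def _store(self, beta, cov, ll, lm, theta, frailty, n, n_events, conv, it, p,
               theta_estimated=False):
        self.coef_ = np.asarray(beta)
        self.se_ = np.sqrt(np.clip(np.diag(cov), 0, None)) if p else np.zeros(0)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.chi2_ = np.where(self.se_ > 0, (self.coef_ / self.se_) ** 2, np.inf)
        self.loglik_ = float(ll)
        self.marginal_loglik_ = lm
        self.theta_ = float(theta)
        self.frailty_ = frailty
        k = p + (1 if theta_estimated else 0)
        base = lm if (theta > 0 or theta_estimated) and lm is not None else ll
        self.aic_ = -2.0 * base + 2.0 * k
        self.n_ = n
        self.n_events_ = n_events
        self.converged_ = bool(conv)
        self.n_iter_ = int(it)
        # per-SD effect > 15 means a hazard ratio above e^15 across one SD of
        # the covariate: a monotone-likelihood signature, not a real effect
        x_sd = getattr(self, "_x_sd", np.ones(p))
        self.separation_flag_ = bool(p and np.any(np.abs(self.coef_) * x_sd > 15))
        if self.separation_flag_:
            warnings.warn(
                "very large coefficient(s): possible monotone likelihood "
                "(perfect separation)",
                stacklevel=3,
            )
        if not conv:
            warnings.warn(
                f"Newton–Raphson did not converge in {self.n_iter_} iterations",
                stacklevel=3,
            )

    def _set_null(self, p, n):
        self.coef_ = np.zeros(p)
        self.se_ = np.full(p, np.nan)
        self.chi2_ = np.full(p, np.nan)
        self.loglik_ = 0.0
        self.marginal_loglik_ = None
        self.theta_ = 0.0
        self.frailty_ = None
        self.aic_ = 2.0 * p
        self.n_ = n
        self.n_events_ = 0
        self.converged_ = True
        self.n_iter_ = 0

    def predict(self, X):
        """Log relative hazard x' beta for new covariate rows."""
        Xv = X.values.astype(float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return Xv @ self.coef_

    def predict_partial_hazard(self, X):
        return np.exp(self.predict(X))

    def result(self, spec: ModelSpec | None = None) -> HazardFit:
        return HazardFit(
            terms=tuple(self.coef_names_),
            coef=self.coef_,
            se=self.se_,
            chi2=self.chi2_,
            loglik=self.loglik_,
            aic=self.aic_,
            theta=self.theta_,
            marginal_loglik=self.marginal_loglik_,
            frailty=self.frailty_,
            n=self.n_,
            n_events=self.n_events_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            spec=spec,
        )


# ---------------------------------------------------------------------------
# record-level wrappers


def _design(records: pd.DataFrame, spec: ModelSpec):
    terms = list(spec.terms)
    missing = [t for t in terms if t not in records.columns]
    if missing:
        raise KeyError(f"records lack term column(s): {missing}")
    X = records[terms] if terms else pd.DataFrame(index=records.index)
    ycols = ["time", "event"] + (["start"] if "start" in records.columns else [])
    y = records[ycols]
    cluster = records["plot_id"].values if "plot_id" in records.columns else None
    return X, y, cluster


def fit_cox(records: pd.DataFrame, spec: ModelSpec, theta: float | None = None) -> HazardFit:
    """Fit one model specification on an assembled record set."""
    X, y, cluster = _design(records, spec)
    if not spec.terms:
        # null model: loglik from risk-set sizes only
        ll = cox_partial_loglik(
            np.zeros((len(records), 0)),
            y["time"].values,
            y["event"].values,
            start=y["start"].values if "start" in y else None,
            ties=spec.ties,
        )
        return HazardFit(
            terms=(), coef=np.zeros(0), se=np.zeros(0), chi2=np.zeros(0),
            loglik=ll, aic=-2.0 * ll, theta=0.0, marginal_loglik=None,
            frailty=None, n=len(records), n_events=int(y["event"].sum()),
            converged=True, n_iter=0, spec=spec,
        )
    est = CoxFrailtyHazard(frailty=spec.frailty, ties=spec.ties, theta=theta)
    est.fit(X, y, cluster=cluster if spec.frailty else None)
    return est.result(spec)


def model_ladder(records: pd.DataFrame, specs: Sequence[ModelSpec]) -> pd.DataFrame:
    """Fit every spec on the same record set and rank by AIC (ΔAIC ascending)."""
    rows = []
    for spec in specs:
        desc = spec.description or " + ".join(spec.terms) or "Null model"
        try:
            fit = fit_cox(records, spec)
            rows.append(
                {
                    "description": desc, "terms": spec.terms, "aic": fit.aic,
                    "loglik": fit.loglik, "theta": fit.theta, "k": len(spec.terms),
                    "converged": fit.converged, "failed": False,
                }
            )
        except Exception as exc:  # failed fits keep their ladder row
            rows.append(
                {
                    "description": desc, "terms": spec.terms, "aic": np.nan,
                    "loglik": np.nan, "theta": np.nan, "k": len(spec.terms),
                    "converged": False, "failed": True, "error": str(exc),
                }
            )
    out = pd.DataFrame(rows)
    best = out["aic"].min()
    out["delta_aic"] = out["aic"] - best
    return out.sort_values("delta_aic", na_position="last").reset_index(drop=True)


def table1_specs(frailty: bool = True) -> list[ModelSpec]:
    """The standard model-comparison ladder (full model, drop-one rows, null)."""
    T, S = TREE_TERMS, SPECIES_TERMS
    mk = lambda t, s, d: ModelSpec(tree_terms=t, species_terms=s, frailty=frailty, description=d)
    return [
        mk(T, S, "Full model"),
        mk(T, ("max_d", "mean_growth", "wood_density"), "Excluding WDA"),
        mk(("rel_growth", "D"), S, "Linear relationship with size"),
        mk(T, ("max_d", "mean_growth", "wda"), "Excluding WD"),
        mk(("rel_growth",), S, "Excluding stem size"),
        mk(("D", "D2"), S, "Excluding stem relative growth"),
        mk((), S, "Species-level risk factors only"),
        mk(T, ("mean_growth", "wood_density", "wda"), "Excluding species max size"),
        mk(T, ("max_d", "wood_density", "wda"), "Excluding species mean growth"),
        mk((), ("mean_growth",), "Species mean growth only"),
        mk(T, (), "Tree-level risk factors only"),
        mk(("rel_growth",), (), "Relative growth only"),
        mk((), (), "Null model"),
    ]


def stepwise_aic(
    records: pd.DataFrame,
    full: ModelSpec,
    refit_frailty: bool = True,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Bidirectional stepwise AIC search from the full model.

    Single-term additions and removals respect the D/D² hierarchy; the
    search stops at a local AIC minimum.  With ``refit_frailty=False`` the
    frailty variance is profiled once on the full model and held fixed for
    candidate fits (fast approximation).
    """
    theta_fixed = None
    if full.frailty and not refit_frailty:
        theta_fixed = fit_cox(records, full).theta

    def aic_of(spec):
        return fit_cox(records, spec, theta=theta_fixed).aic

    current = full
    current_aic = aic_of(current)
    universe = set(full.terms)
    trace = [{"step": 0, "action": "start", "terms": current.terms, "aic": current_aic}]
    step = 0
    while True:
        step += 1
        candidates = []
        for t in current.terms:  # removals (D only removable once D2 is out)
            if t == "D" and "D2" in current.terms:
                continue
            candidates.append(("drop", t, current.drop(t)))
        for t in universe - set(current.terms):  # additions (D2 needs D)
            if t == "D2" and "D" not in current.terms:
                continue
            candidates.append(("add", t, current.add(t)))
        best = None
        for action, term, spec in candidates:
            a = aic_of(spec)
            trace.append({"step": step, "action": f"{action} {term}", "terms": spec.terms, "aic": a})
            if best is None or a < best[0]:
                best = (a, spec)
        if best is None or best[0] >= current_aic - 1e-9:
            break
        current_aic, current = best
    trace_df = pd.DataFrame(trace)
    return replace(current, description="Selected model"), trace_df


def vif(records: pd.DataFrame, terms: Sequence[str]) -> pd.Series:
    """Variance inflation factors; exact collinearity reported as inf."""
    terms = list(terms)
    if len(terms) < 2:
        raise ValueError("need at least two terms for VIF")
    X = records[terms].values.astype(float)
    if X.shape[0] <= len(terms):
        raise ValueError("need more records than terms")
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    import statsmodels.api as sm

    Xc = sm.add_constant(X)
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j in range(len(terms)):
            try:
                v = variance_inflation_factor(Xc, j + 1)
            except Exception:
                v = np.inf
            out.append(np.inf if not np.isfinite(v) else float(v))
    return pd.Series(out, index=terms, name="vif")


def fit_by_mode(records: pd.DataFrame, spec: ModelSpec) -> dict:
    """Independent fits per mode of death.

    For each target mode, deaths of the other mode — and unassessed deaths —
    are treated as censored at their death time.  Modes with no events are
    skipped with a report entry.
    """
    out = {}
    for mode in ("standing", "broken_uprooted"):
        sub = records.copy()
        sub["event"] = ((sub["event"] == 1) & (sub["death_mode"] == mode)).astype(int)
        if sub["event"].sum() < 1:
            out[mode] = f"skipped: no {mode} events"
            continue
        out[mode] = fit_cox(sub, spec)
    return out


def lr_tests(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Per-term likelihood-ratio chi-square by drop-one refits (Wald's companion)."""
    full = fit_cox(records, spec)
    base = full.marginal_loglik if full.theta > 0 else full.loglik
    rows = []
    for i, t in enumerate(spec.terms):
        if t == "D" and "D2" in spec.terms:
            reduced_spec = spec.drop("D2").drop("D")
            k = 2
        else:
            reduced_spec = spec.drop(t)
            k = 1
        red = fit_cox(records, reduced_spec)
        red_ll = red.marginal_loglik if red.theta > 0 else red.loglik
        lr = 2.0 * (base - red_ll)
        rows.append(
            {"term": t, "lr_chi2": lr, "df": k, "p": float(chi2_dist.sf(lr, k)),
             "wald_chi2": float(full.chi2[i])}
        )
    return pd.DataFrame(rows)
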