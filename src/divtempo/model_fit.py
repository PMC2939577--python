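"""Maximum-likelihood fitting and AIC comparison of six diversification
models on branching times.

All six likelihoods are crown-conditioned on the reconstructed process and
share the same model-independent constant ``sum_{k=2}^{n-1} ln k``, so AIC
differences are meaningful across models:

* ``pure_birth``  — constant speciation, no extinction (1 free parameter);
  ``lnL = sum_{k=2}^{n-1} ln(k lam) - lam T``, MLE ``lam = (n-2)/T``.
* ``birth_death`` — constant speciation and extinction, parameterised by the
  net rate ``r = lam - mu`` and extinction fraction ``a = mu/lam`` (2);
  the Nee--May--Harvey constant-rate reconstructed-process likelihood.
* ``spvar``       — exponentially decaying speciation
  ``lam(t) = lam0 exp(-k t)`` (t forward from the crown), constant
  extinction (3).
* ``exvar``       — constant speciation, saturating extinction
  ``mu(t) = mu0 (1 - exp(-z t))`` (3).
* ``yule2rate`` / ``yule3rate`` — pure birth with one / two abrupt rate
  shifts at times before present (3 / 5); given the shifts, the per-segment
  rate MLEs are closed-form ``B_j / L_j`` (births over lineage-time).

The time-varying likelihoods use the general reconstructed-process form

    lnL = sum_{k=2}^{n-1} ln k + sum_{i=3}^{n} ln lam(s_i)
          + 2 rho(0, S) + sum_{i=3}^{n} rho(s_i, S)
          + 2 sum_{i=2}^{n} ln P(s_i, S),

with ``s_i`` the forward time of node ``i``, ``S`` the crown age,
``rho(t, S) = int_t^S (mu - lam)``, and ``P(t, S)`` the probability that a
lineage at ``t`` leaves descendants at the present,
``P = [1 + int_t^S exp(rho(t, u)) mu(u) du]^{-1}``.  At constant rates this
reduces algebraically to the birth--death expression, and at ``mu = 0`` to
pure birth; both reductions are enforced by tests.  The survival integral
is evaluated in log space by piecewise Gauss--Legendre quadrature between
node times, with the subdivision refined adaptively to abs tol 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .chronogram import BranchingTimes, Chronogram

__all__ = [
    "ModelFit",
    "MODELS",
    "loglik_pure_birth",
    "loglik_bd",
    "loglik_spvar",
    "loglik_exvar",
    "loglik_piecewise_yule",
    "fit_model",
    "fit_all",
]

MODELS = ("pure_birth", "birth_death", "spvar", "exvar", "yule2rate", "yule3rate")
K_FREE = {"pure_birth": 1, "birth_death": 2, "spvar": 3, "exvar": 3,
          "yule2rate": 3, "yule3rate": 5}

_QUAD_TOL = 1e-8
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(20)


@dataclass(frozen=True)
class ModelFit:
    model: str
    params: dict
    lnL: float
    k_free: int
    notes: dict = field(default_factory=dict, compare=False)

    @property
    def AIC(self) -> float:
        return -2.0 * self.lnL + 2.0 * self.k_free

    def to_json(self) -> dict:
        return {"model": self.model, "params": self.params, "lnL": self.lnL,
                "k_free": self.k_free, "AIC": self.AIC, **self.notes}


def _bt(bt) -> BranchingTimes:
    return bt.branching_times() if isinstance(bt, Chronogram) else bt


def _ln_k_const(n: int) -> float:
    """The shared conditioning constant sum_{k=2}^{n-1} ln k."""
    return float(np.sum(np.log(np.arange(2, n))))


# ---------------------------------------------------------------------------
# constant-rate models
# ---------------------------------------------------------------------------

def loglik_pure_birth(bt, lam: float) -> float:
    bt = _bt(bt)
    if lam <= 0:
        raise ValueError("lam must be positive")
    return _ln_k_const(bt.n) + (bt.n - 2) * np.log(lam) - lam * bt.T


def loglik_bd(bt, r_net: float, a: float) -> float:
    """Constant-rate reconstructed-process log-likelihood in the
    (net rate, extinction fraction) parameterisation."""
    bt = _bt(bt)
    if r_net <= 0:
        raise ValueError("r_net must be positive")
    if not 0.0 <= a < 1.0:
        raise ValueError("extinction fraction a must lie in [0, 1)")
    x = bt.x
    n = bt.n
    # ln(exp(r x) - a) = r x + log1p(-a exp(-r x)), overflow-safe
    ln_terms = r_net * x + np.log1p(-a * np.exp(-r_net * x))
    return float(
        _ln_k_const(n)
        + (n - 2) * np.log(r_net)
        + r_net * np.sum(x[1:])
        + n * np.log1p(-a)
        - 2.0 * np.sum(ln_terms)
    )


# ---------------------------------------------------------------------------
# time-varying models (general reconstructed-process likelihood)
# ---------------------------------------------------------------------------

def _timevar_loglik(bt, lam_fn, mu_fn, R_fn, tol: float = _QUAD_TOL) -> float:
    """General crown-conditioned lnL for vectorised rate functions of
    forward time and closed-form cumulative ``R(t) = int_0^t (mu - lam)``."""
    bt = _bt(bt)
    x = bt.x
    n = bt.n
    S = x[0]  # crown age = forward time of the present
    s = S - x  # forward node times, ascending, s[0] = 0
    lam_at = lam_fn(s[1:])
    if np.any(lam_at <= 0):
        return -np.inf
    bounds = np.unique(np.concatenate((s, [S])))
    idx = np.searchsorted(bounds, s)
    R_s = R_fn(s)
    R_S = float(R_fn(np.array([S]))[0])
    rho = R_S - R_s  # rho(s_i, S)

    prev = None
    n_sub = 1
    for _ in range(7):  # adaptive doubling of the subdivision
        lo = np.repeat(bounds[:-1], n_sub)
        step = np.repeat(np.diff(bounds), n_sub) / n_sub
        lo = lo + step * np.tile(np.arange(n_sub), bounds.size - 1)
        half = step / 2.0
        u = lo[:, None] + half[:, None] * (_GL_NODES[None, :] + 1.0)
        Ru = R_fn(u.ravel()).reshape(u.shape)
        Rmax = max(float(Ru.max()), float(R_s.max()), R_S)
        fu = mu_fn(u.ravel()).reshape(u.shape) * np.exp(Ru - Rmax)
        seg = (half[:, None] * _GL_WEIGHTS[None, :] * fu).sum(axis=1)
        seg = seg.reshape(bounds.size - 1, n_sub).sum(axis=1)
        # J(b_j) = int_{b_j}^{S} exp(R - Rmax) mu
        J = np.concatenate((np.cumsum(seg[::-1])[::-1], [0.0]))
        with np.errstate(divide="ignore"):
            lnH = np.log(J[idx]) + Rmax - R_s
        lnP = -np.logaddexp(0.0, lnH)
        lnL = (
            _ln_k_const(n)
            + float(np.sum(np.log(lam_at)))
            + 2.0 * rho[0]
            + float(np.sum(rho[1:]))
            + 2.0 * float(np.sum(lnP))
        )
        if prev is not None and abs(lnL - prev) < tol:
            return float(lnL)
        prev = lnL
        n_sub *= 2
    raise RuntimeError("survival-integral quadrature did not converge to tolerance")


def loglik_spvar(bt, lam0: float, kdecay: float, mu0: float) -> float:
    """Declining-speciation model: lam(t) = lam0 exp(-kdecay t) forward from
    the crown, constant extinction mu0."""
    if lam0 <= 0 or kdecay < 0 or mu0 < 0:
        raise ValueError("need lam0 > 0, kdecay >= 0, mu0 >= 0")

    def lam_fn(t):
        return lam0 * np.exp(-kdecay * t)

    def mu_fn(t):
        return np.full_like(np.asarray(t, dtype=float), mu0)

    if kdecay == 0.0:
        def R_fn(t):
            return (mu0 - lam0) * np.asarray(t, dtype=float)
    else:
        def R_fn(t):
            t = np.asarray(t, dtype=float)
            return mu0 * t - lam0 * -np.expm1(-kdecay * t) / kdecay

    return _timevar_loglik(bt, lam_fn, mu_fn, R_fn)


def loglik_exvar(bt, lam0: float, mu0: float, z: float) -> float:
    """Saturating-extinction model: constant speciation lam0,
    mu(t) = mu0 (1 - exp(-z t)) forward from the crown."""
    if lam0 <= 0 or mu0 < 0 or z < 0:
        raise ValueError("need lam0 > 0, mu0 >= 0, z >= 0")

    def lam_fn(t):
        return np.full_like(np.asarray(t, dtype=float), lam0)

    def mu_fn(t):
        t = np.asarray(t, dtype=float)
        return mu0 * -np.expm1(-z * t)

    def R_fn(t):
        t = np.asarray(t, dtype=float)
        if z == 0.0:
            return -lam0 * t
        return (mu0 - lam0) * t - mu0 * -np.expm1(-z * t) / z

    return _timevar_loglik(bt, lam_fn, mu_fn, R_fn)


# ---------------------------------------------------------------------------
# piecewise pure birth
# ---------------------------------------------------------------------------

def _cum_lineage_time(bt: BranchingTimes):
    """Return C(s) = int_0^s k(t) dt, the lineage-time accumulated between
    the present and age ``s`` (piecewise linear, vectorised)."""
    x = bt.x
    n = bt.n
    asc = x[::-1]  # x_n .. x_2 ascending
    # counts on (0, x_n): n; (x_n, x_{n-1}): n-1; ...; (x_3, x_2): 2
    seg_counts = np.arange(n, 1, -1, dtype=float)
    widths = np.diff(np.concatenate(([0.0], asc)))
    C_at = np.concatenate(([0.0], np.cumsum(seg_counts * widths)))  # at 0, x_n, ..., x_2

    def C(sv):
        sv = np.asarray(sv, dtype=float)
        j = np.searchsorted(asc, sv, side="left")
        base = C_at[j]
        lower = np.where(j > 0, asc[np.maximum(j - 1, 0)], 0.0)
        return base + seg_counts[np.minimum(j, seg_counts.size - 1)] * (sv - lower)

    return C


def _segment_stats(bt: BranchingTimes, shifts: np.ndarray):
    """Birth counts B_j and lineage-times L_j per segment, oldest first.

    Segments are delimited by ``shifts`` (ages, strictly decreasing); an
    event exactly at a boundary belongs to the older segment.
    """
    x = bt.x
    events = x[1:]  # ages of the n-2 non-crown events
    C = _cum_lineage_time(bt)
    edges = np.concatenate(([np.inf], shifts, [0.0]))  # descending
    B = np.array([
        np.sum((events >= edges[j + 1]) & (events < edges[j]))
        if j > 0 else np.sum(events >= edges[1])
        for j in range(edges.size - 1)
    ])
    Cvals = np.concatenate(([bt.T], C(shifts), [0.0])) if shifts.size else np.array([bt.T, 0.0])
    L = -np.diff(Cvals)
    return B, L


def loglik_piecewise_yule(bt, rates, shifts=()) -> float:
    """Pure birth with piecewise-constant rate: ``rates[j]`` applies within
    segment ``j`` (oldest first; ``shifts`` strictly decreasing ages)."""
    bt = _bt(bt)
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    shifts = np.atleast_1d(np.asarray(shifts, dtype=float)) if np.size(shifts) else np.array([])
    if rates.size != shifts.size + 1:
        raise ValueError("need len(rates) == len(shifts) + 1")
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    if shifts.size and (np.any(np.diff(shifts) >= 0)
                        or shifts[0] >= bt.crown_age or shifts[-1] <= 0):
        raise ValueError("shifts must be strictly decreasing within (0, crown age)")
    B, L = _segment_stats(bt, shifts)
    return float(
        _ln_k_const(bt.n) + np.sum(B * np.log(rates)) - np.sum(rates * L)
    )


def _piecewise_profile_lnL(bt: BranchingTimes, shifts: np.ndarray):
    """Profile lnL at the closed-form per-segment MLEs lam_j = B_j / L_j;
    -inf when any segment is empty (a positive rate cannot fit B_j = 0)."""
    B, L = _segment_stats(bt, shifts)
    if np.any(B == 0) or np.any(L <= 0):
        return -np.inf, None
    lam = B / L
    lnL = _ln_k_const(bt.n) + float(np.sum(B * np.log(lam))) - float(B.sum())
    return lnL, lam


def _shift_candidates(bt: BranchingTimes, grid_step: float) -> np.ndarray:
    """Union of the regular grid and the observed branching times, open
    interval (0, crown age), sorted descending (ties then prefer older)."""
    grid = np.arange(grid_step, bt.crown_age, grid_step)
    cand = np.unique(np.concatenate((grid, bt.x[1:])))
    cand = cand[(cand > 0) & (cand < bt.crown_age)]
    return cand[::-1]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _multistart(negfun, starts, bounds):
    best = None
    for s0 in starts:
        res = optimize.minimize(negfun, s0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("optimizer failed for all starts")
    return best


def fit_model(bt, model: str, grid_step: float = 1.0) -> ModelFit:
    """Maximum-likelihood fit of one diversification model.

    Closed forms where available (pure birth; the per-segment rates of the
    piecewise models, with an exhaustive search over shift candidates drawn
    from a ``grid_step``-My grid united with the observed branching times);
    bounded multi-start L-BFGS-B otherwise.
    """
    bt = _bt(bt)
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n, T = bt.n, bt.T
    lam_pb = (n - 2) / T

    if model == "pure_birth":
        return ModelFit(model, {"lam": lam_pb}, loglik_pure_birth(bt, lam_pb), 1)

    def _neg(fun):
        def neg(p):
            v = fun(p)
            return -v if np.isfinite(v) else 1e10
        return neg

    if model == "birth_death":
        neg = _neg(lambda p: loglik_bd(bt, p[0], p[1]))
        starts = [(lam_pb, 0.0), (lam_pb, 0.5), (0.5 * lam_pb, 0.3),
                  (2.0 * lam_pb, 0.8), (lam_pb, 0.95)]
        res = _multistart(neg, starts, [(1e-8, 10.0), (0.0, 1.0 - 1e-6)])
        r_net, a = res.x
        lam = r_net / (1.0 - a)
        return ModelFit(model, {"r_net": float(r_net), "a": float(a)},
                        -float(res.fun), 2,
                        notes={"lam": float(lam), "mu": float(lam * a)})

    if model == "spvar":
        neg = _neg(lambda p: loglik_spvar(bt, p[0], p[1], p[2]))
        starts = [(lam_pb, 0.0, 0.0), (2 * lam_pb, 0.05, 0.01),
                  (4 * lam_pb, 0.1, 0.0), (lam_pb, 0.01, 0.1),
                  (8 * lam_pb, 0.2, 0.05)]
        res = _multistart(neg, starts, [(1e-8, 10.0), (0.0, 10.0), (0.0, 10.0)])
        return ModelFit(model, {"lam0": float(res.x[0]), "kdecay": float(res.x[1]),
                                "mu0": float(res.x[2])}, -float(res.fun), 3)

    if model == "exvar":
        neg = _neg(lambda p: loglik_exvar(bt, p[0], p[1], p[2]))
        starts = [(lam_pb, 0.0, 0.0), (lam_pb, 0.5 * lam_pb, 0.1),
                  (2 * lam_pb, lam_pb, 1.0), (lam_pb, 0.1 * lam_pb, 0.01),
                  (1.5 * lam_pb, 0.9 * lam_pb, 5.0)]
        res = _multistart(neg, starts, [(1e-8, 10.0), (0.0, 10.0), (0.0, 100.0)])
        return ModelFit(model, {"lam0": float(res.x[0]), "mu0": float(res.x[1]),
                                "z": float(res.x[2])}, -float(res.fun), 3)

    cand = _shift_candidates(bt, grid_step)
    n_ev = n - 2
    const = _ln_k_const(n)
    events = bt.x[1:]
    # events with age >= s, per candidate (events sorted descending)
    n_older = np.searchsorted(-events, -cand, side="right")
    C_cand = _cum_lineage_time(bt)(cand)

    def _term(B, L):
        # B ln(B/L), 0-safe (masked to -inf by the B==0 check below)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(B > 0, B * (np.log(B) - np.log(L)), -np.inf)

    if model == "yule2rate":
        B1, B2 = n_older, n_ev - n_older
        L1, L2 = T - C_cand, C_cand
        lnL = const + _term(B1, L1) + _term(B2, L2) - n_ev
        ok = (B1 > 0) & (B2 > 0)
        lnL[~ok] = -np.inf
        if not np.any(ok):
            raise RuntimeError("no admissible shift candidate for yule2rate")
        i = int(np.argmax(lnL))  # cand descending: ties resolve to the older shift
        s1 = float(cand[i])
        return ModelFit(model, {"lam1": float(B1[i] / L1[i]),
                                "lam2": float(B2[i] / L2[i]), "st1": s1},
                        float(lnL[i]), 3, notes={"n_candidates": int(cand.size)})

    # yule3rate: exhaustive over ordered candidate pairs (s1 > s2)
    i1, i2 = np.triu_indices(cand.size, k=1)  # cand desc => cand[i1] > cand[i2]
    B1 = n_older[i1]
    B2 = n_older[i2] - n_older[i1]
    B3 = n_ev - n_older[i2]
    L1 = T - C_cand[i1]
    L2 = C_cand[i1] - C_cand[i2]
    L3 = C_cand[i2]
    lnL = const + _term(B1, L1) + _term(B2, L2) + _term(B3, L3) - n_ev
    ok = (B1 > 0) & (B2 > 0) & (B3 > 0)
    lnL[~ok] = -np.inf
    if not np.any(ok):
        raise RuntimeError("no admissible shift pair for yule3rate")
    j = int(np.argmax(lnL))  # row-major: ties prefer older s1, then older s2
    s1, s2 = float(cand[i1[j]]), float(cand[i2[j]])
    return ModelFit(model, {"lam1": float(B1[j] / L1[j]), "lam2": float(B2[j] / L2[j]),
                            "lam3": float(B3[j] / L3[j]), "st1": s1, "st2": s2},
                    float(lnL[j]), 5, notes={"n_candidates": int(cand.size)})


_NESTED_PAIRS = [
    ("pure_birth", "birth_death"),
    ("pure_birth", "yule2rate"),
    ("yule2rate", "yule3rate"),
    ("birth_death", "spvar"),
    ("birth_death", "exvar"),
]


def fit_all(bt, grid_step: float = 1.0) -> pd.DataFrame:
    """Fit all six models; rank by AIC; report LRT p-values for the nested
    pairs.  A model whose optimiser fails contributes a gap row (NaN) rather
    than aborting the table.  The tree is fit as sampled — no correction for
    missing species is applied inside these likelihoods, so rate estimates
    describe the sampled chronogram, not the full clade.
    """
    bt = _bt(bt)
    fits: dict[str, ModelFit | None] = {}
    errors: dict[str, str] = {}
    for model in MODELS:
        try:
            fits[model] = fit_model(bt, model, grid_step)
        except Exception as e:  # keep going; report the gap
            fits[model] = None
            errors[model] = str(e)
    rows = []
    for model in MODELS:
        f = fits[model]
        if f is None:
            rows.append({"model": model, "params": None, "lnL": np.nan,
                         "k_free": K_FREE[model], "AIC": np.nan})
        else:
            rows.append({"model": model, "params": f.params, "lnL": f.lnL,
                         "k_free": f.k_free, "AIC": f.AIC})
    df = pd.DataFrame(rows)
    best_aic = df["AIC"].min()
    df["delta_AIC"] = df["AIC"] - best_aic
    df["best"] = df["AIC"] == best_aic
    lrt = []
    for null, alt in _NESTED_PAIRS:
        f0, f1 = fits[null], fits[alt]
        if f0 is None or f1 is None:
            lrt.append({"null": null, "alt": alt, "stat": np.nan,
                        "df": K_FREE[alt] - K_FREE[null], "p": np.nan})
            continue
        stat = max(0.0, 2.0 * (f1.lnL - f0.lnL))
        dof = f1.k_free - f0.k_free
        lrt.append({"null": null, "alt": alt, "stat": stat, "df": dof,
                    "p": float(stats.chi2.sf(stat, dof))})
    df.attrs["lrt"] = pd.DataFrame(lrt)
    df.attrs["fits"] = fits
    df.attrs["errors"] = errors
    df.attrs["grid_step"] = grid_step
    df.attrs["caveat"] = (
        "rates describe the sampled chronogram; no incomplete-sampling "
        "correction is applied inside the likelihoods"
    )
    return df
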