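"""Whole-tree tempo statistics: the gamma statistic, the constant-rates (CR)
test, its Monte-Carlo analogue under incomplete sampling (MCCR), and
lineages-through-time (LTT) curves with simulation envelopes.

The gamma statistic standardises the position of a chronogram's internal
nodes against the pure-birth expectation: with internode gaps ``g_k`` and
partial lineage-times ``T_i = sum_{k=2}^{i} k g_k`` (``T = T_n``),

    gamma = [ (1/(n-2)) sum_{i=2}^{n-1} T_i  -  T/2 ]
            / [ T sqrt(1 / (12 (n-2))) ].

Under a completely sampled pure-birth process gamma is asymptotically
standard normal; ``gamma < -1.645`` rejects rate constancy one-tailed at
5% in favour of a slowdown.  Incomplete random sampling pushes gamma
negative even under constant rates, so the MCCR test rebuilds the null by
simulating complete Yule trees at the clade's true richness, subsampling
to the observed tip count, and recomputing gamma (gamma is invariant to
time rescaling, so the null can be simulated at unit rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chronogram import BranchingTimes, Chronogram
from .simulate import yule_subsampled_branching_times

__all__ = [
    "GammaResult",
    "MCCRResult",
    "LTTCurve",
    "gamma_stat",
    "gamma_from_ages",
    "cr_test",
    "mccr_test",
    "ltt",
    "ltt_envelope",
]

#: One-tailed 5% lower critical value of the standard normal.
CR_CRITICAL = -1.645


# ---------------------------------------------------------------------------
# gamma and the CR test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaResult:
    gamma: float
    n: int
    p_one_tailed: float  # standard-normal lower-tail probability of gamma

    def to_json(self) -> dict:
        return {"gamma": self.gamma, "n": self.n, "p_one_tailed": self.p_one_tailed}


def gamma_from_ages(x: np.ndarray) -> float:
    """Gamma from branching times (ages, sorted descending); fast path used
    inside Monte-Carlo loops."""
    x = np.asarray(x, dtype=float)
    n = x.size + 1
    if n < 3:
        raise ValueError("gamma requires n >= 3 tips")
    g = -np.diff(np.append(x, 0.0))
    k = np.arange(2, n + 1, dtype=float)
    Ti = np.cumsum(k * g)  # T_2 .. T_n
    T = Ti[-1]
    if T <= 0:
        raise ValueError("degenerate tree: total lineage-time is zero")
    mean_inner = Ti[:-1].mean()  # (1/(n-2)) sum_{i=2}^{n-1} T_i
    return float((mean_inner - T / 2.0) / (T * np.sqrt(1.0 / (12.0 * (n - 2)))))


def gamma_stat(bt: BranchingTimes | Chronogram) -> GammaResult:
    """The Pybus--Harvey gamma statistic with its lower-tail normal p."""
    if isinstance(bt, Chronogram):
        bt = bt.branching_times()
    gam = gamma_from_ages(bt.x)
    return GammaResult(gam, bt.n, float(stats.norm.cdf(gam)))


def cr_test(g: GammaResult, tail: str = "lower") -> dict:
    """Constant-rates test: compare gamma to the standard normal.

    ``tail='lower'`` (default) tests for a slowdown (reject when
    ``gamma < -1.645``); ``tail='upper'`` tests for a speed-up.
    """
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    p = float(stats.norm.cdf(g.gamma)) if tail == "lower" else float(stats.norm.sf(g.gamma))
    return {
        "gamma": g.gamma,
        "n": g.n,
        "tail": tail,
        "p": p,
        "critical_value": CR_CRITICAL,
        "reject": bool(g.gamma < CR_CRITICAL) if tail == "lower" else bool(-g.gamma < CR_CRITICAL),
        "alpha": 0.05,
    }


# ---------------------------------------------------------------------------
# MCCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCCRResult:
    gamma_observed: float
    clade_richness: int
    sample_size: int
    reps: int
    seed: int
    null_gamma: np.ndarray = field(repr=False, compare=False)
    p: float  # add-one estimator (1 + #{null <= obs}) / (reps + 1)
    p_plain: float  # plain proportion, as published analyses report
    critical_value: float  # 5th percentile of the null

    def to_json(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "null_gamma"}
        return d


def mccr_null(
    N_total: int, m: int, reps: int, seed: int, rate: float = 1.0
) -> np.ndarray:
    """Null gamma sample: complete Yule(N_total) trees at ``rate``,
    subsampled uniformly to ``m`` tips.  Gamma is scale-invariant, so the
    unit default rate is without loss of generality."""
    if not 3 <= m <= N_total:
        raise ValueError("need 3 <= m <= N_total")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if N_total > 10**6:
        import warnings

        warnings.warn(f"N_total = {N_total}: null simulation will be slow", stacklevel=2)
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    for i in range(reps):
        x = yule_subsampled_branching_times(N_total, m, rate, rng)
        out[i] = gamma_from_ages(x)
    return out


def mccr_test(
    gamma_obs: float,
    N_total: int,
    m: int,
    reps: int = 1000,
    seed: int = 0,
    rate: float = 1.0,
    null_gamma: np.ndarray | None = None,
) -> MCCRResult:
    """Monte-Carlo constant-rates test with an incomplete-sampling null.

    One-tailed for a slowdown: p is the (add-one) fraction of null gammas at
    or below the observed gamma; reject at 5% when the observed gamma falls
    below the null's 5th percentile.  A precomputed ``null_gamma`` sample
    may be supplied to amortise the simulation across many observed trees.
    """
    if null_gamma is None:
        null_gamma = mccr_null(N_total, m, reps, seed, rate)
    else:
        null_gamma = np.asarray(null_gamma, dtype=float)
        reps = null_gamma.size
    n_le = int(np.sum(null_gamma <= gamma_obs))
    return MCCRResult(
        gamma_observed=float(gamma_obs),
        clade_richness=int(N_total),
        sample_size=int(m),
        reps=int(reps),
        seed=int(seed),
        null_gamma=null_gamma,
        p=float((1 + n_le) / (reps + 1)),
        p_plain=float(n_le / reps),
        critical_value=float(np.percentile(null_gamma, 5.0)),
    )


# ---------------------------------------------------------------------------
# LTT
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LTTCurve:
    """Step function of reconstructed lineage count against time before
    present: count ``i`` holds on ``[times[i-2], times[i-1])`` going
    tipward; starts at 2 at the crown, ends at ``n`` at the present."""

    times: np.ndarray  # event times, descending, My before present
    counts: np.ndarray  # lineage count reached at each event

    @property
    def n(self) -> int:
        return int(self.counts[-1])

    def count_at(self, ages) -> np.ndarray:
        """Reconstructed lineage count at each age (My before present)."""
        ages = np.asarray(ages, dtype=float)
        # number of branching events at or older than `age`, plus one
        asc = self.times[::-1]
        return 1 + (asc.size - np.searchsorted(asc, ages, side="left"))

    def to_tsv(self) -> str:
        lines = ["time_My\tlineages"]
        lines += [f"{t!r}\t{c}" for t, c in zip(self.times, self.counts)]
        return "\n".join(lines) + "\n"


def ltt(tree: Chronogram | BranchingTimes) -> LTTCurve:
    """Lineages-through-time curve of a chronogram."""
    x = tree.branching_times().x if isinstance(tree, Chronogram) else tree.x
    counts = np.arange(2, x.size + 2)
    return LTTCurve(times=np.asarray(x, dtype=float), counts=counts)


def ltt_envelope(
    N_total: int,
    m: int,
    reps: int = 1000,
    seed: int = 0,
    rate: float = 1.0,
    grid_points: int = 256,
    empirical: Chronogram | BranchingTimes | None = None,
) -> dict:
    """Pointwise mean and 2.5/97.5 percentile LTT curves of ``reps``
    subsampled Yule trees on a common relative-time grid (0 = crown,
    1 = present), with an optional empirical overlay.

    Trees of differing crown ages are averaged on relative time; counts are
    returned on the grid, alongside the grid itself.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, grid_points)
    counts = np.empty((reps, grid_points))
    for i in range(reps):
        x = yule_subsampled_branching_times(N_total, m, rate, rng)
        curve = LTTCurve(times=x, counts=np.arange(2, x.size + 2))
        ages = x[0] * (1.0 - grid)  # relative -> My before present
        counts[i] = curve.count_at(ages)
    out = {
        "grid": grid,
        "mean": counts.mean(axis=0),
        "lo": np.percentile(counts, 2.5, axis=0),
        "hi": np.percentile(counts, 97.5, axis=0),
        "reps": reps,
        "seed": seed,
        "N_total": N_total,
        "m": m,
    }
    if empirical is not None:
        curve = ltt(empirical)
        ages = curve.times[0] * (1.0 - grid)
        out["empirical"] = curve.count_at(ages)
        out["empirical_crown_age"] = float(curve.times[0])
    return out


def plot_ltt(curves: dict, path: str) -> None:
    """Thin optional plotting layer: semilog LTT envelope figure.

    ``curves`` is the dict returned by :func:`ltt_envelope`.  Requires
    matplotlib; every statistic above is computed independently of it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    g = curves["grid"]
    ax.fill_between(g, curves["lo"], curves["hi"], alpha=0.25, label="95% envelope")
    ax.plot(g, curves["mean"], lw=1.5, label="simulated mean")
    if "empirical" in curves:
        ax.plot(g, curves["empirical"], "k-", lw=2, label="empirical")
    ax.set_yscale("log")
    ax.set_xlabel("relative time (0 = crown, 1 = present)")
    ax.set_ylabel("reconstructed lineages")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
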