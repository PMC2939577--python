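"""Chronogram simulators: the synthetic-data generators for every
diversification process the analyses assume.

Four generating processes are covered:

* constant-rate pure birth (Yule),
* constant-rate birth--death with the extinct lineages pruned
  (the *reconstructed* process),
* piecewise-constant pure birth with rate shifts anchored in time before
  present (the "yule2rate"/"yule3rate" generating model),
* continuously time-varying birth--death, simulated by thinning
  (the SPVAR/EXVAR generating models),

plus uniform random tip subsampling, which emulates the incomplete taxon
sampling of real supertree studies (e.g. 193 sampled of ~19,811 extant
species).  All simulators use flat parent/time arrays (no recursion), are
driven by a single seeded :class:`numpy.random.Generator`, and emit
validated :class:`~divtempo.chronogram.Chronogram` objects.  Fast paths
that return branching times only (no tree object) are provided for the
Monte-Carlo loops of the MCCR test and LTT envelopes.

Conditioning conventions
------------------------
Yule and birth--death simulators run forward until the n-th surviving
lineage appears and then append the waiting time to the next (discarded)
event as the final interval to the present, so the last internode is
properly distributed rather than truncated at a birth.  The piecewise
pure-birth simulator instead draws branching times exactly from the process
conditioned on (n, crown age): conditioned on those two quantities the
non-crown node ages are iid with density proportional to
``lambda(t) * exp(-Lambda(t))`` (``Lambda`` the cumulative rate looking back
from the present), which is the only exact construction available when rate
shifts are pinned to times before the present and n is fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .chronogram import BranchingTimes, Chronogram

__all__ = [
    "SimulationSpec",
    "simulate_yule",
    "simulate_bd_reconstructed",
    "simulate_piecewise_yule",
    "simulate_time_varying",
    "subsample_tips",
    "harpaline_fixture",
    "yule_branching_times",
    "yule_subsampled_branching_times",
]

DEFAULT_RETRY_CAP = 10_000


@dataclass
class SimulationSpec:
    """Full description of one simulated-tree experiment."""

    process: str  # yule | birth_death | piecewise_yule | time_varying
    n_total: int
    lam: float | None = None
    mu: float = 0.0
    rates: tuple[float, ...] | None = None
    shifts: tuple[float, ...] | None = None
    m: int | None = None
    replicates: int = 1
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if self.m is not None and not (2 <= self.m <= self.n_total):
            raise ValueError("retained sample size m must satisfy 2 <= m <= n_total")
        if self.shifts is not None and np.any(np.diff(self.shifts) >= 0):
            raise ValueError("shift times must be strictly decreasing")

    def metadata(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if v is not None and v != {}}
        return json.dumps(d, sort_keys=True)


# ---------------------------------------------------------------------------
# flat-array machinery
# ---------------------------------------------------------------------------

def _erm_topology(event_times: np.ndarray, present: float, rng: np.random.Generator):
    """Grow a pure-birth (equal-rates-Markov) topology over given forward
    event times.  Returns (parent, node_time, tip_ids); node 0 is the crown,
    children always have larger ids than parents."""
    n = event_times.size + 2
    N = 2 * n - 1
    parent = np.full(N, -1, dtype=np.int64)
    ntime = np.zeros(N)
    active = [1, 2]
    parent[1] = parent[2] = 0
    nxt = 3
    picks = rng.random(event_times.size)
    for j, t in enumerate(event_times):
        i = int(picks[j] * len(active))
        v = active[i]
        ntime[v] = t
        parent[nxt] = v
        parent[nxt + 1] = v
        active[i] = nxt
        active.append(nxt + 1)
        nxt += 2
    tips = np.array(active, dtype=np.int64)
    ntime[tips] = present
    return parent, ntime, tips


def _descendant_counts(parent, keep_mask):
    """Bottom-up pass: per node, the number of kept tips below it and the
    number of its children whose subtree contains a kept tip."""
    N = parent.size
    cnt = keep_mask.astype(np.int64).copy()
    pos = np.zeros(N, dtype=np.int64)
    for v in range(N - 1, 0, -1):
        if cnt[v]:
            cnt[parent[v]] += cnt[v]
            pos[parent[v]] += 1
    return cnt, pos


def _induced_branching_ages(parent, ntime, tip_ids, present):
    """Node ages of the subtree induced by ``tip_ids``, sorted descending."""
    N = parent.size
    keep = np.zeros(N, dtype=bool)
    keep[tip_ids] = True
    _, pos = _descendant_counts(parent, keep)
    ages = present - ntime[pos == 2]
    return np.sort(ages)[::-1]


def _induced_chronogram(parent, ntime, tip_ids, present, labels) -> Chronogram:
    """Build the reconstructed/induced chronogram on ``tip_ids`` from flat
    arrays (degree-2 nodes suppressed, ages preserved)."""
    N = parent.size
    keep = np.zeros(N, dtype=bool)
    keep[tip_ids] = True
    _, pos = _descendant_counts(parent, keep)
    induced = pos == 2
    # nearest induced internal at-or-above each node
    rep = np.full(N, -1, dtype=np.int64)
    anc = np.full(N, -1, dtype=np.int64)
    for v in range(N):
        p = parent[v]
        anc[v] = rep[p] if p >= 0 else -1
        rep[v] = v if induced[v] else anc[v]

    taxa = dendropy.TaxonNamespace()
    nodes: dict[int, dendropy.Node] = {}
    for v in np.flatnonzero(induced):
        nodes[v] = dendropy.Node()
    label_of = dict(zip(tip_ids.tolist(), labels))
    for t in tip_ids:
        nd = dendropy.Node()
        nd.taxon = taxa.new_taxon(label=label_of[int(t)])
        nodes[int(t)] = nd
    root_id = None
    for v, nd in nodes.items():
        a = int(anc[v])
        if a < 0:
            root_id = v
            continue
        nodes[a].add_child(nd)
        nd.edge.length = float(ntime[v] - ntime[a])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[root_id])
    return Chronogram(tree)


def _default_labels(k: int, prefix: str = "t") -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(k)]


# ---------------------------------------------------------------------------
# Yule
# ---------------------------------------------------------------------------

def _yule_event_times(n: int, lam: float, rng: np.random.Generator):
    """Forward waiting-time construction: births while k=2..n-1 lineages
    exist, plus the final Exp(n*lam) interval to the present.  Returns
    (birth_times ascending, present)."""
    k = np.arange(2, n + 1, dtype=float)
    w = rng.exponential(1.0 / (k * lam))
    t = np.cumsum(w)
    return t[:-1], float(t[-1])


def yule_branching_times(n: int, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Branching times (ages, descending) of a complete Yule tree — the fast
    path for null distributions, no topology built."""
    births, present = _yule_event_times(n, lam, rng)
    x = present - np.concatenate(([0.0], births))
    return x  # already descending


def yule_subsampled_branching_times(
    n_total: int, m: int, lam: float, rng: np.random.Generator
) -> np.ndarray:
    """Branching times of a complete Yule(n_total) tree subsampled uniformly
    to m tips — the fast path used by the MCCR null and LTT envelopes."""
    if not 2 <= m <= n_total:
        raise ValueError("need 2 <= m <= n_total")
    births, present = _yule_event_times(n_total, lam, rng)
    parent, ntime, tips = _erm_topology(births, present, rng)
    if m == n_total:
        sampled = tips
    else:
        sampled = rng.choice(tips, size=m, replace=False)
    return _induced_branching_ages(parent, ntime, sampled, present)


def simulate_yule(n: int, lam: float, seed: int) -> Chronogram:
    """A reconstructed pure-birth chronogram with exactly ``n`` tips.

    Lineages split at per-capita rate ``lam`` (My^-1); ages are measured
    back from the appended final interval (see module docstring).
    """
    if n < 2 or lam <= 0:
        raise ValueError("need n >= 2 and lam > 0")
    rng = np.random.default_rng(seed)
    births, present = _yule_event_times(n, lam, rng)
    parent, ntime, tips = _erm_topology(births, present, rng)
    return _induced_chronogram(parent, ntime, tips, present, _default_labels(n))


# ---------------------------------------------------------------------------
# birth--death
# ---------------------------------------------------------------------------

def simulate_bd_reconstructed(
    n: int, lam: float, mu: float, seed: int, max_tries: int = DEFAULT_RETRY_CAP
) -> Chronogram:
    """Constant-rate birth--death tree conditioned (by retry) on exactly
    ``n`` tips surviving to the present; extinct lineages are pruned."""
    if not (lam > mu >= 0):
        raise ValueError("need lam > mu >= 0")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    total_rate = lam + mu
    p_birth = lam / total_rate
    event_cap = 200 * n + 10_000
    for _ in range(max_tries):
        parent = [-1, 0, 0]
        ntime = [0.0, 0.0, 0.0]
        active = [1, 2]
        t = 0.0
        ok = False
        for _ev in range(event_cap):
            k = len(active)
            t += rng.exponential(1.0 / (k * total_rate))
            if k == n:
                # n survivors reached: the waiting time just drawn is the
                # (discarded) next event; stop the clock there
                ok = True
                break
            i = int(rng.random() * k)
            v = active[i]
            if rng.random() < p_birth:
                ntime[v] = t
                parent.extend((v, v))
                ntime.extend((0.0, 0.0))
                active[i] = len(parent) - 2
                active.append(len(parent) - 1)
            else:
                ntime[v] = t  # death time
                active[i] = active[-1]
                active.pop()
                if not active:
                    break
        if not ok:
            continue
        present = t
        parent = np.asarray(parent, dtype=np.int64)
        ntime_arr = np.asarray(ntime)
        tips = np.asarray(active, dtype=np.int64)
        ntime_arr[tips] = present
        return _induced_chronogram(parent, ntime_arr, tips, present, _default_labels(n))
    raise RuntimeError(f"no simulation reached {n} survivors in {max_tries} attempts")


# ---------------------------------------------------------------------------
# piecewise pure birth (rate shifts in time before present)
# ---------------------------------------------------------------------------

def _piecewise_cumrate(rates, shifts):
    """Return (Lambda, Lambda_inv) for a piecewise-constant looking-back rate:
    rates oldest-first, shifts strictly decreasing (My before present)."""
    rates = np.asarray(rates, dtype=float)
    shifts = np.asarray(shifts, dtype=float)
    if rates.size != shifts.size + 1:
        raise ValueError("need len(rates) == len(shifts) + 1")
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    if shifts.size and (np.any(np.diff(shifts) >= 0) or np.any(shifts <= 0)):
        raise ValueError("shifts must be positive and strictly decreasing")
    # young-first boundaries and rates
    a = shifts[::-1].copy()          # ascending boundaries
    q = rates[::-1].copy()           # q[i] applies on [a[i-1], a[i])
    cum_at = np.concatenate(([0.0], np.cumsum(q[:-1] * np.diff(np.concatenate(([0.0], a))))))

    def Lam(t):
        t = np.asarray(t, dtype=float)
        if not a.size:
            return q[0] * t
        j = np.searchsorted(a, t, side="right")
        base = np.where(j > 0, cum_at[j], 0.0)
        lower = np.where(j > 0, a[np.maximum(j - 1, 0)], 0.0)
        return base + q[j] * (t - lower)

    def LamInv(y):
        y = np.asarray(y, dtype=float)
        if not a.size:
            return y / q[0]
        j = np.searchsorted(cum_at[1:], y, side="right")
        base = np.where(j > 0, cum_at[j], 0.0)
        lower = np.where(j > 0, a[np.maximum(j - 1, 0)], 0.0)
        return lower + (y - base) / q[j]

    return Lam, LamInv


def simulate_piecewise_yule(
    n: int,
    rates,
    shifts=(),
    seed: int = 0,
    crown_age: float | None = None,
) -> Chronogram:
    """Pure-birth chronogram whose speciation rate is ``rates[j]`` within
    segment ``j`` (segments delimited by ``shifts``, oldest segment first,
    shift times in My before present), with exactly ``n`` tips.

    Branching times are drawn exactly from the process conditioned on
    (n, crown age).  If ``crown_age`` is omitted: with no shifts the crown
    age is drawn from the forward Yule construction (making this identical
    in distribution to :func:`simulate_yule`); with shifts it is set to the
    expectation-matching anchor ``Lambda(t_c) = ln(n/2)``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    rates = tuple(float(r) for r in np.atleast_1d(rates))
    shifts = tuple(float(s) for s in np.atleast_1d(shifts)) if np.size(shifts) else ()
    Lam, LamInv = _piecewise_cumrate(rates, shifts)
    if crown_age is None:
        if not shifts:
            k = np.arange(2, n + 1, dtype=float)
            crown_age = float(np.sum(rng.exponential(1.0 / (k * rates[0]))))
        else:
            crown_age = float(LamInv(np.log(n / 2.0)))
    if shifts and shifts[0] >= crown_age:
        raise ValueError("oldest shift must be younger than the crown age")
    Z = -np.expm1(-Lam(crown_age))  # 1 - exp(-Lambda(t_c))
    u = rng.random(n - 2)
    ages = LamInv(-np.log1p(-u * Z))  # inverse CDF of lambda(t)exp(-Lambda(t))
    births = np.sort(crown_age - ages)  # forward times, ascending
    parent, ntime, tips = _erm_topology(births, crown_age, rng)
    return _induced_chronogram(parent, ntime, tips, crown_age, _default_labels(n))


# ---------------------------------------------------------------------------
# continuously time-varying birth--death (thinning)
# ---------------------------------------------------------------------------

def simulate_time_varying(
    n: int,
    lam_fn,
    mu_fn,
    t_max: float,
    seed: int,
    max_tries: int = DEFAULT_RETRY_CAP,
) -> Chronogram:
    """Forward simulation with rates ``lam_fn(t)``, ``mu_fn(t)`` (functions
    of forward time from the crown, My^-1), by thinning against the grid
    supremum of lam + mu on ``[0, t_max]``.

    Uses the same conditioning as :func:`simulate_bd_reconstructed`: run
    forward until ``n`` lineages are alive, then stop the clock at the next
    (discarded) accepted event; with constant rate functions the output is
    therefore identical in distribution to the constant-rate birth--death
    simulator.  Attempts that go extinct, or that fail to reach ``n``
    lineages before ``t_max``, are retried up to ``max_tries``.
    """
    if n < 2 or t_max <= 0:
        raise ValueError("need n >= 2 and t_max > 0")
    grid = np.linspace(0.0, t_max, 1025)
    lam_g = np.asarray([lam_fn(t) for t in grid], dtype=float)
    mu_g = np.asarray([mu_fn(t) for t in grid], dtype=float)
    if np.any(lam_g < 0) or np.any(mu_g < 0) or not (
        np.all(np.isfinite(lam_g)) and np.all(np.isfinite(mu_g))
    ):
        raise ValueError("rate functions must be non-negative and bounded on [0, t_max]")
    bound = float((lam_g + mu_g).max()) * 1.0000001
    if bound <= 0:
        raise ValueError("rates are identically zero")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        parent = [-1, 0, 0]
        ntime = [0.0, 0.0, 0.0]
        active = [1, 2]
        t = 0.0
        done = False
        while active and t < t_max:
            k = len(active)
            t += rng.exponential(1.0 / (k * bound))
            if t >= t_max:
                break
            u = rng.random()
            accepted = u < (lam_fn(t) + mu_fn(t)) / bound
            if not accepted:
                continue
            if k == n:
                done = True  # next accepted event: stop the clock here
                break
            i = int(rng.random() * k)
            v = active[i]
            if u < lam_fn(t) / bound:
                ntime[v] = t
                parent.extend((v, v))
                ntime.extend((0.0, 0.0))
                active[i] = len(parent) - 2
                active.append(len(parent) - 1)
            else:
                ntime[v] = t  # death
                active[i] = active[-1]
                active.pop()
        if not done:
            continue
        present = t
        parent = np.asarray(parent, dtype=np.int64)
        ntime_arr = np.asarray(ntime)
        tips = np.asarray(active, dtype=np.int64)
        ntime_arr[tips] = present
        return _induced_chronogram(parent, ntime_arr, tips, present, _default_labels(n))
    raise RuntimeError(
        f"no simulation reached {n} survivors before t_max in {max_tries} attempts"
    )


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def subsample_tips(
    tree: Chronogram, m: int, seed: int, depth_bias_exponent: float = 0.0
) -> Chronogram:
    """Prune to a random subset of ``m`` tips.

    By default tips are drawn uniformly without replacement (the MCCR-test
    assumption).  ``depth_bias_exponent > 0`` weights each tip by its
    pendant-edge length raised to that exponent, a sensitivity knob for
    sampling regimes that over-represent deep lineages.
    """
    labels = tree.tip_labels  # sorted -> deterministic given seed
    if not 2 <= m <= len(labels):
        raise ValueError("need 2 <= m <= number of tips")
    rng = np.random.default_rng(seed)
    if m == len(labels):
        return tree.copy()
    if depth_bias_exponent == 0.0:
        chosen = rng.choice(labels, size=m, replace=False)
    else:
        pend = {
            lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()
        }
        w = np.array([pend[l] for l in labels], dtype=float) ** depth_bias_exponent
        chosen = rng.choice(labels, size=m, replace=False, p=w / w.sum())
    return tree.prune_to_tips(set(chosen.tolist()))


# ---------------------------------------------------------------------------
# packaged demo bundle
# ---------------------------------------------------------------------------

#: Extant species richness of the study clades (supertree counts).
RICHNESS_TABLE = {"Harpalinae": 19811, "Brachininae": 655, "Austral psydrines": 100}

#: Generating parameters of the demo bundle: two sister clades of equal
#: crown age; the diverse clade diversifies under a three-rate schedule with
#: shifts near 41 and 12 My (rates scaled so the expectation anchor yields
#: the full richness at the 98.5 My crown), the depauperate sister under a
#: single rate.
FIXTURE_PARAMS = {
    "crown_age": 98.5,
    "harpaline": {"n": 19811, "m": 193, "shifts": (41.34, 11.87)},
    "brachinine": {"n": 655, "m": 10},
}


def _anchor_rates(profile, shifts, n, crown_age):
    """Scale a relative rate profile so Lambda(crown_age) = ln(n/2)."""
    profile = np.asarray(profile, dtype=float)
    bounds = np.concatenate(([crown_age], shifts, [0.0]))
    durations = -np.diff(bounds)
    total = float(np.sum(profile * durations))
    return tuple(profile * (np.log(n / 2.0) / total))


def harpaline_fixture(seed: int) -> dict:
    """Deterministic demo bundle emulating the study design: a ~19,811-tip
    clade sampled to 193 tips with rate decreases near 41 and 12 My, plus a
    655-tip same-age sister sampled to 10 tips, and the richness table.

    Returns a dict with keys ``harpaline_full``, ``harpaline_sampled``,
    ``brachinine_full``, ``brachinine_sampled``, ``richness``, ``params``.
    """
    p = FIXTURE_PARAMS
    tc = p["crown_age"]
    h = p["harpaline"]
    rates_h = _anchor_rates((0.08, 0.02, 0.004), h["shifts"], h["n"], tc)
    full_h = simulate_piecewise_yule(
        h["n"], rates_h, h["shifts"], seed=seed, crown_age=tc
    )
    samp_h = subsample_tips(full_h, h["m"], seed=seed + 1)
    b = p["brachinine"]
    rate_b = np.log(b["n"] / 2.0) / tc
    full_b = simulate_piecewise_yule(b["n"], (rate_b,), (), seed=seed + 2, crown_age=tc)
    samp_b = subsample_tips(full_b, b["m"], seed=seed + 3)
    return {
        "harpaline_full": full_h,
        "harpaline_sampled": samp_h,
        "brachinine_full": full_b,
        "brachinine_sampled": samp_b,
        "richness": dict(RICHNESS_TABLE),
        "params": {
            "seed": seed,
            "crown_age": tc,
            "harpaline_rates": rates_h,
            "harpaline_shifts": h["shifts"],
            "brachinine_rate": float(rate_b),
        },
    }
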