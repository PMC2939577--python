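"""Point statistics on clade richness and single chronograms.

Three classical tools for asking "is this clade unusually diverse, and
where in the tree did the rate change?":

* the Slowinski--Guyer sister-clade test: under the equal-rates-Markov
  (ERM) null every ordered split of ``n = r + s`` species between two
  sister clades is equally probable, so the one-tailed probability of a
  split at least as uneven as (r, s) is ``s / (n - 1)``;
* the Magallón--Sanderson estimators of net diversification
  ``r = lambda - mu`` from a clade's extant richness and age, under a
  relative extinction fraction ``epsilon = mu / lambda``;
* the relative-cladogenesis (RC) test, which slices the tree at each
  branch's origin and asks, via the broken-stick (uniform composition)
  null, whether that branch left more of the present-day tips than
  expected given how many lineages were alive at the slice, with
  Bonferroni correction across branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chronogram import Chronogram

__all__ = ["SGResult", "MSRateEstimate", "slowinski_guyer", "ms_rate", "rc_test"]


# ---------------------------------------------------------------------------
# Slowinski--Guyer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SGResult:
    r: int  # species in the larger clade
    s: int  # species in the smaller clade
    tail: str  # "one" | "two"
    p: float

    def to_json(self) -> dict:
        return {"r": self.r, "s": self.s, "tail": self.tail, "p": self.p}


def slowinski_guyer(r: int, s: int, tail: str = "one") -> SGResult:
    """ERM probability that a sister pair with ``r + s`` total species is at
    least as uneven as (r, s), with ``r >= s >= 1``.

    One-tailed: ``p = s / (r + s - 1)``; two-tailed doubles it, capped at 1.
    Exact integer arithmetic, evaluated as a float at the end.
    """
    if not (isinstance(r, (int, np.integer)) and isinstance(s, (int, np.integer))):
        raise TypeError("species counts must be integers")
    if s < 1 or r < s:
        raise ValueError("need r >= s >= 1")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    n = r + s
    if n == 2:  # (1, 1): no asymmetry possible
        return SGResult(int(r), int(s), tail, 1.0)
    p = s / (n - 1)
    if tail == "two":
        p = min(1.0, 2.0 * p)
    return SGResult(int(r), int(s), tail, float(p))


# ---------------------------------------------------------------------------
# Magallón--Sanderson net diversification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MSRateEstimate:
    n: int
    t: float  # clade age, My
    mode: str  # "stem" | "crown"
    epsilon: float  # mu / lambda
    r_hat: float  # net diversification, My^-1

    def to_json(self) -> dict:
        return {
            "n": self.n, "t": self.t, "mode": self.mode,
            "epsilon": self.epsilon, "r_hat": self.r_hat,
        }


def ms_rate(n: int, t: float, epsilon: float = 0.0, mode: str = "crown") -> MSRateEstimate:
    """Net diversification rate of a clade of extant richness ``n`` and age
    ``t`` (stem or crown age, My) under extinction fraction ``epsilon``.

    Stem:  ``r = ln(n (1 - eps) + eps) / t``.
    Crown: ``r = (1/t) * (ln[ n (1 - eps^2)/2 + 2 eps
    + (1 - eps)/2 * sqrt(n (n eps^2 - 8 eps + 2 n eps + n)) ] - ln 2)``.
    Both reduce at ``epsilon = 0`` to the familiar ``ln(n)/t`` and
    ``ln(n/2)/t`` pure-birth forms.
    """
    if mode not in ("stem", "crown"):
        raise ValueError("mode must be 'stem' or 'crown'")
    if t <= 0:
        raise ValueError("clade age must be positive")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    if n < (2 if mode == "crown" else 1):
        raise ValueError(f"n too small for {mode} mode")
    if mode == "stem":
        r_hat = math.log(n * (1.0 - epsilon) + epsilon) / t
    else:
        disc = n * (n * epsilon**2 - 8.0 * epsilon + 2.0 * n * epsilon + n)
        arg = (
            n * (1.0 - epsilon**2) / 2.0
            + 2.0 * epsilon
            + (1.0 - epsilon) / 2.0 * math.sqrt(disc)
        )
        r_hat = (math.log(arg) - math.log(2.0)) / t
    return MSRateEstimate(int(n), float(t), mode, float(epsilon), float(r_hat))


# ---------------------------------------------------------------------------
# relative cladogenesis
# ---------------------------------------------------------------------------

def _rc_p_raw(n: int, k: int, r_desc: int) -> float:
    """Tail probability that one given lineage among ``k`` contemporaneous
    ancestors leaves >= ``r_desc`` of the ``n`` present-day tips, under the
    uniform (broken-stick) composition null:
    ``C(n - r_desc, k - 1) / C(n - 1, k - 1)``."""
    return math.comb(n - r_desc, k - 1) / math.comb(n - 1, k - 1)


def rc_test(tree: Chronogram, correction: str = "bonferroni") -> pd.DataFrame:
    """Relative-cladogenesis table for every internal branch of ``tree``.

    Each internal branch (the edge above a non-root internal node) is sliced
    at its origin — its parent node's age ``t_b``; ``k`` counts the
    reconstructed lineages alive then (ties at identical ages count every
    lineage originating at or above the slice), and ``r_desc`` counts the
    branch's extant sampled descendants.  ``p_raw`` is the broken-stick tail
    probability; the Bonferroni factor is the number of branches tested.
    The ``trickle_down`` column marks significant branches that also contain
    a significant descendant branch, supporting the conservative
    "shallowest significant branch" reading.

    Returns a :class:`pandas.DataFrame` with columns ``branch``, ``t_b``,
    ``k``, ``r_desc``, ``n``, ``p_raw``, ``p_bonferroni``, ``significant``,
    ``trickle_down``; the number of tests is stored in ``df.attrs``.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    n = tree.n_tips
    if n < 3:
        raise ValueError("RC test needs at least 3 tips")
    t = tree.tree
    internal_ages = tree.internal_ages()  # descending
    rows = []
    node_rows = {}
    for nd in t.preorder_node_iter():
        if not nd.child_nodes() or nd is t.seed_node:
            continue
        t_b = float(nd.parent_node.age_my)
        # lineages alive at the slice: 1 + #(internal nodes with age >= t_b)
        k = 1 + int(np.searchsorted(-internal_ages, -t_b, side="right"))
        r_desc = sum(1 for _ in nd.leaf_iter())
        branch_id = min(lf.taxon.label for lf in nd.leaf_iter())
        rows.append(
            {"branch": branch_id, "node": nd, "t_b": t_b, "k": k,
             "r_desc": r_desc, "n": n, "p_raw": _rc_p_raw(n, k, r_desc)}
        )
        node_rows[nd] = rows[-1]
    m_tests = len(rows)
    for row in rows:
        factor = m_tests if correction == "bonferroni" else 1
        row["p_bonferroni"] = min(1.0, row["p_raw"] * factor)
        row["significant"] = row["p_bonferroni"] < 0.05
    for row in rows:  # trickle-down: a significant branch below this one?
        row["trickle_down"] = row["significant"] and any(
            node_rows[d]["significant"]
            for d in row["node"].preorder_iter()
            if d is not row["node"] and d in node_rows
        )
    df = pd.DataFrame(
        [{k2: v for k2, v in r.items() if k2 != "node"} for r in rows]
    ).sort_values(["t_b", "branch"], ascending=[False, True], ignore_index=True)
    df.attrs["n_tests"] = m_tests
    df.attrs["correction"] = correction
    return df
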