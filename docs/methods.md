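# Methods

This note records the models, conventions and numerical choices behind
`divtempo`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and conventions

The unit of analysis is the **chronogram**: a rooted, binary, ultrametric
tree with branch lengths in millions of years (My). Time is measured
**before present** (0 = present); the crown age is the largest node age.
The forward-time rate functions of the SPVAR/EXVAR models convert
internally via `t_fwd = crown_age − t_bp`. Any length on the root edge is
ignored: every analysis is crown-conditioned.

Every downstream statistic consumes the **branching times**
x₂ ≥ x₃ ≥ … ≥ xₙ (internal-node ages; x₂ the crown age), their internode
gaps g_k = x_k − x_{k+1} (g_n = x_n), and the total lineage-time
T = Σ k·g_k, which satisfies the algebraic identity T = 2x₂ + Σ_{i≥3} x_i
(asserted to 1e-9 relative in tests).

Validation tolerances: a tree counts as ultrametric when the spread of
root-to-tip path lengths is ≤ 1e-6 × tree height. Published chronograms
carry rounding error from the dating software that produced them, so a
`coerce_ultrametric` option extends terminal branches to the maximum tip
depth (logged); the default tolerance is our choice, as dating pipelines
do not document their output precision. Polytomies are rejected by
default; an option resolves them into zero-length binary splits with a
deterministic left-ascending rule, producing tied branching times that are
flagged but well-defined (a g_k = 0 contributes nothing to any statistic).

Newick parsing is delegated to dendropy; writing uses a deterministic
emitter (children ordered lexicographically by smallest descendant label,
fixed decimal precision) so identical analyses produce byte-identical
files.

## Simulators (what the synthetic data emulates)

The generators reproduce the study design of a severely undersampled
radiation: a ~19,811-species clade represented by 193 tips and a 655-species
same-age sister represented by 10 tips, with richness table
(19,811 / 655 / 100). The packaged demo bundle
(`harpaline_fixture`) builds exactly that geometry: both clades share a
98.5-My crown; the diverse clade diversifies under a three-rate schedule
with shifts at 41.34 and 11.87 My whose relative profile (0.08 : 0.02 :
0.004) is scaled so that the cumulative rate anchor Λ(98.5) = ln(n/2)
reproduces the full richness; the sister runs at the single rate
ln(655/2)/98.5 ≈ 0.059 /My.

Conditioning conventions, in decreasing order of orthodoxy:

* **Yule / birth–death**: forward simulation; when the n-th surviving
  lineage appears the clock stops at the waiting time to the *next*
  (discarded) event, so the final internode is properly distributed rather
  than truncated at a birth. Birth–death attempts that go extinct are
  retried (capped at 10,000 with a clear error).
* **Time-varying birth–death**: the same construction, with events
  proposed by thinning against the grid supremum of λ(t) + μ(t) on
  [0, t_max]; with constant rate functions the output is identical in
  distribution to the constant-rate simulator (asserted by a KS test).
* **Piecewise pure birth**: here the shifts are anchored in time before
  present while n is fixed, so a forward construction is ill-posed (the
  present is unknown until the simulation ends). We instead draw the
  branching times *exactly* from the process conditioned on (n, crown
  age): conditioned on those two quantities the non-crown node ages are
  iid with density λ(t)e^{−Λ(t)} on (0, crown age), sampled by inverse CDF
  through the piecewise-linear cumulative rate Λ, with uniform (ERM)
  topology — every lineage of a pure-birth process is equally likely to
  split regardless of the rate schedule. With no shifts the crown age is
  drawn from the forward construction, making the degenerate case
  distribution-equal to the Yule simulator (KS-tested); with shifts it
  defaults to the expectation-matching anchor Λ(t_c) = ln(n/2), or a
  user-supplied `crown_age`.

Subsampling is uniform over tips without replacement, as the MCCR null
assumes. Real supertree sampling is usually biased toward deep lineages,
so a sensitivity option weights tips by their pendant-edge length raised
to a user exponent (default off). All simulators run on flat
parent-index/node-time arrays (no recursion; a 19,811-tip tree costs
tens of milliseconds) and a single seeded `numpy` generator; equal seeds
give byte-identical output.

What the generators do **not** emulate: non-uniform (clade-biased) real
sampling, diversity-dependent or trait-dependent rates, extinction pulses,
and dating error in the chronogram itself. Passing tests therefore show
the statistics behave correctly under their own assumptions, not that
those assumptions hold for any particular empirical tree.

## Statistics

**Slowinski–Guyer.** One-tailed p = s/(r+s−1); the two-tailed value doubles
it, capped at 1. The one-tailed form is the package default because it is
the convention under which the canonical worked example (19,811 vs 655 →
p = 0.032) reproduces exactly. Exact integer arithmetic; verified against
brute-force ERM split enumeration for all totals ≤ 20.

**Magallón–Sanderson.** Stem: r̂ = ln(n(1−ε)+ε)/t. Crown:
r̂ = (1/t)·(ln[n(1−ε²)/2 + 2ε + ((1−ε)/2)·√(n(nε²−8ε+2nε+n))] − ln 2).
Both reduce at ε = 0 to ln(n)/t and ln(n/2)/t; r̂·t depends only on
(n, ε, mode). Both modes are always reported, because published rate
figures rarely state which age they used; for n = 19,811 at t = 98.5 the
two forms bracket [0.093, 0.100] /My.

**Relative cladogenesis.** Each internal branch is sliced at its origin
(its parent node's age); k counts reconstructed lineages alive then, with
ties counting every lineage originating at or above the slice; p_raw =
C(n−r, k−1)/C(n−1, k−1), verified against enumeration of all compositions
of n into k positive parts for n ≤ 12. The Bonferroni factor is the
number of branches tested (the n − 2 non-root internal branches),
reported in the table metadata. A `trickle_down` column marks significant
branches that contain significant descendants, supporting the
conservative "shallowest significant branch" reading as a post-filter
rather than a different statistic. The test operates on sampled tips
only; a caveat is logged when the tree is flagged as subsampled.

**γ / CR / MCCR.** γ as defined in the README; exactly scale-invariant
(asserted), which justifies simulating the MCCR null at unit rate
regardless of the clade's true timescale. The CR test is one-tailed for a
slowdown by default (reject at γ < −1.645); an upper-tail orientation is
exposed because positive γ values are naturally reported on that side.
The MCCR p-value uses the add-one permutation estimator
(1 + #{γ_null ≤ γ_obs})/(reps + 1) to avoid p = 0; the plain proportion
is reported alongside, as published analyses quote that form. The null
tree size follows the user-supplied true richness (a warning fires above
10⁶ tips).

**LTT envelopes.** Trees of differing crown ages are averaged on a
relative-time grid (0 = crown, 1 = present; 256 points), with pointwise
mean and 2.5/97.5 percentiles; empirical curves are overlaid on the same
grid. Absolute-time curves are used everywhere else. Plotting is a thin
optional matplotlib layer; no statistic depends on it.

## Diversification likelihoods

All six models share the crown-conditioned reconstructed-process
likelihood with the *same* model-independent constant Σ_{k=2}^{n−1} ln k,
so AIC values are comparable across models; at parameter settings where
models coincide their lnL values coincide (asserted to 1e-6).

* Pure birth: lnL = Σ ln(k·λ) − λT; MLE λ̂ = (n−2)/T in closed form.
* Birth–death, parameterised by net rate r = λ−μ and extinction fraction
  a = μ/λ (the boundary â = 0 is reachable): lnL = Σ ln k + (n−2)ln r +
  r Σ_{i≥3} x_i + n ln(1−a) − 2Σ_{i≥2} ln(e^{r x_i} − a), evaluated
  overflow-safely via ln(e^{rx}−a) = rx + log1p(−a e^{−rx}). Verified to
  reduce to pure birth at a = 0 through the identity T = 2x₂ + Σ x_i.
* SPVAR (λ(t) = λ₀e^{−kt}, μ constant) and EXVAR (λ constant,
  μ(t) = μ₀(1−e^{−zt})) use the general form
  lnL = Σ ln k + Σ_{i≥3} ln λ(s_i) + 2ρ(0,S) + Σ_{i≥3} ρ(s_i,S)
  + 2Σ_{i≥2} ln P(s_i,S), with ρ(t,S) = ∫_t^S (μ−λ) (closed form per
  model) and survival probability P(t,S) = [1 + ∫_t^S e^{ρ(t,u)}μ(u)du]^{−1}.
  The survival integral is computed in log space (max-shifted) by
  20-point Gauss–Legendre quadrature on the panels between consecutive
  node times, with panel subdivision doubled until the lnL changes by
  < 1e-8 (raising, never returning NaN, if seven doublings fail).
  Contracts enforced by tests: SPVAR(k=0) ≡ BD (1e-6), EXVAR(μ₀=0) ≡ PB
  (1e-6), EXVAR(z→10⁶) ≡ BD (1e-4).
* Piecewise pure birth: lnL = Σ_events ln(k_e·λ(age_e)) − Σ_j λ_j L_j with
  L_j the lineage-time inside segment j; an event exactly on a boundary
  belongs to the older segment. Given the shifts, the segment MLEs are
  closed-form λ̂_j = B_j/L_j (births over lineage-time), checked against a
  numeric optimizer to 1e-5 relative lnL.

**Shift-time search.** Candidates are the union of a regular grid
(default 1 My, the conventional spacing) and the observed branching times
— published fitted shifts are typically non-integer, which the branching
times supply. yule3rate searches all ordered candidate pairs
(vectorised; ~10 ms at n ≈ 200). A candidate that leaves any segment
empty (B_j = 0) is rejected with lnL = −∞ rather than fitted at a zero
rate, since the model requires λ > 0; ties in lnL resolve toward the
older shift (candidates are scanned oldest-first).

**Optimisation.** BD/SPVAR/EXVAR use bounded multi-start L-BFGS-B
(5 deterministic starts seeded from the pure-birth MLE; bounds r ∈
(1e-8, 10), a ∈ [0, 1−1e-6), decay/onset parameters in [0, 10] or
[0, 100]). Non-finite likelihoods are clamped for the line search;
total optimiser failure raises and surfaces as a gap row in `fit_all`,
never a silent NaN.

**Model choice.** `fit_all` ranks by AIC = −2lnL + 2k with k = (1, 2, 3,
3, 3, 5) and reports χ² LRTs for the nested pairs (PB⊂BD, PB⊂yule2rate⊂
yule3rate, BD⊂SPVAR, BD⊂EXVAR) alongside. Two caveats are deliberate and
documented rather than patched: (i) no incomplete-sampling correction is
applied inside these likelihoods — fits describe the sampled chronogram,
and `fit_all` says so in its output metadata; (ii) plain AIC is known to
favour the piecewise models on constant-rate data, because maximising
over a dense grid of shift candidates inflates their profile likelihood —
a property of this model-selection procedure itself. The calibration
facts that do hold, and are tested, are that the PB-vs-BD LRT rejects at
roughly its nominal rate on pure-birth data and that the shift/rate
estimates of the piecewise models recover their generating values.

## Problem sizes used by the test suite

Calibration and recovery checks run at desk scale, chosen to keep each
claim statistically sharp while the whole suite stays fast: 1,000
complete 100-tip trees for the γ null; a 2,000-rep MCCR null at
(N = 2,000 → m = 100) with 500 observed replicates for type-I error; 100
replicates at n = 193 for shift recovery and model-selection power;
enumeration oracles at n ≤ 12 (compositions) and n ≤ 20 (ERM splits).
The R/ape implementations of branching times, γ and the constant-rate
birth–death fit serve as independent cross-checks on small trees.

## Known limitations

* Likelihoods are not corrected for sampling fraction; they are the
  uncorrected forms classical rate-shift analyses used, with the caveat
  surfaced in every fit table.
* The Bonferroni factor for the RC test and its behaviour under
  subsampling inherit the classical test's conservatism; no attempt is
  made to re-calibrate it for incompletely sampled trees.
* The piecewise simulator's expectation-matching crown-age anchor is a
  modelling choice, not an estimate; analyses that need a different crown
  age should pass `crown_age` explicitly.
* Diversity-dependent, trait-dependent and fossilised birth–death
  processes are out of scope.
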