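# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the method description
in the literature is open, and what the synthetic generators do and do not
emulate.

## Replacement index and Zahnreihe segmentation

A tooth family is all generations at one alveolus. With functional crown
length `ℓ_f` and replacement lengths `ℓ_r`, each measurable replacement gets
index `RI = ℓ_r / ℓ_f ∈ (0, ∞)` (values above 1 — a successor outgrowing a
worn functional tooth — are legal and flagged), and the functional tooth
gets `1 + max RI`, or exactly 1.0 with no measurable successor. A family
whose functional tooth has no length is excluded with a warning (no quotient
exists); unmeasurable germs are skipped individually but still counted by
the ontogeny module. The plot series orders points by position, functional
point before replacement points within a position.

**Segmentation.** A Zahnreihe is a degressive sequence: strictly increasing
positions, strictly decreasing indices. The implementation traces waves
greedily through the plot series: each point attaches to the open Zahnreihe
whose last member lies at a strictly earlier position with a strictly
greater index, preferring the nearest preceding position and then the
smallest index drop; if none qualifies, a new Zahnreihe begins. Two facts
drove this choice over the simpler alternative of cutting the series into
maximal strictly decreasing runs:

* On series with one plotted tooth per position the two rules coincide
  exactly (a run boundary is precisely a point with no qualifying
  predecessor).
* On complete dentitions — a functional tooth *and* a germ at every
  alveolus, the situation in well-preserved material — run-cutting
  degenerates: every (functional, germ) pair at one position is its own
  two-point vertical run, every spacing measurement collapses to 1.0, and
  the wave period is unrecoverable. Wave tracing instead follows each
  diagonal line through the functional points and onward into the
  replacement points, which is how the classical plots are read.

Position-gap priority matters: preferring the smallest index drop lets a
wave that has run off the row's end absorb later points of neighbouring
waves (verified to corrupt spacing by up to a factor of 2 on noise-free
input).

Ties in index (equal consecutive values) never extend a Zahnreihe.
Zahnreihen are ordered by (first position, first index ascending), i.e. by
where each wave stands along the jaw.

**Z-spacing.** Each Zahnreihe is a polyline in (position, index) space. For
every member of every Zahnreihe except the last, the next Zahnreihe's
polyline is evaluated at the member's index by linear interpolation and the
position-axis distance is one measurement; indices outside the next
polyline's range are skipped rather than extrapolated (extrapolation invents
geometry the plot does not contain). A single-point polyline matches only
its own index. The summary statistic is the arithmetic mean of all
measurements, reported half-up to 2 decimals. Horizontal (position-axis)
distance is the only reading that yields the dimensionless tooth-position
units in which Z-spacing is conventionally reported.

**Direction.** `Z > 2 + tol` → rostral→caudal, `|Z − 2| ≤ tol` →
alternating, else caudal→rostral. The default `tol = 0` (alternation only at
exactly 2.0) is configurable. The classification describes the travel of the
*wave* along the jaw; note that a rostral→caudal wave with `2 < Z < 3` means
successive new teeth at neighbouring odd- or even-numbered alveoli actually
appear in caudal→rostral order — the two statements are about different
things and are both true. The package reports the wave direction only.

**Summary tables.** Per-side means are rounded half-up to 2 decimals before
grand means are taken, and grand means are computed in decimal arithmetic
from the rounded cells (float accumulation would corrupt the final printed
digit: a true cell mean of 2.4775 must print as 2.478 at 3 decimals).
Half-up rounding throughout matches how measurement tables are printed;
Python's default banker's rounding does not. Grand means are reported at
both 2 and 3 decimals, since published tables use either precision. A side
with fewer than two Zahnreihen yields an empty cell, not a failure. Left and
right sides are never merged: premaxillary waves are known to run
asynchronously between sides in some individuals, and averaging would erase
exactly that signal.

## Odontochronology

Formation time is the couplet count (whole days); DDAR is the unweighted
mean couplet width (no weighting is defensible without per-couplet quality
scores, and the mean is computed over all supplied widths). The conservation
identity `formation_time × DDAR = Σ widths` holds to float tolerance and is
tested. The replacement-rate logic is deliberately narrow: the
formation-time bound applies *only* to a newly erupted tooth with no
successor in its family (the bound's supremum is reported as the point
figure, with an `upper_bound_newly_erupted` qualifier carried everywhere);
any other configuration raises, directing the caller to the family-difference
method (older minus younger increment count), which requires destructive
sampling of two generations. Increment identification on microscope images
is out of scope; the module consumes measured width series.

## Ontogeny summaries

Counts are pure tabulations per element and side: alveoli = tooth families,
replacement teeth split into first and later generations, remnants counted
from flags. The replacement ratio is replacement/functional (undefined at
zero functional teeth; a (low, high) count range yields both ratios).
Ontogenetic order is growth-stage rank with skull length breaking ties;
trend verdicts are plain monotonicity reads (non-decreasing /
non-increasing / flat / mixed) with no statistical test — six-specimen
growth series do not support one.

## Time calibration ('equal' method)

Tips sit at their first appearance date (FAD; the LAD column is validated,
`FAD ≥ LAD`, and retained for optional midpoint dating), internal nodes at
the oldest descendant FAD, and the root is pushed back by `root_extension`
Myr (no published value exists for this constant; it is a required explicit
choice, default 5 Myr in the CLI). Zero-length chains are then resolved: for
each node with a positive incoming branch of duration `L` and a chain of
zero-length descendants, the longest such chain of `k` edges shares the time
equally — every internal node of the chain slides rootward so each of the
`k + 1` branches gets `L/(k+1)`; tip ages never move, and sliding is always
rootward, so no branch ever goes negative. With a positive root extension
every branch ends strictly positive; with zero extension, zero-length chains
hanging from the root remain (there is no time to share). Root-to-tip path
lengths (root age − tip FAD) are invariant under the redistribution — the
total sum of branch lengths is not, since sliding a node stretches all of
its other child edges.

## Mk model, fitting and stochastic mapping

The character is k-state continuous-time Markov with generator Q (rows sum
to zero, off-diagonals ≥ 0). Likelihood is Felsenstein pruning with
per-node rescaling; transition matrices `P(t) = e^{Qt}` are computed by
eigendecomposition vectorised over all branch lengths, with a `scipy`
`expm` fallback for defective Q. Polytomies are hard. The root prior is
flat by default (no published choice exists), switchable to the stationary
distribution of Q.

Fitting maximises the likelihood over log rates (L-BFGS-B, bounds
`e^{−18}`–`e^{8}`, tolerance 1e-8) for ER (1 free rate), SYM (k(k−1)/2) and
ARD (k(k−1)). The ER optimum is found first by bounded scalar minimisation
and seeds the SYM/ARD multistarts (5 starts: the ER solution, a heuristic
scale of a-few-changes-per-tree-length, and seeded log-normal
perturbations); this keeps the nested likelihood ordering
`logL(ER) ≤ logL(SYM) ≤ logL(ARD)` to optimiser tolerance on every dataset
tested. Monomorphic tip data raise a degenerate-data error — no rate is
identifiable. AIC = 2p − 2 logL; Akaike weights follow the standard
formula.

Stochastic maps: node states are drawn from their exact joint conditional
(root from prior × partial likelihood; each child given its parent through
`P(t)` and the child's partials), then each branch history is an
endpoint-conditioned CTMC path — rejection sampling (simulate forward,
accept on matching endpoint) capped at 1000 attempts per branch, then
uniformization (dominating Poisson process at rate `μ = max |Q_ii|`, jump
count drawn from its exact endpoint-conditioned distribution, virtual jumps
discarded). Rejection is exact and almost always accepted at the low rates
typical of morphology; uniformization guarantees bounded runtime when the
endpoints are improbable. Dwell times on every branch sum to the branch
length to 1e-9. Model averaging allocates a map budget (default 1000) by
largest-remainder rounding of the Akaike weights and pools the per-node
state frequencies; the root row of the summary is the ancestral-state
estimate.

## Synthetic generators

* **Dentition**: the noise-free replacement index at position x is the
  degressive sawtooth `RI(x) = 1 − frac((x − phase)/period)` mapped onto
  (0, 1] — the index falls by 1/period per position and resets one full
  wave every `period` positions, which is exactly the piecewise-linear
  degressive geometry of real replacement-index plots. Every alveolus
  carries a functional tooth (lengths from a unimodal profile peaking at
  position 8, as in real maxillary rows) and one germ of length
  `RI × ℓ_f`. Noise is independent multiplicative lognormal with chosen CV
  on every length — lengths are strictly positive, so additive Gaussian
  noise would be wrong at small germs. Defaults: 14 positions, period 2.5,
  no noise; recovery experiments use 16 positions and CV 3%.
* **Increments**: n daily widths, lognormal with exact mean `mean_width`
  (cv = 0 gives constant widths); the count is the ground-truth formation
  time.
* **Mk tips**: states evolved root→tips by exponential waiting times; true
  internal states retained in provenance.

All generators are deterministic under a fixed seed, embed their ground
truth in a provenance dict (recovery tests read truth only from there), and
emit the same file formats the readers consume.

What the generators do **not** emulate: missing or unmeasurable teeth,
broken jaw elements, within-row drift of the wave period, wear-dependent
length bias, left/right asynchrony, and (for the tree generator)
extinct-lineage sampling — trees are pure-birth and ultrametric before
calibration. Passing recovery tests therefore demonstrate correctness of
the algorithms under the stated model, not robustness to every taphonomic
insult of real material.

## Problem sizes in the test suite

Recovery experiments run at sizes chosen to make their statistical
thresholds meaningful: Z-spacing recovery uses 200 replicates per period at
CV 3%; ER rate recovery 100 replicates on a 50-tip tree (generating rate
0.01/Myr, recovery within a factor of 2); SIMMAP calibration 10,000 maps on
a cherry against the closed-form conditional (3 Monte-Carlo SE); the
ancestral-state check 20 runs on 60-tip trees at generating rate 0.001/Myr
with 200 model-averaged maps each. Sixty tips are used for the last check
because on substantially smaller trees a single deep state change onto a
large clade — which genuinely erases the root signal — is common enough to
drop root-mode recovery below the 95% criterion for reasons unrelated to
implementation correctness. Datasets for that check are redrawn until at
least two states are observed, since an Mk fit is undefined on monomorphic
tips.

## Known limitations

* Z-spacing is undefined (by design) with fewer than two Zahnreihen; very
  short or heavily damaged tooth rows yield empty summary cells.
* The wave-tracing segmentation is greedy; pathological index
  configurations (noise CV well above ~10%, or period drift within a row)
  can mis-thread waves. At the CVs measured dentitions plausibly show
  (≤ 5%), recovery is ≥ 95% across periods 1.5–3.5.
* The 'equal' calibration, like all FAD-based scaling, inherits the
  fossil-record bias of its age table; no uncertainty is propagated.
* Model averaging is over three fixed Mk parameterisations; no rate
  heterogeneity across branches and no MCMC over Q (maps condition on the
  ML rate matrix of each model).
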