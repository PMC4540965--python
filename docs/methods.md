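# Methods and design notes

## The two-site coevolution model

A pair of binary characters evolves as a reversible continuous-time Markov
chain on the joint states (00, 01, 10, 11).  Under the mutational
(independent) process each site flips one at a time toward the mutational
state frequencies π₀, π₁; the instantaneous rate of simultaneous
double changes (00→11, 01→10) is exactly zero, as in codon models — double
differences can only accumulate through intermediate states.  Coevolution
is modeled as selection on the joint state: 00 and 11 are equally favored,
01 and 10 equally deleterious, and every mutational rate is multiplied by
the fixation factor f(S) = S / (1 − e^(−S)) when the target state is
favored and by f(−S) when it is not.  S is the population-scaled selection
coefficient (2·Ne·s in haploids); Ne, s and the mutation rate μ never
appear separately — μ is absorbed into the time scale, so t is measured in
expected substitutions of the neutral pair process.  S = 0 recovers the
independent process exactly.

The stationary distribution weights the mutational joint frequencies by
the fixation factor of each state's selective class and normalizes; it is
verified in the tests both as the left null vector of the generator and
through detailed balance π_i Q_ij = π_j Q_ji (the chain is reversible).

Three derived quantities drive the analysis:

* **relative rate** — the stationary substitution rate of the coevolving
  process over that of the independent process, computed directly as the
  ratio of −Σ π_i Q_ii terms (at π = ½ this simplifies to
  2S e^(−S) / (1 − e^(−2S)), which the tests verify to 1e−10);
* **change-class probabilities** — with the start state stationary, the
  probabilities that the two ends of an interval of length t differ at no,
  one, or both sites, from the stationary-weighted entries of
  P(t) = e^(Qt);
* **single fraction** — p_single / (p_single + p_double), the share of
  observable change events that look like independent substitutions.

All headline results use π₀ = π₁ = ½, the most favorable case for
detecting coevolution through covariation.  Representative values (driver
`analysis/01_model_curves.py` recomputes them): at S = 2 the relative rate
is 0.551 and the single fraction at t = 1.0 is 72.3%; at S = 5 the
relative rate is 0.067, and even at t = 2.5 the observable double- and
single-change probabilities are only 0.037 and 0.013.  That is the
coevolution paradox: the selection needed to force compensatory double
changes suppresses observable change almost entirely.

## Covariation metrics

All logarithms are base 2, so two identical evenly split binary columns
reach MI = 1 bit.  Frequencies are raw counts (no pseudocounts, no
sequence weighting); gaps are handled by pairwise-complete deletion.  The
implemented metrics: column entropy, MI, MI / H(X,Y), MIp (the
average-product correction MI(a,b) − MI(a,·)·MI(b,·)/⟨MI⟩), a
permutation-null-corrected MI (observed MI minus the mean MI over
row-shuffled replicates of one column, deterministic given a seed — a
documented stand-in for published background-adjusted MI scores whose
exact formulas live in their own codebases), and the Pearson chi-square
statistic without continuity correction, skipping cells with zero
expectation.  Sparse-inverse-covariance and direct-information scores are
consumed from files, never re-derived.

Invariant columns (≤ 1 distinct non-gap symbol) are removed before any
covariation analysis; the filter reports the surviving columns' original
indices, and all pair tables are keyed by original 1-based columns.

## Parsimony decomposition

Ancestral states are reconstructed with the Hartigan vote-counting form of
Fitch small parsimony, which returns the exact minimum on multifurcating
trees and reduces to classic Fitch on binary trees; an exhaustive
enumeration oracle confirms the counts on all random instances with ≤ 6
leaves and ≤ 3 states.  A single deterministic reconstruction is chosen
top-down: each node takes its parent's state when that state is in its
optimal set, otherwise the alphabetically smallest member; leaves with
missing data inherit the parent's state.  Gaps, `?`, `X` and `.` are
missing data and impose no constraint.  Zero-length branches still count
as branches (branch counts are topological).

For a column pair, branches are classified from the two per-site
reconstructions — double-change if both sites change on the branch,
single-change if exactly one does — while MP_ind is the sum of the two
independent minima and MP_dep the joint-character minimum (equivalently,
the number of branches with any change in the joint reconstruction).
Classification from per-site reconstructions is the default; the joint
reconstruction is available through the same machinery.  The
single:double ratio is +∞ when no doubles occur (ranked last when
selecting small ratios) and undefined (excluded) when no changes occur.

A parsimony rate proxy — Fitch changes per unit tree length — stands in
when no per-site rate table is supplied.  On synthetic data its ranks
correlate strongly with the true simulated multipliers (Spearman ρ > 0.5
in the recovery test), but on a saturated binary alignment it collapses
all invariant columns into an exact tie at rate 0; see "Rate tables versus
the proxy" below.

## Structure and burial

Distances are minimum heavy-atom (non-hydrogen) Euclidean distances; a
pair is a contact below a 10 Å threshold by default, with an optional
minimum sequence separation (default 0).  Relative accessibility comes
from Naccess-style `.rsa` files (relative all-atom column by default) or
from an internal Shrake–Rupley implementation on a deterministic
golden-spiral point mesh, normalized by the Tien et al. (2013) theoretical
maximum ASA per residue type — an approximation, not a re-implementation
of Naccess.  Burial classes: completely buried at exactly 0% relative
accessibility (within 1e−9), core below 10%, exposed otherwise.  Pair
accessibility is the residue-volume-weighted mean, with Zamyatnin (1972)
mean residue volumes shipped as the default table.

## Evaluation

Each metric selects its top floor(L/5) pairs (minimum 1), where L is the
full alignment length — largest first for covariation scores, smallest
first for rate- and parsimony-based predictors — with ties broken by
ascending pair index and undefined scores skipped.  Precision is
successes/predictions against the contact labels.  The random expectation
is a percentile bootstrap: k pairs resampled with replacement from the
metric's own pair universe, 1,000 replicates, central 95% interval,
deterministic given the seed.  Selected-versus-rest comparisons use
two-sided Mann–Whitney tests with Benjamini–Hochberg control across
metrics; fully tied samples return p = 1 with a degeneracy flag.

Two pair universes coexist deliberately: covariation metrics only ever see
invariant-filtered columns, whereas rate- and parsimony-based predictors
rank pairs over **all** columns, invariant ones included — invariant sites
are precisely the slowest and, in a rate-coupled structure, the most
buried.  Each metric family is therefore compared against a bootstrap band
drawn from its own universe.

## The synthetic-data generator

The generator emulates a single well-curated protein family at the scale
the analysis targets: a Yule topology over 48–64 taxa whose exponential
branch lengths are rescaled to a total tree length of 15 (several expected
substitutions per average-rate site — deep but not degenerate divergence);
~100–200 independent binary sites with gamma-distributed rate multipliers
(shape 0.5, mean 1, i.e. strong among-site heterogeneity of the kind +Γ
fits report for enzymes); optional coevolving pairs evolved jointly under
the selection generator at chosen S (default 5, firmly in the
strong-selection regime); and a synthetic structure.  Simulation is exact
event-driven (Gillespie) sampling — no discretization — so empirical
change-class frequencies can be tested against the analytic P(t) (they
agree within 3 binomial standard errors over 20,000 replicates), and the
event log proves no jump ever changes both sites at once.  Ground truth
records every branch's endpoint changes, per-site event counts, the true
rate multipliers, the embedded pairs, and the column shuffle.

The structure generator places sites in a Gaussian blob: each site's
radial percentile is the rank of a ρ-weighted blend of its rate rank with
uniform noise (ρ = 1 makes burial order equal rate order exactly; ρ = 0
decouples them), the radius is the matching χ²(3 df) quantile scaled so
packing density is protein-like (~115 Å³ per residue), and relative
accessibility is a monotone function of the radial percentile with the
innermost 10% of sites completely buried.  Contacts are site–site
distances under the 10 Å threshold; the resulting contact density (~5–10%)
matches globular proteins.  What the generator does **not** emulate:
20-letter alphabets, indels, secondary-structure geometry, chain
connectivity (consecutive sites are not spatial neighbors), or
correlation between amino-acid identity and burial.  Passing tests
therefore demonstrate the internal consistency of the mechanism — low
rate → core → contacts, and the rarity of observable double changes under
strong selection — not performance on real proteins.

## Rate tables versus the proxy

The end-to-end experiments feed the generator's continuous true rates to
the rate predictors, playing the role a per-site rate table from an
external ML fit plays in a real run.  The parsimony proxy is available and
rank-accurate, but on a saturated binary alignment it produces dozens of
exactly tied zero-change columns; the deterministic tie-break then piles
the selected pairs onto a few shared columns, whose spatially correlated
contact labels inflate the variance of precision beyond what iid pair
resampling models.  With continuous rate tables the tie degeneracy
disappears and the null calibration behaves nominally (all metrics inside
the 95% band in 94% of 50 replicate datasets, measured at the conditions
below).

## Problem sizes and numerical choices

Replicated experiments run at: null calibration — 50 datasets of 32 taxa ×
100 sites, tree length 12; paradox signature — 50 datasets of 48 taxa ×
(40 independent sites + 8 coevolving pairs at S = 5), tree length 15, 40
random independent control pairs, pooled counts per replicate, sign tests
across replicates; rate-burial recovery — one dataset of 64 taxa × 194
sites at ρ = 0.9 with k = 38 and a 1,000-replicate band.  These sizes were
chosen to represent a mid-sized protein family while keeping the whole
suite comfortably desk-scale.

Matrix exponentials use eigendecomposition of the π^½-symmetrized
generator (exact for the reversible chains here, stable for stiff
generators at large S), falling back to scaling-and-squaring for
non-reversible input; t = 0 returns the exact identity.  The fixation
factor uses a series expansion for |S| < 1e−6 to avoid 0/0 at the neutral
point.  All randomness flows from one seed through named substreams
(`numpy` `SeedSequence.spawn`), so every generator is bitwise reproducible
and stage-level reruns are byte-identical.

## Known limitations

The model is binary; with 20 amino acids the number of favored joint
states and the mutational connectivity differ, though the qualitative
rate-suppression argument carries over.  S is never estimated from data —
the package characterizes the forward model and decomposes empirical
signal, it does not fit the selection strength.  The internal SASA is an
approximation whose completely-buried calls can differ from Naccess at the
margin, which matters for exact buried-pair counts on real structures.
Reconstruction-dependent quantities (branch classifications) are reported
under one deterministic most-parsimonious reconstruction; other MPRs can
shift individual branch classes, which is why the aggregate scores MP_ind
and MP_dep — invariant across MPRs — accompany them.
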