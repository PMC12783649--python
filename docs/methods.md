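# Methods

This note documents the models, estimators, defaults and design choices
behind `tracnet`, and what the synthetic fixtures do and do not
demonstrate.

## Input model

The unit of analysis is the binary contact fingerprint: a frames ×
contacts matrix with entry 1 when a residue pair is in contact at a
frame. Contact *detection* (distance/angle criteria) is upstream and out
of scope; `tracnet` parses the tab-separated output of such detectors
(`frame  type  CHAIN:RESNAME:RESID:ATOM  CHAIN:RESNAME:RESID:ATOM`).
By default all interaction types between the same residue pair are
collapsed into one column, since the analysis graph is defined over
residue pairs; a flag keeps typed contacts separate. Canonical column
labels put the endpoint with the smaller (chain, resid) first, so (a, b)
and (b, a) observations cannot produce duplicate columns. Water-bridged
records are treated as ordinary protein–protein pair contacts
(configurable): the two protein residues are the endpoints of interest
even when the bridge is solvent-mediated.

## Feature selection

Two filters reduce the full contact set C_all to the significant set C:

* **Neighbor exclusion** drops intra-chain contacts with
  |resid_a − resid_b| ≤ `neighbor_min_separation` (default 1, i.e.
  i ± 1). "Neighboring" is inherently a modelling choice; 1 is the
  minimal reading and the parameter is exposed.
* **MI filter** keeps a contact iff its best pairwise mutual information
  with any other contact exceeds `mi_filter_bits` (default 0.01 bits).
  MI is the plug-in estimate from the empirical 2×2 table, log base 2,
  0·log 0 ≡ 0, with no bias correction — the fixed bit threshold is
  defined against the plain plug-in estimator. Constant columns are
  dropped unconditionally. The full MI matrix is computed blockwise;
  the result is independent of block size.

Per-trajectory survivor sets are combined by **intersection** (default)
or union. Intersection is chosen because each trajectory typically
retains far more contacts than the final cross-trajectory set, which is
consistent with an intersection-like reduction; union (with zero-filled
absences) is available because real ensembles can be heterogeneous.

## Universal dataset

The graph is learned from a single table D^U over C. Concatenation is
lossless but grows linearly with ensemble size; the **enriched** mode
samples `n_per_traj` frames per trajectory uniformly with replacement
from a `region_frames`-wide window (default 5,000 frames total, ±2,500)
centered on that trajectory's macro-transition, concentrating
statistical power where the transition dynamics live. Row provenance
(trajectory, source frame) is recorded for every sampled row, and each
trajectory has its own seeded generator stream (`seed + index`), so
draws are reproducible independent of ensemble composition. A guard
warns above ~1,000 contacts or ~15,000 rows, the practical scale limit
for structure search.

The transition is located on a 1-D proxy trace (one value per frame,
e.g. an interhelical distance) as the **least-squares single change
point** of the smoothed trace: the split minimizing the two-segment
within-segment sum of squared deviations, computed exactly with prefix
sums and returned as the first frame of the second segment. Smoothing is
a centered moving average with shrinking edge windows (window 1 =
identity). This detector was chosen because it is deterministic and
oracle-checkable by exhaustive split scan; a constant trace returns a
distinct "no transition" result, and an externally supplied transition
frame can override the detector. Multiple change points are out of
scope.

## Universal graph

The graph G = (C, E) is a directed acyclic model factorizing
P(C) = ∏ᵢ p(cᵢ | pa(cᵢ)). Structure is found by greedy hill climbing
over add/delete/reverse moves maximizing the decomposable **BIC/MDL**
score: per family, the maximized multinomial log-likelihood (natural
log) of the binary child given each parent configuration, minus
(ln n / 2)·2^k free parameters for k parents. BIC was selected because
it is standard, decomposable and closed-form checkable; the parent cap
is `max_parents` = 3. Restart 0 starts from the empty graph and further
seeded restarts (default 2) from sparse random DAGs; candidate moves are
scanned in a fixed label order, so equal-score ties always resolve
identically and the search is deterministic given (data, seed). Constant
columns are rejected (strict mode) or dropped with a warning.

**Edge strength** is defined as the plug-in pairwise MI (bits) of the
edge endpoints over D^U — one unit shared with the time-resolved layer —
and the weighted degree Dᵢ sums incident strengths, direction ignored.
The node neighborhood Γᵢ used downstream is parents ∪ children (moral
co-parents excluded), i.e. plain graph adjacency. Exact structure
learning, parameter posteriors and dynamic Bayesian networks are
non-goals: the universal graph is a static superset of dependencies that
the time-resolved layer localizes in time.

## Time-resolved rescoring

For each trajectory and each edge (i, j), the windowed MI

MI_t(i, j | δ) = H(Xᵢ,w) + H(Xⱼ,w) − H(Xᵢ, Xⱼ, w),  w = [t − δ, t + δ)

is evaluated on a stride of times (default every 10 frames), maximizing
over a grid of **full window lengths** (default 150, 300, …, 1050
frames; δ is the half-width). Conventions worth stating:

* The grid is read as full lengths 2δ; both this and the grid itself are
  configurable.
* The maximization is per edge *and per time point* (the most granular
  reading); per-edge global window choice is a mode.
* Plug-in MI inflates in small windows, so ties resolve toward the
  **largest** feasible window. An optional Miller–Madow correction
  exists but is off by default, keeping the estimator consistent with
  the fixed bit thresholds.
* Evaluation times are restricted to where the smallest window fits, so
  every edge has a value at every evaluated time and the community trace
  Dᵢ(t) = Σ_{j∈Γᵢ} MI_t(i, j | δ) is an exact sum of the stored per-edge
  traces. Where no window fits the value is missing, never zero.

## Signal analysis

A trace's **amplitude** in a trajectory is max_t Dᵢ(t). Peaks are local
maxima strictly above `peak_threshold_bits` (default 1.0 bit; a
data-driven alternative — one pooled standard deviation of all trace
values — is provided), separated by at least `min_peak_separation`
frames (default twice the largest window, so one transition event never
counts as two peaks; the higher of two conflicting maxima wins; plateau
maxima report their center). Ranking sorts contacts by the number of
trajectories above threshold, then mean amplitude, then label. Key TRACs
must (1) exceed the threshold, (2) do so in every trajectory, and
(3) show at most `max_peaks` (default 2) peaks per trajectory — the
macro-transition criterion. A 2.0-bit preset exists for handing a
stricter contact set to the conservation analysis. Enabler/effector
order uses strict **first-peak** precedence in every shared trajectory
(ties or a single flip → unordered); trajectories where either node
lacks peaks are excluded and counted. Connectors are nodes adjacent
(direction ignored) to both hubs.

## State analysis

PCA over the fingerprint restricted to a contact subset (typically the
enabler + effector subnetwork) uses column centering **without**
unit-variance scaling — autoscaling 0/1 columns over-weights rare
contacts — and SVD, with each component's sign fixed by making the
largest-magnitude loading entry positive. States are assigned by seeded
k-means (n_init = 10, capped iterations) on the scores and renumbered by
first occurrence, so state 1 always contains the first frame. The
number of states is user-set (default 3: before/between/after two
transitions). Free-energy estimation and Markov state modelling are
non-goals.

## Conservation and specificity

Per alignment column, residue frequencies P (gaps dropped and
renormalized; columns over 50% gaps are flagged low-confidence) and a
similarity matrix S define the density matrix
ρ = P^{1/2} S P^{1/2} / tr(·). The symmetric P^{1/2}SP^{1/2} form is
used because it guarantees a real, non-negative spectrum, which the
asymmetric P·S product does not; the trace-normalized P·S variant is
available for comparison. S comes from BLOSUM50 (via biopython):
entries are min-max mapped to [0, 1] and rescaled to a unit diagonal
(s_ab = b′_ab / √(b′_aa b′_bb), clipped to [0, 1]), since raw log-odds
scores are not usable as similarities. The column entropy is
Sᵢ = −Σ λ log₂₀ λ over eigenvalues of ρ (eigenvalues below 1e−12
treated as zero), so the maximum is exactly 1 and the conservation score
is Cᵢ = 1 − Sᵢ. This module is the only place the logarithm base is 20;
all MI quantities are in bits.

Specificity works on a supplied position subset: a position is *fully
conserved* if one residue type occurs in all sequences of all classes
(any gap disqualifies, configurable), and *perfectly specific* to a
class if the class is invariant at the position and its residue never
occurs there in any other class. The ratio ρ = log₂|S|/|C| uses ±∞/NaN
sentinels for empty sets.

## Synthetic fixtures

`generate_ensemble` plants the structure the method assumes: each
community follows a latent two-state signal that switches once (the
enabler community early, the effector late, jittered per trajectory);
members copy the latent state with probability `coupling`, else draw a
fair coin; background contacts are independent two-state **Markov**
chains (flip rate 0.02/frame) rather than i.i.d. noise, so windowed MI
faces realistic autocorrelation; and a proxy trace steps down at the
effector switch with Gaussian noise, tying the change-point detector and
enriched sampling into the same workflow as real data. Defaults — 12
trajectories × 8,000 frames × 40 contacts, two communities of 5 at
coupling 0.95 switching at 3,000 and 5,000 ± 200 frames, 30 background
contacts — are the study condition used by the end-to-end tests; the
worked example and some unit fixtures use smaller instances of the same
generator for speed, and the test suite states the sizes it uses.

What passing on this generator shows: the pipeline recovers planted
dependency communities, their switch times and their order under
realistic autocorrelated noise at desk scale. What it does not show:
behavior on real MD contact data, whose communities are not two-state,
whose couplings drift, and whose contact counts are an order of
magnitude larger — headline analyses of real receptor ensembles depend
on external multi-microsecond trajectories and curated alignments and
are outside the test scope. `generate_msa` likewise plants conserved and
class-specific columns with controllable background diversity for exact
round-trip checks of the specificity classifier.

## Numerical and degenerate-input conventions

* All MI estimators share 0·log 0 ≡ 0 and clamp tiny negative rounding
  to 0; the pairwise estimator sums its per-cell terms in sorted order,
  making MI(x, y) = MI(y, x) bit-exact.
* Constant streams/columns yield MI 0 and are dropped (filter) or
  rejected/dropped with warning (structure learning).
* A constant proxy trace yields "no transition", distinct from any
  frame index.
* Empty neighborhoods yield valid all-zero traces, flagged; graph nodes
  missing from a trajectory's columns are treated as constant zero with
  a warning.
* Hill-climbing accepts a move only above a 1e−9 score gain; the search
  and k-means are seeded; sampling uses per-trajectory generator
  streams.
* Fingerprint serialization is self-describing plain text with an end
  marker, so truncation is detected rather than silently accepted.

## Pipeline

`run_pipeline` executes the stages in order from one YAML config
(unknown keys rejected; all violations reported at once; defaults:
0.01-bit filter, 1.0-bit peak threshold, 2.0-bit handoff preset,
150–1050 window grid, 5,000-frame region). Every stage persists its
artifacts, so downstream stages can be re-run from upstream outputs —
structure learning is the slow stage and the rescoring layer is
re-runnable per trajectory without relearning the graph. The manifest
records parameters, the seed, stage timings and artifact checksums;
reruns with the same config and inputs are bit-identical. A failed stage
leaves a FAILED marker naming the stage and keeps partial outputs.

## Known limitations

* The BIC-based search is a heuristic: on real-scale data (hundreds of
  nodes) the learned edge set is a local optimum and will differ
  edge-by-edge between score functions and implementations, even on
  identical data; downstream conclusions should rest on communities and
  their timing, not on individual edges.
* Single change point only; multi-step transitions need external
  transition frames.
* The plug-in MI bias floor (~1/(2n ln 2) per degree of freedom) sets
  the smallest detectable windowed dependency; the smallest grid window
  (150 frames) bounds time resolution from below, and the bias guard
  (tie toward large windows) trades a little localization for estimator
  stability.
* Continuous-valued features are unsupported by design: the model is
  defined over binary contacts.
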