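# tracnet

Time-resolved probabilistic-network analysis of residue-contact dynamics
from molecular-dynamics (MD) simulations.

## The problem

Proteins such as G-protein-coupled receptors (GPCRs) switch between
conformational macro-states (e.g. active and inactive). Long MD
trajectories can capture these transitions, but locating *which residue
communities enable and effect a transition, and when*, is buried in
millions of frames of pairwise contact data. `tracnet` is for structural
bioinformaticians who have an ensemble of transition-containing
trajectories — encoded as binary residue-contact fingerprints — and want
an interpretable, fully data-driven account of the transition machinery.

## The method

Each trajectory is a frames × contacts 0/1 matrix (contact formed or
not, as produced by an upstream contact detector such as GetContacts).
The analysis proceeds in five steps:

1. **Feature selection.** Sequence-neighbor contacts are excluded, and a
   contact is kept only if its pairwise mutual information (plug-in
   estimate, bits) with some other contact exceeds 0.01 bits in a
   trajectory; per-trajectory survivor sets are intersected into the
   significant set *C*.
2. **Universal dataset.** Frames are sampled with replacement from a
   5,000-frame region centered on each trajectory's macro-transition
   (located on a 1-D transition proxy, e.g. a TM3–TM6 interhelical
   distance, by least-squares change-point detection), giving the
   transition-enriched table *D^U*.
3. **Universal graph.** A directed acyclic graphical model *G = (C, E)*
   is learned from *D^U* by greedy score-based search (BIC), factorizing
   the joint distribution as P(C) = ∏ᵢ p(cᵢ | pa(cᵢ)). Edges are direct,
   non-transitive dependencies; edge strength is the endpoint MI in bits,
   and the weighted degree Dᵢ sums a node's incident strengths.
4. **Time-resolved rescoring.** Along each trajectory, every edge (i, j)
   is rescored with sliding-window MI, MI_t(i, j | δ) = H(Xᵢ) + H(Xⱼ) −
   H(Xᵢ, Xⱼ) over the window [t − δ, t + δ), maximizing over a grid of
   window sizes (150–1050 frames). The time-resolved weighted degree of
   contact i and its neighborhood Γᵢ — its time-resolved allosteric
   community (TRAC) — is Dᵢ(t) = Σ_{j∈Γᵢ} MI_t(i, j | δ).
5. **Signal analysis.** Peaks of Dᵢ(t) above 1 bit are detected;
   contacts are ranked by ensemble prevalence and amplitude; key TRACs
   must exceed the threshold in every trajectory with at most two peaks
   each; strict first-peak precedence across all trajectories labels one
   community the *enabler* and the other the *effector* of the
   transition, and contacts adjacent to both hubs are their *connectors*.

Companion modules delineate conformational states by PCA over the
enabler + effector subnetwork, and score the evolutionary conservation of
alignment positions with a chemistry-aware Von Neumann entropy
(BLOSUM50-weighted density matrix, base-20 logarithm, conservation score
Cᵢ = 1 − Sᵢ) plus a specificity ratio ρ = log₂|S|/|C| over fully
conserved and class-specific positions.

## Worked example

The bundled generator plants two coupled contact communities that switch
at different times inside otherwise-independent Markov background
contacts — the statistical structure the method assumes:

```python
import numpy as np
from tracnet import (
    generate_ensemble, exclude_neighbors, mi_filter, combine_features,
    detect_transition, enriched_sample, learn_structure, edge_strengths,
    trac_traces, rank_contacts, find_peaks, classify_order,
)

matrices, traces, truth = generate_ensemble(
    n_trajectories=4, n_frames=6000, n_contacts=24,
    communities=((4, 0.95), (4, 0.95)),
    t_enabler=2200, t_effector=3800, jitter=150, seed=42)

kept = []
for m in matrices:
    _, report = mi_filter(exclude_neighbors(m))
    kept.append(set(report.kept))
C = combine_features(kept)
print(f"significant contacts: {len(C)} of {matrices[0].n_contacts}")

restricted = [m.restrict(C) for m in matrices]
transitions = [detect_transition(t) for t in traces]
print(f"detected transitions: {transitions}")

data = enriched_sample(restricted, transitions, n_per_traj=1200, seed=42)
graph = edge_strengths(learn_structure(data, seed=42), data)
print(f"universal graph: {len(graph.nodes)} nodes, {len(graph.edges)} edges")

all_traces = {m.trajectory_id: trac_traces(m, graph) for m in restricted}
ranking = rank_contacts(all_traces, threshold=1.0)
for node in ranking.ranking[:4]:
    amps = ranking.amplitudes.loc[node]
    print(f"  {node}: above 1 bit in {ranking.n_above(node)}/4 trajectories, "
          f"mean max D_i(t) = {amps.mean():.2f} bits")

enabler = next(n for n in ranking.ranking if truth.community_of[n] == 0)
effector = next(n for n in ranking.ranking if truth.community_of[n] == 1)
peaks_e = {t: find_peaks(all_traces[t][enabler]) for t in all_traces}
peaks_f = {t: find_peaks(all_traces[t][effector]) for t in all_traces}
label, report = classify_order(peaks_e, peaks_f)
print(f"order({enabler}, {effector}) = {label} "
      f"({report['a_first']}/{report['n_compared']} trajectories)")
```

Output:

```
significant contacts: 10 of 24
detected transitions: [3714, 3681, 3684, 3793]
universal graph: 10 nodes, 22 edges
  A:ALA:90_A:PHE:186: above 1 bit in 4/4 trajectories, mean max D_i(t) = 2.78 bits
  A:GLU:158_A:GLY:181: above 1 bit in 4/4 trajectories, mean max D_i(t) = 2.54 bits
  A:GLU:258_A:SER:383: above 1 bit in 4/4 trajectories, mean max D_i(t) = 2.52 bits
  A:ARG:267_A:GLY:281: above 1 bit in 4/4 trajectories, mean max D_i(t) = 2.50 bits
order(A:ALA:90_A:PHE:186, A:GLU:158_A:GLY:181) = a_precedes_b (4/4 trajectories)
```

The MI filter recovers exactly the ten planted community members; the
change-point detector lands on the planted effector switch (~3,800,
jittered per trajectory); the learned graph connects the communities;
ranking puts community members on top; and the early-switching community
is classified as preceding the late one in every trajectory — the
enabler/effector call.

The same workflow is available as a CLI over a YAML config:

```sh
tracnet synth --seed 3 --out demo_data --n-trajectories 3
tracnet run-all config.yaml        # or: ingest/select/dataset/learn/rescore/signals/states/evolve
```

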