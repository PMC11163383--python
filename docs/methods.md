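# Methods

This note documents the model, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Model and assumptions

The method assumes that (i) a true complex's members are co-active in time
or co-located in space, so interactions lacking both witnesses are noise;
(ii) complexes have core–attachment structure — a dense, coherent core plus
loosely attached peripherals; and (iii) RNA-mediated co-regulation is
evidence for protein association even when a direct PPI record is missing
(two proteins sharing a regulator RNA become meta-path neighbours).

**Activity.** A protein is active at time *t* when its expression reaches
`u + k·σ·(1 − 1/(1+σ²))`. The comparison is `≥`, so a zero-variance protein
(threshold = mean) counts as always active rather than never; discarding
constitutively expressed proteins would be biologically wrong. The rule's
σ-dependent correction keeps the threshold near the mean for quiet profiles
and near `u + k·σ` for strongly varying ones.

**Edge filter.** Retention requires a nonempty shared-active-time set OR a
nonempty shared-compartment set (either witness suffices). Candidate cores
are later re-checked at group level: all members must share one time point
or one compartment, which is strictly stronger than pairwise overlap.

**RNA partners.** "Above average" is read per protein, over the scores
recorded for that protein (not over all RNAs — most pairs have no recorded
score, and imputing zeros would make the mean meaningless). The comparison
is strict, so a protein with a single recorded association keeps no
partner.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 1.0 | activity-threshold multiplier; larger → sparser network (0–3 is the sensible range) |
| `lam` (λ) | 0.4 | adhesion threshold for attachments, in cosine units [0, 1] |
| `hidden_dim` (d) | 128 | embedding dimension; the best-performing size in sensitivity scans |
| `feature_dim` (h) | 64 | learnable initial feature rows per node |
| `tau_stru`, `tau_pat` | 0.5 | InfoNCE temperatures |
| `epochs` / `lr` | 400 / 5e-3 | Adam, early stop on a 10-epoch moving-average plateau (patience 50) |
| `dropout` | 0.3 | on projected features; small networks overfit contrastive objectives quickly |
| `topk` | 10 | per-row sparsification degree of the deep-domain adjacency |

Training hyperparameters (temperatures, optimiser, learning rate, epochs)
are this package's own choices; the method definition does not fix them.

## Numerical and design choices

- **Autodiff.** No GPU framework is used; the encoder and losses are built
  on a compact reverse-mode autodiff engine over float64 numpy arrays
  (`_autodiff.py`). Training is exactly reproducible for a fixed seed.
- **Weight constraints.** The pattern weights are free parameters passed
  through a softmax (wide-domain α, keeping the combination convex) and a
  sigmoid (deep-domain ε, bounding the Gram-matrix scale). The deep-domain
  `normalize(D·Dᵀ)` is: zero the diagonal, then symmetric degree
  normalisation `Λ^(-1/2) S Λ^(-1/2)`; all-zero rows map to zero rows.
- **Sparsification.** The dense deep-domain adjacency is pruned to each
  node's top-10 entries, union-symmetrised. The *support* is frozen at
  initialisation (uniform ε); the *weights* on that support are recomputed
  differentiably every step, so α and ε still receive gradients through the
  attention logits. Recomputing a discrete top-K support each step is
  non-differentiable and would only jitter the neighbourhoods.
- **Attention.** Node-level logits are `LeakyReLU(μᵀ[h_p‖h_q])` (slope
  0.2) plus `log(w + 1e-8)` for the pattern-adjacency edge weight, which
  preserves the softmax form while letting layer support shift attention.
  Empty neighbourhoods yield zero vectors, not errors. Activation is ELU.
  Type-level scores average `μᵀ tanh(Wz + b)` over **all** protein nodes.
- **Meta-paths.** Fixed to protein–protein–protein (two hops in the
  pattern adjacency) and protein–RNA–protein (shared selected RNA partner);
  the graph convolution is exactly one layer with the
  `1/√((d_p+1)(d_q+1))` normalisation and `1/(d_p+1)` self term.
- **Loss.** `L = L_stru(wide) + L_stru(deep) + L_pat`: each aggregator has
  its own inter-view term (both are summed) plus one inter-pattern term.
  No projection head; cosine similarities are used directly. The positive
  pair sits in the denominator along with the negatives.
- **Reweighting.** Cosine weights are assigned on the *input* PPI edge set
  (after dedup/self-loop removal), not the filtered one; the group-level
  co-activity check on candidate cores is what enforces spatiotemporal
  coherence at identification time.
- **Core mining.** Maximal cliques come from Bron–Kerbosch with pivoting
  (networkx). Density `d_s` sums each unordered pair once (doubling would
  not change the ranking). Ties break by larger size, then lexicographic
  member order, making extraction invariant to edge ordering. An
  overlapping candidate's non-overlapping remainder re-enters the pool if
  it still has ≥ 3 proteins *and* still passes the co-activity check
  (removing the witness member can invalidate it); remainders are not
  required to be cliques.
- **Enrichment.** The hypergeometric upper tail is evaluated with
  `scipy.stats.hypergeom.sf` (log-space internally); the tests cross-check
  it against exact binomial-coefficient sums on small universes.
- **Mismatch count.** The disagreement between an identified and a
  reference complex is reported as `max(#extra, #missing)`. This convention
  is inferred from worked examples (it reproduces all nine published
  counts), not from a published definition — treat it accordingly.

## Synthetic benchmark

The generator plants `n_complexes` disjoint complexes: a core (3–6
proteins, within-core edge probability 0.9) plus 0–3 attachments each
linked to at least half the core. All members share a 4-point activity
window out of T = 12 time points and a home compartment from the canonical
11; expression is baseline 3.0 + amplitude 2.0 inside the window with
Gaussian noise (σ = 0.3), a regime in which the k = 1 threshold recovers
the window for ≥ 95 % of members. Background proteins get their own random
windows and compartments (metabolic-cycle-like periodicity, not flat
noise), and background edges appear with probability 0.02. Each complex
gets 2 regulator RNAs scoring 0.7–0.95 against its members; decoy RNAs
score 0.05–0.4 against random proteins, so per-protein mean-thresholding
keeps regulators and drops most decoys. Defaults (300 proteins,
20 complexes) mirror yeast-scale structure at desk size; the acceptance
run and the end-to-end tests use exactly these conditions.

What passing on this benchmark shows: the pipeline's stages compose
correctly and recover planted structure under realistic activity noise,
and removing the spatiotemporal constraints does not help. What it does
not show: performance on real PPI networks, whose degree distributions are
scale-free, whose complexes overlap heavily, and whose localisation and
expression annotations are incomplete and biased — none of which the
generator emulates.

## Known limitations

- Planted complexes are disjoint; the overlap-pruning step (4) is
  exercised by unit traces but not stress-tested by the benchmark.
- Full-graph training is O(n²) per epoch in memory and time; the intended
  scale is 10²–10⁴ proteins, not full interactomes on one core.
- The encoder computes RNA-node embeddings internally but only protein
  embeddings are exported.
- With no expression table (e.g. human data), the time layers vanish and
  the pattern stack degenerates to spatial layers only; the code handles
  this but it has weaker constraints.
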