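# Methods

## Problem and model

Disease-causing missense variants are not uniformly distributed over a
protein: they concentrate at residues whose interactions hold the fold
together or mediate its motions.  `hotspotnet` predicts such hotspot *sites*
(residue positions, not specific amino-acid substitutions) from a residue
contact-probability matrix `P`, which can be produced by sequence-only
coevolution predictors or derived from 3-D coordinates.  The pipeline has
three stages: build contact networks, compute per-residue node-importance
scores, and combine the scores with tree-ensemble classifiers trained on
labelled deleterious/neutral sites.

## Contact networks

A `ContactMap` stores a symmetric, zero-diagonal matrix with entries in
[0, 1].  Loaders symmetrize as `(P + P')/2` (predictors occasionally emit
slightly asymmetric matrices; averaging is more useful than rejection) and
clamp entries within 0.01 of the valid range, erroring beyond that.  Two
constructions are supported:

- **Predictor output** — CASP-RR records (`i j d_low d_high p`) or a dense
  matrix.  Unlisted RR pairs get probability 0.
- **Coordinates** — `P_ij = 1 / (1 + exp(d_ij − c))` with soft cutoff
  `c = 10 Å`, so a pair at the cutoff distance has probability 1/2.
  Distances use Cα atoms: every residue has one, and at a 10 Å scale the
  choice of reference atom shifts probabilities only marginally; the cutoff
  is configurable.

The weighted map is used directly wherever an algorithm accepts edge
affinities.  Centralities defined on unweighted graphs use a pruned network:
edges with `P_ij < 0.1` removed, survivors set to weight 1.  Backbone pairs
`(i, i+1)` are always kept, which guarantees connectivity — several
centralities (current-flow, second-order) are undefined on disconnected
graphs, and the bonded chain is physically always present.

## The 20 scores

Weighted degrees: `W_n,i = Σ_{k≠i} (P^n)_ik` for n = 1, 2, 3; `W_∞` is the
principal eigenvector of P (the n → ∞ limit of the normalized `W_n`), with
unit norm and sign fixed by a positive entry sum; `W_s` is the node degree of
the shared-neighbour similarity network `S_ij = Σ_{k≠i,j} P_ik P_jk`, which
for zero-diagonal symmetric maps coincides exactly with `W_2` (kept as a
separate operation and verified against a nested-loop oracle in the tests).

Classical centralities C1–C13 (degree, eigenvector, closeness, betweenness,
current-flow closeness/betweenness, communicability betweenness, load,
subgraph, harmonic, second-order, Laplacian, Katz) use the NetworkX
implementations.  Weighted-affinity scores (C1, C2, C9, C12, C13) run on the
full weighted map — C1 is computed directly as weighted degree/(n−1) because
the library's degree centrality ignores weights; the Katz attenuation factor
is set to 0.85/λ_max to guarantee convergence on any map.  Path- and
flow-based scores (C3–C8, C10, C11) treat weights as distances and therefore
run on the pruned unweighted network.  Both modes are reachable through the
public functions if a different assignment is wanted.

Sequence-GNM scores: the Kirchhoff matrix has `K_ij = −1` for bonded pairs
(overriding the predicted probability — local chain connectivity is a fact,
not a prediction), `K_ij = −P_ij` otherwise, and a diagonal balancing each
row to zero.  `MSF_i = Σ_{m>0} V_mi² / λ_m` is the mean-square fluctuation
(pseudo-inverse diagonal).  The perturbation score formalizes "uniformly
weakening the contacts of residue i" as scaling its off-diagonal couplings by
(1 − ε) with the diagonal re-balanced; first-order perturbation theory gives
`δλ_m,i = −ε Σ_j |K_ij| (V_mi − V_mj)²`, and the reported score is the
ε-normalized magnitude of the summed shifts — parameter-free, and equal for
any small ε (the summed shift is linear in the perturbation, so the
first-order form is exact for the total; the tests verify this against full
re-diagonalization).  Zero modes are detected at `λ < 1e−9·λ_max`; dense
`eigh` is used throughout since chains are ≤ 500 residues.

All scores are percentile-normalized within each protein — average ranks for
ties, mapped as `(rank − 1)/(n − 1)`, constant vectors to 0.5 — so features
are comparable across proteins of different length and contact density.

## Classification

Feature tables hold one row per labelled site and one column per
`source:score` percentile (optionally plus external per-site columns such as
language-model variant scores).  Splits are always by protein, never by
site, to prevent within-protein leakage.

Models are RandomForest, GradientBoosting (scikit-learn), and XGBoost.
Hyper-parameters are drawn by seeded random search: `max_depth` ∈ [2, 16]
and `n_estimators` ∈ [50, 800] for all; `max_features` ∈ (0.1, 1] for
RF/GB; log-uniform `reg_alpha`, `reg_lambda` ∈ [1e−4, 10] for XGB (ranges
bracket the library defaults).  Candidates are scored by mean ROC-AUC under
protein-grouped 5-fold cross-validation.  Selection uses the
one-standard-error rule — the least complex candidate (smallest depth, then
fewest trees) within one SE of the best mean — because with a handful of
grouped folds the plain CV maximum is noisy and systematically prefers
over-deep trees that generalize worse; the 1-SE rule is the standard remedy.
The winner is refit on all training rows.  Everything is deterministic given
the seed.  Class weighting is off by default (a `class_weight` flag exists);
missing feature values are rejected rather than imputed.

Evaluation: ROC by threshold sweep, AUC by trapezoid (identical to the
tie-corrected Mann-Whitney statistic), sensitivity/specificity at the
Youden-J-maximizing threshold — a conventional operating point that needs no
tuned cutoff.

## Synthetic cohorts

The generator emulates the structure of a real variant-annotated cohort:

- **Chains** — self-avoiding random walks, bond length 3.8 Å, non-bonded
  clearance 4.0 Å, confined to a sphere of radius `3·n^(1/3)` Å.  The
  confinement creates a contact-rich core and sparse surface like a globular
  protein; there is no secondary structure or sequence-dependent topology.
- **Maps** — the true map comes from the soft-cutoff transform of the chain;
  predictor noise is emulated by symmetric Gaussian perturbation on the
  logit scale (sigma per source), preserving symmetry, the zero diagonal,
  and the [0, 1] range.
- **Labels** — sites sampled without replacement are deleterious with
  probability `expit(intercept + beta · W1-percentile of the true map)`,
  mirroring the concentration of disease variants at highly connected core
  residues.  Driving labels from the *true* map keeps the Bayes-optimal AUC
  exactly computable from the stored latent probabilities; driving them from
  a corrupted map would confound noise with signal.

Default cohort: 30 proteins of 40–80 residues, three sources at sigma 1.0,
beta 6, intercept −1.5, 20 sites per protein.  Sizes keep the full pipeline
within minutes on one CPU while leaving ~600 sites for training/evaluation;
20 sites on 40–80-residue chains matches the site density (roughly a quarter
of positions labelled) typical of variant-rich curated proteins.  Sub-seeds
come from `SeedSequence([seed, protein_index, stream])`, so extending a
cohort never perturbs existing proteins.

Because chains are not real folds and the noise model is exchangeable across
pairs, passing tests demonstrate that the pipeline recovers a planted
connectivity signal under predictor-like noise — not that any particular AUC
will transfer to real proteins or any specific predictor's error profile.

## End-to-end evaluation protocol

On the default cohort, all three algorithms are trained on the combined
3-source × 20-score table (70% of proteins) with 16 tuning trials and
evaluated on held-out proteins.  The *combined model* reported is the
algorithm with the best grouped-CV AUC on the training split — model
designation, like tuning, never sees the test partition.  Reference points:
the cohort's Bayes AUC, the best single-score AUC on the same test sites
(evaluated per score, as in per-score benchmark tables), and the 7-score
ablation (degrees + GNM only, no classical centralities), which runs ~20×
faster and is expected to trail the full set only marginally since the
top-performing scores are strongly correlated.

## Numerical choices and edge cases

- Iterative/linear-algebra centralities rely on deterministic dense solvers;
  convergence failures raise an error naming the score.
- Eigenvector sign ambiguity is fixed by requiring a positive entry sum.
- `subgraph_centrality` exponentiates the weighted spectrum; on very dense
  high-weight maps this can overflow — real and synthetic contact maps are
  sparse enough in practice.
- A contact map must be ≥ 2 residues; the GNM requires ≥ 3; pruning cutoffs
  must lie in (0, 1]; labels must be binary with unique (protein, position)
  keys.
- Percentile normalization of a length-1 vector returns 0.5.

## Known limitations

- The unit of prediction is the site; per-substitution effects are out of
  scope, as is building contact predictors or structure prediction itself.
- Single-chain proteins only; no multi-chain or complex contact maps.
- The weighted-vs-pruned assignment of C1–C13 follows each algorithm's
  weight semantics; other assignments are defensible and reachable via the
  API, but only the shipped assignment is benchmarked.
- On cohorts where one percentile score sits at the Bayes ceiling, tree
  ensembles can trail the best single score slightly; the ensemble gain
  grows when sources are noisier or complementary.
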