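# Methods

## Model overview and assumptions

The predictor assumes that OGT substrate preference is encoded in the
short sequence flank of the modified residue and that it is
heterogeneous: rather than one consensus, there are several motif
families (e.g. a hydrophobic-flank family and a polar-flank family),
each best described by its own position-specific model. The pipeline
therefore (1) partitions the positive 11-mer windows into motif
subgroups by maximal dependence decomposition, (2) fits one profile HMM
per subgroup, and (3) lets an RBF-kernel SVM arbitrate between the
subgroup bit scores. All windows are fixed-length and pre-aligned on
the central S/T, which removes any need for insert/delete structure in
the default models (see "Profile HMM architecture").

## Peptide windows

Windows have half-width `w = 5` (11-mers). Termini are padded with `-`
rather than discarding near-terminal sites; `-` is carried through the
whole stack as a 21st emission symbol with its own background
frequency, so terminal windows remain scoreable and comparable.
Coordinates are 1-based and fully closed, matching UniProt site
conventions. Unknown residues ingest as `X`; `X` belongs to no
physicochemical group (it is skipped in contingency counts) and is
scored by the HMMs as a neutral wildcard contributing 0 bits, because a
hard error on `X` would make real proteins unpredictable. Within-class
duplicate fragments are removed; a fragment occurring in both classes
is kept in both with a logged warning, since collapsing it either way
would silently bias one class.

## Amino-acid grouping

The default five-group partition is polar {S,T,C,N,Q,Y}, acidic {D,E},
basic {H,K,R}, hydrophobic {A,G,I,L,M,P,V}, aromatic {F,W}. The scheme
is a configuration value (a two-column text table) because grouping
conventions differ between labs; everything downstream adapts
automatically. Tie-breaks over groups use the fixed order polar <
acidic < basic < hydrophobic < aromatic.

## MDD clustering

For each pair of non-center positions, a 5×5 contingency table of group
co-occurrence is built (fragments with `X`/`-` at either position are
skipped) and scored with the chi-squared statistic; cells with zero
expected count contribute zero. A node splits when the maximal pairwise
statistic exceeds 34.3, the upper 0.005 quantile of χ² with 16 degrees
of freedom. The split position maximizes the aggregate D_i = Σ_j
χ²(A_i, A_j) (ties to the smaller offset), and the split group is the
modal group at that position — this aggregate rule is one of several
reasonable readings of "the position with maximal dependence", and is
the package's choice; it produces the expected binary
has-group/lacks-group trees. The center position is excluded (constant
by construction). Recursion stops when a node falls below `min_size`
(default 30), when no pair is significant, when the proposed
(position, group) was already used on the path, or when a child would
be empty. Leaves are labeled OGT1, OGT2, ... depth-first,
with-branch-first.

**Known behavior:** 45 position pairs are tested per node at the 0.005
level, so a dependence-free node of ~100 fragments still splits
spuriously roughly 20–30% of the time (multiplicity, plus mild
chi-squared inflation from sparse cells for the rarer groups). This is
intrinsic to the splitting rule; `min_size` bounds the resulting
fragmentation, and the second layer is robust to a few noisy extra
leaves. Raising `chi2_cutoff` monotonically prunes the tree.

## Profile HMM architecture

Because training fragments form a gapless fixed-length alignment, the
default model is purely positional: match emissions only, with the
transition leak to insert/delete states set to 0, so a bit score is the
per-position sum of log2 emission odds and the closed form
11·log2(20) ≈ 47.54 bits holds exactly for a pseudocount-free consensus
under the uniform null. The full forward algorithm over
match/insert/delete states is implemented for leaky models (`leak > 0`)
and variable-length queries, and doubles as the independent oracle for
the gapless fast path in the tests.

Estimation uses background-weighted additive smoothing: emission =
(count + α·null) / (n + α) with pseudocount α = 1 by default. The null
model is uniform 1/20 over letters, with `-` given its empirical
padding frequency in the training fragments (an empirical pooled null
is available). Zero-probability cells are floored at 1e-12 when taking
logs so every scoreable fragment gets a finite score. Per-model
bit-score thresholds are calibrated by scanning midpoints of the
observed scores and maximizing accuracy (or Youden's J) on the supplied
positives/negatives; ties take the smaller threshold, favoring
sensitivity. E-values are deliberately not computed — the pipeline
thresholds on bit scores only.

## Negative balancing

Negatives are encoded per-position one-hot over the 21 symbols
(group-level one-hot is available) and clustered with k-means, k equal
to the positive count (seeded, single initialization, ≤ 50 iterations);
the member nearest each centroid is selected. Should a cluster come
back empty, the shortfall is backfilled with the unchosen fragments
nearest their own centroids, so the output is always exactly k distinct
input fragments. Selecting representatives rather than sampling keeps
the negative set spread over sequence space.

## Second layer

Features are the k bit scores in fixed leaf order, unscaled (they share
the bit as a unit; optional z-scaling would be stored with the model if
enabled). (C, γ) are chosen on a log2 grid by mean cross-validated
accuracy with a stratified k-fold (default 5) split; ties prefer
smaller C then smaller γ. The probability map is a logistic regression
fit on out-of-fold decision values — Platt scaling that never sees
resubstitution scores. A site is positive when the probability strictly
exceeds 0.5 (exactly 0.5 is negative). Predictions also report the
best-matching motif: the highest-scoring HMM among those above their
calibrated thresholds, otherwise the overall argmax flagged
sub-threshold (`*` in the CLI output), so users always see which motif
family drove a call.

## Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total, MCC with the
0-on-zero-denominator convention. Repeated stratified k-fold CV
(default 5 folds; "thirty rounds" is read as 30 repeats with fresh
seeded partitions; tests and the acceptance script use 3 repeats at
desk scale) re-runs the entire pipeline — MDD, HMMs, balancing, SVM —
inside each training fold by default, to avoid leakage from clustering
on test data; clustering once on all positives is available as a
switch. Reports carry both per-fold averages and per-round pooled
panels, since either reduction is defensible. Independent testing
applies an ungapped-identity homology filter (default cutoff 1.0, i.e.
exact duplicates; padding matches only padding) before scoring.

## Synthetic data

The generator emulates the structure of a curated O-GlcNAcylation
training set: a few hundred positives against a vastly larger negative
pool (defaults 410 vs 27,968), positives drawn from a mixture of motif
families, negatives pure background. Each motif family constrains some
offsets to a physicochemical group with an enforcement probability; the
letter is drawn uniformly within the group. The default two families
overlap at position −3 (hydrophobic at −3/−2/+3 vs polar at −3/−1/+1),
because real substrate motifs are alternatives at the same flank
positions — this positional conflict is what makes a single pooled HMM
inferior to the motif-resolved two-layer model, and the default signal
strength is set so the method attains roughly the published ~85%
cross-validated accuracy scale on the emulated data. The background is
uniform over the 20 letters by default so signal strength is controlled
entirely by the motif specs; a natural-frequency preset is included.
Ground-truth motif assignments are emitted for purity analysis.

What the synthetic data does **not** emulate: realistic flank
composition beyond the planted constraints, homology structure between
proteins, S/T compositional bias around real sites, or annotation
noise. Passing tests on this data therefore demonstrate correctness and
the expected qualitative orderings (two-layer ≥ single HMM, MDD
recovery of planted dependence), not real-data performance.

## Numerical and reproducibility choices

- Chi-squared: zero-expectation cells contribute 0; empty tables are a
  domain error.
- All randomness (generator, k-means, CV partitions, SVM fold
  shuffling) flows from explicit integer seeds; identical seeds give
  byte-identical model bundles (plain-JSON serialization of emissions,
  support vectors, and Platt coefficients; the bundle is written to a
  temporary directory and renamed atomically).
- CV/grid sizes in tests and the acceptance script are desk-scale (200
  positives / 2,000 negatives, 3 repeats, 2×2 grid) — chosen so the
  whole suite re-runs in about a minute while leaving the orderings
  under test unambiguous.

## Limitations

- The split-selection aggregate and the group scheme are documented
  choices; other published MDD variants split on the single maximal
  pair or on consensus letters and can yield different trees.
- Bit-score features are unscaled; if motif HMMs of very different
  lengths were ever mixed (not the case here), scaling would matter.
- The homology filter is windowed ungapped identity, not a full local
  alignment; it is intended for fragment-level deduplication rather
  than family-level redundancy removal.
- No protein-structure features; sites in disordered vs structured
  regions are treated identically.
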