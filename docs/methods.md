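# Methods

## Problem and model

`dicercleave` frames Dicer cleavage-site recognition as balanced binary
classification of 14-nt windows on a pre-miRNA arm. For every annotated
scissile bond the pipeline produces one positive window centred on the bond
(7 nt on each side) and one negative window whose centre lies 6 nt away,
shifted toward the arm's free terminus so that it stays on the same arm and
moves away from the hairpin loop. Each window is augmented with its
*complementary strand*: position-wise, the base of the pairing partner in
the predicted secondary structure, or the symbol `O` when the position is
unpaired (loop/bulge). All sequence/structure coordinates are 0-based
internally; CT files and annotation TSVs are 1-based on disk and converted
at the boundary.

Two feature families feed the classifier:

- **Relational features** p_1..p_14 — the ordered categorical pair
  (window[i], complement[i]) ∈ {A,C,G,U} × {A,C,G,U,O}, 20 codes per
  position. They encode sequence and local pairing jointly.
- **A class feature** — the cluster id assigned by affinity propagation run
  on the training patterns under the similarity
  s(i,j) = −D_similar(i,j), where D_similar is the sum of the Levenshtein
  distances between the two windows and between the two complements
  (`O` is an ordinary symbol with unit substitution cost). Test patterns
  inherit the id of the exemplar with minimum D_similar; ties go to the
  lowest exemplar index. Using the window+complement distance for test
  assignment keeps the test-time metric identical to the training-time
  similarity; this is a deliberate design choice where either convention
  was defensible.

## Affinity propagation

Responsibilities and availabilities follow the standard message-passing
form, with the availability sum running over i′ ∉ {i, k}; the damped
update is new = λ·old + (1−λ)·computed with λ = 0.5 by default. A run is
*converged* when the exemplar set (points with a(k,k) + r(k,k) > 0) has
been unchanged for `conv_window` = 50 consecutive sweeps, up to
`max_iter` = 1000 sweeps. Non-convergence sets a flag rather than raising;
the experiment protocol discards such runs and re-draws the split.

After convergence the canonical final step of the reference
implementation is applied: within each cluster the member with the largest
within-cluster similarity sum becomes the exemplar, and every point is
assigned to its most similar exemplar. For two-member clusters the two
within-cluster sums are exactly equal (the matrix is symmetric and the
diagonal preference identical), so the exemplar choice there is a pure
tie; we resolve ties deterministically by lowest index. The diagonal
preference defaults to the median of the off-diagonal similarities —
standard practice, and consistent with the high cluster counts (order
10² clusters per 1.6 k samples) this similarity produces.

## Classifier and hyperparameter search

LightGBM consumes the 15 categorical columns natively (pandas `category`
dtype; no one-hot encoding). The search grid is
max_depth ∈ {10, 20, 30, 40, 50, 60}, learning_rate ∈ {0.05, 0.1, 0.15},
num_leaves ∈ {200, 300, 400}, evaluated exhaustively by stratified 5-fold
cross-validated accuracy on the training set only and refit on the full
training set. Boosting uses 100 rounds without early stopping; the
classification threshold is fixed at 0.5 (classes are balanced by
construction). Feature importance is reported both as split counts and as
total gain, averaged over repeats when several models are supplied.

LightGBM's categorical regularisers (`min_data_per_group`,
`cat_smooth`, `cat_l2`) default to values sized for hundreds of rows;
on very small fixtures they can forbid any split. The grid accepts these
as ordinary parameters, and the tiny-fixture tests relax them explicitly;
the defaults are left untouched at experiment scale.

## Evaluation protocol

Metrics are the closed forms Sn = TP/(TP+FN), Sp = TN/(TN+FP),
Acc = (TP+TN)/total and the Matthews correlation coefficient; a zero MCC
denominator is reported as 0 with an explicit flag. The repeated-split
experiment draws, per repeat, a disjoint random split **over pre-miRNA
ids** (not pattern rows), so a cleavage window and its sibling decoy never
straddle train and test — a leakage guard that also matches the
800 + 156 = 956 id arithmetic of the full-scale protocol. Per-repeat
generators derive deterministically from (master seed, repeat index,
redraw index). The permutation null (`shuffle_labels=True`) swaps the two
labels within each id with probability ½, destroying the label↔window
association while preserving the per-id class balance that id-level
splitting requires.

## Synthetic hairpins

`HairpinSpec` defaults: stem 30 nt, loop 8 nt, bulge rate 0.05 per stem
position (random strand), mismatch rate 0.10, cleavage bond 21 nt from
each free terminus (the ~21-nt mature-miRNA length), total length 68 nt.
The 3p arm is the reverse complement of the 5p arm; a mismatch makes both
partners unpaired with a non-complementary base, a bulge unpairs one
strand's position and re-aligns the remainder, keeping the structure
nested. The pair table is emitted by the generator itself — it is ground
truth, not a folding prediction, so tests never depend on a fold tool.

An optional motif is planted at cleavage-window offsets 5..8 (1-based
positions 6–9) with probability `motif_strength`, independently per arm.
Because cleavage and decoy windows overlap by 8 nt, the decoy window sees
a trailing fragment of the motif at different offsets; the relational
features are positional, so the signal remains cleanly separable and the
planted positions dominate the feature-importance ranking. The 3p motif
copy overwrites the derived strand, so base pairs under it may become
non-canonical; with `motif=None` and zero noise rates every stem pair is
exact Watson–Crick. `bulge_rate=1` is rejected as degenerate (no pairable
stem remains).

What the generator does *not* emulate: thermodynamic folding (no G-U
wobble enrichment, no multi-loop structures), miRBase-like sequence
composition, or fold-prediction errors. Passing tests therefore
demonstrate that the pipeline recovers a planted, structure-annotated
signal under controlled noise — not that it reproduces published
performance on real miRBase data, which would require the original
annotated sequences and external fold predictions.

## Problem sizes and numerical choices

The benchmark experiments run at reduced scale — 200+200 training ids and
50+50 test ids, 10 repeats — which keeps every stage (O(n²) edit-distance
matrix, AP message passing, the 54-point grid search) comfortable on a
single CPU while preserving the protocol's structure. Pairwise Levenshtein
distances are computed by a numpy-vectorised DP over the pair grid,
pinned by tests to the scalar two-row DP, to an independent shortest-path
oracle, and to edlib. Multi-structure fold files contribute only their
first (minimum-free-energy) structure; pseudoknotted CT input is
rejected, as the dot-bracket dialect used cannot express it.

## Known limitations

- Affinity propagation convergence is not guaranteed; the protocol
  re-draws the split (bounded retries) rather than falling back to another
  clustering algorithm.
- Exemplar identity within a two-member cluster is decided by a
  deterministic tie-break; implementations that jitter the similarity
  matrix may report the tied co-member instead.
- The non-cleavage shift direction on the 3p arm (toward the 3′ terminus)
  mirrors the 5p convention; both windows always move away from the loop.
- The scissile bond of an even-length window is placed between window
  positions 7 and 8 (1-based), i.e. the annotated position is the last
  nucleotide 5′ of the bond.
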