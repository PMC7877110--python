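# dicercleave

Structure-aware prediction of human Dicer cleavage sites on pre-miRNA arms.

Human Dicer is the RNase III enzyme that cuts a ~60–80 nt pre-miRNA hairpin
into mature miRNAs; its RNase IIIa and IIIb domains cleave the 3p- and
5p-arms of the stem. Where exactly Dicer cuts determines the mature miRNA
sequence, so predicting the scissile bond from sequence and secondary
structure is of direct biological interest. `dicercleave` implements a
gradient-boosting classifier over *relational* and *class* features that
distinguishes true cleavage windows from nearby decoy windows, for
bioinformaticians studying miRNA biogenesis.

## The method

Given a pre-miRNA sequence, its secondary structure (dot-bracket or CT),
and an annotated cleavage position, the pipeline builds:

1. **Patterns.** The *cleavage pattern* is the 14-nt window with the
   scissile bond at its centre (7 nt each side); the *non-cleavage pattern*
   is the window shifted 6 nt toward the arm's free terminus. Each window
   gets a *complementary strand* read position-wise from the structure —
   the pairing partner's base, or `O` for a loop/bulge.
2. **Relational features.** p_i = (window[i], complement[i]) for
   i = 1..14, each a categorical code from {A,C,G,U} × {A,C,G,U,O}.
3. **Class feature.** Patterns are compared by
   D_similar(E, F) = D_edit(E₁, F₁) + D_edit(E₂, F₂) — Levenshtein distance
   on windows plus complements — and clustered by affinity propagation on
   the similarity matrix s(i,j) = −D_similar(i,j). Each training pattern's
   cluster id is its class feature; test patterns inherit the nearest
   exemplar's id.
4. **Classifier.** A LightGBM model consumes the 15 categorical features
   natively (no one-hot). Hyperparameters are chosen by exhaustive grid
   search (max_depth ∈ {10..60}, learning_rate ∈ {0.05, 0.1, 0.15},
   num_leaves ∈ {200, 300, 400}) with stratified cross-validated accuracy.
5. **Evaluation.** Repeated random splits drawn over pre-miRNA ids
   (default 800+800 train / 156+156 test patterns, 10 repeats, repeats
   with non-converged affinity propagation re-drawn), reporting mean
   Sn, Sp, Acc and MCC.

A synthetic-hairpin generator (stem + loop + reverse-complement stem, with
bulges, mismatches and an optionally planted cleavage-window motif)
provides structure-annotated data with known ground truth, so the whole
pipeline runs and is tested without any external download or fold server.

## Worked example

```python
from dicercleave import (HairpinSpec, generate_hairpins, build_dataset,
                         run_experiment)

spec = HairpinSpec(motif="UGGC", motif_strength=0.9)
premirnas, tables, annotations = generate_hairpins(260, spec, seed=7)
patterns = build_dataset(premirnas, tables, annotations, arm="5p")
print("patterns:", len(patterns))

report = run_experiment(patterns, n_repeats=3, train_pos=200, train_neg=200,
                        test_pos=50, test_neg=50, seed=7)
m = report.mean
print(f"mean over 3 repeats: Sn={m.Sn:.3f} Sp={m.Sp:.3f} "
      f"Acc={m.Acc:.3f} MCC={m.MCC:.3f}")
```

prints

```
patterns: 520
mean over 3 repeats: Sn=0.967 Sp=0.967 Acc=0.967 MCC=0.934
```

520 patterns are one cleavage plus one non-cleavage window per hairpin
(5p arm only). With a 4-mer motif planted in 90 % of cleavage windows the
classifier recovers the signal almost perfectly; with `motif_strength=0`
or label-shuffled data the same pipeline scores at chance (≈ 0.5),
confirming that the performance comes from the planted signal rather than
leakage. Affinity propagation on these patterns typically finds ~50
clusters per 400 training patterns, most of them pure cleavage or pure
non-cleavage — the bimodal class-ratio profile that makes the cluster id
an informative feature.

The same steps are available from the shell:

```sh
dicercleave simulate --n 260 --motif UGGC --strength 0.9 --seed 7 --out fixtures/
dicercleave extract --fasta fixtures/hairpins.fasta --struct fixtures/hairpins.db \
    --annot fixtures/annotations.tsv --arm 5p --out patterns.tsv
dicercleave evaluate --patterns patterns.tsv --repeats 3 \
    --train-size 200 --test-size 50 --seed 7 --out report.json
```

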