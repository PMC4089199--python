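# Methods

## Model and assumptions

A protein sequence is treated as a string over the 20 standard amino acids
and represented by the occurrence frequencies of all contiguous n-grams of
length 1–3 counted with overlapping (stride-1) windows. The encoding is
alignment-free: two sequences are compared only through composition, so
positional homology is never assumed. Frequencies are normalized per
k-block — the value of a k-gram is its count divided by the number of
windows of width k (L − k + 1 for a clean length-L sequence) — which makes
the representation length-invariant within each block and means every
populated block sums to 1.

The selector is a pure filter: it ranks features by a statistic computed
from per-class means and variances, independently of any classifier. Its
implicit model is that a useful feature has class-conditional frequency
distributions that are well-summarized by mean and variance (roughly
Gaussian or at least unimodal), and that features act independently — no
interactions or feature combinations are scored. The min-over-pairs
aggregation encodes the assumption that a feature is only as good as its
*worst* class pair: a feature that perfectly separates two classes but is
identically distributed in the third scores low.

## The two forms of the pair statistic

The pair statistic shipped as `as_printed` divides each class variance by
the feature-space size N_total (8420) and takes no square root:

    vd_pq(j) = |X̄_p(j) − X̄_q(j)| / (S_p²(j)/N_total + S_q²(j)/N_total)

This is implemented verbatim and is the default, for fidelity to the metric
as published. It is almost certainly a typographical corruption of Welch's
two-sample t statistic, which divides each variance by its class's sample
count and square-roots the sum; that form is shipped as `welch`:

    vd_pq(j) = |X̄_p(j) − X̄_q(j)| / sqrt(S_p²(j)/N_p + S_q²(j)/N_q)

The two are *not* rank-equivalent: `as_printed` scales as Δ/σ² rather than
Δ/σ, so it boosts low-variance features more aggressively and the selected
sets can differ. Which form produced the published benchmark accuracies is
not determinable, so both are first-class; the variant is a recorded run
parameter and appears in every output.

Degenerate cells are defined once: zero denominator with zero numerator
gives 0 (the feature says nothing about the pair); zero denominator with a
positive numerator gives +inf (the feature separates the pair perfectly,
e.g. constant-but-different in both classes) and outranks every finite
value. Ties in the final ranking are broken by ascending feature index, so
selection is deterministic.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_max` | 3 | largest n-gram length; 3 gives 8420 descriptors. 4–5 are supported but multiply the space by 20 each |
| `k_features` | 50 | features kept; the published experiments reduced 8420 to "approximately 20 to 50", and 50 is the upper end. `--min-metric` offers an absolute-threshold mode instead |
| `variant` | `as_printed` | pair statistic form (above) |
| `train_fraction` | 0.70 | stratified per class, floor/ceil to the closest split with ≥ 1 row on each side |
| `n_runs` | 10 | repeated random splits; each run r uses seed + r |
| `residue_policy` | `drop_ngrams` | non-standard residues (B, J, O, U, X, Z, \*, gaps): keep the sequence but exclude windows overlapping the bad positions from counts *and* denominators. `reject` and `skip_sequence` are available; rejecting whole UniProt-style records would bias class counts, which is why exclusion is the default |
| neural net | 1 hidden layer × 10 units, ≤ 500 epochs | the one back-end not left at library defaults; one output unit per class |

## Evaluation protocol

The harness runs ten independent stratified 70/30 splits and averages the
metric panel (the protocol's description of "tenfold cross validation"
alongside "70% … 30%" is contradictory as written; repeated 70/30 splits
match the operative description, and a conventional k-fold CV mode is
available as `--cv N`). A `--split prefix` mode takes the literal first 70%
of each class in file order instead of a random subset.

Class statistics and the feature selection are fitted on the training
partition only, then the frozen column set is applied to the test
partition. Fitting selection on all rows would leak test-set information
into the feature ranking; the no-leakage property (deleting any test row
leaves a run's selected set unchanged) is asserted in the test suite.

The metric panel is computed from the confusion matrix by one-vs-rest
reduction. Whether the published single-number metrics are macro or
weighted averages is unstated, so both are always emitted, along with every
per-class value. Any 0/0 ratio (e.g. precision of a never-predicted class)
is reported as 0 and flagged in the report's `undefined` list rather than
raised, so degenerate runs still aggregate.

## Synthetic data: what it emulates and what it does not

The generator emulates exactly one property of real superfamily data:
class-dependent n-gram occurrence rates against an i.i.d. uniform
background. Planted copies are written at uniformly chosen non-overlapping
positions so the expected realized rate count/(L − k + 1) equals the
target; the background can also produce incidental copies, so the
generation report records the *realized* per-class frequency of every
planted descriptor, and recovery experiments treat the report as ground
truth. Defaults: lengths uniform on [80, 120], uniform background, and
per-preset planting of three distinct trigrams with graded rates
0.06/0.03/0 cyclically shifted across the three classes.

The graded rates are a deliberate calibration. A descriptor elevated in
only one class leaves one class pair unseparated, so its min-over-pairs
score is driven by noise in that pair and selection quality becomes
erratic at small sample sizes; graded rates put the signal in the regime
the min-over-pairs metric is designed for. A two-class recovery experiment
(one trigram at rate 0.05 vs 0, 300 sequences per class) needs no grading
because a single pair is its own minimum.

Real protein families differ from this generator in every other respect:
residue composition is not uniform, motifs are positionally constrained,
sequences within a family share phylogenetic correlation rather than being
i.i.d., and signal is spread over many weak features rather than a few
strong ones. Passing the synthetic benchmarks therefore demonstrates that
the implementation is correct and that the selector recovers the signal it
models — not that the published real-data accuracies would be reproduced,
which would require the original UniProtKB selections.

## Numerical choices

- Frequencies are exact IEEE doubles (count/denominator); nothing is
  rounded internally. The 2-decimal display used in the worked-example
  tables truncates toward zero (2/7 → 0.28, 1/6 → 0.16), matching the
  printed values that a round-half rule would not; `format_frequency` is
  presentation-only. A handful of printed cells are arithmetically
  inconsistent with the sequences they describe (several 1/8 cells printed
  0.13, one row computed as if the sequence had length 10, bigram rows
  disagreeing with the printed sequence); the tests anchor on the exact
  fractions and on the consistent cells only.
- Per-class variance uses the sample divisor N_i − 1; classes need N_i ≥ 2
  and a smaller class is a hard error, not a silent skip. Variance is
  computed from Σx² − N·mean² on sparse rows and clamped at 0 to absorb
  cancellation residue; the test suite checks the vectorized path against
  a naive two-pass loop to 1e−10 relative.
- The feature matrix is CSR-sparse (a 1–3-gram vector has at most ~3L
  nonzeros of 8420); back-ends receive dense arrays only after column
  restriction, except in the all-features mode where the dense matrix is
  materialized deliberately.
- Problem sizes in the test and acceptance runs (60–300 sequences per
  class, 20 generator seeds for recovery, 10 splits per experiment) were
  chosen as the smallest sets at which the measured properties are stable
  across seeds; the full presets (up to 1830 sequences) are exercised
  end-to-end in the acceptance script.

## Known limitations

- `as_printed` divides by N_total, so its values are comparable *across*
  features only because every feature shares the same N_total; it is not a
  calibrated test statistic, and no p-values are attached to either
  variant.
- The selector scores features marginally; correlated descriptors (a
  trigram and its substrings) are selected together rather than
  de-duplicated, which spends part of the top-k budget on redundancy.
- Threshold-mode selection (`--min-metric`) has no principled default, as
  the underlying threshold was never published; top-k is the primary mode.
- The FASTA reader assumes protein input; nucleotide files are rejected
  only insofar as they contain non-standard letters (a pure ACGT file
  would be read as amino acids).
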