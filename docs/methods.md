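# Methods

## The model

`ibpp` predicts bacterial sigma70 promoters with a template artifact
called an **image**: a fixed-width string over `{a, t, c, g, -}` in
which nucleotide characters encode conserved sequence features and runs
of `-` encode the flexible spacing between them. The biological
motivation is the architecture of the sigma70 core promoter: a −35 box
(consensus `ttgaca`) and a −10 box (consensus `tataat`) whose spacer
varies between 14 and 20 nt even within one genome, which defeats
fixed-column models such as a PWM unless the training sequences are
first aligned. The image sidesteps alignment by making the spacing part
of the model.

### Scoring

A sequence is compared with an image by pairing image positions with
sequence positions and counting matched nucleotides `Ny` and mismatched
nucleotides `Nx` over the image's non-gap positions:

    score = Ny − p · Nx,    p = 0.4 by default.

Gap positions contribute nothing. Two mechanisms absorb spacing
variability:

* **Elastic gaps.** Each maximal gap run of length `L` may be replaced
  by any length in `[L − d, L + d]`, `d = floor(f · L)` with
  flexibility `f = 0.2`. A 10-nt run therefore also tries lengths
  8, 9, 11 and 12. By default one run varies at a time (`per_run`),
  which bounds the number of variants linearly in total gap length; a
  `cartesian` mode enumerates joint combinations under a hard cap
  (default 500) and logs a warning when truncating.
* **Shift alignment.** The sequence is slid across the image over the
  offsets −5..+4 — ten alignments including the unshifted one. The
  asymmetric window is deliberate: a symmetric ±5 window plus zero
  would be eleven alignments, and the method is defined by a count of
  ten; we keep offset 0 and drop +5.

The reported score is the maximum over all (variant, offset) pairs.
Sequence positions holding non-ACGT characters (IUPAC ambiguity codes)
match nothing and mismatch nothing; image positions that overhang the
sequence likewise contribute nothing, so large shifts are not
penalized structurally. A sequence that never overlaps a nucleotide
position scores exactly 0.

Numerically, the scorer expands every (variant, offset) pair into a
template row in sequence coordinates and computes `Ny` and the
compared-position count as one-hot float32 matrix products. Both
counts are small integers (≤ the image width), hence exact in float32;
the final `Ny − p·Nx` arithmetic is float64, so the fast path agrees
bit-for-bit with naive enumeration (asserted exactly in the tests, on
1,000+ random instances against a pure-Python oracle). Tie-breaking:
when several pairs attain the maximum, diagnostics report the first in
enumeration order — original image first, variants in enumeration
order, offsets ascending. The score itself is order-independent.

### Evolution

Images are trained by an evolutionary loop over a library of
candidates. Fitness is the **D-score**

    D = mean score on training promoters − mean score on training non-promoters.

(The selection direction requires higher-D images to be the
discriminative ones; promoters must outscore non-promoters for the
artifact to be useful, so D is defined promoter-minus-non-promoter.)

Each cycle applies, in order:

1. **Replenish** — if the library has fewer than 400 members, pour in
   2,000 fresh seed-images (a seed-image is 10 contiguous random
   nucleotides at a uniform position in an otherwise all-gap 81-nt
   string). The initial library holds 20,000 seeds. The threshold is
   checked once per cycle.
2. **Recombination** — `2 × n` children are appended, each the product
   of a two-point crossover (`a[0:i] + b[i:j] + a[j:]`, cuts uniform
   with `i ≤ j`) of a uniformly drawn ordered pair of distinct
   members. Parents are drawn from the library as it stood at the
   start of the step; pairs may repeat across draws.
3. **Mutation** — exactly `round(0.2 × n)` distinct members are
   mutated in place: one uniformly chosen position flips to a
   different character from `{a, t, c, g, -}` (gaps can be created and
   destroyed).
4. **Scoring** — D-scores are computed for every member whose image
   changed (new children, fresh seeds, mutants); unchanged members
   keep their cached value, which is bit-identical to a recomputation.
5. **Screening** — the top `ceil(0.1 × n)` members by D-score survive;
   ties keep the earlier-inserted member.

The loop runs a fixed number of generations (100 at full scale). There
is no elitism inside the loop; instead the best image ever scored is
tracked across the run and returned, so the deliverable never
regresses. All randomness flows through a single seeded generator and
a run is exactly reproducible from its seed.

Library homogenization is tracked as nucleotide diversity π of the top
100 members: the mean over unordered pairs of the per-site difference
fraction, with `-` counted as a fifth character state (excluding gap
positions would leave π undefined on gap-only columns).

### SVM combination

Independently evolved images (same training data, different seeds)
carry partly complementary information. The ensemble classifier maps
each sequence to the vector of its scores against k images and trains
a soft-margin C-SVC with RBF kernel, `gamma = 0.1`, `C = 1`
(scikit-learn's libsvm backend). Raw scores are used as coordinates —
no standardization is applied, matching the method's definition; users
wanting scaling can wrap the estimator in a sklearn pipeline. Promoter
is the positive class.

### Scanning long sequences

An 81-nt window slides with step 1. Single-image mode records a hit
where the window score strictly exceeds the threshold (default 12, the
value recommended for genome scanning; sensitivity falls and
specificity rises monotonically with it). Ensemble mode records a hit
where the SVM calls the window positive, scored by the mean of the
image scores. A real promoter lights up a cluster of overlapping
windows, so hits are merged: greedily by descending score, a retained
hit suppresses anything within 50 nt (ties keep the smaller
coordinate), iterated to a fixed point by construction. The predicted
TSS of a hit is `window_start + 60` because images are trained on
−60..+20 windows. Only the forward strand is scanned by default; an
opt-in mode scans the reverse complement and reports hits in
forward coordinates with strand `-`.

### Metrics

Short sequences use sensitivity `TP/(TP+FN)`, specificity
`TN/(TN+FP)` and `F1 = 2TP/(2TP+FP+FN)`; zero denominators yield NaN,
never a silent 0. For long sequences, a sequence is a true positive
when a merged hit lands within ±50 nt of its TSS, and sensitivity is
TP over the number of sequences. Specificity needs a negative unit
along the rest of the sequence: the region outside the ±50 window is
tiled into 101-nt bins laid outward from the window edges (partial
bins at the ends count); an occupied bin is an FP, an empty bin a TN,
and specificity is `TN/(TN+FP)`. A literal per-hit FP count (hits in
the ±50 window divided by 101) is implemented behind
`LongSeqEvalConfig(literal_fp=True)` for comparison, but it is not a
coherent false-positive count and is not the default.

## Synthetic benchmark

The generator plants the sigma70 architecture into random background:

| parameter | default | meaning |
|---|---|---|
| `window_width` / `tss_offset` | 81 / 60 | −60..+20 window, TSS at index 60 |
| `minus35_motif`, `minus10_motif` | `ttgaca`, `tataat` | planted consensus boxes |
| `spacer_range` | 14–20 nt | uniform spacer between the boxes |
| `minus10_to_tss_range` | 4–9 nt | uniform gap from the −10 box to the TSS |
| `motif_noise` | 0.1 | per-base substitution probability on motif positions |
| `long_length` | 2,000 nt | fragment length, TSS centered |

Non-promoters are concatenated random codons drawn from a fixed
E. coli-like codon usage table (coding-style background rather than
uniform noise), rejection-sampled so no verbatim −35/spacer/−10
arrangement occurs by chance. The 4–9 nt −10-to-TSS range is this
package's choice (the window geometry constrains but does not fix it)
and is configurable. A metadata record of all planted coordinates
accompanies every promoter so tests never re-derive truth by parsing
sequences.

What passing tests on this benchmark show: the scorer, trainer,
combiner, scanner and metrics interact correctly and the method
recovers planted signal under spacer variability and 10% motif noise.
What they do not show: performance on real promoter collections, where
motif degeneracy, background composition and TSS annotation noise are
all harsher than the simulation.

## Problem sizes used in checks

End-to-end checks run the loop at reduced scale: 50+50 training
windows, 500 initial seeds, replenishment 100 below 50 members, 30
generations (about 10 s per run). Trend checks (diversity decline,
SVM-vs-single-image sensitivity) average five seeded replicates. The
acceptance script uses the same scaled conditions with 200+200
held-out short windows and 25 long fragments. Under these conditions
the evolved images carry fewer informative characters than a
full-scale run (20,000 seeds, 100 generations), so absolute scores sit
lower and the genome-scan threshold of 12 is conservative: the
single-image sensitivity it reports is accordingly modest while
specificity is near-perfect, and the SVM ensemble — which needs no
threshold — is far more sensitive at similar specificity. The
full-scale defaults remain the package defaults.

## Known limitations

* Single-sigma-factor, single-motif-architecture model; no UP
  elements, extended −10 recognition, or multi-TSS fragments.
* The `per_run` gap enumeration is a deliberate approximation: joint
  gap variation is exponential and is only available capped.
* The loop's runtime is dominated by scoring freshly created members;
  at full published scale a run is hours, not seconds.
* Merging suppresses genuinely close promoters (< 50 nt apart) by
  design.
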