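# Methods

This note documents the models, numerical choices and limitations of
`lncfuse`. The positive class throughout is lncRNA (label 1), the negative
class mRNA (label 0); sequences are normalised to the DNA alphabet
{A, T, C, G} with U mapped to T and case folded.

## Encodings

**p-nucleotide tokens.** A window with both length and stride *p* slides
along the sequence; each complete window is one "word" and a trailing
partial window (L mod p ≠ 0) is discarded — the stride-*p* window yields
only complete words, and at the default *p* = 3 this drops at most two
terminal bases. Words map to integers 1 … 4ᵖ lexicographically with digit
order A < T < C < G, matching the one-hot row order; the map is therefore
invertible, and 0 is reserved for padding. Token vectors are post-padded
(trailing zeros) to the batch width ⌊max L / p⌋ computed **on the training
set only**; test-time sequences longer than that width are truncated with
a logged warning. The padding token has a frozen zero embedding so padding
cannot inject signal.

**One-hot matrices.** 4 × N binary matrices, rows (A, T, C, G), one unit
column per base; N is the longest training-sequence length, shorter
sequences get trailing all-zero columns, longer test sequences are
truncated with a warning.

## Base models

Both networks are implemented directly in numpy with hand-written
backpropagation (`lncfuse.nn`); gradients are verified against central
finite differences in the test suite.

**BiLSTM (token view).** Embedding → bidirectional LSTM → dropout → dense
sigmoid scalar; binary cross-entropy, Adam. Fixed by the architecture: 64
units and dropout 0.4 by default, sigmoid output. Free parameters (with
the reasoning that they are not architecture-determined): embedding
dimension (default 64), epochs (10), batch size (32), Adam learning rate
(10⁻³), and an optional global-norm gradient clip (off by default;
recurrent nets occasionally show divergent loss spikes and clipping at
norm 5 stabilises small models). Padded timesteps are masked: the hidden
and cell states carry through them unchanged in both directions, so the
final forward state is the state at the last real token and the backward
state at the first.

**CNN (one-hot view).** conv(32 filters) → max-pool → conv(64 filters) →
max-pool → dropout 0.4 → 2-way softmax; categorical cross-entropy, SGD.
The first kernel spans all four rows, so the 2-D "image" convolution
reduces to a 1-D convolution over columns with 4 input channels; kernel
width 8, pool 2 by default, all config-exposed. Cp_C is the lncRNA
component of the softmax pair; the two components sum to one exactly.
SGD momentum defaults to 0 and is exposed (small models train more
reliably with momentum 0.9 and a slightly higher rate).

Determinism: all randomness (init, shuffling, dropout) flows through one
`numpy` Generator seeded from `random_state`, so training histories and
weights are bitwise reproducible single-threaded.

## Decision-level fusion

Every strategy selects one of (Cp_L, Cp_C) per sample using the
decisiveness |2·Cp − 1|; none averages. The greedy rule takes the more
decisive value with ties resolved to the CNN (the "≤" branch); the
dominant rules keep the lead model's value unless its decisiveness is
≤ 0.5, i.e. its confidence lies in [0.25, 0.75], in which case the other
model decides. Note the greedy rule is driven by decisiveness, not by the
larger Cp: a confident *rejection* (Cp near 0) also wins. Labels come from
the fixed threshold Cp ≥ 0.5 → 1. LSTM-dominant is the default strategy,
reflecting that the token/LSTM view carries more information per sample.

## Class balancing

Negatives are clustered with k-means (k-means++ init, fixed seed,
`n_init=5`) on the concatenated 1-mer + 2-mer frequency vector (20
dimensions, same weighting as the feature extractor), 200 centers by
default, scaled down to the sample count for small runs. From cluster *i*
of size xᵢ, Oᵢ = round(xᵢ/total · target) members are drawn uniformly
without replacement; `round` is half-up. Independent rounding bounds the
total's deviation by half the cluster count and the per-cluster proportion
error by 1/target; an optional largest-remainder correction
(`exact_total=True`) enforces the exact total. The cluster count must stay
well below the negative count, otherwise most clusters are singletons and
round to zero.

## Classical features (90 dimensions)

Order: 84 k-mer frequencies | int, cov, nORF | n_pairs, gc, nMFE.

* **k-mer frequencies** for k = 1, 2, 3 (4 + 16 + 64 forms, lexicographic
  within each k): fⱼ = aₖ·cⱼ/sₖ with sₖ = L − k + 1 stride-1 window matches
  and the scale-equalising weight aₖ = 1/4^(3−k), so each k-block sums to
  1/16.
* **ORF features** from an internal three-forward-frame finder
  (transcripts are sense-strand cDNA; reverse-strand ORFs are not
  considered). Within a frame the scan is greedy — first ATG, then the
  next in-frame stop — so ORFs in one frame never overlap; ORFs shorter
  than `min_codons` (default 30) are discarded, and an ATG without a
  downstream in-frame stop yields nothing (integrity requires both ends).
  int = [n ≥ 1], cov = Σlₘ/L (stop included in lₘ), nORF = n/L.
* **Structure features**: GC content (N_G + N_C)/L; base-pair count and a
  proxy minimum free energy from a Nussinov maximum-pairing dynamic
  program (pairs G−C, A−T and the G−T wobble; minimum hairpin loop 3 nt)
  with per-pair scores 3/2/1 and MFE = −score, normalised by L. The pair
  count is the true maximum; among maximum-pairing structures the one with
  the best proxy score is chosen (lexicographic optimisation packed into a
  single integer DP, so no traceback is needed). These proxy energies are
  on an arbitrary scale: they order structures sensibly but are **not**
  thermodynamic kcal/mol values, and the `engine="external"` adapter that
  parses RNAfold output exists for users who need them. The DP is O(L³)
  and is the slow part of the feature extractor on long transcripts.

## Synthetic data

The generator emulates the two classes with controllable separability so
the whole pipeline is testable offline. Background sequences are i.i.d.
multinomial over the four bases. mRNA-like sequences carry exactly one
embedded ORF — ATG, interior sense codons, one stop — covering
`orf_frac_mrna` of the length (default 0.9), placed uniformly; interior
codons are drawn from (1 − s)·uniform + s·positional-preference over the
61 sense codons, where s = `periodicity_strength` (default 0.9) and the
preference gives each codon position a distinct base profile (the
3-periodicity a real coding region shows). lncRNA-like sequences are pure
background, always ≥ 201 nt (the class-defining threshold), with G+C
composition shifted by `gc_shift` (default 0.1; real plant lncRNAs differ
compositionally from mRNAs, and the sign of the shift is irrelevant to the
classifiers). Defaults (400 + 400 sequences, lengths 210–400 nt) are the
strong-effect study condition used by the acceptance checks.

Degenerate settings are exact nulls: at s = 0 no ORF is embedded at all
(the class is pure background rather than a stop-free mosaic, so
triplet-composition tests cannot tell the classes apart), and with
additionally `gc_shift = 0` the two classes are statistically identical.

What the generator does **not** emulate: UTR/splice architecture, repeat
content, sequencing error, length–class correlations beyond the 201-nt
floor, and real k-mer autocorrelation. Passing the separation checks
therefore shows the pipeline's machinery is sound, not that the
desk-scale models reach publication-level accuracy on real plant
transcriptomes.

## Evaluation

Confusion-derived criteria (sensitivity, precision, accuracy, F1, GM) use
lncRNA as the positive class; metrics with a zero denominator are NaN with
a warning rather than silently 0, so fold averages are not corrupted. AUC
comes from the ROC curve with rank-average tie handling (equal to the
normalised Mann–Whitney U; the test suite checks this identity to 1e−12).
Cross-validation uses stratified folds (shuffled, seeded); per-fold
reports are retained and fold-averaged summaries derived from them.
Fisher's LSD is the classical unprotected procedure: one-way ANOVA pooled
error variance, pairwise two-sided t statistics on the error degrees of
freedom; with zero variance everywhere, equal means give p = 1.

## Pipeline scale and reproducibility

`run_hdeep` chains balance → stratified 80/20 split → encode → train both
models → fuse → evaluate, with one master seed expanded deterministically
per stage and a JSON manifest (config snapshot, input digests, outputs)
per run. The acceptance script and heavy tests run the tiny configuration
(embedding/units 24, 18 epochs for the BiLSTM; 8/16 filters, 15 epochs for
the CNN) on 400 + 400 sequences — sizes chosen so a complete three-seed
replication with shuffled-label controls finishes in minutes on one CPU
core. The label-shuffled control is judged on the accuracy averaged over
the three seeds: a single shuffled run memorises label noise and its
held-out accuracy scatters several percentage points around chance.

## Known limitations

* The internal energy proxy and pair counts differ numerically from a
  thermodynamic folding program (by design; see above).
* ORF detection is forward-strand only and greedy, which can concatenate
  across a missed upstream start but cannot report nested or overlapping
  candidates within a frame.
* The numpy networks are desk-scale: no GPU path, no attention variants,
  and full-transcriptome training (tens of thousands of sequences) is out
  of scope.
* `p` > 4 shrinks token sequences sharply and is supported but untested
  beyond the vocabulary invariants.
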