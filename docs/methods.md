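# Methods

## The prediction problem

Ancestral exposure of a gestating female rat to an environmental toxicant
induces sperm DNA-methylation changes that persist into the unexposed F3
generation. MeDIP-seq comparisons of exposure and control lineages assign
each 1000 bp genomic window a p-value for the null hypothesis that the
window is *not* differentially methylated. `epidmr` treats susceptibility
as a property of the DNA sequence itself and learns a binary classifier
from sequence to {DMR, non-DMR}.

## Training-set construction

* **Positives.** A window is a DMR when its p-value is below `1e-5`
  (strict inequality) in at least one exposure. The union rule reflects
  the goal of an exposure-general model: nine different toxicant exposures
  contribute, and a region differentially methylated under any of them is
  a susceptible region.
* **Negatives.** Only windows with *zero* CpG dinucleotides. Cytosine
  methylation requires a CpG, so these windows are unambiguous negatives;
  they also happen to be roughly as numerous as the positives, giving a
  nearly balanced training set. Windows that carry CpGs but miss the
  p-value cutoff are left out of training entirely — failing a
  significance threshold is not evidence of non-susceptibility.
* Two further negative rules are implemented but **off by default**:
  CpG-island windows (density above a configurable 10–20% cutoff; default
  20%) and windows whose minimum p-value across exposures is large. They
  add only a percent or two of negatives and degrade the classifier.
* **Maximum possible DMRs.** Windows with between 1 and 200 CpGs (1–20%
  density at 1000 bp; "more than 200" is strict, so exactly 200 is
  included). This set upper-bounds how many windows any model could call
  DMR and is reported by the genome-scan summary.

Coordinates are 0-based half-open; genomes are tiled from position 0 of
each chromosome and a trailing partial window is dropped, because the
network input is fixed at 5 × window_size. IUPAC ambiguity codes collapse
to N, the fifth alphabet row.

## The network

Input is the 5 × 1000 one-hot window. Two convolutional blocks follow,
each holding two width-20 convolutions (the first valid-padded, the second
same-padded), batch normalization and ReLU after every convolution, then
max pooling (size 2) and dropout 0.4. Block 1 has 32 filters, block 2
has 64. The head is flatten → dense 256 → dense 128 → dense 2 with
softmax. Loss is cross-entropy (optionally class-weighted by
n/(2·n_class); on by default), the optimizer Adam. Training monitors the
loss on a stratified 10% validation split and stops when it has not
improved for 5 epochs, restoring the best-validation weights.

Values not fixed by the published design and their defaults here:
learning rate 1e-3, batch size 64, at most 100 epochs, He-style
variance-scaling initialization, batch-norm momentum 0.99 and epsilon
1e-3. All are estimator parameters.

The network is implemented directly in NumPy (`epidmr._nnet`):
convolutions are lowered to per-tap GEMMs, training is single-threaded and
bit-reproducible for a fixed `random_state` on one platform. Backprop is
verified against finite differences in the test suite, and the first-layer
activations against a brute-force sliding dot product.

**Batch-norm calibration.** With datasets of a few thousand windows an
epoch contains only tens of optimizer steps, and the usual exponential
running estimates of the batch-norm statistics (momentum 0.99) are then
far from the true population moments — bad enough to distort both the
early-stopping signal and the extracted features. After training (and, on
a 512-window subsample, before each validation evaluation) the running
statistics are therefore replaced by exact moments computed in one
deterministic pass over the training data with dropout off.

## The hybrid model

After training, the 32 first-layer kernels re-express every window: the
kernel's post-batchnorm/ReLU activation map (length 981 for defaults) is
pooled to a single value. An XGBoost classifier (200 trees, depth 6,
learning rate 0.1, `scale_pos_weight = n_nonDMR/n_DMR`, single-thread
`hist`) is trained on these 32-vectors and makes the final prediction;
the network's own softmax head is only the vehicle for feature learning.
A configuration hook can append extra named feature columns (e.g. CpG
density) to the boosted stage.

**Pooling.** The aggregation of the 981 per-position activations into one
feature per kernel is a design choice the published description leaves
open. This package defaults to the **mean**: it measures how strongly and
how often a kernel's pattern occurs, which is the signal that separates
CpG-bearing from CpG-free windows, and on the synthetic fixture it
dominates max pooling (fivefold CV accuracy 1.0 after a single training
epoch versus a plateau near 0.92) — the maximum over ~1000 positions is
an extreme order statistic whose distribution is similar in both classes.
**Max** pooling (`pooling="max"`) reads as "is this motif present
anywhere" and is position-invariant; it is the right representation for
interpretation and is used by the motif-recovery analysis.

**Evaluation.** Stratified fivefold cross-validation; *both* stages are
retrained inside each fold on the fold's 80% training partition, so held-
out windows never influence the features they are scored with. Reported
metrics (accuracy, precision, recall, F1 with the DMR class positive) are
arithmetic means of per-fold values. F1 is the harmonic mean
2PR/(P+R) — the definition that reproduces the published per-chromosome
table from its own printed precision and recall; zero-denominator
precision or recall is defined as 0.

## Motif visualization

Each kernel becomes a 5 × 20 position weight matrix. Subsequence
collection has two modes:

* `all_positions` (API default): every window position whose activation
  reaches `threshold_fraction` (default 0.5) of the kernel's dataset-wide
  maximum contributes its 20-mer.
* `per_window_max`: only each window's single maximally-activating 20-mer
  (gated by the same threshold) — the convention of convolutional-kernel
  visualization tools. This mode keeps the PWM from being swamped by weak
  background hits and is what the motif-recovery analysis uses.

Kernels are classified as DMR detectors (mean pooled activation higher
over DMR examples than non-DMR examples) or non-DMR detectors, and motif
sets are ordered most-DMR-biased first. MEME export redistributes the N
row uniformly over A/C/G/T because standard motif tools use the 4-letter
alphabet; the TSV export keeps all five rows.

## Genome scanning

A trained hybrid model scores every full window of a FASTA in batches
(bounded memory), calling DMR at probability ≥ 0.5 — always through the
boosted stage. The summary reports, per chromosome and overall, the
number and percentage of predicted DMRs, the maximum-possible-DMR bound,
and the recall of a supplied training-DMR set. A seeded uniform sample of
predicted DMRs (default 0.02%) supports visualization tracks; output is
BED6 with score = round(1000 × probability).

## The synthetic generator

`epidmr.simulate` emulates the statistical structure of the real task:

* **Positives**: uniform-background sequence carrying `motif_copies`
  (default 3) independently mutated copies (per-position rate, default
  0.1) of a planted 20-mer consensus at non-overlapping uniform positions,
  plus CG dinucleotides injected outside motif spans until the window
  holds `pos_cpg_rate` (default 20) CpGs — a realistic ~2% CpG density.
  The default consensus `TGCATTACGGTCACGATGCA` carries two CpGs and was
  chosen with low self-overlap so that recovering it from a learned kernel
  has a unique alignment.
* **Negatives**: background sequence with every CG destroyed by resampling
  the G from {A,C,T} until none remain (mirroring the zero-CpG negative
  rule). Destruction necessarily depresses the G frequency by roughly the
  destroyed-CpG mass (~6% absolute under a uniform background); the test
  suite checks composition against a naive destruction oracle rather than
  the raw background frequencies.
* **Harder mode** (`cpg_free_negatives=False`): negatives receive the same
  CpG load as positives, removing the CpG-presence shortcut so that the
  planted motif is the *only* class signal. The default fixture reproduces
  the real task's confound — CpG presence alone separates the classes —
  which is faithful for accuracy evaluation but means first-layer kernels
  need not align to the planted motif there; motif-recovery claims are
  therefore evaluated in the harder mode.

A companion generator emits the per-region p-value table (true positives
get p ~ U(0, 1e-6) in one random exposure; every window also gets a
non-significant row, exercising the union rule), and a toy-genome
assembler concatenates shuffled windows into a FASTA with a truth table
for end-to-end scan tests.

What the generator does **not** emulate: genomic repeat structure, GC
isochores, chromosome-scale composition gradients, the real (much larger)
imbalance between unlabeled and labeled windows, and any biological
relationship between motif content and methylation beyond the planted
signal. Passing tests therefore demonstrate that the pipeline's machinery
is correct and can learn sequence signals of the planted kind at desk
scale — not that the published genome-scale performance is reproduced.

## Problem sizes and training budgets

The test and acceptance runs use sizes a single CPU handles comfortably:

* Separable fixture: 2,000 windows of 1000 bp (1,000 per class), planted
  20-mer, mutation rate 0.1. Fivefold hybrid CV trains the network for
  **1 epoch per fold** — this fixture saturates immediately (measured fold
  accuracy 1.0), so additional epochs only cost time. The permutation-null
  run uses identical settings on shuffled labels.
* Motif recovery: 2,000 windows in the harder CpG-matched mode, network
  trained up to 10 epochs at batch 32 (learning rate 1e-3), hybrid stage
  on max-pooled features; the reported quantity is the fraction of the 20
  consensus positions matched by the top-importance kernel's PWM consensus
  (per-window-max subsequences at threshold 0.5).
* Unit tests run the same architecture on 100 bp windows.

## Numerical and degenerate-input conventions

* One-hot encoding rejects characters outside {A,C,G,T,N}; upstream
  normalization maps everything else to N.
* `tile_windows` of an empty or too-short sequence returns an empty list;
  scanning skips such chromosomes with a log entry.
* Duplicate (window, exposure) statistic rows keep the minimum p-value
  with a warning; stats rows not aligned to the tiling are an error.
* A window that is simultaneously DMR-labeled and CpG-free indicates
  inconsistent input and is excluded from negatives with a logged error.
* Detector ties (activation difference exactly 0) are assigned non-DMR
  with a logged note.
* A kernel that never activates yields no subsequences and no PWM (with a
  warning); an empty subsequence list is an error distinct from a
  degenerate PWM.
* Non-finite training or validation loss raises immediately, reporting
  the epoch.

## Known limitations

* Seeded training is bit-reproducible on a single thread and platform;
  across BLAS builds results may differ in the last float32 bits
  (documented as best-effort, as for any deep-learning stack).
* The NumPy engine targets this architecture family (1-D conv stacks with
  dense heads) and fixed-size inputs; it is not a general autograd.
* Whole-genome scans stream with bounded memory, but multi-gigabyte
  genomes at full scale are an operation this package supports rather
  than a result it reproduces in its tests.
* Early stopping uses a single stratified validation split, not nested
  cross-validation; hyperparameter search is out of scope.
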