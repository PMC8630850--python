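# epidmr

Hybrid deep-learning / gradient-boosting prediction of genomic windows
susceptible to becoming **environmentally induced transgenerational
differentially methylated regions** (DMRs, also called epimutations).

Exposure of a gestating female to certain toxicants (atrazine, DDT,
glyphosate, vinclozolin, pesticides, dioxin, jet fuel, methoxychlor,
plastics) induces sperm DNA-methylation changes that persist into the F3
generation — the first with no direct exposure. MeDIP-seq analysis of such
lineages yields, for every 1000 bp genomic window, a p-value that the
window is *not* differentially methylated. `epidmr` learns, from DNA
sequence alone, which windows are susceptible:

1. **Windows.** A genome FASTA is tiled into non-overlapping 1000 bp
   windows, one-hot encoded as 5 × 1000 matrices over (A, C, G, T, N).
2. **Labels.** A window is a DMR if its p-value is `< 1e-5` in *any*
   exposure (union rule). Negatives are windows with **zero CpG
   dinucleotides** — without a CpG there is nothing to methylate. Windows
   with CpGs but no significant p-value stay unlabeled.
3. **Feature learning.** A two-block convolutional network (32 then 64
   filters of width 20; each conv followed by batch-norm and ReLU; max
   pooling and dropout 0.4 per block; dense 256/128; 2-node softmax) is
   trained on the labeled windows with Adam, cross-entropy and early
   stopping on validation loss.
4. **Hybrid classification.** Each window is re-expressed as 32 features —
   the pooled activation of each first-layer kernel — and an XGBoost
   classifier (200 trees, depth 6, learning rate 0.1, positive-class
   weight n_nonDMR/n_DMR) makes the final call. XGBoost's gain ranking
   says which learned features matter.
5. **Interpretation.** Every kernel becomes a position weight matrix (PWM)
   built from the subsequences that drive it to ≥ 50% of its maximum
   activation, labeled a DMR or non-DMR *detector* by the sign of its
   mean activation difference between classes, exportable as MEME motifs.
6. **Genome scan.** The trained hybrid model scores every window of any
   genome into BED calls plus a summary with the "maximum possible DMR"
   bound (windows with 1–200 CpGs).

Everything is testable offline: `epidmr.simulate` generates labeled
windows with planted motifs, CpG-free (or CpG-matched) negatives, matching
p-value tables, and toy genomes.

## Worked example

```python
import numpy as np
from epidmr import (ConvNetClassifier, HybridDMRClassifier, cross_validate,
                    generate)
from epidmr.simulate import SyntheticSpec

ds = generate(SyntheticSpec(n_per_class=1000, seed=1))   # 2000 windows
X, y = ds.encode(), ds.labels                            # (2000, 5, 1000)

model = HybridDMRClassifier(network=ConvNetClassifier(max_epochs=1))
report = cross_validate(model, X, y, k=5, seed=1)
print(f"mean accuracy {report.mean.accuracy:.4f}  "
      f"precision {report.mean.precision:.4f}  recall {report.mean.recall:.4f}")
```

prints

```
mean accuracy 0.9975  precision 0.9980  recall 0.9970
```

i.e. fivefold cross-validation of the full two-stage pipeline on the
separable synthetic fixture: each fold retrains both the network and the
boosted classifier on 80% of the windows and scores the held-out 20%, so
the numbers are honest out-of-sample estimates. On real MeDIP-seq-derived
tables the same protocol is run per chromosome or genome-wide via the CLI:

```bash
epidmr simulate --out-dir fixtures/ --n-per-class 200 --seed 1
epidmr cv   --fasta fixtures/genome.fa --stats fixtures/stats.tsv --out cv.tsv
epidmr train --fasta fixtures/genome.fa --stats fixtures/stats.tsv --model-out model.pkl
epidmr scan --fasta fixtures/genome.fa --model model.pkl --out scan.bed --summary summary.tsv
epidmr motifs --fasta fixtures/genome.fa --stats fixtures/stats.tsv --model model.pkl --out motifs.meme
```

## Layout

| module | contents |
| --- | --- |
| `epidmr.windows` | FASTA reading, 1000 bp tiling, one-hot encoding, CpG stats |
| `epidmr.dataset` | p-value labeling, zero-CpG negatives, max-possible-DMR bound |
| `epidmr.network` | `ConvNetClassifier` (NumPy CNN, sklearn estimator API) |
| `epidmr.features` | conv-1 activation pooling, detector classification |
| `epidmr.hybrid` | `HybridDMRClassifier` (CNN features + XGBoost) |
| `epidmr.evaluate` | metrics, stratified CV with per-fold retraining |
| `epidmr.motifs` | activating subsequences, PWMs, MEME/TSV export |
| `epidmr.scan` | whole-genome scanning, summaries, BED output |
| `epidmr.simulate` | synthetic fixtures: planted motifs, p-value tables, toy genomes |
| `epidmr.cli` | `epidmr` command-line interface |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
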