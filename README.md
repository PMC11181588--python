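# strgcn

EEG classification from functional connectivity: wavelet-coherence channel
graphs feeding a spatial–temporal residual graph convolutional network
(STRGCN), with the complete preprocessing, connectivity, training and
evaluation pipeline and a synthetic-data generator that makes every stage
testable without any external recordings.

The package is aimed at neuroinformatics work on psychiatric-disorder
classification from multichannel EEG — the running example is separating
schizophrenia patients (SZ) from healthy controls (HC) — and at anyone who
needs a clean, NumPy-level reference implementation of the building blocks:
continuous wavelet coherence, spectral graph convolution, causal temporal
convolution, channel attention, and k-fold evaluation.

## The method

**Connectivity.** For channels *x*, *y* the continuous wavelet transform
W<sub>x</sub>(t, f) (complex Morlet, ω₀ = 6) yields a smoothed cross-spectrum

CW<sub>xy</sub>(t, f) = ∫<sub>t−θ/2</sub><sup>t+θ/2</sup> W<sub>x</sub>(μ, f)·W<sub>y</sub>\*(μ, f) dμ,  θ(f) = c/f,

and the wavelet coherence

WC<sub>xy</sub>(t, f) = |CW<sub>xy</sub>| / (CW<sub>xx</sub>·CW<sub>yy</sub>)<sup>1/2</sup> ∈ [0, 1].

Averaging WC over time and a frequency band gives a symmetric channel×channel
connectivity matrix **W**, the weighted adjacency of the EEG channel graph.

**Graph operators.** From **W** the package builds the normalized Laplacian
L = I − D<sup>−1/2</sup>WD<sup>−1/2</sup>, Chebyshev polynomial filters
Θ\*<sub>𝒢</sub>x ≈ Σ<sub>k</sub> θ<sub>k</sub>T<sub>k</sub>(L̃)x, and the
first-order renormalized propagation operator
P = D̃<sup>−1/2</sup>(W + I)D̃<sup>−1/2</sup> used inside the network.

**Network.** Two ST-Conv blocks, each: causal temporal convolution → spatial
graph convolution (P X Θ per time step) → channel attention
(σ(MLP(AvgPool) + MLP(MaxPool)) gates per feature) → causal temporal
convolution → layer normalization, wrapped in an additive residual shortcut.
Each block's features are time-averaged, flattened over nodes×features, and
integrated by a linear softmax head.  Ablations: TRCN (graph stage removed)
and SRGCN (temporal stages removed).

**Evaluation.** Stratified k-fold cross-validation (default k = 10), Adam
with validation-based early stopping, and confusion-matrix metrics —
accuracy, recall, precision, F1 = 2·TP/(2·TP + FP + FN) — plus ROC/AUC.

The network and its training loop run on a small reverse-mode autodiff
engine included in the package (`strgcn.autograd`), so the only heavy
dependencies are the scientific Python stack.

## Worked example

```python
import numpy as np
from strgcn import (SynthConfig, synth_two_class_dataset,
                    TrainConfig, run_cv_experiment, compute_f1)

# two-class dataset: 19 channels, 4-s epochs at 256 Hz; the HC class
# couples four fronto-central channel pairs at 0.9, the SZ class at 0.2
ds = synth_two_class_dataset(SynthConfig(n_epochs_per_class=50, seed=1))

res = run_cv_experiment(
    ds, train_cfg=TrainConfig(max_epochs=40, patience=10, batch_size=16,
                              validation_fraction=0.15, seed=0), k=5)
print(f"mean accuracy {res.mean['accuracy']:.1f}%  "
      f"per fold {[r.accuracy for r in res.fold_reports]}")
print("F1 from published precision/recall:", compute_f1(95.60, 91.02))
```

Output from the code above:

```
mean accuracy 100.0%  per fold [100.0, 100.0, 100.0, 100.0, 100.0]
F1 from published precision/recall: 93.25
```

The 100% five-fold accuracy says the pipeline — per-epoch coherence graphs,
noise-floor screening, the fixed training-fold adjacency, and the network —
recovers the designed coupling contrast (0.9 vs 0.2) from 100 labeled
epochs; `93.25` is the F1 score implied by a precision of 95.60% and recall
of 91.02%, reproducing the published table row for the full model.

A command-line interface mirrors the library:

```bash
strgcn synth --n-epochs 50 --seed 1 --out epochs.npz
strgcn connectivity --epochs epochs.npz --band full --threshold 0.6 --out conn
strgcn train --epochs epochs.npz --variant STRGCN --k 10 --seed 0 --out run/
strgcn evaluate --weights run/weights.npz --epochs epochs.npz --out metrics.json
```

## Layout

| module | contents |
| --- | --- |
| `strgcn.preprocessing` | EDF/matrix readers, Butterworth band-pass, sub-bands, channel selection, epoching |
| `strgcn.connectivity` | CWT, smoothed cross-spectra, wavelet coherence, band-mean matrices, thresholding, group t-tests |
| `strgcn.graph` | Laplacian/propagation operators, Chebyshev filtering, spectral oracle |
| `strgcn.model` | ST-Conv blocks, attention, residual wrapping, STRGCN/TRCN/SRGCN |
| `strgcn.training` | Adam, early stopping, k-fold CV, metrics, ROC |
| `strgcn.simulate` | coupled-oscillator EEG generator, analytic coherence oracle |
| `strgcn.autograd` | the tape-based autodiff engine the model runs on |

See `docs/methods.md` for the modelling choices, estimator calibration, and
known limitations.
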