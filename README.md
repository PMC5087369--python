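# aiqp — abnormal intra-QRS potential analysis of signal-averaged ECGs

Abnormal intra-QRS potentials (AIQPs) are weak, rapidly varying notch-and-slur
signals buried *inside* the QRS complex of a signal-averaged electrocardiogram.
They accompany the arrhythmic substrates seen in patients at risk of
ventricular tachycardia (VT), but unlike ventricular late potentials they
cannot be read off the end of the complex — they have to be separated from a
signal three orders of magnitude stronger.

This package implements a residual-based estimator for clinicians' and signal-
processing researchers' use at desk scale. A measured QRS complex
`y(n), n = 1..p` is approximated by a Gaussian radial-basis-function network
whose basis functions all share one spread σ:

```
ŷ(n) = Σⱼ wⱼ φ(n − cⱼ),   φ(n − c) = exp(−(n − c)² / 2σ²)
```

Because every basis function is equally smooth, the network acts as a
smoothness filter: the slow, strong "normal" part of the complex is captured
by ŷ, while anything sharper than the basis — the AIQP — survives in the
residual `e = y − ŷ`. The M center locations cⱼ are picked greedily from all
p sample positions by orthogonal least squares (OLS): at each step every
remaining candidate column is Gram–Schmidt-orthogonalized against the selected
ones and the candidate with the largest *error reduction ratio*
`[err] = g²·sᵀs / yᵀy` is appended. Two summary statistics follow:

* **AIQP** = RMS of the residual (µV);
* **AQR** = AIQP / RMS(y), the AIQP-to-QRS ratio, which removes the overall
  amplitude of the complex (the residual scales linearly with it).

AQR values swept over grids of (M, σ) — conventionally `AQR(20, 1:20)` and
`AQR(2:40, 10)` per lead — are combined across the X, Y and Z leads by
Fisher's linear discriminant, and performance is reported as specificity,
sensitivity, total prediction accuracy (TPA) and ROC area (AUC), with VT as
the positive class.

The package also provides the standard preprocessing around the estimator
(beat averaging with correlation alignment, 40–250 Hz zero-phase Butterworth
filtering, XYZ vector magnitude, QRS bounds, and the fQRSD / RMS40 / LAS40
late-potential indices) and a synthetic-data module (smooth QRS complexes,
colored-noise AIQPs, labelled two-group cohorts) so the whole chain is
testable without patient data.

## Worked example

```python
from aiqp import fit_rbfnn, simulate_qrs

qrs = simulate_qrs()                      # 100 ms synthetic complex at 2 kHz
model, result, trace = fit_rbfnn(qrs, M=20, sigma=10.0)
print(f"{qrs.rms:.1f} uV QRS, AIQP {result.aiqp:.2f} uV, AQR {100*result.aqr:.2f} %")
```

prints

```
607.3 uV QRS, AIQP 6.66 uV, AQR 1.10 %
```

— a 607 µV complex whose 20-neuron approximation leaves a 6.66 µV residual,
i.e. an AQR of 1.1%. This inherent residual of a *clean* complex is the crux
of the method's failure mode: an added abnormal potential that is partly out
of phase with it can *lower* the residual, making a sick beat look cleaner
(`examples/02_misjudgment_study.py` shows three such misjudgments in 50
repetitions at (20, 10), corrected by the (20, 12) configuration and vice
versa). The `examples/` directory walks through each capability: a single
fit, the misjudgment study, the preprocessing/VLP chain, and an end-to-end
cohort classification. A thin CLI (`aiqp fit / grid / vlp / simulate /
classify / roc`) wraps the same functions for shell use.

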