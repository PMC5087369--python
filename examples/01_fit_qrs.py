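"""Fit an RBF network to a synthetic QRS complex and read off the AIQP.

Builds the default synthetic normal QRS (100 ms at 2 kHz, ~607 uV RMS),
approximates it with a 20-neuron Gaussian RBF network of spread 10 samples
selected by orthogonal least squares, and prints the residual statistics.
The residual RMS is the AIQP estimate in microvolts; AQR divides it by the
QRS RMS so that subjects with big and small complexes are comparable.
"""

import numpy as np

from aiqp import fit_rbfnn, simulate_qrs

qrs = simulate_qrs()
model, result, trace = fit_rbfnn(qrs, M=20, sigma=10.0)

print(f"QRS RMS:            {qrs.rms:8.1f} uV")
print(f"residual RMS (AIQP):{result.aiqp:8.2f} uV")
print(f"AQR:                {100 * result.aqr:8.2f} %")
print(f"first 5 centers:    {model.centers[:5].tolist()} (sample indices)")
print(f"energy explained:   {100 * np.sum(trace.err_ratios):8.4f} %")
# The inherent ~1% AQR is the part of a clean complex the smooth basis
# cannot synthesize; an embedded abnormal potential adds on top of it.
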