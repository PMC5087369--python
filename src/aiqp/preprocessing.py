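"""Signal-averaged ECG preprocessing and time-domain late-potential indices.

Covers the standard chain in front of any intra-QRS analysis: averaging an
aligned beat ensemble to suppress uncorrelated noise, 40-250 Hz Butterworth
bandpass filtering (zero-phase by default), the XYZ vector magnitude, QRS
onset/offset detection on the vector magnitude, and the three conventional
time-domain ventricular-late-potential parameters:

* fQRSD -- filtered QRS duration, onset to offset, in ms;
* RMS40 -- RMS voltage of the terminal 40 ms of the filtered QRS, in uV;
* LAS40 -- duration the terminal filtered QRS stays below 40 uV, in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import (
    EmptyEnsembleError,
    InvalidInputError,
    InvalidParameterError,
    NoQRSDetectedError,
)
from .signals import BeatEnsemble, BeatSignal, as_samples

__all__ = [
    "AveragingInfo",
    "VLPParams",
    "signal_average",
    "bandpass_filter",
    "vector_magnitude",
    "detect_qrs_bounds",
    "vlp_params",
]


@dataclass(frozen=True)
class AveragingInfo:
    """Alignment bookkeeping: per-beat shift applied and acceptance flag."""

    shifts: np.ndarray  # samples each beat was shifted by before averaging
    kept: np.ndarray  # boolean acceptance mask
    peak_correlations: np.ndarray


def signal_average(
    ensemble: BeatEnsemble,
    align: bool = True,
    reject_correlation_below: float = 0.98,
    return_info: bool = False,
):
    """Average a beat ensemble into one signal-averaged window.

    With ``align`` on, each beat is shifted by the integer lag maximizing
    its cross-correlation with the first beat (the template); beats whose
    peak normalized correlation falls below the rejection threshold are
    discarded. Shifts are applied circularly, which is harmless for beat
    windows whose edges sit near baseline. The mean of the surviving
    aligned beats is returned (optionally with an :class:`AveragingInfo`).
    """
    beats = ensemble.as_matrix()
    n_beats, p = beats.shape
    template = beats[0]
    tnorm = np.linalg.norm(template)
    shifts = np.zeros(n_beats, dtype=int)
    peaks = np.ones(n_beats)
    kept = np.ones(n_beats, dtype=bool)
    aligned = beats.copy()
    if align and tnorm > 0:
        for i in range(1, n_beats):
            b = beats[i]
            bnorm = np.linalg.norm(b)
            if bnorm == 0:
                peaks[i] = 0.0
                continue
            xc = sps.correlate(template, b, mode="full")
            lag = int(np.argmax(xc)) - (p - 1)  # template ~ b shifted by +lag
            peaks[i] = float(np.max(xc) / (tnorm * bnorm))
            shifts[i] = lag
            aligned[i] = np.roll(b, lag)
        kept = peaks >= reject_correlation_below
    if not kept.any():
        raise EmptyEnsembleError("every beat was rejected during alignment")
    avg = aligned[kept].mean(axis=0)
    out = BeatSignal(avg, fs=ensemble.fs, lead=ensemble.lead)
    if return_info:
        return out, AveragingInfo(shifts=shifts, kept=kept, peak_correlations=peaks)
    return out


def bandpass_filter(
    x,
    low: float = 40.0,
    high: float = 250.0,
    order: int = 4,
    zero_phase: bool = True,
    fs: float = 2000.0,
    mode: str = "standard",
):
    """Butterworth bandpass of analog-prototype order ``order``.

    ``zero_phase`` applies the filter forward and backward (squared
    magnitude response, no phase distortion); otherwise a single forward
    pass is used. ``mode="segmented"`` instead filters forward over the
    first half of the record and backward over the second half, the
    segment-wise bidirectional scheme some SAECG systems use to keep
    filter ringing from smearing across the QRS; the standard zero-phase
    mode is the default. Reflection padding of three filter lengths guards
    the edges in all modes.

    Note the "order" is the analog prototype order before the bandpass
    transformation (a 4th-order bandpass has 8 poles).
    """
    arr = as_samples(x)
    if not (0 < low < high < fs / 2):
        raise InvalidParameterError(
            f"band ({low}, {high}) is invalid at fs={fs} (need 0 < low < high < fs/2)"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    ntaps = 2 * order + 1  # length of the transfer-function polynomials
    pad = min(3 * ntaps, arr.size - 1)
    if mode == "segmented":
        mid = arr.size // 2
        padded = np.concatenate([arr[pad:0:-1], arr, arr[-2 : -pad - 2 : -1]])
        fwd = sps.sosfilt(sos, padded)[pad : pad + arr.size]
        bwd = sps.sosfilt(sos, padded[::-1])[::-1][pad : pad + arr.size]
        out = np.concatenate([fwd[:mid], bwd[mid:]])
    elif zero_phase:
        out = sps.sosfiltfilt(sos, arr, padlen=pad)
    else:
        padded = np.concatenate([arr[pad:0:-1], arr, arr[-2 : -pad - 2 : -1]])
        out = sps.sosfilt(sos, padded)[pad : pad + arr.size]
    if isinstance(x, BeatSignal):
        return BeatSignal(out, fs=x.fs, lead=x.lead, onset_idx=x.onset_idx,
                          offset_idx=x.offset_idx)
    return out


def vector_magnitude(x, y, z) -> np.ndarray:
    """Pointwise Euclidean norm sqrt(x^2 + y^2 + z^2) of the three leads."""
    ax, ay, az = as_samples(x), as_samples(y), as_samples(z)
    if not (ax.size == ay.size == az.size):
        raise InvalidInputError(
            f"lead lengths differ: {ax.size}, {ay.size}, {az.size}"
        )
    return np.sqrt(ax**2 + ay**2 + az**2)


def detect_qrs_bounds(
    vm,
    noise_window: tuple,
    k_sigma: float = 3.0,
    sustain_ms: float = 5.0,
    fs: float = 2000.0,
):
    """QRS onset/offset on the vector magnitude by sustained thresholding.

    The detection threshold is noise mean + ``k_sigma`` x noise SD over the
    given ``noise_window`` (0-based [start, end) indices, taken outside the
    QRS). The onset is the first sample from which the vector magnitude
    stays above threshold for ``sustain_ms``; the offset is the last sample
    of the last such sustained excursion. Returns
    ``(onset_idx, offset_idx, noise_rms)`` with 0-based indices.
    """
    v = as_samples(vm)
    if sustain_ms <= 0:
        raise InvalidParameterError("sustain_ms must be positive")
    a, b = noise_window
    if not (0 <= a < b <= v.size):
        raise InvalidParameterError(f"noise window {noise_window} outside the record")
    noise = v[a:b]
    threshold = float(noise.mean() + k_sigma * noise.std())
    noise_rms = float(np.sqrt(np.mean(noise**2)))
    run = max(1, int(round(sustain_ms * fs / 1000.0)))
    above = v > threshold
    # sustained[i] == True when above[i:i+run] is all True
    sustained = (
        np.convolve(above.astype(int), np.ones(run, dtype=int), mode="valid") == run
    )
    starts = np.nonzero(sustained)[0]
    if starts.size == 0:
        raise NoQRSDetectedError(
            f"no {sustain_ms} ms sustained crossing of {threshold:.3g} uV found"
        )
    onset = int(starts[0])
    offset = int(starts[-1] + run - 1)
    return onset, offset, noise_rms


@dataclass(frozen=True)
class VLPParams:
    """Time-domain ventricular-late-potential parameters."""

    fqrsd_ms: float
    rms40_uV: float
    las40_ms: float
    onset_idx: int
    offset_idx: int
    noise_rms_uV: float | None = None

    def to_dict(self) -> dict:
        return {
            "fqrsd_ms": self.fqrsd_ms,
            "rms40_uV": self.rms40_uV,
            "las40_ms": self.las40_ms,
            "onset_idx": self.onset_idx,
            "offset_idx": self.offset_idx,
            "noise_rms_uV": self.noise_rms_uV,
        }


def vlp_params(
    vm,
    onset_idx: int,
    offset_idx: int,
    fs: float = 2000.0,
    las_threshold_uV: float = 40.0,
    noise_rms: float | None = None,
) -> VLPParams:
    """fQRSD, RMS40 and LAS40 from a filtered vector magnitude.

    ``onset_idx``/``offset_idx`` are 0-based sample indices (inclusive).
    RMS40 is computed over the 40 ms ending at the offset; LAS40 scans
    backward from the offset to the last sample exceeding the low-amplitude
    threshold (conventionally 40 uV) and reports the elapsed duration; if
    nothing within the QRS exceeds it, LAS40 equals fQRSD.
    """
    v = as_samples(vm)
    if not (0 <= onset_idx < offset_idx < v.size):
        raise InvalidInputError(
            f"need 0 <= onset < offset < {v.size}, got ({onset_idx}, {offset_idx})"
        )
    n40 = int(round(0.040 * fs))
    if offset_idx + 1 < n40:
        raise InvalidInputError(
            f"only {offset_idx + 1} samples before the offset; 40 ms needs {n40}"
        )
    fqrsd = (offset_idx - onset_idx) / fs * 1000.0
    rms40 = float(np.sqrt(np.mean(v[offset_idx + 1 - n40 : offset_idx + 1] ** 2)))
    seg = v[onset_idx : offset_idx + 1]
    above = np.nonzero(seg > las_threshold_uV)[0]
    if above.size == 0:
        las40 = fqrsd
    else:
        las40 = (seg.size - 1 - int(above[-1])) / fs * 1000.0
    return VLPParams(
        fqrsd_ms=float(fqrsd),
        rms40_uV=rms40,
        las40_ms=float(min(las40, fqrsd)),
        onset_idx=int(onset_idx),
        offset_idx=int(offset_idx),
        noise_rms_uV=noise_rms,
    )
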