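"""Core signal containers.

A :class:`BeatSignal` is one lead's QRS window: a uniformly sampled amplitude
series in microvolts together with its sampling rate. Sample indices follow
the 1-based convention n = 1..p used throughout the RBF formulation, so a
center at index c coincides with the c-th sample of the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = ["BeatSignal", "BeatEnsemble", "as_samples"]


def as_samples(y) -> np.ndarray:
    """Coerce a BeatSignal or array-like to a 1-D float64 sample array."""
    if isinstance(y, BeatSignal):
        return y.samples
    arr = np.asarray(y, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"expected a 1-D sample array, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class BeatSignal:
    """One lead's QRS-window samples.

    Parameters
    ----------
    samples : array-like
        Amplitudes in microvolts, length p >= 2, all finite.
    fs : float
        Sampling frequency in Hz (default 2000, i.e. 0.5 ms per sample).
    lead : str
        Lead label; conventionally one of "X", "Y", "Z".
    onset_idx, offset_idx : int or None
        Optional QRS onset/offset annotations (1-based sample indices).
    """

    samples: np.ndarray
    fs: float = 2000.0
    lead: str = "X"
    onset_idx: int | None = None
    offset_idx: int | None = None

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise InvalidInputError("a BeatSignal needs at least 2 samples in 1-D")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("BeatSignal samples must all be finite")
        if not (self.fs > 0):
            raise InvalidParameterError(f"sampling rate must be positive, got {self.fs}")
        arr.setflags(write=False)
        object.__setattr__(self, "samples", arr)

    @property
    def p(self) -> int:
        """Window length in samples."""
        return self.samples.size

    @property
    def rms(self) -> float:
        """Root-mean-square amplitude in microvolts."""
        return float(np.sqrt(np.mean(self.samples**2)))

    def scaled(self, alpha: float) -> "BeatSignal":
        """Return an amplitude-scaled copy (same fs, lead, annotations)."""
        return BeatSignal(self.samples * alpha, self.fs, self.lead,
                          self.onset_idx, self.offset_idx)


@dataclass
class BeatEnsemble:
    """A stack of equal-length single-lead beat windows for signal averaging."""

    beats: list = field(default_factory=list)
    fs: float = 2000.0
    lead: str = "X"

    def __post_init__(self):
        if len(self.beats) < 1:
            raise InvalidInputError("an ensemble needs at least one beat")
        arrs = [as_samples(b) for b in self.beats]
        n = arrs[0].size
        if any(a.size != n for a in arrs):
            raise InvalidInputError("all beats in an ensemble must have equal length")
        self.beats = arrs

    @property
    def n_beats(self) -> int:
        return len(self.beats)

    def as_matrix(self) -> np.ndarray:
        """Beats stacked as an (n_beats, p) array."""
        return np.vstack(self.beats)
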