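"""Recording harmonization, epoching, artifact screening, re-referencing.

A raw multichannel recording is band-passed (0.1-45 Hz, zero phase),
down-sampled to 256 Hz when needed, cut into non-overlapping 2-s epochs,
screened for high-frequency (muscle-like) artifacts with a robust
threshold on 30-70 Hz log-power, and re-referenced to the common average.
Artifactual epochs are flagged, never deleted, so retained fractions can
be reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import signal

from .montage import CHANNELS_1020, normalize_label

__all__ = [
    "Recording",
    "EpochSet",
    "harmonize",
    "epoch",
    "screen_artifacts",
    "rereference_common_average",
    "preprocess_recording",
    "TARGET_FS",
]

TARGET_FS = 256.0
BANDPASS = (0.1, 45.0)
BANDPASS_ORDER = 4        # Butterworth order (per pass; applied forward+backward)


@dataclass
class Recording:
    """A 19-channel scalp recording in microvolts."""

    subject_id: str
    channel_labels: tuple
    fs: float
    data: np.ndarray               # (19, n_samples), µV
    reference: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        labels = tuple(normalize_label(c) for c in self.channel_labels)
        if len(labels) != 19 or len(set(labels)) != 19:
            raise ValueError(
                f"expected 19 unique 10-20 channels, got {len(labels)}: {labels}"
            )
        if set(labels) != set(CHANNELS_1020):
            missing = set(CHANNELS_1020) - set(labels)
            raise ValueError(f"missing canonical channels: {sorted(missing)}")
        if labels != tuple(CHANNELS_1020):
            order = [labels.index(c) for c in CHANNELS_1020]
            self.data = self.data[order]
        self.channel_labels = tuple(CHANNELS_1020)
        if self.data.shape[0] != 19:
            raise ValueError("data must be (19, n_samples)")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class EpochSet:
    """Fixed-length segments of a recording with per-epoch artifact flags."""

    epochs: np.ndarray             # (n_epochs, 19, samples_per_epoch)
    fs: float
    flags: np.ndarray = None       # True = artifactual
    provenance: str = ""
    reference: str = "unknown"

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.flags is None:
            self.flags = np.zeros(len(self.epochs), dtype=bool)
        self.flags = np.asarray(self.flags, bool)

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def retained_fraction(self) -> float:
        return float(1.0 - self.flags.mean()) if self.n_epochs else 0.0

    def unflagged(self) -> np.ndarray:
        return self.epochs[~self.flags]


@lru_cache(maxsize=16)
def _zero_phase_response(n: int, fs: float, band: tuple, order: int) -> np.ndarray:
    """Squared-magnitude Butterworth band-pass response on the rfft grid.

    Zero-phase filtering is implemented in the frequency domain: the data
    spectrum is multiplied by |H(f)|² of an order-``order`` Butterworth
    band-pass, the exact response of a forward-backward pass without the
    edge transients of time-domain filtering.
    """
    f = np.fft.rfftfreq(n, 1.0 / fs)
    lo, hi = band
    with np.errstate(divide="ignore"):
        hp = 1.0 / (1.0 + (np.divide(lo, np.maximum(f, 1e-12))) ** (2 * order))
    lp = 1.0 / (1.0 + (f / hi) ** (2 * order))
    return hp * lp


def bandpass_zero_phase(data: np.ndarray, fs: float, band=BANDPASS,
                        order=BANDPASS_ORDER) -> np.ndarray:
    """Zero-phase band-pass along the last axis (see _zero_phase_response)."""
    n = data.shape[-1]
    H = _zero_phase_response(n, fs, tuple(band), order)
    spec = np.fft.rfft(data, axis=-1)
    spec *= H
    return np.fft.irfft(spec, n=n, axis=-1)


def harmonize(rec: Recording, bandpass=BANDPASS, order=BANDPASS_ORDER) -> Recording:
    """Band-pass (zero-phase) and resample to 256 Hz.

    Sampling rates below 256 Hz are rejected; above, polyphase resampling
    brings the recording onto the common rate before epoching.
    """
    if rec.fs < TARGET_FS:
        raise ValueError(f"sampling rate {rec.fs} Hz < required {TARGET_FS} Hz")
    data = rec.data
    fs = rec.fs
    if fs > TARGET_FS:
        frac = Fraction(TARGET_FS / fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
        fs = TARGET_FS
    data = bandpass_zero_phase(data, fs, bandpass, order)
    return Recording(
        subject_id=rec.subject_id,
        channel_labels=rec.channel_labels,
        fs=fs,
        data=data,
        reference=rec.reference,
    )


def epoch(rec: Recording, epoch_seconds: float = 2.0) -> EpochSet:
    """Cut into consecutive non-overlapping epochs; the remainder is dropped."""
    spe = int(round(epoch_seconds * rec.fs))
    n = rec.data.shape[1] // spe
    if n < 1:
        raise ValueError(
            f"recording of {rec.duration:.3f} s is shorter than one "
            f"{epoch_seconds} s epoch"
        )
    cut = rec.data[:, : n * spe].reshape(19, n, spe).transpose(1, 0, 2)
    return EpochSet(
        epochs=cut.copy(), fs=rec.fs, provenance=rec.subject_id,
        reference=rec.reference,
    )


def _hf_logpower(epochs: np.ndarray, fs: float, band) -> np.ndarray:
    """Per-epoch mean (over channels) log10 power in ``band``."""
    n = epochs.shape[-1]
    w = np.hanning(n)
    spec = np.abs(np.fft.rfft(epochs * w, axis=-1)) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    m = (freqs >= band[0]) & (freqs <= band[1])
    p = spec[..., m].sum(axis=-1).mean(axis=-1)     # (n_epochs,)
    return np.log10(np.maximum(p, 1e-300))


def screen_artifacts(
    eps: EpochSet, hf_band=(30.0, 70.0), k: float = 4.0
) -> EpochSet:
    """Flag epochs with unusually high 30-70 Hz power.

    An epoch is flagged when its channel-mean log10 high-frequency power
    exceeds the per-recording median by ``k`` robust (MAD-based) standard
    deviations.  Flags accumulate; nothing is deleted.
    """
    if eps.fs < 2 * hf_band[1] * 0.99 and eps.fs < 2 * hf_band[1]:
        # band only partially resolvable; use what the Nyquist allows
        hf_band = (hf_band[0], min(hf_band[1], eps.fs / 2))
    lp = _hf_logpower(eps.epochs, eps.fs, hf_band)
    med = np.median(lp)
    mad = np.median(np.abs(lp - med))
    sd = 1.4826 * mad
    if sd == 0.0:
        new_flags = np.zeros_like(eps.flags)
    else:
        new_flags = lp > med + k * sd
    flags = eps.flags | new_flags
    out = EpochSet(
        epochs=eps.epochs, fs=eps.fs, flags=flags,
        provenance=eps.provenance, reference=eps.reference,
    )
    if flags.all():
        import warnings

        warnings.warn(
            f"all {eps.n_epochs} epochs flagged as artifactual for "
            f"{eps.provenance!r}; spectral estimation will fail downstream",
            stacklevel=2,
        )
    return out


def rereference_common_average(eps: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across channels (idempotent)."""
    if eps.epochs.shape[1] < 2:
        raise ValueError("common average reference needs at least 2 channels")
    data = eps.epochs - eps.epochs.mean(axis=1, keepdims=True)
    return EpochSet(
        epochs=data, fs=eps.fs, flags=eps.flags.copy(),
        provenance=eps.provenance, reference="common-average",
    )


def preprocess_recording(
    rec: Recording, epoch_seconds: float = 2.0, hf_k: float = 4.0
) -> EpochSet:
    """harmonize -> epoch -> screen -> common average, in the study's order."""
    return rereference_common_average(
        screen_artifacts(epoch(harmonize(rec), epoch_seconds), k=hf_k)
    )
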