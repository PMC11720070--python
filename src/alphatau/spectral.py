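"""Welch spectra, TF/IAF landmarks, and individualized frequency bands.

The per-subject spectral description: average Hanning-windowed
periodograms over the artifact-free 2-s epochs (0.5 Hz resolution), find
the transition frequency (TF, the 3-8 Hz power minimum) and individual
alpha frequency (IAF, the 6-14 Hz peak), and build the eight-band scheme
anchored on those landmarks (delta/theta/alpha1-3 individualized,
beta1/beta2/gamma fixed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import CHANNELS_1020, POSTERIOR_CHANNELS
from .preprocess import EpochSet

__all__ = [
    "PowerSpectrum",
    "SpectralLandmarks",
    "BandScheme",
    "welch_psd",
    "welch_csd",
    "detect_landmarks",
    "build_bands",
    "band_power",
    "GRID_DF",
    "GRID_RANGE",
]

GRID_DF = 0.5
GRID_RANGE = (0.5, 45.0)
TF_WINDOW = (3.0, 8.0)
IAF_WINDOW = (6.0, 14.0)
IAF_FALLBACK = 9.0
FIXED_BANDS = {"beta1": (14.0, 20.0), "beta2": (20.0, 30.0), "gamma": (30.0, 40.0)}
BAND_ORDER = ("delta", "theta", "alpha1", "alpha2", "alpha3",
              "beta1", "beta2", "gamma")


@dataclass
class PowerSpectrum:
    """Per-channel power spectral density on the 0.5-45 Hz half-Hz grid."""

    freqs: np.ndarray              # (n_bins,), 0.5 Hz spacing
    density: np.ndarray            # (19, n_bins), µV²/Hz
    n_epochs_used: int
    channel_labels: tuple = tuple(CHANNELS_1020)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        self.density = np.asarray(self.density, float)
        if not np.allclose(np.diff(self.freqs), GRID_DF):
            raise ValueError("frequency grid spacing must be exactly 0.5 Hz")
        if np.any(self.density < -1e-12):
            raise ValueError("power density must be non-negative")

    def channel_mean(self, channels) -> np.ndarray:
        idx = [self.channel_labels.index(c) for c in channels]
        return self.density[idx].mean(axis=0)


@dataclass
class SpectralLandmarks:
    """Transition frequency and individual alpha frequency, with fallbacks."""

    tf: float
    iaf: float
    tf_fallback_used: bool = False
    iaf_fallback_used: bool = False

    def __post_init__(self):
        if not (TF_WINDOW[0] <= self.tf <= TF_WINDOW[1]):
            raise ValueError(f"TF {self.tf} outside search window {TF_WINDOW}")
        if not (IAF_WINDOW[0] <= self.iaf <= IAF_WINDOW[1]):
            raise ValueError(f"IAF {self.iaf} outside search window {IAF_WINDOW}")
        if self.tf >= self.iaf:
            raise ValueError(f"TF ({self.tf}) must lie below IAF ({self.iaf})")


class BandScheme(dict):
    """Eight named half-open frequency intervals [lo, hi), Hz.

    delta..alpha3 are contiguous and anchored on the subject's TF/IAF;
    beta1/beta2/gamma are fixed.  When IAF + 2 exceeds 14 Hz, alpha3
    overlaps the fixed beta1 band; bands are always reported independently
    and never summed across that boundary.
    """

    def __init__(self, bands: dict):
        missing = set(BAND_ORDER) - set(bands)
        if missing:
            raise ValueError(f"missing bands: {sorted(missing)}")
        super().__init__({k: tuple(map(float, bands[k])) for k in BAND_ORDER})
        for name, (lo, hi) in self.items():
            if hi <= lo:
                raise ValueError(f"band {name} is empty: [{lo}, {hi})")


def _snap(x: float) -> float:
    """Nearest 0.5 Hz grid value, ties upward."""
    return np.floor(2.0 * x + 0.5) / 2.0


def welch_psd(eps: EpochSet) -> PowerSpectrum:
    """Average Hanning periodogram over the unflagged epochs.

    The window is power-normalized (density scaling), so the rectangle-rule
    integral of the density of a pure sinusoid of amplitude A over its
    spectral support is A²/2.  Epochs are used whole: 2 s at 256 Hz gives
    the 0.5 Hz grid directly, with no sub-segmentation or overlap.
    """
    data = eps.unflagged()
    if len(data) == 0:
        raise ValueError("no unflagged epochs; cannot estimate a spectrum")
    n = data.shape[-1]
    w = np.hanning(n)
    scale = 1.0 / (eps.fs * (w**2).sum())
    spec = np.abs(np.fft.rfft(data * w, axis=-1)) ** 2 * scale
    spec[..., 1:-1] *= 2.0                     # one-sided
    density = spec.mean(axis=0)                # (19, n_bins_full)
    freqs = np.fft.rfftfreq(n, 1.0 / eps.fs)
    keep = (freqs >= GRID_RANGE[0] - 1e-9) & (freqs <= GRID_RANGE[1] + 1e-9)
    return PowerSpectrum(freqs=freqs[keep], density=density[:, keep],
                         n_epochs_used=len(data))


def welch_csd(eps: EpochSet):
    """Per-bin Hermitian cross-spectral matrices over unflagged epochs.

    Returns ``(csd, freqs)`` with csd of shape (n_bins, 19, 19), same
    scaling as :func:`welch_psd` (the diagonal equals the PSD).
    """
    data = eps.unflagged()
    if len(data) == 0:
        raise ValueError("no unflagged epochs; cannot estimate cross-spectra")
    n = data.shape[-1]
    w = np.hanning(n)
    scale = 1.0 / (eps.fs * (w**2).sum())
    F = np.fft.rfft(data * w, axis=-1)         # (e, 19, bins)
    freqs = np.fft.rfftfreq(n, 1.0 / eps.fs)
    keep = (freqs >= GRID_RANGE[0] - 1e-9) & (freqs <= GRID_RANGE[1] + 1e-9)
    F = F[..., keep]
    csd = np.einsum("eck,edk->kcd", F, F.conj()) * (scale / len(data))
    inner = (freqs[keep] > 1e-9) & (freqs[keep] < eps.fs / 2 - 1e-9)
    csd[inner] *= 2.0
    return csd, freqs[keep]


def detect_landmarks(
    spectrum: PowerSpectrum, channel_policy: str = "posterior"
) -> SpectralLandmarks:
    """TF and IAF from the policy-averaged density.

    TF is the frequency of the 3-8 Hz minimum (a boundary minimum is
    accepted but flagged).  IAF is the largest strictly local 6-14 Hz peak
    (plateau ties resolved to the higher frequency); if the window holds no
    local peak the 9 Hz fallback is used and flagged.
    """
    if channel_policy == "posterior":
        d = spectrum.channel_mean(POSTERIOR_CHANNELS)
    elif channel_policy == "all":
        d = spectrum.density.mean(axis=0)
    else:
        raise ValueError(f"unknown channel policy: {channel_policy!r}")
    f = spectrum.freqs
    if f[0] > TF_WINDOW[0] or f[-1] < IAF_WINDOW[1]:
        raise ValueError("spectrum grid must cover 3-14 Hz")

    tf_mask = (f >= TF_WINDOW[0]) & (f <= TF_WINDOW[1])
    tf_idx = np.flatnonzero(tf_mask)
    tf_pos = tf_idx[np.argmin(d[tf_mask])]
    tf = float(f[tf_pos])
    tf_fallback = tf_pos in (tf_idx[0], tf_idx[-1])

    iaf_mask = (f >= IAF_WINDOW[0]) & (f <= IAF_WINDOW[1])
    iaf_idx = np.flatnonzero(iaf_mask)
    peaks = [
        i for i in iaf_idx
        if 0 < i < len(f) - 1 and d[i] > d[i - 1] and d[i] >= d[i + 1]
    ]
    # plateau ties: keep the highest-frequency bin of equal-valued peaks
    if peaks:
        best = max(d[p] for p in peaks)
        iaf = float(f[max(p for p in peaks if d[p] == best)])
        iaf_fallback = False
    else:
        iaf, iaf_fallback = IAF_FALLBACK, True

    # a TF-IAF gap under 1 Hz cannot host the alpha1/alpha2 split; treat as
    # a degenerate spectrum and fall back
    if iaf - tf < 1.0:
        iaf, iaf_fallback = IAF_FALLBACK, True
        if iaf - tf < 1.0:
            tf, tf_fallback = 5.5, True
    return SpectralLandmarks(
        tf=tf, iaf=iaf,
        tf_fallback_used=bool(tf_fallback), iaf_fallback_used=bool(iaf_fallback),
    )


def build_bands(landmarks: SpectralLandmarks) -> BandScheme:
    """Individualized band scheme from the TF/IAF landmarks.

    Edges are snapped to the 0.5 Hz grid (ties upward); the delta lower
    edge is clamped at the 0.5 Hz grid start.  The alpha1/alpha2 split is
    the snapped midpoint of the raw TF-IAF range.
    """
    if landmarks.tf >= landmarks.iaf:
        raise ValueError("TF must lie strictly below IAF")
    tf = _snap(landmarks.tf)
    iaf = _snap(landmarks.iaf)
    mid = _snap(0.5 * (landmarks.tf + landmarks.iaf))
    if not (tf < mid < iaf):
        raise ValueError(
            f"degenerate landmarks after grid snapping: TF={tf}, mid={mid}, "
            f"IAF={iaf}; the TF-IAF gap must be at least 1 Hz"
        )
    bands = {
        "delta": (max(tf - 4.0, GRID_RANGE[0]), tf - 2.0),
        "theta": (tf - 2.0, tf),
        "alpha1": (tf, mid),
        "alpha2": (mid, iaf),
        "alpha3": (iaf, iaf + 2.0),
        **FIXED_BANDS,
    }
    return BandScheme(bands)


def band_power(spectrum: PowerSpectrum, band) -> np.ndarray:
    """Rectangle-rule integral of the density over bins in [lo, hi), per channel."""
    lo, hi = band
    mask = (spectrum.freqs >= lo - 1e-9) & (spectrum.freqs < hi - 1e-9)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}) contains no frequency bins")
    return spectrum.density[:, mask].sum(axis=1) * GRID_DF
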