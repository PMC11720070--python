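"""Idealized 10-20 electrode geometry and channel-label normalization.

Coordinate frame: +x toward the right preauricular point, +y toward the
nasion, +z toward the vertex; electrodes live on the scalp sphere.  The
positions follow the proportional 10-20 construction on a sphere: midline
and ear-to-ear electrodes at 20% arc steps (36 degrees), the outer ring at
the 10% circle (72 degrees from the vertex), and the intermediate F3/F4 /
P3/P4 sites on great-circle midpoints of their neighbors.
"""

from __future__ import annotations

import numpy as np

# canonical ordering used throughout the package (old-dialect names)
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

# both 10-20 naming dialects are accepted; normalized to the old names
LABEL_ALIASES = {
    "T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6",
}

POSTERIOR_CHANNELS = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")


def normalize_label(label: str) -> str:
    """Map a raw channel label onto the canonical 19-name set.

    Accepts either naming dialect (T3/T7 etc.), any capitalization, and
    common reference suffixes such as 'O1-AVG'.
    """
    canon = {c.upper(): c for c in CHANNELS_1020}
    canon.update({k.upper(): v for k, v in LABEL_ALIASES.items()})
    for token in label.replace("-", " ").split():
        if token.upper() in canon:
            return canon[token.upper()]
    raise ValueError(f"unknown 10-20 channel label: {label!r}")


def _sph(incl_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector from inclination (from +z) and azimuth (from +x, CCW)."""
    t = np.deg2rad(incl_deg)
    p = np.deg2rad(azim_deg)
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def _slerp(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle midpoint of two unit vectors."""
    m = a + b
    return m / np.linalg.norm(m)


def electrode_positions(radius: float = 1.0) -> np.ndarray:
    """Positions of the canonical 19 channels, ordered as CHANNELS_1020."""
    P = {}
    P["Cz"] = _sph(0, 0)
    P["Fz"] = _sph(36, 90)
    P["Pz"] = _sph(36, -90)
    P["C4"] = _sph(36, 0)
    P["C3"] = _sph(36, 180)
    P["T4"] = _sph(72, 0)
    P["T3"] = _sph(72, 180)
    # outer (10%) ring, 18-degree azimuthal steps starting at Fpz (azim 90)
    ring = {
        "Fp2": 72, "F8": 36, "T6": -36, "O2": -72,
        "O1": -108, "T5": -144, "F7": 144, "Fp1": 108,
    }
    for name, az in ring.items():
        P[name] = _sph(72, az)
    P["F3"] = _slerp(P["Fz"], P["F7"])
    P["F4"] = _slerp(P["Fz"], P["F8"])
    P["P3"] = _slerp(P["Pz"], P["T5"])
    P["P4"] = _slerp(P["Pz"], P["T6"])
    return radius * np.stack([P[c] for c in CHANNELS_1020])
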