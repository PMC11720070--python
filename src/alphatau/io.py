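"""File interfaces: EDF recordings, cohort tables, spectra, solutions.

Recordings are exchanged as 16-bit European Data Format (EDF) so synthetic
and real inputs share one ingestion path: writing uses a small built-in
encoder (the format is a fixed-layout ASCII header plus little-endian
int16 samples), reading goes through mne's EDF reader so the encoder is
always exercised against an independent decoder.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Recording

__all__ = [
    "write_edf",
    "read_edf",
    "write_cohort_table",
    "read_cohort_table",
    "write_spectrum",
    "write_landmarks",
    "write_activity_table",
    "write_solution_h5",
]

COHORT_COLUMNS = [
    # column dictionary of the tab-separated cohort table
    ("id", "subject identifier"),
    ("group", "Healthy | noADMCI | ADMCI"),
    ("age", "years"),
    ("sex", "M | F"),
    ("education", "years"),
    ("mmse", "Mini-Mental State Examination score, 0-30"),
    ("apoe4", "APOE epsilon-4 carrier (0/1)"),
    ("csf_abeta42", "CSF amyloid-beta 1-42, pg/mL (empty for Healthy)"),
    ("csf_ptau", "CSF phospho-tau 181, pg/mL (empty for Healthy)"),
    ("csf_ttau", "CSF total tau, pg/mL (empty for Healthy)"),
    ("parietal_thickness", "parietal cortical thickness, arbitrary units"),
    ("precuneus_thickness", "precuneus cortical thickness, arbitrary units"),
    ("wm_hypointensity", "white-matter hypo-intensity volume, arbitrary units"),
    ("true_tf", "generator latent transition frequency, Hz"),
    ("true_iaf", "generator latent individual alpha frequency, Hz"),
]


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: Recording, physical_max: float | None = None) -> Path:
    """Write a recording as EDF (16-bit, physical units µV).

    One data record per second.  Samples are clipped to the symmetric
    physical range (default: 1.05x the absolute maximum of the data).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.data.shape[0]
    n_rec = rec.data.shape[1] // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one 1-s data record")
    data = rec.data[:, : n_rec * fs]
    pmax = float(physical_max or max(1.05 * np.abs(data).max(), 1.0))
    dmax, dmin = 32767, -32768
    scaled = np.clip(np.round(data / pmax * dmax), dmin, dmax).astype("<i2")

    hdr = b""
    hdr += _edf_field("0", 8)
    hdr += _edf_field(rec.subject_id.replace(" ", "_") or "X", 80)
    hdr += _edf_field("synthetic rsEEG", 80)
    now = datetime.datetime(2000, 1, 1)
    hdr += _edf_field(now.strftime("%d.%m.%y"), 8)
    hdr += _edf_field(now.strftime("%H.%M.%S"), 8)
    hdr += _edf_field(256 + n_ch * 256, 8)
    hdr += _edf_field("", 44)
    hdr += _edf_field(n_rec, 8)
    hdr += _edf_field(1, 8)            # record duration, s
    hdr += _edf_field(n_ch, 4)
    for lab in rec.channel_labels:
        hdr += _edf_field(f"EEG {lab}", 16)
    hdr += b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(n_ch))
    hdr += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    hdr += b"".join(_edf_field(f"{-pmax:.4g}", 8) for _ in range(n_ch))
    hdr += b"".join(_edf_field(f"{pmax:.4g}", 8) for _ in range(n_ch))
    hdr += b"".join(_edf_field(dmin, 8) for _ in range(n_ch))
    hdr += b"".join(_edf_field(dmax, 8) for _ in range(n_ch))
    hdr += b"".join(_edf_field("", 80) for _ in range(n_ch))
    hdr += b"".join(_edf_field(fs, 8) for _ in range(n_ch))
    hdr += b"".join(_edf_field("", 32) for _ in range(n_ch))
    assert len(hdr) == 256 + n_ch * 256

    with open(path, "wb") as fh:
        fh.write(hdr)
        # record-major, channel-major within record
        rec_view = scaled.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec_view).tobytes())
    return path


def read_edf(path, subject_id: str | None = None) -> Recording:
    """Read a 19-channel EDF through mne's decoder into a Recording (µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6          # mne uses volts internally
    return Recording(
        subject_id=subject_id or Path(path).stem,
        channel_labels=tuple(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        data=data,
        reference="as-recorded",
    )


def write_cohort_table(path, subjects) -> Path:
    path = Path(path)
    rows = []
    for s in subjects:
        rows.append({
            "id": s.id, "group": s.group, "age": round(s.age, 1),
            "sex": s.sex, "education": round(s.education, 1), "mmse": s.mmse,
            "apoe4": int(s.apoe4),
            "csf_abeta42": s.csf_abeta42, "csf_ptau": s.csf_ptau,
            "csf_ttau": s.csf_ttau,
            "parietal_thickness": s.parietal_thickness,
            "precuneus_thickness": s.precuneus_thickness,
            "wm_hypointensity": s.wm_hypointensity,
            "true_tf": s.true_tf, "true_iaf": s.true_iaf,
        })
    pd.DataFrame(rows, columns=[c for c, _ in COHORT_COLUMNS]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {c for c, _ in COHORT_COLUMNS[:7]} - set(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks required columns: {sorted(missing)}")
    return df


def write_spectrum(path, spectrum) -> Path:
    """Tabular spectrum: one row per frequency, one column per channel."""
    path = Path(path)
    df = pd.DataFrame(spectrum.density.T, columns=spectrum.channel_labels)
    df.insert(0, "freq_hz", spectrum.freqs)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_landmarks(path, landmarks, bands=None) -> Path:
    """Per-subject JSON sidecar with TF/IAF and the band scheme."""
    payload = {
        "tf_hz": landmarks.tf, "iaf_hz": landmarks.iaf,
        "tf_fallback_used": landmarks.tf_fallback_used,
        "iaf_fallback_used": landmarks.iaf_fallback_used,
    }
    if bands is not None:
        payload["bands_hz"] = {k: list(v) for k, v in bands.items()}
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


def write_activity_table(path, activities) -> Path:
    """Tidy regional activity: subject, roi, band, value, log10_value."""
    rows = []
    for act in activities:
        for i, roi in enumerate(act.rois):
            for j, band in enumerate(act.bands):
                v = float(act.values[i, j])
                rows.append({
                    "subject": act.subject_id, "roi": roi, "band": band,
                    "value": v,
                    "log10_value": np.log10(v) if v > 0 else np.nan,
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def write_solution_h5(path, solution, regional=None) -> Path:
    """HDF5 container: voxel x bin solution plus optional ROI x band table."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=solution.values)
        fh.create_dataset("freqs", data=solution.freqs)
        fh.attrs["normalized"] = bool(solution.normalized)
        if regional is not None:
            g = fh.create_group("regional")
            g.create_dataset("values", data=regional.values)
            g.attrs["rois"] = list(regional.rois)
            g.attrs["bands"] = list(regional.bands)
            g.attrs["subject_id"] = regional.subject_id
    return Path(path)
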