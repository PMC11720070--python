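"""Synthetic prodromal-AD cohort and resting-state EEG generator.

Generates subjects (group label, demographics, CSF amyloid-tau markers,
APOE4 status, MRI thickness markers, latent spectral parameters) and
19-channel resting-state recordings with the statistical structure the
downstream analysis assumes:

* CSF analytes are lognormal with group means matched to the clinical
  calibration, jointly constrained by the Abeta42/p-tau positivity rule
  (carriers < 15.2, non-carriers < 8.9; biomarker-negative patients above
  their cutoff).  Because conditioning on the rule shifts lognormal means,
  the location parameters are re-calibrated in closed form so the
  *post-constraint* means hit the configured targets.
* Each subject carries a latent transition frequency (TF), individual
  alpha frequency (IAF) and posterior-alpha source power.  The log10 alpha
  power is linearly coupled to the standardized log-CSF markers with
  configurable standardized effect sizes, so the population correlation
  between log10 marker and log10 alpha source power equals the configured
  coupling exactly.
* Recordings mix a coherent posterior alpha oscillation, a co-located
  slow (delta-theta) component, distributed 1/f background dipoles and
  white sensor noise through the spherical head model.  The slow-bump
  center is solved per subject so the posterior-sensor spectrum attains
  its 3-8 Hz minimum at the subject's latent TF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .montage import CHANNELS_1020
from .preprocess import Recording
from .source import HeadModel, cached_head_model

__all__ = [
    "Subject",
    "GroupCsf",
    "GroupSpectral",
    "NoiseModel",
    "CohortConfig",
    "generate_cohort",
    "generate_recording",
    "inject_hf_burst",
    "csf_cutoff",
    "GROUPS",
]

GROUPS = ("Healthy", "noADMCI", "ADMCI")

# CSF Abeta42/p-tau positivity cutoffs (APOE4 carriers / non-carriers)
CUTOFF_APOE4 = 15.2
CUTOFF_NO_APOE4 = 8.9


def csf_cutoff(apoe4: bool) -> float:
    return CUTOFF_APOE4 if apoe4 else CUTOFF_NO_APOE4


@dataclass
class Subject:
    id: str
    group: str
    age: float
    sex: str
    education: float
    mmse: int
    apoe4: bool
    csf_abeta42: float | None = None
    csf_ptau: float | None = None
    csf_ttau: float | None = None
    parietal_thickness: float = np.nan
    precuneus_thickness: float = np.nan
    wm_hypointensity: float = np.nan
    # generator latents
    true_iaf: float = np.nan
    true_tf: float = np.nan
    alpha_log10_power: float = np.nan
    seed_key: tuple = ()

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not (0 <= self.mmse <= 30):
            raise ValueError(f"MMSE {self.mmse} outside [0, 30]")
        has_csf = self.csf_abeta42 is not None
        if self.group == "Healthy":
            if has_csf:
                raise ValueError("Healthy subjects carry no CSF values")
        else:
            if not has_csf or self.csf_ptau is None or self.csf_ttau is None:
                raise ValueError(f"{self.group} subject requires CSF values")
            if min(self.csf_abeta42, self.csf_ptau, self.csf_ttau) <= 0:
                raise ValueError("CSF values must be positive")
            ratio = self.csf_abeta42 / self.csf_ptau
            cut = csf_cutoff(self.apoe4)
            if self.group == "ADMCI" and not ratio < cut:
                raise ValueError(
                    f"ADMCI subject {self.id}: Abeta42/p-tau {ratio:.2f} not "
                    f"below the positivity cutoff {cut}"
                )
            if self.group == "noADMCI" and not ratio >= cut:
                raise ValueError(
                    f"noADMCI subject {self.id}: Abeta42/p-tau {ratio:.2f} "
                    f"below the cutoff {cut} (must be CSF-negative)"
                )


@dataclass(frozen=True)
class GroupCsf:
    """Target post-constraint moments of the CSF analytes (pg/mL)."""

    abeta42_mean: float
    abeta42_sd: float
    ptau_mean: float
    ptau_sd: float
    ttau_mean: float
    ttau_sd: float
    log_corr_ptau_ttau: float = 0.8

    def __post_init__(self):
        for name in ("abeta42", "ptau", "ttau"):
            m, s = getattr(self, f"{name}_mean"), getattr(self, f"{name}_sd")
            if m <= 0 or s < 0:
                raise ValueError(f"csf_calibration.{name}: mean must be > 0 "
                                 f"and sd >= 0 (got {m}, {s})")
        if abs(self.log_corr_ptau_ttau) >= 1:
            raise ValueError("log_corr_ptau_ttau must be in (-1, 1)")


@dataclass(frozen=True)
class GroupSpectral:
    """Latent spectral calibration of one group."""

    tf_mean: float
    tf_sd: float
    iaf_mean: float
    iaf_sd: float
    alpha_log10_power: float      # log10 of the posterior alpha source power
    alpha_log10_sd: float

    def __post_init__(self):
        if self.tf_sd < 0 or self.iaf_sd < 0 or self.alpha_log10_sd < 0:
            raise ValueError("spectral_calibration: dispersions must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Spectral shape of the non-alpha signal content.

    Powers are in source units relative to a Healthy-group mean alpha
    power of 1; the slow component co-scales with the *group mean* alpha
    power so the theta-alpha valley is stable across subjects.
    """

    alpha_width: float = 1.0           # Hz, Gaussian bump sigma
    slow_width: float = 1.5            # Hz
    slow_ratio: float = 1.0            # slow power / group-mean alpha power
    background_exponent: float = 1.0   # 1/f^gamma
    background_level: float = 0.01     # summed bg source PSD at 9 Hz
    delta_power: float = 2.0           # low-delta block total power (< ~2 Hz)
    delta_cutoff: float = 1.8          # Hz, delta block corner
    hf_plateau: float = 0.015          # beta-gamma floor PSD above ~13 Hz
    hf_onset: float = 13.0             # Hz
    n_background: int = 40             # background dipoles
    sensor_noise: float = 1e-4         # flat sensor PSD, source units²/Hz
    output_scale_uv: float = 40.0      # µV per source unit at the sensors


@dataclass(frozen=True)
class GroupMri:
    parietal_mean: float
    parietal_sd: float
    precuneus_mean: float
    precuneus_sd: float
    wm_hypo_median: float = 2000.0
    wm_hypo_log10_sd: float = 0.15
    abeta42_coupling: float = 0.27     # standardized, onto thickness
    ttau_coupling: float = -0.12


@dataclass(frozen=True)
class GroupDemographics:
    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    mmse_mean: float
    mmse_sd: float
    male_fraction: float


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults are the study conditions."""

    group_sizes: dict = field(default_factory=lambda: {
        "Healthy": 45, "noADMCI": 45, "ADMCI": 70,
    })
    # SDs are SE * sqrt(n) at the printed group sizes
    csf_calibration: dict = field(default_factory=lambda: {
        "noADMCI": GroupCsf(940.0, 36.0 * math.sqrt(45),
                            49.0, 2.0 * math.sqrt(45),
                            312.0, 24.0 * math.sqrt(45)),
        "ADMCI": GroupCsf(498.0, 16.0 * math.sqrt(70),
                          86.0, 4.0 * math.sqrt(70),
                          642.0, 48.0 * math.sqrt(70)),
    })
    apoe4_prevalence: dict = field(default_factory=lambda: {
        "Healthy": 0.25, "noADMCI": 2.0 / 45.0, "ADMCI": 53.0 / 70.0,
    })
    spectral_calibration: dict = field(default_factory=lambda: {
        "Healthy": GroupSpectral(5.5, 0.2 * math.sqrt(45),
                                 9.2, 0.1 * math.sqrt(45), 0.0, 0.35),
        "noADMCI": GroupSpectral(5.5, 0.2 * math.sqrt(45),
                                 9.1, 0.2 * math.sqrt(45), -0.19, 0.35),
        "ADMCI": GroupSpectral(5.3, 0.1 * math.sqrt(70),
                               8.8, 0.1 * math.sqrt(70), -0.40, 0.35),
    })
    # standardized effect of each log10 CSF marker on log10 alpha power
    coupling: dict = field(default_factory=lambda: {
        "Healthy": {},
        "noADMCI": {"abeta42": 0.436},
        "ADMCI": {"ptau": -0.367},
    })
    mri_calibration: dict = field(default_factory=lambda: {
        "Healthy": GroupMri(8.73, 0.10 * math.sqrt(45),
                            4.43, 0.05 * math.sqrt(45),
                            abeta42_coupling=0.0, ttau_coupling=0.0),
        "noADMCI": GroupMri(8.73, 0.10 * math.sqrt(45),
                            4.43, 0.05 * math.sqrt(45)),
        "ADMCI": GroupMri(8.27, 0.07 * math.sqrt(70),
                          4.20, 0.04 * math.sqrt(70)),
    })
    demographics: dict = field(default_factory=lambda: {
        "Healthy": GroupDemographics(68.6, 1.0 * math.sqrt(45),
                                     11.0, 0.6 * math.sqrt(45),
                                     27.6, 0.2 * math.sqrt(45), 20 / 45),
        "noADMCI": GroupDemographics(69.6, 1.2 * math.sqrt(45),
                                     10.0, 0.6 * math.sqrt(45),
                                     25.7, 0.4 * math.sqrt(45), 18 / 45),
        "ADMCI": GroupDemographics(70.0, 0.7 * math.sqrt(70),
                                   11.0, 0.5 * math.sqrt(70),
                                   25.2, 0.2 * math.sqrt(70), 32 / 70),
    })
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    duration_s: float = 300.0
    fs: float = 256.0
    head_n_voxels: int = 1000
    seed: int = 0
    max_rejections: int = 1000

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if g not in GROUPS or n < 0:
                raise ValueError(f"group_sizes: invalid entry {g!r}: {n}")
        for g, couplings in self.coupling.items():
            total = sum(v**2 for v in couplings.values())
            if any(abs(v) > 1 for v in couplings.values()) or total > 1:
                raise ValueError(
                    f"coupling[{g!r}]: standardized effects must satisfy "
                    f"|rho| <= 1 and sum(rho²) <= 1"
                )


# ---------------------------------------------------------------------------
# CSF calibration under the positivity constraint (closed form)
# ---------------------------------------------------------------------------

def _constrained_lognormal_params(csf: GroupCsf, cutoff: float, positive: bool):
    """Location parameters so post-constraint lognormal means hit targets.

    Logs (a, p, t) = (ln Abeta42, ln p-tau, ln t-tau) are jointly normal
    with a independent of (p, t) and corr(p, t) given.  The constraint is
    s = a - p < ln(cutoff) (CSF-positive) or >= (negative).  For jointly
    normal (x, s),  E[e^x | s < c] = exp(mu_x + sx²/2) * Phi((c - mu_s -
    cov(x,s))/sd_s) / Phi((c - mu_s)/sd_s); the two location parameters
    (mu_a, mu_p) solve the corresponding pair of equations and mu_t then
    follows in closed form.  Log-variances are fixed from the target CVs.
    """
    sa = math.sqrt(math.log(1 + (csf.abeta42_sd / csf.abeta42_mean) ** 2))
    sp = math.sqrt(math.log(1 + (csf.ptau_sd / csf.ptau_mean) ** 2))
    st = math.sqrt(math.log(1 + (csf.ttau_sd / csf.ttau_mean) ** 2))
    rho = csf.log_corr_ptau_ttau
    c = math.log(cutoff)
    ss = math.hypot(sa, sp)
    norm = stats.norm

    def cond_mean_factor(cov_xs, mu_s):
        # E[e^x | constraint] / E[e^x]  (x has unit exp-mean here)
        if positive:
            return norm.cdf((c - mu_s - cov_xs) / ss) / norm.cdf((c - mu_s) / ss)
        return norm.sf((c - mu_s - cov_xs) / ss) / norm.sf((c - mu_s) / ss)

    def equations(mu):
        mu_a, mu_p = mu
        mu_s = mu_a - mu_p
        ea = math.exp(mu_a + sa**2 / 2) * cond_mean_factor(sa**2, mu_s)
        ep = math.exp(mu_p + sp**2 / 2) * cond_mean_factor(-(sp**2), mu_s)
        return [ea - csf.abeta42_mean, ep - csf.ptau_mean]

    mu0 = [math.log(csf.abeta42_mean) - sa**2 / 2,
           math.log(csf.ptau_mean) - sp**2 / 2]
    sol, info, ok, msg = optimize.fsolve(equations, mu0, full_output=True)
    if ok != 1:
        raise ValueError(
            f"csf_calibration cannot satisfy the positivity constraint "
            f"(cutoff {cutoff}, positive={positive}): {msg}"
        )
    mu_a, mu_p = sol
    mu_s = mu_a - mu_p
    cov_ts = -rho * st * sp
    mu_t = (math.log(csf.ttau_mean) - st**2 / 2
            - math.log(cond_mean_factor(cov_ts, mu_s)))

    # conditional moments of p (log p-tau) under the constraint, used to
    # standardize the marker before coupling it to alpha power
    alpha_z = (c - mu_s) / ss
    if positive:
        lam = norm.pdf(alpha_z) / norm.cdf(alpha_z)
        delta = lam * (lam + alpha_z)
        shift = -lam
    else:
        lam = norm.pdf(alpha_z) / norm.sf(alpha_z)
        delta = lam * (lam - alpha_z)
        shift = lam
    cond = {}
    for name, mu_x, s_x, cov_xs in (
        ("abeta42", mu_a, sa, sa**2),
        ("ptau", mu_p, sp, -(sp**2)),
        ("ttau", mu_t, st, cov_ts),
    ):
        beta = cov_xs / ss
        cond[name] = (
            mu_x + beta * shift,
            math.sqrt(max(s_x**2 - beta**2 * delta, 1e-12)),
        )
    return (mu_a, sa), (mu_p, sp), (mu_t, st), cond


class _CsfSampler:
    """Draws constrained CSF triples for one (group, APOE4) cell."""

    def __init__(self, csf: GroupCsf, cutoff: float, positive: bool,
                 max_rejections: int):
        (self.pa, self.pp, self.pt, self.cond) = _constrained_lognormal_params(
            csf, cutoff, positive
        )
        self.rho = csf.log_corr_ptau_ttau
        self.cutoff = math.log(cutoff)
        self.positive = positive
        self.max_rejections = max_rejections

    def draw(self, rng: np.random.Generator):
        (mu_a, sa), (mu_p, sp), (mu_t, st) = self.pa, self.pp, self.pt
        for _ in range(self.max_rejections):
            a = rng.normal(mu_a, sa)
            p = rng.normal(mu_p, sp)
            t = mu_t + st * (self.rho * (p - mu_p) / sp
                             + math.sqrt(1 - self.rho**2) * rng.standard_normal())
            ok = (a - p < self.cutoff) if self.positive else (a - p >= self.cutoff)
            if ok:
                z = {
                    name: (x - m) / s
                    for name, x, (m, s) in zip(
                        ("abeta42", "ptau", "ttau"), (a, p, t),
                        (self.cond["abeta42"], self.cond["ptau"],
                         self.cond["ttau"]),
                    )
                }
                return math.exp(a), math.exp(p), math.exp(t), z
        raise RuntimeError(
            f"CSF rejection sampling exceeded {self.max_rejections} draws; "
            f"the configured distributions are incompatible with the "
            f"positivity constraint"
        )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _subject_rng(seed: int, group_index: int, subject_index: int,
                 purpose: int = 0) -> np.random.Generator:
    """Counter-based per-subject stream: reproducible under any batching."""
    ss = np.random.SeedSequence(
        entropy=seed, spawn_key=(group_index, subject_index, purpose)
    )
    return np.random.default_rng(ss)


def _draw_latent_spectral(spec: GroupSpectral, rng: np.random.Generator):
    """Truncated latent IAF and TF with a >= 1 Hz individual alpha range."""
    for _ in range(1000):
        iaf = rng.normal(spec.iaf_mean, spec.iaf_sd)
        if 7.0 <= iaf <= 13.0:
            break
    else:
        iaf = spec.iaf_mean
    iaf = round(2.0 * iaf) / 2.0          # landmarks live on the analysis grid
    for _ in range(1000):
        tf = rng.normal(spec.tf_mean, spec.tf_sd)
        if 3.5 <= tf <= 7.5 and iaf - tf >= 1.5:
            break
    else:
        tf = min(spec.tf_mean, iaf - 1.5)
    return round(2.0 * tf) / 2.0, iaf


def generate_cohort(config: CohortConfig) -> list:
    """Draw the full cohort; a pure function of (config, seed)."""
    samplers = {}
    subjects = []
    prefix = {"Healthy": "HC", "noADMCI": "NO", "ADMCI": "AD"}
    for gi, group in enumerate(GROUPS):
        n = config.group_sizes.get(group, 0)
        demo = config.demographics[group]
        spec = config.spectral_calibration[group]
        mri = config.mri_calibration[group]
        couplings = config.coupling.get(group, {})
        for si in range(n):
            rng = _subject_rng(config.seed, gi, si)
            apoe4 = bool(rng.random() < config.apoe4_prevalence[group])
            csf = (None, None, None)
            z = {}
            if group != "Healthy":
                key = (group, apoe4)
                if key not in samplers:
                    samplers[key] = _CsfSampler(
                        config.csf_calibration[group], csf_cutoff(apoe4),
                        positive=(group == "ADMCI"),
                        max_rejections=config.max_rejections,
                    )
                ab, pt, tt, z = samplers[key].draw(rng)
                csf = (ab, pt, tt)

            tf, iaf = _draw_latent_spectral(spec, rng)
            rho2 = sum(v**2 for v in couplings.values())
            eps = rng.standard_normal()
            zsum = sum(v * z.get(k, 0.0) for k, v in couplings.items())
            alpha_lp = spec.alpha_log10_power + spec.alpha_log10_sd * (
                zsum + math.sqrt(max(1.0 - rho2, 0.0)) * eps
            )

            e_th = rng.standard_normal()
            th = {}
            for name in ("parietal", "precuneus"):
                m = getattr(mri, f"{name}_mean")
                s = getattr(mri, f"{name}_sd")
                r_ab, r_tt = mri.abeta42_coupling, mri.ttau_coupling
                resid = math.sqrt(max(1 - r_ab**2 - r_tt**2, 0.0))
                own = rng.standard_normal()
                noise = 0.7 * e_th + math.sqrt(1 - 0.49) * own
                th[name] = m + s * (r_ab * z.get("abeta42", 0.0)
                                    + r_tt * z.get("ttau", 0.0) + resid * noise)
            wm = mri.wm_hypo_median * 10 ** rng.normal(0.0, mri.wm_hypo_log10_sd)

            mmse = int(np.clip(round(rng.normal(demo.mmse_mean, demo.mmse_sd)),
                               24 if group != "Healthy" else 24, 30))
            subjects.append(Subject(
                id=f"{prefix[group]}-{si:03d}",
                group=group,
                age=float(np.clip(rng.normal(demo.age_mean, demo.age_sd), 55, 90)),
                sex="M" if rng.random() < demo.male_fraction else "F",
                education=float(max(5.0, rng.normal(demo.education_mean,
                                                    demo.education_sd))),
                mmse=mmse,
                apoe4=apoe4,
                csf_abeta42=csf[0], csf_ptau=csf[1], csf_ttau=csf[2],
                parietal_thickness=float(th["parietal"]),
                precuneus_thickness=float(th["precuneus"]),
                wm_hypointensity=float(wm),
                true_iaf=float(iaf), true_tf=float(tf),
                alpha_log10_power=float(alpha_lp),
                seed_key=(config.seed, gi, si),
            ))
    return subjects


# ---------------------------------------------------------------------------
# recording generation
# ---------------------------------------------------------------------------

def _posterior_source_footprint(model: HeadModel) -> np.ndarray:
    """Sensor footprint (19,) of the coherent posterior alpha generator.

    A fixed set of radially oriented dipoles: the three most posterior
    voxels of the parietal and occipital ROIs and the two most posterior
    temporal voxels (down-weighted), normalized to unit RMS footprint.
    """
    idx = model.roi_indices()
    g = np.zeros(model.n_channels)
    for roi, k, w in (("parietal", 3, 1.0), ("occipital", 3, 1.0),
                      ("temporal", 2, 0.6)):
        vox = idx[roi]
        order = np.argsort(model.voxel_xyz[vox, 1])      # most posterior first
        for j in vox[order[:k]]:
            g += w * model.gain_for(j, model.voxel_xyz[j])
    return g / np.sqrt((g**2).mean())


def _background_footprints(model: HeadModel, n_bg: int) -> np.ndarray:
    """(n_bg, 19) radial-dipole footprints on a fixed subsampled grid."""
    step = max(model.n_voxels // n_bg, 1)
    vox = np.arange(0, model.n_voxels, step)[:n_bg]
    G = np.stack([model.gain_for(j, model.voxel_xyz[j]) for j in vox])
    return G / np.sqrt((G**2).mean(axis=1, keepdims=True))


_POSTERIOR = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")


def _mixing_geometry(model: HeadModel, n_background: int):
    """Cached per-model mixing quantities for recording synthesis.

    Returns the posterior oscillator footprint, the sensor-space Cholesky
    factor of the background cross-covariance, and the background level at
    the posterior sensors relative to the oscillator footprint (the scale
    the TF solver needs).
    """
    cache = getattr(model, "_mixing_cache", None)
    if cache is not None and cache[0] == n_background:
        return cache[1]
    g_post = _posterior_source_footprint(model)
    post_idx = [i for i, c in enumerate(CHANNELS_1020) if c in _POSTERIOR]
    a_post = float((g_post[post_idx] ** 2).mean())
    if n_background > 0:
        G_bg = _background_footprints(model, n_background)
        L = np.linalg.cholesky(G_bg.T @ G_bg / n_background
                               + 1e-12 * np.eye(19))
        b_post = float((G_bg[:, post_idx] ** 2).sum(axis=0).mean()
                       / n_background)
        out = (g_post, L, b_post / a_post)
    else:
        out = (g_post, None, 0.0)
    model._mixing_cache = (n_background, out)
    return out


def _background_psd(f: np.ndarray, nm: NoiseModel) -> np.ndarray:
    """Summed one-sided PSD of the distributed background (source units²/Hz).

    Three parts, all carried by the background dipoles: a shallow 1/f
    continuum, a low-delta block confined below ~2 Hz (steep roll-off so it
    leaves the 3-8 Hz valley untouched), and a small flat beta-gamma floor
    above ~13 Hz (EMG-like).  Most broadband power lives here, which keeps
    the posterior alpha bump a modest fraction of the grand-mean solution.
    """
    f = np.asarray(f, float)
    psd = nm.background_level * (9.0 / np.maximum(f, 0.25)) ** nm.background_exponent
    if nm.delta_power > 0:
        shape = 1.0 / (1.0 + (np.maximum(f, 1e-3) / nm.delta_cutoff) ** 10)
        psd = psd + nm.delta_power * shape / _delta_block_norm(nm.delta_cutoff)
    if nm.hf_plateau > 0:
        psd = psd + nm.hf_plateau / (1.0 + np.exp(-(f - nm.hf_onset) / 0.4))
    return psd


@lru_cache(maxsize=8)
def _delta_block_norm(cutoff: float) -> float:
    """Integral on [0, 45] of the delta-block shape (total-power scaling)."""
    grid = np.arange(0.0, 45.0, 0.01)
    return float(np.trapezoid(
        1.0 / (1.0 + (np.maximum(grid, 1e-3) / cutoff) ** 10), grid
    ))


def _gauss_bump(f: np.ndarray, center: float, width: float,
                power: float) -> np.ndarray:
    """One-sided PSD of a narrowband component with total power ``power``."""
    if width <= 0:
        raise ValueError("bump width must be positive for stochastic synthesis")
    s = np.exp(-0.5 * ((f - center) / width) ** 2)
    return power * s / (width * math.sqrt(2 * math.pi))


def _synth_oscillator(center: float, width: float, power: float, n: int,
                      fs: float, rng: np.random.Generator,
                      mod_period_s: float = 15.0) -> np.ndarray:
    """Constant-amplitude oscillator with slowly wandering frequency.

    The instantaneous frequency sweeps the quantiles of N(center, width²)
    (clipped at ±2.5 width) along a triangle schedule, so the epoch-averaged
    spectrum is a Gaussian bump of total power ``power`` while the envelope
    is deterministic - band powers then scale exactly with the configured
    source power instead of fluctuating with a random envelope.  Width 0
    degenerates to a pure sinusoid.
    """
    if width <= 0:
        t = np.arange(n) / fs
        return math.sqrt(2 * power) * np.sin(
            2 * math.pi * center * t + rng.uniform(0, 2 * math.pi)
        )
    z = _sweep_quantiles(n, fs, mod_period_s)
    f_inst = np.clip(center + width * z, 0.3, fs / 2 - 1)
    phase = 2 * math.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * math.pi)
    return math.sqrt(2 * power) * np.sin(phase)


@lru_cache(maxsize=8)
def _sweep_quantiles(n: int, fs: float, mod_period_s: float) -> np.ndarray:
    """Clipped Gaussian quantiles along the triangle schedule (cached)."""
    u = np.arange(n) / fs / mod_period_s
    tri = 2 * np.abs(u - np.floor(u + 0.5))
    z = stats.norm.ppf(np.clip(tri, 1e-3, 1 - 1e-3))
    return np.clip(z, -2.5, 2.5)


def _gaussian_spectrum_amp(amp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """rfft coefficients of a stationary Gaussian series with amplitude
    spectrum ``amp`` = sqrt(psd * n * fs / 4); DC and Nyquist are zeroed."""
    shape = amp.shape
    Z = np.empty(shape, complex)
    Z.real = rng.standard_normal(shape, dtype=np.float32)
    Z.imag = rng.standard_normal(shape, dtype=np.float32)
    Z *= amp
    Z[..., 0] = 0.0
    Z[..., -1] = 0.0
    return Z


@lru_cache(maxsize=8)
def _background_amp(nm: NoiseModel, n: int, fs: float) -> np.ndarray:
    """(19, n//2+1) rfft amplitude of the per-channel background factor."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.sqrt(_background_psd(freqs, nm) * (n * fs / 4.0))
    return np.broadcast_to(amp, (19, freqs.size))


def _solve_slow_center(tf: float, iaf: float, alpha_power: float,
                       slow_power: float, nm: NoiseModel,
                       bg_scale: float) -> float:
    """Slow-bump center making the posterior spectrum's 3-8 Hz minimum = TF.

    Works on the analytic source-level posterior spectrum (alpha bump +
    slow bump + scaled distributed background, all referred to the
    posterior footprint).  Falls back to the mirror point 2*TF - IAF when
    no root exists (weak-alpha degenerate spectra).
    """
    alpha_width = max(nm.alpha_width, 1e-3)
    slow_width = nm.slow_width

    def total_psd(f, c):
        return (_gauss_bump(f, iaf, alpha_width, alpha_power)
                + _gauss_bump(f, c, slow_width, slow_power)
                + bg_scale * _background_psd(f, nm))

    def slope_at_tf(c):
        h = 1e-4
        return (total_psd(tf + h, c) - total_psd(tf - h, c)) / (2 * h)

    lo, hi = 0.3, tf - 0.3
    if hi <= lo:
        return 2 * tf - iaf
    try:
        if slope_at_tf(lo) * slope_at_tf(hi) > 0:
            return max(2 * tf - iaf, lo)
        c = optimize.brentq(slope_at_tf, lo, hi, xtol=1e-4)
    except ValueError:
        return max(2 * tf - iaf, lo)
    return float(c)


def sensor_spectrum(
    subject: Subject,
    config: CohortConfig,
    model: HeadModel | None = None,
    duration_s: float | None = None,
) -> np.ndarray:
    """Frequency-domain sensor signal (19 x n//2+1 rfft coefficients).

    The recording is defined in the frequency domain (oscillators are
    transformed, Gaussian components synthesized directly there); the
    time-domain recording is its inverse FFT.  Deterministic given
    (config.seed, subject identity); the coupling to CSF markers enters
    only through the subject's latent ``alpha_log10_power``, drawn at
    cohort-generation time.
    """
    if not np.isfinite(subject.true_iaf) or not np.isfinite(subject.true_tf):
        raise ValueError(
            f"subject {subject.id} lacks latent spectral fields; generate it "
            f"through generate_cohort"
        )
    if model is None:
        model = cached_head_model(config.head_n_voxels)
    nm = config.noise_model
    fs = config.fs
    dur = config.duration_s if duration_s is None else duration_s
    n = int(round(dur * fs))
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=tuple(subject.seed_key[1:]) + (7,)
    ))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)

    spec = config.spectral_calibration[subject.group]
    alpha_power = 10.0 ** subject.alpha_log10_power
    slow_power = nm.slow_ratio * 10.0 ** spec.alpha_log10_power
    g_post, L_bg, bg_scale = _mixing_geometry(model, nm.n_background)

    osc = _synth_oscillator(subject.true_iaf, nm.alpha_width,
                            alpha_power, n, fs, rng)
    if slow_power > 0 and nm.slow_width > 0:
        c1 = _solve_slow_center(
            subject.true_tf, subject.true_iaf, alpha_power, slow_power,
            nm, bg_scale,
        )
        osc = osc + _synth_oscillator(c1, nm.slow_width, slow_power, n, fs,
                                      rng)
    sensor = np.outer(g_post, np.fft.rfft(osc))

    if nm.n_background > 0:
        # the dipoles share one PSD, so the sensor background is Gaussian
        # with cross-spectrum psd(f) * (G^T G / n_bg): synthesize it
        # directly in sensor space through the Cholesky factor
        Z = _gaussian_spectrum_amp(_background_amp(nm, n, fs), rng)
        sensor += L_bg @ Z

    if nm.sensor_noise > 0:
        Zn = _gaussian_spectrum_amp(
            np.full((19, freqs.size), math.sqrt(nm.sensor_noise * n * fs / 4.0)),
            rng,
        )
        sensor += Zn
    sensor *= nm.output_scale_uv
    return sensor


def generate_recording(
    subject: Subject,
    config: CohortConfig,
    model: HeadModel | None = None,
    duration_s: float | None = None,
) -> Recording:
    """Synthesize the subject's 19-channel resting-state recording (µV)."""
    fs = config.fs
    dur = config.duration_s if duration_s is None else duration_s
    n = int(round(dur * fs))
    spec = sensor_spectrum(subject, config, model=model, duration_s=dur)
    return Recording(
        subject_id=subject.id,
        channel_labels=tuple(CHANNELS_1020),
        fs=fs,
        data=np.fft.irfft(spec, n=n, axis=-1),
        reference="common-average",
    )


def inject_hf_burst(
    rec: Recording, start_s: float, duration_s: float = 2.0,
    freq: float = 50.0, amplitude_uv: float = 50.0,
) -> Recording:
    """Add a high-frequency (muscle-like) burst for screening tests."""
    i0 = int(start_s * rec.fs)
    i1 = min(i0 + int(duration_s * rec.fs), rec.data.shape[1])
    t = np.arange(i1 - i0) / rec.fs
    data = rec.data.copy()
    data[:, i0:i1] += amplitude_uv * np.sin(2 * np.pi * freq * t)
    return replace(rec, data=data)
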