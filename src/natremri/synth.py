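"""Synthetic study-condition generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: sodium
phantom/tumour scenes, diffusion-weighted series, cohort feature tables,
SBFI fluorescence calibration traces and ion-selective-electrode
recordings. All generators are deterministic given their seed, and all
return the ground truth needed for recovery testing downstream.

Noise models: Rician on magnitude MR images (the magnitude of a complex
Gaussian-corrupted signal), Gaussian on fluorescence and voltage traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dwiadc import DWISeries
from .image import ImageVolume, ROISet

__all__ = [
    "ScenePhantomSpec",
    "DWISceneSpec",
    "CohortSpec",
    "SBFITraceSpec",
    "ISMERecordingSpec",
    "rician",
    "generate_sodium_image",
    "generate_dwi_series",
    "generate_cohort",
    "generate_sbfi_traces",
    "generate_isme_recordings",
]


def rician(true_signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Rician-distributed magnitude: |A + n1 + i*n2| with n1, n2 ~ N(0, sigma)."""
    a = np.asarray(true_signal, dtype=float)
    if sigma == 0:
        return a.copy()
    n1 = rng.normal(0.0, sigma, a.shape)
    n2 = rng.normal(0.0, sigma, a.shape)
    return np.hypot(a + n1, n2)


def _ellipsoid_mask(grid: np.ndarray, centre, semi_axes) -> np.ndarray:
    rel = (grid - np.asarray(centre, float)) / np.asarray(semi_axes, float)
    return np.sum(rel**2, axis=-1) <= 1.0


def surface_coil_gain(
    grid: np.ndarray, coil_origin, d0: float = 2.0, gain_constant: float = 1.0
) -> np.ndarray:
    """Inverse-square receive gain g(x) = G / (d(x) + d0)^2 of a surface coil.

    ``d0`` (mm) is a floor distance keeping the gain finite on the coil plane.
    """
    d = np.linalg.norm(grid - np.asarray(coil_origin, float), axis=-1)
    return gain_constant / (d + d0) ** 2


# ---------------------------------------------------------------------------
# sodium scene


@dataclass
class ScenePhantomSpec:
    """A sodium imaging scene: in-plane NaCl phantom, tumour, background.

    Defaults follow the study conditions: a 50 mM NaCl reference phantom
    (8.2 mm inner diameter tube), a tumour with elevated heterogeneous
    sodium concentration, and background (non-tumour) tissue at a healthy
    baseline near 30 mM.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    phantom_centre: tuple[float, ...] = (38.0, 10.0, 12.0)
    phantom_radius: float = 4.1  # mm; 8.2 mm inner diameter tube
    phantom_conc: float = 50.0  # mM
    tumour_centre: tuple[float, ...] = (14.0, 32.0, 12.0)
    tumour_semi_axes: tuple[float, ...] = (7.0, 6.0, 6.0)
    tumour_conc_mean: float = 46.9  # mM, elevated total tumour sodium
    tumour_conc_heterogeneity_sd: float = 6.0  # mM, smoothed texture amplitude
    background_conc: float = 29.7  # mM, healthy mammary tissue baseline
    non_tumour_centre: tuple[float, ...] | None = None  # default: mirrored tumour
    coil_mode: str = "volume"  # "volume" (flat gain) or "surface" (1/r^2)
    coil_origin: tuple[float, ...] = (24.0, 0.0, 12.0)
    coil_d0: float = 2.0  # mm, gain floor distance
    noise_sigma: float = 0.0  # signal units
    heterogeneity_smoothing_vox: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.grid_shape) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("grid dimensions and voxel size must be positive")
        for c in (self.phantom_conc, self.tumour_conc_mean, self.background_conc):
            if c < 0:
                raise ValueError("concentrations must be non-negative")
        if self.coil_mode not in ("volume", "surface"):
            raise ValueError(f"unknown coil_mode {self.coil_mode!r}")
        extent = np.array(self.grid_shape) * np.array(self.voxel_size)
        for centre, radius in (
            (self.phantom_centre, self.phantom_radius),
            (self.tumour_centre, max(self.tumour_semi_axes)),
        ):
            c = np.asarray(centre, float)
            if np.any(c - radius < 0) or np.any(c + radius > extent):
                raise ValueError("geometric bodies must lie inside the grid")
        gap = np.linalg.norm(
            np.asarray(self.phantom_centre, float) - np.asarray(self.tumour_centre, float)
        )
        if gap <= self.phantom_radius + max(self.tumour_semi_axes):
            raise ValueError("phantom and tumour regions overlap")


def generate_sodium_image(
    spec: ScenePhantomSpec,
) -> tuple[ImageVolume, ROISet, np.ndarray]:
    """Render a magnitude sodium image from a scene specification.

    The noise-free signal is the coil gain field times a signal proportional
    to the sodium concentration (proportionality constant 1 signal-unit/mM);
    Rician noise then degrades it. Returns the image, the exact phantom /
    tumour / non-tumour masks, and the ground-truth concentration map.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    img = ImageVolume(
        np.zeros(spec.grid_shape), spec.voxel_size, modality="na23", meta={"seed": spec.seed}
    )
    grid = img.coordinate_grid()

    phantom = (
        np.linalg.norm(grid - np.asarray(spec.phantom_centre, float), axis=-1)
        <= spec.phantom_radius
    )
    tumour = _ellipsoid_mask(grid, spec.tumour_centre, spec.tumour_semi_axes)
    if spec.non_tumour_centre is None:
        extent = np.array(spec.grid_shape) * np.array(spec.voxel_size)
        nt_centre = extent - np.asarray(spec.tumour_centre, float)
    else:
        nt_centre = np.asarray(spec.non_tumour_centre, float)
    non_tumour = _ellipsoid_mask(grid, nt_centre, spec.tumour_semi_axes)
    non_tumour &= ~phantom & ~tumour

    conc = np.full(spec.grid_shape, float(spec.background_conc))
    conc[phantom] = spec.phantom_conc
    if spec.tumour_conc_heterogeneity_sd > 0:
        texture = gaussian_filter(
            rng.standard_normal(spec.grid_shape), spec.heterogeneity_smoothing_vox
        )
        sd = texture.std()
        texture *= spec.tumour_conc_heterogeneity_sd / sd if sd > 0 else 0.0
    else:
        texture = np.zeros(spec.grid_shape)
    conc[tumour] = np.clip(spec.tumour_conc_mean + texture[tumour], 0.0, None)

    if spec.coil_mode == "surface":
        # unit-mean gain: receiver scale is arbitrary, and this keeps
        # noise_sigma on the same signal scale as the volume-coil case
        gain = surface_coil_gain(grid, spec.coil_origin, d0=spec.coil_d0)
        gain /= gain.mean()
    else:
        gain = np.ones(spec.grid_shape)
    img.data = rician(gain * conc, spec.noise_sigma, rng)
    rois = ROISet({"tumour": tumour, "non_tumour": non_tumour, "phantom": phantom})
    rois.validate_against(img)
    return img, rois, conc


def generate_b1_reference(
    spec: ScenePhantomSpec, reference_conc: float = 1000.0
) -> ImageVolume:
    """Image of a uniform concentrated phantom (1 M NaCl by default) filling
    the field of view, under the same coil as the scene.

    Its intensity profile is the coil gain up to scale, which is what the
    B1-correction fit consumes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    probe = ImageVolume(np.zeros(spec.grid_shape), spec.voxel_size, modality="na23")
    grid = probe.coordinate_grid()
    if spec.coil_mode == "surface":
        gain = surface_coil_gain(grid, spec.coil_origin, d0=spec.coil_d0)
        gain /= gain.mean()
    else:
        gain = np.ones(spec.grid_shape)
    probe.data = rician(gain * reference_conc, spec.noise_sigma, rng)
    return probe


# ---------------------------------------------------------------------------
# diffusion-weighted series


@dataclass
class DWISceneSpec:
    """Mono-exponential diffusion scene S(b) = S0 exp(-b * ADC).

    Defaults use the acquisition's b-values {0, 100, 300, 700} s/mm^2, a
    restricted-diffusion tumour (low ADC from high cellularity) in a
    free-water-like background.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 12)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 1.0)
    b_values: tuple[float, ...] = (0.0, 100.0, 300.0, 700.0)  # s/mm^2
    tumour_centre: tuple[float, ...] = (8.0, 8.0, 6.0)
    tumour_semi_axes: tuple[float, ...] = (4.0, 3.5, 3.5)
    adc_tumour: float = 0.7e-3  # mm^2/s, restricted
    adc_background: float = 1.8e-3  # mm^2/s
    s0: float = 1000.0  # b=0 signal, uniform
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        b = np.asarray(self.b_values, float)
        if b.min() < 0 or len(np.unique(b)) != len(b):
            raise ValueError("b-values must be distinct and non-negative")
        if 0.0 not in b:
            raise ValueError("a b = 0 volume is required (S0 reference)")
        if self.adc_tumour <= 0 or self.adc_background <= 0:
            raise ValueError("ADC values must be positive")


def generate_dwi_series(
    spec: DWISceneSpec,
) -> tuple[DWISeries, np.ndarray, np.ndarray]:
    """Simulate a multi-b DWI series.

    Returns the series, the ground-truth ADC map (mm^2/s) and the tumour mask.
    Rician noise is drawn independently per b-volume.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    probe = ImageVolume(np.zeros(spec.grid_shape), spec.voxel_size, modality="dwi")
    grid = probe.coordinate_grid()
    tumour = _ellipsoid_mask(grid, spec.tumour_centre, spec.tumour_semi_axes)
    adc_map = np.where(tumour, spec.adc_tumour, spec.adc_background)

    volumes = []
    for b in spec.b_values:
        signal = spec.s0 * np.exp(-b * adc_map)
        vol = ImageVolume(
            rician(signal, spec.noise_sigma, rng),
            spec.voxel_size,
            modality="dwi",
            meta={"b_value": float(b), "seed": spec.seed},
        )
        volumes.append((float(b), vol))
    return DWISeries(volumes), adc_map, tumour


# ---------------------------------------------------------------------------
# cohort feature tables


@dataclass
class CohortSpec:
    """Bivariate (max 23Na signal, ADC) class model for tumour / non-tumour ROIs.

    Defaults emulate the observed feature structure: tumour regions show a
    high phantom-normalised maximum sodium signal and low ADC, non-tumour
    regions the reverse, with a negative pooled Na-ADC correlation. The
    mean sodium signal is generated as a fixed fraction of the maximum with
    correlated jitter (tumour heterogeneity keeps the mean below the max).
    """

    n_subjects: int = 16
    # class means as (max_na_norm [phantom units], adc [mm^2/s]); spreads give
    # overlapping classes, as in small rodent cohorts where single-feature
    # classifiers sit near 80-90% accuracy
    tumour_mean: tuple[float, float] = (1.9, 1.0e-3)
    non_tumour_mean: tuple[float, float] = (0.9, 1.5e-3)
    tumour_cov: tuple[tuple[float, float], ...] = (
        (0.2025, -5.6e-5),
        (-5.6e-5, 6.25e-8),
    )
    non_tumour_cov: tuple[tuple[float, float], ...] = (
        (0.1225, -2.6e-5),
        (-2.6e-5, 6.25e-8),
    )
    mean_na_fraction: float = 0.55  # mean 23Na signal as fraction of max
    mean_na_jitter_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        for cov in (self.tumour_cov, self.non_tumour_cov):
            c = np.asarray(cov, float)
            if np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("class covariance must be positive-definite")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a balanced cohort feature table (one tumour + one non-tumour ROI per subject).

    Columns: subject, region, max_na_norm, mean_na_norm, adc.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, mean, cov in (
        ("tumour", spec.tumour_mean, spec.tumour_cov),
        ("non_tumour", spec.non_tumour_mean, spec.non_tumour_cov),
    ):
        draws = rng.multivariate_normal(np.asarray(mean, float), np.asarray(cov, float),
                                        size=spec.n_subjects)
        max_na = np.clip(draws[:, 0], 1e-6, None)
        adc = np.clip(draws[:, 1], 1e-6, None)
        mean_na = max_na * np.clip(
            spec.mean_na_fraction + rng.normal(0, spec.mean_na_jitter_sd, spec.n_subjects),
            0.05,
            0.95,
        )
        for i in range(spec.n_subjects):
            rows.append(
                {
                    "subject": f"m{i:03d}",
                    "region": label,
                    "max_na_norm": max_na[i],
                    "mean_na_norm": mean_na[i],
                    "adc": adc[i],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SBFI fluorescence traces


def one_phase_association(conc, y0: float, plateau: float, k: float):
    """Saturating calibration curve Y(x) = Y0 + (Plateau - Y0)(1 - exp(-K x))."""
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * np.asarray(conc, float)))


@dataclass
class SBFITraceSpec:
    """SBFI in-situ calibration protocol for one tumour slice.

    A baseline phase at the (unknown) resting intracellular sodium is
    followed by ionophore-equilibrated plateau phases at each calibration
    concentration (10, 20, 50 mM). Fluorescence follows a one-phase
    association of concentration with per-cell parameter scatter and
    multiplicative frame noise.
    """

    n_cells: int = 13
    true_resting_nai: float = 25.9  # mM, ground truth to recover
    calibration_concs: tuple[float, ...] = (10.0, 20.0, 50.0)
    frames_per_phase: int = 6
    y0: float = 1.0  # fluorescence, a.u.
    plateau: float = 2.0
    k: float = 0.05  # 1/mM
    cell_param_cv: float = 0.05  # per-cell scatter of Y0/Plateau
    noise_cv: float = 0.02  # multiplicative frame noise
    seed: int = 0

    def validate(self) -> None:
        concs = np.asarray(self.calibration_concs, float)
        if not np.all(np.diff(concs) > 0):
            raise ValueError("calibration concentrations must be strictly increasing")
        if self.k <= 0:
            raise ValueError("rate constant K must be positive")
        if self.plateau <= self.y0:
            raise ValueError("Plateau must exceed Y0")
        if self.frames_per_phase < 3:
            raise ValueError(
                "frames_per_phase must be >= 3 (plateau averaging uses the final 3 frames)"
            )
        if self.true_resting_nai < 0:
            raise ValueError("resting [Na+]i must be non-negative")


def generate_sbfi_traces(spec: SBFITraceSpec) -> pd.DataFrame:
    """Simulate per-cell SBFI traces for one slice.

    Returns a tidy frame with columns cell, phase ("baseline" or the
    calibration concentration as a string), conc_mM (NaN for baseline),
    frame, fluorescence.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cell in range(spec.n_cells):
        y0_c = spec.y0 * (1.0 + rng.normal(0, spec.cell_param_cv))
        pl_c = spec.plateau * (1.0 + rng.normal(0, spec.cell_param_cv))
        pl_c = max(pl_c, y0_c * 1.05)  # keep the curve increasing per cell
        phases = [("baseline", spec.true_resting_nai)] + [
            (f"{c:g}", c) for c in spec.calibration_concs
        ]
        for phase, conc in phases:
            level = one_phase_association(conc, y0_c, pl_c, spec.k)
            noise = 1.0 + rng.normal(0, spec.noise_cv, spec.frames_per_phase)
            for frame, f in enumerate(level * noise):
                rows.append(
                    {
                        "cell": cell,
                        "phase": phase,
                        "conc_mM": np.nan if phase == "baseline" else conc,
                        "frame": frame,
                        "fluorescence": f,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ion-selective microelectrode recordings


@dataclass
class ISMERecordingSpec:
    """Electrode calibration and tissue-recording protocol for one slice.

    The electrode response is simulated as near-Nernstian,
    V(C) = slope * log10(C / C_ref), with tissue recordings additionally
    shifted by the bath-vs-calibration-tube junction potential. Standards
    are measured before and after the experiment; the post-calibration
    sensitivity is scaled by ``1 + sensitivity_drift_fraction``.
    """

    standards: tuple[float, ...] = (48.0, 96.0, 144.0, 192.0)  # mM
    slope: float = 58.0  # mV/decade, near-Nernstian at ~30 C
    reference_conc: float = 144.0  # mM, zero-voltage point of the response
    junction_offset: float = 10.0  # mV, bath vs calibration tube
    true_tissue_nae: float = 157.8  # mM, ground truth to recover
    n_recordings: int = 12
    voltage_noise_sd: float = 0.3  # mV
    sensitivity_drift_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        std = np.asarray(self.standards, float)
        if len(std) < 3:
            raise ValueError("at least 3 standards are required for a Padé(1,1) fit")
        if not np.all(np.diff(std) > 0):
            raise ValueError("standards must be strictly increasing")
        if not 0 <= abs(self.sensitivity_drift_fraction) <= 0.5:
            raise ValueError("implausible sensitivity drift fraction")
        if self.true_tissue_nae <= 0:
            raise ValueError("tissue [Na+]e must be positive")


def _nernst_voltage(conc, slope: float, reference_conc: float) -> np.ndarray:
    return slope * np.log10(np.asarray(conc, float) / reference_conc)


def generate_isme_recordings(spec: ISMERecordingSpec) -> dict[str, pd.DataFrame]:
    """Simulate one slice's electrode session.

    Returns ``{"standards": ..., "tissue": ...}``: the standards frame has
    columns (conc_mM, mV, stage in {pre, post}); the tissue frame has
    columns (recording, mV). Tissue voltages include the junction offset.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for stage, drift in (("pre", 0.0), ("post", spec.sensitivity_drift_fraction)):
        v = _nernst_voltage(spec.standards, spec.slope * (1.0 + drift), spec.reference_conc)
        v = v + rng.normal(0, spec.voltage_noise_sd, len(spec.standards))
        for c, volt in zip(spec.standards, v):
            rows.append({"conc_mM": c, "mV": volt, "stage": stage})
    standards = pd.DataFrame(rows)

    v_tissue = (
        _nernst_voltage(spec.true_tissue_nae, spec.slope, spec.reference_conc)
        + spec.junction_offset
        + rng.normal(0, spec.voltage_noise_sd, spec.n_recordings)
    )
    tissue = pd.DataFrame({"recording": np.arange(spec.n_recordings), "mV": v_tissue})
    return {"standards": standards, "tissue": tissue}
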