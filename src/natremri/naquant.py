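"""Sodium image quantification: B1 correction, ROI statistics, phantom
normalisation to concentration, and tumour volume estimation.

Concentration reporting assumes the sodium signal is linear in [NaCl] and
ignores differential T1 saturation between phantom and tissue; the values
are therefore phantom-normalised signal expressed on a mM scale rather than
absolute tissue concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .image import ImageVolume, ROISet
from .synth import surface_coil_gain


@dataclass
class B1Field:
    """Fitted surface-coil receive field g(x) = G / (d(x) + d0)^2."""

    coil_origin: tuple[float, ...]
    d0: float  # mm
    gain_constant: float
    gain_map: np.ndarray  # normalised to unit mean

    def __post_init__(self) -> None:
        if np.any(self.gain_map <= 0):
            raise ValueError("gain map must be strictly positive")


@dataclass
class SodiumROIStats:
    """Raw, phantom-normalised and concentration-scale statistics for one ROI."""

    roi: str
    mean_raw: float
    max_raw: float
    n_vox: int
    mean_norm: float | None = None  # phantom units (phantom = 1)
    max_norm: float | None = None
    mean_mM: float | None = None
    max_mM: float | None = None


@dataclass
class VolumeEstimate:
    source: str  # "roi" | "calliper"
    volume: float  # mm^3
    length: float | None = None  # mm (calliper)
    width: float | None = None  # mm (calliper)


def fit_b1_field(
    reference: ImageVolume,
    coil_origin,
    d0_bounds: tuple[float, float] = (0.1, 50.0),
    log_space: bool = True,
    mask: np.ndarray | None = None,
) -> B1Field:
    """Fit the inverse-square gain model to a uniform-phantom reference image.

    The reference (e.g. a 1 M NaCl phantom filling the field of view) has
    spatially constant true signal, so its intensity profile is the coil
    gain up to scale. The fit minimises squared error in log-signal space by
    default — robust to the large dynamic range of a concentrated phantom —
    over (log G, d0). The returned gain map is normalised to unit mean so
    that correction preserves overall image scale.
    """
    grid = reference.coordinate_grid()
    d = np.linalg.norm(grid - np.asarray(coil_origin, float), axis=-1)
    sel = reference.data > 0
    if mask is not None:
        sel &= np.asarray(mask, bool)
    if not sel.any():
        raise ValueError("no positive reference voxels to fit")
    d_sel, s_sel = d[sel], reference.data[sel]
    if np.ptp(d_sel) < 1e-9:
        raise ValueError("degenerate fit: all reference voxels equidistant from coil")

    # flat reference: the 1/r^2 model cannot represent it, return unit gain
    if s_sel.std() / s_sel.mean() < 1e-9:
        return B1Field(tuple(coil_origin), d0=float("inf"), gain_constant=1.0,
                       gain_map=np.ones(reference.shape))

    def residual(params):
        log_g, d0 = params
        model = log_g - 2.0 * np.log(d_sel + d0)
        if log_space:
            return model - np.log(s_sel)
        return np.exp(model) - s_sel

    d0_init = np.median(d_sel) / 2.0
    x0 = [float(np.log(s_sel.mean()) + 2 * np.log(d_sel.mean() + d0_init)), d0_init]
    fit = least_squares(
        residual, x0, bounds=([-np.inf, d0_bounds[0]], [np.inf, d0_bounds[1]])
    )
    log_g, d0 = fit.x
    gain = surface_coil_gain(grid, coil_origin, d0=d0, gain_constant=float(np.exp(log_g)))
    if np.any(gain <= 0):
        raise ValueError("fitted gain is not strictly positive")
    gain_norm = gain / gain.mean()
    return B1Field(tuple(coil_origin), d0=float(d0), gain_constant=float(np.exp(log_g)),
                   gain_map=gain_norm)


def b1_correct(
    image: ImageVolume,
    reference_phantom_image: ImageVolume,
    coil_origin,
    log_space: bool = True,
) -> tuple[ImageVolume, B1Field]:
    """Divide out the coil receive field fitted from a uniform phantom image.

    The correction is scale-invariant: multiplying the reference by any
    positive constant leaves the corrected image unchanged (the gain map is
    unit-mean normalised).
    """
    if reference_phantom_image.shape != image.shape:
        raise ValueError("reference and image grids differ")
    field = fit_b1_field(reference_phantom_image, coil_origin, log_space=log_space)
    corrected = ImageVolume(
        image.data / field.gain_map,
        image.spacing,
        modality=image.modality,
        meta={**image.meta, "b1_corrected": True, "b1_d0_mm": field.d0},
    )
    return corrected, field


def roi_stats(image: ImageVolume, rois: ROISet,
              median_filter_size: int | None = None) -> dict[str, SodiumROIStats]:
    """Raw per-ROI mean / max / voxel count.

    The max statistic is taken on the unsmoothed image by default; pass
    ``median_filter_size`` to pre-filter (the max is noise-sensitive).
    """
    rois.validate_against(image)
    data = image.data
    if median_filter_size:
        from scipy.ndimage import median_filter

        data = median_filter(data, size=median_filter_size)
    out = {}
    for name, mask in rois.masks.items():
        vals = data[mask]
        out[name] = SodiumROIStats(
            roi=name,
            mean_raw=float(vals.mean()),
            max_raw=float(vals.max()),
            n_vox=int(mask.sum()),
        )
    return out


def normalize_to_phantom(
    stats: dict[str, SodiumROIStats],
    phantom_roi: str = "phantom",
    phantom_conc: float = 50.0,
) -> dict[str, SodiumROIStats]:
    """Normalise raw ROI statistics by the phantom ROI mean and scale to mM.

    normalised = raw / phantom mean; concentration = normalised * phantom
    reference concentration (50 mM NaCl by default). The phantom ROI itself
    self-normalises to 1.0 and to the reference concentration.
    """
    if phantom_roi not in stats:
        raise ValueError(f"no '{phantom_roi}' ROI among {list(stats)}")
    ref = stats[phantom_roi].mean_raw
    if ref <= 0:
        raise ValueError("phantom ROI mean must be positive")
    out = {}
    for name, s in stats.items():
        out[name] = SodiumROIStats(
            roi=name,
            mean_raw=s.mean_raw,
            max_raw=s.max_raw,
            n_vox=s.n_vox,
            mean_norm=s.mean_raw / ref,
            max_norm=s.max_raw / ref,
            mean_mM=s.mean_raw / ref * phantom_conc,
            max_mM=s.max_raw / ref * phantom_conc,
        )
    return out


def stats_table(stats: dict[str, SodiumROIStats], subject: str = "") -> pd.DataFrame:
    """Flatten per-ROI statistics into the cohort CSV layout."""
    rows = []
    for s in stats.values():
        rows.append(
            {
                "subject": subject,
                "roi": s.roi,
                "mean_raw": s.mean_raw,
                "max_raw": s.max_raw,
                "mean_norm": s.mean_norm,
                "max_norm": s.max_norm,
                "mean_mM": s.mean_mM,
                "max_mM": s.max_mM,
                "n_vox": s.n_vox,
            }
        )
    return pd.DataFrame(rows)


def roi_volume(mask: np.ndarray, spacing) -> VolumeEstimate:
    """Tumour volume from an ROI: voxel count times voxel volume."""
    mask = np.asarray(mask, bool)
    voxvol = float(np.prod([float(s) for s in spacing]))
    if voxvol <= 0:
        raise ValueError("voxel spacing must be positive")
    return VolumeEstimate(source="roi", volume=float(mask.sum()) * voxvol)


def ellipsoid_volume(length: float, width: float) -> VolumeEstimate:
    """Calliper tumour volume by the modified ellipsoidal formula V = L*W^2 / 2.

    Length is the longer calliper axis by convention; swapped inputs are
    sorted rather than rejected.
    """
    if length < 0 or width < 0:
        raise ValueError("calliper measurements must be non-negative")
    length, width = max(length, width), min(length, width)
    return VolumeEstimate(
        source="calliper", volume=0.5 * length * width**2, length=length, width=width
    )
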