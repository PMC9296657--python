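"""Apparent diffusion coefficient estimation from multi-b DWI series.

The signal model is mono-exponential, S(b) = S0 * exp(-b * ADC). With two
b-values the ADC is the closed form -ln(S/S0)/b; with more, the ADC is the
negative slope of an ordinary least-squares fit of ln(S) on b (which reduces
exactly to the closed form in the two-point case). Per-pair two-point ADCs
are also reported for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import ImageVolume


@dataclass
class DWISeries:
    """Ordered (b-value, volume) pairs sharing one grid, with exactly one b = 0."""

    volumes: list[tuple[float, ImageVolume]]

    def __post_init__(self) -> None:
        if not self.volumes:
            raise ValueError("empty DWI series")
        b = self.b_values
        if len(np.unique(b)) != len(b):
            raise ValueError("b-values must be distinct")
        if np.count_nonzero(b == 0) != 1:
            raise ValueError("exactly one b = 0 (S0 / A0) volume is required")
        shapes = {vol.shape for _, vol in self.volumes}
        if len(shapes) > 1:
            raise ValueError("all volumes must share one grid")
        self.volumes = sorted(self.volumes, key=lambda bv: bv[0])

    @property
    def b_values(self) -> np.ndarray:
        return np.array([b for b, _ in self.volumes], dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[0][1].shape

    def stacked(self) -> np.ndarray:
        """Signals stacked along a leading b axis, shape (n_b, *grid)."""
        return np.stack([vol.data for _, vol in self.volumes])


@dataclass
class ADCResult:
    """An ADC estimate: a scalar per-ROI value or a voxelwise map."""

    scope: str  # "roi" | "voxel_map"
    adc: float | np.ndarray  # mm^2/s
    residual: float | np.ndarray  # sum of squared log-signal residuals
    b_values: np.ndarray
    pairwise_adc: dict[float, float] = field(default_factory=dict)
    invalid_fraction: float = 0.0
    invalid_mask: np.ndarray | None = None


def _loglinear_fit(b: np.ndarray, log_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of log-signal on b along the leading axis; returns (adc, residual)."""
    design = np.stack([np.ones_like(b), -b], axis=1)
    coef, *_ = np.linalg.lstsq(design, log_s.reshape(len(b), -1), rcond=None)
    fitted = design @ coef
    resid = np.sum((log_s.reshape(len(b), -1) - fitted) ** 2, axis=0)
    adc = coef[1]
    return adc.reshape(log_s.shape[1:]), resid.reshape(log_s.shape[1:])


def compute_adc_roi(series: DWISeries, mask: np.ndarray) -> ADCResult:
    """ADC from the mean ROI signal at each b.

    With exactly two b-values this is the closed form -ln(S/S0)/b; with more
    it is the negative OLS slope of ln(mean signal) on b. Mean signals must
    be positive at every b (non-positive means usually indicate the ROI has
    fallen to the noise floor).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape:
        raise ValueError("mask shape does not match the DWI grid")
    if not mask.any():
        raise ValueError("empty ROI mask")
    b = series.b_values
    if len(b) < 2:
        raise ValueError("at least two b-values are required")
    s_mean = np.array([vol.data[mask].mean() for _, vol in series.volumes])
    if np.any(s_mean <= 0):
        raise ValueError(
            "non-positive mean ROI signal; the ROI is at or below the noise floor"
        )
    log_s = np.log(s_mean)
    adc, resid = _loglinear_fit(b, log_s[:, None])
    s0 = s_mean[0]
    pairwise = {
        float(bi): float(-np.log(si / s0) / bi)
        for bi, si in zip(b[1:], s_mean[1:])
    }
    return ADCResult(
        scope="roi",
        adc=float(adc[0]),
        residual=float(resid[0]),
        b_values=b,
        pairwise_adc=pairwise,
    )


def compute_adc_map(
    series: DWISeries, noise_floor: float = 0.0
) -> ADCResult:
    """Voxelwise log-linear ADC map.

    Voxels whose signal at any b is not above ``noise_floor`` (default 0,
    i.e. positivity only) are marked invalid (NaN) rather than erroring;
    the invalid fraction is reported so callers can exclude them from ROI
    summaries.
    """
    b = series.b_values
    if len(b) < 2:
        raise ValueError("at least two b-values are required")
    signals = series.stacked()
    valid = np.all(signals > max(noise_floor, 0.0), axis=0)
    log_s = np.where(valid, np.log(np.where(signals > 0, signals, 1.0)), 0.0)
    adc, resid = _loglinear_fit(b, log_s)
    adc = np.where(valid, adc, np.nan)
    resid = np.where(valid, resid, np.nan)
    return ADCResult(
        scope="voxel_map",
        adc=adc,
        residual=resid,
        b_values=b,
        invalid_fraction=float(1.0 - valid.mean()),
        invalid_mask=~valid,
    )


def summarise_adc_map(result: ADCResult, mask: np.ndarray) -> float:
    """Mean ADC over the valid voxels of an ROI on a voxelwise map."""
    if result.scope != "voxel_map":
        raise ValueError("expected a voxel-map ADCResult")
    values = np.asarray(result.adc)[np.asarray(mask, bool)]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no valid voxels inside the ROI")
    return float(values.mean())


def estimate_background_sigma(volume: ImageVolume, background_mask: np.ndarray) -> float:
    """Rician noise sigma from an air/background region of a magnitude image.

    In signal-free regions the magnitude is Rayleigh distributed with mean
    sigma * sqrt(pi/2).
    """
    vals = volume.data[np.asarray(background_mask, bool)]
    if vals.size == 0:
        raise ValueError("empty background mask")
    return float(vals.mean() / np.sqrt(np.pi / 2.0))
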