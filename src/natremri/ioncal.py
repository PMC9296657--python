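"""Ex vivo ion calibrations.

Two inversions recover tissue sodium from ex vivo recordings:

* SBFI fluorescence -> intracellular [Na+]: per-cell plateau fluorescence at
  known calibration concentrations (ionophore-equilibrated, final three
  frames averaged per perfusion phase) is fitted with a one-phase
  association, Y(x) = Y0 + (Plateau - Y0)(1 - exp(-K x)), and the baseline
  fluorescence is inverted through the fitted curve.

* ion-selective electrode voltage -> extracellular [Na+]: standards are
  fitted with a Padé(1,1) approximant, V(C) = (a + b C)/(1 + c C), the
  bath-vs-calibration-tube junction offset is subtracted from tissue
  recordings, and the corrected voltage is inverted through the rational
  curve. Pre/post calibration sensitivity drift is checked against a 5%
  tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synth import one_phase_association

__all__ = [
    "SBFICalibration",
    "ISMECalibration",
    "fit_one_phase",
    "interpolate_nai",
    "plateau_table",
    "recover_nai_from_traces",
    "fit_pade11",
    "interpolate_nae",
    "drift_check",
    "recover_nae_from_recordings",
]


# ---------------------------------------------------------------------------
# SBFI: one-phase association


@dataclass
class SBFICalibration:
    y0: float
    plateau: float
    k: float  # 1/mM
    residual: float  # sum of squared fluorescence residuals
    concs: np.ndarray
    fluorescence: np.ndarray

    def curve(self, conc):
        return one_phase_association(conc, self.y0, self.plateau, self.k)


def fit_one_phase(concs, fluorescence) -> SBFICalibration:
    """Least-squares one-phase-association fit to plateau points.

    Initialisation is multi-start and deterministic: Y0 and Plateau start
    from the data extremes (Plateau inflated since the largest calibration
    concentration rarely saturates the curve), and K sweeps an 8-point
    log-spaced grid; the best residual wins.
    """
    concs = np.asarray(concs, float)
    fl = np.asarray(fluorescence, float)
    if concs.size < 3 or len(np.unique(concs)) < 3:
        raise ValueError("one-phase fit needs plateaus at >= 3 distinct concentrations")
    order = np.argsort(concs)
    concs, fl = concs[order], fl[order]
    if fl[-1] <= fl[0]:
        warnings.warn("plateau fluorescence is not increasing with concentration")

    def residual(p):
        return one_phase_association(concs, *p) - fl

    span = max(fl[-1] - fl[0], 1e-6)
    best = None
    for k0 in np.geomspace(0.2 / concs[-1], 20.0 / concs[-1], 8):
        x0 = [fl[0], fl[-1] + 0.5 * span, k0]
        try:
            fit = least_squares(
                residual, x0,
                bounds=([-np.inf, fl[0], 1e-8], [fl[-1] + 10 * span, np.inf, np.inf]),
            )
        except ValueError:
            continue
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None or not best.success:
        raise RuntimeError("one-phase association fit failed to converge from all starts")
    y0, plateau, k = best.x
    if plateau <= y0:
        raise RuntimeError("fit degenerate: Plateau <= Y0 (is the data decreasing?)")
    return SBFICalibration(
        y0=float(y0), plateau=float(plateau), k=float(k),
        residual=float(2 * best.cost), concs=concs, fluorescence=fl,
    )


def interpolate_nai(cal: SBFICalibration, baseline_fluorescence: float) -> float:
    """Invert the fitted curve at the resting baseline fluorescence.

    x = -ln(1 - (F - Y0)/(Plateau - Y0)) / K. A baseline at or below Y0
    maps to 0 mM (with a warning); a baseline at or above Plateau is outside
    the curve's range and raises.
    """
    f = float(baseline_fluorescence)
    if f >= cal.plateau:
        raise ValueError(
            f"baseline fluorescence {f:.4g} is at or above the fitted plateau "
            f"{cal.plateau:.4g}; inversion is undefined"
        )
    if f <= cal.y0:
        warnings.warn("baseline fluorescence at or below Y0; reporting 0 mM")
        return 0.0
    return float(-np.log(1.0 - (f - cal.y0) / (cal.plateau - cal.y0)) / cal.k)


def plateau_table(traces: pd.DataFrame, n_final_frames: int = 3) -> pd.DataFrame:
    """Average the final frames of each perfusion phase, per cell.

    Input is the tidy trace layout (cell, phase, conc_mM, frame,
    fluorescence); output has one row per (cell, phase) with the averaged
    plateau fluorescence.
    """
    required = {"cell", "phase", "conc_mM", "frame", "fluorescence"}
    if not required.issubset(traces.columns):
        raise ValueError(f"trace table must have columns {sorted(required)}")
    rows = []
    for (cell, phase), grp in traces.groupby(["cell", "phase"], sort=False):
        tail = grp.sort_values("frame").tail(n_final_frames)
        if len(tail) < n_final_frames:
            raise ValueError(
                f"phase {phase!r} of cell {cell} has fewer than {n_final_frames} frames"
            )
        rows.append(
            {
                "cell": cell,
                "phase": phase,
                "conc_mM": grp["conc_mM"].iloc[0],
                "fluorescence": tail["fluorescence"].mean(),
            }
        )
    return pd.DataFrame(rows)


def recover_nai_from_traces(
    traces: pd.DataFrame, n_final_frames: int = 3, pooled: bool = False
) -> pd.DataFrame:
    """Full SBFI pipeline for one slice: plateau averaging, per-cell
    calibration fits, baseline inversion.

    Default granularity is per-cell (the in-situ calibration controls for
    differences between cells); ``pooled=True`` instead fits one curve to
    all cells' plateaus and inverts each baseline through it. Returns one
    row per cell with the recovered resting [Na+]i.
    """
    plateaus = plateau_table(traces, n_final_frames)
    cal_rows = plateaus[plateaus["phase"] != "baseline"]
    base_rows = plateaus[plateaus["phase"] == "baseline"].set_index("cell")

    shared = None
    if pooled:
        shared = fit_one_phase(cal_rows["conc_mM"], cal_rows["fluorescence"])
    out = []
    for cell, grp in cal_rows.groupby("cell", sort=False):
        cal = shared or fit_one_phase(grp["conc_mM"], grp["fluorescence"])
        nai = interpolate_nai(cal, base_rows.loc[cell, "fluorescence"])
        out.append({"cell": cell, "nai_mM": nai, "fit_residual": cal.residual})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# ISME: Padé(1,1) electrode calibration


@dataclass
class ISMECalibration:
    a: float  # mV
    b: float  # mV/mM
    c: float  # 1/mM
    residual: float
    standards: np.ndarray  # mM
    voltages: np.ndarray  # mV

    def curve(self, conc):
        conc = np.asarray(conc, float)
        return (self.a + self.b * conc) / (1.0 + self.c * conc)

    def sensitivity(self, conc: float = 120.0) -> float:
        """dV/dC (mV/mM) at the given concentration (midrange default)."""
        return (self.b - self.a * self.c) / (1.0 + self.c * conc) ** 2


def fit_pade11(standards, voltages) -> ISMECalibration:
    """Fit V(C) = (a + b C)/(1 + c C) to electrode standards.

    With exactly 3 standards the rational interpolant is exact (linear
    system in a, b, c); with more, a nonlinear least-squares refinement
    starts from the linearised solution. A pole inside or near the standard
    range is rejected, as is a non-monotone fit over the standards.
    """
    c_std = np.asarray(standards, float)
    v_std = np.asarray(voltages, float)
    if c_std.size < 3:
        raise ValueError("Padé(1,1) needs at least 3 distinct standards")
    if len(np.unique(c_std)) != c_std.size:
        raise ValueError("standards must be distinct")
    order = np.argsort(c_std)
    c_std, v_std = c_std[order], v_std[order]

    # linearised system: a + b*C - c*C*V = V
    design = np.column_stack([np.ones_like(c_std), c_std, -c_std * v_std])
    params, *_ = np.linalg.lstsq(design, v_std, rcond=None)
    if c_std.size > 3:

        def residual(p):
            return (p[0] + p[1] * c_std) / (1.0 + p[2] * c_std) - v_std

        fit = least_squares(residual, params)
        params = fit.x
    a, b, c = (float(p) for p in params)

    lo, hi = min(40.0, c_std[0]), max(200.0, c_std[-1])
    if 1.0 + c * lo <= 0 or 1.0 + c * hi <= 0:
        raise RuntimeError(
            "rejected Padé(1,1) fit: pole inside the working range "
            f"[{lo:g}, {hi:g}] mM (c = {c:.4g})"
        )
    cal = ISMECalibration(a=a, b=b, c=c, residual=float(np.sum(
        ((a + b * c_std) / (1.0 + c * c_std) - v_std) ** 2)),
        standards=c_std, voltages=v_std)
    dv = np.diff(cal.curve(np.linspace(c_std[0], c_std[-1], 64)))
    if not (np.all(dv > 0) or np.all(dv < 0)):
        raise RuntimeError("rejected Padé(1,1) fit: non-monotone over the standard range")
    return cal


def interpolate_nae(
    cal: ISMECalibration, voltage: float, junction_offset: float = 0.0
) -> float:
    """Invert the calibration at an offset-corrected tissue voltage.

    C = (V' - a)/(b - c V') with V' = voltage - junction_offset. Voltages
    outside the curve's range over [40, 200] mM raise rather than silently
    extrapolating.
    """
    v = float(voltage) - float(junction_offset)
    v_lo, v_hi = sorted((float(cal.curve(40.0)), float(cal.curve(200.0))))
    if not v_lo <= v <= v_hi:
        raise ValueError(
            f"offset-corrected voltage {v:.3f} mV outside the calibrated range "
            f"[{v_lo:.3f}, {v_hi:.3f}] mV; refusing to extrapolate"
        )
    denom = cal.b - cal.c * v
    if abs(denom) < 1e-12:
        raise ZeroDivisionError("degenerate inversion: b - c*V vanishes")
    return (v - cal.a) / denom


def drift_check(
    cal_pre: ISMECalibration,
    cal_post: ISMECalibration,
    at_conc: float = 120.0,
    tolerance: float = 0.05,
) -> tuple[float, bool]:
    """Relative sensitivity change between pre- and post-experiment
    calibrations, evaluated at midrange; passes iff <= tolerance."""
    s_pre = cal_pre.sensitivity(at_conc)
    s_post = cal_post.sensitivity(at_conc)
    drift = abs(s_post - s_pre) / abs(s_pre)
    # inclusive boundary, robust to float round-off at exactly the tolerance
    return float(drift), drift <= tolerance * (1.0 + 1e-9) + 1e-12


def recover_nae_from_recordings(
    standards: pd.DataFrame,
    tissue: pd.DataFrame,
    junction_offset: float,
    drift_tolerance: float = 0.05,
) -> dict:
    """Full electrode pipeline for one slice.

    Fits the pre-experiment standards, subtracts the junction offset from
    each tissue recording, inverts, and QCs pre-vs-post sensitivity drift
    when post-experiment standards are present. Returns per-recording
    concentrations plus the drift diagnostics.
    """
    pre = standards[standards["stage"] == "pre"]
    cal = fit_pade11(pre["conc_mM"], pre["mV"])
    concs = [
        interpolate_nae(cal, v, junction_offset) for v in tissue["mV"].to_numpy()
    ]
    result = {
        "calibration": cal,
        "nae_mM": pd.DataFrame({"recording": tissue["recording"], "nae_mM": concs}),
        "drift": None,
        "drift_pass": None,
    }
    post = standards[standards["stage"] == "post"]
    if len(post):
        cal_post = fit_pade11(post["conc_mM"], post["mV"])
        drift, ok = drift_check(cal, cal_post, tolerance=drift_tolerance)
        result["drift"], result["drift_pass"] = drift, ok
    return result
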