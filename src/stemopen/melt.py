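"""Two-state thermal denaturation of a FRET-labelled RNA hairpin.

Model
-----
The unfolded fraction follows the van't Hoff two-state form, a logistic in
inverse absolute temperature,

    fu(T) = 1 / (1 + exp[(dH/R) * (1/T - 1/Tm)]),        T in kelvin,

so fu(Tm) = 1/2 and dH (the van't Hoff enthalpy, kcal/mol) sets the
transition sharpness. The measured fluorescence superposes linear folded and
unfolded baselines and a multiplicative thermal-quenching ramp of the
fluorophore:

    S(T) = [(1 - fu)*Bf(T) + fu*Bu(T)] * (1 - q*(T - Tmin)).

Tm extraction
-------------
Two estimators are exposed, mirroring how melt figures are usually read:

* ``derivative_tm`` — the primary estimate: Savitzky-Golay smoothed first
  derivative dS/dT, peak position refined by parabolic interpolation. A
  monotone curve (the fully-protein-disrupted regime, where only quenching
  remains) yields a "no transition" flag instead of a number.
* ``fit_melt`` — the secondary estimate: full nonlinear fit of S(T).

``amplitude_vs_dose`` quantifies how a hairpin-opening protein suppresses the
transition amplitude with dose: the folded population available to melt is
1 - fb(dose), with fb from the ligand-depletion isotherm, so relative
amplitudes should track 1 - fb.

Internally kelvin; all interfaces are in degrees Celsius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .binding import fraction_bound

__all__ = [
    "MeltTruth",
    "MeltCurve",
    "MeltFit",
    "DerivativeTm",
    "R_KCAL",
    "CELSIUS_OFFSET",
    "unfolded_fraction",
    "melt_model",
    "derivative_tm",
    "fit_melt",
    "amplitude_vs_dose",
]

R_KCAL = 1.987204259e-3  # gas constant, kcal / (mol K)
CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class MeltTruth:
    """Ground truth of a two-state melt with linear baselines and quenching.

    tm is in deg C, dh_vh in kcal/mol. Baselines are (intercept, slope/degC)
    evaluated at T in deg C; quench_slope is the fractional fluorescence loss
    per deg C relative to the first scanned temperature.
    """

    tm: float
    dh_vh: float
    baseline_folded: tuple[float, float] = (100.0, -0.1)
    baseline_unfolded: tuple[float, float] = (400.0, -0.5)
    quench_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.dh_vh <= 0:
            raise ValueError(f"dh_vh must be positive, got {self.dh_vh}")


@dataclass
class MeltCurve:
    """Fluorescence versus temperature for one condition (e.g. protein dose)."""

    temps: np.ndarray
    signal: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temps.shape != self.signal.shape:
            raise ValueError("temps and signal must have equal length")
        if self.temps.size == 0:
            raise ValueError("empty temperature grid")
        if np.any(np.diff(self.temps) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return self.temps.size

    def write_csv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# condition = {self.condition}\n")
            fh.write("temp_C,fluorescence\n")
            for t, s in zip(self.temps, self.signal):
                fh.write(f"{t:.10g},{s:.10g}\n")

    @classmethod
    def read_csv(cls, path: str | Path) -> "MeltCurve":
        condition = ""
        temps: list[float] = []
        sig: list[float] = []
        with Path(path).open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition("=")
                    if key.strip() == "condition":
                        condition = val.strip()
                    continue
                if line.lower().startswith("temp"):
                    continue
                t, s = line.split(",")[:2]
                temps.append(float(t))
                sig.append(float(s))
        return cls(np.array(temps), np.array(sig), condition)


def write_melt_set(curves: Sequence[MeltCurve], path: str | Path) -> None:
    """Write several conditions to one delimited file with a condition column."""
    with Path(path).open("w") as fh:
        fh.write("temp_C,fluorescence,condition\n")
        for curve in curves:
            for t, s in zip(curve.temps, curve.signal):
                fh.write(f"{t:.10g},{s:.10g},{curve.condition}\n")


def read_melt_set(path: str | Path) -> list[MeltCurve]:
    df = pd.read_csv(path, comment="#")
    curves = []
    for cond, grp in df.groupby("condition", sort=False):
        curves.append(
            MeltCurve(grp["temp_C"].to_numpy(), grp["fluorescence"].to_numpy(), str(cond))
        )
    return curves


def unfolded_fraction(temp_c: float | np.ndarray, tm_c: float, dh_vh: float) -> float | np.ndarray:
    """Two-state van't Hoff unfolded fraction; temperatures in deg C."""
    if dh_vh <= 0:
        raise ValueError("dh_vh must be positive")
    T = np.asarray(temp_c, dtype=float) + CELSIUS_OFFSET
    Tm = tm_c + CELSIUS_OFFSET
    arg = (dh_vh / R_KCAL) * (1.0 / T - 1.0 / Tm)
    fu = 1.0 / (1.0 + np.exp(np.clip(arg, -700, 700)))
    if fu.ndim == 0:
        return float(fu)
    return fu


def melt_model(temps_c: Sequence[float] | np.ndarray, truth: MeltTruth,
               t_min: float | None = None) -> np.ndarray:
    """Noise-free melt signal at the given temperatures (deg C).

    ``t_min`` anchors the quenching ramp; defaults to the first temperature.
    """
    T = np.asarray(temps_c, dtype=float)
    if T.size == 0:
        raise ValueError("empty temperature grid")
    if t_min is None:
        t_min = float(T[0])
    fu = np.asarray(unfolded_fraction(T, truth.tm, truth.dh_vh))
    bf = truth.baseline_folded[0] + truth.baseline_folded[1] * T
    bu = truth.baseline_unfolded[0] + truth.baseline_unfolded[1] * T
    quench = 1.0 - truth.quench_slope * (T - t_min)
    return ((1.0 - fu) * bf + fu * bu) * quench


@dataclass
class DerivativeTm:
    """First-derivative Tm readout."""

    tm: float | None
    derivative_temps: np.ndarray
    derivative: np.ndarray
    no_transition: bool
    message: str = ""


def derivative_tm(
    curve: MeltCurve,
    smooth_window: int = 5,
    polyorder: int = 2,
    rel_prominence: float = 0.25,
    direction: str = "increase",
) -> DerivativeTm:
    """Tm from the extremum of the smoothed first derivative dS/dT.

    The signal is smoothed with a moving quadratic (Savitzky-Golay, odd
    ``smooth_window``), differentiated by central differences, and the most
    prominent strictly-interior peak of the derivative is located; the peak
    position is refined by parabolic interpolation of the three surrounding
    nodes, so resolution is better than the temperature grid step.

    ``direction="increase"`` looks for a fluorescence-rise transition (the
    FRET-opening case); ``"decrease"`` negates the derivative first. A curve
    with no qualifying interior peak — a flat or monotonically quenched
    trace — returns ``no_transition=True`` and ``tm=None``.
    """
    if smooth_window % 2 == 0 or smooth_window < 3:
        raise ValueError("smooth_window must be odd and >= 3")
    n = len(curve)
    if n < 2 * smooth_window + 3:
        raise ValueError("curve too short for the requested smoothing window")
    if direction not in ("increase", "decrease"):
        raise ValueError(f"unknown direction {direction!r}")

    smoothed = savgol_filter(curve.signal, smooth_window, polyorder)
    deriv = np.gradient(smoothed, curve.temps)
    # trim the smoothing-contaminated edges
    half = smooth_window // 2
    temps_i = curve.temps[half : n - half]
    deriv_i = deriv[half : n - half]
    work = deriv_i if direction == "increase" else -deriv_i

    span = float(np.ptp(work))
    scale = max(float(np.max(np.abs(work))), 1e-300)
    if span <= 1e-8 * scale:
        return DerivativeTm(None, temps_i, deriv_i, True, "derivative constant")
    peaks, props = find_peaks(work, prominence=rel_prominence * span)
    peaks = peaks[work[peaks] > 0]
    if peaks.size == 0:
        return DerivativeTm(None, temps_i, deriv_i, True, "no interior derivative peak")
    best = peaks[np.argmax(work[peaks])]
    tm = float(temps_i[best])
    if 0 < best < len(work) - 1:
        y0, y1, y2 = work[best - 1], work[best], work[best + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            # local grid spacing (grids may be slightly nonuniform)
            dt = 0.5 * (temps_i[min(best + 1, len(work) - 1)] - temps_i[max(best - 1, 0)])
            tm += shift * dt
    return DerivativeTm(tm, temps_i, deriv_i, False)


@dataclass
class MeltFit:
    """Full van't Hoff fit of one melt curve."""

    tm: float
    tm_stderr: float | None
    dh_vh: float
    amplitude: float
    baseline_folded: tuple[float, float]
    baseline_unfolded: tuple[float, float]
    tm_derivative: float | None
    residual_rms: float
    converged: bool
    message: str = ""


def _fit_params_to_truth(p: lmfit.Parameters) -> MeltTruth:
    return MeltTruth(
        tm=p["tm"].value,
        dh_vh=max(p["dh"].value, 1e-6),
        baseline_folded=(p["bf0"].value, p["bf1"].value),
        baseline_unfolded=(p["bu0"].value, p["bu1"].value),
        quench_slope=p["quench"].value,
    )


def fit_melt(
    curve: MeltCurve,
    quench_slope: float = 0.0,
    fix_tm: float | None = None,
    fix_dh: float | None = None,
    smooth_window: int = 5,
) -> MeltFit:
    """Nonlinear least-squares fit of the two-state melt model.

    The quench ramp is supplied (default 0), not fitted — it is degenerate
    with the baseline slopes on a single curve. ``fix_tm``/``fix_dh`` pin the
    transition shape, which makes the amplitude identifiable even for nearly
    transitionless curves (used by the dose-series analysis).

    The reported ``amplitude`` is the baseline gap at the midpoint,
    Bu(Tm) - Bf(Tm), in signal units.
    """
    T = curve.temps
    S = curve.signal
    dtm = derivative_tm(curve, smooth_window=smooth_window)
    n_edge = max(3, len(curve) // 5)
    bf_init = np.polyfit(T[:n_edge], S[:n_edge], 1)  # slope, intercept
    bu_init = np.polyfit(T[-n_edge:], S[-n_edge:], 1)

    params = lmfit.Parameters()
    tm0 = fix_tm if fix_tm is not None else (dtm.tm if dtm.tm is not None else float(np.median(T)))
    dh0 = fix_dh if fix_dh is not None else 50.0
    params.add("tm", value=tm0, min=float(T[0]), max=float(T[-1]), vary=fix_tm is None)
    params.add("dh", value=dh0, min=1.0, max=500.0, vary=fix_dh is None)
    params.add("bf0", value=float(bf_init[1]))
    params.add("bf1", value=float(bf_init[0]))
    params.add("bu0", value=float(bu_init[1]))
    params.add("bu1", value=float(bu_init[0]))
    params.add("quench", value=quench_slope, vary=False)
    t_min = float(T[0])

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return melt_model(T, _fit_params_to_truth(p), t_min=t_min) - S

    result = lmfit.minimize(residual, params, method="leastsq")
    p = result.params
    tm = float(p["tm"].value)
    amplitude = float(
        (p["bu0"].value + p["bu1"].value * tm) - (p["bf0"].value + p["bf1"].value * tm)
    )
    converged = bool(result.success)
    message = str(result.message or "")
    if fix_tm is None and (tm <= T[0] + 1e-9 or tm >= T[-1] - 1e-9):
        converged = False
        message = "tm pinned at scan boundary; " + message
    se = p["tm"].stderr
    return MeltFit(
        tm=tm,
        tm_stderr=float(se) if se is not None else None,
        dh_vh=float(p["dh"].value),
        amplitude=amplitude,
        baseline_folded=(float(p["bf0"].value), float(p["bf1"].value)),
        baseline_unfolded=(float(p["bu0"].value), float(p["bu1"].value)),
        tm_derivative=dtm.tm,
        residual_rms=float(np.sqrt(np.mean(result.residual**2))),
        converged=converged,
        message=message,
    )


def amplitude_vs_dose(
    curves: Sequence[MeltCurve],
    kd: float,
    probe_total: float,
    quench_slope: float = 0.0,
) -> pd.DataFrame:
    """Transition amplitude versus protein dose, against the 1 - fb prediction.

    ``curves`` must share one temperature grid; each ``condition`` label is
    the protein dose in nM (the zero-dose curve is the amplitude reference
    and fixes Tm and dH for the others). Returns a table with the fitted
    absolute and relative amplitudes and the predicted folded fraction
    ``1 - fb(dose)`` from the depletion isotherm; the RMS disagreement
    between relative amplitude and prediction is stored in
    ``df.attrs["agreement_rms"]``.
    """
    if not curves:
        raise ValueError("no curves supplied")
    ref_grid = curves[0].temps
    for c in curves[1:]:
        if c.temps.shape != ref_grid.shape or not np.allclose(c.temps, ref_grid):
            raise ValueError("curves must share one temperature grid")
    doses = [float(c.condition) for c in curves]
    try:
        i_ref = doses.index(0.0)
    except ValueError:
        raise ValueError("a zero-dose reference curve is required") from None

    ref_fit = fit_melt(curves[i_ref], quench_slope=quench_slope)
    rows = []
    for dose, curve in zip(doses, curves):
        if curve is curves[i_ref]:
            fit = ref_fit
        else:
            fit = fit_melt(
                curve, quench_slope=quench_slope, fix_tm=ref_fit.tm, fix_dh=ref_fit.dh_vh
            )
        rel = fit.amplitude / ref_fit.amplitude if ref_fit.amplitude != 0 else math.nan
        fb = fraction_bound(dose, probe_total, kd)
        rows.append(
            {
                "dose_nM": dose,
                "amplitude": fit.amplitude,
                "relative_amplitude": rel,
                "predicted_folded_fraction": 1.0 - fb,
                "tm": fit.tm,
            }
        )
    df = pd.DataFrame(rows).sort_values("dose_nM").reset_index(drop=True)
    resid = df["relative_amplitude"] - df["predicted_folded_fraction"]
    df.attrs["agreement_rms"] = float(np.sqrt(np.mean(resid.to_numpy() ** 2)))
    return df
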