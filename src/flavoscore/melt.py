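"""ThermoFMN melt-curve simulation/fitting and kinetic-rate conversion.

The ThermoFMN assay monitors flavin fluorescence while the sample is
heated (held at 20 °C, then +1.5 °C every 30 s): FMN fluoresces strongly
once released from complex I, so the signal rises sigmoidally.  The curve
is modelled as a four-parameter logistic; for a logistic the steepest
slope sits at the midpoint, which is therefore reported as the
characteristic dissociation temperature, and the amplitude (total
intensity change) is proportional to the amount of complex-bound flavin.

Kinetic traces from plate-reader assays are converted to specific
activities by Beer-Lambert: an absorbance slope divided by ε·l gives a
concentration rate (mM min⁻¹ ≡ µmol ml⁻¹ min⁻¹), normalised by protein
concentration to µmol min⁻¹ mg⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

DEFAULT_T_START = 20.0  # °C, initial hold
DEFAULT_T_STEP = 1.5  # °C per 30 s reading
DEFAULT_T_MAX = 95.0  # °C


class MeltError(ValueError):
    pass


@dataclass(frozen=True)
class MeltCurve:
    temperatures: np.ndarray  # °C, strictly increasing
    fluorescence: np.ndarray  # arbitrary units
    meta: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise MeltError("temperature and fluorescence series must match")
        if t.size < 8:
            raise MeltError("melt curve needs at least 8 readings")
        if not np.all(np.diff(t) > 0):
            raise MeltError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)


@dataclass(frozen=True)
class MeltFit:
    """Fitted logistic: baseline + amplitude / (1 + exp(-(T - t_dissoc)/width))."""

    baseline: float
    amplitude: float
    t_dissoc: float  # midpoint = steepest-slope temperature, °C
    width: float  # °C
    residual_norm: float
    converged: bool


@dataclass(frozen=True)
class AssayParams:
    """Beer-Lambert conversion settings for a plate-reader kinetic trace."""

    extinction_mM: float  # ε, mM⁻¹ cm⁻¹ (e.g. 4.81 for NADH at 340-380 nm)
    path_cm: float = 1.0
    protein_mg_ml: float = 1.0
    stoichiometry_sign: int = 1  # -1 if the chromophore is consumed

    def __post_init__(self) -> None:
        if self.extinction_mM <= 0 or self.path_cm <= 0 or self.protein_mg_ml <= 0:
            raise ValueError("extinction, path length and protein must be positive")
        if self.stoichiometry_sign not in (-1, 1):
            raise ValueError("stoichiometry_sign must be +1 or -1")


def logistic(t: np.ndarray, baseline: float, amplitude: float,
             midpoint: float, width: float) -> np.ndarray:
    return baseline + amplitude / (1.0 + np.exp(-(t - midpoint) / width))


def protocol_temperatures(
    t_start: float = DEFAULT_T_START,
    t_step: float = DEFAULT_T_STEP,
    t_max: float = DEFAULT_T_MAX,
) -> np.ndarray:
    """Instrument temperature grid: one reading per step from t_start."""
    n = int(np.floor((t_max - t_start) / t_step)) + 1
    return t_start + t_step * np.arange(n)


def simulate_melt_curve(
    t_dissoc: float,
    amplitude: float = 1000.0,
    baseline: float = 100.0,
    width: float = 2.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    t_max: float = DEFAULT_T_MAX,
) -> MeltCurve:
    """Logistic melt curve on the instrument grid plus i.i.d. Gaussian noise."""
    if width <= 0:
        raise MeltError("width must be positive")
    if noise_sd < 0:
        raise MeltError("noise_sd must be non-negative")
    temps = protocol_temperatures(t_max=t_max)
    signal = logistic(temps, baseline, amplitude, t_dissoc, width)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=temps.size)
    return MeltCurve(
        temperatures=temps,
        fluorescence=signal,
        meta=f"simulated t_dissoc={t_dissoc} width={width} noise_sd={noise_sd}",
    )


def _initial_guess(t: np.ndarray, f: np.ndarray) -> tuple[float, float, float, float]:
    baseline = float(np.min(f))
    amplitude = float(np.max(f) - np.min(f))
    # midpoint from the max of a lightly smoothed finite-difference slope
    df = np.gradient(f, t)
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(df, kernel, mode="same")
    midpoint = float(t[int(np.argmax(np.abs(smooth)))])
    return baseline, amplitude, midpoint, 2.0


def fit_melt_curve(curve: MeltCurve) -> MeltFit:
    """Least-squares four-parameter logistic fit.

    Non-convergence (flat input, degenerate fit, midpoint escaping the
    observed temperature range) is reported via ``converged=False`` rather
    than an exception, so batch fitting never aborts.
    """
    t, f = curve.temperatures, curve.fluorescence
    p0 = _initial_guess(t, f)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(logistic, t, f, p0=p0, maxfev=10000)
    except (RuntimeError, ValueError):
        return MeltFit(
            baseline=float(np.mean(f)), amplitude=0.0,
            t_dissoc=float(t[0]), width=1.0,
            residual_norm=float(np.linalg.norm(f - np.mean(f))),
            converged=False,
        )
    baseline, amplitude, midpoint, width = (float(v) for v in popt)
    if width < 0:  # mirror-symmetric parameterisation; normalise sign
        baseline, amplitude = baseline + amplitude, -amplitude
        width = -width
    resid = float(np.linalg.norm(f - logistic(t, *popt)))
    span = float(np.max(f) - np.min(f))
    ok = (
        amplitude > 0
        and t[0] <= midpoint <= t[-1]
        and amplitude > 4 * resid / np.sqrt(t.size)  # signal above noise floor
        and span > 0
    )
    return MeltFit(
        baseline=baseline, amplitude=amplitude, t_dissoc=midpoint,
        width=width, residual_norm=resid, converged=bool(ok),
    )


def relative_flavin_content(fit_variant: MeltFit, fit_wt: MeltFit) -> float:
    """Variant/wild-type amplitude ratio ≈ relative bound-flavin content."""
    if fit_wt.amplitude <= 0:
        raise MeltError("wild-type amplitude must be positive")
    return fit_variant.amplitude / fit_wt.amplitude


def rate_from_trace(abs_slope_per_min: float, p: AssayParams) -> float:
    """Specific activity (µmol min⁻¹ mg⁻¹) from an absorbance slope (A min⁻¹)."""
    conc_rate_mM = abs_slope_per_min / (p.extinction_mM * p.path_cm)
    return p.stoichiometry_sign * conc_rate_mM / p.protein_mg_ml


def read_trace(path: Union[str, Path], delimiter: Optional[str] = None) -> MeltCurve:
    """2-column delimited text (temperature/time, signal) with one header line."""
    data = np.loadtxt(path, delimiter=delimiter, skiprows=1)
    if data.ndim != 2 or data.shape[1] < 2:
        raise MeltError(f"{path}: expected two delimited columns")
    return MeltCurve(temperatures=data[:, 0], fluorescence=data[:, 1],
                     meta=str(path))


def write_trace(curve: MeltCurve, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("temperature_C\tfluorescence\n")
        for t, f in zip(curve.temperatures, curve.fluorescence):
            fh.write(f"{t:.3f}\t{f:.6f}\n")


def melt_fit_to_dict(fit: MeltFit) -> dict:
    return {
        "baseline": fit.baseline,
        "amplitude": fit.amplitude,
        "t_dissoc_C": fit.t_dissoc,
        "width_C": fit.width,
        "residual_norm": fit.residual_norm,
        "converged": fit.converged,
    }
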