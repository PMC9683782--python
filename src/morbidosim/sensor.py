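"""Optical sensing chain: OD -> photodiode voltage and back.

The forward model is true Beer-Lambert attenuation,
``V = gain * V0 * 10**(-k * OD)``, with a per-culture-unit multiplicative gain
(3D-printed vial holders position the diodes slightly differently from unit to
unit) and additive Gaussian read noise. The inverse map — what the controller
actually uses — is a polynomial calibration of OD on voltage, fitted by least
squares exactly as one would from a dilution-standard table. Over a narrow OD
range the exponential is locally linear, which is why a degree-1 calibration
works well in practice and higher degrees work slightly better.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P

logger = logging.getLogger(__name__)

__all__ = [
    "SensorModel",
    "CalibrationCurve",
    "od_to_voltage",
    "draw_unit_gains",
    "unit_variability",
    "fit_calibration",
    "voltage_to_od",
    "read_calibration_csv",
    "write_calibration_csv",
]


@dataclass
class SensorModel:
    """Forward optical model of one LED/photodiode pair.

    ``blank_voltage`` (V0) is the photodiode voltage of sterile medium;
    ``absorptivity`` (k) is the effective extinction x pathlength per OD unit
    — below 1 because the vial path is shorter than a 1 cm cuvette and
    scattering recaptures some light; ``unit_gain_cv`` is the fractional
    coefficient of variation of the blank voltage across culture units.
    """

    blank_voltage: float = 2.93
    absorptivity: float = 0.3
    noise_sd: float = 0.01
    unit_gain_cv: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.blank_voltage > 0:
            raise ValueError("blank_voltage must be > 0")
        if not self.absorptivity > 0:
            raise ValueError("absorptivity must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.unit_gain_cv < 0:
            raise ValueError("unit_gain_cv must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class CalibrationCurve:
    """Polynomial voltage -> OD map with its goodness of fit.

    ``coefficients`` are in ascending order (constant first), length
    ``degree + 1``; ``r_squared`` is computed on the OD (response) axis.
    """

    degree: int
    coefficients: list[float]
    r_squared: float

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("need degree+1 coefficients (ascending order)")
        if self.r_squared > 1:
            raise ValueError("r_squared cannot exceed 1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "degree": self.degree,
                "coefficients": list(map(float, self.coefficients)),
                "r_squared": float(self.r_squared),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationCurve":
        d = json.loads(text)
        return cls(d["degree"], d["coefficients"], d["r_squared"])


def od_to_voltage(
    od: float,
    model: SensorModel,
    unit_gain: float = 1.0,
    noisy: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Photodiode voltage for a given culture density (forward model).

    ``V = unit_gain * V0 * 10**(-k*od)``, plus Gaussian read noise of sd
    ``model.noise_sd`` when ``noisy``. Strictly decreasing in OD.
    """
    if od < 0:
        raise ValueError("od must be >= 0")
    if not unit_gain > 0:
        raise ValueError("unit_gain must be > 0")
    v = unit_gain * model.blank_voltage * 10.0 ** (-model.absorptivity * od)
    if noisy:
        if rng is None:
            rng = model.rng()
        v += rng.normal(0.0, model.noise_sd)
    return float(v)


def draw_unit_gains(
    n_units: int,
    model: SensorModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-unit gain factors: lognormal, mean 1, CV = ``model.unit_gain_cv``.

    Lognormal keeps gains positive; with cv = 0 all gains are exactly 1.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if rng is None:
        rng = model.rng()
    cv = model.unit_gain_cv
    if cv == 0:
        # still consume draws so unit seeding stays aligned across cv settings
        rng.standard_normal(n_units)
        return np.ones(n_units)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    mu = -0.5 * sigma2  # exp(mu + sigma^2/2) = 1
    return np.exp(mu + sigma * rng.standard_normal(n_units))


def unit_variability(per_unit_values) -> float:
    """Cross-unit coefficient of variation, percent: 100 * sd / mean.

    The construct-validity metric for a multi-vial optical rig: how much do
    blank-corrected voltages differ between nominally identical units.
    """
    values = np.asarray(per_unit_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 per-unit values")
    if np.any(values <= 0):
        raise ValueError("per-unit voltages must be positive")
    return float(100.0 * values.std(ddof=1) / values.mean())


def fit_calibration(od_values, voltages, degree: int = 1) -> CalibrationCurve:
    """Least-squares polynomial regression of OD on voltage.

    R^2 = 1 - SS_res/SS_tot on the OD axis. Requires at least ``degree + 2``
    points (one more than an exact interpolation, so R^2 is meaningful),
    non-constant OD, and non-constant voltage.
    """
    od = np.asarray(od_values, dtype=float)
    v = np.asarray(voltages, dtype=float)
    if od.shape != v.shape or od.ndim != 1:
        raise ValueError("od_values and voltages must be equal-length 1-D")
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    if od.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if np.ptp(od) == 0:
        raise ValueError("OD values are constant; R^2 undefined")
    if np.ptp(v) == 0:
        raise ValueError("voltages are constant; singular design")
    coeffs = P.polyfit(v, od, degree)
    pred = P.polyval(v, coeffs)
    ss_res = float(np.sum((od - pred) ** 2))
    ss_tot = float(np.sum((od - od.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return CalibrationCurve(degree=degree, coefficients=list(coeffs), r_squared=min(r2, 1.0))


def voltage_to_od(curve: CalibrationCurve, v: float) -> float:
    """Evaluate the calibration polynomial; negative predictions clamp to 0."""
    od = float(P.polyval(v, np.asarray(curve.coefficients)))
    if od < 0:
        logger.debug("calibrated OD %.4f < 0 at V=%.4f; clamped to 0", od, v)
        return 0.0
    return od


def read_calibration_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 2-column calibration table (voltage_v, od)."""
    df = pd.read_csv(path)
    return df["voltage_v"].to_numpy(), df["od"].to_numpy()


def write_calibration_csv(path, voltages, od_values) -> None:
    pd.DataFrame({"voltage_v": voltages, "od": od_values}).to_csv(path, index=False)
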