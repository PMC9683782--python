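"""Endpoint resistance assay: broth microdilution and Hill IC50 fitting.

A sample is grown for a fixed time (default 18 h) across a serial dilution
series of the drug plus a drug-free control well; the endpoint optical
densities are fit with a four-parameter Hill curve

    OD(c) = od_min + (od_max - od_min) / (1 + (c / ic50)**h)

whose midpoint is the half-maximal inhibitory concentration (IC50). The fit
reports an IC50 variance from the linearized parameter covariance (a
residual-bootstrap alternative is available), and fits over time assemble
into a resistance trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponsePlate",
    "HillFit",
    "hill_od",
    "make_dilution_series",
    "fit_hill",
    "ic50_trajectory",
    "read_plate_csv",
    "write_plate_csv",
]


@dataclass
class DoseResponsePlate:
    """One sample's microdilution readout.

    ``doses`` and ``od_readings`` are parallel; replicate wells appear as
    repeated dose entries. Needs at least 4 distinct positive doses and a
    zero-dose control.
    """

    doses: np.ndarray
    od_readings: np.ndarray
    incubation_time: float = 18.0

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.od_readings = np.asarray(self.od_readings, dtype=float)
        if self.doses.shape != self.od_readings.shape or self.doses.ndim != 1:
            raise ValueError("doses and od_readings must be equal-length 1-D")
        if np.any(self.doses < 0) or np.any(self.od_readings < 0):
            raise ValueError("doses and OD readings must be >= 0")
        positive = np.unique(self.doses[self.doses > 0])
        if positive.size < 4:
            raise ValueError("need at least 4 distinct positive doses")
        if not np.any(self.doses == 0):
            raise ValueError("need a zero-dose control well")

    @property
    def top_dose(self) -> float:
        return float(self.doses.max())


@dataclass
class HillFit:
    """Estimated dose-response parameters.

    ``ic50_variance`` is the delta-method variance of the IC50 estimate;
    ``converged`` is False when the optimizer failed or the IC50 ran into its
    upper bound (no inhibition visible within the dose range).
    """

    ic50: float
    hill_coef: float
    od_max: float
    od_min: float
    ic50_variance: float
    converged: bool

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError("ic50 must be > 0")
        if not self.hill_coef > 0:
            raise ValueError("hill_coef must be > 0")
        if self.od_min < 0 or self.od_max < self.od_min:
            raise ValueError("need od_max >= od_min >= 0")
        if self.ic50_variance < 0:
            raise ValueError("ic50_variance must be >= 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "ic50_ugml": self.ic50,
                "hill_coef": self.hill_coef,
                "od_max": self.od_max,
                "od_min": self.od_min,
                "ic50_variance": self.ic50_variance,
                "converged": self.converged,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "HillFit":
        d = json.loads(text)
        return cls(d["ic50_ugml"], d["hill_coef"], d["od_max"], d["od_min"],
                   d["ic50_variance"], d["converged"])


def hill_od(dose, ic50: float, hill_coef: float, od_max: float, od_min: float = 0.0):
    """Four-parameter Hill dose-response curve (monotone non-increasing).

    Accepts scalar or array doses; ``hill_od(0) = od_max`` and
    ``hill_od(ic50) = (od_max + od_min) / 2``.
    """
    c = np.asarray(dose, dtype=float)
    if np.any(c < 0):
        raise ValueError("dose must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ic50) ** hill_coef, 0.0)
    out = od_min + (od_max - od_min) / (1.0 + ratio)
    return float(out) if np.isscalar(dose) else out


def make_dilution_series(top_dose: float, fold: float = 2.0, n_wells: int = 8) -> np.ndarray:
    """Serial dilution series: top, top/fold, ..., plus a 0 control appended."""
    if not top_dose > 0:
        raise ValueError("top_dose must be > 0")
    if not fold > 1:
        raise ValueError("fold must be > 1")
    if n_wells < 2:
        raise ValueError("n_wells must be >= 2")
    series = top_dose / fold ** np.arange(n_wells)
    return np.append(series, 0.0)


def _hill_log_ic50(c, log_ic50, h, od_max, od_min):
    # internal parameterization: optimizer works on log(ic50) for stability
    return hill_od(c, np.exp(log_ic50), h, max(od_max, od_min), min(od_max, od_min))


_IC50_BOUND_FACTOR = 10.0  # upper IC50 bound, in units of the top dose


def fit_hill(plate: DoseResponsePlate, variance: str = "linearized",
             n_boot: int = 200, seed: int = 0) -> HillFit:
    """Fit the four-parameter Hill curve to a plate by nonlinear least squares.

    The optimizer works on log(IC50) with bounds IC50 <= 10x the top dose and
    Hill coefficient in (0, 10]; initialization takes od_max from the
    zero-dose wells, od_min from the lowest reading, and IC50 from the dose
    whose reading is nearest half-range, with two fallback starts on failure.

    ``variance``: "linearized" propagates the covariance of log(IC50) through
    the delta method; "bootstrap" refits ``n_boot`` residual resamples.

    Raises ``ValueError`` when the readings carry no dose response at all;
    returns ``converged=False`` when the optimizer fails or the IC50 estimate
    runs into its upper bound (no inhibition within the tested range).
    """
    c = plate.doses
    y = plate.od_readings
    if np.ptp(y) < 1e-12 * max(1.0, y.max()):
        raise ValueError("no dose response: OD readings are constant")
    if variance not in ("linearized", "bootstrap"):
        raise ValueError("variance must be 'linearized' or 'bootstrap'")

    top = plate.top_dose
    od_max0 = float(y[c == 0].mean())
    od_min0 = float(y.min())
    half = od_min0 + 0.5 * (od_max0 - od_min0)
    pos = c > 0
    ic50_0 = float(c[pos][np.argmin(np.abs(y[pos] - half))])
    ic50_hi = _IC50_BOUND_FACTOR * top
    lo = [np.log(top * 1e-6), 1e-3, 0.0, 0.0]
    hi = [np.log(ic50_hi), 10.0, np.inf, np.inf]

    starts = [
        (np.log(ic50_0), 1.0, od_max0, max(od_min0, 0.0)),
        (float(np.mean(np.log(c[pos]))), 2.0, od_max0, 0.0),  # geometric-mean dose
        (np.log(top / 4), 0.5, float(y.max()), 0.0),
    ]

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            popt, pcov = curve_fit(
                _hill_log_ic50, c, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - _hill_log_ic50(c, *popt)
        ssr = float(resid @ resid)
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)

    if best is None:
        # optimizer never converged: report the initial guess, flagged
        return HillFit(ic50=ic50_0, hill_coef=1.0, od_max=od_max0,
                       od_min=max(od_min0, 0.0), ic50_variance=np.inf,
                       converged=False)

    popt, pcov, _ = best
    log_ic50, h, a, b = popt
    od_max_f, od_min_f = max(a, b), min(a, b)
    ic50 = float(np.exp(log_ic50))
    # an IC50 near its upper bound, or a fitted amplitude indistinguishable
    # from zero, means no inhibition was resolved within the plate; a finite
    # number there would be spurious
    converged = ic50 < 0.5 * ic50_hi
    if od_max_f - od_min_f < 0.02 * max(od_max_f, 1e-12):
        converged = False

    if variance == "linearized":
        var_log = float(pcov[0, 0]) if np.isfinite(pcov[0, 0]) else np.inf
        ic50_var = ic50 * ic50 * var_log  # delta method for exp()
        if not np.isfinite(ic50_var):
            ic50_var = np.inf
            converged = False
        elif ic50_var > ic50 * ic50:
            # standard error exceeds the estimate: IC50 not resolved
            converged = False
    else:
        rng = np.random.default_rng(seed)
        fitted = _hill_log_ic50(c, *popt)
        resid = y - fitted
        draws = []
        for _ in range(n_boot):
            y_b = np.maximum(fitted + rng.choice(resid, size=resid.size), 0.0)
            try:
                popt_b, _ = curve_fit(
                    _hill_log_ic50, c, y_b, p0=popt, bounds=(lo, hi), maxfev=5000
                )
                draws.append(np.exp(popt_b[0]))
            except (RuntimeError, ValueError):
                continue
        ic50_var = float(np.var(draws, ddof=1)) if len(draws) > 1 else np.inf

    if not np.isfinite(ic50_var):
        return HillFit(ic50=ic50, hill_coef=float(h), od_max=float(od_max_f),
                       od_min=float(od_min_f), ic50_variance=0.0, converged=False)
    return HillFit(ic50=ic50, hill_coef=float(h), od_max=float(od_max_f),
                   od_min=float(od_min_f), ic50_variance=max(ic50_var, 0.0),
                   converged=converged)


def ic50_trajectory(fits: list[tuple[float, HillFit]]) -> pd.DataFrame:
    """Resistance-over-time table from timestamped fits.

    Returns time-sorted rows (time_h, ic50_ugml, ic50_var, converged); raises
    on duplicate times.
    """
    times = [t for t, _ in fits]
    if len(set(times)) != len(times):
        raise ValueError("duplicate assay times")
    ordered = sorted(fits, key=lambda tf: tf[0])
    return pd.DataFrame(
        {
            "time_h": [t for t, _ in ordered],
            "ic50_ugml": [f.ic50 for _, f in ordered],
            "ic50_var": [f.ic50_variance for _, f in ordered],
            "converged": [f.converged for _, f in ordered],
        }
    )


def read_plate_csv(path, incubation_time: float = 18.0) -> DoseResponsePlate:
    """Read a plate table (dose_ugml, od600[, replicate])."""
    df = pd.read_csv(path)
    return DoseResponsePlate(
        doses=df["dose_ugml"].to_numpy(),
        od_readings=df["od600"].to_numpy(),
        incubation_time=incubation_time,
    )


def write_plate_csv(path, plate: DoseResponsePlate) -> None:
    order = np.lexsort((np.arange(plate.doses.size), -plate.doses))
    rep: dict[float, int] = {}
    reps = []
    for d in plate.doses[order]:
        rep[d] = rep.get(d, 0) + 1
        reps.append(rep[d])
    pd.DataFrame(
        {
            "dose_ugml": plate.doses[order],
            "od600": plate.od_readings[order],
            "replicate": reps,
        }
    ).to_csv(path, index=False)
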