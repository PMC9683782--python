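"""Closed-loop experiment orchestration.

Wires the morbidostat controller to a backend through a minimal hardware
contract (read a voltage, actuate pumps, advance the clock), so the same loop
drives either the bundled culture simulator or, in principle, a real rig.
Each culture unit runs independently: its own optical gain, its own noise and
mutation random streams (derived deterministically from the master seed, so
adding a unit never perturbs the others), and its own calibration curve
fitted at startup from a dilution-standard table — exactly the workflow used
on a physical device.

Also provides the virtual endpoint resistance assay (grow an effluent sample
across a drug dilution series for 18 h, fit the Hill curve to the endpoint
ODs) and seeded fixture generation for calibration tables, plates, and full
closed-loop trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd
import yaml

from .controller import ControllerConfig, PumpDecision, control_tick
from .doseresponse import DoseResponsePlate, HillFit, fit_hill, ic50_trajectory, make_dilution_series
from .dynamics import (
    CultureState,
    GrowthModel,
    PumpEvent,
    PumpKind,
    StrainPhenotype,
    apply_pump,
    phenotype_table,
    step,
    total_od,
    trajectory_to_frame,
)
from .sensor import (
    CalibrationCurve,
    SensorModel,
    draw_unit_gains,
    fit_calibration,
    od_to_voltage,
    voltage_to_od,
    write_calibration_csv,
)

__all__ = [
    "ExperimentConfig",
    "HardwareBackend",
    "SimulatedBackend",
    "ExperimentResult",
    "run_experiment",
    "assay_mixture",
    "resistance_trajectory",
    "detect_growth_phases",
    "generate_fixtures",
    "write_logs",
]

#: Placeholder incubator temperature logged for driver parity.
INCUBATION_TEMP_C = 37.0


@dataclass
class ExperimentConfig:
    """Full description of one seeded in-silico experiment."""

    n_units: int = 3
    duration_h: float = 28.0
    sampling_interval_h: float = 12.0
    seed: int = 0
    volume_ml: float = 12.0
    # 100 uL of a stationary-phase overnight culture (~OD 2.4) into 12 mL
    inoculum_od: float = 0.02
    ancestor: StrainPhenotype = field(
        default_factory=lambda: StrainPhenotype(growth_rate=1.0, ic50=4.0, hill_coef=2.0)
    )
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    growth: GrowthModel = field(default_factory=lambda: GrowthModel(mode="stochastic"))
    sensor: SensorModel = field(default_factory=SensorModel)

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not self.duration_h > 0:
            raise ValueError("duration_h must be > 0")
        if not self.sampling_interval_h > 0:
            raise ValueError("sampling_interval_h must be > 0")

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "duration_h": self.duration_h,
            "sampling_interval_h": self.sampling_interval_h,
            "seed": self.seed,
            "volume_ml": self.volume_ml,
            "inoculum_od": self.inoculum_od,
            "ancestor": {
                "growth_rate": self.ancestor.growth_rate,
                "ic50": self.ancestor.ic50,
                "hill_coef": self.ancestor.hill_coef,
            },
            "controller": vars(self.controller).copy(),
            "growth": vars(self.growth).copy(),
            "sensor": vars(self.sensor).copy(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        if "ancestor" in kwargs:
            kwargs["ancestor"] = StrainPhenotype(**kwargs["ancestor"])
        if "controller" in kwargs:
            kwargs["controller"] = ControllerConfig(**kwargs["controller"])
        if "growth" in kwargs:
            kwargs["growth"] = GrowthModel(**kwargs["growth"])
        if "sensor" in kwargs:
            kwargs["sensor"] = SensorModel(**kwargs["sensor"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@runtime_checkable
class HardwareBackend(Protocol):
    """The contract a driver must honor for :func:`run_experiment`.

    ``read_voltage`` returns the (strictly positive) photodiode voltage of a
    unit; ``actuate`` executes one pump decision (medium in, equal waste out);
    ``advance`` moves the clock forward; ``clock`` reports hours since start.
    """

    def read_voltage(self, unit: int) -> float: ...
    def actuate(self, unit: int, decision: PumpDecision) -> None: ...
    def advance(self, dt: float) -> None: ...
    def clock(self) -> float: ...


def _unit_seed(master_seed: int, unit: int, stream: int) -> np.random.SeedSequence:
    # derivation depends only on (master, unit, stream): adding a unit or a
    # stream never perturbs existing ones
    return np.random.SeedSequence([int(master_seed), int(unit), int(stream)])


class SimulatedBackend:
    """Virtual rig: evolving cultures + optical chain behind the contract."""

    CAL_OD_MAX = 0.5
    CAL_POINTS = 11

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self._time = 0.0
        n = config.n_units
        gain_rng = np.random.default_rng(_unit_seed(config.seed, 0, 0))
        self.unit_gains = draw_unit_gains(n, config.sensor, rng=gain_rng)
        self._noise_rngs = [
            np.random.default_rng(_unit_seed(config.seed, u, 1)) for u in range(n)
        ]
        self._mut_rngs = [
            np.random.default_rng(_unit_seed(config.seed, u, 2)) for u in range(n)
        ]
        self.states = [
            CultureState(
                time=0.0,
                volume=config.volume_ml,
                drug_conc=0.0,
                subpops={config.ancestor: config.inoculum_od},
            )
            for _ in range(n)
        ]
        self.calibrations = [self._calibrate_unit(u) for u in range(n)]

    def _calibrate_unit(self, unit: int) -> CalibrationCurve:
        """Fit the unit's voltage->OD line from a dilution-standard table."""
        cal_rng = np.random.default_rng(_unit_seed(self.config.seed, unit, 3))
        od_std = np.linspace(0.0, self.CAL_OD_MAX, self.CAL_POINTS)
        volts = np.array(
            [
                od_to_voltage(o, self.config.sensor, self.unit_gains[unit],
                              noisy=True, rng=cal_rng)
                for o in od_std
            ]
        )
        return fit_calibration(od_std, volts, degree=1)

    # -- HardwareBackend contract -----------------------------------------
    def read_voltage(self, unit: int) -> float:
        v = od_to_voltage(
            total_od(self.states[unit]),
            self.config.sensor,
            self.unit_gains[unit],
            noisy=True,
            rng=self._noise_rngs[unit],
        )
        return max(v, 1e-6)

    def actuate(self, unit: int, decision: PumpDecision) -> None:
        state = self.states[unit]
        if decision.volume > 0:
            kind = decision.kind
            c_in = (
                self.config.controller.drug_stock_conc
                if kind is PumpKind.SELECTIVE
                else 0.0
            )
            state = apply_pump(
                state, PumpEvent(self._time, kind, decision.volume, c_in)
            )
            state = apply_pump(
                state, PumpEvent(self._time, PumpKind.WASTE, decision.waste_volume)
            )
        self.states[unit] = state

    def advance(self, dt: float) -> None:
        for u in range(self.config.n_units):
            self.states[u] = step(
                self.states[u], dt, self.config.growth, rng=self._mut_rngs[u]
            )
        self._time += dt

    def clock(self) -> float:
        return self._time

    def snapshot(self, unit: int) -> CultureState:
        return self.states[unit].copy()


@dataclass
class ExperimentResult:
    """Logs of one run: per-unit time series, controller events, samples."""

    config: ExperimentConfig
    unit_logs: dict[int, pd.DataFrame]
    events: pd.DataFrame
    #: per unit: list of (time_h, {phenotype: density}) effluent snapshots
    samples: dict[int, list[tuple[float, dict[StrainPhenotype, float]]]]
    calibrations: list[CalibrationCurve]


def run_experiment(
    config: ExperimentConfig, backend: HardwareBackend | None = None
) -> ExperimentResult:
    """Run the full feedback loop for every culture unit.

    Every ``cycle_period`` minutes, per unit: read the voltage, convert to OD
    through the unit's calibration, run the controller on the recent OD
    history, actuate the chosen pumps, then integrate the culture to the next
    tick. Every ``sampling_interval_h`` the population composition is
    snapshotted — the in-silico analog of freezing an effluent sample.

    Identical configs (same master seed) give bit-identical logs.
    """
    if backend is None:
        backend = SimulatedBackend(config)
    sim = backend if isinstance(backend, SimulatedBackend) else None
    calibrations = sim.calibrations if sim else [None] * config.n_units

    cycle_h = config.controller.cycle_period / 60.0
    n_cycles = math.floor(config.duration_h / cycle_h + 1e-9)

    hist_t: dict[int, list[float]] = {u: [] for u in range(config.n_units)}
    hist_od: dict[int, list[float]] = {u: [] for u in range(config.n_units)}
    rows: dict[int, list[dict]] = {u: [] for u in range(config.n_units)}
    event_rows: list[dict] = []
    samples: dict[int, list] = {u: [] for u in range(config.n_units)}
    next_sample = 0.0

    for tick in range(n_cycles + 1):
        t = backend.clock()
        take_sample = t >= next_sample - 1e-9
        if take_sample:
            next_sample += config.sampling_interval_h

        for u in range(config.n_units):
            v = backend.read_voltage(u)
            if calibrations[u] is not None:
                od_est = voltage_to_od(calibrations[u], v)
            else:
                od_est = v  # raw-voltage fallback for minimal backends
            hist_t[u].append(t)
            hist_od[u].append(od_est)
            decision, rate = control_tick(hist_t[u], hist_od[u], config.controller)

            row = {"time_h": t, "temp_c": INCUBATION_TEMP_C,
                   "voltage_v": v, "od_est": od_est}
            if sim is not None:
                s = sim.snapshot(u)
                row.update(volume_ml=s.volume, drug_ugml=s.drug_conc,
                           od_total=total_od(s))
                if take_sample:
                    samples[u].append((t, dict(s.subpops)))
            rows[u].append(row)

            if tick < n_cycles:  # no actuation after the final reading
                backend.actuate(u, decision)
                event_rows.append(
                    {
                        "time_h": t,
                        "unit_id": u,
                        "decision": decision.kind.value,
                        "volume_ml": decision.volume,
                        "od_at_decision": od_est,
                        "growth_rate_per_h": rate,
                    }
                )
        if tick < n_cycles:
            backend.advance(cycle_h)

    unit_logs = {u: pd.DataFrame(rows[u]) for u in range(config.n_units)}
    events = pd.DataFrame(
        event_rows,
        columns=["time_h", "unit_id", "decision", "volume_ml",
                 "od_at_decision", "growth_rate_per_h"],
    )
    return ExperimentResult(config, unit_logs, events, samples,
                            list(calibrations))


def assay_mixture(
    composition: dict[StrainPhenotype, float],
    model: GrowthModel,
    doses: np.ndarray | None = None,
    inoculum_od: float = 0.005,
    incubation_h: float = 18.0,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DoseResponsePlate:
    """Virtual broth microdilution of a (possibly mixed) population sample.

    The sample is inoculated at ``inoculum_od`` total density, preserving its
    phenotype proportions, into wells spanning a serial dilution series plus
    a drug-free control, grown for ``incubation_h`` at constant drug
    concentration (no pumping, no mutation), and the endpoint total OD per
    well is read out, optionally with multiplicative lognormal-ish noise of
    coefficient of variation ``noise_cv``.
    """
    if doses is None:
        doses = make_dilution_series(32.0, 2.0, 8)
    tot = sum(composition.values())
    if tot <= 0:
        raise ValueError("sample composition is empty")
    assay_model = replace(model, mutation_rate=0.0, mode="deterministic")
    readings = []
    for c in doses:
        state = CultureState(
            time=0.0,
            volume=1.0,
            drug_conc=float(c),
            subpops={p: inoculum_od * d / tot for p, d in composition.items()},
        )
        end = step(state, incubation_h, assay_model)
        od = total_od(end)
        if noise_cv > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            od *= math.exp(rng.normal(0.0, noise_cv))
        readings.append(od)
    return DoseResponsePlate(
        doses=np.asarray(doses, dtype=float),
        od_readings=np.asarray(readings),
        incubation_time=incubation_h,
    )


def resistance_trajectory(
    result: ExperimentResult,
    unit: int = 0,
    doses: np.ndarray | None = None,
    noise_cv: float = 0.0,
) -> tuple[pd.DataFrame, list[tuple[float, HillFit]]]:
    """Assay every effluent sample of a unit and assemble the IC50-over-time
    table — the in-silico twin of a resistance-evolution time course."""
    fits = []
    rng = np.random.default_rng(_unit_seed(result.config.seed, unit, 4))
    for t, comp in result.samples[unit]:
        plate = assay_mixture(comp, result.config.growth, doses=doses,
                              noise_cv=noise_cv, rng=rng)
        fits.append((t, fit_hill(plate)))
    return ic50_trajectory(fits), fits


def detect_growth_phases(
    times, ods, smooth_h: float = 2.0, rate_deadband: float = 0.02
) -> dict[str, bool]:
    """Classify a closed-loop OD trace into expand / decline / rebound.

    The trace is boxcar-smoothed over ``smooth_h`` hours, the log-density
    slope (per hour) is taken, and slopes inside the ``rate_deadband`` are
    ignored as flat; consecutive equal signs collapse into segments.
    Expansion is an initial positive segment during which the density at
    least triples; decline is a later negative segment; rebound is a
    positive segment after that — the +/-/+ signature of a culture that
    grows, is knocked down by the drug, and recovers.
    """
    t = np.asarray(times, dtype=float)
    od = np.asarray(ods, dtype=float)
    if t.size < 5:
        return {"expanded": False, "declined": False, "rebounded": False}
    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(smooth_h / dt)))
    s = np.convolve(od, np.ones(w) / w, mode="valid")
    ts = t[: s.size]
    rate = np.gradient(np.log(np.maximum(s, 1e-6)), ts)

    signs = np.where(rate > rate_deadband, 1, np.where(rate < -rate_deadband, -1, 0))
    segments = [x for x in signs if x != 0]
    collapsed: list[int] = []
    for x in segments:
        if not collapsed or collapsed[-1] != x:
            collapsed.append(x)

    expanded = bool(collapsed and collapsed[0] == 1 and s.max() >= 3.0 * s[0])
    declined = expanded and -1 in collapsed[1:]
    rebounded = False
    if declined:
        i_dec = collapsed[1:].index(-1) + 1
        rebounded = 1 in collapsed[i_dec:]
    return {"expanded": expanded, "declined": declined, "rebounded": rebounded}


def write_logs(result: ExperimentResult, outdir) -> list[Path]:
    """Write per-unit logs, the events file, calibrations and the phenotype
    sidecar as CSV/JSON under ``outdir``; returns the paths written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    all_phenos: list[StrainPhenotype] = []
    for u, log in result.unit_logs.items():
        p = out / f"unit{u}.csv"
        log.to_csv(p, index=False, float_format="%.10g")
        paths.append(p)
        for _, comp in result.samples.get(u, []):
            all_phenos.extend(comp)
    p = out / "events.csv"
    result.events.to_csv(p, index=False, float_format="%.10g")
    paths.append(p)
    if all_phenos:
        p = out / "phenotypes.csv"
        phenotype_table(all_phenos).to_csv(p, index=False, float_format="%.10g")
        paths.append(p)
    for u, curve in enumerate(result.calibrations):
        if curve is not None:
            p = out / f"calibration_unit{u}.json"
            p.write_text(curve.to_json())
            paths.append(p)
    return paths


def generate_fixtures(kind: str, seed: int, outdir) -> list[Path]:
    """Write seeded synthetic data files: a calibration table, a
    dose-response plate, or a short closed-loop trajectory. Byte-identical
    for identical seeds."""
    from .doseresponse import hill_od, write_plate_csv  # local to avoid cycle noise

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if kind == "calibration":
        model = SensorModel(seed=seed)
        od = np.round(np.linspace(0.0, 1.0, 21), 6)
        volts = np.array(
            [od_to_voltage(o, model, noisy=True, rng=rng) for o in od]
        )
        path = out / "calibration.csv"
        write_calibration_csv(path, np.round(volts, 6), od)
        return [path]
    if kind == "plate":
        doses = make_dilution_series(32.0, 2.0, 8)
        clean = hill_od(doses, ic50=4.0, hill_coef=2.0, od_max=1.0, od_min=0.05)
        noisy = clean * np.exp(rng.normal(0.0, 0.05, size=doses.size))
        path = out / "plate.csv"
        write_plate_csv(path, DoseResponsePlate(doses, np.round(noisy, 6)))
        return [path]
    if kind == "trajectory":
        config = ExperimentConfig(n_units=1, duration_h=12.0, seed=seed)
        result = run_experiment(config)
        return write_logs(result, out)
    raise ValueError(f"unknown fixture kind {kind!r}")
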