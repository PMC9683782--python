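"""Virtual evolving bacterial culture.

This module stands in for the physical vial of a morbidostat: a well-mixed
liquid culture of one or more bacterial subpopulations growing under logistic
resource limitation, inhibited and killed by an antibiotic according to a Hill
pharmacodynamic law, diluted by pump events, and (optionally) mutating to
higher-IC50 phenotypes.

Population densities are tracked directly in OD-equivalent units (OD600), so
that the optical sensing chain downstream is exercised without an extra
cell-count conversion; the only place absolute cell numbers enter is the
mutation process, where division counts are needed.

The per-capita net growth rate of a phenotype with maximal rate ``r``,
half-inhibitory concentration ``IC50`` and Hill coefficient ``n`` at drug
concentration ``c`` and total density ``N`` is::

    g(c, N) = r * (1 - N/K) * (1 - E(c)) - d * E(c)
    E(c)    = c**n / (c**n + IC50**n)

so growth is pure logistic at ``c = 0`` and net growth turns negative at high
drug — the regime a morbidostat needs to hold a culture at near-constant
inhibition.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MAX_STEP_H",
    "StrainPhenotype",
    "GrowthModel",
    "CultureState",
    "PumpKind",
    "PumpEvent",
    "hill_effect",
    "per_capita_rate",
    "step",
    "apply_pump",
    "total_od",
    "run_dynamics",
    "trajectory_to_frame",
    "phenotype_table",
]

#: Maximum internal RK4 step, hours. ``step`` subdivides longer intervals.
MAX_STEP_H = 0.01


@dataclass(frozen=True)
class StrainPhenotype:
    """Heritable parameters of one subpopulation.

    Parameters
    ----------
    growth_rate:
        Maximal per-capita growth rate ``r`` (per hour).
    ic50:
        Drug concentration of half-maximal inhibition (ug/mL).
    hill_coef:
        Hill steepness ``n`` (dimensionless, > 0).
    """

    growth_rate: float
    ic50: float
    hill_coef: float

    def __post_init__(self) -> None:
        if not self.growth_rate > 0:
            raise ValueError(f"growth_rate must be > 0, got {self.growth_rate}")
        if not self.ic50 > 0:
            raise ValueError(f"ic50 must be > 0, got {self.ic50}")
        if not self.hill_coef > 0:
            raise ValueError(f"hill_coef must be > 0, got {self.hill_coef}")

    def mutate(self, ic50_step: float) -> "StrainPhenotype":
        """Return the next rung of the resistance ladder (IC50 x ic50_step)."""
        return replace(self, ic50=self.ic50 * ic50_step)


@dataclass
class GrowthModel:
    """Environment and process parameters shared by all phenotypes.

    Defaults describe a fast-growing enteric bacterium in rich medium under a
    bacteriostatic-plus-weakly-bactericidal drug: carrying capacity 1 OD,
    maximal kill rate 0.2/h, resistance mutations at 1e-8 per division each
    doubling the IC50, and 8e8 cells/mL per OD unit.
    """

    carrying_capacity: float = 1.0
    kill_rate: float = 0.2
    mutation_rate: float = 1e-8
    ic50_step: float = 2.0
    cells_per_od: float = 8e8
    mode: str = "deterministic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.carrying_capacity > 0:
            raise ValueError("carrying_capacity must be > 0")
        if self.kill_rate < 0:
            raise ValueError("kill_rate must be >= 0")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if not self.ic50_step > 1:
            raise ValueError("ic50_step must be > 1")
        if not self.cells_per_od > 0:
            raise ValueError("cells_per_od must be > 0")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"mode must be deterministic|stochastic, got {self.mode!r}")

    def rng(self) -> np.random.Generator:
        """A fresh generator seeded from ``seed`` (one per simulation)."""
        return np.random.default_rng(self.seed)


@dataclass
class CultureState:
    """Snapshot of one culture unit: time, volume, drug, subpopulations."""

    time: float = 0.0
    volume: float = 12.0
    drug_conc: float = 0.0
    subpops: dict[StrainPhenotype, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError("volume must be > 0")
        if self.drug_conc < 0:
            raise ValueError("drug_conc must be >= 0")
        for pheno, dens in self.subpops.items():
            if dens < 0:
                raise ValueError(f"negative density {dens} for {pheno}")

    def copy(self) -> "CultureState":
        return CultureState(self.time, self.volume, self.drug_conc, dict(self.subpops))


class PumpKind(enum.Enum):
    PERMISSIVE = "permissive"
    SELECTIVE = "selective"
    WASTE = "waste"


@dataclass(frozen=True)
class PumpEvent:
    """A timed fluid addition or removal.

    PERMISSIVE adds drug-free medium, SELECTIVE adds medium at the drug stock
    concentration, WASTE removes well-mixed culture (cells and drug leave
    together).
    """

    time: float
    kind: PumpKind
    volume: float
    drug_conc_in: float = 0.0

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("pump volume must be >= 0")
        if self.drug_conc_in < 0:
            raise ValueError("drug_conc_in must be >= 0")


def hill_effect(conc: float, ic50: float, hill_coef: float) -> float:
    """Fractional drug effect E(c) = c^n / (c^n + IC50^n), in [0, 1)."""
    if conc < 0:
        raise ValueError("drug concentration must be >= 0")
    if conc == 0:
        return 0.0
    # compute on the log scale to avoid overflow at extreme doses
    ratio = (conc / ic50) ** hill_coef
    return ratio / (1.0 + ratio)


def per_capita_rate(
    phenotype: StrainPhenotype,
    drug_conc: float,
    total_od: float,
    model: GrowthModel,
) -> float:
    """Net per-capita growth rate (per hour) of a phenotype.

    ``r*(1 - N/K)*(1 - E(c)) - d*E(c)``: logistic growth dampened by the Hill
    inhibition factor, minus a Hill-shaped kill term. Strictly decreasing in
    the drug concentration for N < K, negative at saturating drug.
    """
    if drug_conc < 0:
        raise ValueError("drug_conc must be >= 0")
    if total_od < 0:
        raise ValueError("total_od must be >= 0")
    effect = hill_effect(drug_conc, phenotype.ic50, phenotype.hill_coef)
    crowding = 1.0 - total_od / model.carrying_capacity
    return phenotype.growth_rate * crowding * (1.0 - effect) - model.kill_rate * effect


def total_od(state: CultureState) -> float:
    """Total optical density: sum of subpopulation densities."""
    return float(sum(state.subpops.values()))


def _derivatives(
    densities: np.ndarray,
    phenos: list[StrainPhenotype],
    drug_conc: float,
    model: GrowthModel,
) -> np.ndarray:
    n_total = max(float(densities.sum()), 0.0)
    rates = np.array(
        [per_capita_rate(p, drug_conc, n_total, model) for p in phenos]
    )
    return rates * densities


def step(
    state: CultureState,
    dt: float,
    model: GrowthModel,
    rng: np.random.Generator | None = None,
) -> CultureState:
    """Advance the culture by ``dt`` hours of growth/kill/mutation.

    Growth is integrated with fixed-step RK4 (internal substeps of at most
    ``MAX_STEP_H``). Drug concentration and volume are untouched — dilution
    happens only through :func:`apply_pump`.

    Mutation: per substep, each phenotype produces
    ``births = max(g_birth, 0) * density * volume * cells_per_od * h`` new
    cells, where ``g_birth = r*(1-N/K)*(1-E(c))`` is the birth part of the
    rate; mutants arise at rate ``mutation_rate`` per birth, entering the
    phenotype with IC50 multiplied by ``ic50_step``. Stochastic mode draws
    Poisson counts from ``rng`` (defaults to ``model.rng()``); deterministic
    mode moves the expected flux. Mutant density is transferred from the
    parent so total cell number is conserved.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if model.mode == "stochastic" and rng is None:
        rng = model.rng()

    n_sub = max(1, math.ceil(dt / MAX_STEP_H - 1e-12))
    h = dt / n_sub

    pops: dict[StrainPhenotype, float] = dict(state.subpops)
    c = state.drug_conc
    vol = state.volume
    mu = model.mutation_rate

    for _ in range(n_sub):
        phenos = list(pops)
        dens = np.array([pops[p] for p in phenos], dtype=float)
        if dens.size:
            # classic RK4 on the coupled per-phenotype ODEs
            k1 = _derivatives(dens, phenos, c, model)
            k2 = _derivatives(dens + 0.5 * h * k1, phenos, c, model)
            k3 = _derivatives(dens + 0.5 * h * k2, phenos, c, model)
            k4 = _derivatives(dens + h * k3, phenos, c, model)
            new_dens = dens + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            new_dens = np.maximum(new_dens, 0.0)
        else:
            new_dens = dens

        new_pops = {p: float(d) for p, d in zip(phenos, new_dens)}

        if mu > 0 and dens.size:
            n_start = max(float(dens.sum()), 0.0)
            crowding = 1.0 - n_start / model.carrying_capacity
            for p, d_start in zip(phenos, dens):
                if d_start <= 0:
                    continue
                effect = hill_effect(c, p.ic50, p.hill_coef)
                g_birth = p.growth_rate * crowding * (1.0 - effect)
                births = max(g_birth, 0.0) * d_start * vol * model.cells_per_od * h
                mean_mutants = mu * births
                if mean_mutants <= 0:
                    continue
                if model.mode == "stochastic":
                    n_mut = float(rng.poisson(mean_mutants))
                else:
                    n_mut = mean_mutants
                if n_mut <= 0:
                    continue
                delta_od = n_mut / (vol * model.cells_per_od)
                delta_od = min(delta_od, new_pops.get(p, 0.0))
                child = p.mutate(model.ic50_step)
                new_pops[p] = new_pops.get(p, 0.0) - delta_od
                new_pops[child] = new_pops.get(child, 0.0) + delta_od

        pops = new_pops

    return CultureState(
        time=state.time + dt, volume=vol, drug_conc=c, subpops=pops
    )


def apply_pump(state: CultureState, event: PumpEvent) -> CultureState:
    """Apply one instantaneous, perfectly mixed pump event.

    Additions (PERMISSIVE/SELECTIVE) conserve drug mass exactly:
    ``c' = (c*V + c_in*dV) / (V + dV)`` and every density scales by
    ``V/(V + dV)``. WASTE removes well-mixed culture, leaving concentrations
    and densities unchanged and reducing the volume.
    """
    dv = event.volume
    if dv == 0:
        return state.copy()
    v = state.volume
    if event.kind is PumpKind.WASTE:
        if dv > v:
            raise ValueError(f"waste volume {dv} exceeds culture volume {v}")
        new_vol = v - dv
        if new_vol <= 0:
            raise ValueError("waste event would empty the vessel")
        return CultureState(state.time, new_vol, state.drug_conc, dict(state.subpops))

    c_in = 0.0 if event.kind is PumpKind.PERMISSIVE else event.drug_conc_in
    new_vol = v + dv
    new_conc = (state.drug_conc * v + c_in * dv) / new_vol
    dilution = v / new_vol
    new_pops = {p: d * dilution for p, d in state.subpops.items()}
    return CultureState(state.time, new_vol, new_conc, new_pops)


def run_dynamics(
    state: CultureState,
    duration: float,
    model: GrowthModel,
    record_interval: float = 0.1,
) -> list[CultureState]:
    """Integrate a closed vial (no pumping) and record snapshots.

    Returns states at t = 0, record_interval, 2*record_interval, ..., duration.
    Stochastic mutation draws come from a single generator seeded by
    ``model.seed``, so trajectories are reproducible.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = model.rng()
    out = [state.copy()]
    n_rec = math.ceil(duration / record_interval - 1e-12)
    cur = state
    for i in range(n_rec):
        dt = min(record_interval, duration - i * record_interval)
        cur = step(cur, dt, model, rng=rng)
        out.append(cur)
    return out


def phenotype_table(phenos: list[StrainPhenotype]) -> pd.DataFrame:
    """Sidecar table (id, r, ic50, hill) for trajectory CSVs, sorted by IC50."""
    ordered = sorted(set(phenos), key=lambda p: (p.ic50, p.growth_rate, p.hill_coef))
    return pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(len(ordered))],
            "growth_rate_per_h": [p.growth_rate for p in ordered],
            "ic50_ugml": [p.ic50 for p in ordered],
            "hill_coef": [p.hill_coef for p in ordered],
        }
    )


def trajectory_to_frame(states: list[CultureState]) -> pd.DataFrame:
    """Serialize culture snapshots: time_h, volume_ml, drug_ugml, od_total, p0.."""
    all_phenos: list[StrainPhenotype] = []
    for s in states:
        all_phenos.extend(s.subpops)
    table = phenotype_table(all_phenos)
    ordered = sorted(
        set(all_phenos), key=lambda p: (p.ic50, p.growth_rate, p.hill_coef)
    )
    rows = []
    for s in states:
        row = {
            "time_h": s.time,
            "volume_ml": s.volume,
            "drug_ugml": s.drug_conc,
            "od_total": total_od(s),
        }
        for pid, p in zip(table["id"], ordered):
            row[pid] = s.subpops.get(p, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
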