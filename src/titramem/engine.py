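"""Stochastic-titration constant-pH dynamics on the surrogate model.

The conformational degrees of freedom of the all-atom method are
replaced by a single overdamped Brownian coordinate z (the membrane
normal); the Poisson-Boltzmann / Monte-Carlo protonation step is
replaced by exact heat-bath sampling of the protonation state from its
Henderson-Hasselbalch conditional at the current position.  The
scheme alternates the two on a fixed cadence, mirroring the usual
stochastic-titration cycle (titration attempts every 20 time units,
exchange attempts every 20 starting at 10, first 25 units flagged as
equilibration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exchange import Window
from .model import DEPROTONATED, PROTONATED, ToyModel

RECORD_COLUMNS = [
    "time",
    "replica_id",
    "replicate_index",
    "pH",
    "window_id",
    "z_nm",
    "state",
    "bias_kJmol",
    "equilibration_flag",
]


@dataclass(frozen=True)
class Frame:
    """One time point of one replica."""

    time: float
    replica_id: str
    replicate_index: int
    pH: float
    z: float  # nm
    state: str
    window_id: Optional[str] = None
    bias_energy: float = 0.0  # kJ/mol

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValueError("replicate_index is 1-based and must be >= 1")
        if self.bias_energy < 0:
            raise ValueError("harmonic bias energy cannot be negative")

    @property
    def proton_count(self) -> int:
        return 1 if self.state == PROTONATED else 0


@dataclass(frozen=True)
class Schedule:
    """Cadence of the stochastic-titration cycle, in toy time units
    ("ps-equivalent")."""

    dt: float = 0.01
    n_steps: int = 0
    titration_period: float = 20.0
    record_period: float = 1.0
    exchange_period: Optional[float] = 20.0
    exchange_offset: float = 10.0
    equilibration_cutoff: float = 25.0

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        for name in ("titration_period", "record_period"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.exchange_period is not None:
            if not (self.exchange_period > 0):
                raise ValueError("exchange_period must be > 0")
            if not (0 <= self.exchange_offset < self.exchange_period):
                raise ValueError("exchange_offset must lie in [0, exchange_period)")
        if self.equilibration_cutoff < 0:
            raise ValueError("equilibration_cutoff must be >= 0")

    def _steps(self, period: float) -> int:
        k = period / self.dt
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"period {period} is not an integer multiple of dt={self.dt}")
        return int(round(k))

    @property
    def titration_steps(self) -> int:
        return self._steps(self.titration_period)

    @property
    def record_steps(self) -> int:
        return self._steps(self.record_period)

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt


def brownian_step(
    frame: Frame,
    model: ToyModel,
    window: Optional[Window],
    dt: float,
    diffusion: float,
    rng: np.random.Generator,
) -> Frame:
    """One overdamped update z' = z - beta*D*dU_total/dz*dt + sqrt(2Ddt)*eta.

    The protonation state is unchanged; time advances by dt.
    """
    if not (dt > 0):
        raise ValueError("dt must be > 0")
    if not (diffusion > 0):
        raise ValueError("diffusion must be > 0")
    grad = float(model.potential_gradient(frame.z, frame.state))
    if window is not None:
        grad += float(window.bias_gradient(frame.z))
    if not math.isfinite(grad):
        raise FloatingPointError(f"non-finite force at z={frame.z}: check the model potentials")
    beta = model.thermo.beta
    eta = float(rng.standard_normal())
    z_new = frame.z - beta * diffusion * grad * dt + math.sqrt(2.0 * diffusion * dt) * eta
    bias = float(window.bias_energy(z_new)) if window is not None else 0.0
    return replace(frame, time=frame.time + dt, z=z_new, bias_energy=bias)


def titration_resample(
    frame: Frame, pH: float, model: ToyModel, rng: np.random.Generator
) -> Frame:
    """Heat-bath resample of the protonation state at fixed position:
    P(deprot | z, pH) = 1 / (1 + 10^(pKa(z) - pH)).  Exact full
    re-equilibration, so detailed balance holds by construction."""
    p_dep = float(model.analytic_deprot_fraction(frame.z, pH))
    state = DEPROTONATED if rng.random() < p_dep else PROTONATED
    return replace(frame, state=state)


class _Propagator:
    """Low-level scalar loop shared by run_segment and the campaign
    orchestrator.  Keeps (time-step-index, z, state) as plain floats and
    records frames into column lists; step indexing is global so the
    titration/record grids stay aligned across chunked advancement."""

    def __init__(
        self,
        frame: Frame,
        model: ToyModel,
        window: Optional[Window],
        schedule: Schedule,
        diffusion: float,
        rng: np.random.Generator,
    ) -> None:
        self.model = model
        self.window = window
        self.schedule = schedule
        self.diffusion = diffusion
        self.rng = rng
        self.z = float(frame.z)
        self.state = frame.state
        self.pH = float(frame.pH)
        self.replica_id = frame.replica_id
        self.replicate_index = frame.replicate_index
        self.step = int(round(frame.time / schedule.dt))
        self.n_titrations = 0
        self.records: dict[str, list] = {c: [] for c in RECORD_COLUMNS}
        self._record()

    @property
    def time(self) -> float:
        return self.step * self.schedule.dt

    @property
    def proton_count(self) -> int:
        return 1 if self.state == PROTONATED else 0

    def _record(self) -> None:
        r = self.records
        r["time"].append(self.time)
        r["replica_id"].append(self.replica_id)
        r["replicate_index"].append(self.replicate_index)
        r["pH"].append(self.pH)
        r["window_id"].append(self.window.window_id if self.window is not None else "")
        r["z_nm"].append(self.z)
        r["state"].append(self.state)
        r["bias_kJmol"].append(
            float(self.window.bias_energy(self.z)) if self.window is not None else 0.0
        )
        r["equilibration_flag"].append(self.time < self.schedule.equilibration_cutoff)

    def _resample(self) -> None:
        p_dep = float(self.model.analytic_deprot_fraction(self.z, self.pH))
        self.state = DEPROTONATED if self.rng.random() < p_dep else PROTONATED
        self.n_titrations += 1

    def advance(self, n_steps: int) -> None:
        sched = self.schedule
        dt, D, beta = sched.dt, self.diffusion, self.model.thermo.beta
        titr, rec = sched.titration_steps, sched.record_steps
        sqrt_noise = math.sqrt(2.0 * D * dt)
        model, window, rng = self.model, self.window, self.rng
        z = self.z
        for _ in range(n_steps):
            grad = float(model.potential_gradient(z, self.state))
            if window is not None:
                grad += window.k * (z - window.xi_ref)
            if not math.isfinite(grad):
                raise FloatingPointError(f"non-finite force at z={z}")
            z = z - beta * D * grad * dt + sqrt_noise * float(rng.standard_normal())
            self.step += 1
            self.z = z
            if self.step % titr == 0:
                self._resample()
                z = self.z  # unchanged, but keeps the local in sync
            if self.step % rec == 0:
                self._record()
        self.z = z

    def to_frame(self) -> Frame:
        return Frame(
            time=self.time,
            replica_id=self.replica_id,
            replicate_index=self.replicate_index,
            pH=self.pH,
            z=self.z,
            state=self.state,
            window_id=self.window.window_id if self.window is not None else None,
            bias_energy=float(self.window.bias_energy(self.z)) if self.window is not None else 0.0,
        )

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records)
        df["replicate_index"] = df["replicate_index"].astype(int)
        df["equilibration_flag"] = df["equilibration_flag"].astype(bool)
        return df


def run_segment(
    initial: Frame,
    model: ToyModel,
    window: Optional[Window],
    schedule: Schedule,
    rng: np.random.Generator,
    diffusion: float = 0.05,
) -> pd.DataFrame:
    """Run one stochastic-titration segment and return the recorded
    trajectory table (the initial frame is always row 0).

    Deterministic given (rng state, schedule, model): identical seeds
    give identical tables.
    """
    prop = _Propagator(initial, model, window, schedule, diffusion, rng)
    prop.advance(schedule.n_steps)
    return prop.table()
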