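"""Multi-replica campaign orchestration for the four sampling schemes.

Methods
-------
``cphmd``
    Independent constant-pH runs, one per (replicate, pH).
``phre``
    One replica per pH value; adjacent pH labels attempt Metropolis
    swaps every ``exchange_period`` starting at ``exchange_offset`` (to
    misalign from the titration attempts, which start at 0).
``us``
    Independent umbrella-restrained runs, one per
    (replicate, pH, window); the pH ladder optionally carries the two
    US-ext values on the ionized side.
``reus``
    One replica per umbrella window at each (replicate, pH); adjacent
    windows attempt bias-energy Metropolis swaps on the same cadence.
    Windows advance in lockstep between synchronized exchange barriers
    within one process.

Equilibration frames (time < ``equilibration_cutoff``) are flagged, not
deleted; the analysis layer owns the discard rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import CampaignConfig, config_hash
from .engine import DEPROTONATED, PROTONATED, Frame, _Propagator
from .exchange import LadderReplica, Window, exchange_sweep

EXCHANGE_LOG_COLUMNS = [
    "time",
    "replicate_index",
    "pH",
    "mode",
    "parity",
    "pair_lo",
    "pair_hi",
    "rung_lo",
    "rung_hi",
    "delta",
    "accepted",
    "uniform_draw",
]


@dataclass
class CampaignResult:
    records: pd.DataFrame
    exchange_log: pd.DataFrame
    manifest: dict


def _initial_state(model, z: float, pH: float, rng: np.random.Generator) -> str:
    """Titration attempts start at time 0: draw the initial state from
    the exact conditional at the starting position."""
    p_dep = float(model.analytic_deprot_fraction(z, pH))
    return DEPROTONATED if rng.random() < p_dep else PROTONATED


def _make_propagator(
    config: CampaignConfig,
    replicate_index: int,
    replica_id: str,
    pH: float,
    window: Optional[Window],
    rng: np.random.Generator,
) -> _Propagator:
    model = config.model
    if window is not None:
        z0 = window.xi_ref
    elif config.z_init is not None:
        z0 = config.z_init
    else:
        z0 = model.z_water_ref
    frame = Frame(
        time=0.0,
        replica_id=replica_id,
        replicate_index=replicate_index,
        pH=pH,
        z=z0,
        state=_initial_state(model, z0, pH, rng),
        window_id=window.window_id if window is not None else None,
        bias_energy=float(window.bias_energy(z0)) if window is not None else 0.0,
    )
    return _Propagator(frame, model, window, config.schedule, config.diffusion, rng)


def _exchange_boundaries(schedule) -> list[int]:
    """Global step indices at which exchange sweeps happen."""
    if schedule.exchange_period is None:
        return []
    per = schedule._steps(schedule.exchange_period)
    off = int(round(schedule.exchange_offset / schedule.dt))
    if abs(off * schedule.dt - schedule.exchange_offset) > 1e-9:
        raise ValueError("exchange_offset is not an integer multiple of dt")
    return [s for s in range(off if off > 0 else per, schedule.n_steps + 1, per)]


def _run_exchange_group(
    config: CampaignConfig,
    replicate_index: int,
    mode: str,
    props: list[_Propagator],
    exchange_rng: np.random.Generator,
    log_rows: list,
    group_ph: Optional[float],
) -> None:
    """Advance a ladder of replicas in lockstep with exchange barriers."""
    schedule = config.schedule
    props.sort(key=(lambda p: p.pH) if mode == "phre" else (lambda p: p.window.xi_ref))
    boundaries = _exchange_boundaries(schedule)
    if len(props) < 2 and boundaries:
        warnings.warn(
            f"{mode} ladder has a single rung; exchange scheduling disabled", stacklevel=2
        )
        boundaries = []
    current = 0
    parity_cycle = ("even", "odd")
    n_attempts = 0
    for boundary in boundaries:
        for p in props:
            p.advance(boundary - current)
        current = boundary
        parity = parity_cycle[n_attempts % 2]
        n_attempts += 1
        # ladder order: props are kept sorted along the ladder
        reps = [
            LadderReplica(
                replica_id=p.replica_id,
                z=p.z,
                proton_count=p.proton_count,
                pH=p.pH,
                window=p.window,
            )
            for p in props
        ]
        decisions = exchange_sweep(
            reps, parity, mode, exchange_rng, thermo=config.model.thermo,
            time=current * schedule.dt,
        )
        by_id = {p.replica_id: p for p in props}
        for r in reps:
            p = by_id[r.replica_id]
            if mode == "phre":
                p.pH = r.pH
            else:
                p.window = r.window
        props.sort(key=(lambda p: p.pH) if mode == "phre" else (lambda p: p.window.xi_ref))
        for d in decisions:
            log_rows.append(
                {
                    "time": d.time,
                    "replicate_index": replicate_index,
                    "pH": group_ph if group_ph is not None else np.nan,
                    "mode": mode,
                    "parity": parity,
                    "pair_lo": d.pair[0],
                    "pair_hi": d.pair[1],
                    "rung_lo": d.ladder_pair[0],
                    "rung_hi": d.ladder_pair[1],
                    "delta": d.delta,
                    "accepted": d.accepted,
                    "uniform_draw": d.uniform_draw,
                }
            )
    for p in props:
        p.advance(schedule.n_steps - current)


def run_campaign(config: CampaignConfig) -> CampaignResult:
    """Run the configured campaign; returns tagged record and exchange
    tables plus a run manifest.  Bit-reproducible from (config, seeds)."""
    tables: list[pd.DataFrame] = []
    log_rows: list[dict] = []
    titration_counts: dict[str, int] = {}
    ph_values = config.effective_ph_ladder

    for ridx, seed in enumerate(config.seeds, start=1):
        ss = np.random.SeedSequence(seed)
        if config.method == "cphmd":
            children = ss.spawn(len(ph_values))
            for pH, child in zip(ph_values, children):
                rng = np.random.default_rng(child)
                prop = _make_propagator(config, ridx, f"rep{ridx}-pH{pH:g}", pH, None, rng)
                prop.advance(config.schedule.n_steps)
                tables.append(prop.table())
                titration_counts[prop.replica_id] = prop.n_titrations
        elif config.method == "us":
            combos = [(pH, w) for pH in ph_values for w in config.windows]
            children = ss.spawn(len(combos))
            for (pH, window), child in zip(combos, children):
                rng = np.random.default_rng(child)
                prop = _make_propagator(
                    config, ridx, f"rep{ridx}-pH{pH:g}-{window.window_id}", pH, window, rng
                )
                prop.advance(config.schedule.n_steps)
                tables.append(prop.table())
                titration_counts[prop.replica_id] = prop.n_titrations
        elif config.method == "phre":
            children = ss.spawn(len(ph_values) + 1)
            exchange_rng = np.random.default_rng(children[-1])
            props = [
                _make_propagator(
                    config, ridx, f"rep{ridx}-cfg{i}", pH, None, np.random.default_rng(child)
                )
                for i, (pH, child) in enumerate(zip(ph_values, children[:-1]))
            ]
            _run_exchange_group(config, ridx, "phre", props, exchange_rng, log_rows, None)
            for p in props:
                tables.append(p.table())
                titration_counts[p.replica_id] = p.n_titrations
        elif config.method == "reus":
            for pj, pH in enumerate(ph_values):
                children = ss.spawn(len(config.windows) + 1)
                exchange_rng = np.random.default_rng(children[-1])
                ordered = sorted(config.windows, key=lambda w: w.xi_ref)
                props = [
                    _make_propagator(
                        config,
                        ridx,
                        f"rep{ridx}-pH{pH:g}-cfg{i}",
                        pH,
                        window,
                        np.random.default_rng(child),
                    )
                    for i, (window, child) in enumerate(zip(ordered, children[:-1]))
                ]
                _run_exchange_group(config, ridx, "reus", props, exchange_rng, log_rows, pH)
                for p in props:
                    tables.append(p.table())
                    titration_counts[p.replica_id] = p.n_titrations
        else:  # pragma: no cover - guarded by config validation
            raise ValueError(f"unknown method {config.method!r}")

    records = pd.concat(tables, ignore_index=True)
    exchange_log = pd.DataFrame(log_rows, columns=EXCHANGE_LOG_COLUMNS)
    manifest = {
        "package_version": __version__,
        "method": config.method,
        "replicates": config.replicates,
        "seeds": list(config.seeds),
        "ph_values": [float(p) for p in ph_values],
        "n_windows": len(config.windows) if config.windows else 0,
        "n_frames": int(len(records)),
        "n_exchange_attempts": int(len(exchange_log)),
        "titration_attempts": titration_counts,
        "config_hash": config_hash(config),
    }
    return CampaignResult(records=records, exchange_log=exchange_log, manifest=manifest)
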