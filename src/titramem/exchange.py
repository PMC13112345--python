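"""Umbrella windows, ladders, and the two replica-exchange kernels.

REUS swaps between adjacent umbrella windows use the Metropolis
criterion on the harmonic bias energies,

    Delta = beta * [V_m(xi_j) - V_m(xi_i) - V_n(xi_j) + V_n(xi_i)],

accepted with probability min(1, exp(-Delta)).  pH replica exchange
(pHRE) uses the standard discrete-protonation criterion

    Delta = ln(10) * (pH_i - pH_j) * (N_i - N_j),

with N the proton count of each replica (0 or 1 for a single site).
Exchanges swap ladder labels (pH values or window references) between
replicas rather than coordinates — equivalent and cheaper.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .units import ANGSTROM_PER_NM, LN10, ThermoContext


@dataclass(frozen=True)
class Window:
    """A harmonic umbrella V(xi) = (k/2)(xi - xi_ref)^2.

    xi_ref in nm, k in kJ mol^-1 nm^-2.
    """

    window_id: str
    xi_ref: float
    k: float

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"window force constant must be > 0, got {self.k}")

    def bias_energy(self, xi):
        return 0.5 * self.k * (np.asarray(xi, dtype=float) - self.xi_ref) ** 2

    def bias_gradient(self, xi):
        """dV/dxi; the restoring force is the negative of this."""
        return self.k * (np.asarray(xi, dtype=float) - self.xi_ref)


@dataclass(frozen=True)
class ExchangeDecision:
    pair: tuple[str, str]  # replica ids
    delta: float
    accepted: bool
    uniform_draw: float
    time: float | None = None
    ladder_pair: tuple = ("", "")  # ladder rung labels (window ids or pH values)

    def __post_init__(self) -> None:
        expected = (self.delta <= 0.0) or (self.uniform_draw < math.exp(-self.delta))
        if self.accepted != expected:
            raise ValueError("inconsistent ExchangeDecision: accepted flag does not match draw")


def harmonic_bias(xi, window: Window):
    """Umbrella bias energy (k/2)(xi - xi_ref)^2 in kJ/mol."""
    return window.bias_energy(xi)


def harmonic_force(xi, window: Window):
    """Restoring force -k(xi - xi_ref) in kJ mol^-1 nm^-1."""
    return -window.bias_gradient(xi)


def reus_delta(
    xi_i: float, xi_j: float, win_m: Window, win_n: Window, thermo: ThermoContext
) -> float:
    """Metropolis exponent for swapping configurations i (in window m)
    and j (in window n); antisymmetric under (i,m) <-> (j,n)."""
    vm_i = win_m.bias_energy(xi_i)
    vm_j = win_m.bias_energy(xi_j)
    vn_i = win_n.bias_energy(xi_i)
    vn_j = win_n.bias_energy(xi_j)
    return thermo.beta * (vm_j - vm_i - vn_j + vn_i)


def phre_delta(n_i: int, n_j: int, ph_i: float, ph_j: float) -> float:
    """Metropolis exponent for swapping the pH labels of two replicas
    with proton counts N_i, N_j:

        Delta = ln(10) * (pH_i - pH_j) * (N_j - N_i).

    Derivation: the semi-grand weight of proton count N at pH is
    proportional to 10^(N (pKa - pH)), so the swap's stationary-ratio
    exponent is ln10 (pH_i - pH_j)(N_j - N_i); min(1, e^-Delta) then
    satisfies detailed balance exactly (asserted by an enumeration test).
    Moving the protonated configuration to the lower-pH rung gives
    Delta < 0 (always accepted)."""
    return LN10 * (ph_i - ph_j) * (n_j - n_i)


def metropolis_accept(
    delta: float,
    rng: np.random.Generator,
    pair: tuple[str, str] = ("i", "j"),
    time: float | None = None,
    ladder_pair: tuple = ("", ""),
) -> ExchangeDecision:
    """Accept with probability min(1, exp(-delta)); the uniform draw is
    recorded even for the always-accept branch so decisions replay."""
    u = float(rng.random())
    accepted = (delta <= 0.0) or (u < math.exp(-delta))
    return ExchangeDecision(
        pair=pair, delta=float(delta), accepted=accepted, uniform_draw=u,
        time=time, ladder_pair=ladder_pair,
    )


@dataclass
class LadderReplica:
    """Mutable per-replica exchange state: current configuration plus the
    ladder label (pH or window) it currently holds."""

    replica_id: str
    z: float  # nm
    proton_count: int  # 0 or 1
    pH: float | None = None
    window: Window | None = None


def exchange_sweep(
    replicas: Sequence[LadderReplica],
    parity: str,
    mode: str,
    rng: np.random.Generator,
    thermo: ThermoContext | None = None,
    time: float | None = None,
) -> list[ExchangeDecision]:
    """Attempt swaps on disjoint adjacent pairs of the given parity.

    ``replicas`` must be ordered along the ladder (ascending pH for
    pHRE, ascending xi_ref for REUS).  On acceptance the ladder labels
    (pH values or window references) are swapped in place, so the list
    order remains the ladder order.
    """
    if parity not in ("even", "odd"):
        raise ValueError(f"parity must be 'even' or 'odd', got {parity!r}")
    if mode not in ("phre", "reus"):
        raise ValueError(f"mode must be 'phre' or 'reus', got {mode!r}")
    n = len(replicas)
    if n < 2:
        return []
    decisions: list[ExchangeDecision] = []
    start = 0 if parity == "even" else 1
    for i in range(start, n - 1, 2):
        a, b = replicas[i], replicas[i + 1]
        if mode == "phre":
            delta = phre_delta(a.proton_count, b.proton_count, a.pH, b.pH)
            ladder_pair = (f"{a.pH:g}", f"{b.pH:g}")
        else:
            if thermo is None:
                raise ValueError("REUS sweep requires a ThermoContext")
            delta = reus_delta(a.z, b.z, a.window, b.window, thermo)
            ladder_pair = (a.window.window_id, b.window.window_id)
        decision = metropolis_accept(
            delta, rng, pair=(a.replica_id, b.replica_id), time=time, ladder_pair=ladder_pair
        )
        if decision.accepted:
            if mode == "phre":
                a.pH, b.pH = b.pH, a.pH
            else:
                a.window, b.window = b.window, a.window
            # keep ladder order: swap list slots so index == ladder rung
            replicas[i], replicas[i + 1] = b, a  # type: ignore[index]
        decisions.append(decision)
    return decisions


KRule = Callable[[float], float]


def constant_k_rule(k: float) -> KRule:
    return lambda xi_A: k


def piecewise_k_rule(segments: Sequence[tuple[float, float, float]]) -> KRule:
    """k_rule from (lo_A, hi_A, k) segments, inclusive bounds in Angstrom."""

    def rule(xi_A: float) -> float:
        for lo, hi, k in segments:
            if min(lo, hi) - 1e-9 <= xi_A <= max(lo, hi) + 1e-9:
                return k
        raise ValueError(f"no k_rule segment covers window reference {xi_A} A")

    return rule


#: Dual-force REUS ladder: weaker umbrellas (500 kJ mol^-1 nm^-2) in the
#: homogeneous water region +20..+8 A, stronger (1000) from +6 A inward.
DUAL_FORCE_RULE = piecewise_k_rule([(8.0, 20.0, 500.0), (-12.0, 6.0, 1000.0)])


def build_window_ladder(start_A: float, stop_A: float, spacing_A: float, k_rule: KRule) -> list[Window]:
    """Inclusive umbrella ladder from start to stop (Angstrom) at the
    given spacing; windows are returned ordered from start to stop with
    xi_ref stored in nm."""
    if not (spacing_A > 0):
        raise ValueError("spacing must be > 0")
    if start_A == stop_A:
        raise ValueError("start and stop must differ")
    span = abs(start_A - stop_A)
    n_intervals = span / spacing_A
    if abs(n_intervals - round(n_intervals)) > 1e-9:
        raise ValueError(
            f"spacing {spacing_A} A does not divide the range [{start_A}, {stop_A}] A exactly"
        )
    n = int(round(n_intervals)) + 1
    sign = 1.0 if stop_A > start_A else -1.0
    windows = []
    for i in range(n):
        xi_A = start_A + sign * i * spacing_A
        windows.append(
            Window(window_id=f"w{xi_A:+g}", xi_ref=xi_A / ANGSTROM_PER_NM, k=float(k_rule(xi_A)))
        )
    return windows


def extend_ph_ladder(ladder: Sequence[float], residue_class: str) -> list[float]:
    """Append the two extra pH values that improve ionized-species
    sampling: continuing the ladder spacing on the high-pH side for
    anionic (acid) residues, on the low-pH side for cationic (base)
    residues."""
    values = sorted(float(p) for p in ladder)
    if len(values) < 2:
        raise ValueError("pH ladder must have at least 2 values to define a spacing")
    diffs = np.diff(values)
    if not np.allclose(diffs, diffs[0]):
        raise ValueError(f"pH ladder is not uniformly spaced: {values}")
    step = float(diffs[0])
    if residue_class == "acid":
        return values + [values[-1] + step, values[-1] + 2 * step]
    if residue_class == "base":
        return [values[0] - 2 * step, values[0] - step] + values
    raise ValueError(f"residue_class must be 'acid' or 'base', got {residue_class!r}")


def acceptance_summary(decisions: Sequence[ExchangeDecision]):
    """Per-pair attempt counts and acceptance ratios as a DataFrame."""
    import pandas as pd

    rows: dict[tuple[str, str], list[int]] = {}
    for d in decisions:
        key = tuple(sorted(d.pair))
        rows.setdefault(key, [0, 0])
        rows[key][0] += 1
        rows[key][1] += int(d.accepted)
    return pd.DataFrame(
        [
            {"pair": f"{a}|{b}", "attempts": att, "accepted": acc, "ratio": acc / att}
            for (a, b), (att, acc) in sorted(rows.items())
        ]
    )
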