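"""The titratable-particle membrane surrogate.

A single titratable site moves along the membrane normal ``z`` (nm,
water side positive) under a protonation-state-dependent potential
``U_s(z)``, while its protonation state is governed by a
Henderson-Hasselbalch equilibrium whose position-dependent pKa follows
from the difference of the two state potentials:

    pKa(z) = pKa_w + beta * [U_deprot(z) - U_prot(z)] / ln(10)

Both potentials vanish at a water reference position ``z_water_ref``,
so the aqueous pKa equals the configured reference value ``pKa_w``.
Because the model is one-dimensional and analytic, every downstream
estimator (WHAM PMFs, ionized-population profiles, pKa profiles) has a
closed-form ground truth to be checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .units import LN10, ThermoContext

PROTONATED = "prot"
DEPROTONATED = "deprot"
STATES = (PROTONATED, DEPROTONATED)

ACID = "acid"
BASE = "base"


@dataclass(frozen=True)
class PotentialTerm:
    """One analytic term of a state potential, in z (nm).

    Shapes
    ------
    ``gaussian``
        amplitude * exp(-(z - center)^2 / (2 width^2)) — interface wells
        or localized barriers.
    ``sigmoid-step``
        amplitude / (1 + exp((z - center) / width)) — a smooth step with
        plateau ``amplitude`` on the membrane-interior (low-z) side and 0
        on the water side.  A negative amplitude, after the water
        reference subtraction, acts as a wall on the high-z side.
    """

    shape: str
    amplitude: float  # kJ/mol
    center: float  # nm
    width: float  # nm

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "sigmoid-step"):
            raise ValueError(f"unknown potential term shape {self.shape!r}")
        if not (self.width > 0):
            raise ValueError(f"term width must be > 0, got {self.width}")

    def energy(self, z):
        z = np.asarray(z, dtype=float)
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-((z - self.center) ** 2) / (2.0 * self.width**2))
        u = (z - self.center) / self.width
        return self.amplitude / (1.0 + np.exp(u))

    def gradient(self, z):
        """dU/dz of this term (kJ mol^-1 nm^-1)."""
        z = np.asarray(z, dtype=float)
        if self.shape == "gaussian":
            return -self.amplitude * (z - self.center) / self.width**2 * np.exp(
                -((z - self.center) ** 2) / (2.0 * self.width**2)
            )
        u = (z - self.center) / self.width
        s = 1.0 / (1.0 + np.exp(u))
        return -self.amplitude * s * (1.0 - s) / self.width


@dataclass(frozen=True)
class ToyModel:
    """State-dependent 1-D potentials plus an aqueous reference pKa.

    Parameters
    ----------
    residue_class : {"acid", "base"}
        For an acid the ionized state is the deprotonated one; for a
        base it is the protonated one.  This single mapping is used
        everywhere downstream.
    pKa_w : float
        Aqueous reference pKa (the value at ``z_water_ref``).
    temperature : float
        K; default 300.
    potential_terms : mapping state -> sequence of PotentialTerm
        Terms are summed; the value of the sum at ``z_water_ref`` is
        subtracted so that U_s(z_water_ref) = 0 for both states.
    z_water_ref : float
        nm; position in the water phase where both potentials vanish.
    """

    residue_class: str
    pKa_w: float
    temperature: float = 300.0
    potential_terms: Mapping[str, Sequence[PotentialTerm]] = field(
        default_factory=lambda: {PROTONATED: (), DEPROTONATED: ()}
    )
    z_water_ref: float = 2.0

    def __post_init__(self) -> None:
        if self.residue_class not in (ACID, BASE):
            raise ValueError(f"residue_class must be 'acid' or 'base', got {self.residue_class!r}")
        if not (self.temperature > 0):
            raise ValueError("temperature must be > 0")
        for s in STATES:
            if s not in self.potential_terms:
                raise ValueError(f"potential_terms missing state {s!r}")

    @property
    def thermo(self) -> ThermoContext:
        return ThermoContext(self.temperature)

    @property
    def ionized_state(self) -> str:
        return DEPROTONATED if self.residue_class == ACID else PROTONATED

    @property
    def neutral_state(self) -> str:
        return PROTONATED if self.residue_class == ACID else DEPROTONATED

    # -- state potentials ------------------------------------------------

    def _raw_energy(self, z, state: str):
        terms = self.potential_terms[state]
        if not terms:
            return np.zeros_like(np.asarray(z, dtype=float))
        return sum(t.energy(z) for t in terms)

    def potential_energy(self, z, state: str):
        """U_state(z) in kJ/mol, zero at ``z_water_ref`` by construction."""
        if state not in STATES:
            raise ValueError(f"unknown protonation state {state!r}; expected one of {STATES}")
        return self._raw_energy(z, state) - self._raw_energy(self.z_water_ref, state)

    def potential_gradient(self, z, state: str):
        """dU_state/dz in kJ mol^-1 nm^-1 (force is the negative of this)."""
        if state not in STATES:
            raise ValueError(f"unknown protonation state {state!r}; expected one of {STATES}")
        terms = self.potential_terms[state]
        if not terms:
            return np.zeros_like(np.asarray(z, dtype=float))
        return sum(t.gradient(z) for t in terms)

    # -- analytic ground truth -------------------------------------------

    def analytic_pka(self, z):
        """pKa(z) = pKa_w + beta*[U_deprot(z) - U_prot(z)]/ln(10)."""
        du = self.potential_energy(z, DEPROTONATED) - self.potential_energy(z, PROTONATED)
        return self.pKa_w + self.thermo.beta * du / LN10

    def analytic_deprot_fraction(self, z, pH):
        """Henderson-Hasselbalch deprotonated fraction at (z, pH)."""
        return 1.0 / (1.0 + 10.0 ** (self.analytic_pka(z) - pH))

    def analytic_ionized_fraction(self, z, pH):
        f_dep = self.analytic_deprot_fraction(z, pH)
        return f_dep if self.residue_class == ACID else 1.0 - f_dep

    def _log_state_weights(self, z, pH):
        """Unnormalized log weights of both states on a z array.

        Semi-grand-canonical weights: the deprotonated/protonated weight
        ratio in water is 10^(pH - pKa_w); the state potentials shift it
        with position.  Returns (log_w_prot, log_w_deprot).
        """
        beta = self.thermo.beta
        lw_prot = -beta * np.asarray(self.potential_energy(z, PROTONATED), dtype=float)
        lw_dep = -beta * np.asarray(self.potential_energy(z, DEPROTONATED), dtype=float) + LN10 * (
            pH - self.pKa_w
        )
        return lw_prot, lw_dep

    def effective_potential(self, z, pH):
        """pH-dependent free-energy landscape -kT ln sum_s w_s(z), kJ/mol.

        Defined up to a constant; anchored to 0 at ``z_water_ref``.
        This is the analytic PMF oracle for WHAM.
        """
        lw_prot, lw_dep = self._log_state_weights(z, pH)
        g = -self.thermo.kT * np.logaddexp(lw_prot, lw_dep)
        lw0_p, lw0_d = self._log_state_weights(self.z_water_ref, pH)
        g0 = -self.thermo.kT * np.logaddexp(lw0_p, lw0_d)
        return g - g0

    def analytic_density(self, pH, grid):
        """Normalized position density on ``grid``, marginalized over state."""
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("grid must not be empty")
        lw_prot, lw_dep = self._log_state_weights(grid, pH)
        logp = np.logaddexp(lw_prot, lw_dep)
        logp -= logsumexp(logp)
        return np.exp(logp)

    def analytic_biased_density(self, pH, grid, window) -> np.ndarray:
        """Normalized density under an umbrella bias V(z) on ``grid``."""
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("grid must not be empty")
        lw_prot, lw_dep = self._log_state_weights(grid, pH)
        logp = np.logaddexp(lw_prot, lw_dep) - self.thermo.beta * window.bias_energy(grid)
        logp -= logsumexp(logp)
        return np.exp(logp)


# -- module-level operation aliases (thin functional surface) -------------


def potential_energy(z, state: str, model: ToyModel):
    return model.potential_energy(z, state)


def analytic_pka(z, model: ToyModel):
    return model.analytic_pka(z)


def analytic_deprot_fraction(z, pH, model: ToyModel):
    return model.analytic_deprot_fraction(z, pH)


def analytic_density(pH, model: ToyModel, grid):
    return model.analytic_density(pH, grid)


# -- shipped example models ------------------------------------------------


def _confining_walls(z_low: float = -1.2, z_high: float = 2.3) -> tuple[PotentialTerm, ...]:
    """Steep walls keeping the particle in [z_low, z_high] (shared by both states)."""
    return (
        PotentialTerm("sigmoid-step", 50.0, z_low, 0.1),
        PotentialTerm("sigmoid-step", -50.0, z_high, 0.1),
    )


def asp_like(pKa_w: float = 3.94, temperature: float = 300.0) -> ToyModel:
    """Aspartate-like acid: the ionized (deprotonated) form is penalized
    inside the membrane; the neutral form has a mild interface well."""
    walls = _confining_walls()
    return ToyModel(
        residue_class=ACID,
        pKa_w=pKa_w,
        temperature=temperature,
        potential_terms={
            PROTONATED: walls + (PotentialTerm("gaussian", -4.0, 0.3, 0.3),),
            DEPROTONATED: walls + (PotentialTerm("sigmoid-step", 20.0, 0.5, 0.25),),
        },
    )


def his_like(pKa_w: float = 6.54, temperature: float = 300.0) -> ToyModel:
    """Histidine-like base: the ionized (protonated) form is penalized
    inside the membrane, shifting pKa(z) downward on insertion."""
    walls = _confining_walls()
    return ToyModel(
        residue_class=BASE,
        pKa_w=pKa_w,
        temperature=temperature,
        potential_terms={
            PROTONATED: walls + (PotentialTerm("sigmoid-step", 20.0, 0.5, 0.25),),
            DEPROTONATED: walls + (PotentialTerm("gaussian", -4.0, 0.3, 0.3),),
        },
    )


def flat_model(
    residue_class: str = ACID, pKa_w: float = 4.0, temperature: float = 300.0, confined: bool = True
) -> ToyModel:
    """z-independent titration: pKa(z) = pKa_w everywhere.

    With ``confined`` the shared walls keep unbiased dynamics bounded;
    they cancel exactly in pKa(z).
    """
    walls = _confining_walls() if confined else ()
    return ToyModel(
        residue_class=residue_class,
        pKa_w=pKa_w,
        temperature=temperature,
        potential_terms={PROTONATED: walls, DEPROTONATED: walls},
    )


def double_well(
    residue_class: str = ACID,
    pKa_w: float = 4.0,
    temperature: float = 300.0,
    barrier: float = 10.0,
) -> ToyModel:
    """Symmetric-ish double well along z shared by both states, plus an
    ionized-state membrane penalty.  The WHAM oracle model: its analytic
    PMF has two minima separated by a ``barrier`` kJ/mol gaussian hump."""
    walls = _confining_walls()
    shared = walls + (
        PotentialTerm("gaussian", barrier, 0.4, 0.25),
        PotentialTerm("gaussian", -5.0, -0.4, 0.3),
    )
    ionized_extra = (PotentialTerm("sigmoid-step", 15.0, 0.3, 0.3),)
    prot = shared + (ionized_extra if residue_class == BASE else ())
    deprot = shared + (ionized_extra if residue_class == ACID else ())
    return ToyModel(
        residue_class=residue_class,
        pKa_w=pKa_w,
        temperature=temperature,
        potential_terms={PROTONATED: prot, DEPROTONATED: deprot},
    )


def model_from_dict(mapping: Mapping) -> ToyModel:
    """Build a ToyModel from a declarative config mapping."""
    allowed = {"residue_class", "pka_w", "temperature", "z_water_ref", "terms", "shared_terms"}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown model keys: {sorted(unknown)}")
    for key in ("residue_class", "pka_w"):
        if key not in mapping:
            raise ValueError(f"model block missing required key {key!r}")

    def parse_terms(items: Iterable[Mapping]) -> tuple[PotentialTerm, ...]:
        out = []
        for item in items:
            extra = set(item) - {"shape", "amplitude", "center", "width"}
            if extra:
                raise ValueError(f"unknown potential term keys: {sorted(extra)}")
            out.append(
                PotentialTerm(
                    shape=item["shape"],
                    amplitude=float(item["amplitude"]),
                    center=float(item["center"]),
                    width=float(item["width"]),
                )
            )
        return tuple(out)

    shared = parse_terms(mapping.get("shared_terms", ()))
    state_terms = mapping.get("terms", {})
    unknown_states = set(state_terms) - {"protonated", "deprotonated"}
    if unknown_states:
        raise ValueError(f"unknown states in model terms: {sorted(unknown_states)}")
    return ToyModel(
        residue_class=mapping["residue_class"],
        pKa_w=float(mapping["pka_w"]),
        temperature=float(mapping.get("temperature", 300.0)),
        potential_terms={
            PROTONATED: shared + parse_terms(state_terms.get("protonated", ())),
            DEPROTONATED: shared + parse_terms(state_terms.get("deprotonated", ())),
        },
        z_water_ref=float(mapping.get("z_water_ref", 2.0)),
    )
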