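"""Ionized-population and pKa profiles along the insertion coordinate.

The pKa profile scans the insertion range (default -12..22 A) with a
1 A sliding bin advanced in 0.25 A steps.  For each bin, frames are
pooled across replicates and pH values, the protonation state is
averaged per pH, and the averages are fitted to a single-site
Henderson-Hasselbalch curve

    <protonated>(pH) = 1 / (1 + 10^(pH - pKa)),

with the Hill slope fixed at 1.  Fitting only happens when the bin
passes the sampling gates: at least 50 frames in *each* protonation
state, each state observed at >= 2 pH values and >= 2 replicates, and
per-pH mean protonation non-increasing with pH (within a small slack).
Errors come from a Bayesian bootstrap: 1000 flat-Dirichlet reweightings
of the frames within each pH group, refitting the curve each time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .model import ACID, BASE, PROTONATED, ToyModel
from .units import ANGSTROM_PER_NM

GATE_FITTED = "fitted"
GATE_POINTS = "insufficient-points"
GATE_PH = "insufficient-pH"
GATE_REPLICAS = "insufficient-replicas"
GATE_MONOTONIC = "non-monotonic"

PROFILE_COLUMNS = [
    "bin_left",
    "bin_center",
    "status",
    "pka",
    "boot_err",
    "n_ionized",
    "n_neutral",
    "n_ph",
    "n_replicas",
]


def hh_protonated_fraction(pH, pka):
    """Henderson-Hasselbalch protonated fraction."""
    return 1.0 / (1.0 + 10.0 ** (np.asarray(pH, dtype=float) - pka))


# -- ionized-population profile --------------------------------------------


@dataclass(frozen=True)
class IonizedProfile:
    """Ionized counts/fractions on a fixed insertion grid (default 0.2 A
    bins from -15 to 25 A, half-open [lo, hi))."""

    bin_edges: np.ndarray  # Angstrom
    ionized: np.ndarray  # per-bin (possibly weighted) ionized counts
    total: np.ndarray  # per-bin total counts

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def fraction(self) -> np.ndarray:
        """Per-bin ionized fraction (NaN where the bin is empty)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.ionized / self.total, np.nan)

    @property
    def density(self) -> np.ndarray:
        """Ionized counts normalized to a density over the grid — the
        alternative reading of a 'probability of the ionized species'."""
        s = self.ionized.sum()
        return self.ionized / s if s > 0 else np.zeros_like(self.ionized)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "insertion_A": self.centers,
                "ionized": self.ionized,
                "total": self.total,
                "fraction": self.fraction,
                "density": self.density,
            }
        )


def _insertion_column(records: pd.DataFrame) -> np.ndarray:
    """Insertion coordinate in Angstrom: an explicit ``insertion_A``
    column when geometry results were attached, else the reaction
    coordinate z itself (the surrogate has no lipids to deform)."""
    if "insertion_A" in records.columns:
        return records["insertion_A"].to_numpy(dtype=float)
    return records["z_nm"].to_numpy(dtype=float) * ANGSTROM_PER_NM


def _ionized_mask(records: pd.DataFrame, residue_class: str) -> np.ndarray:
    prot = records["state"].to_numpy() == PROTONATED
    if residue_class == ACID:
        return ~prot
    if residue_class == BASE:
        return prot
    raise ValueError(f"residue_class must be 'acid' or 'base', got {residue_class!r}")


def ionized_population_profile(
    records: pd.DataFrame,
    residue_class: str,
    weights: Optional[np.ndarray] = None,
    lo: float = -15.0,
    hi: float = 25.0,
    bin_width: float = 0.2,
) -> IonizedProfile:
    """Count ionized configurations per insertion bin across all
    replicates and pH values (optionally frame-weighted); equilibration
    frames are excluded."""
    keep = ~records["equilibration_flag"].to_numpy(dtype=bool)
    x = _insertion_column(records)[keep]
    ionized = _ionized_mask(records, residue_class)[keep]
    w = np.ones(keep.sum()) if weights is None else np.asarray(weights, dtype=float)[keep]
    n_bins = int(round((hi - lo) / bin_width))
    # edges as width * integers where possible, so round values land on
    # exact bin boundaries and the [lo, hi) convention is unambiguous
    i0 = lo / bin_width
    if abs(i0 - round(i0)) < 1e-9:
        edges = bin_width * (np.arange(n_bins + 1) + round(i0))
    else:
        edges = lo + bin_width * np.arange(n_bins + 1)
    in_range = (x >= edges[0]) & (x < edges[-1])
    if not np.any(in_range):
        warnings.warn("no frames in the ionized-population range; profile is all zero",
                      stacklevel=2)
    idx = np.clip(np.searchsorted(edges, x[in_range], side="right") - 1, 0, n_bins - 1)
    total = np.bincount(idx, weights=w[in_range], minlength=n_bins)
    ion = np.bincount(idx, weights=(w[in_range] * ionized[in_range]), minlength=n_bins)
    return IonizedProfile(bin_edges=edges, ionized=ion, total=total)


# -- Henderson-Hasselbalch fit ---------------------------------------------


@dataclass(frozen=True)
class HHFitResults:
    pka: float
    sse: float
    n_obs: int
    pH: np.ndarray
    mean_protonation: np.ndarray

    def summary(self) -> str:
        lines = [
            "Henderson-Hasselbalch fit (Hill slope fixed at 1)",
            f"pKa = {self.pka:.4f}   SSE = {self.sse:.3e}   n = {self.n_obs}",
            "pH      observed  fitted",
        ]
        for p, m in zip(self.pH, self.mean_protonation):
            lines.append(f"{p:<7g} {m:<9.4f} {float(hh_protonated_fraction(p, self.pka)):.4f}")
        return "\n".join(lines)


class HendersonHasselbalch:
    """Single-parameter titration-curve model for per-pH mean
    protonations; optional per-pH counts act as least-squares weights."""

    def __init__(
        self,
        pH: Sequence[float],
        mean_protonation: Sequence[float],
        counts: Optional[Sequence[float]] = None,
    ) -> None:
        self.pH = np.asarray(pH, dtype=float)
        self.y = np.asarray(mean_protonation, dtype=float)
        self.w = None if counts is None else np.asarray(counts, dtype=float)
        if self.pH.shape != self.y.shape:
            raise ValueError("pH and mean_protonation must have the same length")
        if not np.all(np.isfinite(self.pH)) or not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite values in titration data")
        if len(np.unique(self.pH)) < 2:
            raise ValueError("need >= 2 distinct pH values to fit a titration curve")
        if np.all(self.y <= 0.0) or np.all(self.y >= 1.0):
            raise ValueError("titration data is flat (all 0 or all 1); pKa is unidentifiable")

    def _sse(self, pka: float) -> float:
        r = self.y - hh_protonated_fraction(self.pH, pka)
        if self.w is not None:
            return float(np.sum(self.w * r**2))
        return float(np.sum(r**2))

    def fit(self) -> HHFitResults:
        lo = float(self.pH.min()) - 12.0
        hi = float(self.pH.max()) + 12.0
        res = minimize_scalar(self._sse, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-9})
        return HHFitResults(
            pka=float(res.x),
            sse=float(res.fun),
            n_obs=len(self.pH),
            pH=self.pH,
            mean_protonation=self.y,
        )


def hh_fit(
    pH: Sequence[float],
    mean_protonation: Sequence[float],
    counts: Optional[Sequence[float]] = None,
) -> float:
    """Least-squares pKa of the Henderson-Hasselbalch curve (Hill slope
    1); deterministic given its inputs."""
    return HendersonHasselbalch(pH, mean_protonation, counts).fit().pka


# -- Bayesian bootstrap -----------------------------------------------------


def _vectorized_hh_fit(y: np.ndarray, ph: np.ndarray, center: float, half_span: float = 4.0,
                       step: float = 0.01) -> np.ndarray:
    """Fit many titration curves at once: grid scan around ``center``
    with parabolic refinement.  y: (B, P) per-pH means."""
    grid = center + np.arange(-half_span, half_span + step, step)
    f = hh_protonated_fraction(ph[None, :], grid[:, None])  # (G, P)
    # SSE(b, g) = |y_b|^2 - 2 y_b . f_g + |f_g|^2
    sse = (y**2).sum(axis=1)[:, None] - 2.0 * y @ f.T + (f**2).sum(axis=1)[None, :]
    best = np.argmin(sse, axis=1)
    pka = grid[best].astype(float)
    interior = (best > 0) & (best < len(grid) - 1)
    b = np.where(interior)[0]
    if b.size:
        s0 = sse[b, best[b] - 1]
        s1 = sse[b, best[b]]
        s2 = sse[b, best[b] + 1]
        denom = s0 - 2 * s1 + s2
        ok = denom > 0
        shift = np.zeros_like(s1)
        shift[ok] = 0.5 * (s0[ok] - s2[ok]) / denom[ok]
        pka[b] += np.clip(shift, -1.0, 1.0) * step
    pka[~interior] = np.nan  # grid-boundary hits are failed refits
    return pka


@dataclass(frozen=True)
class BootstrapResult:
    error: float
    n_boot: int
    n_failed: int
    degenerate: bool  # fewer than 2 usable bootstrap estimates

    @property
    def failed_fraction(self) -> float:
        return self.n_failed / self.n_boot if self.n_boot else 0.0


def bayesian_bootstrap_pka(
    frames_by_ph: Mapping[float, np.ndarray],
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
    center: Optional[float] = None,
) -> BootstrapResult:
    """Bayesian-bootstrap error of the fitted pKa.

    ``frames_by_ph`` maps each pH to the 0/1 protonation indicators of
    its frames.  Per bootstrap, flat-Dirichlet weights are drawn over
    the frames within each pH group, the weighted per-pH means are
    refitted, and the error is the standard deviation of the bootstrap
    pKa distribution.  Refit failures (grid-boundary hits or flat
    resamples) are counted, not silently dropped into the estimate.
    """
    rng = np.random.default_rng() if rng is None else rng
    phs = np.array(sorted(frames_by_ph))
    means = np.empty((n_boot, len(phs)))
    for j, p in enumerate(phs):
        s = np.asarray(frames_by_ph[p], dtype=float)
        g = rng.standard_gamma(1.0, size=(n_boot, len(s)))
        means[:, j] = (g * s[None, :]).sum(axis=1) / g.sum(axis=1)
    if center is None:
        center = hh_fit(phs, means.mean(axis=0))
    flat = np.all(means <= 0.0, axis=1) | np.all(means >= 1.0, axis=1)
    pka = np.full(n_boot, np.nan)
    if np.any(~flat):
        pka[~flat] = _vectorized_hh_fit(means[~flat], phs, center)
    valid = np.isfinite(pka)
    n_failed = int(n_boot - valid.sum())
    if valid.sum() < 2:
        return BootstrapResult(error=0.0, n_boot=n_boot, n_failed=n_failed, degenerate=True)
    return BootstrapResult(
        error=float(np.std(pka[valid], ddof=1)),
        n_boot=n_boot,
        n_failed=n_failed,
        degenerate=n_boot < 2,
    )


# -- sliding-bin pKa profile -----------------------------------------------


@dataclass
class PKaProfileResults:
    """Per-bin pKa estimates, bootstrap errors and gate statuses."""

    table: pd.DataFrame
    residue_class: str
    n_boot: int

    @property
    def fitted(self) -> pd.DataFrame:
        return self.table[self.table["status"] == GATE_FITTED]

    def summary(self) -> str:
        counts = self.table["status"].value_counts()
        lines = [
            "pKa profile",
            "===========",
            f"bins scanned:  {len(self.table)}",
        ]
        for status in (GATE_FITTED, GATE_POINTS, GATE_PH, GATE_REPLICAS, GATE_MONOTONIC):
            lines.append(f"{status:>22}: {int(counts.get(status, 0))}")
        fit = self.fitted
        if len(fit):
            lines.append(
                f"pKa range: {fit['pka'].min():.2f} .. {fit['pka'].max():.2f} "
                f"(median bootstrap error {fit['boot_err'].median():.3f})"
            )
        return "\n".join(lines)

    def plot(self, ax=None, model: Optional[ToyModel] = None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fit = self.fitted
        ax.errorbar(fit["bin_center"], fit["pka"], yerr=fit["boot_err"], fmt=".", **kwargs)
        if model is not None:
            grid = np.linspace(self.table["bin_center"].min(), self.table["bin_center"].max(), 200)
            ax.plot(grid, model.analytic_pka(grid / ANGSTROM_PER_NM), "k--", lw=1,
                    label="analytic")
        ax.set_xlabel("insertion (Å)")
        ax.set_ylabel("pKa")
        return ax


class PKaProfiler:
    """Sliding-bin pKa profiling model over a campaign record table.

    Bins are left-edge anchored, half-open [lo, lo + bin_width), advanced
    by ``stride``; with the defaults the left edges run -12.00, -11.75,
    ..., 21.00 A.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        residue_class: str,
        scan_lo: float = -12.0,
        scan_hi: float = 22.0,
        bin_width: float = 1.0,
        stride: float = 0.25,
        min_points: int = 50,
        min_ph: int = 2,
        min_replicas: int = 2,
        mono_slack: float = 0.02,
        n_boot: int = 1000,
    ) -> None:
        if residue_class not in (ACID, BASE):
            raise ValueError(f"residue_class must be 'acid' or 'base', got {residue_class!r}")
        self.records = records
        self.residue_class = residue_class
        self.scan_lo = scan_lo
        self.scan_hi = scan_hi
        self.bin_width = bin_width
        self.stride = stride
        self.min_points = min_points
        self.min_ph = min_ph
        self.min_replicas = min_replicas
        self.mono_slack = mono_slack
        self.n_boot = n_boot

    def bin_left_edges(self) -> np.ndarray:
        n = int(np.floor((self.scan_hi - self.bin_width - self.scan_lo) / self.stride + 1e-9)) + 1
        return self.scan_lo + self.stride * np.arange(n)

    def _gate_and_fit(self, x, prot, ph, rep, lo, rng) -> dict:
        """Gate one bin [lo, lo+width) and fit it if admissible.

        Gate order: point counts, pH coverage, replica coverage,
        monotonicity.  Row order of the records never matters: all
        reductions are permutation-invariant (counts, set cardinalities,
        per-pH means)."""
        row = {
            "bin_left": lo,
            "bin_center": lo + self.bin_width / 2.0,
            "status": None,
            "pka": np.nan,
            "boot_err": np.nan,
            "n_ionized": 0,
            "n_neutral": 0,
            "n_ph": 0,
            "n_replicas": 0,
        }
        sel = (x >= lo) & (x < lo + self.bin_width)
        prot_b, ph_b, rep_b = prot[sel], ph[sel], rep[sel]
        ion_b = ~prot_b if self.residue_class == ACID else prot_b
        row["n_ionized"] = int(ion_b.sum())
        row["n_neutral"] = int((~ion_b).sum())
        row["n_ph"] = len(np.unique(ph_b))
        row["n_replicas"] = len(np.unique(rep_b))
        if row["n_ionized"] < self.min_points or row["n_neutral"] < self.min_points:
            row["status"] = GATE_POINTS
            return row
        for state_mask in (ion_b, ~ion_b):
            if len(np.unique(ph_b[state_mask])) < self.min_ph:
                row["status"] = GATE_PH
                return row
        for state_mask in (ion_b, ~ion_b):
            if len(np.unique(rep_b[state_mask])) < self.min_replicas:
                row["status"] = GATE_REPLICAS
                return row
        phs = np.unique(ph_b)
        means = np.array([prot_b[ph_b == p].mean() for p in phs])
        if np.any(np.diff(means) > self.mono_slack):
            row["status"] = GATE_MONOTONIC
            return row
        counts = np.array([(ph_b == p).sum() for p in phs])
        try:
            pka = hh_fit(phs, means, counts)
        except ValueError:
            row["status"] = GATE_MONOTONIC if len(phs) >= 2 else GATE_PH
            return row
        boot = bayesian_bootstrap_pka(
            {p: prot_b[ph_b == p].astype(float) for p in phs},
            n_boot=self.n_boot,
            rng=rng,
            center=pka,
        )
        row.update(status=GATE_FITTED, pka=pka, boot_err=boot.error)
        return row

    def fit(self, rng: Optional[np.random.Generator] = None, seed: int = 0) -> PKaProfileResults:
        rng = np.random.default_rng(seed) if rng is None else rng
        rec = self.records[~self.records["equilibration_flag"].to_numpy(dtype=bool)]
        x = _insertion_column(rec)
        prot = rec["state"].to_numpy() == PROTONATED
        ph = rec["pH"].to_numpy(dtype=float)
        rep = rec["replicate_index"].to_numpy(dtype=int)
        rows = [self._gate_and_fit(x, prot, ph, rep, lo, rng) for lo in self.bin_left_edges()]
        table = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
        return PKaProfileResults(table=table, residue_class=self.residue_class,
                                 n_boot=self.n_boot)


def pka_profile(records: pd.DataFrame, residue_class: str, **kwargs) -> PKaProfileResults:
    """Functional wrapper around PKaProfiler(...).fit()."""
    seed = kwargs.pop("seed", 0)
    rng = kwargs.pop("rng", None)
    return PKaProfiler(records, residue_class, **kwargs).fit(rng=rng, seed=seed)
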