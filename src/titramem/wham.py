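"""WHAM potentials of mean force, jackknife errors, and reweighting.

The weighted histogram analysis method self-consistently solves

    P(xi_b) = sum_j n_jb / sum_j N_j exp(beta (f_j - V_j(xi_b)))
    exp(-beta f_j) = sum_b P(xi_b) exp(-beta V_j(xi_b))

for the unbiased bin probabilities P and the per-window free energies
f_j, iterating until the free energies are stationary.  PMF =
-kT ln P, anchored so its minimum over occupied bins is zero.  All
internal energies are kJ/mol; reported PMFs are kcal/mol on an
Angstrom grid.

Organised statsmodels-style: :class:`WHAM` is the model object,
``WHAM(...).fit()`` returns a :class:`WHAMResults` carrying the PMF
profile, window free energies, convergence diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exchange import Window
from .units import ANGSTROM_PER_NM, KJ_PER_KCAL, ThermoContext


@dataclass(frozen=True)
class PMFProfile:
    """A potential of mean force on an insertion grid.

    grid in Angstrom (bin centers); values and errors in kcal/mol,
    anchored so the minimum over reported bins is zero.
    """

    grid: np.ndarray
    value: np.ndarray
    error: Optional[np.ndarray] = None
    note: str = "anchored: min over occupied bins = 0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "value", np.asarray(self.value, dtype=float))
        if self.error is not None:
            err = np.asarray(self.error, dtype=float)
            if np.any(err[np.isfinite(err)] < 0):
                raise ValueError("PMF errors must be >= 0")
            object.__setattr__(self, "error", err)

    @property
    def value_kJ(self) -> np.ndarray:
        return self.value * KJ_PER_KCAL

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"insertion_A": self.grid, "pmf_kcal": self.value})
        if self.error is not None:
            df["error_kcal"] = self.error
        return df

    def shifted(self, constant: float) -> "PMFProfile":
        return PMFProfile(self.grid, self.value + constant, self.error, self.note)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.error is not None:
            ax.fill_between(
                self.grid, self.value - self.error, self.value + self.error, alpha=0.3
            )
        ax.plot(self.grid, self.value, **kwargs)
        ax.set_xlabel("insertion (Å)")
        ax.set_ylabel("PMF (kcal/mol)")
        return ax


@dataclass
class HistogramSet:
    """Per-window reaction-coordinate histograms on a shared grid.

    bin_edges in nm; counts has shape (n_windows, n_bins); n_frames[j]
    equals counts[j].sum().
    """

    windows: Sequence[Window]
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.windows), len(self.bin_edges) - 1):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.windows)} windows x {len(self.bin_edges) - 1} bins"
            )

    @property
    def n_frames(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_samples(
        cls,
        windows: Sequence[Window],
        samples: Sequence[np.ndarray],
        bin_width_A: float = 0.05,
        lo_A: Optional[float] = None,
        hi_A: Optional[float] = None,
    ) -> "HistogramSet":
        """Histogram per-window xi samples (nm) on a shared grid.

        Half-open [lo, hi) bins; the grid spans the sample range
        (padded to whole bins) unless lo/hi are given in Angstrom.
        """
        if len(windows) != len(samples):
            raise ValueError("one sample array per window required")
        all_xi = np.concatenate([np.asarray(s, dtype=float) for s in samples])
        w = bin_width_A / ANGSTROM_PER_NM
        lo = (lo_A / ANGSTROM_PER_NM) if lo_A is not None else np.floor(all_xi.min() / w) * w
        hi = (hi_A / ANGSTROM_PER_NM) if hi_A is not None else (np.floor(all_xi.max() / w) + 1) * w
        n_bins = int(round((hi - lo) / w))
        edges = lo + w * np.arange(n_bins + 1)
        counts = np.vstack([np.histogram(s, bins=edges)[0] for s in samples])
        return cls(windows=list(windows), bin_edges=edges, counts=counts)

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        windows: Sequence[Window],
        bin_width_A: float = 0.05,
        include_equilibration: bool = False,
        **kwargs,
    ) -> "HistogramSet":
        """Histogram a campaign record table (one histogram per window);
        equilibration-flagged frames are excluded by default."""
        df = records if include_equilibration else records[~records["equilibration_flag"]]
        samples = [df.loc[df["window_id"] == w.window_id, "z_nm"].to_numpy() for w in windows]
        return cls.from_samples(windows, samples, bin_width_A=bin_width_A, **kwargs)


@dataclass
class WHAMResults:
    """WHAM estimates: PMF profile, window free energies, diagnostics."""

    pmf: PMFProfile
    f_kT: np.ndarray  # per-window free energies in kT, f[0] = 0
    log_prob: np.ndarray  # ln P per bin (normalized over occupied bins)
    bin_counts: np.ndarray  # pooled counts per bin
    n_iter: int
    residual: float
    converged: bool
    histograms: HistogramSet
    thermo: ThermoContext

    def summary(self) -> str:
        lines = [
            "WHAM results",
            "============",
            f"windows:        {len(self.histograms.windows)}",
            f"bins:           {len(self.pmf.grid)}",
            f"total frames:   {int(self.histograms.counts.sum())}",
            f"iterations:     {self.n_iter} (residual {self.residual:.2e} kT, "
            f"{'converged' if self.converged else 'NOT converged'})",
            f"PMF range:      0 .. {np.nanmax(self.pmf.value):.3f} kcal/mol",
            "",
            "window   xi_ref(A)        k   f(kT)",
        ]
        for w, f in zip(self.histograms.windows, self.f_kT):
            lines.append(
                f"{w.window_id:>7} {w.xi_ref * ANGSTROM_PER_NM:>9.2f} {w.k:>8.0f} {f:>7.3f}"
            )
        return "\n".join(lines)


class WHAM:
    """Weighted histogram analysis model over a HistogramSet."""

    def __init__(self, histograms: HistogramSet, thermo: ThermoContext) -> None:
        self.histograms = histograms
        self.thermo = thermo
        self._check_overlap()

    def _check_overlap(self) -> None:
        hs = self.histograms
        order = np.argsort([w.xi_ref for w in hs.windows])
        occupied = hs.counts > 0
        for a, b in zip(order[:-1], order[1:]):
            if not np.any(occupied[a] & occupied[b]):
                wa, wb = hs.windows[a], hs.windows[b]
                raise ValueError(
                    f"no histogram overlap between adjacent windows "
                    f"{wa.window_id} and {wb.window_id}: WHAM cannot bridge the gap"
                )

    def fit(self, tol: float = 1e-7, max_iter: int = 100_000) -> WHAMResults:
        """Self-consistent iteration until max |delta f_j| < tol (kT)."""
        if not (tol > 0):
            raise ValueError("tol must be > 0")
        hs = self.histograms
        kT = self.thermo.kT
        centers = hs.centers
        # Effective bias per (window, bin) in kT: -ln of the Boltzmann
        # average of exp(-beta V) over the bin (5-point Gauss-Legendre),
        # not the bin-center value.  With stiff umbrellas the bias varies
        # substantially within a bin and the bin-center approximation
        # accumulates a systematic offset across the ladder.
        nodes, weights = np.polynomial.legendre.leggauss(5)
        half = 0.5 * np.diff(hs.bin_edges)
        quad = centers[None, :] + half[None, :] * nodes[:, None]  # (5, n_bins)
        u = np.empty((len(hs.windows), len(centers)))
        for j, w in enumerate(hs.windows):
            b = -w.bias_energy(quad) / kT  # (5, n_bins)
            u[j] = -logsumexp(b, axis=0, b=0.5 * weights[:, None])
        n_j = hs.n_frames  # (n_windows,)
        pooled = hs.counts.sum(axis=0)  # (n_bins,)
        occ = pooled > 0
        log_nj = np.log(np.where(n_j > 0, n_j, 1.0))
        log_pooled = np.where(occ, np.log(np.where(occ, pooled, 1.0)), -np.inf)

        f = np.zeros(len(hs.windows))
        residual = np.inf
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            # ln denominator per bin: logsumexp_j [ln N_j + f_j - u_jb]
            log_denom = logsumexp(log_nj[:, None] + f[:, None] - u, axis=0)
            log_p = np.where(occ, log_pooled - log_denom, -np.inf)
            log_p -= logsumexp(log_p[occ])
            f_new = -logsumexp(log_p[None, occ] - u[:, occ], axis=1)
            f_new -= f_new[0]
            residual = float(np.max(np.abs(f_new - f)))
            f = f_new
            if residual < tol:
                break
        else:
            raise RuntimeError(
                f"WHAM did not converge in {max_iter} iterations "
                f"(residual {residual:.3e} kT > tol {tol:g} kT)"
            )
        log_denom = logsumexp(log_nj[:, None] + f[:, None] - u, axis=0)
        log_p = np.where(occ, log_pooled - log_denom, -np.inf)
        log_p -= logsumexp(log_p[occ])
        # PMF = -kT ln P, anchored to min 0 over occupied bins
        pmf_kJ = np.full_like(log_p, np.nan)
        pmf_kJ[occ] = -kT * log_p[occ]
        pmf_kJ -= np.nanmin(pmf_kJ)
        profile = PMFProfile(grid=centers * ANGSTROM_PER_NM, value=pmf_kJ / KJ_PER_KCAL)
        return WHAMResults(
            pmf=profile,
            f_kT=f,
            log_prob=log_p,
            bin_counts=pooled,
            n_iter=n_iter,
            residual=residual,
            converged=True,
            histograms=hs,
            thermo=self.thermo,
        )


def wham(
    histograms: HistogramSet,
    thermo: ThermoContext,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> WHAMResults:
    """Functional wrapper around WHAM(...).fit()."""
    return WHAM(histograms, thermo).fit(tol=tol, max_iter=max_iter)


def jackknife_pmf_error(
    replicate_histograms: Sequence[HistogramSet],
    thermo: ThermoContext,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> PMFProfile:
    """Leave-one-out jackknife error of the pooled-WHAM PMF.

    Each leave-one-out PMF is computed from the pooled histograms of
    the remaining replicates and anchored with the common min-0
    convention, so the error is invariant to the global offset.
    error(xi) = sqrt((n-1)/n * sum_i (PMF_i - mean)^2).
    """
    n = len(replicate_histograms)
    if n < 2:
        raise ValueError("jackknife requires >= 2 replicates")
    ref = replicate_histograms[0]
    for hs in replicate_histograms[1:]:
        if not np.allclose(hs.bin_edges, ref.bin_edges):
            raise ValueError("replicate histograms must share a common grid")
    loo_values = []
    for i in range(n):
        counts = sum(hs.counts for j, hs in enumerate(replicate_histograms) if j != i)
        pooled = HistogramSet(windows=ref.windows, bin_edges=ref.bin_edges, counts=counts)
        res = wham(pooled, thermo, tol=tol, max_iter=max_iter)
        loo_values.append(res.pmf.value)
    loo = np.vstack(loo_values)
    mean = np.nanmean(loo, axis=0)
    err = np.sqrt((n - 1) / n * np.nansum((loo - mean) ** 2, axis=0))
    err[np.all(np.isnan(loo), axis=0)] = np.nan
    total = HistogramSet(
        windows=ref.windows,
        bin_edges=ref.bin_edges,
        counts=sum(hs.counts for hs in replicate_histograms),
    )
    full = wham(total, thermo, tol=tol, max_iter=max_iter)
    return PMFProfile(grid=full.pmf.grid, value=full.pmf.value, error=err)


def reweight_frames(
    xi: np.ndarray,
    results: WHAMResults,
) -> np.ndarray:
    """MBAR-consistent umbrella-reweighting weights for frames at
    reaction-coordinate values ``xi`` (nm):

        w(xi) ∝ 1 / sum_j N_j exp(f_j - beta V_j(xi)),

    normalized to mean 1.  Frames outside the histogram support get a
    weight from the same global formula, with a tail warning.
    """
    xi = np.asarray(xi, dtype=float)
    hs = results.histograms
    kT = results.thermo.kT
    lo, hi = hs.bin_edges[0], hs.bin_edges[-1]
    n_out = int(np.sum((xi < lo) | (xi >= hi)))
    if n_out:
        warnings.warn(
            f"{n_out} frame(s) lie outside the histogram support "
            f"[{lo:.3f}, {hi:.3f}] nm; their weights extrapolate the WHAM tails",
            stacklevel=2,
        )
    u = np.vstack([w.bias_energy(xi) for w in hs.windows]) / kT  # (n_windows, n_frames)
    log_nj = np.log(np.where(hs.n_frames > 0, hs.n_frames, 1.0))
    log_denom = logsumexp(log_nj[:, None] + results.f_kT[:, None] - u, axis=0)
    logw = -log_denom
    w = np.exp(logw - logw.max())
    return w / w.mean()


def align_pmf(profile: PMFProfile, reference: PMFProfile, region: tuple[float, float]) -> PMFProfile:
    """Shift ``profile`` by the constant minimizing the mean squared
    difference to ``reference`` over the insertion interval ``region``
    (Angstrom, inclusive).  Used to align ladders that cover different
    ranges in the common water region."""
    lo, hi = min(region), max(region)
    mask_p = (profile.grid >= lo) & (profile.grid <= hi) & np.isfinite(profile.value)
    sel = profile.grid[mask_p]
    if sel.size == 0:
        raise ValueError(f"profile has no points in the alignment region [{lo}, {hi}] A")
    ref_interp = np.interp(sel, reference.grid[np.isfinite(reference.value)],
                           reference.value[np.isfinite(reference.value)],
                           left=np.nan, right=np.nan)
    valid = np.isfinite(ref_interp)
    if not np.any(valid):
        raise ValueError(f"reference does not cover the alignment region [{lo}, {hi}] A")
    shift = float(np.mean(ref_interp[valid] - profile.value[mask_p][valid]))
    return profile.shifted(shift)
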