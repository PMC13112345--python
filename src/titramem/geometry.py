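"""Membrane-insertion and local-deformation calculators.

Insertion of a titratable site is measured along the membrane normal
relative to the *local* phosphate surface of the closest leaflet: the
mean z of phosphate-group atoms within a 6 A radius of the site,
provided at least 5 atoms are present (otherwise the whole closest
leaflet is used and the result is flagged).  Local deformation compares
the phosphate surface near the site (<= 6 A) with the bulk surface
(> 15 A away).  Both quantities are signed water-positive.

Includes a fixed-column GRO reader (multi-frame series) and a synthetic
membrane-surface generator with recorded ground truth, standing in for
lipid phosphate coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .units import ANGSTROM_PER_NM

UPPER = "upper"
LOWER = "lower"


@dataclass
class MembraneSnapshot:
    """Labeled coordinates (nm) of phosphate pseudo-atoms and the
    titratable site for one frame."""

    site_position: np.ndarray  # (3,)
    phosphate_xyz: np.ndarray  # (N, 3)
    leaflet: np.ndarray  # (N,) of {"upper", "lower"}
    box: np.ndarray  # (3,) Lx, Ly, Lz
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.site_position = np.asarray(self.site_position, dtype=float)
        self.phosphate_xyz = np.atleast_2d(np.asarray(self.phosphate_xyz, dtype=float))
        self.leaflet = np.asarray(self.leaflet)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(self.box > 0):
            raise ValueError(f"box lengths must be > 0, got {self.box}")
        for tag in (UPPER, LOWER):
            if not np.any(self.leaflet == tag):
                raise ValueError(f"snapshot has no phosphate atoms in the {tag} leaflet")

    def leaflet_atoms(self, tag: str) -> np.ndarray:
        return self.phosphate_xyz[self.leaflet == tag]


@dataclass(frozen=True)
class InsertionResult:
    insertion: float  # Angstrom, water-positive
    n_local_atoms: int
    fallback_used: bool  # true iff n_local_atoms fell below the min_atoms gate


# -- GRO I/O ----------------------------------------------------------------


def _parse_gro_frames(path: Path):
    """Yield (title, atoms, box, first_line_number) from a fixed-column
    (possibly multi-frame) GRO file.  atoms: list of (resname, atomname, x, y, z)."""
    lines = path.read_text().splitlines()
    i = 0
    n_total = len(lines)
    while i < n_total:
        if lines[i].strip() == "" and i == n_total - 1:
            break
        title = lines[i]
        if i + 1 >= n_total:
            raise ValueError(f"{path}: truncated file at line {i + 1}: missing atom count")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError as exc:
            raise ValueError(
                f"{path}: line {i + 2}: expected atom count, got {lines[i + 1]!r}"
            ) from exc
        atom_start = i + 2
        if atom_start + natoms >= n_total + 1 and atom_start + natoms + 1 > n_total:
            raise ValueError(f"{path}: truncated frame starting at line {i + 1}")
        atoms = []
        for j in range(natoms):
            ln = atom_start + j
            line = lines[ln]
            if len(line) < 44:
                raise ValueError(f"{path}: line {ln + 1}: atom line too short for GRO format")
            try:
                resname = line[5:10].strip()
                atomname = line[10:15].strip()
                x = float(line[20:28])
                y = float(line[28:36])
                z = float(line[36:44])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln + 1}: malformed atom line {line!r}") from exc
            atoms.append((resname, atomname, x, y, z))
        box_ln = atom_start + natoms
        if box_ln >= n_total:
            raise ValueError(f"{path}: truncated frame: missing box line after line {box_ln}")
        box_fields = lines[box_ln].split()
        if len(box_fields) < 3:
            raise ValueError(f"{path}: line {box_ln + 1}: malformed box line")
        box = np.array([float(v) for v in box_fields[:3]])
        yield title, atoms, box, i + 1
        i = box_ln + 1
        while i < n_total and lines[i].strip() == "":
            i += 1


def read_gro(
    path,
    site_atoms: Sequence[str],
    phosphate_atoms: Sequence[str],
) -> list[MembraneSnapshot]:
    """Read a (multi-frame) GRO file into a MembraneSnapshot series.

    ``site_atoms``: atom names whose center of geometry defines the
    titratable-site reference (two names for the His imidazole case).
    ``phosphate_atoms``: atom names of the phosphate group (phosphorus
    plus its bound oxygens).  Leaflets are assigned by z relative to the
    phosphate median, per frame.
    """
    path = Path(path)
    site_set = set(site_atoms)
    phos_set = set(phosphate_atoms)
    snapshots = []
    for title, atoms, box, lineno in _parse_gro_frames(path):
        site_xyz = np.array([(x, y, z) for _, name, x, y, z in atoms if name in site_set])
        phos_xyz = np.array([(x, y, z) for _, name, x, y, z in atoms if name in phos_set])
        if site_xyz.size == 0:
            raise ValueError(
                f"{path}: frame at line {lineno}: site selection {sorted(site_set)} matched no atoms"
            )
        if phos_xyz.size == 0:
            raise ValueError(
                f"{path}: frame at line {lineno}: phosphate selection "
                f"{sorted(phos_set)} matched no atoms"
            )
        z_med = np.median(phos_xyz[:, 2])
        leaflet = np.where(phos_xyz[:, 2] >= z_med, UPPER, LOWER)
        snapshots.append(
            MembraneSnapshot(
                site_position=site_xyz.mean(axis=0),
                phosphate_xyz=phos_xyz,
                leaflet=leaflet,
                box=box,
                metadata={"title": title.strip()},
            )
        )
    if not snapshots:
        raise ValueError(f"{path}: no frames found")
    return snapshots


# -- distance helpers -------------------------------------------------------


def _site_distances(snapshot: MembraneSnapshot, atoms: np.ndarray, mode: str) -> np.ndarray:
    """Distances from the site to atoms, minimum-image in xy; z is the
    membrane normal and treated as non-periodic."""
    d = atoms - snapshot.site_position
    for ax in (0, 1):
        L = snapshot.box[ax]
        d[:, ax] -= L * np.round(d[:, ax] / L)
    if mode == "lateral":
        return np.hypot(d[:, 0], d[:, 1])
    if mode == "3d":
        return np.linalg.norm(d, axis=1)
    raise ValueError(f"distance mode must be '3d' or 'lateral', got {mode!r}")


def closest_leaflet(snapshot: MembraneSnapshot) -> str:
    z_site = snapshot.site_position[2]
    means = {tag: snapshot.leaflet_atoms(tag)[:, 2].mean() for tag in (UPPER, LOWER)}
    return min(means, key=lambda tag: abs(z_site - means[tag]))


def _orientation(snapshot: MembraneSnapshot, leaflet_tag: str) -> float:
    """Water-positive sign: above the upper leaflet is water (+z), below
    the lower leaflet is water (-z)."""
    return 1.0 if leaflet_tag == UPPER else -1.0


def compute_insertion(
    snapshot: MembraneSnapshot,
    radius: float = 6.0,
    min_atoms: int = 5,
    mode: str = "3d",
    orientation: Optional[float] = None,
) -> InsertionResult:
    """Signed insertion (A) of the site relative to the local phosphate
    surface of the closest leaflet.

    ``radius`` in Angstrom.  With fewer than ``min_atoms`` phosphate
    atoms inside the radius, the whole closest leaflet serves as the
    reference and the result is flagged.  ``orientation`` (+1/-1) can
    fix the water-positive sign per trajectory; by default it follows
    the closest leaflet of this frame.
    """
    tag = closest_leaflet(snapshot)
    atoms = snapshot.leaflet_atoms(tag)
    if atoms.size == 0:
        raise ValueError(f"closest leaflet {tag!r} is empty")
    dist = _site_distances(snapshot, atoms, mode)
    local = atoms[dist <= radius / ANGSTROM_PER_NM]
    fallback = len(local) < min_atoms
    ref_atoms = atoms if fallback else local
    sign = _orientation(snapshot, tag) if orientation is None else orientation
    insertion_nm = sign * (snapshot.site_position[2] - ref_atoms[:, 2].mean())
    return InsertionResult(
        insertion=insertion_nm * ANGSTROM_PER_NM,
        n_local_atoms=int(len(local)),
        fallback_used=bool(fallback),
    )


def local_deformation(
    snapshot: MembraneSnapshot,
    r_local: float = 6.0,
    r_bulk: float = 15.0,
    mode: str = "lateral",
    orientation: Optional[float] = None,
) -> Optional[float]:
    """Mean phosphate z within ``r_local`` A of the site minus the mean
    beyond ``r_bulk`` A, on the closest leaflet, water-positive (A).

    The neighborhood is lateral (xy, minimum-image) by default: the
    quantity compares surface heights under and away from the solute,
    and a 3-D ball around a site hovering above the surface would lose
    exactly the depressed atoms it is meant to measure.  Returns None
    when either set is empty (missing value, not fabricated)."""
    tag = closest_leaflet(snapshot)
    atoms = snapshot.leaflet_atoms(tag)
    dist = _site_distances(snapshot, atoms, mode)
    local = atoms[dist <= r_local / ANGSTROM_PER_NM]
    bulk = atoms[dist > r_bulk / ANGSTROM_PER_NM]
    if len(local) == 0 or len(bulk) == 0:
        return None
    sign = _orientation(snapshot, tag) if orientation is None else orientation
    return float(sign * (local[:, 2].mean() - bulk[:, 2].mean()) * ANGSTROM_PER_NM)


def deformation_series(snapshots, **kwargs):
    """Per-frame deformations with missing values counted, not invented."""
    values = [local_deformation(s, **kwargs) for s in snapshots]
    present = [v for v in values if v is not None]
    return present, len(values) - len(present)


# -- synthetic surface generator -------------------------------------------


def synth_membrane_surface(
    lattice_spacing: float = 3.0,  # A
    box: tuple[float, float, float] = (60.0, 60.0, 80.0),  # A
    dimple_amplitude: float = 0.0,  # A, depth of the depression under the site
    dimple_sigma: float = 8.0,  # A
    roughness_sd: float = 0.0,  # A
    leaflet_separation: float = 35.0,  # A
    site_track: Optional[Sequence[Sequence[float]]] = None,  # (n_frames, 3) A
    n_frames: int = 1,
    seed: int = 0,
    r_local: float = 6.0,
    r_bulk: float = 15.0,
    insertion_mode: str = "3d",
    deformation_mode: str = "lateral",
) -> list[MembraneSnapshot]:
    """Generate phosphate pseudo-atoms on a jittered square lattice with
    a Gaussian dimple of depth ``dimple_amplitude`` under the site in the
    upper leaflet:

        z_upper(r) = sep/2 - A * exp(-|r - r_site|^2 / (2 sigma^2)) + noise

    Ground truth for each frame is recorded in snapshot metadata:
    ``truth_insertion`` and ``truth_deformation`` are computed from the
    noiseless z-field over the actual atom positions with the same
    radii/mode the estimators use, so with zero roughness the estimators
    must reproduce them to machine precision.
    """
    rng = np.random.default_rng(seed)
    Lx, Ly, Lz = box
    nx = max(int(Lx // lattice_spacing), 2)
    ny = max(int(Ly // lattice_spacing), 2)
    xs = (np.arange(nx) + 0.5) * (Lx / nx)
    ys = (np.arange(ny) + 0.5) * (Ly / ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    lattice_xy = np.column_stack([gx.ravel(), gy.ravel()])
    if site_track is None:
        site_track = [(Lx / 2.0, Ly / 2.0, leaflet_separation / 2.0 + 4.0)] * n_frames
    site_track = np.asarray(site_track, dtype=float)
    if site_track.ndim == 1:
        site_track = np.tile(site_track, (n_frames, 1))
    if len(site_track) != n_frames:
        raise ValueError("site_track length must equal n_frames")

    snapshots = []
    for f in range(n_frames):
        site = site_track[f]
        # jitter the lattice in xy only, so the surface shape stays exact
        xy = lattice_xy + rng.normal(0.0, 0.15 * lattice_spacing, size=lattice_xy.shape)
        xy[:, 0] %= Lx
        xy[:, 1] %= Ly
        d = xy - site[:2]
        d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
        d[:, 1] -= Ly * np.round(d[:, 1] / Ly)
        r2 = (d**2).sum(axis=1)
        z_clean_upper = leaflet_separation / 2.0 - dimple_amplitude * np.exp(
            -r2 / (2.0 * dimple_sigma**2)
        )
        z_upper = z_clean_upper + rng.normal(0.0, roughness_sd, size=len(xy))
        z_lower = -leaflet_separation / 2.0 + rng.normal(0.0, roughness_sd, size=len(xy))
        coords = np.vstack(
            [
                np.column_stack([xy, z_upper]),
                np.column_stack([xy, z_lower]),
            ]
        )
        leaflet = np.array([UPPER] * len(xy) + [LOWER] * len(xy))
        snap = MembraneSnapshot(
            site_position=site / ANGSTROM_PER_NM,
            phosphate_xyz=coords / ANGSTROM_PER_NM,
            leaflet=leaflet,
            box=np.array([Lx, Ly, Lz]) / ANGSTROM_PER_NM,
            metadata={"frame": f},
        )
        # ground truth from the noiseless field over the same atoms
        clean = snap.phosphate_xyz.copy()
        clean[: len(xy), 2] = z_clean_upper / ANGSTROM_PER_NM
        clean[len(xy):, 2] = -leaflet_separation / 2.0 / ANGSTROM_PER_NM
        clean_snap = MembraneSnapshot(
            site_position=snap.site_position,
            phosphate_xyz=clean,
            leaflet=leaflet,
            box=snap.box,
        )
        truth_ins = compute_insertion(clean_snap, radius=r_local, mode=insertion_mode)
        truth_def = local_deformation(
            clean_snap, r_local=r_local, r_bulk=r_bulk, mode=deformation_mode
        )
        snap.metadata.update(
            truth_insertion=truth_ins.insertion,
            truth_deformation=truth_def,
            dimple_amplitude=dimple_amplitude,
        )
        snapshots.append(snap)
    return snapshots
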