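"""Leaflet decomposition, gridded membrane thickness maps, and mismatch calculus.

Thickness maps bin lipid marker atoms (head-group phosphorus for P-P thickness,
acyl chain alpha carbons for hydrophobic thickness) onto a lateral grid
(default spacing 3.3 A) and average surface z per leaflet over atoms and
frames.  The bulk reference is the occupancy-weighted mean thickness over the
grid cells laterally furthest from the protein footprint.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Frame, Trajectory, select

__all__ = [
    "LeafletSplit",
    "ThicknessMap",
    "MismatchReport",
    "DegenerateBilayerError",
    "split_leaflets",
    "thickness_map",
    "bulk_thickness",
    "hydrophobic_length",
    "mismatch_report",
    "RISE_PER_RESIDUE",
]

RISE_PER_RESIDUE = 1.5  # Angstrom per residue for a canonical alpha helix


class DegenerateBilayerError(ValueError):
    """Marker atoms do not form two leaflets."""


@dataclass
class LeafletSplit:
    upper: np.ndarray          # atom indices
    lower: np.ndarray
    midplane_z: np.ndarray     # per frame, Angstrom

    def __post_init__(self) -> None:
        if len(self.upper) == 0 or len(self.lower) == 0:
            raise DegenerateBilayerError("each leaflet must be non-empty")
        if set(self.upper) & set(self.lower):
            raise ValueError("leaflet assignments overlap")


@dataclass
class ThicknessMap:
    spacing: tuple[float, float]       # actual cell size (dx, dy), Angstrom
    nx: int
    ny: int
    box: np.ndarray                    # (Lx, Ly)
    upper_z: np.ndarray                # (nx, ny), NaN where unoccupied
    lower_z: np.ndarray
    thickness: np.ndarray              # (nx, ny), NaN where undefined
    occupancy: np.ndarray              # (nx, ny) marker-atom counts, both leaflets
    bulk: float | None = None
    perturbation: np.ndarray | None = None

    @property
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        dx, dy = self.spacing
        cx = (np.arange(self.nx) + 0.5) * dx
        cy = (np.arange(self.ny) + 0.5) * dy
        return cx, cy

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        dx, dy = self.spacing
        return (int((x % self.box[0]) // dx) % self.nx,
                int((y % self.box[1]) // dy) % self.ny)

    def with_bulk(self, bulk: float) -> "ThicknessMap":
        self.bulk = float(bulk)
        self.perturbation = self.thickness - self.bulk
        return self


@dataclass(frozen=True)
class MismatchReport:
    peptide_length: float          # Angstrom
    membrane_thickness: float      # Angstrom
    mismatch: float                # peptide - membrane
    label: str                     # positive | negative | matched


def split_leaflets(traj: Trajectory, marker_query: str = "name P") -> LeafletSplit:
    """Partition marker atoms into upper/lower leaflets by first-frame z.

    Assignment is frozen at the first frame (no flip-flop tracking); the
    midplane is the mass-weighted mean marker z, recorded per frame.
    """
    frame0 = traj.frames[0]
    markers = select(frame0, marker_query)
    if len(markers) < 2:
        raise DegenerateBilayerError("need at least 2 marker atoms")
    masses = frame0.masses[markers]
    mids = np.empty(len(traj.frames))
    for i, frame in enumerate(traj.frames):
        z = frame.positions[markers, 2]
        mids[i] = np.average(z, weights=masses)
    z0 = frame0.positions[markers, 2]
    upper = markers[z0 > mids[0]]
    lower = markers[z0 <= mids[0]]
    if len(upper) == 0 or len(lower) == 0:
        raise DegenerateBilayerError("all marker atoms on one side of the midplane")
    return LeafletSplit(upper=upper, lower=lower, midplane_z=mids)


def _frame_indices(n_frames: int, frames, discard_fraction: float | None):
    if frames is not None:
        return np.asarray(frames, dtype=int)
    if discard_fraction:
        start = int(round(discard_fraction * n_frames))
        return np.arange(start, n_frames)
    return np.arange(n_frames)


def thickness_map(traj: Trajectory, split: LeafletSplit, spacing: float = 3.3,
                  fill: str = "nearest", frames=None,
                  discard_fraction: float | None = None) -> ThicknessMap:
    """Time-and-atom averaged per-cell leaflet surfaces and thickness.

    Marker atoms are wrapped into the lateral box and binned; per-cell surface
    z is the mean over all binned markers of that leaflet across the analysed
    frames.  Empty cells are filled per *fill*: 'nearest' (periodic
    nearest-occupied cell), 'idw' (inverse-squared-distance over occupied
    cells), or 'none' (left NaN).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if fill not in ("nearest", "idw", "none"):
        raise ValueError(f"unknown fill mode {fill!r}")
    frame_idx = _frame_indices(len(traj.frames), frames, discard_fraction)
    box0 = traj.frames[0].box
    for i in frame_idx:
        if np.any(np.abs(traj.frames[i].box[:2] - box0[:2]) > 0.01 * box0[:2]):
            raise ValueError("frames differ in lateral box size by more than 1%")
    Lx, Ly = float(box0[0]), float(box0[1])
    if spacing > min(Lx, Ly) / 2:
        raise ValueError("grid spacing exceeds half the lateral box")
    nx = max(2, int(round(Lx / spacing)))
    ny = max(2, int(round(Ly / spacing)))
    dx, dy = Lx / nx, Ly / ny

    sums = {s: np.zeros((nx, ny)) for s in ("upper", "lower")}
    counts = {s: np.zeros((nx, ny), dtype=int) for s in ("upper", "lower")}
    leaflets = {"upper": split.upper, "lower": split.lower}
    for i in frame_idx:
        pos = traj.frames[i].positions
        for side, idx in leaflets.items():
            p = pos[idx]
            ix = np.floor((p[:, 0] % Lx) / dx).astype(int) % nx
            iy = np.floor((p[:, 1] % Ly) / dy).astype(int) % ny
            np.add.at(sums[side], (ix, iy), p[:, 2])
            np.add.at(counts[side], (ix, iy), 1)

    surfaces = {}
    for side in ("upper", "lower"):
        with np.errstate(invalid="ignore"):
            surf = np.where(counts[side] > 0, sums[side] / np.maximum(counts[side], 1),
                            np.nan)
        surfaces[side] = _fill_cells(surf, counts[side] > 0, dx, dy, Lx, Ly, fill)

    thickness = surfaces["upper"] - surfaces["lower"]
    return ThicknessMap(
        spacing=(dx, dy), nx=nx, ny=ny, box=np.array([Lx, Ly]),
        upper_z=surfaces["upper"], lower_z=surfaces["lower"],
        thickness=thickness, occupancy=counts["upper"] + counts["lower"],
    )


def _fill_cells(surface: np.ndarray, occupied: np.ndarray, dx: float, dy: float,
                Lx: float, Ly: float, fill: str) -> np.ndarray:
    if fill == "none" or occupied.all():
        return surface
    if not occupied.any():
        raise ValueError("no occupied cells to fill from")
    nx, ny = surface.shape
    cx = (np.arange(nx) + 0.5) * dx
    cy = (np.arange(ny) + 0.5) * dy
    occ_ix, occ_iy = np.nonzero(occupied)
    occ_vals = surface[occ_ix, occ_iy]
    out = surface.copy()
    emp_ix, emp_iy = np.nonzero(~occupied)
    # periodic lateral distances empty x occupied
    ddx = np.abs(cx[emp_ix][:, None] - cx[occ_ix][None, :])
    ddx = np.minimum(ddx, Lx - ddx)
    ddy = np.abs(cy[emp_iy][:, None] - cy[occ_iy][None, :])
    ddy = np.minimum(ddy, Ly - ddy)
    d2 = ddx ** 2 + ddy ** 2
    if fill == "nearest":
        # average over all ties at the minimal distance so the fill is
        # invariant under lattice permutations
        dmin = d2.min(axis=1, keepdims=True)
        tie = d2 <= dmin + 1e-9
        out[emp_ix, emp_iy] = (tie * occ_vals[None, :]).sum(axis=1) / tie.sum(axis=1)
    else:  # idw
        w = 1.0 / np.maximum(d2, 1e-12)
        out[emp_ix, emp_iy] = (w * occ_vals[None, :]).sum(axis=1) / w.sum(axis=1)
    return out


def bulk_thickness(tmap: ThicknessMap, protein_xy: np.ndarray,
                   far_fraction: float = 0.25) -> float:
    """Occupancy-weighted mean thickness over the cells furthest from the protein.

    Cell distance is the minimal periodic lateral distance from the cell
    center to any protein coordinate; the cells in the top *far_fraction* of
    distances (among cells with defined thickness) enter the average.
    """
    protein_xy = np.atleast_2d(np.asarray(protein_xy, dtype=float))
    if protein_xy.size == 0:
        raise ValueError("protein_xy must be non-empty")
    if not 0.0 < far_fraction <= 1.0:
        raise ValueError("far_fraction must be in (0, 1]")
    cx, cy = tmap.cell_centers
    CX, CY = np.meshgrid(cx, cy, indexing="ij")
    Lx, Ly = tmap.box
    dmin = np.full((tmap.nx, tmap.ny), np.inf)
    for px, py in protein_xy:
        ddx = np.abs(CX - (px % Lx))
        ddx = np.minimum(ddx, Lx - ddx)
        ddy = np.abs(CY - (py % Ly))
        ddy = np.minimum(ddy, Ly - ddy)
        dmin = np.minimum(dmin, np.hypot(ddx, ddy))
    defined = np.isfinite(tmap.thickness)
    if not defined.any():
        raise ValueError("thickness map has no defined cells")
    dists = dmin[defined]
    cutoff = np.quantile(dists, 1.0 - far_fraction)
    far = defined & (dmin >= cutoff)
    if not far.any():
        raise ValueError("far cell set is empty")
    weights = np.maximum(tmap.occupancy[far], 1)  # filled cells carry weight 1
    return float(np.average(tmap.thickness[far], weights=weights))


def hydrophobic_length(n_residues: int) -> float:
    """Hydrophobic length in Angstrom of an n-residue alpha-helical stretch (1.5 A/residue)."""
    if n_residues < 0:
        raise ValueError("residue count must be non-negative")
    return RISE_PER_RESIDUE * float(n_residues)


def mismatch_report(peptide_len: float, hydrophobic_thickness: float,
                    tolerance: float = 1.0) -> MismatchReport:
    """Hydrophobic mismatch (peptide - membrane) with a sign label.

    positive: peptide longer than the membrane is thick; negative: shorter;
    matched when |mismatch| < tolerance.
    """
    if peptide_len < 0 or hydrophobic_thickness < 0:
        raise ValueError("lengths must be non-negative")
    mismatch = peptide_len - hydrophobic_thickness
    if abs(mismatch) < tolerance:
        label = "matched"
    elif mismatch > 0:
        label = "positive"
    else:
        label = "negative"
    return MismatchReport(peptide_length=peptide_len,
                          membrane_thickness=hydrophobic_thickness,
                          mismatch=mismatch, label=label)
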