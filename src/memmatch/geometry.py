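"""Dimer orientation and deviation metrics.

Tilt is the angle between the motif-spanning vector (COM of the three flanking
residues above both motifs minus COM of the three below) and the membrane
normal (+z), folded into [0, 90] degrees.  The crossing angle is the angle
between the per-chain vectors connecting the residues immediately below and
above each chain's motif, in [0, 180] degrees.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import DimerTopology, Frame, Trajectory, MOTIF_LENGTH

__all__ = [
    "TiltSeries",
    "DeviationSeries",
    "DegenerateGeometryError",
    "motif_flank_selection",
    "dimer_tilt",
    "crossing_angle",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "tilt_series",
]


class DegenerateGeometryError(ValueError):
    """Raised when an orientation vector has (near-)zero length."""


@dataclass
class TiltSeries:
    tilt_deg: np.ndarray       # per frame, [0, 90]
    crossing_deg: np.ndarray   # per frame, [0, 180]
    times_ps: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.tilt_deg) == len(self.crossing_deg) == len(self.times_ps)):
            raise ValueError("series lengths differ")

    def mean_tilt(self, discard_fraction: float = 0.0) -> float:
        return float(np.mean(self.tilt_deg[self._start(discard_fraction):]))

    def mean_crossing(self, discard_fraction: float = 0.0) -> float:
        return float(np.mean(self.crossing_deg[self._start(discard_fraction):]))

    def _start(self, discard_fraction: float) -> int:
        if not 0.0 <= discard_fraction < 1.0:
            raise ValueError("discard_fraction must be in [0, 1)")
        return int(round(discard_fraction * len(self.tilt_deg)))


@dataclass
class DeviationSeries:
    """Per-frame RMSD over a named selection and/or per-residue RMSF (Angstrom)."""

    rmsd: np.ndarray | None = None
    reference_frame: int = 0
    selection_name: str = ""
    rmsf: np.ndarray | None = None
    rmsf_residues: list[tuple[str, int]] = field(default_factory=list)


def motif_flank_selection(topo: DimerTopology, side: str) -> dict[str, list[int]]:
    """Residue indices flanking the 9-residue motif, per chain.

    side='above'   -> the 3 residues C-terminal to the motif end
    side='below'   -> the 3 residues N-terminal to the motif start
    side='adjacent'-> the single residues immediately before and after the motif
    """
    out: dict[str, list[int]] = {}
    for cid, start in ((topo.chain_a_id, topo.motif_start_a),
                       (topo.chain_b_id, topo.motif_start_b)):
        end = start + MOTIF_LENGTH - 1  # last motif residue
        if side == "above":
            resids = [end + 1, end + 2, end + 3]
        elif side == "below":
            resids = [start - 3, start - 2, start - 1]
        elif side == "adjacent":
            resids = [start - 1, end + 1]
        else:
            raise ValueError(f"unknown side {side!r}")
        if resids[0] < 0:
            raise IndexError(f"chain {cid}: fewer than 3 residues below the motif")
        out[cid] = resids
    return out


def _residue_atom_indices(frame: Frame, chain_id: str, resids: list[int],
                          backbone_only: bool = False) -> np.ndarray:
    wanted = set(resids)
    idx = [i for i, a in enumerate(frame.atoms)
           if a.chain_id == chain_id and a.residue_index in wanted
           and (not backbone_only or a.name in ("N", "CA", "C", "O"))]
    if not idx:
        raise ValueError(f"no atoms for chain {chain_id} residues {sorted(wanted)}")
    return np.asarray(idx)


def _com(frame: Frame, indices: np.ndarray, mass_weighted: bool = True) -> np.ndarray:
    pos = frame.positions[indices]
    if not mass_weighted:
        return pos.mean(axis=0)
    w = frame.masses[indices]
    return (pos * w[:, None]).sum(axis=0) / w.sum()


def dimer_tilt(frame: Frame, topo: DimerTopology, mass_weighted: bool = True) -> float:
    """Angle (deg, [0, 90]) between the pooled motif top-bottom vector and +z."""
    above = motif_flank_selection(topo, "above")
    below = motif_flank_selection(topo, "below")
    top_idx = np.concatenate([
        _residue_atom_indices(frame, cid, resids) for cid, resids in above.items()
    ])
    bot_idx = np.concatenate([
        _residue_atom_indices(frame, cid, resids) for cid, resids in below.items()
    ])
    v = _com(frame, top_idx, mass_weighted) - _com(frame, bot_idx, mass_weighted)
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise DegenerateGeometryError("motif top and bottom coincide")
    cos = abs(v[2]) / norm
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def crossing_angle(frame: Frame, topo: DimerTopology, mass_weighted: bool = True,
                   triplet: bool = False) -> float:
    """Angle (deg, [0, 180]) between the two per-chain motif-spanning vectors."""
    if triplet:
        above = motif_flank_selection(topo, "above")
        below = motif_flank_selection(topo, "below")
    else:
        adj = motif_flank_selection(topo, "adjacent")
        below = {cid: [r[0]] for cid, r in adj.items()}
        above = {cid: [r[1]] for cid, r in adj.items()}
    vectors = []
    for cid in topo.chain_ids:
        lo = _com(frame, _residue_atom_indices(frame, cid, below[cid]), mass_weighted)
        hi = _com(frame, _residue_atom_indices(frame, cid, above[cid]), mass_weighted)
        v = hi - lo
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise DegenerateGeometryError(f"chain {cid}: degenerate motif vector")
        vectors.append(v / norm)
    cos = float(np.dot(vectors[0], vectors[1]))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal (weighted) rigid superposition of *mobile* onto *reference*.

    Returns (rotation 3x3, translation 3-vector, fitted coordinates) with
    fitted = mobile @ R.T + t and R a proper rotation (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be (n, 3) arrays of equal shape")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)
    s = np.linalg.svd(ref_c, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("reference points are (near-)collinear")
    H = (w[:, None] * mob_c).T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    ref_cent = (w[:, None] * reference).sum(axis=0)
    mob_cent = (w[:, None] * mobile).sum(axis=0)
    t = ref_cent - R @ mob_cent
    fitted = mobile @ R.T + t
    return R, t, fitted


def _weighted_rmsd(a: np.ndarray, b: np.ndarray, w: np.ndarray | None = None) -> float:
    d2 = np.sum((a - b) ** 2, axis=1)
    if w is None:
        return float(np.sqrt(d2.mean()))
    w = w / w.sum()
    return float(np.sqrt(np.sum(w * d2)))


def motif5_atom_indices(frame: Frame, topo: DimerTopology) -> np.ndarray:
    """Backbone atoms of the 5 conserved motif residues (G, V, G, V, T) per chain."""
    idx = []
    for cid, start in ((topo.chain_a_id, topo.motif_start_a),
                       (topo.chain_b_id, topo.motif_start_b)):
        resids = [start + k for k in (0, 1, 4, 5, 8)]
        idx.append(_residue_atom_indices(frame, cid, resids, backbone_only=True))
    return np.concatenate(idx)


def _selection_indices(frame: Frame, topo: DimerTopology, selection) -> np.ndarray:
    if isinstance(selection, str):
        if selection == "motif5":
            return motif5_atom_indices(frame, topo)
        if selection == "whole_dimer":
            return np.asarray([i for i, a in enumerate(frame.atoms)
                               if a.chain_id in topo.chain_ids])
        raise ValueError(f"unknown selection {selection!r}")
    return np.asarray(selection, dtype=int)


def rmsd_series(traj: Trajectory, topo: DimerTopology, selection="motif5",
                fit_selection=None, reference_frame: int = 0) -> DeviationSeries:
    """Per-frame RMSD of *selection* vs the reference frame, after a least-squares fit.

    The fit is performed on *fit_selection* (default: the analysis selection
    itself) and the resulting transform applied before measuring the deviation.
    """
    frame0 = traj.frames[reference_frame]
    sel = _selection_indices(frame0, topo, selection)
    if sel.size == 0:
        raise ValueError("empty analysis selection")
    fit = sel if fit_selection is None else _selection_indices(frame0, topo, fit_selection)
    ref_fit = frame0.positions[fit]
    ref_sel = frame0.positions[sel]
    rmsds = np.empty(len(traj.frames))
    for i, frame in enumerate(traj.frames):
        pos = frame.positions
        R, t, _ = kabsch_superpose(pos[fit], ref_fit)
        moved = pos[sel] @ R.T + t
        rmsds[i] = _weighted_rmsd(moved, ref_sel)
    name = selection if isinstance(selection, str) else "custom"
    return DeviationSeries(rmsd=rmsds, reference_frame=reference_frame,
                           selection_name=name)


def rmsf_per_residue(traj: Trajectory, selection=None) -> DeviationSeries:
    """Per-residue RMSF of alpha carbons after fitting frames to the time average.

    *selection* is an optional array of CA atom indices; by default all atoms
    named CA.  Frames are first fitted to frame 0, the mean structure taken,
    then refitted to that mean before computing fluctuations.
    """
    if len(traj.frames) < 2:
        raise ValueError("RMSF undefined for a single frame")
    frame0 = traj.frames[0]
    if selection is None:
        sel = np.asarray([i for i, a in enumerate(frame0.atoms) if a.name == "CA"])
    else:
        sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty RMSF selection")
    coords = traj.coordinates(sel)  # (n_frames, k, 3)
    ref = coords[0]
    fitted = np.empty_like(coords)
    for i in range(coords.shape[0]):
        _, _, fitted[i] = kabsch_superpose(coords[i], ref)
    mean = fitted.mean(axis=0)
    for i in range(coords.shape[0]):
        _, _, fitted[i] = kabsch_superpose(coords[i], mean)
    mean = fitted.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((fitted - mean[None]) ** 2, axis=2), axis=0))
    residues = [(frame0.atoms[i].chain_id, frame0.atoms[i].residue_index) for i in sel]
    return DeviationSeries(rmsf=rmsf, rmsf_residues=residues, selection_name="CA")


def tilt_series(traj: Trajectory, topo: DimerTopology,
                mass_weighted: bool = True) -> TiltSeries:
    """Tilt and crossing angle for every frame of *traj*."""
    tilts = np.empty(len(traj.frames))
    crossings = np.empty(len(traj.frames))
    for i, frame in enumerate(traj.frames):
        tilts[i] = dimer_tilt(frame, topo, mass_weighted)
        crossings[i] = crossing_angle(frame, topo, mass_weighted)
    return TiltSeries(tilt_deg=tilts, crossing_deg=crossings, times_ps=traj.times)
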