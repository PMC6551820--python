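"""Alpha-helix assignment from backbone hydrogen-bond energies.

Uses the classic electrostatic H-bond model: E = 0.084 * 332 * (1/r_ON +
1/r_CH - 1/r_OH - 1/r_CN) kcal/mol, with a bond called below -0.5 kcal/mol.
A residue is assigned 'H' when it lies inside two consecutive i -> i+4
hydrogen-bonded turns; only the alpha class is distinguished, everything else
is 'other'.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Atom, DimerTopology, Frame, Trajectory

__all__ = [
    "HelicitySeries",
    "ClashError",
    "place_amide_hydrogens",
    "hbond_energy",
    "assign_alpha",
    "helicity_series",
    "HBOND_CUTOFF",
]

Q_FACTOR = 0.084 * 332.0      # kcal/mol * Angstrom
HBOND_CUTOFF = -0.5           # kcal/mol
NH_BOND_LENGTH = 1.01         # Angstrom
MIN_DISTANCE = 0.5            # Angstrom, clash guard


class ClashError(ValueError):
    """Donor/acceptor atoms unphysically close."""


@dataclass
class HelicitySeries:
    """Per-frame per-chain helical fraction and the residue assignment matrix."""

    chain_ids: list[str]
    fractions: dict[str, np.ndarray]           # chain -> (n_frames,)
    assignments: dict[str, np.ndarray]         # chain -> (n_frames, n_res) bool

    def mean_fraction(self, chain: str, discard_fraction: float = 0.0) -> float:
        f = self.fractions[chain]
        start = int(round(discard_fraction * len(f)))
        return float(np.mean(f[start:]))


def _backbone_by_residue(frame: Frame, chain: str) -> list[dict[str, np.ndarray]]:
    """Per-residue dict of backbone atom positions for one chain, in residue order."""
    residues: dict[int, dict[str, np.ndarray]] = {}
    names: dict[int, str] = {}
    for a in frame.atoms:
        if a.chain_id != chain:
            continue
        residues.setdefault(a.residue_index, {})[a.name] = a.position
        names[a.residue_index] = a.residue_name
    if not residues:
        raise KeyError(f"chain {chain!r} not present in frame")
    ordered = []
    for ri in sorted(residues):
        rec = residues[ri]
        rec["_resname"] = names[ri]  # type: ignore[assignment]
        rec["_index"] = ri           # type: ignore[assignment]
        ordered.append(rec)
    return ordered


def place_amide_hydrogens(frame: Frame, topo: DimerTopology | None = None) -> Frame:
    """Return a frame with backbone amide hydrogens added where missing.

    For each non-N-terminal residue the H is placed 1.01 A from N along the
    unit bisector opposing the C(prev)->N and CA->N directions.  Existing H
    atoms are left untouched.
    """
    chains = topo.chain_ids if topo is not None else sorted(
        {a.chain_id for a in frame.atoms if a.name == "CA"}
    )
    new_atoms = list(frame.atoms)
    for chain in chains:
        residues = _backbone_by_residue(frame, chain)
        for k, res in enumerate(residues):
            for nm in ("N", "CA", "C", "O"):
                if nm not in res:
                    raise ValueError(
                        f"chain {chain} residue {res['_index']}: missing backbone atom {nm}"
                    )
        for k in range(1, len(residues)):
            res = residues[k]
            if "H" in res:
                continue
            n_pos = res["N"]
            h_pos = _amide_h_position(residues[k - 1]["C"], n_pos, res["CA"])
            new_atoms.append(Atom(
                name="H", element="H", residue_index=int(res["_index"]),  # type: ignore[arg-type]
                residue_name=str(res["_resname"]), chain_id=chain, position=h_pos,
            ))
    return Frame(atoms=new_atoms, box=frame.box.copy(), time=frame.time)


def _amide_h_position(c_prev: np.ndarray, n: np.ndarray, ca: np.ndarray) -> np.ndarray:
    u = n - c_prev
    u = u / np.linalg.norm(u)
    v = n - ca
    v = v / np.linalg.norm(v)
    b = u + v
    b = b / np.linalg.norm(b)
    return n + NH_BOND_LENGTH * b


def hbond_energy(donor_res: dict[str, np.ndarray],
                 acceptor_res: dict[str, np.ndarray]) -> float:
    """Electrostatic H-bond energy (kcal/mol) of donor N-H vs acceptor C=O."""
    N, H = donor_res["N"], donor_res["H"]
    C, O = acceptor_res["C"], acceptor_res["O"]
    r_on = np.linalg.norm(O - N)
    r_ch = np.linalg.norm(C - H)
    r_oh = np.linalg.norm(O - H)
    r_cn = np.linalg.norm(C - N)
    if min(r_on, r_ch, r_oh, r_cn) < MIN_DISTANCE:
        raise ClashError("donor/acceptor atoms closer than 0.5 A")
    return float(Q_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def _turn4(residues: list[dict[str, np.ndarray]]) -> np.ndarray:
    """turn4[i] is True when CO(i) accepts an H-bond from NH(i+4)."""
    n = len(residues)
    turns = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        donor = residues[i + 4]
        if str(donor.get("_resname")) == "PRO" or "H" not in donor:
            continue  # prolines (and chain N-termini) cannot donate
        try:
            e = hbond_energy(donor, residues[i])
        except ClashError:
            continue  # clashing geometry in a distorted frame: no bond
        turns[i] = e < HBOND_CUTOFF
    return turns


def assign_alpha(frame: Frame, chain: str) -> np.ndarray:
    """Boolean per-residue alpha-helix assignment for one chain.

    A residue is 'H' when covered by two consecutive i -> i+4 turns, i.e.
    residues i..i+3 are marked whenever turn4(i-1) and turn4(i) both hold.
    Runs are therefore always at least 4 residues long.
    """
    prepared = place_amide_hydrogens(frame)
    residues = _backbone_by_residue(prepared, chain)
    turns = _turn4(residues)
    n = len(residues)
    helix = np.zeros(n, dtype=bool)
    for i in range(1, n):
        if turns[i - 1] and i < len(turns) and turns[i]:
            helix[i:i + 4] = True
    return helix


def helicity_series(traj: Trajectory, topo: DimerTopology) -> HelicitySeries:
    """Per-chain helical fraction for every frame, reported separately per chain."""
    chain_ids = list(topo.chain_ids)
    fractions: dict[str, list[float]] = {c: [] for c in chain_ids}
    assigns: dict[str, list[np.ndarray]] = {c: [] for c in chain_ids}
    for frame in traj.frames:
        prepared = place_amide_hydrogens(frame, topo)
        for chain in chain_ids:
            residues = _backbone_by_residue(prepared, chain)
            turns = _turn4(residues)
            n = len(residues)
            helix = np.zeros(n, dtype=bool)
            for i in range(1, n):
                if turns[i - 1] and i < len(turns) and turns[i]:
                    helix[i:i + 4] = True
            fractions[chain].append(helix.sum() / n)
            assigns[chain].append(helix)
    return HelicitySeries(
        chain_ids=chain_ids,
        fractions={c: np.asarray(v) for c, v in fractions.items()},
        assignments={c: np.asarray(v) for c, v in assigns.items()},
    )
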