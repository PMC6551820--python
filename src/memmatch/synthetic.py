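"""Synthetic ground-truth generators: ideal helical dimers in planar
pseudo-bilayers with configurable tilt, crossing angle, thickness, Gaussian
dent and thermal noise, plus plate-style fluorescence assay tables.

The generator validates estimators; it does not simulate membrane physics.
Noise is i.i.d. isotropic Gaussian per atom per frame, drawn from numpy's
PCG64 generator so that a fixed seed reproduces ensembles bit-identically.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._elements import mass_of
from .structure import (Atom, DimerTopology, Frame, ONE_TO_THREE, Trajectory,
                        find_motif)

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "build_ideal_helix",
    "build_extended_chain",
    "build_dimer_frame",
    "generate_trajectory",
    "generate_assay_table",
    "chimera_sequence",
    "RNG_ALGORITHM",
]

RNG_ALGORITHM = "numpy.random.PCG64"

# Backbone torsions and N-CA-C angle solved so the helix has exactly
# 1.5 A rise and 100 deg twist per residue with standard bond geometry.
PHI_DEG = -63.55927665
PSI_DEG = -41.43295193
N_CA_C_DEG = 109.74592519

BOND = {"N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231}
ANGLE = {"CA_C_N": 116.2, "C_N_CA": 121.7, "CA_C_O": 120.8}

AREA_PER_LIPID = 68.0  # Angstrom^2, typical fluid-phase phosphatidylcholine


@dataclass(frozen=True)
class SyntheticConfig:
    sequence_a: str
    sequence_b: str
    tilt_deg: float = 0.0
    crossing_deg: float = 0.0
    inter_axial_distance: float = 7.0
    bulk_pp_thickness: float = 38.7
    bulk_hydrophobic_thickness: float = 27.4
    lipids_per_leaflet: int = 200
    dent_amplitude: float = 0.0
    dent_sigma: float = 10.0
    noise_sigma: float = 0.0
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bulk_pp_thickness <= 0 or self.bulk_hydrophobic_thickness <= 0:
            raise ValueError("thicknesses must be positive")
        if self.bulk_hydrophobic_thickness >= self.bulk_pp_thickness:
            raise ValueError("hydrophobic thickness must be below P-P thickness")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0 or self.dent_sigma <= 0:
            raise ValueError("sigmas must be non-negative (dent_sigma positive)")
        if self.lipids_per_leaflet < 4:
            raise ValueError("need at least 4 lipids per leaflet")


@dataclass
class SyntheticGroundTruth:
    config: SyntheticConfig
    topology: DimerTopology
    box: np.ndarray
    dent_center: np.ndarray        # lateral (x, y)
    midplane_z: float
    rng_algorithm: str = RNG_ALGORITHM

    def expected_pp_thickness(self, x: float, y: float) -> float:
        """Closed-form P-P thickness at lateral position (x, y)."""
        cfg = self.config
        r2 = self._periodic_r2(x, y)
        return cfg.bulk_pp_thickness + cfg.dent_amplitude * math.exp(
            -r2 / (2.0 * cfg.dent_sigma ** 2))

    def expected_hydrophobic_thickness(self, x: float, y: float) -> float:
        cfg = self.config
        r2 = self._periodic_r2(x, y)
        return cfg.bulk_hydrophobic_thickness + cfg.dent_amplitude * math.exp(
            -r2 / (2.0 * cfg.dent_sigma ** 2))

    def _periodic_r2(self, x: float, y: float) -> float:
        Lx, Ly = self.box[0], self.box[1]
        dx = abs((x - self.dent_center[0]) % Lx)
        dx = min(dx, Lx - dx)
        dy = abs((y - self.dent_center[1]) % Ly)
        dy = min(dy, Ly - dy)
        return dx * dx + dy * dy


# ----------------------------------------------------------------------------
# Ideal chain construction
# ----------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom d bonded to c with internal coordinates."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(n_res: int, phi: float, psi: float,
                    ncac: float) -> list[dict[str, np.ndarray]]:
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND["N_CA"], 0.0, 0.0])
    ang = math.radians(ncac)
    C = CA + np.array([-BOND["CA_C"] * math.cos(ang),
                       BOND["CA_C"] * math.sin(ang), 0.0])
    res = [{"N": N, "CA": CA, "C": C}]
    for _ in range(1, n_res):
        prev = res[-1]
        Np = _place_atom(prev["N"], prev["CA"], prev["C"], BOND["C_N"],
                         ANGLE["CA_C_N"], psi)
        CAp = _place_atom(prev["CA"], prev["C"], Np, BOND["N_CA"],
                          ANGLE["C_N_CA"], 180.0)
        Cp = _place_atom(prev["C"], Np, CAp, BOND["CA_C"], ncac, phi)
        res.append({"N": Np, "CA": CAp, "C": Cp})
    for r in res:
        r["O"] = _place_atom(r["N"], r["CA"], r["C"], BOND["C_O"],
                             ANGLE["CA_C_O"], psi + 180.0)
    return res


def _align_axis_to_z(residues: list[dict[str, np.ndarray]]) -> None:
    """Rotate/translate the chain so its screw axis is +z (N->C term upward)
    and the CA centroid sits at the origin."""
    from scipy.spatial.transform import Rotation

    P = np.array([residues[0]["N"], residues[0]["CA"], residues[0]["C"]])
    Q = np.array([residues[1]["N"], residues[1]["CA"], residues[1]["C"]])
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    R, _ = Rotation.align_vectors(Q - Qc, P - Pc)
    rv = R.as_rotvec()
    axis = rv / np.linalg.norm(rv)
    term_dir = residues[-1]["CA"] - residues[0]["CA"]
    if np.dot(axis, term_dir) < 0:
        axis = -axis
    rot, _ = Rotation.align_vectors(np.array([[0.0, 0.0, 1.0]]),
                                    axis[None, :])
    Rm = rot.as_matrix()
    for r in residues:
        for k in ("N", "CA", "C", "O"):
            r[k] = Rm @ r[k]
    centroid = np.mean([r["CA"] for r in residues], axis=0)
    for r in residues:
        for k in ("N", "CA", "C", "O"):
            r[k] = r[k] - centroid


def _chain_atoms(sequence: str, residues: list[dict[str, np.ndarray]],
                 chain_id: str) -> list[Atom]:
    atoms = []
    for i, (letter, r) in enumerate(zip(sequence, residues)):
        try:
            resname = ONE_TO_THREE[letter]
        except KeyError as exc:
            raise ValueError(f"unknown residue letter {letter!r}") from exc
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(Atom(name=name, element=element, residue_index=i,
                              residue_name=resname, chain_id=chain_id,
                              position=r[name].copy()))
    return atoms


def build_ideal_helix(sequence: str, chain_id: str = "A") -> list[Atom]:
    """Backbone (N, CA, C, O) of an ideal alpha helix along +z, centered at origin.

    CA atoms lie on a helix with exactly 1.5 A rise and 100 deg twist per
    residue; bond lengths/angles follow standard backbone geometry.
    """
    if len(sequence) < 4:
        raise ValueError("sequence must have at least 4 residues")
    residues = _build_backbone(len(sequence), PHI_DEG, PSI_DEG, N_CA_C_DEG)
    _align_axis_to_z(residues)
    return _chain_atoms(sequence, residues, chain_id)


def build_extended_chain(sequence: str, chain_id: str = "A") -> list[Atom]:
    """Backbone of a fully extended (phi = psi = 180 deg) chain along +z."""
    if len(sequence) < 4:
        raise ValueError("sequence must have at least 4 residues")
    residues = _build_backbone(len(sequence), 180.0, 180.0, N_CA_C_DEG)
    _align_axis_to_z(residues)
    return _chain_atoms(sequence, residues, chain_id)


def chimera_sequence(n_hydrophobic: int, flank: str = "KK") -> str:
    """A chimeric TM sequence: hydrophobic core of given length containing a
    centered GVLLGVLLT dimerization motif, padded with leucines, with charged
    flanks on both ends."""
    if n_hydrophobic < 9:
        raise ValueError("hydrophobic core must hold the 9-residue motif")
    pad = n_hydrophobic - 9
    left = pad // 2
    right = pad - left
    return flank + "L" * left + "GVLLGVLLT" + "L" * right + flank


def _rotation(axis: str, angle_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def _motif_vector_alignment(atoms: list[Atom], topo: DimerTopology) -> np.ndarray:
    """Rotation matrix mapping the pooled motif top-bottom vector onto +z."""
    from .geometry import motif_flank_selection

    above = motif_flank_selection(topo, "above")
    below = motif_flank_selection(topo, "below")
    coms = {}
    for side, sel in (("above", above), ("below", below)):
        wsum = 0.0
        acc = np.zeros(3)
        for a in atoms:
            if a.chain_id in sel and a.residue_index in sel[a.chain_id]:
                acc += a.mass * a.position
                wsum += a.mass
        coms[side] = acc / wsum
    v = coms["above"] - coms["below"]
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    c = float(np.dot(v, z))
    if s < 1e-12:
        return np.eye(3) if c > 0 else _rotation("x", 180.0)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def build_dimer_frame(cfg: SyntheticConfig) -> tuple[Frame, SyntheticGroundTruth]:
    """One frame: the helical dimer inside a planar two-leaflet marker bilayer.

    The two helices are rotated +-crossing/2 about the inter-axial (x) axis,
    separated along x, then rigidly tilted about y; the bilayer consists of
    one P and two chain-alpha-carbon pseudo-atoms per lipid on a lateral
    lattice, each surface displaced by a radial Gaussian dent centered on the
    dimer's lateral position.
    """
    seq_a, seq_b = cfg.sequence_a, cfg.sequence_b
    topo = DimerTopology(
        chain_a_id="A", chain_b_id="B", sequence_a=seq_a, sequence_b=seq_b,
        motif_start_a=find_motif(seq_a), motif_start_b=find_motif(seq_b),
    )
    helix_a = build_ideal_helix(seq_a, "A")
    helix_b = build_ideal_helix(seq_b, "B")

    n_lip = cfg.lipids_per_leaflet
    L = math.sqrt(n_lip * AREA_PER_LIPID)
    if cfg.inter_axial_distance + 10.0 > L:
        raise ValueError("bilayer box too small to hold the dimer")
    helix_extent = 1.5 * max(len(seq_a), len(seq_b))
    box_z = max(cfg.bulk_pp_thickness + 30.0, helix_extent + 20.0)
    mid_z = box_z / 2.0
    center = np.array([L / 2.0, L / 2.0])

    rot_a = _rotation("x", +cfg.crossing_deg / 2.0)
    rot_b = _rotation("x", -cfg.crossing_deg / 2.0)
    half = cfg.inter_axial_distance / 2.0
    atoms: list[Atom] = []
    for helix, rot, xoff in ((helix_a, rot_a, -half), (helix_b, rot_b, +half)):
        for a in helix:
            p = rot @ a.position + np.array([xoff, 0.0, 0.0])
            atoms.append(replace(a, position=p))
    # The flank-residue COMs sit slightly off the helix axes, so the motif
    # top-bottom vector is not exactly +z; align it before tilting so the
    # configured tilt is the ground truth of the tilt estimator.
    align = _motif_vector_alignment(atoms, topo)
    tilt = _rotation("y", cfg.tilt_deg) @ align
    offset = np.array([center[0], center[1], mid_z])
    for a in atoms:
        a.position = tilt @ a.position + offset

    # lipid marker lattice
    n_side = math.ceil(math.sqrt(n_lip))
    pitch = L / n_side
    sites = []
    for iy in range(n_side):
        for ix in range(n_side):
            if len(sites) < n_lip:
                sites.append(((ix + 0.5) * pitch, (iy + 0.5) * pitch))
    amp2 = cfg.dent_amplitude / 2.0
    sig2 = 2.0 * cfg.dent_sigma ** 2
    lipid_index = 0
    for leaflet_sign in (+1, -1):
        for (x, y) in sites:
            dx = abs(x - center[0]) % L
            dx = min(dx, L - dx)
            dy = abs(y - center[1]) % L
            dy = min(dy, L - dy)
            g = math.exp(-(dx * dx + dy * dy) / sig2)
            zp = mid_z + leaflet_sign * (cfg.bulk_pp_thickness / 2.0 + amp2 * g)
            zc = mid_z + leaflet_sign * (cfg.bulk_hydrophobic_thickness / 2.0 + amp2 * g)
            for name, element, z in (("P", "P", zp), ("C22", "C", zc), ("C32", "C", zc)):
                atoms.append(Atom(name=name, element=element,
                                  residue_index=lipid_index, residue_name="LIP",
                                  chain_id="M", position=np.array([x, y, z]),
                                  mass=mass_of(element)))
            lipid_index += 1

    frame = Frame(atoms=atoms, box=np.array([L, L, box_z]), time=0.0)
    truth = SyntheticGroundTruth(config=cfg, topology=topo,
                                 box=frame.box.copy(), dent_center=center,
                                 midplane_z=mid_z)
    return frame, truth


def generate_trajectory(cfg: SyntheticConfig, tilt_schedule=None,
                        noise_schedule=None) -> tuple[Trajectory, SyntheticGroundTruth]:
    """n_frames noisy copies of the base dimer frame, deterministic under seed.

    Optional per-frame schedules override the config tilt or noise sigma: each
    may be a (start, end) pair (linear ramp) or an array of length n_frames.
    """
    tilts = _schedule(tilt_schedule, cfg.tilt_deg, cfg.n_frames)
    noises = _schedule(noise_schedule, cfg.noise_sigma, cfg.n_frames)
    if np.any(noises < 0):
        raise ValueError("noise sigma must be non-negative")
    rng = np.random.default_rng(cfg.seed)
    base_frame, truth = build_dimer_frame(cfg)
    frames = []
    rebuild = tilt_schedule is not None
    for i in range(cfg.n_frames):
        if rebuild:
            fr, _ = build_dimer_frame(replace(cfg, tilt_deg=float(tilts[i])))
        else:
            fr = base_frame
        pos = fr.positions
        if noises[i] > 0:
            pos = pos + rng.normal(0.0, noises[i], size=pos.shape)
        frames.append(base_frame.with_positions(pos, time=float(i)))
    return Trajectory(frames=frames), truth


def _schedule(spec, default: float, n: int) -> np.ndarray:
    if spec is None:
        return np.full(n, float(default))
    arr = np.asarray(spec, dtype=float)
    if arr.shape == (2,) and n != 2:
        return np.linspace(arr[0], arr[1], n)
    if arr.shape == (n,):
        return arr
    raise ValueError("schedule must be a (start, end) pair or length n_frames")


# ----------------------------------------------------------------------------
# Assay plate generator
# ----------------------------------------------------------------------------

def generate_assay_table(design, effects, n_replicates: int = 4, cv: float = 0.1,
                         seed: int = 0, n_batches: int = 1,
                         normalizer_median: float = 1.0,
                         normalizer_cv: float = 0.2) -> pd.DataFrame:
    """Long-format synthetic fluorescence table.

    Parameters
    ----------
    design : list of (construct_n, construct_c) pairs
    effects : per-pair mean relative fluorescence (list aligned with design,
        or dict keyed by pair)
    cv : multiplicative lognormal noise on the raw signal
    normalizer_median, normalizer_cv : lognormal parameters of the per-record
        normalizer (OD600 or luciferase counts)

    Raw signal = effect * normalizer * LogNormal(0, cv), so normalized values
    equal the configured effect exactly when cv = 0.
    """
    if isinstance(effects, dict):
        eff = [effects[pair] for pair in design]
    else:
        eff = list(effects)
    if len(eff) != len(design):
        raise ValueError("effects must align with design")
    if any(e <= 0 for e in eff):
        raise ValueError("effects must be positive")
    if not 0.0 <= cv < 1.0:
        raise ValueError("cv must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records = []
    for b in range(n_batches):
        for (cn, cc), e in zip(design, eff):
            for r in range(n_replicates):
                normalizer = normalizer_median * rng.lognormal(0.0, normalizer_cv)
                noise = rng.lognormal(0.0, cv) if cv > 0 else 1.0
                records.append({
                    "construct_n": cn, "construct_c": cc,
                    "replicate": f"r{r}", "batch": f"b{b}",
                    "raw_fluorescence": e * normalizer * noise,
                    "normalizer": normalizer,
                })
    return pd.DataFrame.from_records(records)
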