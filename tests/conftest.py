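import numpy as np
import pytest

from memmatch import synthetic
from memmatch.structure import Atom, DimerTopology, Frame, Trajectory


@pytest.fixture(scope="session")
def seq23() -> str:
    return synthetic.chimera_sequence(23)


@pytest.fixture(scope="session")
def topo23(seq23) -> DimerTopology:
    from memmatch.structure import find_motif
    m = find_motif(seq23)
    return DimerTopology(chain_a_id="A", chain_b_id="B", sequence_a=seq23,
                         sequence_b=seq23, motif_start_a=m, motif_start_b=m)


@pytest.fixture(scope="session")
def base_cfg(seq23) -> synthetic.SyntheticConfig:
    return synthetic.SyntheticConfig(sequence_a=seq23, sequence_b=seq23)


@pytest.fixture()
def dimer_frame(base_cfg):
    frame, truth = synthetic.build_dimer_frame(base_cfg)
    return frame, truth


def line_chain(chain_id: str, n_res: int, origin, direction, rise: float = 1.5,
               name: str = "CA") -> list[Atom]:
    """Degenerate 'helix': one CA per residue on a straight line (exact vectors)."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    return [
        Atom(name=name, element="C", residue_index=i, residue_name="LEU",
             chain_id=chain_id, position=origin + i * rise * direction)
        for i in range(n_res)
    ]


def make_frame(atoms, box=(200.0, 200.0, 200.0), time=0.0) -> Frame:
    return Frame(atoms=list(atoms), box=np.asarray(box, dtype=float), time=time)


def make_traj(frames) -> Trajectory:
    return Trajectory(frames=list(frames))


@pytest.fixture(scope="session")
def line_topology() -> DimerTopology:
    seq = "LLLL" + "LLL" + "GVLLGVLLT" + "LLL" + "LLLL"  # motif at 7, len 23
    return DimerTopology(chain_a_id="A", chain_b_id="B", sequence_a=seq,
                         sequence_b=seq, motif_start_a=7, motif_start_b=7)
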