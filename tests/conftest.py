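import numpy as np
import pytest

from modesteer import anm, synthgen


@pytest.fixture(scope="session")
def bundle():
    """Canonical 3x20 Cα helix bundle."""
    return synthgen.make_helix_bundle(synthgen.BundleSpec())


@pytest.fixture(scope="session")
def bundle_allatom():
    return synthgen.make_helix_bundle(synthgen.BundleSpec(all_atom=True))


@pytest.fixture(scope="session")
def bundle_modes(bundle):
    net = anm.build_network(bundle)
    return anm.compute_modes(net)


def random_connected_coords(rng: np.random.Generator, n: int,
                            cutoff: float = 12.0) -> np.ndarray:
    """Random 3-D points forming a connected, rigid network at the given
    cutoff: uniform in a box of side ~cutoff, so the contact graph is
    dense and mechanism-free."""
    return rng.uniform(0.0, cutoff, (n, 3))


def write_pdb_text(path, text: str) -> str:
    path.write_text(text)
    return str(path)


def pdb_atom_line(serial: int, name: str, res_name: str, res_id: int,
                  x: float, y: float, z: float, chain: str = "A",
                  alt: str = " ", occ: float = 1.0) -> str:
    element = name[0]
    return (f"ATOM  {serial:>5} {name:<4}{alt}{res_name:<3} {chain}{res_id:>4}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          "
            f"{element:>2}\n")
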