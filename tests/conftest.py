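import numpy as np
import pytest

from ppaffinity.structures import AtomRecord, ComplexEntry

# pools used to build random two-chain complexes for oracle comparisons
ATOM_POOL = [
    ("N", "N", "GLY"),
    ("CA", "C", "GLY"),
    ("C", "C", "GLY"),
    ("O", "O", "GLY"),
    ("CB", "C", "ALA"),
    ("CD1", "C", "ILE"),
    ("SG", "S", "CYS"),
    ("NZ", "N", "LYS"),
    ("OD1", "O", "ASP"),
    ("OE1", "O", "GLU"),
]


def random_entry(
    rng: np.random.Generator,
    n_per_chain: int = 50,
    box: float = 15.0,
    complex_id: str = "RND1",
) -> ComplexEntry:
    """Two chains of random atoms in a shared box (dense enough to interact)."""
    atoms = []
    serial = 1
    for chain in ("A", "B"):
        for i in range(n_per_chain):
            name, element, resname = ATOM_POOL[rng.integers(0, len(ATOM_POOL))]
            x, y, z = rng.uniform(0, box, 3)
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=name,
                    element=element,
                    residue_name=resname,
                    residue_seq=i + 1,
                    chain_id=chain,
                    x=float(x),
                    y=float(y),
                    z=float(z),
                )
            )
            serial += 1
    return ComplexEntry(
        complex_id=complex_id,
        receptor_chains=frozenset({"A"}),
        ligand_chains=frozenset({"B"}),
        atoms=atoms,
    )


def two_atom_entry(distance: float) -> ComplexEntry:
    """A minimal dimer: one carbon per chain, ``distance`` Angstrom apart."""
    return ComplexEntry(
        complex_id="PAIR",
        receptor_chains=frozenset({"A"}),
        ligand_chains=frozenset({"B"}),
        atoms=[
            AtomRecord(1, "CA", "C", "GLY", 1, "A", 0.0, 0.0, 0.0),
            AtomRecord(2, "CA", "C", "GLY", 1, "B", distance, 0.0, 0.0),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20170323)
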