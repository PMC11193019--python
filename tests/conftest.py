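import numpy as np
import pytest

from presteady.kinetics import asct2_default_scheme
from presteady.model_io import AtomicModel, AtomRecord


@pytest.fixture(scope="session")
def default_scheme():
    """The calibrated 6-state exchanger scheme (calibration is deterministic)."""
    return asct2_default_scheme()


@pytest.fixture()
def toy_pqr(tmp_path):
    """Three-atom whitespace-delimited PQR file with net charge zero."""
    path = tmp_path / "toy.pqr"
    path.write_text(
        "REMARK toy fixture\n"
        "ATOM      1 N    LIG A   1     0.000   0.000   1.000   0.5000 1.5000\n"
        "ATOM      2 O    LIG A   1     0.000   0.000  -1.000  -0.5000 1.4000\n"
        "HETATM    3 C    LIG A   1     1.000   0.000   0.000   0.0000 1.7000\n"
        "END\n"
    )
    return path


@pytest.fixture()
def zwitterion_complex():
    """10 'protein' atoms plus a 3-atom zwitterionic ligand (net 0)."""
    rng = np.random.default_rng(7)
    protein = [
        AtomRecord(name=f"CA{i}", residue="ALA", chain="A", residue_number=i,
                   position=tuple(rng.uniform(-5, 5, 3)), charge=0.0, radius=2.0)
        for i in range(10)
    ]
    ligand = [
        AtomRecord(name="N", residue="LIG", chain="B", residue_number=99,
                   position=(0.0, 0.0, 2.0), charge=1.0, radius=1.5),
        AtomRecord(name="OXT", residue="LIG", chain="B", residue_number=99,
                   position=(0.0, 0.0, -2.0), charge=-1.0, radius=1.4),
        AtomRecord(name="CB", residue="LIG", chain="B", residue_number=99,
                   position=(1.0, 0.0, 0.0), charge=0.0, radius=1.7),
    ]
    return AtomicModel(atoms=tuple(protein + ligand))
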