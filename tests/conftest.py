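import numpy as np
import pytest

from gridqsar import dataset, pipeline
from gridqsar.config import RunConfig
from gridqsar.molecule import COMSIA_PROPS, Molecule3D


@pytest.fixture(scope="session")
def records():
    return dataset.load_table()


@pytest.fixture(scope="session")
def aligned_series(records):
    """Single-conformer series, embedded and aligned (for alignment tests)."""
    cfg = RunConfig()
    mols = dataset.build_series(records, seed=cfg.seed)
    from gridqsar import alignment

    aligned, core_map = alignment.align_series(mols, reference_id=cfg.reference_id)
    return aligned, core_map


@pytest.fixture(scope="session")
def aligned_ensembles(records):
    """Template-based conformer ensembles, aligned (the modelling input)."""
    _, ensembles, reference = pipeline.build_aligned_series(RunConfig())
    return ensembles, reference


@pytest.fixture(scope="session")
def comsia_result(records, aligned_ensembles):
    ensembles, _ = aligned_ensembles
    return pipeline.run_real_model(records, ensembles, RunConfig(), family="comsia")


def point_molecule(
    positions, s=None, e=None, h=None, d=None, a=None, charges=None, radii=None, cid=1
):
    """Toy molecule of bare interaction sites with explicit property values."""
    positions = np.atleast_2d(np.asarray(positions, float))
    n = positions.shape[0]

    def arr(x, default):
        if x is None:
            return np.full(n, default, float)
        return np.asarray(x, float)

    radii_arr = arr(radii, 1.7)
    return Molecule3D(
        compound_id=cid,
        elements=["X"] * n,
        coords=positions,
        charges=arr(charges, 0.0),
        vdw_radii=radii_arr,
        props={
            "S": arr(s, 1.0),
            "E": arr(e, 0.0),
            "H": arr(h, 0.0),
            "D": arr(d, 0.0),
            "A": arr(a, 0.0),
        },
        core_atom_indices=list(range(n)),
    )


@pytest.fixture
def toy_molecule():
    return point_molecule
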