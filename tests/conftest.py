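import numpy as np
import pytest

from potts_surrogate import CPMParams, DiffusionField
from potts_surrogate.lattice import (
    LatticeState,
    recount_surfaces,
    recount_volumes,
)


@pytest.fixture
def small_params():
    return CPMParams(lattice_size=16, v_target=4)


def random_state(rng: np.random.Generator, size: int, max_id: int,
                 params: CPMParams) -> LatticeState:
    """A random (not physically relaxed) lattice with consistent bookkeeping."""
    cell_id = rng.integers(0, max_id + 1, size=(size, size)).astype(np.int64)
    return LatticeState(
        cell_id=cell_id,
        volumes=recount_volumes(cell_id, max_id=max_id),
        surfaces=recount_surfaces(cell_id, params.contact_neighborhood,
                                  max_id=max_id),
        rng=rng,
        params=params,
    )


def random_field(rng: np.random.Generator, size: int) -> DiffusionField:
    return DiffusionField(conc=rng.random((size, size)))


@pytest.fixture(scope="session")
def toy_models():
    """Shared toy end-to-end artefacts: 2-class procedural data, trained
    verification classifier and trained diffusion surrogate."""
    from potts_surrogate.ddpm import ConditionalDiffusionSurrogate
    from potts_surrogate.toy import toy_dataset
    from potts_surrogate.verify import SnapshotClassifier

    X, y = toy_dataset(n_per_class=500, size=32, seed=0)
    clf = SnapshotClassifier(epochs=10, random_state=0).fit(X, y)
    surrogate = ConditionalDiffusionSurrogate(random_state=0).fit(X, y)
    return {"X": X, "y": y, "classifier": clf, "surrogate": surrogate}
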