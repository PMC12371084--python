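import numpy as np
import pytest

from v0scape.synthetic import (
    GeneratorConfig,
    canonical_alignment_reference,
    generate_ensemble,
)
from v0scape.trajio import kabsch_align, select_atoms


@pytest.fixture(scope="session")
def default_ensemble():
    """The default synthetic ensemble (fixed seed) with its ground truth."""
    return generate_ensemble(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def aligned_default(default_ensemble):
    """Default ensemble with global rigid motion removed (canonical frame)."""
    ens, truth = default_ensemble
    calpha = select_atoms(ens.topology, "calpha", require_nonempty=True)
    aligned, _ = kabsch_align(
        ens, canonical_alignment_reference(ens.topology), calpha
    )
    return aligned, truth, calpha


@pytest.fixture(scope="session")
def small_clean_ensemble():
    """Small, noise-free, motion-free ensemble: planted states are exact."""
    return generate_ensemble(
        GeneratorConfig(
            n_frames=40, noise_sigma=0.0, global_motion=False, seed=3
        )
    )


def make_blob_embedding(seed=0, n_per=120, spread=0.05):
    """Four tight, well-separated 2D Gaussian blobs with labels."""
    from v0scape.autoencoder import Embedding

    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    Z = np.concatenate(
        [c + spread * rng.normal(size=(n_per, 2)) for c in centers]
    )
    labels = np.repeat(np.arange(4), n_per)
    perm = rng.permutation(len(Z))
    emb = Embedding(latent=Z[perm], is_train=np.zeros(len(Z), dtype=bool))
    return emb, labels[perm]
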