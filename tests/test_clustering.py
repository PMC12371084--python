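import numpy as np
import pytest

from conftest import make_blob_embedding
from v0scape.autoencoder import Embedding
from v0scape.clustering import (
    AmbiguousIdentificationError,
    ClusterAssignment,
    MixtureModel,
    ParameterError,
    assign_clusters,
    cluster_populations,
    fit_bgmm,
    functional_order,
    identify_assembly_cluster,
)


def embedding_of(Z):
    return Embedding(latent=np.asarray(Z, float),
                     is_train=np.zeros(len(Z), dtype=bool))


def test_single_blob_collapses_to_one_component():
    rng = np.random.default_rng(0)
    emb = embedding_of(rng.normal(0, 0.05, (300, 2)))
    model = fit_bgmm(emb, k_max=9, seed=1)
    assert model.n_effective == 1


def test_four_planted_blobs_recovered_with_right_count():
    emb, labels = make_blob_embedding(seed=3)
    model = fit_bgmm(emb, k_max=9, seed=2)
    assert model.n_effective == 4
    from sklearn.metrics import adjusted_rand_score

    assignment = assign_clusters(model, emb)
    assert adjusted_rand_score(labels, assignment.labels) >= 0.99


def test_fit_is_seed_deterministic():
    emb, _ = make_blob_embedding(seed=5)
    w1 = fit_bgmm(emb, k_max=9, seed=7).weights
    w2 = fit_bgmm(emb, k_max=9, seed=7).weights
    assert np.allclose(w1, w2, atol=1e-12)


def symmetric_two_component_model(d=3.0):
    cov = np.array([[[0.5, 0.0], [0.0, 0.5]]] * 2)
    return MixtureModel(
        weights=np.array([0.5, 0.5]),
        means=np.array([[-d, 0.0], [d, 0.0]]),
        covariances=cov,
    )


def test_point_at_component_mean_dominates():
    model = symmetric_two_component_model()
    a = assign_clusters(model, embedding_of([[-3.0, 0.0]]))
    assert a.responsibilities[0, 0] > 0.99
    assert not a.boundary[0]


def test_equidistant_point_sits_on_decision_boundary():
    model = symmetric_two_component_model()
    a = assign_clusters(model, embedding_of([[0.0, 0.0], [0.0, 5.0]]))
    assert np.allclose(a.responsibilities[0], [0.5, 0.5], atol=1e-12)
    assert a.boundary[0] and a.boundary[1]


def test_responsibilities_normalize_per_frame():
    emb, _ = make_blob_embedding(seed=11)
    model = fit_bgmm(emb, k_max=9, seed=4)
    a = assign_clusters(model, emb)
    assert np.allclose(a.responsibilities.sum(axis=1), 1.0, atol=1e-9)


def test_representatives_carry_their_clusters_majority_label():
    emb, labels = make_blob_embedding(seed=13)
    model = fit_bgmm(emb, k_max=9, seed=4)
    a = assign_clusters(model, emb)
    for c, frame in enumerate(a.representative_frames):
        members = labels[a.labels == c]
        majority = np.bincount(members).argmax()
        assert labels[frame] == majority


def test_dimension_mismatch_rejected():
    model = symmetric_two_component_model()
    with pytest.raises(ParameterError):
        assign_clusters(model, embedding_of(np.zeros((4, 3))))


def test_too_few_frames_rejected():
    with pytest.raises(ParameterError):
        fit_bgmm(embedding_of(np.zeros((20, 2))), k_max=9)


def test_effective_count_non_increasing_in_threshold():
    emb, _ = make_blob_embedding(seed=17)
    model = fit_bgmm(emb, k_max=9, seed=5)
    counts = []
    for thr in (0.0, 0.01, 0.02, 0.1, 0.3):
        model.weight_threshold = thr
        counts.append(model.n_effective)
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# -- populations ------------------------------------------------------------

def assignment_from_labels(labels, n_clusters):
    labels = np.asarray(labels)
    return ClusterAssignment(
        responsibilities=np.eye(n_clusters)[labels],
        labels=labels,
        boundary=np.zeros(len(labels), dtype=bool),
        representative_frames=np.arange(n_clusters),
        component_ids=np.arange(n_clusters),
        latent=np.zeros((len(labels), 2)),
    )


def test_single_cluster_population_is_one():
    a = assignment_from_labels([0, 0, 0], 1)
    table = cluster_populations(a, ["X"] * 3)
    assert table.loc["X", "cluster_0"] == 1.0


def test_populations_sum_to_one_per_composition():
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 4, 200)
    comps = np.repeat(["A", "B"], 100)
    table = cluster_populations(assignment_from_labels(labels, 4), comps)
    assert np.allclose(table.sum(axis=1), 1.0, atol=1e-9)


def test_populations_invariant_to_frame_order():
    rng = np.random.default_rng(3)
    labels = rng.integers(0, 3, 150)
    comps = rng.choice(["A", "B"], 150)
    t1 = cluster_populations(assignment_from_labels(labels, 3), comps)
    perm = rng.permutation(150)
    t2 = cluster_populations(
        assignment_from_labels(labels[perm], 3), comps[perm]
    )
    assert np.allclose(t1.sort_index(), t2.sort_index(), atol=1e-12)


def test_planted_weight_recovered_within_binomial_error():
    from v0scape.synthetic import GeneratorConfig, generate_ensemble

    weights = (0.1, 0.3, 0.3, 0.3)
    _, truth = generate_ensemble(
        GeneratorConfig(n_frames=1500, state_weights=weights, seed=31)
    )
    a = assignment_from_labels(truth.state_labels, 4)
    table = cluster_populations(a, ["M"] * 1500)
    se = np.sqrt(0.1 * 0.9 / 1500)
    assert abs(table.loc["M", "cluster_0"] - 0.1) <= 3 * se


def test_unknown_composition_length_errors():
    a = assignment_from_labels([0, 1], 2)
    with pytest.raises(ParameterError):
        cluster_populations(a, ["X"])


# -- assembly-cluster identification ----------------------------------------

def test_fewest_contacts_wins():
    a = assignment_from_labels([0] * 5 + [1] * 5, 2)
    counts = np.array([40.0] * 5 + [0.0] * 5)
    assert identify_assembly_cluster(a, counts) == 1


def test_tie_raises_ambiguity():
    a = assignment_from_labels([0] * 5 + [1] * 5, 2)
    with pytest.raises(AmbiguousIdentificationError):
        identify_assembly_cluster(a, np.ones(10))


def test_identified_frames_invariant_to_cluster_permutation():
    rng = np.random.default_rng(8)
    labels = rng.integers(0, 3, 90)
    counts = np.where(labels == 2, 0.0, 30.0) + rng.normal(0, 0.1, 90)
    a = assignment_from_labels(labels, 3)
    winner = identify_assembly_cluster(a, counts)
    frames = set(np.flatnonzero(labels == winner))

    perm = np.array([2, 0, 1])
    a2 = assignment_from_labels(perm[labels], 3)
    winner2 = identify_assembly_cluster(a2, counts)
    assert set(np.flatnonzero(perm[labels] == winner2)) == frames


def test_functional_order_puts_assembly_cluster_last():
    labels = np.repeat([0, 1, 2], 30)
    counts = np.concatenate([np.full(30, 5.0), np.full(30, 50.0),
                             np.full(30, 0.0)])
    a = assignment_from_labels(labels, 3)
    order = functional_order(a, counts)
    assert order[-1] == identify_assembly_cluster(a, counts) == 2
    assert list(order) == [1, 0, 2]
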