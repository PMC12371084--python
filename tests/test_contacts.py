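import numpy as np
import pytest

from v0scape.contacts import (
    GridConfig,
    SaltBridgePair,
    TopologyError,
    contacts_by_cluster,
    count_contacts,
    occupancy_map,
    salt_bridge_frequency,
)
from v0scape.trajio import (
    AtomSelection,
    Ensemble,
    SelectionError,
    Topology,
    select_atoms,
)


def point_ensemble(coords_per_frame):
    coords = np.asarray(coords_per_frame, dtype=float)
    n = coords.shape[1]
    topo = Topology(
        atom_name=np.array(["CA"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        res_id=np.arange(1, n + 1),
        res_name=np.array(["GLY"] * n, dtype=object),
        chain_id=np.array(["A"] * n, dtype=object),
        region=np.array(["other"] * n, dtype=object),
        is_calpha=np.ones(n, dtype=bool),
    )
    return Ensemble(topology=topo, coords=coords)


def sel(indices, name="sel"):
    return AtomSelection(name=name, indices=np.asarray(indices))


def brute_force_count(a, b, cutoff):
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return int((d <= cutoff).sum())


def test_far_and_near_pairs():
    ens = point_ensemble([[[0, 0, 0], [10, 0, 0]]])
    assert count_contacts(ens, sel([0]), sel([1]), 4.0).counts[0] == 0
    ens2 = point_ensemble([[[0, 0, 0], [3, 0, 0]]])
    assert count_contacts(ens2, sel([0]), sel([1]), 4.0).counts[0] == 1


@pytest.mark.parametrize("seed", range(20))
def test_kdtree_count_equals_all_pairs_oracle(seed):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 20, (3, 100, 3))
    ens = point_ensemble(coords)
    a, b = sel(np.arange(50)), sel(np.arange(50, 100))
    series = count_contacts(ens, a, b, 4.0)
    for f in range(3):
        assert series.counts[f] == brute_force_count(
            coords[f, :50], coords[f, 50:], 4.0
        )


def test_contact_count_symmetric_in_selections():
    rng = np.random.default_rng(1)
    ens = point_ensemble(rng.uniform(0, 15, (4, 60, 3)))
    a, b = sel(np.arange(30)), sel(np.arange(30, 60))
    c1 = count_contacts(ens, a, b, 4.0).counts
    c2 = count_contacts(ens, b, a, 4.0).counts
    assert np.array_equal(c1, c2)


def test_counts_non_decreasing_in_cutoff():
    rng = np.random.default_rng(2)
    ens = point_ensemble(rng.uniform(0, 15, (2, 80, 3)))
    a, b = sel(np.arange(40)), sel(np.arange(40, 80))
    prev = None
    for cutoff in (1.0, 2.0, 4.0, 8.0):
        counts = count_contacts(ens, a, b, cutoff).counts
        if prev is not None:
            assert (counts >= prev).all()
        prev = counts


def test_overlapping_or_empty_selections_rejected():
    ens = point_ensemble(np.zeros((1, 4, 3)))
    with pytest.raises(SelectionError):
        count_contacts(ens, sel([0, 1]), sel([1, 2]), 4.0)
    with pytest.raises(SelectionError):
        count_contacts(ens, sel([]), sel([1]), 4.0)
    with pytest.raises(ValueError):
        count_contacts(ens, sel([0]), sel([1]), -1.0)


def test_aggregation_reduces_to_series_mean():
    rng = np.random.default_rng(3)
    ens = point_ensemble(rng.uniform(0, 10, (6, 40, 3)))
    series = count_contacts(ens, sel(np.arange(20)),
                            sel(np.arange(20, 40)), 4.0)
    table = contacts_by_cluster(series, np.zeros(6, dtype=int))
    assert table.loc[0, "mean"] == series.counts.mean()


def test_aggregates_invariant_to_joint_frame_permutation():
    rng = np.random.default_rng(4)
    ens = point_ensemble(rng.uniform(0, 10, (10, 40, 3)))
    series = count_contacts(ens, sel(np.arange(20)),
                            sel(np.arange(20, 40)), 4.0)
    labels = rng.integers(0, 2, 10)
    t1 = contacts_by_cluster(series, labels)
    perm = rng.permutation(10)
    series.counts = series.counts[perm]
    t2 = contacts_by_cluster(series, labels[perm])
    assert np.allclose(
        t1.sort_values("cluster")[["mean", "sem"]],
        t2.sort_values("cluster")[["mean", "sem"]],
        equal_nan=True,
    )


def test_head_d1_contacts_lowest_in_head_away_state(aligned_default):
    aligned, truth, _ = aligned_default
    head = select_atoms(aligned.topology, "region a2_head")
    d1 = select_atoms(aligned.topology, "region d1")
    series = count_contacts(aligned, head, d1, 4.0)
    means = [series.counts[truth.state_labels == s].mean() for s in range(4)]
    assert np.argmin(means) == 0
    assert means[0] < min(means[1:]) - 0.1


# -- salt bridges -----------------------------------------------------------

def test_planted_bridge_frequencies(small_clean_ensemble):
    ens, truth = small_clean_ensemble
    table = salt_bridge_frequency(ens, cluster_labels=truth.state_labels)
    overall = table[table.cluster == "all"]
    away_frac = (truth.state_labels == 0).mean()
    for _, row in overall.iterrows():
        assert row.frequency == pytest.approx(away_frac)
    state0 = table[table.cluster == 0]
    assert (state0.frequency == 1.0).all()
    docked = table[table.cluster.isin([1, 2, 3])]
    assert (docked.frequency == 0.0).all()


def test_bridge_frequency_extremes():
    n = 4
    topo = Topology(
        atom_name=np.array(["CA", "OE1", "CA", "NH1"], dtype=object),
        element=np.array(["C", "O", "C", "N"], dtype=object),
        res_id=np.array([81, 81, 436, 436]),
        res_name=np.array(["GLU", "GLU", "ARG", "ARG"], dtype=object),
        chain_id=np.array(["A"] * n, dtype=object),
        region=np.array(["a2_arm", "a2_arm", "a2_body", "a2_body"],
                        dtype=object),
        is_calpha=np.array([True, False, True, False]),
    )
    pair = (SaltBridgePair(81, "a2_arm", 436, "a2_body", cutoff=4.0),)
    near = Ensemble(topology=topo, coords=np.array(
        [[[0, 0, 0], [1, 0, 0], [5, 0, 0], [4, 0, 0]]] * 3, dtype=float))
    assert salt_bridge_frequency(near, pair).frequency.iloc[0] == 1.0
    far = Ensemble(topology=topo, coords=np.array(
        [[[0, 0, 0], [0, 0, 0], [8, 0, 0], [8, 0, 0]]] * 3, dtype=float))
    assert salt_bridge_frequency(far, pair).frequency.iloc[0] == 0.0


def test_missing_bridge_residue_errors(small_clean_ensemble):
    ens, _ = small_clean_ensemble
    with pytest.raises(TopologyError):
        salt_bridge_frequency(
            ens, (SaltBridgePair(999, "a2_arm", 436, "a2_body"),)
        )


# -- occupancy maps ---------------------------------------------------------

def lipid_ensemble(positions, species="PI4P", n_frames=1):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    topo = Topology(
        atom_name=np.array(["P"] * n, dtype=object),
        element=np.array(["P"] * n, dtype=object),
        res_id=np.arange(1, n + 1),
        res_name=np.array(["PI4"] * n, dtype=object),
        chain_id=np.array(["L"] * n, dtype=object),
        region=np.array([f"lipid_{species}"] * n, dtype=object),
        is_calpha=np.zeros(n, dtype=bool),
    )
    coords = np.repeat(positions[None], n_frames, axis=0)
    return Ensemble(topology=topo, coords=coords)


def test_single_bead_hits_exactly_one_voxel():
    ens = lipid_ensemble([[3.2, 7.7, 10.0]])
    grid = GridConfig(origin=(0, 0), spacing=1.0, shape=(20, 20),
                      z_range=(0, 20))
    omap = occupancy_map(ens, "PI4P", grid)
    assert omap.counts.sum() == 1
    assert omap.counts[3, 7] == 1


def test_raw_count_conservation_for_static_layout():
    rng = np.random.default_rng(5)
    pos = np.column_stack(
        [rng.uniform(0, 20, 30), rng.uniform(0, 20, 30),
         np.full(30, 5.0)]
    )
    ens = lipid_ensemble(pos, n_frames=7)
    grid = GridConfig(origin=(0, 0), spacing=1.0, shape=(20, 20),
                      z_range=(0, 20))
    omap = occupancy_map(ens, "PI4P", grid)
    in_grid = ((pos[:, 0] >= 0) & (pos[:, 0] < 20)
               & (pos[:, 1] >= 0) & (pos[:, 1] < 20)).sum()
    assert omap.counts.sum() == 7 * in_grid


def test_map_invariant_to_frame_order():
    rng = np.random.default_rng(6)
    coords = rng.uniform(0, 20, (5, 10, 3))
    ens = lipid_ensemble(coords[0])
    ens.coords = coords
    grid = GridConfig(origin=(0, 0), spacing=2.0, shape=(10, 10),
                      z_range=(0, 20))
    m1 = occupancy_map(ens, "PI4P", grid).counts
    ens.coords = coords[::-1].copy()
    m2 = occupancy_map(ens, "PI4P", grid).counts
    assert np.array_equal(m1, m2)


def test_invalid_grid_rejected():
    with pytest.raises(ValueError):
        GridConfig(spacing=0.0)


def test_pocket_occupancy_contrast_between_biases():
    """PI(4)P fills the pocket when unblocked; cholesterol displaces it."""
    from v0scape.membrane import MembraneComposition, build_membrane_spec
    from v0scape.synthetic import (
        POCKET_CENTER_XY,
        POCKET_RADIUS,
        GeneratorConfig,
        generate_ensemble,
    )

    maps = {}
    for bias, spec in (
        ("pi4p_in_pocket", build_membrane_spec(MembraneComposition(80, 20, 0))),
        ("chol_blocks_pocket",
         build_membrane_spec(MembraneComposition(70, 10, 20))),
    ):
        ens, _ = generate_ensemble(
            GeneratorConfig(n_frames=8, global_motion=False, seed=12,
                            lipid_spec=spec, pocket_bias=bias)
        )
        maps[bias] = {
            sp: (
                occupancy_map(ens, sp).pocket_occupancy(
                    POCKET_CENTER_XY, POCKET_RADIUS
                )
                if (ens.topology.region == f"lipid_{sp}").any()
                else 0.0
            )
            for sp in ("PI4P", "CHOL")
        }
    assert maps["pi4p_in_pocket"]["PI4P"] > maps["chol_blocks_pocket"]["PI4P"]
    assert maps["chol_blocks_pocket"]["CHOL"] > maps["pi4p_in_pocket"]["CHOL"]
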