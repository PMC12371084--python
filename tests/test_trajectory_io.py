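import numpy as np
import pytest

from v0scape.synthetic import (
    GeneratorConfig,
    default_region_partition,
    generate_ensemble,
)
from v0scape.trajio import (
    AlignmentError,
    EmptyInputError,
    Ensemble,
    SelectionError,
    Topology,
    kabsch_align,
    kabsch_transform,
    read_ensemble,
    select_atoms,
    write_ensemble,
)


def tiny_topology(n=3):
    return Topology(
        atom_name=np.array(["CA"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        res_id=np.arange(1, n + 1),
        res_name=np.array(["GLY"] * n, dtype=object),
        chain_id=np.array(["A"] * n, dtype=object),
        region=np.array(["other"] * n, dtype=object),
        is_calpha=np.ones(n, dtype=bool),
    )


def test_minimal_single_model_file(tmp_path):
    ens = Ensemble(topology=tiny_topology(),
                   coords=np.arange(9.0).reshape(1, 3, 3))
    path = tmp_path / "tiny.pdb"
    write_ensemble(ens, path)
    back = read_ensemble(path)
    assert back.coords.shape == (1, 3, 3)


def test_round_trip_within_pdb_precision(tmp_path):
    rng = np.random.default_rng(0)
    ens = Ensemble(topology=tiny_topology(5),
                   coords=rng.uniform(-50, 50, (4, 5, 3)))
    path = tmp_path / "rt.pdb"
    write_ensemble(ens, path)
    back = read_ensemble(path)
    assert back.coords.shape == ens.coords.shape
    assert np.allclose(back.coords, ens.coords, atol=1e-3)


def test_write_is_idempotent(tmp_path):
    ens = Ensemble(topology=tiny_topology(),
                   coords=np.arange(18.0).reshape(2, 3, 3))
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_ensemble(ens, p1)
    write_ensemble(read_ensemble(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_model_count_preserved(tmp_path):
    ens, _ = generate_ensemble(
        GeneratorConfig(n_frames=50, seed=4, global_motion=False)
    )
    path = tmp_path / "ens.pdb"
    write_ensemble(ens, path)
    assert read_ensemble(path).n_frames == 50


def test_synthetic_round_trip_keeps_frame_order(tmp_path):
    """Planted state labels still align frame-for-frame after write/read."""
    from v0scape.synthetic import STATE_HEAD_CENTERS

    ens, truth = generate_ensemble(
        GeneratorConfig(n_frames=25, seed=9, global_motion=False)
    )
    path = tmp_path / "ens.pdb"
    write_ensemble(ens, path)
    back = read_ensemble(path, default_region_partition())
    head = select_atoms(back.topology, "region a2_head").indices
    centers = back.coords[:, head, :].mean(axis=1)
    recovered = np.argmin(
        np.linalg.norm(centers[:, None, :] - STATE_HEAD_CENTERS[None], axis=2),
        axis=1,
    )
    assert np.array_equal(recovered, truth.state_labels)


def test_empty_ensemble_rejected():
    with pytest.raises(EmptyInputError):
        Ensemble(topology=tiny_topology(), coords=np.empty((0, 3, 3)))


def test_out_of_range_coordinates_rejected(tmp_path):
    ens = Ensemble(topology=tiny_topology(),
                   coords=np.full((1, 3, 3), 2e4))
    with pytest.raises(Exception):
        write_ensemble(ens, tmp_path / "big.pdb")


# -- selections -------------------------------------------------------------

def test_calpha_flag_count(small_clean_ensemble):
    ens, _ = small_clean_ensemble
    sel = select_atoms(ens.topology, "calpha")
    assert len(sel) == int(ens.topology.is_calpha.sum()) == 200


def test_selection_set_algebra(small_clean_ensemble):
    ens, _ = small_clean_ensemble
    head = set(select_atoms(ens.topology, "region a2_head").indices)
    ca = set(select_atoms(ens.topology, "calpha").indices)
    both = set(select_atoms(ens.topology, "region a2_head and calpha").indices)
    either = set(select_atoms(ens.topology, "region a2_head or calpha").indices)
    assert both == head & ca
    assert either == head | ca
    notca = set(select_atoms(ens.topology, "not calpha").indices)
    assert notca == set(range(ens.n_atoms)) - ca


def test_resid_selection_hits_planted_residue(small_clean_ensemble):
    ens, _ = small_clean_ensemble
    sel = select_atoms(ens.topology, "resid 81 and region a2_arm")
    names = set(ens.topology.atom_name[sel.indices])
    assert names == {"CA", "OE1"}  # planted pseudo-residue + charged bead


def test_unknown_selector_token_errors(small_clean_ensemble):
    ens, _ = small_clean_ensemble
    with pytest.raises(SelectionError):
        select_atoms(ens.topology, "backbone")
    with pytest.raises(SelectionError):
        select_atoms(ens.topology, "region nowhere")


def test_empty_selection_flagged_when_required(small_clean_ensemble):
    ens, _ = small_clean_ensemble
    assert len(select_atoms(ens.topology, "resid 9999")) == 0
    with pytest.raises(SelectionError):
        select_atoms(ens.topology, "resid 9999", require_nonempty=True)


# -- Kabsch alignment -------------------------------------------------------

def rotation_z(deg):
    a = np.deg2rad(deg)
    return np.array(
        [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
    )


def test_exact_rigid_motion_removed():
    rng = np.random.default_rng(1)
    ref = rng.uniform(-10, 10, (6, 3))
    moved = ref @ rotation_z(90).T + np.array([5.0, 0, 0])
    ens = Ensemble(topology=tiny_topology(6), coords=moved[None])
    sel = select_atoms(ens.topology, "calpha")
    aligned, rmsds = kabsch_align(ens, ref, sel)
    assert rmsds[0] <= 1e-6
    assert np.allclose(aligned.coords[0], ref, atol=1e-6)


def test_identity_frame_zero_rmsd():
    rng = np.random.default_rng(2)
    ref = rng.uniform(-10, 10, (5, 3))
    ens = Ensemble(topology=tiny_topology(5), coords=ref[None])
    _, rmsds = kabsch_align(ens, ref, select_atoms(ens.topology, "calpha"))
    assert rmsds[0] <= 1e-9


def test_kabsch_beats_rotation_grid_search():
    """Post-fit RMSD is a global minimum: no rotation on a dense Euler grid
    does better (small-system brute-force oracle)."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(3)
    ref = rng.uniform(-5, 5, (5, 3))
    frame = ref + rng.normal(0, 1.0, ref.shape)
    R, t = kabsch_transform(frame, ref)
    best = np.sqrt(np.mean(np.sum((frame @ R.T + t - ref) ** 2, axis=1)))

    grid = np.deg2rad(np.arange(0, 360, 9.0))
    fc = frame - frame.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    brute = np.inf
    for a in grid:
        for b in np.deg2rad(np.arange(0, 180, 9.0)):
            for c in grid:
                Rg = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                val = np.sqrt(np.mean(np.sum((fc @ Rg.T - rc) ** 2, axis=1)))
                brute = min(brute, val)
    assert best <= brute + 1e-3


def test_degenerate_fit_configurations_rejected():
    line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
    with pytest.raises(AlignmentError):
        kabsch_transform(line, line)
    with pytest.raises(AlignmentError):
        kabsch_transform(line[:2], line[:2])


def test_alignment_recovers_motion_free_frames(default_ensemble):
    """Kabsch-aligning a frame onto its own motion-free counterpart undoes
    the recorded global motion to numerical precision."""
    ens, truth = default_ensemble
    cfg = GeneratorConfig(seed=7, global_motion=False)
    motion_free, _ = generate_ensemble(cfg)
    sel = select_atoms(ens.topology, "calpha")
    for f in (0, 500, 1999):
        single = ens.subset_frames([f])
        aligned, rmsds = kabsch_align(single, motion_free.coords[f], sel)
        assert rmsds[0] <= 1e-6
        assert np.allclose(aligned.coords[0], motion_free.coords[f],
                           atol=1e-6)


def test_prealignment_rigid_motion_changes_nothing(aligned_default):
    """Applying an arbitrary rigid motion to every frame before alignment
    leaves the aligned coordinates unchanged (pipeline invariance)."""
    aligned, _, calpha = aligned_default
    sub = aligned.subset_frames(np.arange(20))
    R = rotation_z(37.0) @ rotation_z(0.0)
    moved = Ensemble(
        topology=sub.topology,
        coords=sub.coords @ R.T + np.array([3.0, -7.0, 11.0]),
    )
    ref = aligned.coords[0]
    a1, _ = kabsch_align(sub, ref, calpha)
    a2, _ = kabsch_align(moved, ref, calpha)
    assert np.allclose(a1.coords, a2.coords, atol=1e-6)
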