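"""V0-V1 assembly compatibility by superposition and clash counting.

Simulated V0 conformations are rigidly fitted, one frame at a time, onto
the V0 part of a labeled holo (V0+V1) reference complex, using the parts of
V0 that do not take part in the head/arm rearrangement (c-ring + d1 by
default) as the fit selection.  Steric incompatibility with the docked V1
region is quantified as the number of atom-atom contacts between a mobile
selection of the fitted V0 (the a2 arm by default) and the V1 atoms within
a distance cutoff.

A packaged toy holo reference shares the synthetic generator's V0 geometry
(assembly-promoting pose) with an added V1 bead block positioned above d1 so
that head-docked poses clash with it; any user-supplied structure with V0/V1
subunit labels (e.g. a cryo-EM holo complex) can be passed through the same
interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajio import (
    AtomSelection,
    Ensemble,
    Topology,
    kabsch_transform,
    rmsd,
    select_atoms,
)


class MappingError(KeyError):
    pass


class ReferenceError(ValueError):
    pass


DEFAULT_CLASH_CUTOFF = 3.0  # A, bead center-to-center on the toy fixture


@dataclass
class HoloReference:
    """A labeled V0+V1 complex used as the docking reference."""

    topology: Topology
    coords: np.ndarray           # (n_atoms, 3)
    v1_mask: np.ndarray          # bool; True for V1-region atoms
    fit_selector: str = "region c_ring or region d1"
    provenance: str = "packaged toy fixture"

    def __post_init__(self):
        if not self.v1_mask.any():
            raise ReferenceError("holo reference has no V1-tagged atoms")
        if self.v1_mask.all():
            raise ReferenceError("holo reference has no V0-tagged atoms")

    @property
    def v1_coords(self) -> np.ndarray:
        return self.coords[self.v1_mask]


def build_toy_holo(v1_spacing: float = 4.0) -> HoloReference:
    """Toy holo complex: the generator's V0 in its assembly-promoting pose
    plus a V1 bead block docked above d1 (clashing with head-docked poses)."""
    from .synthetic import D1_CENTER, build_protein_topology_and_poses

    topo, poses = build_protein_topology_and_poses()
    v0_coords = poses[0]

    xs = np.arange(-2.0, 18.1, v1_spacing)
    ys = np.arange(-10.0, 10.1, v1_spacing)
    zs = np.arange(26.0, 42.1, v1_spacing)
    block = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    # keep V1 from interpenetrating the d1 blob
    block = block[np.linalg.norm(block - D1_CENTER, axis=1) > 9.5]

    n_v1 = len(block)
    v1_topo = Topology(
        atom_name=np.array(["CA"] * n_v1, dtype=object),
        element=np.array(["C"] * n_v1, dtype=object),
        res_id=(601 + np.arange(n_v1)).astype(int),
        res_name=np.array(["GLY"] * n_v1, dtype=object),
        chain_id=np.array(["V"] * n_v1, dtype=object),
        region=np.array(["other"] * n_v1, dtype=object),
        is_calpha=np.ones(n_v1, dtype=bool),
    )
    from .synthetic import _concat_topologies

    full = _concat_topologies(topo, v1_topo)
    v1_mask = np.zeros(full.n_atoms, dtype=bool)
    v1_mask[topo.n_atoms:] = True
    return HoloReference(
        topology=full,
        coords=np.concatenate([v0_coords, block]),
        v1_mask=v1_mask,
    )


def holo_from_ensemble_frame(
    ensemble: Ensemble, frame: int, v1_chains=("V",),
    fit_selector: str = "region c_ring or region d1",
    provenance: str = "user-supplied structure",
) -> HoloReference:
    """Wrap one frame of a labeled structure as a holo reference; atoms in
    ``v1_chains`` are the V1 region."""
    v1_mask = np.isin(ensemble.topology.chain_id.astype(str), v1_chains)
    return HoloReference(
        topology=ensemble.topology,
        coords=ensemble.coords[frame],
        v1_mask=v1_mask,
        fit_selector=fit_selector,
        provenance=provenance,
    )


def _correspondence(topology: Topology, holo: HoloReference,
                    selector: str) -> tuple[np.ndarray, np.ndarray]:
    """Match fit-selection atoms between a frame topology and the holo by
    (chain, residue, atom name)."""
    sel_frame = select_atoms(topology, selector, require_nonempty=True)
    sel_holo = select_atoms(holo.topology, selector, require_nonempty=True)

    def keys(top, idx):
        return [
            (top.chain_id[i], int(top.res_id[i]), top.atom_name[i])
            for i in idx
        ]

    holo_map = dict(zip(keys(holo.topology, sel_holo.indices),
                        sel_holo.indices))
    frame_idx, holo_idx, missing = [], [], []
    for key, i in zip(keys(topology, sel_frame.indices), sel_frame.indices):
        j = holo_map.get(key)
        if j is None:
            missing.append(key)
        else:
            frame_idx.append(i)
            holo_idx.append(j)
    if missing:
        raise MappingError(
            f"{len(missing)} fit atoms missing in holo reference, e.g. "
            f"{missing[:3]}"
        )
    return np.array(frame_idx), np.array(holo_idx)


def superpose_onto_holo(
    frame_coords: np.ndarray,
    topology: Topology,
    holo: HoloReference,
    fit_selector: str | None = None,
) -> tuple[np.ndarray, float]:
    """Rigidly fit a simulated V0 frame onto the holo's V0 core.

    Returns the transformed full-frame coordinates and the post-fit RMSD
    over the fit selection.
    """
    selector = fit_selector or holo.fit_selector
    frame_idx, holo_idx = _correspondence(topology, holo, selector)
    R, t = kabsch_transform(frame_coords[frame_idx], holo.coords[holo_idx])
    fitted = frame_coords @ R.T + t
    return fitted, rmsd(fitted[frame_idx], holo.coords[holo_idx])


@dataclass
class ClashResult:
    """Per-frame clash counts of a mobile V0 selection against V1."""

    mobile_selector: str
    cutoff: float
    counts: np.ndarray      # (n_frames,) int
    fit_rmsd: np.ndarray    # (n_frames,)


def count_clashes(
    fitted_coords: np.ndarray,
    topology: Topology,
    holo: HoloReference,
    mobile_selector: str = "region a2_arm",
    cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> int:
    """Atom pairs between the fitted mobile selection and V1 within cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mobile = select_atoms(topology, mobile_selector, require_nonempty=True)
    return int(
        cKDTree(fitted_coords[mobile.indices]).count_neighbors(
            cKDTree(holo.v1_coords), cutoff
        )
    )


def clash_series(
    ensemble: Ensemble,
    holo: HoloReference,
    mobile_selector: str = "region a2_arm",
    cutoff: float = DEFAULT_CLASH_CUTOFF,
    fit_selector: str | None = None,
) -> ClashResult:
    """Fit every frame onto the holo and count its V1 clashes."""
    counts = np.empty(ensemble.n_frames, dtype=int)
    rmsds = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        fitted, rms = superpose_onto_holo(
            ensemble.coords[f], ensemble.topology, holo, fit_selector
        )
        counts[f] = count_clashes(
            fitted, ensemble.topology, holo, mobile_selector, cutoff
        )
        rmsds[f] = rms
    return ClashResult(
        mobile_selector=mobile_selector, cutoff=cutoff,
        counts=counts, fit_rmsd=rmsds,
    )


def clashes_by_group(
    result: ClashResult,
    cluster_labels,
    composition_labels=None,
) -> pd.DataFrame:
    """Mean, standard error and n of clash counts per cluster (and
    composition)."""
    labels = np.asarray(cluster_labels)
    if len(labels) != len(result.counts):
        raise ValueError("cluster labels and clash series are misaligned")
    frame = pd.DataFrame({"cluster": labels, "count": result.counts})
    keys = ["cluster"]
    if composition_labels is not None:
        comp = np.asarray(composition_labels, dtype=object)
        if len(comp) != len(result.counts):
            raise ValueError("composition labels misaligned with series")
        frame["composition"] = comp
        keys = ["composition", "cluster"]
    agg = frame.groupby(keys, sort=True)["count"].agg(
        mean="mean", sem=lambda c: c.std(ddof=1) / np.sqrt(len(c)), n="size"
    )
    return agg.reset_index()
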