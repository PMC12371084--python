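"""Contact counting, salt-bridge frequencies and lipid occupancy maps.

An "interaction" is an atom pair, one atom from each of two named
selections, within a distance cutoff (4.0 A by default, heavy-atom
center-to-center); counts are exact per frame and computed with a k-d tree
whose result equals the brute-force all-pairs count by construction.  Salt
bridges are scored on the charged-group beads of the designated residue
pairs (minimum N/O pair distance within cutoff).  Occupancy maps accumulate
per-voxel visit counts of a lipid species over frames, in the aligned frame
of reference, as a top-view 2D grid over the cytosolic leaflet by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajio import AtomSelection, Ensemble, SelectionError, select_atoms


class TopologyError(KeyError):
    pass


@dataclass
class ContactSeries:
    """Per-frame atom-pair contact counts between selections A and B."""

    name_a: str
    name_b: str
    cutoff: float
    counts: np.ndarray  # (n_frames,) int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)


def count_contacts(
    ensemble: Ensemble,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    cutoff: float = 4.0,
) -> ContactSeries:
    """Count atom pairs (a in A, b in B) with ||a - b|| <= cutoff, per frame."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise SelectionError("contact selections must be non-empty")
    if np.intersect1d(sel_a.indices, sel_b.indices).size:
        raise SelectionError("contact selections must be disjoint")
    counts = np.empty(ensemble.n_frames, dtype=int)
    for f in range(ensemble.n_frames):
        a = ensemble.coords[f, sel_a.indices]
        b = ensemble.coords[f, sel_b.indices]
        counts[f] = cKDTree(a).count_neighbors(cKDTree(b), cutoff)
    return ContactSeries(sel_a.name, sel_b.name, cutoff, counts)


def contacts_by_cluster(
    series: ContactSeries,
    cluster_labels,
    composition_labels=None,
) -> pd.DataFrame:
    """Mean, standard error and n of the contact counts per cluster
    (optionally further split by composition)."""
    labels = np.asarray(cluster_labels)
    if len(labels) != len(series.counts):
        raise ValueError("cluster labels and contact series are misaligned")
    frame = pd.DataFrame({"cluster": labels, "count": series.counts})
    keys = ["cluster"]
    if composition_labels is not None:
        comp = np.asarray(composition_labels, dtype=object)
        if len(comp) != len(series.counts):
            raise ValueError("composition labels misaligned with series")
        frame["composition"] = comp
        keys = ["composition", "cluster"]
    agg = frame.groupby(keys, sort=True)["count"].agg(
        mean="mean", sem=lambda c: c.std(ddof=1) / np.sqrt(len(c)), n="size"
    )
    return agg.reset_index()


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaltBridgePair:
    """A donor/acceptor residue pair scored on charged-group (N/O) beads."""

    donor_resid: int
    donor_region: str
    acceptor_resid: int
    acceptor_region: str
    cutoff: float = 4.0

    @property
    def label(self) -> str:
        return (
            f"{self.donor_resid}({self.donor_region})-"
            f"{self.acceptor_resid}({self.acceptor_region})"
        )


#: The planted pocket salt bridges: E81(arm)-R436(body), D76(arm)-R126(c-ring).
DEFAULT_SALT_BRIDGES = (
    SaltBridgePair(81, "a2_arm", 436, "a2_body"),
    SaltBridgePair(76, "a2_arm", 126, "c_ring"),
)


def _charged_atoms(ensemble: Ensemble, resid: int, region: str) -> np.ndarray:
    top = ensemble.topology
    sel = select_atoms(top, f"resid {resid} and region {region}")
    charged = sel.indices[
        np.isin(top.element[sel.indices].astype(str), ("N", "O"))
        & ~top.is_calpha[sel.indices]
    ]
    if charged.size == 0:
        raise TopologyError(
            f"no charged-group atoms for residue {resid} in region {region}"
        )
    return charged


def salt_bridge_frequency(
    ensemble: Ensemble,
    pairs=DEFAULT_SALT_BRIDGES,
    cluster_labels=None,
) -> pd.DataFrame:
    """Fraction of frames in which each bridge is formed (min charged-group
    distance <= cutoff), overall and per cluster when labels are given."""
    records = []
    for pair in pairs:
        don = _charged_atoms(ensemble, pair.donor_resid, pair.donor_region)
        acc = _charged_atoms(
            ensemble, pair.acceptor_resid, pair.acceptor_region
        )
        d = ensemble.coords[:, don, None, :] - ensemble.coords[:, None, acc, :]
        mind = np.sqrt((d ** 2).sum(-1)).min(axis=(1, 2))
        present = mind <= pair.cutoff
        records.append(
            {"pair": pair.label, "cluster": "all",
             "frequency": float(present.mean()), "n": len(present)}
        )
        if cluster_labels is not None:
            labels = np.asarray(cluster_labels)
            for c in np.unique(labels):
                mask = labels == c
                records.append(
                    {"pair": pair.label, "cluster": int(c),
                     "frequency": float(present[mask].mean()),
                     "n": int(mask.sum())}
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Occupancy maps
# ---------------------------------------------------------------------------

@dataclass
class GridConfig:
    origin: tuple[float, float] = (-75.0, -90.0)
    spacing: float = 1.0
    shape: tuple[int, int] = (185, 180)
    z_range: tuple[float, float] = (0.0, 40.0)  # cytosolic leaflet slab

    def __post_init__(self):
        if self.spacing <= 0 or min(self.shape) < 1:
            raise ValueError("grid must have positive spacing and shape")


@dataclass
class OccupancyMap:
    """Voxelized visit counts of one lipid species (top-view projection)."""

    species: str
    grid: GridConfig
    counts: np.ndarray       # (nx, ny) raw visit counts
    n_frames: int
    normalization: str = "raw"

    def normalized(self) -> np.ndarray:
        """Per-frame visit fraction per voxel."""
        return self.counts / self.n_frames

    def pocket_occupancy(self, center_xy, radius: float) -> float:
        """Mean per-frame bead count within a lateral disc of the map."""
        nx, ny = self.grid.shape
        x = self.grid.origin[0] + (np.arange(nx) + 0.5) * self.grid.spacing
        y = self.grid.origin[1] + (np.arange(ny) + 0.5) * self.grid.spacing
        xx, yy = np.meshgrid(x, y, indexing="ij")
        mask = (xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2 <= radius ** 2
        return float(self.counts[mask].sum() / self.n_frames)

    def write_text(self, path) -> None:
        """Documented gridded text format: header lines + one row per x."""
        with open(path, "w") as fh:
            fh.write(f"# occupancy map, species {self.species}\n")
            fh.write(
                f"# origin {self.grid.origin[0]} {self.grid.origin[1]} "
                f"spacing {self.grid.spacing} shape {self.grid.shape[0]} "
                f"{self.grid.shape[1]} frames {self.n_frames}\n"
            )
            np.savetxt(fh, self.counts, fmt="%d")


def occupancy_map(
    ensemble: Ensemble,
    species: str,
    grid: GridConfig | None = None,
    frame_subset=None,
) -> OccupancyMap:
    """Accumulate per-voxel visit counts of ``species`` beads over frames.

    Beads outside the grid bounds or the z slab are ignored; the sum of raw
    counts therefore equals the number of (frame, in-grid bead) incidences
    exactly.
    """
    grid = grid or GridConfig()
    sel = select_atoms(
        ensemble.topology, f"species {species}", require_nonempty=True
    )
    frames = (
        np.arange(ensemble.n_frames)
        if frame_subset is None
        else np.asarray(frame_subset)
    )
    nx, ny = grid.shape
    counts = np.zeros((nx, ny), dtype=int)
    for f in frames:
        xyz = ensemble.coords[f, sel.indices]
        zok = (xyz[:, 2] >= grid.z_range[0]) & (xyz[:, 2] <= grid.z_range[1])
        ix = np.floor((xyz[zok, 0] - grid.origin[0]) / grid.spacing).astype(int)
        iy = np.floor((xyz[zok, 1] - grid.origin[1]) / grid.spacing).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(counts, (ix[ok], iy[ok]), 1)
    return OccupancyMap(
        species=species, grid=grid, counts=counts, n_frames=len(frames)
    )
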