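"""Synthetic V0-like conformational ensembles with planted ground truth.

The generator builds a desk-scale bead model of the V0 region — a c-ring of
ten proteolipid subunits spanning the membrane, the d1 subunit as an apical
blob, and an a2 subunit split into a membrane-embedded body, an arm, and a
mobile head — and emits multi-frame ensembles in which the head/arm adopt one
of up to four planted rigid-body poses per frame:

* state 0: head swung away from d1, out over the membrane (the
  assembly-promoting pose: no head-d1 contacts, salt bridges
  E81-R436 and D76-R126 formed near the a2/c-ring pocket);
* states 1..3: head docked toward d1 with increasing proximity (increasing
  head-d1 contact counts, broken salt bridges).

Isotropic Gaussian coordinate noise emulates thermal fluctuations, an
optional random rigid motion per frame emulates tumbling of the simulation
box content, and lipid headgroup beads are laid out in two leaflet planes at
the integer counts of a :class:`~v0scape.membrane.MembraneSpec`, with an
optional bias controlling whether PI(4)P or cholesterol occupies the pocket
between the a2 body and the c-ring.

Pose separations are >= 10x the default noise sigma, so state recovery by
the downstream embedding + mixture pipeline is unambiguous by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .membrane import MembraneComposition, MembraneSpec, build_membrane_spec
from .trajio import Ensemble, RegionPartition, Topology, apply_region_partition

# ---------------------------------------------------------------------------
# Geometry constants (Angstrom)
# ---------------------------------------------------------------------------

RING_RADIUS = 22.0
RING_SUBUNITS = 10
D1_CENTER = np.array([0.0, 0.0, 30.0])
D1_RADIUS = 8.0
HEAD_RADIUS = 4.5
HINGE = np.array([25.0, 0.0, 14.0])  # arm pivot at the a2 body / pocket edge
LEAFLET_Z = 17.5                     # headgroup-bead plane per leaflet
MEMBRANE_BOX = 180.0                 # lateral box edge (~65 A^2 per lipid)
MEMBRANE_CENTER = np.array([16.0, 0.0])
MIN_LIPID_PROTEIN_SEP = 3.0

#: Planted head-centroid positions per state (state 0 = head away).
#: Docked approaches fan out in azimuth so pairwise pose separations stay
#: >= 10x the default noise sigma (C-alpha RMS between poses > 3 A).
STATE_HEAD_CENTERS = np.array(
    [
        [52.0, 0.0, 10.0],                                   # away, near membrane
        D1_CENTER + 15.5 * np.array([0.758, 0.637, 0.139]),  # docked, small gap
        D1_CENTER + 14.5 * np.array([0.990, 0.000, 0.139]),  # docked, closer
        D1_CENTER + 13.0 * np.array([0.758, -0.637, 0.139]),  # docked, touching
    ]
)
MAX_STATES = len(STATE_HEAD_CENTERS)

#: Pocket between the a2 body and the c-ring (cytosolic leaflet).
POCKET_CENTER_XY = np.array([24.0, 0.0])
POCKET_RADIUS = 3.0

#: Fixed charged-group bead positions for the planted salt-bridge acceptors.
R436_CHARGE = np.array([34.0, 2.0, 13.5])   # a2 body, residue 436
R126_CHARGE = np.array([23.5, 1.0, 7.0])    # c-ring, residue 126
SALT_BRIDGE_DISTANCE = 3.0                  # planted donor-acceptor distance

ARM_RESIDUES = (74, 93)
HEAD_RESIDUES = (201, 220)
BODY_RESIDUES = (420, 469)
RING_RESIDUES = (121, 200)
D1_RESIDUES = (301, 330)


class ConfigError(ValueError):
    pass


def default_region_partition() -> RegionPartition:
    """Residue-range to region mapping matching the generator's numbering."""
    return RegionPartition(
        ranges={
            "A": (
                (ARM_RESIDUES[0], ARM_RESIDUES[1], "a2_arm"),
                (HEAD_RESIDUES[0], HEAD_RESIDUES[1], "a2_head"),
                (BODY_RESIDUES[0], BODY_RESIDUES[1], "a2_body"),
            ),
            "C": ((RING_RESIDUES[0], RING_RESIDUES[1], "c_ring"),),
            "D": ((D1_RESIDUES[0], D1_RESIDUES[1], "d1"),),
        }
    )


def canonical_alignment_reference(topology: Topology) -> np.ndarray:
    """Reference coordinates (clean assembly-promoting pose) for Kabsch
    alignment of generator ensembles.

    Aligning onto this reference places frames back into the generator's
    membrane frame, which the pocket region and occupancy grids are defined
    in.  Only protein positions are meaningful; lipid rows are zero-filled
    (they never enter a C-alpha fit selection).
    """
    _, poses = build_protein_topology_and_poses()
    n_protein = poses.shape[1]
    if topology.n_atoms < n_protein or not np.all(
        topology.is_protein[:n_protein]
    ):
        raise ConfigError(
            "topology does not start with the generator's protein block"
        )
    ref = np.zeros((topology.n_atoms, 3))
    ref[:n_protein] = poses[0]
    return ref


def in_pocket(coords: np.ndarray) -> np.ndarray:
    """Boolean mask: which points lie in the cytosolic a2/c-ring pocket."""
    coords = np.atleast_2d(coords)
    lateral = np.linalg.norm(coords[:, :2] - POCKET_CENTER_XY, axis=1)
    return (lateral <= POCKET_RADIUS) & (coords[:, 2] > 0)


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

def _default_spec() -> MembraneSpec:
    return build_membrane_spec(MembraneComposition(80.0, 20.0, 0.0))


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic ensemble."""

    n_frames: int = 2000
    n_states: int = 4
    state_weights: tuple[float, ...] | None = None  # balanced when None
    noise_sigma: float = 0.3
    global_motion: bool = True
    lipid_spec: MembraneSpec = field(default_factory=_default_spec)
    pocket_bias: str = "none"  # pi4p_in_pocket | chol_blocks_pocket | none
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.n_states <= MAX_STATES):
            raise ConfigError(
                f"n_states must be in [1, {MAX_STATES}], got {self.n_states}"
            )
        if self.n_frames < 1:
            raise ConfigError("n_frames must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be non-negative")
        if self.pocket_bias not in ("pi4p_in_pocket", "chol_blocks_pocket",
                                    "none"):
            raise ConfigError(f"unknown pocket_bias: {self.pocket_bias!r}")
        if self.state_weights is None:
            self.state_weights = tuple([1.0 / self.n_states] * self.n_states)
        if len(self.state_weights) != self.n_states:
            raise ConfigError("state_weights length must equal n_states")
        if abs(sum(self.state_weights) - 1.0) > 1e-9:
            raise ConfigError("state_weights must sum to 1")


@dataclass
class GroundTruth:
    """Planted per-frame truth for recovery tests."""

    state_labels: np.ndarray          # (n_frames,), int in [0, n_states)
    rotations: np.ndarray             # (n_frames, 3, 3) applied global rotation
    translations: np.ndarray          # (n_frames, 3) applied global translation
    head_centers: np.ndarray          # (n_states, 3) pose parameters
    pocket_species: str | None        # species planted in the pocket, if any

    def to_json(self) -> str:
        return json.dumps(
            {
                "state_labels": self.state_labels.tolist(),
                "rotations": self.rotations.tolist(),
                "translations": self.translations.tolist(),
                "head_centers": self.head_centers.tolist(),
                "pocket_species": self.pocket_species,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            state_labels=np.array(d["state_labels"], dtype=int),
            rotations=np.array(d["rotations"]),
            translations=np.array(d["translations"]),
            head_centers=np.array(d["head_centers"]),
            pocket_species=d["pocket_species"],
        )


# ---------------------------------------------------------------------------
# Protein geometry
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return radius * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _ring_beads() -> tuple[np.ndarray, np.ndarray]:
    """c-ring: 10 subunits x 8 beads (2 azimuthal columns x 4 z levels)."""
    coords, resids = [], []
    for s in range(RING_SUBUNITS):
        for j in range(8):
            az = np.deg2rad(36.0 * s + (10.0 if j % 2 else 0.0) - 5.0)
            z = -12.0 + 8.0 * (j // 2)
            coords.append(
                [RING_RADIUS * np.cos(az), RING_RADIUS * np.sin(az), z]
            )
            resids.append(RING_RESIDUES[0] + 8 * s + j)
    return np.array(coords), np.array(resids)


def _body_beads() -> tuple[np.ndarray, np.ndarray]:
    """a2 body: 5 x 2 x 5 grid beside the ring, spanning the membrane."""
    xs = [26.0, 30.0, 34.0, 38.0, 42.0]
    ys = [-2.0, 2.0]
    zs = [-12.0, -6.0, 0.0, 6.0, 12.0]
    coords = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    resids = np.arange(BODY_RESIDUES[0], BODY_RESIDUES[1] + 1)
    # Residue 436 must sit at the bead nearest the planted R436 charged group.
    target = np.argmin(np.linalg.norm(coords - R436_CHARGE, axis=1))
    current = int(np.where(resids == 436)[0][0])
    resids = resids.copy()
    resids[[target, current]] = resids[[current, target]]
    return coords, resids


def _arm_head_pose(state: int) -> tuple[np.ndarray, np.ndarray]:
    """Arm bead line and head blob for one planted state."""
    center = STATE_HEAD_CENTERS[state]
    delta = center - HINGE
    length = np.linalg.norm(delta)
    u = delta / length
    arm_len = length - HEAD_RADIUS - 0.5
    n_arm = ARM_RESIDUES[1] - ARM_RESIDUES[0] + 1
    t = (np.arange(n_arm) + 1.0) / (n_arm + 1.0) * arm_len
    arm = HINGE + t[:, None] * u
    head = center + _fibonacci_sphere(
        HEAD_RESIDUES[1] - HEAD_RESIDUES[0] + 1, HEAD_RADIUS
    )
    return arm, head


def _charge_offsets() -> tuple[np.ndarray, np.ndarray]:
    """Lab-frame side-chain offsets for E81 and D76, fixed by the state-0
    geometry so the planted donor-acceptor distances are exactly 3.0 A."""
    arm0, _ = _arm_head_pose(0)
    ca81 = arm0[81 - ARM_RESIDUES[0]]
    ca76 = arm0[76 - ARM_RESIDUES[0]]
    u81 = (ca81 - R436_CHARGE) / np.linalg.norm(ca81 - R436_CHARGE)
    u76 = (ca76 - R126_CHARGE) / np.linalg.norm(ca76 - R126_CHARGE)
    e81 = R436_CHARGE + SALT_BRIDGE_DISTANCE * u81
    d76 = R126_CHARGE + SALT_BRIDGE_DISTANCE * u76
    return e81 - ca81, d76 - ca76


def build_protein_topology_and_poses() -> tuple[Topology, np.ndarray]:
    """Toy V0 topology plus the (n_states, n_atoms, 3) clean pose stack."""
    ring_xyz, ring_res = _ring_beads()
    d1_xyz = D1_CENTER + _fibonacci_sphere(
        D1_RESIDUES[1] - D1_RESIDUES[0] + 1, D1_RADIUS
    )
    d1_res = np.arange(D1_RESIDUES[0], D1_RESIDUES[1] + 1)
    body_xyz, body_res = _body_beads()
    off81, off76 = _charge_offsets()

    poses = []
    for s in range(MAX_STATES):
        arm, head = _arm_head_pose(s)
        e81 = arm[81 - ARM_RESIDUES[0]] + off81
        d76 = arm[76 - ARM_RESIDUES[0]] + off76
        charge = np.stack([e81, d76, R436_CHARGE, R126_CHARGE])
        poses.append(
            np.concatenate([ring_xyz, d1_xyz, body_xyz, arm, head, charge])
        )
    poses = np.array(poses)

    n_ring, n_d1, n_body = len(ring_xyz), len(d1_xyz), len(body_xyz)
    n_arm = ARM_RESIDUES[1] - ARM_RESIDUES[0] + 1
    n_head = HEAD_RESIDUES[1] - HEAD_RESIDUES[0] + 1
    arm_res = np.arange(ARM_RESIDUES[0], ARM_RESIDUES[1] + 1)
    head_res = np.arange(HEAD_RESIDUES[0], HEAD_RESIDUES[1] + 1)

    atom_name = ["CA"] * (n_ring + n_d1 + n_body + n_arm + n_head) + [
        "OE1", "OD1", "NH1", "NH2"
    ]
    element = ["C"] * (n_ring + n_d1 + n_body + n_arm + n_head) + [
        "O", "O", "N", "N"
    ]
    res_id = np.concatenate(
        [ring_res, d1_res, body_res, arm_res, head_res, [81, 76, 436, 126]]
    )
    chain = (
        ["C"] * n_ring + ["D"] * n_d1
        + ["A"] * (n_body + n_arm + n_head)
        + ["A", "A", "A", "C"]
    )
    res_name = ["GLY"] * (n_ring + n_d1 + n_body + n_arm + n_head) + [
        "GLU", "ASP", "ARG", "ARG"
    ]
    n = len(atom_name)
    topology = Topology(
        atom_name=np.array(atom_name, dtype=object),
        element=np.array(element, dtype=object),
        res_id=res_id.astype(int),
        res_name=np.array(res_name, dtype=object),
        chain_id=np.array(chain, dtype=object),
        region=np.array(["other"] * n, dtype=object),
        is_calpha=np.array([a == "CA" for a in atom_name]),
    )
    return apply_region_partition(topology, default_region_partition()), poses


# ---------------------------------------------------------------------------
# Lipid layout
# ---------------------------------------------------------------------------

def generate_lipid_layout(
    spec: MembraneSpec,
    pocket_bias: str = "none",
    seed: int = 0,
    protein_coords: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place one headgroup bead per lipid in two leaflet planes.

    Returns (coords, species, leaflet) where species entries are
    POPC/PI4P/CHOL and leaflet entries are +1 (cytosolic/upper) or -1.
    Beads keep >= 3 A separation from every protein bead (evaluated against
    all planted poses); the pocket bias forces the chosen species into the
    a2/c-ring pocket and keeps the other anionic/sterol species out.
    """
    if pocket_bias not in ("pi4p_in_pocket", "chol_blocks_pocket", "none"):
        raise ConfigError(f"unknown pocket_bias: {pocket_bias!r}")
    rng = np.random.default_rng(seed)
    if protein_coords is None:
        _, poses = build_protein_topology_and_poses()
        protein_coords = poses.reshape(-1, 3)
    tree = cKDTree(protein_coords)

    biased_species = {"pi4p_in_pocket": "PI4P",
                      "chol_blocks_pocket": "CHOL"}.get(pocket_bias)
    if biased_species is not None:
        if spec.per_leaflet_counts.get(biased_species, 0) == 0:
            raise ConfigError(
                f"pocket_bias requests {biased_species} but the composition "
                f"contains none"
            )

    coords, species, leaflet = [], [], []
    for side in (+1, -1):
        z = side * LEAFLET_Z
        counts = spec.leaflet_counts(side)
        placed_pocket = 0
        if biased_species is not None and side == +1:
            n_pocket = min(2, counts[biased_species])
            for _ in range(n_pocket):
                r = POCKET_RADIUS * 0.5 * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                coords.append(
                    [POCKET_CENTER_XY[0] + r * np.cos(ang),
                     POCKET_CENTER_XY[1] + r * np.sin(ang), z]
                )
                species.append(biased_species)
                leaflet.append(side)
            counts[biased_species] -= n_pocket
            placed_pocket = n_pocket

        n_needed = sum(counts.values())
        m = int(np.ceil(np.sqrt(n_needed * 1.2)))
        spacing = MEMBRANE_BOX / m
        gx, gy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        cand = np.stack(
            [
                MEMBRANE_CENTER[0] - MEMBRANE_BOX / 2 + (gx.ravel() + 0.5) * spacing,
                MEMBRANE_CENTER[1] - MEMBRANE_BOX / 2 + (gy.ravel() + 0.5) * spacing,
            ],
            axis=1,
        )
        cand = cand + rng.uniform(-2.0, 2.0, size=cand.shape)
        cand = cand[rng.permutation(len(cand))]
        cand3 = np.column_stack([cand, np.full(len(cand), z)])
        ok = tree.query(cand3, k=1)[0] >= MIN_LIPID_PROTEIN_SEP
        if biased_species is not None and side == +1:
            lateral = np.linalg.norm(cand - POCKET_CENTER_XY, axis=1)
            ok &= lateral > POCKET_RADIUS + 1.0
        cand3 = cand3[ok]
        if len(cand3) < n_needed:
            raise RuntimeError("lipid placement grid exhausted")
        sp = np.concatenate(
            [np.repeat(s, c) for s, c in counts.items() if c > 0]
        )
        sp = sp[rng.permutation(len(sp))]
        coords.extend(cand3[:n_needed].tolist())
        species.extend(sp.tolist())
        leaflet.extend([side] * n_needed)
        assert placed_pocket + n_needed == sum(
            spec.leaflet_counts(side).values()
        )

    return (
        np.array(coords),
        np.array(species, dtype=object),
        np.array(leaflet, dtype=int),
    )


def _lipid_topology(species: np.ndarray, leaflet: np.ndarray) -> Topology:
    from .trajio import SPECIES_TO_RESNAME

    n = len(species)
    res_id = np.where(leaflet > 0, 1001 + np.arange(n), 2001 + np.arange(n))
    atom_name = np.where(species == "CHOL", "O3", "P").astype(object)
    element = np.where(species == "CHOL", "O", "P").astype(object)
    return Topology(
        atom_name=atom_name,
        element=element,
        res_id=res_id.astype(int),
        res_name=np.array(
            [SPECIES_TO_RESNAME[s] for s in species], dtype=object
        ),
        chain_id=np.array(["L"] * n, dtype=object),
        region=np.array([f"lipid_{s}" for s in species], dtype=object),
        is_calpha=np.zeros(n, dtype=bool),
    )


def _concat_topologies(a: Topology, b: Topology) -> Topology:
    return Topology(
        **{
            f: np.concatenate([getattr(a, f), getattr(b, f)])
            for f in ("atom_name", "element", "res_id", "res_name",
                      "chain_id", "region", "is_calpha")
        }
    )


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------

def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random rotation matrices via normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w),
                      2 * (x * z + y * w)], axis=-1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z),
                      2 * (y * z - x * w)], axis=-1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w),
                      1 - 2 * (x * x + y * y)], axis=-1),
        ],
        axis=-2,
    )


def generate_ensemble(cfg: GeneratorConfig) -> tuple[Ensemble, GroundTruth]:
    """Draw a planted-state ensemble under the given study conditions.

    Randomness is split over independent seeded streams (state draws,
    thermal noise, lipid layout, global motion), so regenerating with
    ``global_motion=False`` and the same seed reproduces the motion-free
    coordinates of every frame exactly.
    """
    ss = np.random.SeedSequence(cfg.seed)
    states_rng, noise_rng, lipid_rng, motion_rng = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    topo_protein, poses = build_protein_topology_and_poses()
    lipid_xyz, lipid_species, leaflet = generate_lipid_layout(
        cfg.lipid_spec,
        cfg.pocket_bias,
        seed=lipid_rng.integers(2**31),
        protein_coords=poses.reshape(-1, 3),
    )
    topology = _concat_topologies(topo_protein, _lipid_topology(
        lipid_species, leaflet))

    labels = states_rng.choice(
        cfg.n_states, size=cfg.n_frames, p=np.asarray(cfg.state_weights)
    )
    n_atoms = topology.n_atoms
    coords = np.empty((cfg.n_frames, n_atoms, 3))
    for s in range(cfg.n_states):
        mask = labels == s
        coords[mask] = np.concatenate([poses[s], lipid_xyz])[None]
    if cfg.noise_sigma > 0:
        coords += noise_rng.normal(
            0.0, cfg.noise_sigma, size=coords.shape
        )

    rotations = np.repeat(np.eye(3)[None], cfg.n_frames, axis=0)
    translations = np.zeros((cfg.n_frames, 3))
    if cfg.global_motion:
        rotations = _random_rotations(motion_rng, cfg.n_frames)
        translations = motion_rng.uniform(-15.0, 15.0, size=(cfg.n_frames, 3))
        coords = np.einsum("fij,faj->fai", rotations, coords) + \
            translations[:, None, :]

    truth = GroundTruth(
        state_labels=labels,
        rotations=rotations,
        translations=translations,
        head_centers=STATE_HEAD_CENTERS[: cfg.n_states].copy(),
        pocket_species={"pi4p_in_pocket": "PI4P",
                        "chol_blocks_pocket": "CHOL"}.get(cfg.pocket_bias),
    )
    label = cfg.lipid_spec.composition.label
    ensemble = Ensemble(
        topology=topology,
        coords=coords,
        frame_labels=np.array([label] * cfg.n_frames, dtype=object),
        replica_ids=np.arange(cfg.n_frames) % cfg.lipid_spec.replicas,
    )
    return ensemble, truth
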