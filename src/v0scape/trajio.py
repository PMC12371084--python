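"""Ensemble containers, structure I/O, atom selections and rigid alignment.

The universal currency of the pipeline is an :class:`Ensemble`: a stack of
frames (frames x atoms x 3, in Angstrom) plus a :class:`Topology` labelling
every atom with a pseudo-residue, chain, region tag and species.  Multi-model
PDB is the on-disk format (one MODEL per frame), read and written through
biotite.  Global rigid-body motion is removed by Kabsch superposition onto a
reference structure.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

#: Closed vocabulary of region tags.
REGIONS = (
    "a2_head",
    "a2_arm",
    "a2_body",
    "d1",
    "c_ring",
    "lipid_POPC",
    "lipid_PI4P",
    "lipid_CHOL",
    "other",
)

#: PDB residue names used for the lipid species (3-char, PDB-safe).
LIPID_RESNAMES = {"POP": "lipid_POPC", "PI4": "lipid_PI4P", "CHL": "lipid_CHOL"}
SPECIES_TO_RESNAME = {"POPC": "POP", "PI4P": "PI4", "CHOL": "CHL"}


class FormatError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


class SelectionError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Topology and Ensemble
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Per-atom metadata; arrays are parallel, indexed 0..n_atoms-1."""

    atom_name: np.ndarray   # str
    element: np.ndarray     # str
    res_id: np.ndarray      # int
    res_name: np.ndarray    # str
    chain_id: np.ndarray    # str
    region: np.ndarray      # str, one of REGIONS
    is_calpha: np.ndarray   # bool

    def __post_init__(self):
        n = len(self.atom_name)
        for name in ("element", "res_id", "res_name", "chain_id", "region",
                     "is_calpha"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"topology field {name} has wrong length")
        bad = set(np.unique(self.region)) - set(REGIONS)
        if bad:
            raise FormatError(f"unknown region tags: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def is_protein(self) -> np.ndarray:
        return ~np.char.startswith(self.region.astype(str), "lipid_")


@dataclass
class Ensemble:
    """Stack of conformations sharing one topology.

    coords: (n_frames, n_atoms, 3) float64, Angstrom.
    frame_labels: composition label per frame; replica_ids: bookkeeping.
    """

    topology: Topology
    coords: np.ndarray
    frame_labels: np.ndarray | None = None
    replica_ids: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise EmptyInputError("ensemble must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise FormatError("coordinate atom count does not match topology")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")
        if self.frame_labels is None:
            self.frame_labels = np.array([""] * self.n_frames, dtype=object)
        else:
            self.frame_labels = np.asarray(self.frame_labels, dtype=object)
        if self.replica_ids is None:
            self.replica_ids = np.zeros(self.n_frames, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def subset_frames(self, idx) -> "Ensemble":
        return Ensemble(
            topology=self.topology,
            coords=self.coords[idx],
            frame_labels=self.frame_labels[idx],
            replica_ids=self.replica_ids[idx],
        )


def concat_ensembles(ensembles: list[Ensemble]) -> Ensemble:
    """Stack ensembles that share an identical topology along the frame axis."""
    if not ensembles:
        raise EmptyInputError("nothing to concatenate")
    top = ensembles[0].topology
    for e in ensembles[1:]:
        if e.topology.n_atoms != top.n_atoms or not np.array_equal(
            e.topology.res_id, top.res_id
        ):
            raise FormatError("ensembles have incompatible topologies")
    return Ensemble(
        topology=top,
        coords=np.concatenate([e.coords for e in ensembles], axis=0),
        frame_labels=np.concatenate([e.frame_labels for e in ensembles]),
        replica_ids=np.concatenate([e.replica_ids for e in ensembles]),
    )


# ---------------------------------------------------------------------------
# Region partitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionPartition:
    """Maps residue-number ranges per chain to region tags.

    ``ranges``: mapping chain id -> list of (first_res, last_res, region),
    inclusive bounds, non-overlapping within a chain.  Lipid atoms are always
    tagged by residue name regardless of the partition.
    """

    ranges: dict[str, tuple[tuple[int, int, str], ...]]

    def __post_init__(self):
        for chain, spans in self.ranges.items():
            spans = sorted(spans)
            for (a0, a1, _), (b0, b1, _) in zip(spans, spans[1:]):
                if b0 <= a1:
                    raise FormatError(
                        f"overlapping residue ranges in chain {chain}"
                    )

    def region_of(self, chain: str, res_id: int) -> str:
        for lo, hi, tag in self.ranges.get(chain, ()):
            if lo <= res_id <= hi:
                return tag
        return "other"


def apply_region_partition(topology: Topology,
                           partition: RegionPartition) -> Topology:
    region = np.array(
        [
            LIPID_RESNAMES.get(rn, None) or partition.region_of(ch, int(ri))
            for rn, ch, ri in zip(
                topology.res_name, topology.chain_id, topology.res_id
            )
        ],
        dtype=object,
    )
    return replace(topology, region=region)


# ---------------------------------------------------------------------------
# Multi-model PDB I/O
# ---------------------------------------------------------------------------

def _to_atom_array_stack(ensemble: Ensemble) -> struc.AtomArrayStack:
    top = ensemble.topology
    n = top.n_atoms
    stack = struc.AtomArrayStack(ensemble.n_frames, n)
    stack.coord = ensemble.coords.astype(np.float32)
    stack.chain_id = top.chain_id.astype("U4")
    stack.res_id = top.res_id.astype(int)
    stack.res_name = top.res_name.astype("U5")
    stack.atom_name = top.atom_name.astype("U6")
    stack.element = top.element.astype("U2")
    stack.hetero = ~top.is_protein
    return stack


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write a standard multi-model PDB (MODEL/ENDMDL, one model per frame).

    Output bytes are deterministic for identical inputs.  Coordinates must
    fit the fixed-width PDB coordinate fields (|x| < 10000 A).
    """
    if ensemble.n_frames < 1:
        raise EmptyInputError("cannot write an ensemble with no frames")
    if np.any(np.abs(ensemble.coords) >= 10000.0):
        raise FormatError("coordinates exceed PDB fixed-width field range")
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(ensemble))
    with open(path, "w", newline="\n") as fh:
        pdb.write(fh)


def read_ensemble(path, region_partition: RegionPartition | None = None
                  ) -> Ensemble:
    """Read a multi-model PDB into an Ensemble (one frame per MODEL record).

    Region tags come from ``region_partition`` when given; lipid residues
    (POP/PI4/CHL) are tagged by species either way.  Without a partition,
    protein atoms are tagged ``other``.
    """
    pdb = PDBFile.read(path)
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on ragged / missing models
        raise FormatError(f"could not parse multi-model PDB: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if stack.stack_depth() == 0:
        raise EmptyInputError("PDB file contains no models")
    topology = Topology(
        atom_name=stack.atom_name.astype(object),
        element=stack.element.astype(object),
        res_id=stack.res_id.astype(int),
        res_name=stack.res_name.astype(object),
        chain_id=stack.chain_id.astype(object),
        region=np.array(["other"] * stack.array_length(), dtype=object),
        is_calpha=(stack.atom_name == "CA"),
    )
    for i, rn in enumerate(topology.res_name):
        if rn in LIPID_RESNAMES:
            topology.region[i] = LIPID_RESNAMES[rn]
    if region_partition is not None:
        topology = apply_region_partition(topology, region_partition)
    return Ensemble(topology=topology, coords=stack.coord.astype(float))


# ---------------------------------------------------------------------------
# Atom selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomSelection:
    name: str
    indices: np.ndarray

    def __len__(self):
        return len(self.indices)


_KEYWORDS = {"and", "or", "not", "(", ")"}


def _tokenize(selector: str) -> list[str]:
    return selector.replace("(", " ( ").replace(")", " ) ").split()


class _SelParser:
    """Recursive-descent parser for the closed selection vocabulary.

    Grammar: expr := term ('or' term)*; term := factor ('and' factor)*;
    factor := 'not' factor | '(' expr ')' | primitive.
    Primitives: calpha | protein | lipid | region TAG | species NAME |
    chain ID | resid N[-M].
    """

    def __init__(self, tokens: list[str], top: Topology):
        self.toks = tokens
        self.pos = 0
        self.top = top

    def peek(self):
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token: {self.peek()!r}")
        return mask

    def expr(self):
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self):
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self):
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primitive()

    def primitive(self):
        top = self.top
        tok = self.take()
        if tok is None:
            raise SelectionError("empty selector")
        if tok == "calpha":
            return top.is_calpha.copy()
        if tok == "protein":
            return top.is_protein
        if tok == "lipid":
            return ~top.is_protein
        if tok == "region":
            tag = self.take()
            if tag not in REGIONS:
                raise SelectionError(f"unknown region tag: {tag!r}")
            return top.region.astype(str) == tag
        if tok == "species":
            name = self.take()
            if name not in SPECIES_TO_RESNAME:
                raise SelectionError(f"unknown species: {name!r}")
            return top.region.astype(str) == f"lipid_{name}"
        if tok == "chain":
            cid = self.take()
            if cid is None or cid in _KEYWORDS:
                raise SelectionError("chain requires an identifier")
            return top.chain_id.astype(str) == cid
        if tok == "resid":
            spec = self.take()
            if spec is None:
                raise SelectionError("resid requires a number or range")
            try:
                if "-" in spec:
                    lo, hi = (int(x) for x in spec.split("-", 1))
                else:
                    lo = hi = int(spec)
            except ValueError as exc:
                raise SelectionError(f"bad resid spec: {spec!r}") from exc
            return (top.res_id >= lo) & (top.res_id <= hi)
        raise SelectionError(f"unknown selector token: {tok!r}")


def select_atoms(topology: Topology, selector: str,
                 require_nonempty: bool = False) -> AtomSelection:
    """Evaluate a selector string; result is ordered by atom index."""
    mask = _SelParser(_tokenize(selector), topology).parse()
    idx = np.flatnonzero(mask)
    if require_nonempty and len(idx) == 0:
        raise SelectionError(f"selection {selector!r} matched no atoms")
    return AtomSelection(name=selector, indices=idx)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_transform(mobile: np.ndarray, target: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t mapping mobile onto
    target: x -> R @ (x - mobile_centroid) + target_centroid.

    Standard SVD solution with a reflection correction so det(R) = +1.
    """
    if mobile.shape[0] < 3:
        raise AlignmentError("need at least 3 atoms for a rigid fit")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12:  # rank < 2: collinear or coincident points
        raise AlignmentError("degenerate (collinear) fit configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, ct - R @ cm


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def kabsch_align(
    ensemble: Ensemble,
    reference: np.ndarray,
    selection: AtomSelection,
) -> tuple[Ensemble, np.ndarray]:
    """Superpose every frame onto ``reference`` using the fit selection.

    The optimal proper rotation + translation is computed on the selection
    atoms and applied to ALL atoms of the frame.  Returns the aligned
    ensemble and the per-frame post-fit RMSD over the selection.
    """
    if len(selection) < 3:
        raise AlignmentError("fit selection must contain at least 3 atoms")
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (ensemble.n_atoms, 3):
        raise AlignmentError("reference must match the ensemble atom layout")
    ref_sel = reference[selection.indices]
    out = np.empty_like(ensemble.coords)
    rmsds = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        frame = ensemble.coords[f]
        R, t = kabsch_transform(frame[selection.indices], ref_sel)
        out[f] = frame @ R.T + t
        rmsds[f] = rmsd(out[f][selection.indices], ref_sel)
    return (
        Ensemble(
            topology=ensemble.topology,
            coords=out,
            frame_labels=ensemble.frame_labels,
            replica_ids=ensemble.replica_ids,
        ),
        rmsds,
    )
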