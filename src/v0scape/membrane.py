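"""Membrane composition bookkeeping.

Turns mol% lipid compositions into concrete, symmetric per-leaflet integer
bead counts for the bilayer hosting the V0 region.  The four standard model
systems (pure POPC and POPC with varying PI(4)P / cholesterol content, 980
lipids, 150 mM KCl, 8 replicas of 750 ns each) are exposed as ready-made
specifications.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

SPECIES = ("POPC", "PI4P", "CHOL")


class CompositionError(ValueError):
    """Raised when mol% values are out of range or do not sum to 100."""


class SymmetryError(ValueError):
    """Raised when the total lipid count cannot be split into two equal leaflets."""


@dataclass(frozen=True)
class MembraneComposition:
    """Lipid composition of a bilayer in mol%.

    Percentages must each lie in [0, 100] and sum to exactly 100.
    """

    popc_molpct: float
    pi4p_molpct: float
    chol_molpct: float
    label: str = ""

    def __post_init__(self):
        pcts = (self.popc_molpct, self.pi4p_molpct, self.chol_molpct)
        for p in pcts:
            if not (0.0 <= p <= 100.0):
                raise CompositionError(f"mol% out of [0, 100]: {p}")
        if abs(sum(pcts) - 100.0) > 1e-9:
            raise CompositionError(f"mol% must sum to 100, got {sum(pcts)}")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        parts = ["V0"]
        if self.pi4p_molpct:
            parts.append(f"{self.pi4p_molpct:g}PI4")
        if self.chol_molpct:
            parts.append(f"{self.chol_molpct:g}Chol")
        return "-".join(parts)

    @property
    def molpct(self) -> dict[str, float]:
        return {
            "POPC": self.popc_molpct,
            "PI4P": self.pi4p_molpct,
            "CHOL": self.chol_molpct,
        }


@dataclass(frozen=True)
class MembraneSpec:
    """Realized membrane: integer lipid counts per species per leaflet.

    ``per_leaflet_counts`` holds the count of each species in the upper
    (cytosolic) leaflet.  By default leaflets are symmetric and the lower
    leaflet mirrors it; an explicit ``lower_leaflet_counts`` supports
    asymmetric distributions (not part of the standard systems).
    """

    composition: MembraneComposition
    total_lipids: int
    per_leaflet_counts: dict[str, int]
    salt_mM: float = 150.0
    replicas: int = 8
    duration_ns: float = 750.0
    lower_leaflet_counts: dict[str, int] | None = None

    def __post_init__(self):
        if self.lower_leaflet_counts is None:
            object.__setattr__(
                self, "lower_leaflet_counts", dict(self.per_leaflet_counts)
            )
        total = (sum(self.per_leaflet_counts.values())
                 + sum(self.lower_leaflet_counts.values()))
        if total != self.total_lipids:
            raise SymmetryError(
                "leaflet counts do not sum to the total lipid count"
            )

    @property
    def is_symmetric(self) -> bool:
        return self.per_leaflet_counts == self.lower_leaflet_counts

    def leaflet_counts(self, side: int) -> dict[str, int]:
        """Counts for one leaflet; ``side`` +1 = upper, -1 = lower."""
        return dict(
            self.per_leaflet_counts if side > 0 else self.lower_leaflet_counts
        )

    @property
    def total_counts(self) -> dict[str, int]:
        """Per-species counts summed over both leaflets."""
        return {
            s: self.per_leaflet_counts.get(s, 0)
            + self.lower_leaflet_counts.get(s, 0)
            for s in SPECIES
        }

    def recovered_molpct(self) -> dict[str, float]:
        return {
            s: 100.0 * c / self.total_lipids for s, c in self.total_counts.items()
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.composition.label,
                "molpct": self.composition.molpct,
                "total_lipids": self.total_lipids,
                "per_leaflet_counts": self.per_leaflet_counts,
                **(
                    {}
                    if self.is_symmetric
                    else {"lower_leaflet_counts": self.lower_leaflet_counts}
                ),
                "salt_mM": self.salt_mM,
                "replicas": self.replicas,
                "duration_ns": self.duration_ns,
            },
            indent=2,
            sort_keys=True,
        )

    def to_table_row(self) -> str:
        """Tab-separated row mirroring the standard system table column order."""
        c = self.composition
        return "\t".join(
            str(v)
            for v in (
                c.label,
                f"{c.popc_molpct:g}",
                f"{c.pi4p_molpct:g}",
                f"{c.chol_molpct:g}",
                f"{self.duration_ns:g}",
                self.replicas,
            )
        )


def _largest_remainder(weights: dict[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` integer slots proportionally to ``weights``.

    Classic largest-remainder (Hamilton) rounding: floor every quota, then
    hand the leftover slots to the largest fractional remainders.  Ties are
    broken by species order for determinism.
    """
    quotas = {s: total * w / 100.0 for s, w in weights.items()}
    counts = {s: int(q) for s, q in quotas.items()}
    leftover = total - sum(counts.values())
    order = sorted(
        weights, key=lambda s: (-(quotas[s] - counts[s]), SPECIES.index(s))
    )
    for s in order[:leftover]:
        counts[s] += 1
    return counts


def build_membrane_spec(
    composition: MembraneComposition,
    total_lipids: int = 980,
    *,
    salt_mM: float = 150.0,
    replicas: int = 8,
    duration_ns: float = 750.0,
    leaflet_overrides: dict[str, tuple[int, int]] | None = None,
) -> MembraneSpec:
    """Realize a mol% composition as symmetric integer per-leaflet counts.

    Largest-remainder rounding is applied within one leaflet (the other is
    its mirror image), so each leaflet holds exactly ``total_lipids / 2``
    beads with at most one slot of rounding distortion per species.

    ``leaflet_overrides`` maps a species to explicit (upper, lower) counts
    for asymmetric distributions; the species' bilayer total must be
    preserved, so the override redistributes between leaflets only.
    """
    if total_lipids <= 0 or total_lipids % 2 != 0:
        raise SymmetryError(
            f"total_lipids must be even and positive for symmetric leaflets, "
            f"got {total_lipids}"
        )
    per_leaflet = _largest_remainder(composition.molpct, total_lipids // 2)
    lower = None
    if leaflet_overrides:
        upper = dict(per_leaflet)
        lower = dict(per_leaflet)
        for species, (up, lo) in leaflet_overrides.items():
            if up + lo != 2 * per_leaflet[species]:
                raise CompositionError(
                    f"leaflet override for {species} changes its bilayer "
                    f"total ({up}+{lo} != {2 * per_leaflet[species]})"
                )
            upper[species], lower[species] = up, lo
        per_leaflet = upper
    return MembraneSpec(
        composition=composition,
        total_lipids=total_lipids,
        per_leaflet_counts=per_leaflet,
        salt_mM=salt_mM,
        replicas=replicas,
        duration_ns=duration_ns,
        lower_leaflet_counts=lower,
    )


#: The four standard compositions (POPC / PI(4)P / cholesterol mol%).
TABLE1_COMPOSITIONS = (
    (100.0, 0.0, 0.0),
    (80.0, 20.0, 0.0),
    (70.0, 20.0, 10.0),
    (70.0, 10.0, 20.0),
)


def table1_systems() -> list[MembraneSpec]:
    """The four standard simulated model systems.

    980 lipids symmetrically distributed over two leaflets, 150 mM KCl, and
    bookkeeping metadata of 8 replicas x 750 ns per system.
    """
    return [
        build_membrane_spec(
            MembraneComposition(popc, pi4p, chol),
            total_lipids=980,
            salt_mM=150.0,
            replicas=8,
            duration_ns=750.0,
        )
        for popc, pi4p, chol in TABLE1_COMPOSITIONS
    ]
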