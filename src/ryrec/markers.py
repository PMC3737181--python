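"""Marker map and haplotype model for the *rosy* transgene recombination assay.

The assay measures intragenic meiotic recombination between two engineered,
allelic *rosy* transgenes, *ry606N* and *ry609N*, carried at the same landing
site on homologous chromosomes of a heteroallelic female.  The transgenes
differ at 25 polymorphic sites: two *selected* sites (the null point mutations
at −468 and +3506 — a gamete must carry the wild-type base at both to survive
purine selection), two *flanking* restriction-site markers (a destroyed KpnI
site at −3149 on *ry606N* and a destroyed AgeI site at +6998 on *ry609N*) used
to distinguish crossovers from noncrossovers, and 21 silent polymorphisms used
to map gene-conversion tracts.

Coordinates follow the *rosy*-locus convention in which +1 lies within an
EcoRI site in the second exon and position zero does not exist; +1 corresponds
to 3R:8,859,890 on genome assembly release 5.44.  All distance arithmetic is
done after conversion to assembly coordinates so that the missing zero can
never introduce an off-by-one across the origin.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: 3R assembly coordinate (release 5.44, 1-based) of locus position +1.
COTE_ANCHOR_3R = 8_859_890

#: Locus positions of the two selected (purine-selection) null mutations.
SELECTED_POSITIONS = (-468, 3506)

#: Locus positions of the two flanking restriction-site markers (KpnI, AgeI).
FLANKING_POSITIONS = (-3149, 6998)

#: State string denoting a deletion relative to the reference sequence.
DELETION = "-"

ROLES = ("selected", "flanking", "silent")

DEFAULT_ALLELES = ("ry_plus", "ry606N", "ry609N")


def cote_to_assembly(position: int, anchor: int = COTE_ANCHOR_3R) -> int:
    """Convert a signed locus coordinate to a 1-based assembly coordinate.

    The locus coordinate system has no zero: +1 maps to the anchor, −1 to the
    base immediately upstream of it.  Raises ``ValueError`` for position 0.
    """
    position = int(position)
    if position == 0:
        raise ValueError("position 0 does not exist in the locus coordinate system")
    return anchor + position - 1 if position > 0 else anchor + position


def assembly_to_cote(coordinate: int, anchor: int = COTE_ANCHOR_3R) -> int:
    """Inverse of :func:`cote_to_assembly`."""
    offset = int(coordinate) - anchor
    return offset + 1 if offset >= 0 else offset


@dataclass
class PolymorphicSite:
    """One polymorphic site distinguishing the transgene alleles.

    ``states`` maps each allele name to its sequence state; ``"-"`` denotes a
    deletion.  Indels are modelled as point markers at their stated position,
    so distances never count inserted bases.
    """

    position: int
    states: dict[str, str]
    role: str = "silent"
    note: str = ""

    def __post_init__(self) -> None:
        self.position = int(self.position)
        if self.position == 0:
            raise ValueError("polymorphic site at position 0: no such coordinate exists")
        if self.role not in ROLES:
            raise ValueError(f"site {self.position:+d}: unknown role {self.role!r}")
        if len(set(self.states.values())) < 2:
            raise ValueError(
                f"site {self.position:+d}: at least two allele states must differ"
            )
        if self.role == "selected" and self.position not in SELECTED_POSITIONS:
            raise ValueError(
                f"site {self.position:+d}: role 'selected' is only valid at "
                f"{SELECTED_POSITIONS}"
            )
        if self.role == "flanking" and self.position not in FLANKING_POSITIONS:
            raise ValueError(
                f"site {self.position:+d}: role 'flanking' is only valid at "
                f"{FLANKING_POSITIONS}"
            )

    @property
    def assembly_position(self) -> int:
        return cote_to_assembly(self.position)


@dataclass
class Haplotype:
    """A state vector over every site of a :class:`MarkerMap`."""

    label: str
    states: tuple[str, ...]
    marker_map: "MarkerMap" = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.states) != len(self.marker_map):
            raise ValueError(
                f"haplotype {self.label!r}: {len(self.states)} states for "
                f"{len(self.marker_map)} sites"
            )
        for site, state in zip(self.marker_map, self.states):
            if state not in site.states.values():
                raise ValueError(
                    f"haplotype {self.label!r}: state {state!r} at site "
                    f"{site.position:+d} is not one of that site's declared states"
                )

    def state(self, position: int) -> str:
        return self.states[self.marker_map.index_of(position)]

    def with_state(self, position: int, state: str) -> "Haplotype":
        """Return a copy with one site's state replaced."""
        i = self.marker_map.index_of(position)
        states = list(self.states)
        states[i] = state
        return Haplotype(self.label, tuple(states), self.marker_map)


class MarkerMap:
    """Ordered polymorphic sites of the transgene pair, with allele states."""

    def __init__(
        self,
        sites: Iterable[PolymorphicSite],
        allele_names: Sequence[str] = DEFAULT_ALLELES,
        anchor: int = COTE_ANCHOR_3R,
    ) -> None:
        sites = sorted(sites, key=lambda s: cote_to_assembly(s.position, anchor))
        if not sites:
            raise ValueError("no sites: a marker map must contain at least one site")
        positions = [s.position for s in sites]
        dupes = {p for p in positions if positions.count(p) > 1}
        if dupes:
            raise ValueError(f"duplicate position(s): {sorted(dupes)}")
        for site in sites:
            missing = [a for a in allele_names if a not in site.states]
            if missing:
                raise ValueError(
                    f"site {site.position:+d}: no state for allele(s) {missing}"
                )
        roles = {r: [s.position for s in sites if s.role == r] for r in ROLES}
        for pos in SELECTED_POSITIONS:
            if pos not in roles["selected"]:
                raise ValueError(f"missing selected site at {pos:+d}")
        for pos in FLANKING_POSITIONS:
            if pos not in roles["flanking"]:
                raise ValueError(f"missing flanking site at {pos:+d}")
        self.sites: list[PolymorphicSite] = sites
        self.allele_names = tuple(allele_names)
        self.anchor = int(anchor)
        self._index = {s.position: i for i, s in enumerate(sites)}
        self.positions = np.array(positions, dtype=np.int64)
        self.assembly_positions = np.array(
            [cote_to_assembly(p, anchor) for p in positions], dtype=np.int64
        )

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[PolymorphicSite]:
        return iter(self.sites)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerMap):
            return NotImplemented
        return (
            self.anchor == other.anchor
            and self.allele_names == other.allele_names
            and len(self) == len(other)
            and all(
                a.position == b.position
                and a.states == b.states
                and a.role == b.role
                and a.note == b.note
                for a, b in zip(self.sites, other.sites)
            )
        )

    def index_of(self, position: int) -> int:
        try:
            return self._index[int(position)]
        except KeyError:
            raise KeyError(f"no polymorphic site at position {position:+d}") from None

    def site(self, position: int) -> PolymorphicSite:
        return self.sites[self.index_of(position)]

    @property
    def span(self) -> tuple[int, int]:
        """Outermost marker positions (locus coordinates)."""
        return int(self.positions[0]), int(self.positions[-1])

    @property
    def assembly_span(self) -> tuple[int, int]:
        return int(self.assembly_positions[0]), int(self.assembly_positions[-1])

    def haplotype(self, label: str) -> Haplotype:
        """The parental haplotype for one of the map's allele names."""
        if label not in self.allele_names:
            raise KeyError(f"unknown allele {label!r}; map has {self.allele_names}")
        return Haplotype(label, tuple(s.states[label] for s in self.sites), self)

    def selected_sites(self) -> list[PolymorphicSite]:
        return [s for s in self.sites if s.role == "selected"]

    def flanking_sites(self) -> list[PolymorphicSite]:
        return [s for s in self.sites if s.role == "flanking"]


def heterologies(h1: Haplotype, h2: Haplotype, marker_map: MarkerMap | None = None) -> list[PolymorphicSite]:
    """Sites at which two haplotypes differ, in ascending position order."""
    marker_map = marker_map or h1.marker_map
    if h1.marker_map != h2.marker_map or h1.marker_map != marker_map:
        raise ValueError("haplotypes are defined on different marker maps")
    return [
        site
        for site, a, b in zip(marker_map.sites, h1.states, h2.states)
        if a != b
    ]


def is_functional(h: Haplotype, marker_map: MarkerMap | None = None) -> bool:
    """True iff the haplotype is wild type at both selected (null) positions.

    This is the purine-selection predicate: only gametes reconstituting a
    functional *rosy* gene survive the screen.
    """
    marker_map = marker_map or h.marker_map
    if h.marker_map != marker_map:
        raise ValueError("haplotype is not defined on the given marker map")
    return all(
        h.state(s.position) == s.states["ry_plus"] for s in marker_map.selected_sites()
    )


def load_marker_map(path: os.PathLike | str) -> MarkerMap:
    """Read a marker-map TSV (columns: position, one per allele, role, note)."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, na_filter=False)
    if frame.empty:
        raise ValueError(f"no sites: {path} contains no marker rows")
    required = {"position", "role"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    allele_names = [
        c for c in frame.columns if c not in ("position", "role", "note")
    ]
    if len(allele_names) < 2:
        raise ValueError(f"{path}: need at least two allele columns")
    sites = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            sites.append(
                PolymorphicSite(
                    position=int(row.position),
                    states={a: getattr(row, a) for a in allele_names},
                    role=row.role,
                    note=getattr(row, "note", ""),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {row_number}: {exc}") from exc
    return MarkerMap(sites, allele_names=allele_names)


def write_marker_map(marker_map: MarkerMap, path: os.PathLike | str) -> None:
    """Write a marker map in the same TSV layout that :func:`load_marker_map` reads."""
    frame = pd.DataFrame(
        {
            "position": [s.position for s in marker_map],
            **{
                a: [s.states[a] for s in marker_map]
                for a in marker_map.allele_names
            },
            "role": [s.role for s in marker_map],
            "note": [s.note for s in marker_map],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
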