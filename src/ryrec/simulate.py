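"""Forward simulation of meioses in *ry606N*/*ry609N* heteroallelic females.

Each transmitted chromatid independently carries a recombination event at the
transgene with a small probability.  An event initiates at a double-strand
break (DSB) drawn uniformly from a configurable window, acquires a conversion
tract extending each way from the break by independent geometric lengths, and
resolves as a crossover (CO) or a noncrossover gene conversion (NCO).
Conversion is unidirectional: the broken (recipient) chromatid copies the
donor homolog's sequence across the tract; donor information is never altered.

For a CO the exchange falls at one end of the conversion tract, so the two
reciprocal products are a recipient/donor junction at the left tract edge and
a donor/recipient junction at the right edge; the transmitted chromatid is a
fair draw between them.  Because each parental transgene is null at one
selected site, at most one CO product can be wild type at both selected
positions — purine selection therefore recovers at most half of the
crossovers, the factor-2 correction used when converting counts to map units.

The simulator also reproduces the experiment's bookkeeping: progeny totals
are estimated from the count of a single untreated bottle per tray.
"""

from __future__ import annotations

import hashlib
import os
import warnings
from dataclasses import dataclass, field, fields, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .markers import (
    Haplotype,
    MarkerMap,
    assembly_to_cote,
    cote_to_assembly,
    is_functional,
)

CO = "CO"
NCO = "NCO"


@dataclass
class SimConfig:
    """Parameters of one simulated purine-selection screen.

    Defaults are the magnitudes of the assay itself: an event probability of
    3 × 10⁻⁵ per transmitted chromatid (the scale of the observed per-progeny
    rates), a crossover resolution probability of 0.68 (the crossover share of
    events recovered at the endogenous locus, 112 of 165), a mean total
    conversion-tract length of 800 bp, and DSB initiation uniform across the
    full marker span.
    """

    n_progeny: int
    event_rate: float = 3.0e-5
    p_co: float = 0.68
    mean_tract_bp: float = 800.0
    dsb_window: tuple[int, int] | None = None  # locus coords; None = full marker span
    location_label: str = "sim"
    seed: int = 0
    selection_recovery: float = 2.0
    alleles: tuple[str, str] = ("ry606N", "ry609N")

    def __post_init__(self) -> None:
        self.n_progeny = int(self.n_progeny)
        self.event_rate = float(self.event_rate)
        self.p_co = float(self.p_co)
        self.mean_tract_bp = float(self.mean_tract_bp)
        self.seed = int(self.seed)
        self.selection_recovery = float(self.selection_recovery)
        self.alleles = tuple(self.alleles)
        if self.n_progeny < 0:
            raise ValueError("n_progeny must be nonnegative")
        if not 0.0 <= self.event_rate <= 1.0:
            raise ValueError("event_rate must lie in [0, 1]")
        if not 0.0 <= self.p_co <= 1.0:
            raise ValueError("p_co must lie in [0, 1]")
        if self.mean_tract_bp <= 0:
            raise ValueError("mean_tract_bp must be positive")
        if self.dsb_window is not None:
            self.dsb_window = (int(self.dsb_window[0]), int(self.dsb_window[1]))

    def resolved_window(self, marker_map: MarkerMap) -> tuple[int, int]:
        """DSB window in assembly coordinates, defaulting to the marker span."""
        if self.dsb_window is None:
            return marker_map.assembly_span
        lo, hi = (cote_to_assembly(p) for p in self.dsb_window)
        span_lo, span_hi = marker_map.assembly_span
        if lo > hi or lo < span_lo or hi > span_hi:
            raise ValueError(
                f"dsb_window {self.dsb_window} does not lie within the marker span "
                f"{marker_map.span}"
            )
        return lo, hi

    @classmethod
    def from_yaml(cls, path: os.PathLike | str) -> "SimConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"invalid config key(s): {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dsb_window"] = list(self.dsb_window) if self.dsb_window else None
        d["alleles"] = list(self.alleles)
        return d

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class RecombinationEvent:
    """One DSB-repair event on a transmitted chromatid.

    Positions are locus (signed) coordinates; ``tract`` is the closed interval
    of converted sequence around the break, and ``exchange_point`` (CO only)
    is the tract end at which flanking arms were exchanged.
    """

    recipient: str
    dsb_position: int
    tract: tuple[int, int]
    outcome: str
    exchange_point: int | None = None

    def __post_init__(self) -> None:
        left, right = self.tract
        if not (
            cote_to_assembly(left)
            <= cote_to_assembly(self.dsb_position)
            <= cote_to_assembly(right)
        ):
            raise ValueError("DSB position must lie inside the conversion tract")
        if self.outcome == NCO and self.exchange_point is not None:
            raise ValueError("an NCO event has no exchange point")
        if self.outcome == CO and self.exchange_point not in (left, right):
            raise ValueError("exchange point must be one end of the conversion tract")

    @property
    def assembly_tract(self) -> tuple[int, int]:
        return cote_to_assembly(self.tract[0]), cote_to_assembly(self.tract[1])

    @property
    def tract_length_bp(self) -> int:
        """Span of the true tract in bp (assembly distance between its ends)."""
        left, right = self.assembly_tract
        return right - left


@dataclass
class SimulatedProgeny:
    """One selected gamete with its generating event, for oracle testing."""

    id: str
    gamete: Haplotype
    true_event: RecombinationEvent | None
    selected: bool


def _geometric_extension(mean_bp: float, rng: np.random.Generator) -> int:
    # One-sided tract extension: shifted geometric on {0, 1, ...} with the
    # requested mean, so the total (left + right) tract averages mean_tract_bp.
    p = 1.0 / (1.0 + mean_bp)
    return int(rng.geometric(p)) - 1


def draw_event(
    config: SimConfig,
    rng: np.random.Generator,
    marker_map: MarkerMap,
) -> RecombinationEvent:
    """Draw one recombination event under the configured generative model."""
    lo, hi = config.resolved_window(marker_map)
    dsb_asm = int(rng.integers(lo, hi + 1))
    left_asm = dsb_asm - _geometric_extension(config.mean_tract_bp / 2.0, rng)
    right_asm = dsb_asm + _geometric_extension(config.mean_tract_bp / 2.0, rng)
    recipient = config.alleles[int(rng.integers(2))]
    outcome = CO if rng.random() < config.p_co else NCO
    tract = (assembly_to_cote(left_asm), assembly_to_cote(right_asm))
    exchange = None
    if outcome == CO:
        exchange = tract[int(rng.integers(2))]
    return RecombinationEvent(
        recipient=recipient,
        dsb_position=assembly_to_cote(dsb_asm),
        tract=tract,
        outcome=outcome,
        exchange_point=exchange,
    )


def co_products(
    event: RecombinationEvent,
    parents: Sequence[Haplotype],
    marker_map: MarkerMap,
) -> tuple[Haplotype, Haplotype]:
    """The two reciprocal crossover products of an event.

    With conversion confined to the recipient chromatid and the exchange at a
    tract end, the pair is always (recipient left-arm | donor from the left
    tract edge onward, donor up to the right tract edge | recipient right-arm).
    """
    recipient, donor = _resolve_parents(event, parents)
    left_asm, right_asm = event.assembly_tract
    asm = marker_map.assembly_positions
    product_left = tuple(
        r if a < left_asm else d
        for a, r, d in zip(asm, recipient.states, donor.states)
    )
    product_right = tuple(
        d if a <= right_asm else r
        for a, r, d in zip(asm, recipient.states, donor.states)
    )
    return (
        Haplotype("co_product_left", product_left, marker_map),
        Haplotype("co_product_right", product_right, marker_map),
    )


def _resolve_parents(
    event: RecombinationEvent, parents: Sequence[Haplotype]
) -> tuple[Haplotype, Haplotype]:
    labels = [p.label for p in parents]
    if event.recipient not in labels:
        raise ValueError(
            f"event recipient {event.recipient!r} is not one of the parents {labels}"
        )
    i = labels.index(event.recipient)
    return parents[i], parents[1 - i]


def apply_event(
    event: RecombinationEvent,
    parents: Sequence[Haplotype],
    marker_map: MarkerMap,
    rng: np.random.Generator,
) -> Haplotype:
    """Apply one event and return the transmitted gamete haplotype."""
    recipient, donor = _resolve_parents(event, parents)
    left_asm, right_asm = event.assembly_tract
    span_lo, span_hi = marker_map.assembly_span
    if left_asm < span_lo or right_asm > span_hi:
        warnings.warn(
            "conversion tract extends beyond the marker span; "
            "truncated to the span for state substitution",
            RuntimeWarning,
            stacklevel=2,
        )
        left_asm = max(left_asm, span_lo)
        right_asm = min(right_asm, span_hi)
    if event.outcome == NCO:
        asm = marker_map.assembly_positions
        states = tuple(
            d if left_asm <= a <= right_asm else r
            for a, r, d in zip(asm, recipient.states, donor.states)
        )
        return Haplotype("nco_gamete", states, marker_map)
    product_left, product_right = co_products(event, parents, marker_map)
    return product_left if rng.random() < 0.5 else product_right


def simulate_experiment(
    config: SimConfig, marker_map: MarkerMap
) -> tuple[int, list[SimulatedProgeny]]:
    """Simulate one selection screen; return (total progeny, selected records).

    Gametes are sampled independently.  Progeny without a recombination event
    transmit an unmodified parental transgene; those are enumerated in bulk
    since their selection status is fixed by the parental haplotypes.
    """
    rng = np.random.default_rng(config.seed)
    parents = [marker_map.haplotype(a) for a in config.alleles]
    records: list[SimulatedProgeny] = []
    n_events = int(rng.binomial(config.n_progeny, config.event_rate))
    for k in range(n_events):
        event = draw_event(config, rng, marker_map)
        gamete = apply_event(event, parents, marker_map, rng)
        if is_functional(gamete, marker_map):
            records.append(
                SimulatedProgeny(
                    id=f"{config.location_label}-{len(records) + 1:05d}",
                    gamete=gamete,
                    true_event=event,
                    selected=True,
                )
            )
    # Heteroallelic parents are both null, so parental gametes never pass
    # selection; handle the general case anyway for non-null parent labels.
    functional_parents = [p for p in parents if is_functional(p, marker_map)]
    if functional_parents:
        n_parental = config.n_progeny - n_events
        n_functional = int(
            rng.binomial(n_parental, len(functional_parents) / len(parents))
        )
        for k in range(n_functional):
            records.append(
                SimulatedProgeny(
                    id=f"{config.location_label}-p{k + 1:05d}",
                    gamete=functional_parents[k % len(functional_parents)],
                    true_event=None,
                    selected=True,
                )
            )
    return config.n_progeny, records


def estimate_progeny(
    untreated_bottle_count: int,
    bottles_per_tray: int,
    trays: int,
    multiplier_mode: str = "treated_only",
) -> int:
    """Estimate progeny screened from the single untreated bottle per tray.

    ``treated_only`` multiplies by the treated bottles per tray (one fewer
    than the tray size); ``all`` multiplies by the full tray size.
    """
    if min(untreated_bottle_count, trays) < 0:
        raise ValueError("counts must be nonnegative")
    if bottles_per_tray < 2:
        raise ValueError("a tray must contain at least two bottles")
    if multiplier_mode == "treated_only":
        per_tray = bottles_per_tray - 1
    elif multiplier_mode == "all":
        per_tray = bottles_per_tray
    else:
        raise ValueError(f"unknown multiplier_mode {multiplier_mode!r}")
    return untreated_bottle_count * per_tray * trays


# ---------------------------------------------------------------------------
# Recombinant-records table I/O


def flank_presence(gamete: Haplotype, marker_map: MarkerMap) -> dict[int, str]:
    """'present'/'absent' restriction-site status at each flanking marker.

    A flanking site is scored present when the gamete carries the wild-type
    (site-intact) state, absent when it carries the destroyed-site variant.
    """
    out = {}
    for site in marker_map.flanking_sites():
        intact = site.states["ry_plus"]
        out[site.position] = (
            "present" if gamete.state(site.position) == intact else "absent"
        )
    return out


def site_column(position: int) -> str:
    return f"{position:+d}"


def records_to_frame(
    records: Sequence[SimulatedProgeny],
    marker_map: MarkerMap,
    location_label: str,
) -> pd.DataFrame:
    """Tabulate selected gametes in the recombinant-records layout.

    Columns: id, location, flank_kpn, flank_age, one observed-state column per
    marker position, then the simulation truth (outcome and tract bounds) for
    oracle testing.
    """
    kpn_pos, age_pos = (s.position for s in marker_map.flanking_sites())
    rows = []
    for rec in records:
        flanks = flank_presence(rec.gamete, marker_map)
        row: dict[str, object] = {
            "id": rec.id,
            "location": location_label,
            "flank_kpn": flanks[kpn_pos],
            "flank_age": flanks[age_pos],
        }
        for site, state in zip(marker_map, rec.gamete.states):
            row[site_column(site.position)] = state
        if rec.true_event is not None:
            row["true_outcome"] = rec.true_event.outcome
            row["true_tract_left"] = rec.true_event.tract[0]
            row["true_tract_right"] = rec.true_event.tract[1]
        rows.append(row)
    columns = (
        ["id", "location", "flank_kpn", "flank_age"]
        + [site_column(s.position) for s in marker_map]
        + ["true_outcome", "true_tract_left", "true_tract_right"]
    )
    return pd.DataFrame(rows, columns=columns)


def write_records(
    frame: pd.DataFrame, path: os.PathLike | str, metadata: dict | None = None
) -> None:
    """Write a records TSV with commented provenance header lines."""
    with open(path, "w") as handle:
        for key, value in (metadata or {}).items():
            handle.write(f"# {key}: {value}\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_records(path: os.PathLike | str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, na_filter=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def run_summary(
    config: SimConfig, total_progeny: int, records: Sequence[SimulatedProgeny]
) -> dict:
    """Run-level JSON summary: totals, counts by true outcome, config echo."""
    n_co = sum(1 for r in records if r.true_event and r.true_event.outcome == CO)
    n_nco = sum(1 for r in records if r.true_event and r.true_event.outcome == NCO)
    return {
        "total_progeny": int(total_progeny),
        "n_selected": len(records),
        "n_true_co": n_co,
        "n_true_nco": n_nco,
        "seed": config.seed,
        "config": config.to_dict(),
    }
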