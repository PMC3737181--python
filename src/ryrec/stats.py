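"""Recombination rates, exact 2×2 comparisons, and genetic map distances.

Per-location event rates are simple proportions (events per progeny screened).
Because the screens differ in size by millions of progeny, locations are
compared with a Fisher exact test on *events versus thousands of progeny
screened* — e.g. 112 crossovers against 3710 thousand progeny at the
endogenous locus — the convention under which the assay's published p-values
are computed.  Thousands are rounded half-up to integers.

Map distances carry the selection correction: purine selection recovers only
the wild-type half of crossover products, so

    map units (cM) = 100 × recovery_factor × crossovers / progeny,

with recovery_factor = 2 by default.  For comparison with the standard
genetic map, map units are normalized by the physical interval assayed: for
the intragenic screen this is the 3974-bp span between the two selected
sites; for regional rates it is the physical size of the flanking-gene
interval in Mb.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .markers import MarkerMap, cote_to_assembly


class Rate(NamedTuple):
    """Events per progeny; ``no_events`` mirrors the dash printed for zero."""

    value: float
    no_events: bool


def event_rate(count: int, progeny: int) -> Rate:
    """Per-progeny event rate with an explicit zero-events flag."""
    if progeny <= 0:
        raise ValueError("progeny must be positive")
    if count < 0:
        raise ValueError("count must be nonnegative")
    return Rate(value=count / progeny, no_events=count == 0)


def thousands_of_progeny(progeny: int) -> int:
    """Progeny in thousands, rounded half-up."""
    return int(math.floor(progeny / 1000.0 + 0.5))


def per_thousand_table(
    count1: int, progeny1: int, count2: int, progeny2: int
) -> np.ndarray:
    """2×2 table of (events, thousands of progeny screened) for two locations."""
    if min(count1, count2) < 0:
        raise ValueError("counts must be nonnegative")
    if min(progeny1, progeny2) <= 0:
        raise ValueError("progeny must be positive")
    k1, k2 = thousands_of_progeny(progeny1), thousands_of_progeny(progeny2)
    if count1 > k1 or count2 > k2:
        raise ValueError("event count exceeds the rounded thousands of progeny")
    return np.array([[count1, k1], [count2, k2]], dtype=np.int64)


@dataclass
class FisherResult:
    table: np.ndarray
    p_two_sided: float
    method: str = "fisher-exact two-sided (sum of tables with p <= p_observed)"


def fisher_two_sided(table: Sequence[Sequence[int]]) -> FisherResult:
    """Exact conditional two-sided test of a 2×2 table.

    Sums hypergeometric probabilities, over all tables with the observed
    margins, of every table no more probable than the observed one (with a
    1e-7 relative tolerance for ties).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("table entries must be nonnegative")
    if table.sum() == 0:
        raise ValueError("table must contain at least one positive entry")
    p = float(fisher_exact(table, alternative="two-sided").pvalue)
    return FisherResult(table=table, p_two_sided=min(p, 1.0))


def map_units(co_count: int, progeny: int, recovery_factor: float = 2.0) -> float:
    """Crossover counts to centiMorgans, corrected for selection recovery."""
    if progeny <= 0:
        raise ValueError("progeny must be positive")
    if recovery_factor <= 0:
        raise ValueError("recovery_factor must be positive")
    return 100.0 * recovery_factor * co_count / progeny


def map_units_per_mb(map_units_cm: float, interval_bp: int) -> float:
    """Normalize map units by the physical interval assayed (bp → Mb)."""
    if interval_bp <= 0:
        raise ValueError("interval_bp must be positive")
    return map_units_cm / (interval_bp / 1e6)


def regional_rate(genetic_mu: float, physical_mb: float) -> float:
    """Standard-map rate over a flanking-gene interval, in cM per Mb."""
    if physical_mb <= 0:
        raise ValueError("physical span must be positive")
    return genetic_mu / physical_mb


def selected_interval_bp(marker_map: MarkerMap) -> int:
    """Inclusive physical span (bp) between the two selected sites.

    This is the interval within which a crossover restores gene function and
    is therefore the normalization span for intragenic map-unit rates
    (3974 bp on the packaged marker map).
    """
    positions = sorted(
        cote_to_assembly(s.position) for s in marker_map.selected_sites()
    )
    return positions[-1] - positions[0] + 1


@dataclass
class RateRow:
    """Counts for one genomic location of the transgene pair."""

    location: str
    assembly_coord: str
    progeny: int
    co_count: int
    nco_count: int

    @property
    def co_rate(self) -> Rate:
        return event_rate(self.co_count, self.progeny)

    @property
    def nco_rate(self) -> Rate:
        return event_rate(self.nco_count, self.progeny)


def load_location_counts(path: os.PathLike | str) -> list[RateRow]:
    """Read the per-location counts TSV (location, assembly_coord, progeny, co, nco)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"location", "progeny", "co", "nco"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        RateRow(
            location=str(r.location),
            assembly_coord=str(getattr(r, "assembly_coord", "")),
            progeny=int(r.progeny),
            co_count=int(r.co),
            nco_count=int(r.nco),
        )
        for r in frame.itertuples(index=False)
    ]


def load_intervals(path: os.PathLike | str) -> pd.DataFrame:
    """Read the regional-interval TSV (location, interval, genetic_mu, physical_mb)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"interval", "physical_mb"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return frame


def regional_table(intervals: pd.DataFrame) -> pd.DataFrame:
    """cM/Mb for every interval with a known genetic length."""
    out = intervals.copy()
    out["cm_per_mb"] = [
        regional_rate(mu, mb) if pd.notna(mu) else np.nan
        for mu, mb in zip(
            pd.to_numeric(out["genetic_mu"], errors="coerce"), out["physical_mb"]
        )
    ]
    return out


def compare_locations(
    rows: Sequence[RateRow],
    baseline: str,
    interval_bp: int = 3974,
    recovery_factor: float = 2.0,
) -> pd.DataFrame:
    """Exact-test comparison of every location against a baseline location.

    For each non-baseline location and each event class (CO, NCO): the
    events-vs-thousands 2×2 table, the two-sided Fisher p-value, the rate
    ratio versus baseline, and — for crossovers — selection-corrected map
    units per Mb over the selected interval.
    """
    labels = [r.location for r in rows]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate location label(s): {sorted(dupes)}")
    if baseline not in labels:
        raise ValueError(f"baseline {baseline!r} not among locations {labels}")
    base = next(r for r in rows if r.location == baseline)
    out = []
    for row in rows:
        if row.location == baseline:
            continue
        for event_class in ("CO", "NCO"):
            count = row.co_count if event_class == "CO" else row.nco_count
            base_count = base.co_count if event_class == "CO" else base.nco_count
            rate = event_rate(count, row.progeny)
            base_rate = event_rate(base_count, base.progeny)
            table = per_thousand_table(
                count, row.progeny, base_count, base.progeny
            )
            fisher = fisher_two_sided(table)
            record: dict[str, object] = {
                "location": row.location,
                "event_class": event_class,
                "count": count,
                "progeny": row.progeny,
                "rate": rate.value,
                "no_events": rate.no_events,
                "baseline": baseline,
                "baseline_count": base_count,
                "baseline_rate": base_rate.value,
                "rate_ratio": (
                    rate.value / base_rate.value if base_rate.value else np.nan
                ),
                "events": table[0, 0],
                "thousands": table[0, 1],
                "baseline_events": table[1, 0],
                "baseline_thousands": table[1, 1],
                "p_two_sided": fisher.p_two_sided,
            }
            if event_class == "CO":
                mu = map_units(count, row.progeny, recovery_factor)
                record["map_units"] = mu
                record["map_units_per_mb"] = map_units_per_mb(mu, interval_bp)
            else:
                record["map_units"] = np.nan
                record["map_units_per_mb"] = np.nan
            out.append(record)
    return pd.DataFrame(out)
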