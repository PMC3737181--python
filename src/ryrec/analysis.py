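"""Classification of selected recombinants and conversion-tract estimation.

Every recombinant recovered by purine selection is wild type at both null
positions, so the repair event is reconstructed from the flanking
restriction-site markers and the silent polymorphisms:

* flanking markers — *ry606N* is KpnI⁻ AgeI⁺ and *ry609N* is KpnI⁺ AgeI⁻; the
  unique single-exchange (crossover) product that restores function is
  KpnI⁺ AgeI⁺, while a gene conversion leaves the recipient's parental flank
  configuration intact and therefore identifies the recipient allele;
* conversion tracts — for a noncrossover, the sites at which the recipient
  carries the donor's state delimit the tract.  The minimum length is the span
  of the outermost converted sites, the maximum is the open interval between
  the nearest unconverted sites, and the reported (midpoint) estimate places
  each tract end halfway between the outermost converted site and its nearest
  unconverted neighbor.

All lengths are computed in assembly coordinates, so the missing zero of the
locus coordinate system cannot bias spans that straddle the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markers import Haplotype, MarkerMap, cote_to_assembly, heterologies

CLASS_CO = "CO"
CLASS_NCO_606 = "NCO_recipient_606N"
CLASS_NCO_609 = "NCO_recipient_609N"
CLASS_ANOMALOUS = "anomalous"
CLASS_UNCLASSIFIED = "unclassified"

#: Mutant allele whose parental flank configuration matches each NCO class.
RECIPIENT_OF_CLASS = {CLASS_NCO_606: "ry606N", CLASS_NCO_609: "ry609N"}


@dataclass
class RecombinantRecord:
    """One selected recombinant: flank states plus per-site genotype.

    ``genotype`` maps marker positions (locus coordinates) to observed states;
    positions absent from the mapping (or mapped to None/empty) are treated as
    not genotyped.
    """

    id: str
    location: str
    flank_kpn: str | None
    flank_age: str | None
    genotype: dict[int, str | None] = field(default_factory=dict)
    classification: str | None = None
    true_outcome: str | None = None
    true_tract: tuple[int, int] | None = None

    @classmethod
    def from_row(cls, row: Mapping[str, object], marker_map: MarkerMap) -> "RecombinantRecord":
        genotype = {}
        for site in marker_map:
            key = f"{site.position:+d}"
            state = row.get(key)
            genotype[site.position] = state if state not in (None, "") else None
        true_tract = None
        if row.get("true_tract_left") not in (None, ""):
            true_tract = (int(row["true_tract_left"]), int(row["true_tract_right"]))
        return cls(
            id=str(row.get("id", "")),
            location=str(row.get("location", "")),
            flank_kpn=row.get("flank_kpn") or None,
            flank_age=row.get("flank_age") or None,
            genotype=genotype,
            true_outcome=row.get("true_outcome") or None,
            true_tract=true_tract,
        )


def classify(record: RecombinantRecord, marker_map: MarkerMap) -> str:
    """CO/NCO call from the flanking-marker configuration.

    KpnI⁺ AgeI⁺ is the crossover product; a parental flank configuration marks
    a noncrossover conversion with the corresponding recipient; KpnI⁻ AgeI⁻
    matches neither parental nor single-exchange product and is anomalous.
    """
    valid = ("present", "absent")
    if record.flank_kpn not in valid or record.flank_age not in valid:
        record.classification = CLASS_UNCLASSIFIED
        return CLASS_UNCLASSIFIED
    table = {
        ("present", "present"): CLASS_CO,
        ("absent", "present"): CLASS_NCO_606,
        ("present", "absent"): CLASS_NCO_609,
        ("absent", "absent"): CLASS_ANOMALOUS,
    }
    record.classification = table[(record.flank_kpn, record.flank_age)]
    return record.classification


@dataclass
class ConversionCall:
    """Converted positions of one noncrossover, with genotyping caveats."""

    positions: list[int]
    discontinuous: bool
    unobserved: list[int]


def _parent_pair(marker_map: MarkerMap, recipient: str) -> tuple[Haplotype, Haplotype]:
    mutants = [a for a in marker_map.allele_names if a != "ry_plus"]
    if recipient not in mutants:
        raise ValueError(f"recipient must be one of {mutants}, got {recipient!r}")
    donor = next(a for a in mutants if a != recipient)
    return marker_map.haplotype(recipient), marker_map.haplotype(donor)


def converted_sites(
    record: RecombinantRecord, marker_map: MarkerMap, recipient: str
) -> ConversionCall:
    """Positions at which the recipient carries the donor's state.

    Considers every heterology between recipient and donor.  A donor-state
    site separated from the rest of the tract by an observed recipient-state
    site marks the call as discontinuous (reported, never dropped).
    """
    recipient_h, donor_h = _parent_pair(marker_map, recipient)
    converted: list[int] = []
    unconverted: list[int] = []
    unobserved: list[int] = []
    for site in heterologies(recipient_h, donor_h, marker_map):
        observed = record.genotype.get(site.position)
        if observed is None:
            unobserved.append(site.position)
        elif observed == donor_h.state(site.position):
            converted.append(site.position)
        elif observed == recipient_h.state(site.position):
            unconverted.append(site.position)
        else:
            raise ValueError(
                f"record {record.id!r}: state {observed!r} at site "
                f"{site.position:+d} matches neither parental allele"
            )
    discontinuous = False
    if converted:
        lo = cote_to_assembly(min(converted))
        hi = cote_to_assembly(max(converted))
        discontinuous = any(
            lo < cote_to_assembly(p) < hi for p in unconverted
        )
    return ConversionCall(converted, discontinuous, unobserved)


@dataclass
class TractEstimate:
    """Minimum / midpoint / maximum conversion-tract lengths, in bp."""

    min_bp: int
    mid_bp: float
    max_bp: int
    converted: tuple[int, ...]
    left_bound: int | None
    right_bound: int | None
    left_censored: bool
    right_censored: bool
    complete: bool = True

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored


def tract_lengths(
    converted: Sequence[int],
    marker_map: MarkerMap,
    recipient: str,
    observed: Sequence[int] | None = None,
) -> TractEstimate:
    """Tract-length bounds and the midpoint estimate for one conversion.

    With outermost converted sites c1 ≤ c2 and nearest observed unconverted
    heterologies uL < c1 and uR > c2 (assembly coordinates):

    * ``min_bp`` = c2 − c1 (0 for a single converted site),
    * ``mid_bp`` = (c2 + uR)/2 − (c1 + uL)/2,
    * ``max_bp`` = uR − uL − 1 (widest interval strictly between the bounds).

    ``observed`` restricts the informative sites to those actually genotyped
    (defaults to all heterologies).  When no observed unconverted site exists
    on a side, the bound degenerates to one base beyond the outermost
    converted marker and the estimate is flagged censored on that side.
    """
    if not converted:
        raise ValueError("no converted sites: a conversion call must be non-empty")
    recipient_h, donor_h = _parent_pair(marker_map, recipient)
    informative = [s.position for s in heterologies(recipient_h, donor_h, marker_map)]
    bad = sorted(set(converted) - set(informative))
    if bad:
        raise ValueError(
            f"converted position(s) {bad} are not heterologies between "
            f"{recipient_h.label} and {donor_h.label}"
        )
    observed_set = set(informative if observed is None else observed)
    conv_asm = sorted(cote_to_assembly(p) for p in converted)
    c1, c2 = conv_asm[0], conv_asm[-1]
    candidates = sorted(
        cote_to_assembly(p)
        for p in informative
        if p in observed_set and p not in set(converted)
    )
    lefts = [u for u in candidates if u < c1]
    rights = [u for u in candidates if u > c2]
    left_censored, right_censored = not lefts, not rights
    u_left = lefts[-1] if lefts else c1 - 1
    u_right = rights[0] if rights else c2 + 1
    asm_to_cote = {cote_to_assembly(p): p for p in informative}
    return TractEstimate(
        min_bp=c2 - c1,
        mid_bp=(c2 + u_right) / 2.0 - (c1 + u_left) / 2.0,
        max_bp=u_right - u_left - 1,
        converted=tuple(sorted(converted, key=cote_to_assembly)),
        left_bound=None if left_censored else asm_to_cote[u_left],
        right_bound=None if right_censored else asm_to_cote[u_right],
        left_censored=left_censored,
        right_censored=right_censored,
        complete=observed_set >= set(informative),
    )


@dataclass
class TractSummary:
    mean: float
    sem: float | None
    n: int


def summarize_tracts(
    estimates: Sequence[TractEstimate], which: str = "mid"
) -> TractSummary:
    """Mean ± SEM of the chosen tract statistic (SEM undefined for n = 1)."""
    if which not in ("min", "mid", "max"):
        raise ValueError(f"unknown tract statistic {which!r}")
    if not estimates:
        raise ValueError("cannot summarize an empty list of tract estimates")
    values = np.array([getattr(e, f"{which}_bp") for e in estimates], dtype=float)
    sem = None
    if len(values) > 1:
        sem = float(np.std(values, ddof=1) / math.sqrt(len(values)))
    return TractSummary(mean=float(values.mean()), sem=sem, n=len(values))


# ---------------------------------------------------------------------------
# Batch analysis of a records table


def analyze_records(frame: pd.DataFrame, marker_map: MarkerMap) -> pd.DataFrame:
    """Classify every record and estimate tract lengths for the noncrossovers.

    Returns one output row per input row: classification, recipient, converted
    sites, tract bounds/flags, and (for simulated data) agreement with the
    generating event's true outcome.
    """
    base_columns = [
        "id", "location", "classification", "recipient", "converted",
        "n_converted", "discontinuous", "min_bp", "mid_bp", "max_bp",
        "left_bound", "right_bound", "censored", "complete",
    ]
    if frame.empty:
        return pd.DataFrame(columns=base_columns)
    rows = []
    for _, raw in frame.iterrows():
        record = RecombinantRecord.from_row(raw.to_dict(), marker_map)
        call = classify(record, marker_map)
        out: dict[str, object] = {
            "id": record.id,
            "location": record.location,
            "classification": call,
            "recipient": RECIPIENT_OF_CLASS.get(call, ""),
            "converted": "",
            "n_converted": 0,
            "discontinuous": False,
            "min_bp": np.nan,
            "mid_bp": np.nan,
            "max_bp": np.nan,
            "left_bound": pd.NA,
            "right_bound": pd.NA,
            "censored": False,
            "complete": True,
        }
        if call in RECIPIENT_OF_CLASS:
            recipient = RECIPIENT_OF_CLASS[call]
            conversion = converted_sites(record, marker_map, recipient)
            out["discontinuous"] = conversion.discontinuous
            if conversion.positions:
                observed = [
                    p
                    for p in record.genotype
                    if record.genotype[p] is not None
                ]
                estimate = tract_lengths(
                    conversion.positions, marker_map, recipient, observed=observed
                )
                out.update(
                    converted=",".join(f"{p:+d}" for p in estimate.converted),
                    n_converted=len(estimate.converted),
                    min_bp=estimate.min_bp,
                    mid_bp=estimate.mid_bp,
                    max_bp=estimate.max_bp,
                    left_bound=estimate.left_bound,
                    right_bound=estimate.right_bound,
                    censored=estimate.censored,
                    complete=estimate.complete,
                )
        if record.true_outcome is not None:
            out["true_outcome"] = record.true_outcome
            out["agrees_with_truth"] = (
                (record.true_outcome == CLASS_CO and call == CLASS_CO)
                or (record.true_outcome == "NCO" and call in RECIPIENT_OF_CLASS)
            )
        rows.append(out)
    return pd.DataFrame(rows)


def summarize_by_location(
    per_record: pd.DataFrame,
    progeny: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-location counts, rates (when progeny totals are given), and tract
    statistics in the layout of the assay's summary table.

    Tract means use midpoint estimates of complete, uncensored noncrossovers;
    censored or incomplete records are tallied separately rather than pooled.
    """
    summary_columns = [
        "location", "n_records", "n_co", "n_nco", "n_anomalous",
        "n_unclassified", "n_censored_tracts", "tract_mid_mean_bp",
        "tract_mid_sem_bp", "n_tracts",
    ]
    if per_record.empty:
        return pd.DataFrame(columns=summary_columns)
    rows = []
    for location, group in per_record.groupby("location", sort=False):
        is_nco = group["classification"].isin(RECIPIENT_OF_CLASS)
        usable = group[is_nco & ~group["censored"] & group["complete"]]
        mids = usable["mid_bp"].dropna().to_numpy(dtype=float)
        row: dict[str, object] = {
            "location": location,
            "n_records": len(group),
            "n_co": int((group["classification"] == CLASS_CO).sum()),
            "n_nco": int(is_nco.sum()),
            "n_anomalous": int((group["classification"] == CLASS_ANOMALOUS).sum()),
            "n_unclassified": int(
                (group["classification"] == CLASS_UNCLASSIFIED).sum()
            ),
            "n_censored_tracts": int((is_nco & group["censored"]).sum()),
            "tract_mid_mean_bp": float(mids.mean()) if len(mids) else np.nan,
            "tract_mid_sem_bp": (
                float(np.std(mids, ddof=1) / math.sqrt(len(mids)))
                if len(mids) > 1
                else np.nan
            ),
            "n_tracts": len(mids),
        }
        if progeny and location in progeny:
            total = int(progeny[location])
            row["progeny"] = total
            row["co_rate"] = row["n_co"] / total
            row["nco_rate"] = row["n_nco"] / total
        rows.append(row)
    return pd.DataFrame(rows)
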