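import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ryrec.analysis import (
    CLASS_ANOMALOUS,
    CLASS_CO,
    CLASS_NCO_606,
    CLASS_NCO_609,
    CLASS_UNCLASSIFIED,
    RecombinantRecord,
    analyze_records,
    classify,
    converted_sites,
    summarize_tracts,
    tract_lengths,
)
from ryrec.markers import cote_to_assembly
from ryrec.simulate import SimConfig, records_to_frame, simulate_experiment


def _record(kpn, age, genotype=None, **kwargs):
    return RecombinantRecord(
        id="r1", location="6E", flank_kpn=kpn, flank_age=age,
        genotype=genotype or {}, **kwargs,
    )


def _genotype(marker_map, recipient, donor_positions):
    """Recipient genotype with donor states substituted at given positions."""
    donor = {"ry606N": "ry609N", "ry609N": "ry606N"}[recipient]
    recipient_h = marker_map.haplotype(recipient)
    donor_h = marker_map.haplotype(donor)
    return {
        s.position: (
            donor_h.state(s.position)
            if s.position in donor_positions
            else recipient_h.state(s.position)
        )
        for s in marker_map
    }


@pytest.mark.parametrize(
    "kpn, age, expected",
    [
        ("present", "present", CLASS_CO),
        ("absent", "present", CLASS_NCO_606),
        ("present", "absent", CLASS_NCO_609),
        ("absent", "absent", CLASS_ANOMALOUS),
        (None, "present", CLASS_UNCLASSIFIED),
        ("present", None, CLASS_UNCLASSIFIED),
    ],
)
def test_flanking_marker_truth_table(marker_map, kpn, age, expected):
    assert classify(_record(kpn, age), marker_map) == expected


def test_converted_sites_contiguous_conversion(marker_map):
    genotype = _genotype(marker_map, "ry609N", {3506, 3511, 3610})
    record = _record("present", "absent", genotype)
    call = converted_sites(record, marker_map, "ry609N")
    assert call.positions == [3506, 3511, 3610]
    assert not call.discontinuous
    assert call.unobserved == []


def test_converted_sites_minimal_and_discontinuous(marker_map):
    minimal = _record("absent", "present", _genotype(marker_map, "ry606N", {-468}))
    call = converted_sites(minimal, marker_map, "ry606N")
    assert call.positions == [-468] and not call.discontinuous

    skipping = _record(
        "present", "absent", _genotype(marker_map, "ry609N", {3506, 3735})
    )
    call = converted_sites(skipping, marker_map, "ry609N")
    assert call.positions == [3506, 3735]
    assert call.discontinuous, "unconverted +3610 splits the tract"


def test_converted_sites_rejects_non_parental_state(marker_map):
    genotype = _genotype(marker_map, "ry609N", {3506})
    genotype[3610] = "T"  # neither parental base at this site
    record = _record("present", "absent", genotype)
    with pytest.raises(ValueError, match=r"\+3610"):
        converted_sites(record, marker_map, "ry609N")


def test_midpoint_estimator_between_converted_and_unconverted_neighbors(marker_map):
    estimate = tract_lengths([3506, 3511, 3610], marker_map, "ry609N")
    assert (estimate.min_bp, estimate.mid_bp, estimate.max_bp) == (104, 240.5, 376)
    assert (estimate.left_bound, estimate.right_bound) == (3358, 3735)
    assert not estimate.censored and estimate.complete


def test_midpoint_estimator_single_site_full_and_partial_genotyping(marker_map):
    # all 25 sites genotyped: the nearest unconverted neighbors of -468
    full = tract_lengths([-468], marker_map, "ry606N")
    assert (full.min_bp, full.mid_bp, full.max_bp) == (0, 97.5, 194)
    assert (full.left_bound, full.right_bound) == (-527, -332)
    # only three sites genotyped: bounds fall back to the observed neighbors
    partial = tract_lengths([-468], marker_map, "ry606N", observed=[-527, -468, 73])
    assert (partial.min_bp, partial.mid_bp, partial.max_bp) == (0, 299.5, 598)
    assert (partial.left_bound, partial.right_bound) == (-527, 73)
    assert not partial.complete


def test_tract_censoring_at_the_marker_span_boundary(marker_map):
    estimate = tract_lengths([-3149, -2914], marker_map, "ry606N")
    assert estimate.left_censored and not estimate.right_censored
    assert estimate.left_bound is None
    span_lo, span_hi = marker_map.assembly_span
    assert estimate.max_bp <= span_hi - span_lo + 1


def test_tract_lengths_rejects_unmapped_positions(marker_map):
    with pytest.raises(ValueError, match="heterologies"):
        tract_lengths([-468, 999], marker_map, "ry606N")  # +999 is not a marker
    with pytest.raises(ValueError, match="non-empty"):
        tract_lengths([], marker_map, "ry606N")


def test_tract_summary_mean_and_sem(marker_map):
    from ryrec.analysis import TractEstimate

    def est(v):
        return TractEstimate(
            min_bp=0, mid_bp=v, max_bp=1000, converted=(-468,),
            left_bound=-527, right_bound=-332,
            left_censored=False, right_censored=False,
        )

    summary = summarize_tracts([est(100), est(200), est(300)], "mid")
    assert summary.mean == pytest.approx(200.0)
    assert summary.sem == pytest.approx(57.735, abs=0.001)
    assert summary.n == 3
    single = summarize_tracts([est(444)], "mid")
    assert single.mean == 444.0 and single.sem is None
    constant = summarize_tracts([est(50)] * 4, "mid")
    assert constant.sem == 0.0
    with pytest.raises(ValueError):
        summarize_tracts([], "mid")


@settings(max_examples=150, derandomize=True)
@given(data=st.data())
def test_tract_bound_ordering_is_universal(marker_map, data):
    """min <= mid <= max for any conversion call, by construction."""
    recipient = data.draw(st.sampled_from(["ry606N", "ry609N"]))
    positions = [s.position for s in marker_map]
    converted = data.draw(
        st.sets(st.sampled_from(positions), min_size=1, max_size=25)
    )
    observed = data.draw(
        st.sets(st.sampled_from(positions), max_size=25)
    ) | converted
    estimate = tract_lengths(
        sorted(converted), marker_map, recipient, observed=sorted(observed)
    )
    assert estimate.min_bp <= estimate.mid_bp <= estimate.max_bp


@pytest.fixture(scope="module")
def sim_analysis(marker_map):
    """One moderate simulated screen (every gamete event-bearing), analyzed."""
    config = SimConfig(
        n_progeny=40_000, event_rate=1.0, p_co=0.5, seed=11,
        location_label="simtest",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, records = simulate_experiment(config, marker_map)
    frame = records_to_frame(records, marker_map, config.location_label)
    return records, frame, analyze_records(frame, marker_map)


def test_classifier_agrees_with_simulated_truth_away_from_flanks(marker_map, sim_analysis):
    records, frame, per_record = sim_analysis
    flank_asm = [cote_to_assembly(p) for p in (-3149, 6998)]
    checked = 0
    for record, (_, row) in zip(records, per_record.iterrows()):
        left, right = record.true_event.assembly_tract
        if any(left <= f <= right for f in flank_asm):
            continue
        checked += 1
        assert row["agrees_with_truth"]
    assert checked > 1000


def test_estimated_bounds_bracket_the_true_tract(marker_map, sim_analysis):
    records, frame, per_record = sim_analysis
    span_lo, span_hi = marker_map.assembly_span
    checked = 0
    for record, (_, row) in zip(records, per_record.iterrows()):
        event = record.true_event
        if event.outcome != "NCO" or not row["classification"].startswith("NCO"):
            continue
        left, right = event.assembly_tract
        if left < span_lo or right > span_hi:
            continue
        checked += 1
        true_length = right - left
        assert row["min_bp"] <= true_length <= row["max_bp"]
    assert checked > 300


def test_converted_sites_always_include_the_recipient_null_site(sim_analysis):
    records, frame, per_record = sim_analysis
    null_of = {"NCO_recipient_606N": "-468", "NCO_recipient_609N": "+3506"}
    other_of = {"NCO_recipient_606N": "+3506", "NCO_recipient_609N": "-468"}
    ncos = per_record[per_record["classification"].isin(null_of)]
    assert len(ncos) > 300
    for _, row in ncos.iterrows():
        converted = row["converted"].split(",")
        assert null_of[row["classification"]] in converted
        assert other_of[row["classification"]] not in converted
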