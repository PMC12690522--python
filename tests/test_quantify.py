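"""Measurement, size filter, baseline normalization and marker-call contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ifquant as q
from conftest import make_records


def single_object_image(n_pixels=100, value=1234, pixel_size=0.1625):
    labels = np.zeros((20, 20), dtype=np.int32)
    labels.ravel()[:n_pixels] = 1
    raw = np.full((20, 20), value, dtype=np.uint16)
    image = q.MIPImage(channels={"Sox10": raw}, pixel_size=pixel_size, image_id="one")
    return q.LabelMask(labels=labels), image


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def test_area_is_pixel_count_times_pixel_size_squared():
    labels, image = single_object_image(n_pixels=100, pixel_size=0.1625)
    records = q.measure_objects(labels, image)
    assert len(records) == 1
    assert records["area_um2"].iloc[0] == pytest.approx(100 * 0.1625**2, abs=0)
    assert records["area_um2"].iloc[0] == pytest.approx(2.640625, rel=1e-15)


def test_constant_channel_mean_is_exact():
    labels, image = single_object_image(value=4321)
    records = q.measure_objects(labels, image)
    assert records["raw_Sox10"].iloc[0] == 4321.0


def test_shape_mismatch_rejected():
    labels, image = single_object_image()
    bad = q.LabelMask(labels=np.zeros((10, 10), dtype=np.int32))
    with pytest.raises(ValueError):
        q.measure_objects(bad, image)


def test_measured_intensity_recovers_truth(small_scene):
    """raw mean ~= truth cell intensity * gain + background for matched cells."""
    params, image, truth = small_scene
    labels, _ = q.segment_nuclei(image, "Hoechst")
    records = q.measure_objects(labels, image).set_index("label")
    matched = q.match_objects(truth.cells, labels, params.pixel_size)
    merged = matched.merge(truth.cells, on="cell_id")
    expected = merged["intensity_Sox10"] * params.gain + params.background_level
    observed = records.loc[merged["label"], "raw_Sox10"].to_numpy()
    # read noise (sd 50) averages down over the object's pixels; partial-border
    # pixels and discretization keep the agreement at the few-percent level
    rel_err = np.abs(observed - expected.to_numpy()) / expected.to_numpy()
    assert np.median(rel_err) < 0.05


# ---------------------------------------------------------------------------
# size filter
# ---------------------------------------------------------------------------

def test_size_filter_bounds_are_inclusive():
    records = make_records([3.0, 5.0, 10.0, 60.0, 61.0])
    kept, n_dropped = q.size_filter(records, 5.0, 60.0)
    assert list(kept["area_um2"]) == [5.0, 10.0, 60.0]
    assert n_dropped == 2


def test_size_filter_identity_bounds():
    records = make_records([0.5, 1000.0])
    kept, n_dropped = q.size_filter(records, 0.0 + 1e-12, np.inf)
    assert len(kept) == 2 and n_dropped == 0


def test_size_filter_uniform_areas_expected_retention():
    rng = np.random.default_rng(0)
    areas = rng.uniform(1.0, 80.0, size=1000)
    kept, _ = q.size_filter(make_records(areas), 5.0, 60.0)
    p = 55.0 / 79.0
    se = np.sqrt(1000 * p * (1 - p))
    assert abs(len(kept) - 1000 * p) <= 3 * se


# ---------------------------------------------------------------------------
# baseline normalization
# ---------------------------------------------------------------------------

def test_uniform_intensities_normalize_to_one():
    records = make_records(np.full(8, 10.0), Sox10=np.full(8, 321.0))
    out, baselines = q.baseline_normalize(records, ["Sox10"])
    assert np.allclose(out["norm_Sox10"], 1.0)
    assert baselines["baseline"].iloc[0] == 321.0


def test_lowest_decile_baseline_hand_computed():
    """20 records with raw 1..20: baseline = mean{1,2} = 1.5; top = 13.33..."""
    records = make_records(np.full(20, 10.0), Sox10=np.arange(1.0, 21.0))
    out, baselines = q.baseline_normalize(records, ["Sox10"], baseline_fraction=0.10)
    assert baselines["baseline"].iloc[0] == 1.5
    assert baselines["n_baseline"].iloc[0] == 2
    assert out["norm_Sox10"].iloc[-1] == pytest.approx(20.0 / 1.5, rel=1e-15)


def test_baseline_floor_of_one_record():
    records = make_records(np.full(3, 10.0), Sox10=[4.0, 8.0, 16.0])
    out, baselines = q.baseline_normalize(records, ["Sox10"], baseline_fraction=0.10)
    assert baselines["n_baseline"].iloc[0] == 1  # ceil(0.1*3) = 1
    assert list(out["norm_Sox10"]) == [1.0, 2.0, 4.0]


def test_zero_baseline_is_degenerate():
    records = make_records(np.full(10, 10.0), Sox10=np.zeros(10))
    with pytest.raises(q.DegenerateBaselineError):
        q.baseline_normalize(records, ["Sox10"])


def test_baselines_are_per_image_and_per_channel():
    a = make_records(np.full(10, 10.0), image_id="A",
                     Sox10=np.arange(10.0, 20.0), tdTomato=np.arange(100.0, 110.0))
    b = make_records(np.full(10, 10.0), image_id="B",
                     Sox10=np.arange(50.0, 60.0), tdTomato=np.arange(5.0, 15.0))
    out, baselines = q.baseline_normalize(pd.concat([a, b], ignore_index=True),
                                          ["Sox10", "tdTomato"])
    bl = baselines.set_index(["image_id", "channel"])["baseline"]
    assert bl[("A", "Sox10")] == 10.0 and bl[("B", "Sox10")] == 50.0
    assert bl[("A", "tdTomato")] == 100.0 and bl[("B", "tdTomato")] == 5.0


@given(gain=st.sampled_from([0.5, 2.0, 4.0]), seed=st.integers(0, 50))
@settings(max_examples=25, deadline=None)
def test_gain_invariance_of_normalized_values(gain, seed):
    """Power-of-two gains leave normalized values bitwise unchanged."""
    rng = np.random.default_rng(seed)
    raw = rng.uniform(100.0, 5000.0, size=30)
    base = make_records(np.full(30, 10.0), Sox10=raw)
    scaled = make_records(np.full(30, 10.0), Sox10=raw * gain)
    out1, _ = q.baseline_normalize(base, ["Sox10"])
    out2, _ = q.baseline_normalize(scaled, ["Sox10"])
    assert np.array_equal(out1["norm_Sox10"].to_numpy(), out2["norm_Sox10"].to_numpy())


# ---------------------------------------------------------------------------
# marker calls
# ---------------------------------------------------------------------------

def test_strict_rule_excludes_boundary_value():
    records = make_records([10.0], Sox10=[1.0])
    records["norm_Sox10"] = [2.5]
    thr = q.MarkerThresholds({"Sox10": q.MarkerThreshold("Sox10", 2.5, "strict")})
    calls = q.classify_markers(records, thr)
    assert not calls["call_Sox10"].iloc[0]


def test_inclusive_rule_accepts_boundary_value():
    """>=2 semantics: a value of exactly 2 is tumor, below 2 stroma."""
    records = make_records([10.0, 10.0], Sox10=[1.0, 1.0])
    records["norm_Sox10"] = [2.0, 1.999999]
    thr = q.MarkerThresholds({"Sox10": q.MarkerThreshold("Sox10", 2.0, "inclusive")})
    calls = q.classify_markers(records, thr)
    assert list(calls["call_Sox10"]) == [True, False]


def test_unknown_channel_in_thresholds_raises():
    records = make_records([10.0], Sox10=[1.0])
    records["norm_Sox10"] = [1.0]
    thr = q.MarkerThresholds({"Mitf": q.MarkerThreshold("Mitf", 2.0)})
    with pytest.raises(KeyError):
        q.classify_markers(records, thr)


def test_called_fraction_recovers_truth(small_scene, classified_records):
    """Well-separated distributions: called tracer fraction within 3 binomial SE."""
    params, _, truth = small_scene
    calls, _ = classified_records
    p_true = (truth.cells["compartment"] == "tumor").mean()
    called = calls["call_tdTomato"].mean()
    se = np.sqrt(p_true * (1 - p_true) / len(calls))
    assert abs(called - p_true) <= 3 * se + 0.02


def test_raising_cutoff_never_increases_positives(classified_records):
    calls, _ = classified_records
    counts = []
    for cutoff in (1.5, 2.0, 2.5, 3.0, 5.0):
        thr = q.MarkerThresholds({"Sox10": q.MarkerThreshold("Sox10", cutoff)})
        counts.append(int(q.classify_markers(calls, thr)["call_Sox10"].sum()))
    assert counts == sorted(counts, reverse=True)


def test_conjunction_bounded_by_marginals(classified_records):
    calls, _ = classified_records
    both = q.conjunction(calls, ["Sox10", "tdTomato"]).sum()
    assert both <= calls["call_Sox10"].sum()
    assert both <= calls["call_tdTomato"].sum()


def test_stratify_splits_by_marker_state(classified_records):
    calls, _ = classified_records
    strata = q.stratify(calls, "tdTomato", "Sox10")
    assert len(strata["positive"]) + len(strata["negative"]) == len(calls)
    # tracer intensity is higher among nuclear-marker-positive cells
    assert np.median(strata["positive"]) > np.median(strata["negative"])


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _meta(rows):
    return pd.DataFrame(rows, columns=["image_id", "sample_id", "genotype"])


def test_image_proportion_is_count_over_n():
    records = make_records(np.full(10, 10.0), Sox10=np.ones(10))
    records["norm_Sox10"] = [3.0] * 4 + [1.0] * 6
    calls = q.classify_markers(
        records, q.MarkerThresholds({"Sox10": q.MarkerThreshold("Sox10", 2.0)}))
    per_image, _, _ = q.summarize(calls, _meta([("img0", "s0", "g0")]), ["Sox10"])
    assert per_image["prop_Sox10"].iloc[0] == 0.4


def test_sample_value_is_unweighted_mean_of_images():
    """Images with proportions 0.2 (n=10) and 0.6 (n=30) average to 0.4."""
    frames = []
    for image_id, n, k in (("i1", 10, 2), ("i2", 30, 18)):
        r = make_records(np.full(n, 10.0), image_id=image_id, Sox10=np.ones(n))
        r["norm_Sox10"] = [3.0] * k + [1.0] * (n - k)
        frames.append(r)
    calls = q.classify_markers(
        pd.concat(frames, ignore_index=True),
        q.MarkerThresholds({"Sox10": q.MarkerThreshold("Sox10", 2.0)}))
    meta = _meta([("i1", "s0", "g0"), ("i2", "s0", "g0")])
    _, per_sample, _ = q.summarize(calls, meta, ["Sox10"])
    pooled = 20 / 40
    assert per_sample["prop_Sox10"].iloc[0] == pytest.approx(0.4, abs=1e-15)
    assert per_sample["prop_Sox10"].iloc[0] != pooled


def test_empty_image_flagged_and_excluded():
    records = make_records(np.full(5, 10.0), image_id="full", Sox10=np.ones(5))
    records["norm_Sox10"] = 3.0
    calls = q.classify_markers(
        records, q.MarkerThresholds({"Sox10": q.MarkerThreshold("Sox10", 2.0)}))
    meta = _meta([("full", "s0", "g0"), ("void", "s0", "g0")])
    per_image, per_sample, _ = q.summarize(calls, meta, ["Sox10"])
    void_row = per_image.set_index("image_id").loc["void"]
    assert bool(void_row["empty"])
    assert per_sample["n_images"].iloc[0] == 1  # void excluded, not a silent zero
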