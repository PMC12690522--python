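"""Self-validation benchmarks: each stage re-checked against an oracle.

These routines regenerate their own inputs (random probability maps,
constructed disk pairs, a full synthetic cohort) and measure how well the
pipeline recovers known truth. They back both the acceptance test suite and
``scripts/acceptance.py``; all randomness is seeded.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import km_estimate, mann_whitney
from .pipeline import RunConfig, run_pipeline
from .quantify import (MarkerThreshold, MarkerThresholds, classify_markers,
                       size_filter)
from .segmentation import otsu_threshold, watershed_split
from .synthetic import SyntheticCohortParams, generate_survival_table

__all__ = [
    "exhaustive_otsu",
    "otsu_oracle_benchmark",
    "watershed_pair_benchmark",
    "normalization_invariance_benchmark",
    "recovery_cohort_config",
    "recovery_benchmark",
    "mann_whitney_enumeration_benchmark",
    "mann_whitney_type1_benchmark",
    "km_benchmark",
    "size_filter_audit",
]


# ---------------------------------------------------------------------------
# 1. Otsu vs exhaustive scan
# ---------------------------------------------------------------------------

def exhaustive_otsu(values: np.ndarray, n_bins: int = 256) -> float:
    """Reference Otsu: explicit loop over every histogram cut point.

    Cuts directly after an empty bin repeat an earlier partition and are
    skipped, so every candidate partition is scored exactly once.
    """
    counts, edges = np.histogram(values, bins=n_bins,
                                 range=(float(values.min()), float(values.max())))
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    best_var, best_idx = -1.0, 0
    for k in range(n_bins - 1):
        n0 = counts[: k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0 or counts[k] == 0:
            continue
        mu0 = float((counts[: k + 1] * centers[: k + 1]).sum()) / n0
        mu1 = float((counts[k + 1:] * centers[k + 1:]).sum()) / n1
        var = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_idx = var, k
    return float(centers[best_idx])


def otsu_oracle_benchmark(n_maps: int = 200, seed: int = 0) -> dict:
    """Fraction of random probability maps where both routes agree exactly."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_maps):
        n_lo = int(rng.integers(300, 3000))
        n_hi = int(rng.integers(100, 1500))
        values = np.concatenate([rng.beta(2.0, 8.0, n_lo), rng.beta(8.0, 2.0, n_hi)])
        t_impl, _ = otsu_threshold(values)
        if t_impl == exhaustive_otsu(values):
            agree += 1
    return {"agreement_rate": agree / n_maps, "n": n_maps}


# ---------------------------------------------------------------------------
# 2. watershed on constructed touching pairs
# ---------------------------------------------------------------------------

def watershed_pair_benchmark(n_scenes: int = 100, seed: int = 0,
                             pixel_size: float = 0.325,
                             area_tolerance: float = 0.15) -> dict:
    """Equal-disk pairs at 0.9x summed radii: how often do they split cleanly?

    Success = exactly 2 labels with each label's area within
    ``area_tolerance`` of a single disk's pixel count.
    """
    rng = np.random.default_rng(seed)
    successes = 0
    for _ in range(n_scenes):
        radius_um = rng.uniform(2.0, 4.3)  # nuclei of ~12.5-58 um^2
        r = radius_um / pixel_size
        d = 0.9 * 2.0 * r
        h = int(math.ceil(4 * r + 8))
        w = int(math.ceil(4 * r + d + 8))
        rr, cc = np.ogrid[:h, :w]
        c0 = (h / 2.0, 2 * r + 2)
        c1 = (h / 2.0, 2 * r + 2 + d)
        disk0 = (rr - c0[0]) ** 2 + (cc - c0[1]) ** 2 <= r**2
        disk1 = (rr - c1[0]) ** 2 + (cc - c1[1]) ** 2 <= r**2
        result = watershed_split(disk0 | disk1, min_seed_distance=2.5,
                                 pixel_size=pixel_size)
        if result.n_objects != 2:
            continue
        areas = np.bincount(result.labels.ravel())[1:]
        truth_area = disk0.sum()
        if np.all(np.abs(areas - truth_area) / truth_area <= area_tolerance):
            successes += 1
    return {"success_rate": successes / n_scenes, "n": n_scenes}


# ---------------------------------------------------------------------------
# 3. normalization gain invariance
# ---------------------------------------------------------------------------

def normalization_invariance_benchmark(seed: int = 0,
                                       gains=(0.5, 2.0, 10.0)) -> dict:
    """Scale raw intensities by g and re-export: tables must not change.

    Measured records from one synthetic image are rescaled per channel, then
    re-normalized, re-classified and re-summarized; the exported normalized
    values, calls and proportions are compared byte-for-byte against the
    unscaled export.
    """
    import io

    from .quantify import baseline_normalize, measure_objects, summarize
    from .segmentation import segment_nuclei
    from .synthetic import SceneParams, generate_scene

    params = SceneParams(image_shape=(768, 768), pixel_size=0.325, n_cells=250,
                         seed=seed)
    image, _ = generate_scene(params)
    labels, _ = segment_nuclei(image, "Hoechst")
    records = measure_objects(labels, image)
    records, _ = size_filter(records)
    channels = ["Sox10", "tdTomato"]
    thresholds = MarkerThresholds({c: MarkerThreshold(c, 2.0) for c in channels})
    meta = pd.DataFrame([[image.image_id, "s0", "g0"]],
                        columns=["image_id", "sample_id", "genotype"])

    def export(rec: pd.DataFrame) -> bytes:
        norm, _ = baseline_normalize(rec, channels)
        calls = classify_markers(norm, thresholds)
        per_image, _, _ = summarize(calls, meta, channels)
        buf = io.StringIO()
        cols = ([f"norm_{c}" for c in channels] + [f"call_{c}" for c in channels])
        calls[cols].to_csv(buf, index=False, float_format="%.6g")
        per_image.to_csv(buf, index=False, float_format="%.6g")
        return buf.getvalue().encode()

    reference = export(records)
    identical = 0
    for g in gains:
        scaled = records.copy()
        for c in channels:
            scaled[f"raw_{c}"] = scaled[f"raw_{c}"] * g
        if export(scaled) == reference:
            identical += 1
    return {"identical_fraction": identical / len(gains), "n": len(gains),
            "gains": list(gains)}


# ---------------------------------------------------------------------------
# 4. end-to-end parameter recovery
# ---------------------------------------------------------------------------

def recovery_cohort_config(output_dir, seed: int = 0) -> RunConfig:
    """The standard recovery cohort: 3 genotypes x 3 samples x 5 images,
    500 cells per image on a 1024x1024 field at 0.325 um/px."""
    return RunConfig.from_dict({
        "output_dir": str(output_dir),
        "seed": seed,
        "scene": {"image_shape": [1024, 1024], "pixel_size": 0.325,
                  "n_cells": 500},
        "genotypes": {"Ctrl": {"tumor_fraction": 0.4},
                      "Ezh2_GOF": {"tumor_fraction": 0.5},
                      "Wnt_GOF": {"tumor_fraction": 0.3}},
        "samples_per_genotype": 3,
        "images_per_sample": 5,
        "thresholds": "tracer_pair2",
    })


def recovery_benchmark(output_dir, seed: int = 0) -> dict:
    """Run the full pipeline on the recovery cohort and score it against truth.

    Returns, per genotype and overall: the recovered tracer-positive fraction
    (mean of per-image proportions), the recovered nuclear-marker-positive
    fraction among tracer-positive nuclei, their deviations from the realized
    generator truth (percentage points), and per-image checks of cutoff
    monotonicity and conjunction bounds.
    """
    config = recovery_cohort_config(output_dir, seed)
    run_pipeline(config)
    out = Path(config.output_dir)
    nuclei = pd.read_csv(out / "nuclei.csv")
    per_image = pd.read_csv(out / "summary_per_image.csv")
    truth = pd.read_csv(out / "ground_truth.csv")
    meta = per_image.set_index("image_id")["genotype"]

    genotype_stats = {}
    tracer_errors, within_errors = [], []
    for genotype, t in truth.groupby("genotype"):
        true_tracer = t["tdTomato"].mean()
        true_within = t.loc[t["tdTomato"], "Sox10"].mean()
        images = meta.index[meta == genotype]
        est_tracer = per_image.set_index("image_id").loc[images, "prop_tdTomato"].mean()
        sub = nuclei[nuclei["image_id"].isin(images)]
        per_img_within = []
        for _, g in sub.groupby("image_id"):
            pos = g[g["call_tdTomato"]]
            if len(pos):
                per_img_within.append(pos["call_Sox10"].mean())
        est_within = float(np.mean(per_img_within))
        tracer_errors.append(abs(est_tracer - true_tracer))
        within_errors.append(abs(est_within - true_within))
        genotype_stats[genotype] = {
            "true_tracer_fraction": float(true_tracer),
            "recovered_tracer_fraction": float(est_tracer),
            "true_sox10_within_tracer": float(true_within),
            "recovered_sox10_within_tracer": est_within,
        }

    # per-image structural invariants: cutoff monotonicity + conjunction bounds
    monotone = True
    conjunction_ok = True
    for _, g in nuclei.groupby("image_id"):
        prev = None
        for cutoff in (1.5, 2.0, 3.0, 5.0):
            thr = MarkerThresholds({"Sox10": MarkerThreshold("Sox10", cutoff)})
            count = int(classify_markers(g, thr)["call_Sox10"].sum())
            if prev is not None and count > prev:
                monotone = False
            prev = count
        n_both = int((g["call_Sox10"] & g["call_tdTomato"]).sum())
        if n_both > min(g["call_Sox10"].sum(), g["call_tdTomato"].sum()):
            conjunction_ok = False

    return {
        "genotypes": genotype_stats,
        "max_tracer_error_pp": 100.0 * max(tracer_errors),
        "max_within_error_pp": 100.0 * max(within_errors),
        "cutoff_monotonicity_ok": monotone,
        "conjunction_bounds_ok": conjunction_ok,
        "n_images": int(per_image.shape[0]),
        "n_nuclei": int(len(nuclei)),
    }


# ---------------------------------------------------------------------------
# 5. Mann-Whitney
# ---------------------------------------------------------------------------

def mann_whitney_enumeration_benchmark(max_total: int = 10) -> dict:
    """Exact p vs brute-force enumeration over all tie-free rank patterns."""
    import itertools

    checked, agree = 0, 0
    for n in range(2, max_total + 1):
        for n1 in range(1, n):
            for subset in itertools.combinations(range(1, n + 1), n1):
                x = np.array(subset, dtype=float)
                y = np.array(sorted(set(range(1, n + 1)) - set(subset)), dtype=float)
                result = mann_whitney(x, y)
                u_obs = result.u
                us = np.array([sum(c) - n1 * (n1 + 1) / 2 for c in
                               itertools.combinations(range(1, n + 1), n1)])
                p_ref = min(1.0, 2.0 * min(float(np.mean(us <= u_obs)),
                                           float(np.mean(us >= u_obs))))
                checked += 1
                if result.method == "exact" and abs(result.p - p_ref) < 1e-12:
                    agree += 1
    return {"agreement_rate": agree / checked, "n": checked}


def mann_whitney_type1_benchmark(n_replicates: int = 2000, n_per_group: int = 50,
                                 alpha: float = 0.05, seed: int = 0) -> dict:
    """Null rejection rate: both samples from the same continuous distribution."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        x = rng.standard_normal(n_per_group)
        y = rng.standard_normal(n_per_group)
        if mann_whitney(x, y, alpha=alpha).significant:
            rejections += 1
    return {"rejection_rate": rejections / n_replicates, "n": n_replicates,
            "alpha": alpha}


# ---------------------------------------------------------------------------
# 6. Kaplan-Meier
# ---------------------------------------------------------------------------

def km_benchmark(seed: int = 0, medians=(22.0, 32.0, 161.0),
                 n_animals: int = 10_000, n_random_tables: int = 100) -> dict:
    """Hand-worked censoring case, empirical-survival equality, median recovery."""
    hand = km_estimate(pd.DataFrame({
        "animal_id": list("abcd"), "group": "g",
        "time_days": [5.0, 8.0, 12.0, 16.0],
        "event": [True, False, True, True]}))
    hand_ok = (abs(hand.survival_at(5) - 0.75) < 1e-12
               and abs(hand.survival_at(12) - 0.375) < 1e-12
               and hand.median == 12.0)

    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for _ in range(n_random_tables):
        n = int(rng.integers(3, 50))
        times = rng.exponential(30.0, size=n)
        curve = km_estimate(pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(n)], "group": "g",
            "time_days": times, "event": True}))
        for t in curve.times:
            max_dev = max(max_dev, abs(curve.survival_at(t) - np.mean(times > t)))

    recovered = {}
    for m in medians:
        table = generate_survival_table(SyntheticCohortParams(
            n_animals=n_animals, median_survival=m, censor_fraction=0.0,
            seed=int(rng.integers(0, 2**31 - 1))))
        curve = km_estimate(table)
        recovered[m] = {"km_median": float(curve.median),
                        "relative_error": abs(curve.median - m) / m}
    return {"hand_case_ok": hand_ok,
            "max_empirical_deviation": max_dev,
            "median_recovery": recovered,
            "n_random_tables": n_random_tables}


# ---------------------------------------------------------------------------
# 7. size-filter audit
# ---------------------------------------------------------------------------

def size_filter_audit() -> dict:
    """Boundary-spanning record set: inclusive 5/60 um^2 retention, exact."""
    areas = [3.0, 4.999999, 5.0, 10.0, 59.999999, 60.0, 60.000001, 61.0]
    records = pd.DataFrame({"image_id": "audit", "label": range(1, len(areas) + 1),
                            "area_um2": areas, "n_pixels": 1})
    kept, n_dropped = size_filter(records, 5.0, 60.0)
    return {"n_input": len(areas), "n_retained": int(len(kept)),
            "n_dropped": n_dropped,
            "retained_areas": [float(a) for a in kept["area_um2"]],
            "expected_retained": [5.0, 10.0, 59.999999, 60.0]}
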