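"""Per-nucleus measurement, size filtering, normalization, marker calls.

This is the cytometric core: each segmented nucleus becomes one record
carrying its projected area (um^2) and the mean raw intensity of every
channel over its pixels. Records are filtered to a plausible nuclear-area
window (5-60 um^2 by default, bounds inclusive), each channel is then
normalized per image to the mean intensity of the lowest 10% of the
size-filtered nuclei — the "negative cell" baseline — and markers are called
against fixed normalized-intensity cutoffs that are identical across all
images and samples.

Records live in pandas DataFrames with columns::

    image_id, label, area_um2, n_pixels, raw_<channel>..., norm_<channel>...,
    call_<marker>...

Background is deliberately NOT subtracted before normalization (the
procedure divides only); the resulting additive bias is documented and
exercised in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import DegenerateBaselineError
from .image import LabelMask, MIPImage

__all__ = [
    "MarkerThreshold",
    "MarkerThresholds",
    "THRESHOLD_PRESETS",
    "measure_objects",
    "size_filter",
    "baseline_normalize",
    "classify_markers",
    "conjunction",
    "stratify",
    "summarize",
]


# --------------------------------------------------------------------------
# thresholds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerThreshold:
    """Cutoff on normalized intensity for one marker.

    ``rule`` is 'strict' (positive iff value > cutoff) or 'inclusive'
    (positive iff value >= cutoff); the inclusive rule expresses
    ">=2: tumor / <2: stroma"-style stratifications.
    """

    channel: str
    cutoff: float
    rule: str = "strict"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.rule not in ("strict", "inclusive"):
            raise ValueError(f"rule must be 'strict' or 'inclusive', got {self.rule!r}")

    def call(self, values: np.ndarray) -> np.ndarray:
        if self.rule == "strict":
            return values > self.cutoff
        return values >= self.cutoff


@dataclass
class MarkerThresholds:
    """Named set of per-marker cutoffs applied uniformly to a whole run."""

    markers: dict[str, MarkerThreshold] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, spec: dict) -> "MarkerThresholds":
        """Build from ``{marker: cutoff}`` or ``{marker: {channel, cutoff, rule}}``."""
        markers = {}
        for name, v in spec.items():
            if isinstance(v, dict):
                markers[name] = MarkerThreshold(channel=v.get("channel", name),
                                                cutoff=float(v["cutoff"]),
                                                rule=v.get("rule", "strict"))
            else:
                markers[name] = MarkerThreshold(channel=name, cutoff=float(v))
        return cls(markers=markers)

    def __iter__(self):
        return iter(self.markers.items())


#: Shipped cutoff sets. "lineage_high" is the high-stringency pair used for
#: lineage scoring (Sox10 > 2.5, tdTomato > 3); "uniform2" calls every marker
#: at > 2, the working cutoff for proportion panels; the inclusive >=2 form
#: used for tumor/stroma stratification is available per-marker via
#: rule='inclusive'.
THRESHOLD_PRESETS: dict[str, dict] = {
    "lineage_high": {"Sox10": 2.5, "tdTomato": 3.0},
    "tracer_pair2": {"Sox10": 2.0, "tdTomato": 2.0},
    "uniform2": {"Sox10": 2.0, "tdTomato": 2.0, "Pcna": 2.0, "Mitf": 2.0, "Tyrp2": 2.0},
}


def thresholds_from_preset(name: str) -> MarkerThresholds:
    if name not in THRESHOLD_PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(THRESHOLD_PRESETS)}")
    return MarkerThresholds.from_dict(THRESHOLD_PRESETS[name])


# --------------------------------------------------------------------------
# measurement
# --------------------------------------------------------------------------

def measure_objects(labels: LabelMask, image: MIPImage) -> pd.DataFrame:
    """One record per labeled object: area and per-channel raw mean intensity.

    area_um2 = pixel count x pixel_size^2; raw_<channel> is the arithmetic
    mean of the channel over the object's pixels.
    """
    if labels.labels.shape != image.shape:
        raise ValueError(f"label shape {labels.labels.shape} != image shape {image.shape}")
    n = labels.n_objects
    index = np.arange(1, n + 1)
    counts = np.bincount(labels.labels.ravel(), minlength=n + 1)[1:]
    data = {
        "image_id": image.image_id,
        "label": index,
        "area_um2": counts * image.pixel_size**2,
        "n_pixels": counts,
    }
    for name, ch in image.channels.items():
        if n:
            data[f"raw_{name}"] = ndi.mean(ch.astype(np.float64), labels.labels, index)
        else:
            data[f"raw_{name}"] = np.empty(0)
    return pd.DataFrame(data)


def size_filter(records: pd.DataFrame, min_area: float = 5.0,
                max_area: float = 60.0) -> tuple[pd.DataFrame, int]:
    """Retain records with min_area <= area_um2 <= max_area (inclusive bounds).

    Returns the filtered frame (input order preserved) and the number of
    records removed, which callers log for auditability.
    """
    if not min_area < max_area:
        raise ValueError("min_area must be < max_area")
    keep = (records["area_um2"] >= min_area) & (records["area_um2"] <= max_area)
    return records.loc[keep].copy(), int((~keep).sum())


def baseline_normalize(records: pd.DataFrame, channels: list[str] | None = None,
                       baseline_fraction: float = 0.10,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize each channel per image to its lowest-decile baseline.

    For every image and channel independently: rank the (size-filtered)
    records by raw mean, take the ceil(baseline_fraction * n) lowest (at
    least 1), average their raw means — that is the image's "negative cell"
    baseline — and divide every record's raw mean by it.

    Returns the records with ``norm_<channel>`` columns added and a frame of
    the baselines used (image_id, channel, baseline, n_baseline).

    Raises :class:`DegenerateBaselineError` if any baseline is zero.
    """
    if not 0.0 < baseline_fraction <= 1.0:
        raise ValueError("baseline_fraction must be in (0, 1]")
    if channels is None:
        channels = [c[len("raw_"):] for c in records.columns if c.startswith("raw_")]
    out = records.copy()
    baselines = []
    for ch in channels:
        col = f"raw_{ch}"
        if col not in records.columns:
            raise KeyError(f"no measurements for channel {ch!r}")
        out[f"norm_{ch}"] = np.nan
    for image_id, group in records.groupby("image_id", sort=False):
        n = len(group)
        if n == 0:
            continue
        k = max(1, math.ceil(baseline_fraction * n))
        for ch in channels:
            raw = group[f"raw_{ch}"].to_numpy(dtype=np.float64)
            lowest = np.sort(raw)[:k]
            baseline = float(lowest.mean())
            if baseline == 0.0:
                raise DegenerateBaselineError(
                    f"image {image_id!r}, channel {ch!r}: lowest-{baseline_fraction:.0%} "
                    "baseline is zero; cannot normalize")
            out.loc[group.index, f"norm_{ch}"] = raw / baseline
            baselines.append((image_id, ch, baseline, k))
    return out, pd.DataFrame(baselines,
                             columns=["image_id", "channel", "baseline", "n_baseline"])


def classify_markers(records: pd.DataFrame,
                     thresholds: MarkerThresholds) -> pd.DataFrame:
    """Add boolean ``call_<marker>`` columns from normalized intensities."""
    out = records.copy()
    for marker, thr in thresholds:
        col = f"norm_{thr.channel}"
        if col not in records.columns:
            raise KeyError(f"marker {marker!r}: no normalized values for channel "
                           f"{thr.channel!r} (expected column {col})")
        out[f"call_{marker}"] = thr.call(records[col].to_numpy(dtype=np.float64))
    return out


def conjunction(records: pd.DataFrame, markers: list[str]) -> np.ndarray:
    """Boolean AND of several marker calls (e.g. Sox10+ among tdTomato+)."""
    result = np.ones(len(records), dtype=bool)
    for m in markers:
        result &= records[f"call_{m}"].to_numpy(dtype=bool)
    return result


def stratify(records: pd.DataFrame, value_channel: str, by_marker: str,
             ) -> dict[str, np.ndarray]:
    """Normalized intensities of one channel grouped by another marker's call.

    Returns ``{'positive': values, 'negative': values}`` of
    ``norm_<value_channel>``, split on ``call_<by_marker>`` — the
    "intensity of X aggregated per Y expression level" view.
    """
    vals = records[f"norm_{value_channel}"].to_numpy(dtype=np.float64)
    state = records[f"call_{by_marker}"].to_numpy(dtype=bool)
    return {"positive": vals[state], "negative": vals[~state]}


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def summarize(records: pd.DataFrame,
              image_meta: pd.DataFrame,
              markers: list[str],
              conjunctions: list[tuple[str, ...]] = (),
              ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Roll up marker calls image -> sample -> genotype.

    Per-image proportions are computed first; the sample value is the
    unweighted mean of its images' proportions (never the pooled-count
    ratio); the genotype table collects sample values and their mean.

    Parameters
    ----------
    records
        Classified records (``call_`` columns present).
    image_meta
        Columns image_id, sample_id, genotype; every image maps to exactly
        one sample and every sample to one genotype.
    markers
        Marker names to summarize.
    conjunctions
        Marker tuples summarized jointly, e.g. ``[("Sox10", "tdTomato")]``;
        reported under the column name ``"A&B"``.

    Returns (per_image, per_sample, per_genotype) frames. Images present in
    ``image_meta`` but with no records after filtering appear in the
    per-image frame flagged ``empty=True`` and are excluded from roll-ups.
    """
    meta = image_meta.drop_duplicates("image_id").set_index("image_id")
    if meta["sample_id"].isna().any() or meta["genotype"].isna().any():
        raise ValueError("image_meta requires sample_id and genotype for every image")
    prop_cols = list(markers) + ["&".join(c) for c in conjunctions]

    rows = []
    grouped = dict(list(records.groupby("image_id", sort=False)))
    for image_id, m in meta.iterrows():
        g = grouped.get(image_id)
        row = {"image_id": image_id, "sample_id": m["sample_id"],
               "genotype": m["genotype"],
               "n_nuclei": 0 if g is None else len(g),
               "empty": g is None or len(g) == 0}
        if not row["empty"]:
            n = len(g)
            for mk in markers:
                row[f"count_{mk}"] = int(g[f"call_{mk}"].sum())
                row[f"prop_{mk}"] = row[f"count_{mk}"] / n
            for conj in conjunctions:
                name = "&".join(conj)
                cnt = int(conjunction(g, list(conj)).sum())
                row[f"count_{name}"] = cnt
                row[f"prop_{name}"] = cnt / n
        rows.append(row)
    per_image = pd.DataFrame(rows)

    usable = per_image.loc[~per_image["empty"]]
    agg = {f"prop_{c}": (f"prop_{c}", "mean") for c in prop_cols}
    agg["mean_nuclei_per_image"] = ("n_nuclei", "mean")
    per_sample = (usable.groupby(["genotype", "sample_id"], sort=False)
                  .agg(n_images=("image_id", "count"), **agg)
                  .reset_index())
    per_genotype = (per_sample.groupby("genotype", sort=False)
                    .agg(n_samples=("sample_id", "count"),
                         **{f"prop_{c}": (f"prop_{c}", "mean") for c in prop_cols})
                    .reset_index())
    return per_image, per_sample, per_genotype
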