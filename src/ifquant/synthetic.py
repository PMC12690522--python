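"""Synthetic fluorescence scenes and cohort tables with known ground truth.

The generator emulates the acquisition this pipeline is built for: 16-bit
maximum-intensity projections from a 2304x2304 sCMOS sensor behind a 40x
objective (6.5 um sensor pixels, hence 0.1625 um/px in the sample plane),
containing a Hoechst-counterstained nuclear compartment split into a traced
tumor population (lineage tracer + nuclear marker co-expression) and an
unlabeled stromal population. Nuclei are axis-aligned ellipses with mild
eccentricity jitter and projected areas drawn uniformly from a configurable
range; marker intensity is constant across a cell's pixels before noise and
drawn from a lognormal whose median is the positive- or negative-state
location parameter. Per image, a multiplicative gain and an additive
background are applied, then per-pixel Gaussian read noise.

Every scene ships with a ground-truth sidecar (per-cell centroid, area,
compartment and marker states) so downstream stages can be tested by
parameter recovery rather than against fixed images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SceneOvercrowdedError
from .image import LabelMask, MIPImage

__all__ = [
    "MarkerSpec",
    "SceneParams",
    "SyntheticGroundTruth",
    "SyntheticCohortParams",
    "generate_scene",
    "generate_survival_table",
    "generate_growth_tables",
    "match_objects",
    "default_markers",
]


@dataclass(frozen=True)
class MarkerSpec:
    """One marker channel: positive fractions per compartment and intensities.

    ``mean_positive`` / ``mean_negative`` are the lognormal medians (counts,
    before gain and background); ``dispersion`` is the lognormal sigma.
    """

    channel: str
    positive_fraction_tumor: float
    positive_fraction_stroma: float
    mean_positive: float = 8000.0
    mean_negative: float = 400.0
    dispersion: float = 0.3

    def validate(self) -> None:
        for f in (self.positive_fraction_tumor, self.positive_fraction_stroma):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"marker {self.channel!r}: fraction {f} outside [0,1]")
        if self.mean_positive <= 0 or self.mean_negative <= 0:
            raise ValueError(f"marker {self.channel!r}: intensities must be positive")
        if self.dispersion < 0:
            raise ValueError(f"marker {self.channel!r}: dispersion must be >= 0")


def default_markers() -> list[MarkerSpec]:
    """Tumor compartment co-expressing a tracer and a nuclear marker.

    The tracer (tdTomato-like) defines the traced compartment exactly; the
    nuclear marker (Sox10-like) is expressed by nearly all traced cells and
    almost no stromal cells.
    """
    return [
        MarkerSpec("Sox10", positive_fraction_tumor=0.95, positive_fraction_stroma=0.02),
        MarkerSpec("tdTomato", positive_fraction_tumor=1.0, positive_fraction_stroma=0.0),
    ]


@dataclass
class SceneParams:
    """Parameters of one synthetic field of view.

    Defaults emulate the target acquisition: full-sensor 2304x2304 frame at
    0.1625 um/px, nuclei of 5-60 um^2 projected area, 40% of cells in the
    traced tumor compartment.
    """

    image_shape: tuple[int, int] = (2304, 2304)
    pixel_size: float = 0.1625  # um per pixel edge: 6.5 um sensor pixel / 40x
    n_cells: int = 500
    tumor_fraction: float = 0.4
    markers: list[MarkerSpec] = field(default_factory=default_markers)
    nucleus_area_range: tuple[float, float] = (5.0, 60.0)  # um^2
    touching_pair_fraction: float = 0.1
    background_level: float = 300.0  # counts, additive after gain
    gain: float = 1.0
    nuclear_channel: str = "Hoechst"
    nuclear_intensity: float = 15000.0  # lognormal median, counts before gain
    nuclear_dispersion: float = 0.15
    read_noise_sd: float = 50.0  # counts, per pixel, after gain
    min_gap: float = 1.5  # um of clearance enforced between non-touching nuclei
    max_place_attempts: int = 200  # per cell before declaring overcrowding
    seed: int = 0

    def validate(self) -> None:
        nr, nc = self.image_shape
        if nr < 8 or nc < 8:
            raise ValueError("image_shape too small")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name, f in (("tumor_fraction", self.tumor_fraction),
                        ("touching_pair_fraction", self.touching_pair_fraction)):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} {f} outside [0,1]")
        lo, hi = self.nucleus_area_range
        if not 0 < lo < hi:
            raise ValueError("nucleus_area_range must satisfy 0 < min < max")
        # largest nucleus must fit in the field
        max_r = math.sqrt(hi / math.pi) / self.pixel_size
        if 2 * max_r >= min(nr, nc):
            raise ValueError("nucleus_area_range not representable in image_shape")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background_level and read_noise_sd must be >= 0")
        names = [m.channel for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker channel names")
        if self.nuclear_channel in names:
            raise ValueError("nuclear channel cannot double as a marker channel")
        for m in self.markers:
            m.validate()


@dataclass
class SyntheticGroundTruth:
    """Truth sidecar: per-cell states plus the per-image acquisition factors.

    ``cells`` columns: cell_id, centroid_row, centroid_col, area_um2,
    compartment ('tumor' | 'stroma'), one boolean column per marker channel,
    and ``intensity_<channel>`` with the cell's pre-gain mean intensity.
    ``clipped_fraction`` reports, per channel, the fraction of pixels that
    saturated at 65535 (tests run with gain chosen so it is 0).
    """

    cells: pd.DataFrame
    gain: float
    background_level: float
    clipped_fraction: dict[str, float]


def _paint_ellipse(img: np.ndarray, r0: float, c0: float, a: float, b: float,
                   value: float) -> None:
    """Set pixels inside the axis-aligned ellipse to max(current, value)."""
    nr, nc = img.shape
    rmin = max(0, int(math.floor(r0 - a)))
    rmax = min(nr - 1, int(math.ceil(r0 + a)))
    cmin = max(0, int(math.floor(c0 - b)))
    cmax = min(nc - 1, int(math.ceil(c0 + b)))
    if rmin > rmax or cmin > cmax:
        return
    rr = np.arange(rmin, rmax + 1)[:, None]
    cc = np.arange(cmin, cmax + 1)[None, :]
    inside = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
    region = img[rmin:rmax + 1, cmin:cmax + 1]
    region[inside] = np.maximum(region[inside], value)


def _place_centroids(rng: np.random.Generator, params: SceneParams,
                     bound_r: np.ndarray, eq_r: np.ndarray,
                     pair_of: np.ndarray) -> np.ndarray:
    """Sequential hard-core placement; touching pairs at 0.9x summed radii.

    ``bound_r`` is the bounding-circle radius (px) used for clearance checks,
    ``eq_r`` the equivalent-disk radius (px) used for pair spacing.
    """
    nr, nc = params.image_shape
    gap = params.min_gap / params.pixel_size
    n = len(bound_r)
    rows = np.empty(n)
    cols = np.empty(n)
    for i in range(n):
        margin = bound_r[i] + 1.0
        partner = pair_of[i]
        placed = False
        for _ in range(params.max_place_attempts):
            if partner >= 0 and partner < i:
                # second member of a touching pair: fixed distance, random angle
                d = 0.9 * (eq_r[i] + eq_r[partner])
                theta = rng.uniform(0.0, 2.0 * math.pi)
                r0 = rows[partner] + d * math.sin(theta)
                c0 = cols[partner] + d * math.cos(theta)
                if not (margin <= r0 <= nr - 1 - margin and margin <= c0 <= nc - 1 - margin):
                    continue
            else:
                r0 = rng.uniform(margin, nr - 1 - margin)
                c0 = rng.uniform(margin, nc - 1 - margin)
            if i > 0:
                d2 = (rows[:i] - r0) ** 2 + (cols[:i] - c0) ** 2
                req = (bound_r[:i] + bound_r[i] + gap) ** 2
                if partner >= 0 and partner < i:
                    req[partner] = 0.0  # pair partner is allowed to touch
                if np.any(d2 < req):
                    continue
            rows[i], cols[i] = r0, c0
            placed = True
            break
        if not placed:
            raise SceneOvercrowdedError(
                f"could not place cell {i + 1}/{n} after "
                f"{params.max_place_attempts} attempts; reduce n_cells or "
                f"nucleus areas, or enlarge the field")
    return np.column_stack([rows, cols])


def generate_scene(params: SceneParams) -> tuple[MIPImage, SyntheticGroundTruth]:
    """Render one multi-channel scene and its ground-truth sidecar.

    Identical ``params`` (including seed) produce bit-identical images and
    truth tables. Raises :class:`SceneOvercrowdedError` when the requested
    cells cannot be placed without exceeding the attempt budget.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n = params.n_cells
    px = params.pixel_size

    # geometry ---------------------------------------------------------------
    areas_um2 = rng.uniform(*params.nucleus_area_range, size=n)
    areas_px = areas_um2 / px**2
    axis_ratio = rng.uniform(0.75, 1.0, size=n)  # mild eccentricity jitter
    swap = rng.random(n) < 0.5
    semi_a = np.sqrt(areas_px / math.pi * axis_ratio)
    semi_b = np.sqrt(areas_px / math.pi / axis_ratio)
    semi_a, semi_b = np.where(swap, semi_b, semi_a), np.where(swap, semi_a, semi_b)
    eq_r = np.sqrt(areas_px / math.pi)
    bound_r = np.maximum(semi_a, semi_b)

    # touching pairs occupy the first 2*n_pairs slots
    n_pairs = int(round(params.touching_pair_fraction * n / 2.0))
    pair_of = np.full(n, -1, dtype=int)
    for k in range(n_pairs):
        pair_of[2 * k], pair_of[2 * k + 1] = 2 * k + 1, 2 * k

    centroids = (_place_centroids(rng, params, bound_r, eq_r, pair_of)
                 if n > 0 else np.empty((0, 2)))

    # biology ----------------------------------------------------------------
    is_tumor = rng.random(n) < params.tumor_fraction
    marker_state: dict[str, np.ndarray] = {}
    marker_intensity: dict[str, np.ndarray] = {}
    for m in params.markers:
        p = np.where(is_tumor, m.positive_fraction_tumor, m.positive_fraction_stroma)
        state = rng.random(n) < p
        median = np.where(state, m.mean_positive, m.mean_negative)
        marker_state[m.channel] = state
        marker_intensity[m.channel] = median * np.exp(m.dispersion * rng.standard_normal(n))
    nuclear_int = params.nuclear_intensity * np.exp(
        params.nuclear_dispersion * rng.standard_normal(n))

    # rendering --------------------------------------------------------------
    channel_names = [params.nuclear_channel] + [m.channel for m in params.markers]
    channels: dict[str, np.ndarray] = {}
    clipped: dict[str, float] = {}
    for name in channel_names:
        values = nuclear_int if name == params.nuclear_channel else marker_intensity[name]
        canvas = np.zeros(params.image_shape, dtype=np.float64)
        for i in range(n):
            _paint_ellipse(canvas, centroids[i, 0], centroids[i, 1],
                           semi_a[i], semi_b[i], values[i])
        canvas = canvas * params.gain + params.background_level
        if params.read_noise_sd > 0:
            canvas = canvas + rng.normal(0.0, params.read_noise_sd, size=canvas.shape)
        clipped[name] = float(np.mean(canvas > 65535.0))
        channels[name] = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)

    truth_cols = {
        "cell_id": np.arange(n, dtype=int),
        "centroid_row": centroids[:, 0] if n else np.empty(0),
        "centroid_col": centroids[:, 1] if n else np.empty(0),
        "area_um2": areas_um2,
        "compartment": np.where(is_tumor, "tumor", "stroma"),
    }
    for m in params.markers:
        truth_cols[m.channel] = marker_state[m.channel]
    # per-cell pre-gain intensities, for measurement-recovery checks
    truth_cols[f"intensity_{params.nuclear_channel}"] = nuclear_int
    for m in params.markers:
        truth_cols[f"intensity_{m.channel}"] = marker_intensity[m.channel]
    truth = SyntheticGroundTruth(
        cells=pd.DataFrame(truth_cols),
        gain=params.gain,
        background_level=params.background_level,
        clipped_fraction=clipped,
    )
    image = MIPImage(channels=channels, pixel_size=px, image_id=f"scene-{params.seed}")
    return image, truth


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------

@dataclass
class SyntheticCohortParams:
    """Cohort-level generator: survival times and tumor-growth trajectories.

    Event times are exponential with theoretical median ``median_survival``
    days; growth is exponential in time from a per-animal induction day with
    additive Gaussian measurement noise.
    """

    n_animals: int = 32
    median_survival: float = 32.0  # days
    censor_fraction: float = 0.0
    growth_timepoints: tuple[float, ...] = (0.0, 7.0, 14.0, 21.0, 28.0)  # days post induction
    growth_rate: float = 0.08  # per day
    initial_size: float = 50.0  # size units at induction
    noise_sd: float = 0.0  # size units
    induction_day_range: tuple[int, int] = (20, 40)  # absolute day of induction
    group: str = "Ctrl"
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValueError("censor_fraction must be in [0,1)")
        if self.median_survival <= 0:
            raise ValueError("median_survival must be > 0")
        tp = np.asarray(self.growth_timepoints, dtype=float)
        if tp.size == 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("growth_timepoints must be non-empty, strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_survival_table(params: SyntheticCohortParams) -> pd.DataFrame:
    """Per-animal survival records: animal_id, group, time_days, event.

    ``event`` is True when the tumor endpoint was reached, False for records
    censored at a uniform time before their (unobserved) event.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    scale = params.median_survival / math.log(2.0)  # exponential: median = scale*ln2
    times = rng.exponential(scale, size=params.n_animals)
    censored = rng.random(params.n_animals) < params.censor_fraction
    u = rng.uniform(0.0, 1.0, size=params.n_animals)
    times = np.where(censored, times * u, times)
    return pd.DataFrame({
        "animal_id": [f"{params.group}-{i:04d}" for i in range(params.n_animals)],
        "group": params.group,
        "time_days": times,
        "event": ~censored,
    })


def generate_growth_tables(params: SyntheticCohortParams) -> pd.DataFrame:
    """Long-format growth table: animal_id, group, day, induction_day, size.

    ``day`` is the absolute measurement day (induction_day + timepoint);
    size(t) = initial_size * exp(growth_rate * t) + N(0, noise_sd).
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    tp = np.asarray(params.growth_timepoints, dtype=float)
    lo, hi = params.induction_day_range
    rows = []
    for i in range(params.n_animals):
        ind = int(rng.integers(lo, hi + 1))
        sizes = params.initial_size * np.exp(params.growth_rate * tp)
        if params.noise_sd > 0:
            sizes = sizes + rng.normal(0.0, params.noise_sd, size=tp.size)
        for t, s in zip(tp, sizes):
            rows.append((f"{params.group}-{i:04d}", params.group, ind + t, ind, s))
    return pd.DataFrame(rows, columns=["animal_id", "group", "day", "induction_day", "size"])


# --------------------------------------------------------------------------
# truth matching (for recovery/recall checks)
# --------------------------------------------------------------------------

def match_objects(truth_cells: pd.DataFrame, mask: LabelMask, pixel_size: float,
                  max_dist: float = 2.0) -> pd.DataFrame:
    """One-to-one greedy match of truth cells to segmented labels by centroid.

    A pair matches when centroids lie within ``max_dist`` micrometres; pairs
    are accepted closest-first, each cell and each label at most once.
    Returns a frame with cell_id, label, distance_um for the matched pairs.
    """
    from scipy import ndimage as ndi

    n_obj = mask.n_objects
    if n_obj == 0 or len(truth_cells) == 0:
        return pd.DataFrame(columns=["cell_id", "label", "distance_um"])
    com = np.asarray(ndi.center_of_mass(np.ones_like(mask.labels), mask.labels,
                                        index=np.arange(1, n_obj + 1)))
    tc = truth_cells[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    d = np.sqrt(((tc[:, None, :] - com[None, :, :]) ** 2).sum(axis=2)) * pixel_size
    pairs = np.argwhere(d <= max_dist)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]])
    used_cell: set[int] = set()
    used_label: set[int] = set()
    out = []
    for k in order:
        i, j = pairs[k]
        if i in used_cell or j in used_label:
            continue
        used_cell.add(int(i))
        used_label.add(int(j))
        out.append((int(truth_cells["cell_id"].iloc[i]), int(j + 1), float(d[i, j])))
    return pd.DataFrame(out, columns=["cell_id", "label", "distance_um"])
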