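# ifquant

Image cytometry for immunofluorescence tissue sections, plus the cohort
statistics that usually accompany it in mouse tumor studies.

The package addresses a common quantification problem: given multi-channel
maximum-intensity-projection (MIP) images of stained sections — a Hoechst
nuclear counterstain plus marker channels such as a tdTomato lineage tracer,
Sox10, Pcna, Mitf or Tyrp2 — estimate, per image, sample and genotype, what
fraction of cells is positive for each marker and for marker combinations
(e.g. Sox10⁺ among tdTomato-traced tumor cells), and compare groups with
nonparametric statistics. It is aimed at labs quantifying tumor/stroma
composition in genetically traced mouse models (e.g. malignant peripheral
nerve sheath tumors), and at anyone who needs a fully testable, synthetic-
data-backed reimplementation of this style of semi-automated analysis.

## Method

For each MIP:

1. **Segmentation.** The nuclear channel is converted to a probability map
   (Gaussian smoothing + robust 0.1/99.9-percentile rescaling; a trained
   pixel classifier's output can be substituted), binarized with **Otsu's
   threshold** (argmax of between-class variance σ²_b(t) = w₀w₁(μ₀−μ₁)² over
   a 256-bin histogram), and touching nuclei are split by a
   **distance-transform watershed** seeded at local maxima of the Euclidean
   distance transform.
2. **Measurement.** Each labeled object yields its projected area
   A = n_px·(pixel size)² and the mean raw intensity of every channel over
   its pixels.
3. **Size filter.** Nuclei outside **5–60 µm²** (inclusive) are discarded
   and the drop count logged.
4. **Normalization.** Per image and channel, intensities are divided by the
   *negative-cell baseline*: the mean raw intensity of the lowest 10% of
   size-filtered nuclei. Normalized intensity is therefore a unitless ratio
   that is invariant to per-image gain.
5. **Classification.** A cell is marker-positive when its normalized
   intensity exceeds a fixed cutoff shared by all images (presets:
   Sox10 > 2.5 / tdTomato > 3 for high-stringency lineage scoring,
   all markers > 2 for proportion panels; `≥` semantics available for
   tumor/stroma stratification).
6. **Aggregation.** Proportions are computed per image, averaged
   (unweighted) per biological sample, and collected per genotype.

Cohort statistics are implemented from first principles:
**Kaplan–Meier** product-limit estimation S(t) = ∏_{tᵢ≤t} (1 − dᵢ/nᵢ) with
median survival inf{t : S(t) ≤ 0.5}; the unpaired two-sided
**Mann–Whitney U test** (exact by enumeration for tie-free pooled n ≤ 12,
otherwise normal approximation with tie-corrected variance and continuity
correction); induction-aligned tumor-growth summaries (mean ± SD per group
and day); and median/IQR box summaries.

A synthetic-scene generator renders 16-bit multi-channel fields with known
per-cell ground truth (compartment, marker states, intensities), so every
stage is validated by parameter recovery rather than by fixed images.

## Worked example

`examples/02_quantify_markers.py` builds a 500-cell synthetic field
(1024×1024 px at 0.325 µm/px, 40% of cells in the traced tumor
compartment), segments it and quantifies both markers:

```
495 objects measured; 14 outside 5-60 um^2 dropped
  baseline Sox10: 550 counts (mean of the 49 dimmest nuclei)
  baseline tdTomato: 564 counts (mean of the 49 dimmest nuclei)
tdTomato+ fraction: 41.2% (truth 41.2%)
Sox10+ fraction:    39.7%
Sox10+ among tdTomato+: 93.9% (truth 94.7%)
```

The recovered fractions match the generator's truth to about one percentage
point: the tracer marks ~40% of cells and nearly all traced cells co-express
Sox10. The other examples cover segmentation recall
(`01_simulate_and_segment.py`), Kaplan–Meier and growth statistics
(`03_cohort_statistics.py`) and a full multi-genotype run with Mann–Whitney
comparisons (`04_full_pipeline.py`).

The same stages are available as a CLI (`ifquant simulate / segment /
quantify / survival / compare / run`); `ifquant run --config run.yaml`
executes a whole reproducible run and writes a manifest with SHA-256
checksums of every output table.

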