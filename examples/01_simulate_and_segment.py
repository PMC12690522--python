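"""Generate a synthetic stained section and segment its nuclei.

Builds one multi-channel field with known ground truth, runs the nuclear
segmentation chain (probability map -> Otsu -> watershed) on the Hoechst
channel, and scores the result against the truth sidecar.
"""

import ifquant as q

params = q.SceneParams(image_shape=(1024, 1024), pixel_size=0.325, n_cells=400,
                       tumor_fraction=0.4, seed=1)
image, truth = q.generate_scene(params)
print(f"scene: {len(truth.cells)} nuclei on a {image.shape} field "
      f"({params.pixel_size} um/px), "
      f"{(truth.cells.compartment == 'tumor').mean():.1%} in the traced tumor "
      "compartment")

labels, report = q.segment_nuclei(image, "Hoechst")
print(f"segmentation: Otsu threshold {report['threshold']:.3f} on the "
      f"probability map, {report['n_objects']} objects, "
      f"{report['foreground_fraction']:.1%} of pixels foreground")

matched = q.match_objects(truth.cells, labels, params.pixel_size, max_dist=2.0)
print(f"recall: {len(matched)}/{len(truth.cells)} true nuclei matched "
      f"one-to-one within 2 um "
      f"(median centroid error {matched.distance_um.median():.2f} um)")
# A recall near 100% means essentially every simulated nucleus was found as
# exactly one labeled object; misses are mostly small touching pairs merged
# into one object.
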