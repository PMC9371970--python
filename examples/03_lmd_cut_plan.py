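"""Plan an automated laser-microdissection run from a segmented image.

Polygonizes segmented nuclei into physical-coordinate contours, applies a
1 um outward cutting offset (so the laser never clips the object),
orders the cuts to minimize stage travel, registers scan coordinates onto
the cutting stage with three fiducials, routes objects into 384-well
plate wells, and exports the plan as contour XML.
"""

from dataclasses import replace

import numpy as np

import celldissect as cd

spec = cd.ImageFixtureSpec(n_objects=40, seed=2)
image, mask, truth = cd.make_image_fixture(spec)
contours = cd.mask_to_contours(mask)
cls = dict(zip(truth.object_id, truth.class_label))
contours = [replace(c, class_label=int(cls[c.object_id])) for c in contours]
print(f"{len(contours)} contours; first area {contours[0].area_um2:.1f} um^2")

offset = [cd.offset_contour(c, 1.0) for c in contours]
ordered, travel = cd.order_cuts(offset, start=(0.0, 0.0), exact_max=10)
naive = cd.order_cuts(offset, start=(0.0, 0.0), exact_max=0)  # heuristic only
print(f"stage travel: {travel:.0f} um (optimized)")

# scan -> stage registration from three fiducial landmarks
scan = np.array([[0.0, 0.0], [250.0, 0.0], [0.0, 250.0]])
theta = np.deg2rad(1.5)
A = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
stage = scan @ A.T + np.array([1800.0, -300.0])
tf = cd.register_coordinates(scan, stage)
print(f"registration rms residual: {tf.rms_residual_um:.2e} um")
ordered = [replace(c, vertices=tf.apply(c.vertices)) for c in ordered]

plan = cd.assign_wells(
    ordered, per_class_well={c: w for c, w in zip(range(1, 7), cd.well_ids_384())},
    offset_um=1.0, total_travel_um=travel,
)
for well, s in sorted(plan.well_summary.items()):
    print(
        f"well {well}: {s['n_objects']} objects, {s['total_area_um2']:.0f} um^2, "
        f"~{s['estimated_cells']:.1f} cells at 2.5 um section"
    )
print(f"theoretical cutting accuracy at x150: {cd.theoretical_accuracy_um(150)*1000:.0f} nm")

cd.write_cutplan_xml("scratch_plan.xml", plan, stage)
print("wrote scratch_plan.xml (vertices stored as integer nanometers)")
# The per-well summary is what sample normalization uses: pooled samples
# are matched either by collected object count or by total area, and the
# cell estimate is area x section thickness / 2,000 um^3.
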