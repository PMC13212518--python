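"""Round-trip a rendered label mask through measurement and calibration.

Renders a synthetic label mask (0 background, 1 plant, 2 curd) for known
physical areas, measures it back with connected-pixel counting, and
converts pixel counts to cm^2 via a ruler-derived calibration — the same
loop a segmentation network's masks go through.
"""

import caulipheno as cp

# 30 cm ruler spanning 600 px at 1.5 m camera height -> 0.05 cm/px
profile = cp.calibrate_from_ruler(ruler_length=30.0, ruler_pixel_span=600.0,
                                  camera_height=1.5)
print(f"calibration: {profile.pixel_to_length} cm/px, "
      f"{profile.pixel_to_area} cm^2/px")

leaf_area, curd_area = 400.0, 60.0  # cm^2
mask, true_boxes = cp.render_label_mask(leaf_area, curd_area, profile,
                                        canvas=(700, 700), seed=7)
records = cp.extract_instances(mask, plant_id="3-5")
for rec in records:
    area = cp.pixels_to_area(rec.pixel_area, profile)
    requested = leaf_area if rec.class_label == "plant" else curd_area
    dims = cp.bbox_to_dimensions(rec, profile)
    print(f"{rec.class_label}: {rec.pixel_area} px -> {area:.1f} cm^2 "
          f"(requested {requested:.0f}, error {100 * abs(area - requested) / requested:.2f}%), "
          f"bbox-derived diameter {dims['value']:.1f} cm")

name = "3-5-2024-11-12-1"
parsed = cp.parse_filename(name)
print(f"\nfilename {name!r} -> plant {parsed.plant_id}, {parsed.date}, "
      f"acquisition #{parsed.acquisition_index}")
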