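"""Render one synthetic top-view scene and measure it like a photograph.

Builds a lying pig of known planform area, renders it through the pinhole
camera (lens 245 cm above the floor), calibrates pixels-per-m² from a
0.420 m² reference board at the lying reference height (29 cm), and checks
the measured area against the analytic ground truth.
"""

from pigplanim import (
    BoardSpec,
    CameraModel,
    SceneSpec,
    SilhouetteSpec,
    calibrate,
    fit_shape_coefficient,
    measure_area,
    packaged_study_tables,
    render_scene,
)

camera = CameraModel(image_width=1600, image_height=1100, floor_scale=500.0)
coeffs = fit_shape_coefficient(packaged_study_tables())

board_img, _ = render_scene(
    SceneSpec(camera=camera, objects=[BoardSpec(height_cm=29.0)]))
cal = calibrate(board_img, known_area_m2=0.420, reference_height_cm=29.0)
print(f"calibration: {cal.pixels_per_m2:,.0f} px/m² "
      f"({cal.reference_pixel_count:,} px over 0.420 m² at 29 cm)")

pig = SilhouetteSpec("LL", live_weight_kg=107.5, shape_seed=1)
img, truths = render_scene(SceneSpec(camera=camera, objects=[pig]), coeffs)
truth = truths[0]

m = measure_area(img, cal, "LL", subject_id="demo")
err = 100 * (m.area_m2 - truth.planform_area_m2) / truth.planform_area_m2
print(f"ground truth planform area: {truth.planform_area_m2:.4f} m²")
print(f"measured:                   {m.area_m2:.4f} m² "
      f"({m.pixel_count:,} px, {err:+.2f}% vs truth)")
print("\nThe measured value sits within rasterization tolerance of the "
      "polygon's exact shoelace area, mirroring the study's ~0.486 m² mean "
      "for a 107.5 kg pig lying fully recumbent.")
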