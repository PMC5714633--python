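"""Compare a calculated dose plane against a simulated film measurement.

The plan plane (0.772 mm export grid) is upsampled to the film pixel pitch,
the film dose is registered by dose-area centroid, and agreement is reported
as profile FWHMs and the mean dose over the pixels holding >= 80% of the plan
maximum (the high-dose core, excluding the 20-80% penumbra).
"""

from conedose import (
    BeamModelSpec,
    BeamPlan,
    ConeId,
    HorizontalPlaneSpec,
    SlabPhantom,
    compare_planes,
    dose_plane,
    film_to_dose,
    make_beam_model,
    resolve_mu,
)
from conedose.synthetic import FilmNoiseSpec, default_true_curves, simulate_film_scan

beam = make_beam_model(BeamModelSpec(energy_label="6xFFF"))
phantom = SlabPhantom(slabs=[(50.0, 1.0)] * 4, surface_z_mm=100.0)
plan = resolve_mu(
    BeamPlan(cone=ConeId(6.0), prescription=(7.0, (0.0, 0.0, 0.0))),
    beam, phantom,
)
plane = dose_plane(plan, beam, phantom, HorizontalPlaneSpec(z_mm=0.0))

# film displaced 0.4 mm by setup error, 150 counts of scanner noise
curves = default_true_curves()
scan, truth = simulate_film_scan(
    plane, curves,
    FilmNoiseSpec(sigma_counts={"red": 150.0, "green": 150.0},
                  translation_mm=(0.4, -0.2), seed=99),
)
films = {ch: film_to_dose(scan, curves[ch]) for ch in ("red", "green")}
res = compare_planes(plane, films, energy="6xFFF", cone=ConeId(6.0), label="10 cm")

print(f"recovered centroid shift (red): "
      f"({res.centroid_shift_mm['red'][0]:+.2f}, "
      f"{res.centroid_shift_mm['red'][1]:+.2f}) mm "
      f"(applied {truth['translation_mm']})")
print(f"FWHM plan {res.fwhm_plan_h_mm:.2f} mm | "
      f"red {res.fwhm_meas_h_mm['red']:.2f} mm")
print(f"mask mean: plan {res.mean80_plan_gy:.2f} Gy, "
      f"red {res.mean80_meas_gy['red']:.2f} Gy, "
      f"green {res.mean80_meas_gy['green']:.2f} Gy")
print(f"dose agreement: red {res.pct_diff['red']:+.1f}%, "
      f"green {res.pct_diff['green']:+.1f}%, "
      f"red/green average {res.pct_diff_rg:+.1f}%")

# Registration removes the applied translation; with this noise level the
# masked dose agrees well within 1% and the FWHMs to ~0.1 mm.
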