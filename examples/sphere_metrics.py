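"""Segment the spheres on a ground-truth frame and score detectability.

Builds the frozen VOI set (three 131 ml background VOIs plus one
background-corrected 50%-isocontour mask per sphere) on the 180 s frame,
then reports recovery coefficients and contrast-to-noise ratios per sphere
for a short 10 s frame of the same setup.
"""

import petphantomqa as qa

geom = qa.default_nema_geometry()
grid = qa.default_grid(geom, (3.3, 3.3, 3.0))
labels = qa.rasterize(geom, grid)

setup = qa.AcquisitionSetup(sbr=4.0)
setup = setup.with_sensitivity(qa.calibrate_sensitivity(labels, setup))
activity = qa.activity_map(labels, setup)

ground_truth = qa.simulate(activity, setup, 180.0, grid, psf_fwhm_mm=4.0, seed=0)
vois = qa.build_voi_set(ground_truth, labels)

short = qa.simulate(activity, setup, 10.0, grid, psf_fwhm_mm=4.0, seed=1)
true_conc = setup.sbr * setup.bg_activity_kBq_ml  # 21.2 kBq/ml

print(f"CoV_BG at 180 s: {qa.cov_bg(ground_truth.values, vois.background_vois):.1f} %")
print(f"CoV_BG at  10 s: {qa.cov_bg(short.values, vois.background_vois):.1f} %\n")
print("sphere   RC_mean  RC_max    CNR  visible (10 s frame)")
for d, mask in sorted(vois.sphere_vois.items()):
    rc_mean, rc_max = qa.recovery_coefficients(short.values, mask, true_conc)
    cnr = qa.cnr(short.values, mask, vois.background_vois)
    print(
        f"{d:4.0f} mm   {rc_mean:6.2f}  {rc_max:6.2f}  {cnr:5.1f}  "
        f"{'yes' if qa.is_visible(cnr) else 'no'}"
    )

print(
    "\nRecovery near 1 means accurate quantification; CNR >= 5 (Rose "
    "criterion) marks a sphere as visible.  At 10 s the smallest spheres "
    "hover at the visibility threshold."
)
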