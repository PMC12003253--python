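"""Gaussian post-filter trade-off: noise reduction versus resolution loss.

Applies the G2-G20 filter set (FWHM 2 to 20 mm) to a noisy 10 s frame and
compares background noise, similarity to the 180 s ground-truth frame, and
the 10 mm sphere's recovery — the classic trade-off any denoiser
(including a learned one plugged in through DenoiserSpec) must beat.
"""

import petphantomqa as qa

geom = qa.default_nema_geometry()
grid = qa.default_grid(geom, (3.3, 3.3, 3.0))
labels = qa.rasterize(geom, grid)

setup = qa.AcquisitionSetup(sbr=4.0)
setup = setup.with_sensitivity(qa.calibrate_sensitivity(labels, setup))
activity = qa.activity_map(labels, setup)

gt = qa.simulate(activity, setup, 180.0, grid, psf_fwhm_mm=4.0, seed=0)
noisy = qa.simulate(activity, setup, 10.0, grid, psf_fwhm_mm=4.0, seed=1)
vois = qa.build_voi_set(gt, labels)
mask = labels.in_phantom()
peak = qa.suv_peak(gt.values, vois.sphere_vois[37.0], grid)
small = vois.sphere_vois[10.0]
true_conc = setup.sbr * setup.bg_activity_kBq_ml

print("variant     CoV_BG%   SSIM    PSNR(dB)   MAE    RC_mean(10mm)")
variants = [("unfiltered", noisy)]
variants += [(f"G{f:g}", qa.gaussian_postfilter(noisy, f)) for f in (2, 5, 10, 15, 20)]
for name, scan in variants:
    cov = qa.cov_bg(scan.values, vois.background_vois)
    ssim = qa.masked_ssim(scan.values, gt.values, mask)
    psnr = qa.masked_psnr(scan.values, gt.values, mask, peak)
    mae = qa.masked_mae(scan.values, gt.values, mask)
    rc, _ = qa.recovery_coefficients(scan.values, small, true_conc)
    print(f"{name:<10} {cov:7.1f}  {ssim:.3f}   {psnr:7.2f}  {mae:.3f}   {rc:.2f}")

print(
    "\nWider filters suppress noise monotonically but erode the smallest "
    "sphere's recovery — quantification accuracy is traded for smoothness."
)
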