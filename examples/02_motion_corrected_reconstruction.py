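"""Event-by-event motion-corrected reconstruction vs a static scan.

Simulates a moving scan and a matched-count motionless scan of the same
phantom, reconstructs both (list-mode OSEM, 16 subsets x 8 iterations),
and compares regional brain means after the common 1-mm quantification
post-filter.  The motion-corrected means should agree with the static
reference within a few percent.
"""
from awakepet import (ReconConfig, compute_sensitivity, default_marker_model,
                      desk_head_grid, desk_scanner, make_head_phantom,
                      motion_corrected_recon, osem_listmode, regional_means,
                      sample_trajectory, simulate_listmode, smooth_image)

geom = desk_scanner()
grid = desk_head_grid()
activity, _, atlas = make_head_phantom(grid, None)
model = default_marker_model()
cfg = ReconConfig(n_subsets=16, n_iterations=8, psf_sigma_mm=0.0)
sens = compute_sensitivity(geom, grid)

DURATION = 12_000
moving = sample_trajectory(DURATION, 2.0, rest_fraction=0.35, seed=1)
ev_mov, _ = simulate_listmode(activity, model, moving, geom,
                              duration_ms=DURATION, rate_cps=2.5e5, seed=1)
static = sample_trajectory(DURATION, 0.0, rotation_scale_deg_s=0.0, seed=2)
ev_stat, _ = simulate_listmode(activity, model, static, geom,
                               duration_ms=DURATION, rate_cps=2.5e5, seed=2)

img_static = osem_listmode(ev_stat, geom, grid, cfg, sensitivity=sens)
img_moco = motion_corrected_recon(ev_mov, moving, geom, grid, cfg,
                                  sensitivity=sens)

rm_stat = regional_means(smooth_image(img_static, 1.0), atlas)
rm_moco = regional_means(smooth_image(img_moco, 1.0), atlas)
print(f"{'region':18s} {'static':>9s} {'moco':>9s} {'dev %':>7s}")
for region in rm_stat:
    dev = 100 * (rm_moco[region] - rm_stat[region]) / rm_stat[region]
    print(f"{region:18s} {rm_stat[region]:9.4f} {rm_moco[region]:9.4f} "
          f"{dev:7.2f}")
# Deviations of a few percent are count-statistics noise; large values
# would indicate a failure of the event-by-event correction.
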