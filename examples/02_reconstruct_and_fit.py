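"""Slice-to-volume reconstruction and voxelwise T2* mapping.

Simulates a small motion-corrupted scan, reconstructs 1.2 mm multichannel
volumes with shared motion estimates, fits the mono-exponential decay per
voxel, and compares regional mean T2* with the phantom ground truth.
"""

from fetalt2star import AcquisitionSpec, PhantomSpec, simulate_scan, super_resolve
from fetalt2star.reconstruction import ReconConfig
from fetalt2star.regional import regional_mean_t2star
from fetalt2star.relaxometry import compute_t2star_map

spec = PhantomSpec(gestational_age=32.0, grid_shape=(48, 48, 48),
                   motion_amplitude=(3.0, 3.0), seed=7)
acq = AcquisitionSpec(n_dynamics=4)
labels, tissue, volume, stacks = simulate_scan(spec, acq)

config = ReconConfig(n_outer_iterations=2, lsmr_maxiter=200)
recon, prov = super_resolve(
    stacks, config, grid=(labels.labels.shape, labels.affine),
    brain_mask=labels.labels > 0,
)
print(f"mean slice NCC per iteration: {[round(x, 4) for x in prov['mean_ncc']]}")
print(f"slices excluded per iteration: {prov['excluded']}")

t2map = compute_t2star_map(recon, mask=labels.labels > 0)
print(f"{'region':<18} {'recovered':>9} {'truth':>7} {'error':>7}")
for stats in regional_mean_t2star(t2map, labels):
    truth = tissue.t2star[stats.region]
    err = 100 * (stats.mean_t2star - truth) / truth
    print(f"{stats.region:<18} {stats.mean_t2star:9.1f} {truth:7.1f} {err:6.1f}%")
# Regional means should land within a few percent of the ground truth
# despite the per-slice motion; the NCC row shows registration converging.
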