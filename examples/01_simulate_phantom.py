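"""Simulate the three-hair phantom with both imaging modes.

Builds a ground-truth phantom of three tilted hairs descending from the
surface to 1.8 mm, images it through the acoustic-resolution (85 um
lateral, visible to 1.9 mm) and optical-resolution (12 um, visible to
1 mm) system PSFs, and reports how deep each mode can follow the hairs —
the depth/resolution trade-off the enhancement networks are built to
break.
"""

import numpy as np

from pamgan import (
    AR_PSF,
    OR_PSF,
    NoiseModel,
    PhantomSpec,
    make_truth_volume,
    simulate_scan,
    max_amplitude_projection,
)
from pamgan.phantom import Pitches

spec = PhantomSpec(
    kind="hairs", n_hairs=3, extent=(1600.0, 1600.0, 2200.0),
    hair_depth_range=(100.0, 1800.0), hair_diameter_um=150.0,
)
pitches = Pitches(20.0, 20.0, 20.0)
truth = make_truth_volume(spec, pitches, seed=0)
noise = NoiseModel(gaussian_sigma=0.01)

for label, psf in (("AR", AR_PSF), ("OR", OR_PSF)):
    scan = simulate_scan(truth, psf, noise, seed=1)
    z_um = (np.arange(truth.shape[2]) + 0.5) * pitches.dz
    visible = scan.data.max(axis=(0, 1)) > 0.05
    deepest = z_um[visible].max() if visible.any() else 0.0
    proj = max_amplitude_projection(scan)
    print(f"{label}-PAM scan: volume {scan.shape}, "
          f"hairs visible down to {deepest:.0f} um, "
          f"MAP peak amplitude {proj.amplitude.max():.2f}")

print("\nThe acoustic mode follows the hairs ~2x deeper; the optical mode")
print("loses them past ~1 mm — but resolves them ~7x more sharply laterally.")
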