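"""Estimate effective diffusivities from synthetic axial intensity profiles.

Generates noisy erfc profiles at the published coefficients for the intact
(3.5e-8 cm²/s) and enzyme-digested (1.8e-7 cm²/s) GelMA/HAMA hydrogels and
recovers D_eff by single-parameter nonlinear least squares.  A single profile
on the coarse 0-0.2 cm imaging grid is a noisy estimator (the diffusion front
spans only a few pixels), so — as in a real measurement campaign — replicate
profiles are fitted and the median reported.
"""

import numpy as np

from gelrsm import diffusion, synthetic

x = np.linspace(0.0, 0.2, 50)  # cm along the cuvette
t = 60.0  # s of tracer contact
n_rep = 10

for label, d_true in (("intact gel", 3.5e-8), ("digested gel", 1.8e-7)):
    fits = []
    for seed in range(n_rep):
        cfg = synthetic.SimulationConfig(seed=seed, noise_sd_intensity=0.02)
        profile = synthetic.generate_diffusion_profile(d_true, t, x, cfg)
        fits.append(diffusion.fit_effective_diffusivity(profile).d_eff)
    lo, med, hi = np.percentile(fits, [25, 50, 75])
    print(f"{label}: true D_eff = {d_true:.2e} cm²/s, median of {n_rep} "
          f"replicate fits = {med:.2e} cm²/s (IQR {lo:.2e}-{hi:.2e})")

print("\nThe ~5x higher diffusivity after digestion reflects the opened "
      "network once the sacrificial HAMA component is cleaved.")
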