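"""Detector correction and spectral unmixing on a toy 2-fluorophore stack.

Detection channels see a weighted mix of the fluorophores excited by each
laser line.  Given single-fluorophore reference ratios, per-voxel least
squares recovers the abundances.  Before unmixing, the detector's
nonlinearity is corrected with y = a*x + b*(e^(c*x) - 1), and saturated
voxels are discarded as NaN.
"""

import numpy as np

from qdyefinder import (
    ChannelImage,
    LinearityCoefficients,
    apply_linearity_correction,
    unmix,
)
from qdyefinder.spectral import ExcitationGroup, SpectralReference, correction_curve

coeffs = LinearityCoefficients(a=0.9838, b=1.1044, c=0.001,
                               saturation_cutoff=7000.0)
print(f"correction at 7000 counts -> {correction_curve(7000, 0.9838, 1.1044, 0.001):.1f}"
      " (the detector under-reports bright voxels by ~14%)")

mix = np.array([[0.8, 0.3],
                [0.2, 0.7]])  # columns: fluorophore emission per channel
ref = SpectralReference(
    [ExcitationGroup("488 nm", (0, 1), ("green A", "green B"), mix)],
    linearity=coeffs,
)

rng = np.random.default_rng(0)
true_abundance = rng.uniform(0, 8000, size=(2, 4, 16, 16))
true_signal = np.einsum("cf,fzyx->czyx", mix, true_abundance)

# emulate the nonlinear detector: it reports the x for which y(x) = signal
grid_x = np.linspace(0, 20000, 20001)
grid_y = correction_curve(grid_x, 0.9838, 1.1044, 0.001)
measured = np.interp(true_signal, grid_y, grid_x)

img = apply_linearity_correction(ChannelImage(measured), coeffs)
recovered = unmix(img, ref)

finite = np.isfinite(recovered.voxels) & np.isfinite(true_abundance)
r = np.corrcoef(recovered.voxels[finite], true_abundance[finite])[0, 1]
n_sat = int(np.isnan(recovered.voxels).sum())
print(f"recovered vs true abundance: r = {r:.4f}; "
      f"{n_sat} voxel values discarded as saturated")

# r close to 1 shows the mixed channels were cleanly separated back into
# per-fluorophore images; saturated voxels propagate as NaN rather than
# contaminating downstream colour measurements.
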