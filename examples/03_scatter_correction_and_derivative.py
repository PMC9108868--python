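"""Multiplicative scatter correction and second-order differentiation.

Makes scatter-distorted replicates of one clean tomato spectrum, shows MSC
collapsing them back together, then locates the second-derivative extrema
of the clean spectrum in the three diagnostic wavelength windows.
"""

import numpy as np
from scipy.signal import argrelextrema

from fruitspec import (
    SpectrumSet,
    apply_msc,
    default_params,
    fit_msc_reference,
    scatter_replicates,
    second_derivative,
)
from fruitspec.synthetic import mean_clean_spectrum

params = default_params()
base = mean_clean_spectrum(params)

# 20 replicates differing only by per-sample gain and offset
reps, gain, offset = scatter_replicates(base, params.grid, k=20, seed=4)
before = reps.spectra.var(axis=0).mean()
corrected, coef = apply_msc(reps, fit_msc_reference(reps))
after = corrected.spectra.var(axis=0).mean()
print(f"between-replicate variance: before MSC {before:.2e}, "
      f"after MSC {after:.2e}")
print(f"recovered skew range: {coef.skew.min():.3f} - {coef.skew.max():.3f} "
      f"(sampled gains {gain.min():.3f} - {gain.max():.3f})")

# second derivative of the clean spectrum: extrema mark absorption bends
clean = SpectrumSet(base[None, :], params.grid, ["clean"])
d2 = second_derivative(clean)
vals = d2.spectra[0]
wl = d2.grid.values
extrema = np.union1d(argrelextrema(vals, np.greater, order=3)[0],
                     argrelextrema(vals, np.less, order=3)[0])
for lo, hi in ((580, 590), (680, 690), (970, 980)):
    hits = [f"{wl[i]:.1f}" for i in extrema if lo <= wl[i] <= hi]
    print(f"second-derivative extrema in {lo}-{hi} nm: {', '.join(hits)}")
# MSC removes nearly all scatter-induced variance; the derivative extrema
# sit in the pigment-edge, chlorophyll and OH-overtone windows.
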