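"""From a normalized iris raster to an AR spectral model.

Builds a synthetic textured raster standing in for a normalized iris strip,
runs the preprocessing chain (Gabor filter, pupil-side crop, zigzag
vectorization), selects an AR order by AIC, and Burg-fits the spectrum.
"""

import numpy as np
from scipy import ndimage

from iriscap import (
    GaborParams,
    NormalizedIrisImage,
    aic_sweep,
    ar_psd,
    burg_fit,
    preprocess_image,
    select_order,
)

# synthetic stand-in texture: smoothed noise, stronger near the pupil edge
rng = np.random.default_rng(0)
texture = ndimage.gaussian_filter(rng.standard_normal((80, 60)), sigma=1.5)
texture[:40] *= 2.0  # texture concentrates near the pupil
image = NormalizedIrisImage(pixels=100 + 20 * texture, pupil_side="top")

vec = preprocess_image(image, GaborParams(f0=1 / 9, sigma=0.5))
print(f"vector length: {len(vec)} (2 x 40 x 60), mean = {vec.values.mean():.2e}")

curve = aic_sweep(vec.values, orders=range(1, 21))
order = select_order(curve)
model = burg_fit(vec.values, order)
spectrum = ar_psd(model, 1024)
low = spectrum.values[:64].mean() / spectrum.values.mean()
print(f"AIC-selected order: {order}; innovation variance {model.noise_variance:.4g}")
print(f"low-frequency energy concentration: {low:.2f}x the spectral mean")
print(
    "\nThe zigzag-vectorized Gabor response is a low-frequency signal; the"
    " AR fit summarizes one iris image as a smooth power spectrum, the raw"
    " material for enrollment spectra and class distances."
)
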