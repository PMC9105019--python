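"""Translate whole film phantoms with a patch-trained generator.

Trains briefly, then applies the generator to full images (not patches —
the networks are fully convolutional) and shows the contrast statistic
moving from the film domain toward the digital domain.
"""

import numpy as np

from mammogan import (generate_sffdm, make_phantom_dataset,
                      normalize_intensity, otsu_breast_mask, tiny_spec)
from mammogan.phantom import foreground_iqr
from mammogan.training import PatchPool, fit, tiny_train_config

ds = make_phantom_dataset(12, tiny_spec(seed=11), seed=11)
state, _ = fit(tiny_train_config(seed=0), PatchPool(ds.film_pool),
               PatchPool(ds.digital_pool))

digital = []
for i in ds.digital_ids:
    img = normalize_intensity(ds.samples[i].digital_image)
    digital.append(foreground_iqr(img, otsu_breast_mask(img)))
before, after = [], []
for i in ds.film_ids:
    img = normalize_intensity(ds.samples[i].film_image)
    m = otsu_breast_mask(img)
    before.append(foreground_iqr(img, m))
    sffdm = generate_sffdm(state.G, img)
    after.append(foreground_iqr(sffdm, m))

print(f"foreground IQR  film: {np.mean(before):.3f}   "
      f"translated: {np.mean(after):.3f}   digital target: {np.mean(digital):.3f}")
print("The translated images' contrast statistic should sit close to the "
      "digital-domain mean; the input film statistic sits farther away.")
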