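"""Generate two-domain mammogram phantoms with ground truth.

Renders a handful of synthetic anatomies, each in a film-like and a
digital-like acquisition, and prints the contrast statistic that
quantifies the domain gap the translator has to close.
"""

import numpy as np

from mammogan import make_phantom_dataset, tiny_spec
from mammogan.phantom import foreground_iqr

ds = make_phantom_dataset(8, tiny_spec(seed=7), seed=7)

print(f"{len(ds.samples)} anatomies; film pool {len(ds.film_pool)} patches "
      f"(anatomies {ds.film_ids}), digital pool {len(ds.digital_pool)} "
      f"patches (anatomies {ds.digital_ids})")

film = np.mean([foreground_iqr(s.film_image, s.mask)
                for s in ds.samples])
digital = np.mean([foreground_iqr(s.digital_image, s.mask)
                   for s in ds.samples])
print(f"mean foreground IQR: film {film:.3f} < digital {digital:.3f}")
print("The lower film IQR is the compressed-contrast look of digitized "
      "screen films; the translator's job is to move film images toward "
      "the digital statistics.")
print(ds.annotations.groupby("kind").size().to_string())
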