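"""Train the translator at desk scale and watch the cycle loss fall.

Runs a shortened adversarial training (200 iterations, 2-level networks)
on unpaired phantom pools and prints the cycle-consistency loss at the
start and end — the reconstruction error F(G(x)) vs x that anchors the
unpaired translation.  A full desk-scale run uses 500 iterations (see the
acceptance script).
"""

import numpy as np

from mammogan import make_phantom_dataset, tiny_spec
from mammogan.training import PatchPool, fit, tiny_train_config

ds = make_phantom_dataset(12, tiny_spec(seed=11), seed=11)
cfg = tiny_train_config(seed=0, max_iters=200)
state, log = fit(cfg, PatchPool(ds.film_pool), PatchPool(ds.digital_pool))

cyc = (log["l_cyc_x"] + log["l_cyc_y"]).to_numpy()
k = max(1, len(cyc) // 10)
print(f"cycle loss, median of first decile: {np.median(cyc[:k]):.3f}")
print(f"cycle loss, median of last decile:  {np.median(cyc[-k:]):.3f}")
print("A falling cycle loss means the two generators have become near "
      "inverses, so translation preserves anatomy while restyling it.")
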