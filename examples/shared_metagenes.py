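"""Find a metagene shared across two datasets with a masked layout.

Concatenates two synthetic expression datasets that share one planted
profile while each also carries its own private profile.  An H-mask
forbids the dataset-specific basis columns from loading on the other
dataset's samples, so the only column free to explain both is the shared
one.  The run then checks that the recovered shared column correlates
with the planted profile.
"""

import numpy as np

from nmfkit import (FactorizationConfig, TargetMatrix,
                    build_shared_profile_layout, factorize)

rng = np.random.default_rng(8)
n, m1, m2 = 80, 25, 25
shared = rng.uniform(size=(n, 1))
private1 = rng.uniform(size=(n, 1))
private2 = rng.uniform(size=(n, 1))
A = np.hstack([
    shared @ rng.uniform(1, 2, (1, m1)) + private1 @ rng.uniform(1, 2, (1, m1)),
    shared @ rng.uniform(1, 2, (1, m2)) + private2 @ rng.uniform(1, 2, (1, m2)),
])

mask = build_shared_profile_layout(samples_per_dataset=[m1, m2],
                                   k_shared=1, k_specific=[1, 1])
result = factorize(TargetMatrix(A),
                   FactorizationConfig(k=3, seed=9, mask=mask,
                                       max_epochs=3000, rel_tol=1e-13))

r = np.corrcoef(result.W[:, 0], shared[:, 0])[0, 1]
print(f"masked loading entries forced to zero: {mask.fixed_H.sum()}")
print(f"zeros respected in H                 : "
      f"{(result.H[mask.fixed_H] == 0).all()}")
print(f"corr(recovered shared, planted)      : {r:.4f}")
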