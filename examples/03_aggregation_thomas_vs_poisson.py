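"""Aggregated versus uniform cell arrangements under the clustering factor.

Simulates cultures whose cells are placed either uniformly at random
(poisson) or as a Thomas cluster process (aggregates of ~8 cells), and
compares the mean NCF of the nuclei channel over 10 seeds.  Aggregated
scenes score consistently higher; tighter clusters (smaller scatter sigma)
score higher still — the behaviour that lets the statistic rank degrees of
aggregation between treatment groups.
"""

import numpy as np

from assemblyscope import minmax_normalize, ncf_image
from assemblyscope.synth import SceneConfig, ThomasParams, generate_cell_scene


def mean_ncf(arrangement: str, sigma: float = 15.0, n_seeds: int = 10) -> float:
    vals = []
    for seed in range(n_seeds):
        cfg = SceneConfig(seed=seed, arrangement=arrangement,
                          thomas_params=ThomasParams(cluster_sigma_px=sigma))
        scene, _ = generate_cell_scene(cfg)
        vals.append(ncf_image(minmax_normalize(scene["nuclei"])).ncf)
    return float(np.mean(vals))


print(f"uniform (poisson):           mean NCF = {mean_ncf('poisson'):.3f}")
for sigma in (5.0, 15.0, 40.0):
    print(f"aggregated (thomas, s={sigma:>4.0f}): mean NCF = {mean_ncf('thomas', sigma):.3f}")
print("\nHigher NCF = more aggregated; the Thomas scenes separate cleanly from")
print("uniform ones, and NCF falls as the cluster scatter grows.")
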