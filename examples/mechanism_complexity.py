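"""Predictability tracks the complexity of the activity mechanism.

Three generator mechanisms emulate the spread seen across real assay
types: a weighted sum of counts (log D-like partitioning between two
solvents), a saturating single-index response pushed through the
Cheng-Prusoff relation (pIC50-like, assay-condition dependent), and a
product/ratio composition of latent sub-responses with heteroscedastic
noise (bioavailability-like). The same network is trained on each.
"""

import numpy as np

from qsardnn import DNNSetting, SyntheticSpec, TrainConfig, generate_aligned, run_single

setting = DNNSetting("probe", (64,), (10,), minibatch_size=25)
config = TrainConfig(epochs=30, n_runs=1)

for mechanism in ("linear_logD_like", "single_index_nonlinear", "composed_multimechanism"):
    bests = []
    for seed in (0, 1, 2):
        dataset, _ = generate_aligned(
            SyntheticSpec(n_train=1000, n_test=300, n_descriptors=400,
                          mechanism=mechanism, seed=seed)
        )
        bests.append(run_single(dataset, setting, config, seed=0).best_r2)
    print(f"{mechanism:26s} mean best R² = {np.mean(bests):.3f} "
          f"(seeds 0-2: {[round(b, 3) for b in bests]})")

print("\nSimple chemistry-like signals are learnable at desk scale; the")
print("composed in-vivo-like mechanism stays hard at equal size and noise.")
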