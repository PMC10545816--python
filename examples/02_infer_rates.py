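"""Infer cell-specific kinetic rates for simulated genes.

Trains one small network per gene against the neighbor-relayed cosine
loss and prints the recovered transcription-rate clusters: for a two-step
gene, cells in the induction phase get a clearly positive alpha while
repression-phase cells sit near zero — without ever telling the model
that two phases exist.
"""

import numpy as np

from velorelay import RegimeSpec, TrainConfig, generate_dataset, train_genes
from velorelay.benchmark import smooth_dataset
from velorelay.evaluation import predicted_ratio

ds = generate_dataset(RegimeSpec("mono_kinetic", n_cells=800, n_genes=3, seed=0))
su, ss = smooth_dataset(ds)  # first-moment denoising, as on real counts
results = train_genes(su, ss, TrainConfig(seed=0), gene_names=ds.gene_names)

for j, (gene, res) in enumerate(results.items()):
    ind = ds.stage_label == 0
    a = res.rates.alpha
    true_ab = ds.true_alpha[ind, j].mean() / ds.true_beta[0, j]
    pred_ab = float(np.median(predicted_ratio(res, "alpha_over_beta")[ind]))
    print(
        f"{gene}: loss/cell={res.rates.loss / len(a):.4f}  "
        f"alpha(induction)={a[ind].mean():.2f} alpha(repression)={a[~ind].mean():.2f}  "
        f"alpha/beta predicted={pred_ab:.2f} true={true_ab:.2f}"
    )
print("\nA positive induction cluster and a near-zero repression cluster "
      "mean the two-step transcription program was recovered per cell.")
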