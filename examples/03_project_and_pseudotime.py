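"""Project per-gene velocities to 2-D and derive a gene-shared pseudotime.

Runs the full pipeline on a small simulated dataset: train, build the
correlation-kernel transition matrix, project arrows onto a 2-D
embedding (here a gene's denoised phase plane), trace streamlines
through the meta-cell grid and merge the trajectory time zones.  The printed correlation compares the derived
pseudotime with the simulation's hidden time.
"""

import tempfile

import numpy as np
from scipy.stats import spearmanr

from velorelay import DatasetContainer, RegimeSpec, RunConfig, generate_dataset, run_pipeline

ds = generate_dataset(RegimeSpec("mono_kinetic", n_cells=1200, n_genes=8, seed=0))
# embed cells by the first gene's denoised phase-plane coordinates (s, u):
# along a kinetic loop, arc position is monotone in time
from velorelay.benchmark import smooth_dataset

su, ss = smooth_dataset(ds, 50)
container = DatasetContainer(unspliced=ds.u, spliced=ds.s,
                             cell_ids=ds.cell_ids, gene_names=ds.gene_names,
                             embedding=np.column_stack([ss[:, 0], su[:, 0]]))
config = RunConfig(seed=0, smooth_n=50, projection_k=50,
                   grid_shape=(12, 12), n_steps=120, n_repeats=4, n_path=2)

with tempfile.TemporaryDirectory() as out:
    bundle = run_pipeline(config, container, out)

pt = bundle["pseudotime_table"]["pseudotime"].to_numpy()
rho = spearmanr(ds.time, pt).statistic
arrows = bundle["projected"].vel2d
print(f"pseudotime in [{pt.min():.2f}, {pt.max():.2f}], "
      f"Spearman correlation with simulated time: {rho:.2f}")
print(f"mean projected arrow length: {np.linalg.norm(arrows, axis=1).mean():.3f}")
print("A strongly positive correlation means the velocity field ordered "
      "the cells along the simulated differentiation axis.")
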