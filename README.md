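# velorelay

Cell-specific RNA velocity via a relay velocity model.

RNA velocity infers the direction of cellular state change from a
single-cell RNA-seq snapshot by exploiting splicing kinetics: for each
gene, unspliced (`u`) and spliced (`s`) mRNA follow

    du/dt = α − βu,        ds/dt = βu − γs,

with transcription (α), splicing (β) and degradation (γ) rates.
Conventional estimators fit one rate triple per gene, which fails for
genes whose rates change mid-differentiation (transcriptional boosts) or
differ between lineages (branching genes). `velorelay` trains one small
neural network per gene that maps each cell's `(u, s)` to cell-specific
`(α, β, γ)`, optimized against a neighbor-relayed cosine loss: the
displacement predicted by an Euler step of the kinetic equations,
`v_j = Δt·(α − βu_j, βu_j − γs_j)`, must align with the observed
displacement toward one of cell *j*'s nearest neighbors,
`L_j = 1 − max_{j'} cos(v_j, v_{j'})`. Local velocities relayed through
neighbors replace any global kinetic curve, so multi-stage and
multi-lineage genes are handled per cell.

The package is aimed at computational biologists who want velocity
fields, cell-specific kinetic rates, and a velocity-derived pseudotime
from spliced/unspliced count matrices — plus a fully self-contained
simulation benchmark (four kinetic regimes with ground-truth rates,
Gaussian noise, Poisson technical dropout) to validate every stage
without external data.

## What is inside

| module | role |
| --- | --- |
| `velorelay.kinetics` | first-order splicing kinetics: velocities, Euler steps, analytic constant-rate solution |
| `velorelay.simulate` | regime simulator with ground truth; Poisson dropout generator |
| `velorelay.neighbors` | phase-plane / gene-shared kNN, first-moment smoothing |
| `velorelay.dnn` | the per-gene relay velocity learner (network, loss, training) |
| `velorelay.projection` | correlation-kernel transition matrix, 2-D arrow projection |
| `velorelay.pseudotime` | meta-cell grid, streamline tracing, gene-shared pseudotime |
| `velorelay.evaluation` | cosine error rates, rate-ratio recovery, convergence epochs |
| `velorelay.benchmark` | end-to-end simulation benchmark protocols |
| `velorelay.io` / `velorelay.pipeline` / `velorelay.cli` | loom/h5ad/CSV readers, provenance, `velorelay` command |

## Worked example

`examples/02_infer_rates.py` simulates three two-step-transcription genes
(800 cells), denoises them by first-moment smoothing and trains one
network per gene:

```text
gene0: loss/cell=0.0665  alpha(induction)=0.43 alpha(repression)=0.11  alpha/beta predicted=0.52 true=0.52
gene1: loss/cell=0.0229  alpha(induction)=0.57 alpha(repression)=0.05  alpha/beta predicted=0.62 true=0.55
gene2: loss/cell=0.0911  alpha(induction)=0.42 alpha(repression)=0.11  alpha/beta predicted=0.48 true=0.45
```

Each line is one gene. The predicted transcription rate separates into an
active cluster (induction-phase cells) and a near-zero cluster
(repression-phase cells) even though the model was never told two phases
exist, and the recovered α/β ratio matches the simulated truth. The other
examples cover the simulator (`01`), velocity projection plus pseudotime
(`03`, printing the Spearman correlation between derived pseudotime and
the simulation's hidden time), and the error-rate benchmark (`04`).

A full run on your own data goes through the pipeline or the CLI:

```bash
velorelay run --input data.loom --seed 1 --out results/
# or stage by stage:
velorelay simulate --regime transcriptional_boost --n-genes 50 --out sim/
velorelay velocity --input sim/ --out velocity.csv
velorelay project --velocity-table velocity.csv --embedding emb.csv --out proj.csv
velorelay pseudotime --projected proj.csv --out pt.csv
velorelay evaluate --pred velocity.csv --truth sim/truth.csv --out report.json
```

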