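"""Benchmark metrics for simulated regimes.

Measures agreement between inferred and ground-truth kinetics:

* per-cell cosine similarity and the 0.7-cutoff *error rate* (percentage
  of cells whose predicted velocity direction has cosine similarity below
  0.7 with the true velocity);
* recovery R-squared of rate ratios (alpha/beta, gamma/beta, alpha/gamma);
* the epoch at which a training-loss history converges;
* helpers that place predicted (scaled) and true (raw) quantities on a
  common coordinate system.

On scale: the learner sees max-scaled coordinates ``u' = u/u_max``,
``s' = s/s_max`` and only velocity *directions* enter its loss, so the
predicted rates live on the scaled axes.  Rewriting the scaled kinetic
equations in raw units gives the de-scaling conventions used here:
``alpha_raw = a * u_max`` with ``beta_raw = b`` from the unspliced
equation, and ``gamma_raw = g`` from the spliced equation (whose own
splicing term carries the extra factor ``u_max / s_max``).  Ratio helpers
apply the factors consistently per equation; true velocities are mapped
into scaled coordinates before cosine comparisons for the same reason.
"""

from __future__ import annotations

import numpy as np

from .dnn import TrainResult

__all__ = [
    "cosine_similarity",
    "error_rate",
    "recovery_r2",
    "pearson_r",
    "convergence_epoch",
    "predicted_ratio",
    "regime_error_rates",
    "phase_pooled_ratios",
]


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two vectors; zero-length input gives 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _rowwise_cosine(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    denom = na * nb
    dot = np.einsum("ij,ij->i", A, B)
    return np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), 0.0)


def error_rate(pred_velocity, true_velocity, cutoff: float = 0.7) -> float:
    """Percentage of cells with cosine similarity below the cutoff.

    Both arguments are cells x 2 displacement fields on a common
    coordinate system; the result is invariant to positive rescaling of
    either field.
    """
    P = np.atleast_2d(np.asarray(pred_velocity, dtype=float))
    T = np.atleast_2d(np.asarray(true_velocity, dtype=float))
    if P.shape != T.shape or P.shape[0] == 0:
        raise ValueError("need matched, non-empty velocity fields")
    cos = _rowwise_cosine(P, T)
    return 100.0 * float((cos < cutoff).mean())


def pearson_r(x, y) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def recovery_r2(pred, true) -> float:
    """Squared Pearson correlation between predicted and true rate ratios.

    Scale-free: any affine monotone rescaling of the predictions leaves it
    unchanged.  Constant inputs give NaN (reported as missing).
    """
    r = pearson_r(pred, true)
    return r * r if np.isfinite(r) else float("nan")


def convergence_epoch(loss_history) -> int:
    """First checkpoint epoch after which at most 1% of the total loss
    decrease remains.

    ``loss_history`` is a sequence of ``(epoch, loss)`` pairs.  A flat
    history converges at its first checkpoint.
    """
    hist = list(loss_history)
    if len(hist) < 2:
        if not hist:
            raise ValueError("empty loss history")
        return int(hist[0][0])
    epochs = np.array([e for e, _ in hist], dtype=float)
    losses = np.array([l for _, l in hist], dtype=float)
    best_so_far = np.minimum.accumulate(losses)
    total = losses[0] - best_so_far[-1]
    if total <= 0:
        return int(epochs[0])
    remaining = best_so_far - best_so_far[-1]
    idx = int(np.argmax(remaining <= 0.01 * total))
    return int(epochs[idx])


# ---------------------------------------------------------------------------
# mapping predictions and truth onto common scales


def predicted_ratio(result: TrainResult, which: str) -> np.ndarray:
    """Per-cell predicted rate ratio on the raw coordinate scale.

    ``which`` is one of ``alpha_over_beta``, ``gamma_over_beta``,
    ``alpha_over_gamma``.  The unspliced equation de-scales alpha by
    ``u_max``; the spliced equation's splicing term carries
    ``u_max/s_max`` relative to gamma (see module docstring).
    """
    r = result.rates
    with np.errstate(divide="ignore", invalid="ignore"):
        if which == "alpha_over_beta":
            return (r.alpha / r.beta) * result.u_scale
        if which == "gamma_over_beta":
            return (r.gamma / r.beta) * (result.u_scale / result.s_scale)
        if which == "alpha_over_gamma":
            # chain of the two nullclines: (alpha/beta) / (gamma/beta)
            return (r.alpha / r.gamma) * result.s_scale
    raise ValueError(f"unknown ratio {which!r}")


_TRUE_RATIO = {
    "alpha_over_beta": lambda a, b, g: a / b,
    "gamma_over_beta": lambda a, b, g: g / b,
    "alpha_over_gamma": lambda a, b, g: a / g,
}


def phase_pooled_ratios(results: dict, dataset, which: str, eps: float = 1e-6):
    """Pool predicted vs true rate ratios per gene and kinetic phase.

    Within one gene, every cell of a phase (a stage x lineage combination)
    shares one true ratio, so the comparison point is the phase median of
    the per-cell predicted ratio against the phase mean of the truth (the
    median is robust to the blow-up of a ratio of sigmoid outputs in a few
    cells).  Cells whose true denominator is below ``eps`` are excluded.
    Returns ``(pred, true)`` arrays with one entry per gene x phase.
    """
    if which not in _TRUE_RATIO:
        raise ValueError(f"unknown ratio {which!r}")
    phases = dataset.stage_label * 2 + dataset.lineage_label
    pred_pts, true_pts = [], []
    for j, name in enumerate(dataset.gene_names):
        res = results.get(name)
        if res is None or res.failed:
            continue
        pr = predicted_ratio(res, which)
        a = dataset.true_alpha[:, j]
        b = dataset.true_beta[:, j]
        g = dataset.true_gamma[:, j]
        denom = b if which.endswith("over_beta") else g
        safe = denom > eps
        tr = np.full_like(a, np.nan)
        tr[safe] = _TRUE_RATIO[which](a[safe], b[safe], g[safe])
        for ph in np.unique(phases):
            m = (phases == ph) & np.isfinite(tr) & np.isfinite(pr)
            if m.sum() < 2:
                continue
            pred_pts.append(float(np.median(pr[m])))
            true_pts.append(float(tr[m].mean()))
    return np.array(pred_pts), np.array(true_pts)


def regime_error_rates(results: dict, dataset, cutoff: float = 0.7) -> dict:
    """Per-gene 0.7-cutoff error rates against the simulated ground truth.

    The true velocity (raw units) is mapped into each gene's scaled
    coordinates — ``(du/u_max, ds/s_max)`` — before the cosine comparison,
    because anisotropic axis scaling changes angles.
    """
    out = {}
    for j, name in enumerate(dataset.gene_names):
        res = results.get(name)
        if res is None or res.failed:
            continue
        truth = dataset.true_velocity[:, j, :].copy()
        truth[:, 0] /= res.u_scale
        truth[:, 1] /= res.s_scale
        out[name] = error_rate(res.predicted_velocity, truth, cutoff=cutoff)
    return out
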