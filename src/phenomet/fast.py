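"""FAST post-processing of a factor-analytic GxE fit.

Factor-analytic selection tools dissect an FA fit into an overall
performance (OP) indicator and a stability measure (RMSD) per genotype:

* loadings are first rotated to principal-axis form (Lambda' Lambda
  diagonal with non-increasing diagonal, first-factor loading sum
  positive), scores counter-rotated so the fitted common GxE effects
  Lambda F' are unchanged;
* OP_i = mean(lambda_1) * f_i1 — the first-factor regression evaluated at
  the average first loading — optionally re-centered onto the trait scale
  by adding the fitted grand mean (intercept plus average year-site
  effect);
* RMSD_i = sqrt( (1/p) sum_j ( sum_{l>=2} lambda_jl f_il )^2 ) — the
  root-mean-squared deviation of the higher-factor contributions over the
  p fitted environments.  Low RMSD = stable genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stage2 import FAFit

__all__ = ["StabilityResult", "rotate_loadings", "op_rmsd", "stability_table"]


@dataclass
class StabilityResult:
    genotype: str
    op: float
    rmsd: float


def rotate_loadings(fa: FAFit) -> FAFit:
    """Principal-axis rotation of an FA fit (SVD based).

    Returns a copy with Lambda' Lambda diagonal (non-increasing), each
    factor's loading sum non-negative, and scores counter-rotated; the
    fitted effects Lambda F' are invariant.  Idempotent.
    """
    if fa.k < 1:
        raise ValueError("rotation needs at least one factor")
    U, s, Vt = np.linalg.svd(fa.loadings, full_matrices=False)
    lam = U * s
    scores = fa.scores @ Vt.T
    for l in range(lam.shape[1]):
        if lam[:, l].sum() < 0:
            lam[:, l] *= -1
            scores[:, l] *= -1
    return replace(fa, loadings=lam, scores=scores, rotated=True)


def op_rmsd(fa: FAFit, include_mean: bool = True) -> list[StabilityResult]:
    """Overall performance and stability per genotype from a rotated fit.

    ``include_mean`` adds the fitted grand mean (intercept + average
    year-site intercept) so OP lands on the trait scale (e.g. t/ha);
    with ``include_mean=False`` OP is the centered first-factor effect.
    """
    if not fa.rotated:
        raise ValueError("op_rmsd requires a rotated FAFit; call rotate_loadings first")
    lam1_bar = float(fa.loadings[:, 0].mean())
    base = float(np.mean(fa.env_intercepts)) if include_mean else 0.0
    op = base + lam1_bar * fa.scores[:, 0]
    if fa.k > 1:
        dev = fa.scores[:, 1:] @ fa.loadings[:, 1:].T  # m x p higher-factor effects
        rmsd = np.sqrt((dev**2).mean(axis=1))
    else:
        rmsd = np.zeros(len(op))
    return [StabilityResult(g, float(o), float(r)) for g, o, r in zip(fa.genotypes, op, rmsd)]


def stability_table(fa: FAFit, include_mean: bool = True) -> pd.DataFrame:
    """Rotate (if needed) and tabulate genotype, op, rmsd."""
    if not fa.rotated:
        fa = rotate_loadings(fa)
    res = op_rmsd(fa, include_mean=include_mean)
    return pd.DataFrame([(r.genotype, r.op, r.rmsd) for r in res], columns=["genotype", "op", "rmsd"])
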