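"""Selection-efficiency evaluation and protein-per-area trade-off.

Compares a pure breeders' selection against one enriched with a
predicted-overall-performance threshold: lines the breeders kept but
whose predicted OP falls below the threshold are excluded, and the
efficiency of selection — the share of kept lines whose observed
performance confirms the decision — is computed with and without the
threshold.  The threshold can be fixed or optimized retrospectively over
all midpoints of the sorted predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EfficiencyReport", "efficiency_analysis", "protein_per_area"]


@dataclass
class EfficiencyReport:
    threshold: float
    n_total: int
    n_selected_base: int
    n_selected_enhanced: int
    efficiency_base: float
    efficiency_enhanced: float
    efficiency_increase: float
    false_exclusions: int
    #: efficiencies with all candidate lines as denominator (secondary view)
    efficiency_base_total: float = 0.0
    efficiency_enhanced_total: float = 0.0

    def to_json_dict(self):
        return {k: (float(v) if not isinstance(v, int) else v) for k, v in self.__dict__.items()}


def _efficiency(selected, observed, threshold, n_total):
    """Success = a kept line whose observed performance reaches the threshold."""
    if not selected:
        raise ValueError("empty selection set")
    succ = sum(1 for g in selected if observed[g] >= threshold)
    return succ / len(selected), succ / n_total


def efficiency_analysis(
    predicted_op: dict, breeder_selected: set, observed: dict, threshold="optimize"
) -> EfficiencyReport:
    """Efficiency of selection with and without a predicted-OP threshold.

    Parameters
    ----------
    predicted_op
        line -> predicted overall performance (t/ha) for every candidate.
    breeder_selected
        lines the breeders kept (must have observed values).
    observed
        line -> observed performance of the evaluated generation.
    threshold
        numeric threshold on predicted OP, or ``"optimize"`` to scan all
        midpoints of the sorted predictions and keep the one maximizing
        the efficiency *increase* (ties -> lower threshold).  Maximizing
        the raw enhanced efficiency would be degenerate: any threshold far
        below the predictions makes every kept line a trivial success.

    The same threshold value is used both to prune the selection on
    *predicted* OP and as the success criterion on *observed*
    performance.  ``false_exclusions`` counts pruned lines whose observed
    performance actually reached the threshold.
    """
    breeder_selected = set(breeder_selected)
    if not breeder_selected:
        raise ValueError("empty breeder selection")
    missing = breeder_selected - set(predicted_op) | breeder_selected - set(observed)
    if missing:
        raise ValueError(f"lines without prediction or observation: {sorted(missing)}")
    n_total = len(predicted_op)

    def evaluate(thr):
        enhanced = {g for g in breeder_selected if predicted_op[g] >= thr}
        if not enhanced:
            return None
        eff_b, eff_b_tot = _efficiency(breeder_selected, observed, thr, n_total)
        eff_e, eff_e_tot = _efficiency(enhanced, observed, thr, n_total)
        excluded = breeder_selected - enhanced
        false_exc = sum(1 for g in excluded if observed[g] >= thr)
        return EfficiencyReport(
            threshold=float(thr),
            n_total=n_total,
            n_selected_base=len(breeder_selected),
            n_selected_enhanced=len(enhanced),
            efficiency_base=eff_b,
            efficiency_enhanced=eff_e,
            efficiency_increase=eff_e - eff_b,
            false_exclusions=false_exc,
            efficiency_base_total=eff_b_tot,
            efficiency_enhanced_total=eff_e_tot,
        )

    if threshold == "optimize":
        # the increase is piecewise constant with breakpoints wherever the
        # threshold crosses a predicted OP (pruning changes) or an observed
        # value (the success criterion changes), so scan midpoints of both
        vals = [predicted_op[g] for g in breeder_selected] + [observed[g] for g in breeder_selected]
        preds = np.sort(np.unique(vals))
        cands = [preds[0] - 1.0] + list((preds[:-1] + preds[1:]) / 2.0)
        best = None
        for thr in cands:  # ascending; strict improvement keeps the lowest maximizer
            rep = evaluate(thr)
            if rep is not None and (best is None or rep.efficiency_increase > best.efficiency_increase + 1e-12):
                best = rep
        if best is None:
            raise ValueError("no threshold leaves a non-empty enhanced selection")
        return best
    rep = evaluate(float(threshold))
    if rep is None:
        raise ValueError("threshold excludes every breeder-selected line")
    return rep


def protein_per_area(yield_t_ha: float, protein_pct: float) -> float:
    """Harvestable protein per area: yield (t/ha) x protein content (%) / 100."""
    y = np.asarray(yield_t_ha, dtype=float)
    p = np.asarray(protein_pct, dtype=float)
    if np.any(y < 0):
        raise ValueError("yield must be non-negative")
    if np.any((p < 0) | (p > 100)):
        raise ValueError("protein content must lie in [0, 100] percent")
    out = y * p / 100.0
    return float(out) if out.ndim == 0 else out
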