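"""Kolmogorov-Smirnov model selection over circuit-model populations.

Each candidate model is simulated as populations of pPE and nPE circuits
in the fixed and variable conditions (four cells).  Every cell is
compared against the matching reference distribution with a two-sample
KS test.  A model is preferred when none of its cells differs
significantly from the reference; ties break by larger minimum p-value,
then by smaller mean KS statistic.  Model recovery (select the generator
among candidates on fresh simulations) validates the procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .circuit_models import (
    FIXED_CONDITION,
    MODEL_IDS,
    VARIABLE_CONDITION,
    simulate_population,
)

SCHEMA_VERSION = 1
CELLS = tuple(
    (ct, cond) for ct in ("pPE", "nPE") for cond in ("fixed", "variable")
)
SELECTION_RULE = (
    "fewest rejected cells at alpha; ties broken by larger min p, "
    "then smaller mean KS statistic, then model id"
)


def ks_compare(model_samples, data_samples) -> tuple[float, float]:
    """Two-sided two-sample KS test; returns (statistic, p_value)."""
    a = np.asarray(model_samples, dtype=float)
    b = np.asarray(data_samples, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs >= 5 values")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ModelFitReport:
    entries: pd.DataFrame  # model, cell_type, condition, ks_statistic, p_value
    aggregates: pd.DataFrame  # model, n_rejected, min_p, mean_ks
    best_model: str
    alpha: float
    selection_rule: str = SELECTION_RULE
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "alpha": self.alpha,
            "selection_rule": self.selection_rule,
            "best_model": self.best_model,
            "entries": self.entries.to_dict(orient="records"),
            "aggregates": self.aggregates.to_dict(orient="records"),
        }


def _extract_cells(sim: pd.DataFrame) -> dict:
    out = {}
    for ct, cond in CELLS:
        sel = sim[(sim["cell_type"] == ct) & (sim["condition"] == cond)]
        if len(sel) == 0:
            continue
        out[(ct, cond)] = sel["activity"].to_numpy(dtype=float)
    return out


def _scale_alignment(cells: dict, reference: dict) -> dict:
    """One multiplicative factor per model matching its pooled mean to the
    reference's pooled mean (units differ: model activity is dimensionless,
    reference responses are dF/F %)."""
    model_pool = np.concatenate([cells[c] for c in CELLS])
    ref_pool = np.concatenate([reference[c] for c in CELLS])
    if model_pool.mean() <= 0:
        return cells
    factor = ref_pool.mean() / model_pool.mean()
    return {c: v * factor for c, v in cells.items()}


def rank_models(
    simulations: dict,
    reference: dict,
    alpha: float = 0.05,
    aggregation: str = "rejections",
    align: str = "none",
) -> ModelFitReport:
    """Rank candidate models by KS agreement with reference distributions.

    ``simulations`` maps model id to a tidy simulation frame (or directly
    to a {(cell_type, condition): samples} dict); ``reference`` maps
    (cell_type, condition) to reference samples.  ``aggregation`` is
    either 'rejections' (the default rule above) or 'fisher' (rank by
    Fisher-combined p-value, largest first).  ``align='scale'`` rescales
    each model's samples by one pooled factor before testing, for
    references whose units differ from model activity; default is raw
    values.
    """
    if align not in ("none", "scale"):
        raise ValueError(f"unknown align {align!r}")
    missing_ref = [c for c in CELLS if c not in reference]
    if missing_ref:
        raise ValueError(f"missing reference cells: {missing_ref}")
    rows = []
    for model_id, sim in simulations.items():
        cells = sim if isinstance(sim, dict) else _extract_cells(sim)
        missing = [c for c in CELLS if c not in cells]
        if missing:
            raise ValueError(f"model {model_id!r} missing cells: {missing}")
        if align == "scale":
            cells = _scale_alignment(cells, reference)
        for ct, cond in CELLS:
            stat, p = ks_compare(cells[(ct, cond)], reference[(ct, cond)])
            rows.append(
                {
                    "model": model_id,
                    "cell_type": ct,
                    "condition": cond,
                    "ks_statistic": stat,
                    "p_value": p,
                }
            )
    entries = pd.DataFrame(rows)
    agg = (
        entries.groupby("model")
        .agg(
            n_rejected=("p_value", lambda p: int((p < alpha).sum())),
            min_p=("p_value", "min"),
            mean_ks=("ks_statistic", "mean"),
        )
        .reset_index()
    )
    if aggregation == "rejections":
        agg = agg.sort_values(
            by=["n_rejected", "min_p", "mean_ks", "model"],
            ascending=[True, False, True, True],
        ).reset_index(drop=True)
    elif aggregation == "fisher":
        combined = entries.groupby("model")["p_value"].apply(
            lambda p: stats.combine_pvalues(np.clip(p, 1e-300, 1.0))[1]
        )
        agg["fisher_p"] = agg["model"].map(combined)
        agg = agg.sort_values(by=["fisher_p", "model"], ascending=[False, True]).reset_index(
            drop=True
        )
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return ModelFitReport(entries, agg, str(agg.loc[0, "model"]), alpha)


def _reference_from_simulation(sim: pd.DataFrame) -> dict:
    return _extract_cells(sim)


def model_recovery(
    generator_model: str,
    n_replicates: int = 100,
    seed: int | None = None,
    candidates=MODEL_IDS,
    alpha: float = 0.05,
    n_circuits: int = 50,
    npe_modulation: str = "sigma_s",
    **sim_kwargs,
) -> pd.Series:
    """Selection frequencies when the reference is the generator model.

    Each replicate simulates a fresh reference population from
    ``generator_model`` and fresh candidate populations from every model
    (independent weights), then ranks candidates.  Returns the fraction
    of replicates in which each candidate was selected.
    """
    if n_replicates < 10:
        raise ValueError("n_replicates must be >= 10")
    ss = np.random.SeedSequence(seed)
    counts = {m: 0 for m in candidates}
    for rep_ss in ss.spawn(n_replicates):
        ref_seed, cand_seed = [int(s.generate_state(1)[0] % 2**31) for s in rep_ss.spawn(2)]
        reference = _reference_from_simulation(
            simulate_population(
                generator_model,
                FIXED_CONDITION,
                VARIABLE_CONDITION,
                n_circuits=n_circuits,
                seed=ref_seed,
                npe_modulation=npe_modulation,
                **sim_kwargs,
            )
        )
        sims = {
            m: simulate_population(
                m,
                FIXED_CONDITION,
                VARIABLE_CONDITION,
                n_circuits=n_circuits,
                seed=cand_seed + i,
                npe_modulation=npe_modulation,
                **sim_kwargs,
            )
            for i, m in enumerate(candidates)
        }
        report = rank_models(sims, reference, alpha=alpha)
        counts[report.best_model] += 1
    return pd.Series({m: counts[m] / n_replicates for m in candidates}, name=generator_model)


def confusion_matrix(
    generators=MODEL_IDS,
    n_replicates: int = 25,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Model-recovery confusion matrix: rows generator, columns selected."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for g, g_ss in zip(generators, ss.spawn(len(generators))):
        rows.append(
            model_recovery(
                g, n_replicates=n_replicates, seed=int(g_ss.generate_state(1)[0] % 2**31), **kwargs
            )
        )
    return pd.DataFrame(rows, index=list(generators))


#: P and I share the pPE equation, as do S and D: at the level of pPE cells
#: the four models form two separable groups.
MODEL_GROUPS = {"P": "P/I", "I": "P/I", "S": "S/D", "D": "S/D"}


def group_separation_accuracy(confusion: pd.DataFrame) -> float:
    """Fraction of selections landing in the generator's model group."""
    total = 0.0
    for g in confusion.index:
        same = [m for m in confusion.columns if MODEL_GROUPS[m] == MODEL_GROUPS[g]]
        total += confusion.loc[g, same].sum()
    return float(total / len(confusion.index))
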