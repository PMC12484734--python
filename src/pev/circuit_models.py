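"""Rectified-subtraction prediction-error circuit models.

Layer 2/3 prediction-error neurons are modelled as rectified weighted
differences of a bottom-up stimulus ``s`` and a top-down prediction
``E(s)``.  Positive prediction-error (pPE) neurons fire when the stimulus
exceeds the prediction; negative prediction-error (nPE) neurons fire when
the stimulus falls short of it.  Stimulus variability enters through a
variance term ``sigma^2 = sigma0^2 + sigma_s^2`` that multiplicatively
modulates either the prediction (divisively), the stimulus, or one of the
two inhibitory/driving pathways, giving four candidate mechanisms:

=====  =====================  ==========================================
id     name                   modulation
=====  =====================  ==========================================
P      modulated prediction   prediction divided by sigma^2 on both cells
S      modulated stimulus     stimulus multiplied by sigma^2 on both cells
I      modulated inhibition   pPE prediction divided, nPE stimulus multiplied
D      modulated driver       pPE stimulus multiplied, nPE prediction divided
=====  =====================  ==========================================

Each simulated circuit carries a pair of positive synaptic weights
(``w_stim`` on the stimulus term, ``w_pred`` on the prediction term)
drawn from a log-normal distribution and jointly normalised so the
largest weight in the population equals ``max_weight``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MODEL_IDS = ("P", "S", "I", "D")
CELL_TYPES = ("pPE", "nPE")
NPE_MODULATIONS = ("none", "sigma_s", "sigma_total", "sigma_s_floor1")
WEIGHT_MODES = ("pair", "single_gain")

MODEL_NAMES = {
    "P": "modulated prediction",
    "S": "modulated stimulus",
    "I": "modulated inhibition",
    "D": "modulated driver",
}


def discrete_uniform_sd(values=(3, 5, 7)) -> float:
    """Population standard deviation of a discrete uniform distribution.

    The variable whisker-intensity condition draws from three equally
    likely intensities; its standard deviation sets ``sigma_s``.
    """
    return float(np.std(np.asarray(values, dtype=float)))


@dataclass(frozen=True)
class ConditionParams:
    """Stimulus-statistics parameters for one pairing condition.

    Parameters
    ----------
    E_s:
        Prediction, the expected stimulus value (dimensionless intensity).
    s_pos, s_neg:
        Stimulus intensity presented on positive / negative mismatch trials.
    sigma0_sq:
        Baseline variance floor, keeps the divisive terms finite.
    sigma_s:
        Standard deviation of the stimulus distribution experienced in the
        condition (0 when the paired intensity is fixed).
    """

    E_s: float = 5.0
    s_pos: float = 9.0
    s_neg: float = 1.0
    sigma0_sq: float = 1.0
    sigma_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma0_sq <= 0:
            raise ValueError("sigma0_sq must be > 0")
        if self.sigma_s < 0:
            raise ValueError("sigma_s must be >= 0")

    @property
    def sigma_sq(self) -> float:
        return self.sigma0_sq + self.sigma_s**2


#: Fixed-intensity pairing: a single whisker intensity, no stimulus spread.
FIXED_CONDITION = ConditionParams(sigma_s=0.0)
#: Variable-intensity pairing: intensities drawn from {30, 50, 70}%, whose
#: 3/5/7 intensity-unit representation has SD ~1.6.
VARIABLE_CONDITION = ConditionParams(sigma_s=1.6)


def sample_weights(
    n_circuits: int,
    shape: float = 1.0,
    max_weight: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-circuit (w_stim, w_pred) pairs from a log-normal.

    ``shape`` is the log-scale standard deviation.  All 2*n draws are
    rescaled jointly so the pooled maximum equals ``max_weight`` exactly;
    the pre-normalisation scale is therefore irrelevant.

    Returns an array of shape (n_circuits, 2), columns (w_stim, w_pred).
    """
    if n_circuits < 1:
        raise ValueError("n_circuits must be >= 1")
    if shape <= 0:
        raise ValueError("shape must be > 0")
    if max_weight <= 0:
        raise ValueError("max_weight must be > 0")
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(mean=0.0, sigma=shape, size=(n_circuits, 2))
    # divide before scaling so the pooled maximum is max_weight exactly
    return draws / draws.max() * max_weight


def _terms(model_id: str, cell_type: str, cond: ConditionParams, s):
    """Return (stimulus term, prediction term) before weighting.

    The variance either divides the prediction or multiplies the stimulus,
    on the pathway each model designates.
    """
    var = cond.sigma_sq
    pred_down = cond.E_s / var
    if model_id == "P":
        return s, pred_down
    if model_id == "S":
        return var * np.asarray(s, dtype=float), cond.E_s
    if model_id == "I":
        # prediction down-modulated onto pPE, stimulus up-modulated onto nPE
        return (s, pred_down) if cell_type == "pPE" else (var * np.asarray(s, dtype=float), cond.E_s)
    if model_id == "D":
        # stimulus up-modulated onto pPE, prediction down-modulated onto nPE
        return (var * np.asarray(s, dtype=float), cond.E_s) if cell_type == "pPE" else (s, pred_down)
    raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")


def npe_modulation_factor(npe_modulation: str, cond: ConditionParams) -> float:
    if npe_modulation == "none":
        return 1.0
    if npe_modulation == "sigma_s":
        return cond.sigma_s
    if npe_modulation == "sigma_total":
        return float(np.sqrt(cond.sigma_sq))
    if npe_modulation == "sigma_s_floor1":
        return max(cond.sigma_s, 1.0)
    raise ValueError(f"unknown npe_modulation {npe_modulation!r}; expected one of {NPE_MODULATIONS}")


def pe_response(
    model_id: str,
    cell_type: str,
    cond: ConditionParams,
    s: float,
    w_stim=1.0,
    w_pred=1.0,
    npe_modulation: str = "none",
    weight_mode: str = "pair",
):
    """Activity of one prediction-error cell type under one model.

    pPE = max(0, w_stim * stim_term - w_pred * pred_term)
    nPE = max(0, w_pred * pred_term - w_stim * stim_term)

    With ``weight_mode='single_gain'`` the unweighted rectified difference
    is scaled by ``w_stim`` (``w_pred`` is ignored).  If ``npe_modulation``
    is not 'none', nPE activity is additionally multiplied by the selected
    variability factor.  Accepts scalar or array weights; returns the
    matching shape.
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell_type {cell_type!r}; expected one of {CELL_TYPES}")
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    stim_term, pred_term = _terms(model_id, cell_type, cond, s)
    ws = np.asarray(w_stim, dtype=float)
    wp = np.asarray(w_pred, dtype=float)
    if weight_mode == "single_gain":
        diff = stim_term - pred_term if cell_type == "pPE" else pred_term - stim_term
        out = ws * np.maximum(0.0, diff)
    else:
        if cell_type == "pPE":
            out = np.maximum(0.0, ws * stim_term - wp * pred_term)
        else:
            out = np.maximum(0.0, wp * pred_term - ws * stim_term)
    if cell_type == "nPE" and npe_modulation != "none":
        out = out * npe_modulation_factor(npe_modulation, cond)
    return out if np.ndim(out) else float(out)


def simulate_population(
    model_id: str,
    cond_fixed: ConditionParams = FIXED_CONDITION,
    cond_variable: ConditionParams = VARIABLE_CONDITION,
    n_circuits: int = 50,
    seed: int | None = None,
    npe_modulation: str = "sigma_s",
    weight_mode: str = "pair",
    max_weight: float = 0.05,
    shape: float = 1.0,
) -> pd.DataFrame:
    """Simulate pPE and nPE circuit populations in both conditions.

    Weights are sampled once per cell type and reused across conditions,
    so each circuit experiences both the fixed and the variable pairing.
    pPE cells see the positive-mismatch stimulus ``s_pos``; nPE cells see
    the negative-mismatch stimulus ``s_neg``.

    Returns a tidy frame with columns ``model``, ``cell_type``,
    ``condition``, ``circuit_id``, ``activity`` and ``activity_premod``
    (nPE activity before the variability multiplication; identical to
    ``activity`` for pPE cells or when ``npe_modulation='none'``).
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    if (cond_fixed.E_s, cond_fixed.s_pos, cond_fixed.s_neg) != (
        cond_variable.E_s,
        cond_variable.s_pos,
        cond_variable.s_neg,
    ):
        raise ValueError("conditions must share E_s and mismatch stimuli")
    if npe_modulation == "sigma_s" and min(cond_fixed.sigma_s, cond_variable.sigma_s) == 0:
        warnings.warn(
            "npe_modulation='sigma_s' multiplies nPE activity by sigma_s, which is 0 "
            "in a fixed condition: all fixed-condition nPE activity will be zero. "
            "Consider 'sigma_s_floor1' or 'sigma_total'.",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    # one weight pool per simulated population: 50 pPE + 50 nPE circuits,
    # normalised jointly so the single pooled maximum is max_weight
    pooled = sample_weights(2 * n_circuits, shape=shape, max_weight=max_weight, seed=rng)
    weights_by_cell = {"pPE": pooled[:n_circuits], "nPE": pooled[n_circuits:]}
    rows = []
    for cell_type in CELL_TYPES:
        weights = weights_by_cell[cell_type]
        for cond_name, cond in (("fixed", cond_fixed), ("variable", cond_variable)):
            s = cond.s_pos if cell_type == "pPE" else cond.s_neg
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                premod = pe_response(
                    model_id, cell_type, cond, s,
                    w_stim=weights[:, 0], w_pred=weights[:, 1],
                    npe_modulation="none", weight_mode=weight_mode,
                )
            factor = 1.0
            if cell_type == "nPE" and npe_modulation != "none":
                factor = npe_modulation_factor(npe_modulation, cond)
            rows.append(
                pd.DataFrame(
                    {
                        "model": model_id,
                        "cell_type": cell_type,
                        "condition": cond_name,
                        "circuit_id": np.arange(n_circuits),
                        "activity": np.asarray(premod) * factor,
                        "activity_premod": np.asarray(premod),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
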