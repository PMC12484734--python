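"""Shuffle-null responsiveness classification.

A neuron is called responsive to a trial type when the distribution of
its single-trial windowed responses differs from a per-neuron null of
1000 window statistics computed at random positions of its dF/F trace
(each statistic: mean over a 1 s window minus mean over the preceding
1 s, exactly as for real trials).  Significance is a two-sided
Mann-Whitney U test at alpha = 0.05; the sign of (median response -
median null) splits responsive neurons into positively and negatively
modulated, and only positively modulated neurons propagate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signal_processing import (
    EARLY_WINDOW,
    ResponseMatrix,
    WindowSpec,
    seconds_to_frames,
    sliding_window_means,
    trial_response,
)
from .synthetic_data import TraceSet

DEFAULT_N_SHUFFLES = 1000
DEFAULT_ALPHA = 0.05
#: Below this many total observations the exact Mann-Whitney null is used;
#: above it, the normal approximation with tie correction.
EXACT_MWU_MAX_N = 25


@dataclass
class ShuffleNull:
    """Per-neuron null distributions: neurons x n_shuffles window statistics."""

    values: np.ndarray
    positions: np.ndarray
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]


def build_shuffle_null(
    dff: TraceSet,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator | None = None,
    window: WindowSpec = EARLY_WINDOW,
    trials: pd.DataFrame | None = None,
    exclude_event_windows: bool = False,
) -> ShuffleNull:
    """Sample baseline-corrected window means at random trace positions.

    Positions (the virtual "onset" frame) are uniform over frames that
    leave room for both the window and its 1 s pre-baseline, drawn
    independently per neuron.  With ``exclude_event_windows=True`` and a
    trial table, positions whose response window overlaps a real stimulus
    window are excluded.
    """
    rate = dff.frame_rate
    length = window.length_frames(rate)
    off = window.offset_frames(rate)
    base = seconds_to_frames(1.0, rate)
    lo, hi = base, dff.n_frames - off - length  # valid onset range [lo, hi)
    if hi <= lo:
        raise ValueError("trace too short for shuffle events (needs >= 2 s of frames)")

    valid = np.arange(lo, hi)
    if exclude_event_windows:
        if trials is None:
            raise ValueError("exclude_event_windows requires a trial table")
        blocked = np.zeros(dff.n_frames, dtype=bool)
        for onset in trials["whisker_onset_frame"].to_numpy(dtype=int):
            blocked[max(0, onset - length - off + 1) : onset + length + off] = True
        valid = valid[~blocked[valid]]
        if valid.size == 0:
            raise ValueError("no valid shuffle positions outside event windows")

    rng = np.random.default_rng(seed)
    positions = rng.choice(valid, size=(dff.n_neurons, n_shuffles), replace=True)

    rows = np.arange(dff.n_neurons)[:, None]
    win = sliding_window_means(dff.values, length)
    base_win = win if length == base else sliding_window_means(dff.values, base)
    vals = win[rows, positions + off] - base_win[rows, positions - base]
    return ShuffleNull(vals, positions)


@dataclass
class NeuronClassification:
    label: str  # responsive_positive | responsive_negative | not_responsive
    p_value: float
    median_effect_sign: int


def _mwu_label(p_values: np.ndarray, signs: np.ndarray, alpha: float) -> np.ndarray:
    labels = np.full(p_values.shape, "not_responsive", dtype=object)
    sig = p_values < alpha
    labels[sig & (signs > 0)] = "responsive_positive"
    labels[sig & (signs < 0)] = "responsive_negative"
    return labels


def classify_neuron(
    responses: np.ndarray,
    null: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    min_trials: int = 5,
) -> NeuronClassification:
    """Classify one neuron's responses against its shuffle null."""
    responses = np.asarray(responses, dtype=float)
    null = np.asarray(null, dtype=float)
    if responses.size < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {responses.size}")
    combined = np.concatenate([responses, null])
    if np.ptp(combined) == 0:  # all values tied: degenerate ranks, not an error
        return NeuronClassification("not_responsive", 1.0, 0)
    method = "exact" if combined.size < EXACT_MWU_MAX_N else "asymptotic"
    res = stats.mannwhitneyu(responses, null, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    sign = int(np.sign(np.median(responses) - np.median(null)))
    label = _mwu_label(np.array([p]), np.array([sign]), alpha)[0]
    return NeuronClassification(label, p, sign)


def classify_matrix(
    responses: np.ndarray,
    null_values: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Vectorised classification of many neurons at once.

    ``responses`` is neurons x trials, ``null_values`` neurons x shuffles.
    Uses the normal approximation with tie correction (appropriate for
    the default 1000-shuffle null).  Returns a frame with ``neuron_id``,
    ``label``, ``p_value``, ``median_effect_sign``.
    """
    responses = np.asarray(responses, dtype=float)
    null_values = np.asarray(null_values, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(
            responses, null_values, alternative="two-sided", method="asymptotic", axis=1
        )
        p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance (all-tied) rows
    signs = np.sign(np.median(responses, axis=1) - np.median(null_values, axis=1)).astype(int)
    return pd.DataFrame(
        {
            "neuron_id": np.arange(responses.shape[0]),
            "label": _mwu_label(p, signs, alpha),
            "p_value": p,
            "median_effect_sign": signs,
        }
    )


#: trial types tested per session kind
_SESSION_TRIAL_TYPES = {
    "pairing": ("pairing",),
    "interleaved1": ("matched", "mismatch"),
    "interleaved2": ("matched", "mismatch"),
}


def session_classification(
    dff_by_session: dict,
    trials_by_session: dict,
    nulls_by_session: dict | None = None,
    window: WindowSpec = EARLY_WINDOW,
    alpha: float = DEFAULT_ALPHA,
    min_trials: int = 5,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-session, per-trial-type responsiveness labels for a population.

    For each session, single-trial responses on each trial type (all
    trials in the pairing session; matched and mismatch trials separately
    in interleaved sessions) are tested against that session's shuffle
    null.  Positively modulated neurons receive the category
    pairing-/matched-/mismatch-responsive accordingly.  A neuron that is
    mismatch-responsive in both interleaved sessions is "overlapping".

    Returns a long frame: neuron_id, session_kind, trial_type, category,
    label, p_value, overlapping.
    """
    rng = np.random.default_rng(seed)
    records = []
    for session_kind, types in _SESSION_TRIAL_TYPES.items():
        if session_kind not in dff_by_session:
            continue
        dff = dff_by_session[session_kind]
        trials = trials_by_session.get(session_kind)
        if trials is None:
            raise KeyError(f"missing trial table for session {session_kind!r}")
        if nulls_by_session is not None and session_kind in nulls_by_session:
            null = nulls_by_session[session_kind]
        else:
            null = build_shuffle_null(dff, n_shuffles=n_shuffles, seed=rng, window=window)
        rm = trial_response(dff, trials, window)
        for trial_type in types:
            if trial_type == "pairing":
                mask = np.ones(len(trials), dtype=bool)
            elif trial_type == "matched":
                mask = ~trials["is_mismatch"].to_numpy()
            else:
                mask = trials["is_mismatch"].to_numpy()
            if mask.sum() < min_trials:
                continue
            cls = classify_matrix(rm.values[:, mask], null.values, alpha=alpha)
            cls["session_kind"] = session_kind
            cls["trial_type"] = trial_type
            category = trial_type if trial_type != "pairing" else "pairing"
            cls["category"] = np.where(cls["label"] == "responsive_positive", category, "")
            records.append(cls)
    if not records:
        raise ValueError("no sessions with enough trials to classify")
    out = pd.concat(records, ignore_index=True)

    mm = out[(out["trial_type"] == "mismatch") & (out["label"] == "responsive_positive")]
    per_neuron_sessions = mm.groupby("neuron_id")["session_kind"].nunique()
    overlapping_ids = set(per_neuron_sessions[per_neuron_sessions >= 2].index)
    out["overlapping"] = out["neuron_id"].isin(overlapping_ids) & (out["trial_type"] == "mismatch")
    return out


def mismatch_responsive_ids(classification: pd.DataFrame, session_kind: str) -> np.ndarray:
    """Neuron ids labelled mismatch-responsive (positive) in one session."""
    sel = classification[
        (classification["session_kind"] == session_kind)
        & (classification["trial_type"] == "mismatch")
        & (classification["label"] == "responsive_positive")
    ]
    return sel["neuron_id"].to_numpy()


def shuffled_population_ci(
    null_values: np.ndarray,
    sample_fraction=0.10,
    n_draws: int = 1000,
    seed: int | None = None,
    ci: float = 95.0,
) -> tuple[float, float]:
    """Confidence interval of the mean of random shuffled sub-populations.

    Repeatedly draws ``sample_fraction`` of the neurons (a scalar in
    (0, 1], or a (lo, hi) range sampled uniformly per draw, e.g. the
    0.08-0.12 mismatch-neuron prevalence band), averages one null value
    per drawn neuron, and returns the 2.5/97.5 percentiles of the draw
    means.  A measured population mean outside this interval is unlikely
    to arise from chance alignment of null activity.
    """
    null_values = np.asarray(null_values, dtype=float)
    n_neurons = null_values.shape[0]
    if n_neurons < 10:
        raise ValueError("need >= 10 neurons for a population CI")
    if np.isscalar(sample_fraction):
        frac_lo = frac_hi = float(sample_fraction)
    else:
        frac_lo, frac_hi = map(float, sample_fraction)
    if not 0.0 < frac_lo <= frac_hi <= 1.0:
        raise ValueError("sample_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    means = np.empty(n_draws)
    for d in range(n_draws):
        frac = rng.uniform(frac_lo, frac_hi) if frac_hi > frac_lo else frac_lo
        k = max(1, int(round(frac * n_neurons)))
        idx = rng.choice(n_neurons, size=k, replace=False)
        cols = rng.integers(0, null_values.shape[1], size=k)
        means[d] = null_values[idx, cols].mean()
    half = (100.0 - ci) / 2.0
    lo, hi = np.percentile(means, [half, 100.0 - half])
    return float(lo), float(hi)
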