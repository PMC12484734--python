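"""Trial-based delta-F/F conversion and windowed response extraction.

dF/F = (F - F0) / F0 with F0 computed per trial as the mean of the 1 s
window immediately preceding the start cue.  The scalar trial response is
the mean dF/F in a 1 s window at a configurable offset from stimulus
onset, minus the mean dF/F in the 1 s immediately before stimulus onset.
All windows are half-open frame ranges; seconds are converted to frames
with round-half-up (0.65 s -> 20 frames at 30 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import TraceSet


def seconds_to_frames(seconds: float, frame_rate: float) -> int:
    """Convert a duration/offset to whole frames, rounding half up."""
    return int(math.floor(seconds * frame_rate + 0.5))


@dataclass(frozen=True)
class WindowSpec:
    """A 1 s (by default) response window relative to a reference event."""

    offset_s: float = 0.0
    length_s: float = 1.0
    reference: str = "stimulus_onset"

    def __post_init__(self):
        if self.length_s <= 0:
            raise ValueError("length_s must be > 0")
        if self.reference not in ("stimulus_onset", "cue_onset"):
            raise ValueError("reference must be 'stimulus_onset' or 'cue_onset'")

    def offset_frames(self, frame_rate: float) -> int:
        return seconds_to_frames(self.offset_s, frame_rate)

    def length_frames(self, frame_rate: float) -> int:
        return seconds_to_frames(self.length_s, frame_rate)


#: Window from stimulus onset, where mismatch responses are measured.
EARLY_WINDOW = WindowSpec(offset_s=0.0)
#: Late window 0.65 s after stimulus onset, where fixed-vs-variable
#: differences emerge.
LATE_WINDOW = WindowSpec(offset_s=0.65)


@dataclass
class ResponseMatrix:
    """Scalar windowed responses: neurons x trials (dF/F fraction)."""

    values: np.ndarray
    trial_ids: np.ndarray
    window: WindowSpec
    baseline_length_s: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("responses contain non-finite values")

    def to_frame(self) -> pd.DataFrame:
        n_neurons, n_trials = self.values.shape
        return pd.DataFrame(
            {
                "neuron_id": np.repeat(np.arange(n_neurons), n_trials),
                "trial_id": np.tile(self.trial_ids, n_neurons),
                "response": self.values.ravel(),
            }
        )


def _reference_frames(trials: pd.DataFrame, reference: str) -> np.ndarray:
    col = "whisker_onset_frame" if reference == "stimulus_onset" else "cue_frame"
    return trials[col].to_numpy(dtype=int)


def compute_dff(raw: TraceSet, trials: pd.DataFrame) -> TraceSet:
    """Per-trial dF/F with F0 = mean of the 1 s window before the cue.

    Frames outside any trial block are set to 0.  Raises if any (neuron,
    trial) baseline F0 is non-positive, listing the offenders.
    """
    if raw.kind != "raw":
        raise ValueError("compute_dff expects raw traces")
    one_s = seconds_to_frames(1.0, raw.frame_rate)
    out = np.zeros_like(raw.values)
    offenders = []
    for row in trials.itertuples(index=False):
        start, cue = int(row.trial_start_frame), int(row.cue_frame)
        stop = start + int(row.n_frames)
        if cue - one_s < start:
            raise TrialWindowError(int(row.trial_id), "needs >= 1 s of frames before cue_frame")
        f0 = raw.values[:, cue - one_s : cue].mean(axis=1, keepdims=True)
        bad = np.nonzero(f0[:, 0] <= 0)[0]
        if bad.size:
            offenders.extend((int(n), int(row.trial_id)) for n in bad)
            continue
        out[:, start:stop] = raw.values[:, start:stop] / f0 - 1.0
    if offenders:
        raise ValueError(f"non-positive baseline F0 for (neuron, trial): {offenders[:20]}")
    return TraceSet(out, raw.frame_rate, "dff")


class TrialWindowError(ValueError):
    """A response window does not fit inside its trial."""

    def __init__(self, trial_id: int, message: str):
        self.trial_id = trial_id
        super().__init__(f"trial {trial_id}: {message}")


def trial_response(
    dff: TraceSet, trials: pd.DataFrame, window: WindowSpec = EARLY_WINDOW
) -> ResponseMatrix:
    """Baseline-subtracted windowed mean dF/F per (neuron, trial).

    value = mean dF/F over [ref+offset, ref+offset+length)
          - mean dF/F over [ref-1s, ref)
    """
    if dff.kind != "dff":
        raise ValueError("trial_response expects dF/F traces")
    rate = dff.frame_rate
    off = window.offset_frames(rate)
    length = window.length_frames(rate)
    base = seconds_to_frames(1.0, rate)
    refs = _reference_frames(trials, window.reference)

    starts = trials["trial_start_frame"].to_numpy(dtype=int)
    stops = starts + trials["n_frames"].to_numpy(dtype=int)
    for tid, ref, start, stop in zip(trials["trial_id"], refs, starts, stops):
        if ref + off + length > stop:
            raise TrialWindowError(int(tid), "response window overruns trial end")
        if ref - base < start:
            raise TrialWindowError(int(tid), "baseline window precedes trial start")

    resp = sliding_window_means(dff.values, length)[:, refs + off]
    baseline = sliding_window_means(dff.values, base)[:, refs - base]
    return ResponseMatrix(resp - baseline, trials["trial_id"].to_numpy(), window)


def sliding_window_means(values: np.ndarray, length: int) -> np.ndarray:
    """Mean over every half-open frame window [p, p+length).

    Each window is summed independently (not via cumulative-sum
    differences), so windows with identical content give bit-identical
    means — e.g. a constant trace yields exactly zero baseline-corrected
    statistics.
    """
    view = np.lib.stride_tricks.sliding_window_view(values, length, axis=1)
    return view.mean(axis=-1)


def population_average(
    dff: TraceSet,
    trials: pd.DataFrame,
    neuron_ids=None,
    trial_mask=None,
    reference: str = "stimulus_onset",
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-corrected population-average trace around an event.

    Each selected trial is aligned on the reference event; per-neuron
    trial averages are baseline-corrected by subtracting their mean over
    the 1 s pre-event window, then averaged across neurons.

    Returns (times in seconds relative to the event, population trace).
    """
    if neuron_ids is None:
        neuron_ids = np.arange(dff.n_neurons)
    neuron_ids = np.asarray(neuron_ids, dtype=int)
    if neuron_ids.size == 0:
        raise ValueError("neuron selection is empty")
    sel = trials if trial_mask is None else trials.loc[np.asarray(trial_mask)]
    if len(sel) == 0:
        raise ValueError("no trials pass the filter")

    rate = dff.frame_rate
    refs = _reference_frames(sel, reference)
    starts = sel["trial_start_frame"].to_numpy(dtype=int)
    stops = starts + sel["n_frames"].to_numpy(dtype=int)
    pre = int((refs - starts).min())
    post = int((stops - refs).min())

    stack = np.stack([dff.values[neuron_ids, r - pre : r + post] for r in refs])
    per_neuron = stack.mean(axis=0)  # neurons x frames, trial average
    base = seconds_to_frames(1.0, rate)
    per_neuron = per_neuron - per_neuron[:, pre - base : pre].mean(axis=1, keepdims=True)
    trace = per_neuron.mean(axis=0)
    times = (np.arange(-pre, post)) / rate
    return times, trace
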