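"""Synthetic trial-structured calcium fluorescence data.

Emulates the audio-tactile experiment the analysis assumes: 30 Hz raw
fluorescence traces for a population of neurons across trials of 8 s
(2 s baseline, 50 ms start cue, 1 s sound, then a whisker stimulus),
with a configurable minority of neurons carrying mismatch-locked calcium
transients.  Two sound-whisker pairings run per session; interleaved
sessions replace the paired intensity with a mismatch intensity in a
fixed fraction (default 15%) of trials.

Everything is deterministic given (config, seed); a ground-truth table
records each neuron's planted class and amplitude so that classifier
sensitivity and specificity can be measured downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

FRAME_RATE = 30.0

SESSION_KINDS = ("pairing", "interleaved1", "interleaved2")
ALLOWED_INTENSITIES = (10, 30, 50, 70, 90)

#: Planted neuron classes.  ``mismatch_responsive_s1``/``_s2`` respond to
#: mismatch trials of interleaved session 1 / 2; ``matched_responsive``
#: to matched trials of interleaved sessions; ``pairing_responsive`` to
#: every pairing-session trial; ``negatively_modulated`` carry a negative
#: transient on mismatch trials; ``null`` neurons carry noise only.
GT_CLASSES = (
    "mismatch_responsive_s1",
    "mismatch_responsive_s2",
    "mismatch_responsive_both",
    "matched_responsive",
    "pairing_responsive",
    "negatively_modulated",
    "null",
)

TRIAL_COLUMNS = [
    "trial_id",
    "session_kind",
    "sound_id",
    "intensity_percent",
    "is_mismatch",
    "trial_start_frame",
    "cue_frame",
    "sound_onset_frame",
    "whisker_onset_frame",
    "n_frames",
]


class TrialStructureError(ValueError):
    """A trial's events do not fit its frame budget."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class KernelParams:
    """Calcium transient kinetics: difference-of-exponentials kernel.

    Defaults resemble a fast genetically encoded indicator (rise ~50 ms,
    decay ~400 ms).  The kernel is normalised so that its mean over the
    first second equals 1, i.e. a planted amplitude `a` produces a
    windowed (1 s) mean response of `a`.
    """

    rise_s: float = 0.05
    decay_s: float = 0.4
    duration_s: float = 2.0

    def __post_init__(self):
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ValueError("kernel rise/decay times must be positive")

    def evaluate(self, frame_rate: float = FRAME_RATE) -> np.ndarray:
        t = np.arange(0.0, self.duration_s, 1.0 / frame_rate)
        k = np.exp(-t / self.decay_s) - np.exp(-t / self.rise_s)
        window = int(round(frame_rate))
        return k / k[:window].mean()


@dataclass(frozen=True)
class SessionConfig:
    """One session of the audio-tactile protocol.

    ``pair_a``/``pair_b`` map a sound id to the set of whisker intensities
    it may be paired with (one element = fixed pairing, two or more =
    variable pairing; intensities are drawn i.i.d. uniform per trial).
    In interleaved sessions, ``mismatch_fraction`` of all trials present
    ``mismatch_sound`` at ``mismatch_intensity`` instead of its pairing.
    """

    session_kind: str
    n_trials: int
    pair_a: tuple = ("A", (50,))
    pair_b: tuple = ("B", (30, 50, 70))
    mismatch_sound: str | None = None
    mismatch_intensity: int = 90
    mismatch_fraction: float = 0.15
    trial_length_s: float = 8.0
    baseline_s: float = 2.0
    cue_to_sound_s: float = 1.0
    sound_s: float = 1.0

    def __post_init__(self):
        if self.session_kind not in SESSION_KINDS:
            raise ValueError(f"session_kind must be one of {SESSION_KINDS}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.mismatch_fraction <= 1.0:
            raise ValueError("mismatch_fraction must be in [0, 1]")
        for name, (sound, intensities) in (("pair_a", self.pair_a), ("pair_b", self.pair_b)):
            if len(intensities) < 1:
                raise ValueError(f"{name} needs at least one intensity")
            for i in intensities:
                if i not in ALLOWED_INTENSITIES:
                    raise ValueError(f"{name} intensity {i} not in {ALLOWED_INTENSITIES}")
        if self.is_interleaved and self.mismatch_sound is None:
            raise ValueError("interleaved sessions require mismatch_sound")
        if self.mismatch_sound is not None and self.mismatch_sound not in (
            self.pair_a[0],
            self.pair_b[0],
        ):
            raise ValueError("mismatch_sound must be one of the paired sounds")

    @property
    def is_interleaved(self) -> bool:
        return self.session_kind.startswith("interleaved")

    @property
    def n_mismatch_trials(self) -> int:
        if not self.is_interleaved:
            return 0
        return int(round(self.mismatch_fraction * self.n_trials))

    def frames(self, frame_rate: float = FRAME_RATE) -> dict:
        """Per-trial event frames (local to the trial) and frame budget."""
        n_frames = int(round(self.trial_length_s * frame_rate))
        cue = int(round(self.baseline_s * frame_rate))
        sound = cue + int(round(self.cue_to_sound_s * frame_rate))
        whisker = sound + int(round(self.sound_s * frame_rate))
        one_s = int(round(frame_rate))
        if cue < one_s:
            raise TrialStructureError("baseline_s", "needs >= 1 s of frames before the cue")
        if whisker + one_s > n_frames:
            raise TrialStructureError(
                "trial_length_s",
                f"whisker onset frame {whisker} + 1 s window exceeds {n_frames} frames",
            )
        return {"n_frames": n_frames, "cue": cue, "sound": sound, "whisker": whisker}


@dataclass
class TraceSet:
    """Fluorescence traces: neurons x frames at a fixed frame rate."""

    values: np.ndarray
    frame_rate: float = FRAME_RATE
    kind: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (neurons x frames)")
        if self.kind not in ("raw", "dff"):
            raise ValueError("kind must be 'raw' or 'dff'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("traces contain non-finite values")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("traces", data=self.values, track_times=False)
            ds.attrs["frame_rate"] = self.frame_rate
            ds.attrs["kind"] = self.kind

    @classmethod
    def load(cls, path) -> "TraceSet":
        with h5py.File(path, "r") as f:
            ds = f["traces"]
            return cls(ds[()], float(ds.attrs["frame_rate"]), str(ds.attrs["kind"]))


def make_ground_truth(
    n_neurons: int,
    mismatch_prevalence: float = 0.10,
    matched_prevalence: float = 0.10,
    pairing_prevalence: float = 0.10,
    negative_prevalence: float = 0.05,
    amplitude: float = 0.10,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign planted classes and response amplitudes to a population.

    Each interleaved session receives its own mismatch-responsive cohort
    of exactly round(prevalence x n) neurons.  Returns a frame with
    columns ``neuron_id``, ``class_label``, ``amplitude`` (signed
    delta-F/F fraction planted per preferred trial).
    """
    if not 0.0 < mismatch_prevalence < 1.0:
        raise ValueError("mismatch_prevalence must be in (0, 1)")
    counts = {
        "mismatch_responsive_s1": int(round(mismatch_prevalence * n_neurons)),
        "mismatch_responsive_s2": int(round(mismatch_prevalence * n_neurons)),
        "matched_responsive": int(round(matched_prevalence * n_neurons)),
        "pairing_responsive": int(round(pairing_prevalence * n_neurons)),
        "negatively_modulated": int(round(negative_prevalence * n_neurons)),
    }
    if sum(counts.values()) > n_neurons:
        raise ValueError("class prevalences exceed the population")
    rng = np.random.default_rng(seed)
    labels = np.full(n_neurons, "null", dtype=object)
    order = rng.permutation(n_neurons)
    pos = 0
    for cls, k in counts.items():
        labels[order[pos : pos + k]] = cls
        pos += k
    amp = np.where(labels == "null", 0.0, amplitude)
    amp = np.where(labels == "negatively_modulated", -amplitude, amp)
    return pd.DataFrame(
        {"neuron_id": np.arange(n_neurons), "class_label": labels, "amplitude": amp}
    )


def _responding_mask(ground_truth: pd.DataFrame, session_kind: str, is_mismatch: bool) -> np.ndarray:
    cls = ground_truth["class_label"].to_numpy()
    if session_kind == "pairing":
        return cls == "pairing_responsive"
    if is_mismatch:
        own = "mismatch_responsive_s1" if session_kind == "interleaved1" else "mismatch_responsive_s2"
        return (cls == own) | (cls == "mismatch_responsive_both") | (cls == "negatively_modulated")
    return cls == "matched_responsive"


def build_trial_table(config: SessionConfig, seed=None, start_frame: int = 0) -> pd.DataFrame:
    """Randomised trial sequence for one session; frame indices are global."""
    rng = np.random.default_rng(seed)
    fr = config.frames()
    n = config.n_trials
    sound_a, set_a = config.pair_a
    sound_b, set_b = config.pair_b

    is_mismatch = np.zeros(n, dtype=bool)
    if config.is_interleaved and config.n_mismatch_trials:
        is_mismatch[rng.choice(n, size=config.n_mismatch_trials, replace=False)] = True

    sounds = np.where(rng.random(n) < 0.5, sound_a, sound_b).astype(object)
    sounds[is_mismatch] = config.mismatch_sound
    intensities = np.empty(n, dtype=int)
    for i in range(n):
        if is_mismatch[i]:
            intensities[i] = config.mismatch_intensity
        else:
            pool = set_a if sounds[i] == sound_a else set_b
            intensities[i] = pool[rng.integers(len(pool))]

    starts = start_frame + np.arange(n) * fr["n_frames"]
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "session_kind": config.session_kind,
            "sound_id": sounds,
            "intensity_percent": intensities,
            "is_mismatch": is_mismatch,
            "trial_start_frame": starts,
            "cue_frame": starts + fr["cue"],
            "sound_onset_frame": starts + fr["sound"],
            "whisker_onset_frame": starts + fr["whisker"],
            "n_frames": fr["n_frames"],
        }
    )[TRIAL_COLUMNS]


def generate_session(
    config: SessionConfig,
    ground_truth: pd.DataFrame | None = None,
    n_neurons: int = 200,
    kinetics: KernelParams = KernelParams(),
    noise_sd: float = 0.02,
    baseline_f: float = 100.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[TraceSet, pd.DataFrame, pd.DataFrame]:
    """Generate raw fluorescence traces for one session.

    Raw F = baseline x (1 + planted dF/F) + baseline x noise_sd x N(0,1)
    per frame.  Responsive neurons carry a transient kernel locked to the
    whisker onset of their preferred trial type.  If ``ground_truth`` is
    None a fresh population of ``n_neurons`` is drawn (pass an existing
    table to share neurons across sessions of one experiment).

    Returns (raw TraceSet, trial table, ground truth).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if ground_truth is None:
        ground_truth = make_ground_truth(n_neurons, seed=rng)
    trials = build_trial_table(config, seed=rng)
    fr = config.frames()
    n_neurons = len(ground_truth)
    total_frames = config.n_trials * fr["n_frames"]

    kernel = kinetics.evaluate(FRAME_RATE)
    amp = ground_truth["amplitude"].to_numpy()
    dff = np.zeros((n_neurons, total_frames))
    for row in trials.itertuples(index=False):
        mask = _responding_mask(ground_truth, config.session_kind, row.is_mismatch)
        if not mask.any():
            continue
        onset = int(row.whisker_onset_frame)
        end = min(onset + len(kernel), int(row.trial_start_frame) + int(row.n_frames))
        seg = kernel[: end - onset]
        dff[mask, onset:end] += np.outer(amp[mask], seg)

    base = baseline_f * rng.uniform(0.8, 1.2, size=(n_neurons, 1))
    raw = base * (1.0 + dff)
    if noise_sd > 0:
        raw = raw + base * noise_sd * rng.standard_normal((n_neurons, total_frames))
    return TraceSet(raw, FRAME_RATE, "raw"), trials, ground_truth


@dataclass
class Experiment:
    """One imaging experiment: pairing + two interleaved sessions sharing neurons."""

    sessions: dict = field(default_factory=dict)  # session_kind -> (TraceSet, trial table)
    ground_truth: pd.DataFrame | None = None


def default_session_configs(
    design: str = "fixed_vs_variable",
    n_pairing_trials: int = 180,
    n_interleaved_trials: int = 200,
    mismatch_intensity: int = 90,
) -> list[SessionConfig]:
    """Session triplets for the two experimental designs.

    ``fixed_vs_variable``: sound A paired with a fixed 50% intensity and
    sound B with a variable 30/50/70% intensity; mismatches hit sound A
    in interleaved session 1 and sound B in session 2.
    ``delta_scaling``: sound A at 30%, sound B at 50%, so the same
    mismatch intensity gives different deviations per session.
    """
    if design == "fixed_vs_variable":
        pair_a, pair_b = ("A", (50,)), ("B", (30, 50, 70))
    elif design == "delta_scaling":
        pair_a, pair_b = ("A", (30,)), ("B", (50,))
    else:
        raise ValueError(f"unknown design {design!r}")
    common = dict(pair_a=pair_a, pair_b=pair_b, mismatch_intensity=mismatch_intensity)
    return [
        SessionConfig("pairing", n_pairing_trials, **common),
        SessionConfig("interleaved1", n_interleaved_trials, mismatch_sound="A", **common),
        SessionConfig("interleaved2", n_interleaved_trials, mismatch_sound="B", **common),
    ]


def generate_experiment(
    configs: list[SessionConfig] | None = None,
    n_neurons: int = 200,
    kinetics: KernelParams = KernelParams(),
    noise_sd: float = 0.02,
    mismatch_prevalence: float = 0.10,
    amplitude: float = 0.10,
    seed: int | None = None,
) -> Experiment:
    """Generate a full experiment with a shared neuron population."""
    if configs is None:
        configs = default_session_configs()
    rng = np.random.default_rng(seed)
    gt = make_ground_truth(
        n_neurons, mismatch_prevalence=mismatch_prevalence, amplitude=amplitude, seed=rng
    )
    exp = Experiment(ground_truth=gt)
    for config in configs:
        traces, trials, _ = generate_session(
            config, ground_truth=gt, kinetics=kinetics, noise_sd=noise_sd, seed=rng
        )
        exp.sessions[config.session_kind] = (traces, trials)
    return exp


def generate_reference_distributions(
    means,
    sems,
    n_per_group: int = 40,
    seed: int | None = None,
    labels=None,
) -> pd.DataFrame:
    """Right-skewed (log-normal) response samples with given mean and SEM.

    Stand-in for measured mismatch-response distributions when exercising
    model selection: each group is sampled with mean ``means[i]`` and
    standard deviation ``sems[i] * sqrt(n_per_group)`` (delta-F/F %).
    """
    means = np.asarray(means, dtype=float)
    sems = np.asarray(sems, dtype=float)
    if means.shape != sems.shape:
        raise ValueError("means and sems must have equal length")
    if np.any(means <= 0):
        raise ValueError("group means must be positive (mismatch responses are positive-going)")
    if np.any(sems <= 0):
        raise ValueError("sems must be positive")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(means))]
    rng = np.random.default_rng(seed)
    frames = []
    for label, m, sem in zip(labels, means, sems):
        sd = sem * np.sqrt(n_per_group)
        sigma_sq = np.log1p((sd / m) ** 2)
        mu = np.log(m) - sigma_sq / 2.0
        frames.append(
            pd.DataFrame(
                {"group": label, "value": rng.lognormal(mu, np.sqrt(sigma_sq), n_per_group)}
            )
        )
    return pd.concat(frames, ignore_index=True)


#: Mismatch-response summary statistics (delta-F/F %, mean and s.e.m.) used
#: as reference-distribution defaults: pPE fixed/variable, nPE fixed/variable.
REFERENCE_GROUPS = {
    ("pPE", "fixed"): (3.0, 0.3),
    ("pPE", "variable"): (5.9, 1.1),
    ("nPE", "fixed"): (8.4, 2.3),
    ("nPE", "variable"): (2.7, 0.2),
}


def default_reference_distributions(n_per_group: int = 40, seed: int | None = None) -> dict:
    """Reference samples keyed by (cell_type, condition) for model selection."""
    keys = list(REFERENCE_GROUPS)
    means = [REFERENCE_GROUPS[k][0] for k in keys]
    sems = [REFERENCE_GROUPS[k][1] for k in keys]
    df = generate_reference_distributions(
        means, sems, n_per_group=n_per_group, seed=seed, labels=[str(k) for k in keys]
    )
    return {
        key: df.loc[df["group"] == str(key), "value"].to_numpy() for key in keys
    }
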