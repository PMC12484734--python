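"""Run configuration, deterministic pipeline driver, and figures.

``run_pipeline`` chains simulate -> process -> classify -> stats ->
models -> select, writing every artifact into a run directory together
with a manifest of content hashes; identical configs produce identical
manifests.  Figures follow the boxplot convention used throughout the
analysis: median line, 25th/75th percentile box, whiskers to the extreme
points within 1.5 standard deviations of the mean, outliers crossed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import (
    circuit_models,
    model_selection,
    population_stats,
    responsiveness,
    signal_processing,
    synthetic_data,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
STAGES = ("simulate", "process", "classify", "stats", "models", "select")


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with one seed per stochastic stage."""

    out_dir: str = "run"
    schema_version: int = SCHEMA_VERSION
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    seeds: dict = field(
        default_factory=lambda: {"simulate": 1, "classify": 2, "stats": 3, "models": 4, "select": 5}
    )
    simulate: dict = field(
        default_factory=lambda: {
            "design": "fixed_vs_variable",
            "n_neurons": 120,
            "n_pairing_trials": 160,
            "n_interleaved_trials": 200,
            "noise_sd": 0.02,
            "mismatch_prevalence": 0.10,
            "amplitude": 0.10,
        }
    )
    process: dict = field(default_factory=lambda: {"window": "early"})
    classify: dict = field(default_factory=lambda: {"alpha": 0.05, "n_shuffles": 1000})
    models: dict = field(
        default_factory=lambda: {"n_circuits": 50, "npe_modulation": "sigma_s"}
    )
    select: dict = field(
        default_factory=lambda: {"alpha": 0.05, "n_reference": 40, "align": "none"}
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        base = cls()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                default = getattr(base, f.name)
                if isinstance(default, dict):
                    merged = dict(default)
                    merged.update(d[f.name])
                    kwargs[f.name] = merged
                else:
                    kwargs[f.name] = d[f.name]
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as f:
            return cls.from_dict(tomllib.load(f))

    def to_toml(self, path) -> None:
        Path(path).write_text(toml_dumps(self.to_dict()))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def toml_dumps(d: dict, prefix: str = "") -> str:
    """Minimal TOML writer for nested dicts of scalars and lists."""
    lines, tables = [], []
    for k, v in d.items():
        if isinstance(v, dict):
            tables.append((k, v))
        else:
            lines.append(f"{k} = {_toml_value(v)}")
    out = "\n".join(lines)
    for k, v in tables:
        name = f"{prefix}{k}"
        out += f"\n\n[{name}]\n" + toml_dumps(v, prefix=f"{name}.")
    return out.strip() + "\n"


def _hash_h5(path: Path) -> str:
    """Content hash of an HDF5 file (datasets + attrs, not raw bytes,
    which carry library/version metadata)."""
    h = hashlib.sha256()
    with h5py.File(path, "r") as f:
        def visit(name, obj):
            h.update(name.encode())
            for k in sorted(obj.attrs):
                h.update(k.encode())
                h.update(np.asarray(obj.attrs[k]).tobytes())
            if isinstance(obj, h5py.Dataset):
                h.update(np.ascontiguousarray(obj[()]).tobytes())
        f.visititems(visit)
    return h.hexdigest()


def hash_artifact(path) -> str:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _hash_h5(path)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(run_dir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (run_dir / name).exists():
            raise StageError(stage, "missing_artifact", f"required artifact {name!r} not found")


WINDOWS = {"early": signal_processing.EARLY_WINDOW, "late": signal_processing.LATE_WINDOW}


def run_pipeline(config: RunConfig, out_dir=None) -> Path:
    """Execute the enabled stages and write artifacts + manifest.json."""
    run_dir = Path(out_dir if out_dir is not None else config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_toml(run_dir / "config.toml")

    if config.stages.get("simulate", True):
        sim = config.simulate
        configs = synthetic_data.default_session_configs(
            design=sim["design"],
            n_pairing_trials=sim["n_pairing_trials"],
            n_interleaved_trials=sim["n_interleaved_trials"],
        )
        exp = synthetic_data.generate_experiment(
            configs,
            n_neurons=sim["n_neurons"],
            noise_sd=sim["noise_sd"],
            mismatch_prevalence=sim["mismatch_prevalence"],
            amplitude=sim["amplitude"],
            seed=config.seeds["simulate"],
        )
        for kind, (traces, trials) in exp.sessions.items():
            traces.save(run_dir / f"traces_{kind}.h5")
            trials.to_csv(run_dir / f"trials_{kind}.csv", index=False)
        exp.ground_truth.to_csv(run_dir / "ground_truth.csv", index=False)

    window = WINDOWS[config.process.get("window", "early")]
    session_kinds = ("pairing", "interleaved1", "interleaved2")

    if config.stages.get("process", True):
        _require(run_dir, "process", *(f"traces_{k}.h5" for k in session_kinds))
        for kind in session_kinds:
            raw = synthetic_data.TraceSet.load(run_dir / f"traces_{kind}.h5")
            trials = pd.read_csv(run_dir / f"trials_{kind}.csv")
            dff = signal_processing.compute_dff(raw, trials)
            dff.save(run_dir / f"dff_{kind}.h5")
            rm = signal_processing.trial_response(dff, trials, window)
            rm.to_frame().to_csv(run_dir / f"responses_{kind}.csv", index=False)

    if config.stages.get("classify", True):
        _require(run_dir, "classify", *(f"dff_{k}.h5" for k in session_kinds))
        dff_by = {k: synthetic_data.TraceSet.load(run_dir / f"dff_{k}.h5") for k in session_kinds}
        trials_by = {k: pd.read_csv(run_dir / f"trials_{k}.csv") for k in session_kinds}
        labels = responsiveness.session_classification(
            dff_by,
            trials_by,
            window=window,
            alpha=config.classify["alpha"],
            n_shuffles=config.classify["n_shuffles"],
            seed=config.seeds["classify"],
        )
        labels.to_csv(run_dir / "labels.csv", index=False)

    if config.stages.get("stats", True):
        _require(run_dir, "stats", "labels.csv", "responses_interleaved1.csv")
        labels = pd.read_csv(run_dir / "labels.csv")
        report = {"design": config.simulate["design"], "groups": {}}
        responses = {}
        for kind in ("interleaved1", "interleaved2"):
            ids = responsiveness.mismatch_responsive_ids(labels, kind)
            resp = pd.read_csv(run_dir / f"responses_{kind}.csv")
            trials = pd.read_csv(run_dir / f"trials_{kind}.csv")
            mm_trials = set(trials.loc[trials["is_mismatch"], "trial_id"])
            sel = resp[resp["neuron_id"].isin(ids) & resp["trial_id"].isin(mm_trials)]
            responses[kind] = sel.groupby("neuron_id")["response"].mean()
            report["groups"][kind] = {
                "n_neurons": int(len(responses[kind])),
                "mean": float(responses[kind].mean()) if len(responses[kind]) else None,
                "sem": population_stats._sem(responses[kind].to_numpy()),
            }
        overlap = set(responses["interleaved1"].index) & set(responses["interleaved2"].index)
        try:
            cmp = population_stats.compare_mismatch_groups(
                responses["interleaved1"], responses["interleaved2"], overlap
            )
            report["comparison"] = cmp.to_dict()
        except ValueError as e:
            report["comparison"] = {"skipped": str(e)}
        _write_json(run_dir / "report.json", report)

    if config.stages.get("models", True):
        sims = [
            circuit_models.simulate_population(
                m,
                n_circuits=config.models["n_circuits"],
                seed=config.seeds["models"] + i,
                npe_modulation=config.models["npe_modulation"],
            )
            for i, m in enumerate(circuit_models.MODEL_IDS)
        ]
        pd.concat(sims, ignore_index=True).to_csv(run_dir / "sims.csv", index=False)

    if config.stages.get("select", True):
        _require(run_dir, "select", "sims.csv")
        sims = pd.read_csv(run_dir / "sims.csv")
        reference = synthetic_data.default_reference_distributions(
            n_per_group=config.select["n_reference"], seed=config.seeds["select"]
        )
        simulations = {m: g for m, g in sims.groupby("model")}
        fit = model_selection.rank_models(
            simulations,
            reference,
            alpha=config.select["alpha"],
            align=config.select.get("align", "none"),
        )
        _write_json(run_dir / "fit_report.json", fit.to_dict())

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "artifacts": {
            p.name: hash_artifact(p)
            for p in sorted(run_dir.iterdir())
            if p.is_file() and p.name != "manifest.json" and p.suffix != ".png"
        },
    }
    _write_json(run_dir / "manifest.json", manifest)
    return run_dir


def _write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def sd_boxplot_stats(values, label="") -> dict:
    """Boxplot stats with whiskers at the extreme points within 1.5 s.d.

    Matplotlib's default whiskers use the IQR; this analysis instead
    extends whiskers to the largest/smallest observations within 1.5
    standard deviations of the mean, marking points beyond as fliers.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty group")
    mean, sd = x.mean(), x.std(ddof=1) if x.size > 1 else 0.0
    lo, hi = mean - 1.5 * sd, mean + 1.5 * sd
    inside = x[(x >= lo) & (x <= hi)]
    if inside.size == 0:
        inside = x
    return {
        "label": label,
        "med": float(np.median(x)),
        "q1": float(np.percentile(x, 25)),
        "q3": float(np.percentile(x, 75)),
        "whislo": float(inside.min()),
        "whishi": float(inside.max()),
        "fliers": x[(x < lo) | (x > hi)],
        "mean": float(mean),
    }


def make_figures(run_dir) -> list[Path]:
    """Render summary figures from a completed run directory."""
    run_dir = Path(run_dir)
    missing = [n for n in ("sims.csv", "labels.csv") if not (run_dir / n).exists()]
    if missing:
        raise StageError("figures", "missing_artifact", f"missing: {missing}")
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    out = []

    # mismatch-response boxplots per interleaved session
    labels = pd.read_csv(run_dir / "labels.csv")
    groups = []
    for kind in ("interleaved1", "interleaved2"):
        ids = responsiveness.mismatch_responsive_ids(labels, kind)
        resp = pd.read_csv(run_dir / f"responses_{kind}.csv")
        trials = pd.read_csv(run_dir / f"trials_{kind}.csv")
        mm = set(trials.loc[trials["is_mismatch"], "trial_id"])
        vals = (
            resp[resp["neuron_id"].isin(ids) & resp["trial_id"].isin(mm)]
            .groupby("neuron_id")["response"]
            .mean()
            .to_numpy()
        )
        if vals.size:
            groups.append(sd_boxplot_stats(100 * vals, label=kind))
    if groups:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.bxp(groups, showfliers=True, flierprops={"marker": "x"})
        ax.set_ylabel("mismatch response (dF/F %)")
        path = fig_dir / "mismatch_boxplot.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        out.append(path)

    # 4-model grid of simulated activities
    sims = pd.read_csv(run_dir / "sims.csv")
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.5), sharey=False)
    for ax, model in zip(axes, circuit_models.MODEL_IDS):
        sub = sims[sims["model"] == model]
        stats_list = []
        for ct in ("pPE", "nPE"):
            for cond in ("fixed", "variable"):
                vals = sub[(sub["cell_type"] == ct) & (sub["condition"] == cond)]["activity"]
                if len(vals):
                    stats_list.append(sd_boxplot_stats(vals, label=f"{ct}\n{cond}"))
        if stats_list:
            ax.bxp(stats_list, showfliers=True, flierprops={"marker": "x"})
        ax.set_title(circuit_models.MODEL_NAMES[model])
    fig.tight_layout()
    path = fig_dir / "model_grid.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    out.append(path)
    return out
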