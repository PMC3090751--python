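"""Batch pipeline: declarative study configs, staged execution, logging.

A study config is a plain YAML mapping (no embedded code) describing an
ordered list of stages with full parameter sets.  Running it executes
the stages in order, appends every parameter, input hash and decision
to a log file, and halts on the first failure naming the stage and
cause.  Identical configs and inputs give identical numeric outputs;
``resume`` skips stages whose outputs already exist.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io_core, preprocessing, scads, synth
from .containers import EpochSet
from .forward import build_source_model, eeg_leadfield, meg_leadfield
from .inverse import apply_inverse, build_inverse
from .stats import pointwise_ttest

__all__ = ["StudyConfig", "ValidationError", "run_pipeline", "warn_unusual"]

KNOWN_STAGES = ("simulate", "preprocess", "artifacts", "average", "source", "stats", "tf")
_TOP_KEYS = {"stages", "output_root", "master_seed", "files"}


class ValidationError(ValueError):
    """Config rejected before any stage ran."""


@dataclass
class StudyConfig:
    stages: list[dict]
    output_root: str
    master_seed: int = 0
    files: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        if "stages" not in raw or not raw["stages"]:
            raise ValidationError("config must list at least one stage")
        if "output_root" not in raw:
            raise ValidationError("config must name an output_root")
        stages = []
        for i, st in enumerate(raw["stages"]):
            if "stage" not in st:
                raise ValidationError(f"stage {i} lacks a 'stage' name")
            if st["stage"] not in KNOWN_STAGES:
                raise ValidationError(
                    f"unknown stage {st['stage']!r}; known: {KNOWN_STAGES}"
                )
            stages.append(dict(st))
        cfg = cls(
            stages=stages,
            output_root=str(raw["output_root"]),
            master_seed=int(raw.get("master_seed", 0)),
            files=list(raw.get("files", [])),
        )
        first = cfg.stages[0]["stage"]
        if first != "simulate" and not cfg.files:
            raise ValidationError(
                "config lists no input files and does not start by simulating"
            )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def warn_unusual(config: StudyConfig) -> list[str]:
    """Rule-based lints for unusual parameter combinations."""
    warnings: list[str] = []
    stage_names = [s["stage"] for s in config.stages]
    if "stats" in stage_names:
        after = stage_names[stage_names.index("stats") + 1 :]
        for st in config.stages[len(stage_names) - len(after) :]:
            if st["stage"] == "preprocess" and "baseline" in st:
                warnings.append(
                    "rule baseline-on-statistics: baseline correction after a "
                    "statistics stage operates on statistical values"
                )
    for st in config.stages:
        if st["stage"] == "preprocess":
            for f in st.get("filters", []):
                if f.get("kind") == "highpass" and f.get("cutoff_hz", 0) > 1.0:
                    warnings.append(
                        f"rule highpass-cutoff: high-pass at {f['cutoff_hz']} Hz "
                        "removes most ERP energy"
                    )
        if st["stage"] == "source" and st.get("lam", 0.05) == 0:
            warnings.append(
                "rule lambda-zero: unregularized inverse of a rank-deficient "
                "lead field is unstable"
            )
    if "average" in stage_names and "artifacts" not in stage_names:
        warnings.append(
            "rule average-without-artifacts: averaging without artifact "
            "detection lets contaminated trials through"
        )
    return warnings


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


class _Log:
    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)
        self.fh = path.open("a")

    def write(self, record: dict) -> None:
        record = dict(record)
        record["time"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.fh.write(json.dumps(record, default=str) + "\n")
        self.fh.flush()


def run_pipeline(config: StudyConfig, resume: bool = False, log_path=None) -> dict:
    """Execute all stages; returns a context dict of in-memory results."""
    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    log = _Log(Path(log_path) if log_path else root / "analysis.log")
    for w in warn_unusual(config):
        log.write({"warning": w})
    ctx: dict = {"seed": config.master_seed}

    if config.files:
        for f in config.files:
            p = Path(f)
            if not p.exists():
                raise ValidationError(f"input file {f} does not exist")
            log.write({"input": str(f), "sha256": _hash_file(p)})

    for i, st in enumerate(config.stages):
        name = st["stage"]
        params = {k: v for k, v in st.items() if k != "stage"}
        marker = root / f"stage_{i:02d}_{name}.done"
        if resume and marker.exists():
            log.write({"stage": name, "skipped": "resume, outputs present"})
            # re-load what downstream stages need
            _STAGES[name](ctx, params, config, root, log, load_only=True)
            continue
        log.write({"stage": name, "params": params})
        try:
            _STAGES[name](ctx, params, config, root, log, load_only=False)
        except Exception as exc:
            log.write({"stage": name, "error": str(exc)})
            raise RuntimeError(
                f"pipeline halted at stage {i} ({name}): {exc}"
            ) from exc
        marker.write_text("ok\n")
    return ctx


# ---------------------------------------------------------------------------
# Stage implementations


def _stage_simulate(ctx, params, config, root, log, load_only):
    out = root / "epochs"
    if load_only:
        ctx["epochs"] = io_core.read_epoch_container(out)
        return
    sources = tuple(
        synth.SimSource(**s) if isinstance(s, dict) else s
        for s in params.get("sources", [])
    )
    noise = params.get("noise", {})
    noise = synth.NoiseSpec(**noise) if isinstance(noise, dict) else noise
    cfg = synth.SimConfig(
        layout_kind=params.get("layout_kind", "sphere_eeg"),
        n_sensors=params.get("n_sensors", 32),
        sources=sources,
        noise=noise,
        n_trials=params.get("n_trials", 20),
        fs=params.get("fs", 250.0),
        t_pre_s=params.get("t_pre_s", -0.2),
        t_post_s=params.get("t_post_s", 0.6),
        seed=params.get("seed", config.master_seed),
        condition_code=params.get("condition_code", 1),
    )
    epochs, truth = synth.simulate(cfg)
    if "condition_codes" in params:
        codes = params["condition_codes"]
        epochs.conditions.code[:] = [
            codes[t % len(codes)] for t in range(epochs.n_trials)
        ]
    io_core.write_epoch_container(epochs, out)
    ctx["epochs"] = epochs
    ctx["truth"] = truth
    log.write({"simulated": {"n_trials": epochs.n_trials,
                             "n_sensors": epochs.n_channels, "seed": cfg.seed}})


def _stage_preprocess(ctx, params, config, root, log, load_only):
    out = root / "epochs_preprocessed"
    if load_only:
        ctx["epochs"] = io_core.read_epoch_container(out)
        return
    if "epochs" not in ctx:
        # file-based entry: read, filter, epoch
        recs = []
        layout = (
            io_core.read_layout_text(params["layout"]) if "layout" in params else None
        )
        all_epochs = []
        for f in config.files:
            rec = io_core.read_continuous(f, layout=layout)
            for fparams in params.get("filters", []):
                spec = preprocessing.FilterSpec(
                    family=fparams.get("family", "butterworth"),
                    kind=fparams["kind"],
                    cutoffs_hz=fparams.get("cutoff_hz") or tuple(fparams["band_hz"]),
                    order=fparams.get("order", 4),
                )
                rec = preprocessing.filter_continuous(rec, spec)
            triggers = io_core.extract_trigger_events(rec)
            all_epochs.append(
                preprocessing.extract_epochs(
                    rec,
                    triggers,
                    params["codes"],
                    params.get("t_pre_s", -0.1),
                    params.get("t_post_s", 0.5),
                )
            )
        epochs = all_epochs[0]
        ctx["epochs"] = epochs
    else:
        if params.get("filters"):
            raise RuntimeError(
                "filtering applies to continuous data; these inputs are epoched"
            )
        epochs = ctx["epochs"]
    if "baseline" in params:
        epochs = preprocessing.baseline_correct(epochs, tuple(params["baseline"]))
    if params.get("eog_channels"):
        epochs, coef = preprocessing.gratton_eog_correct(
            epochs, params["eog_channels"]
        )
        log.write({"eog_coefficients": coef.propagation.tolist()})
    ctx["epochs"] = epochs
    io_core.write_epoch_container(epochs, out)


def _stage_artifacts(ctx, params, config, root, log, load_only):
    epochs: EpochSet = ctx["epochs"]
    k = params.get("k", 3.0)
    mode = params.get("mode", "average-ref")
    flags, thresholds = scads.two_pass_detect(epochs, k=k, mode=mode)
    flags = scads.apply_feasibility(flags, epochs.layout, thresholds)
    ctx["flags"] = flags
    ctx["thresholds"] = thresholds
    if load_only:
        return
    scads.write_thresholds(thresholds, root / "thresholds.txt", epochs.layout.names)
    counts = scads.scenario_counts(flags)
    log.write({"artifact_scenarios": counts, "k": k, "mode": mode})
    report = [f"trial scenarios: {counts}"]
    for t in range(epochs.n_trials):
        status = (
            "rejected"
            if flags.trial_rejected[t]
            else ("repaired" if flags.sensor_bad[t].any() else "clean")
        )
        report.append(
            f"trial {t}: {status} bad_sensors={int(flags.sensor_bad[t].sum())} "
            f"reasons={flags.reasons.get(t, [])}"
        )
    (root / "qc_report.txt").write_text("\n".join(report) + "\n")


def _stage_average(ctx, params, config, root, log, load_only):
    epochs: EpochSet = ctx["epochs"]
    flags = ctx.get("flags")
    if flags is None:
        flags = scads.ArtifactFlags(
            sensor_bad=np.zeros((epochs.n_trials, epochs.n_channels), bool),
            trial_rejected=np.zeros(epochs.n_trials, bool),
        )
    stats = scads.compute_trial_stats(epochs)
    averages, repaired = scads.repair_and_average(
        epochs, flags, stats=stats, return_repaired=True
    )
    ctx["averages"] = averages
    ctx["repaired"] = repaired
    if load_only:
        return
    for avg in averages:
        np.save(root / f"average_c{avg.condition_code}.npy", avg.data)
        log.write(
            {
                "average": {
                    "condition": avg.condition_code,
                    "n_trials_used": avg.n_trials_used,
                    "interpolated_sensors": int(
                        (avg.interpolation_counts > 0).sum()
                    ),
                }
            }
        )


def _stage_source(ctx, params, config, root, log, load_only):
    averages = ctx["averages"]
    layout = averages[0].layout
    lam = params.get("lam", 0.05)
    shell = params.get("shell_cm", 8.0)
    n_per_shell = params.get("n_per_shell", 655)
    model = build_source_model(
        n_per_shell=n_per_shell,
        modality=layout.modality,
        active_shells=(shell,),
        radii_cm=(2.0, 4.0, 6.0, shell),
    )
    lf = (
        eeg_leadfield(layout, model)
        if layout.modality == "eeg"
        else meg_leadfield(layout, model)
    )
    W = build_inverse(lf, lam)
    ctx["source_model"] = model
    estimates = {}
    for avg in averages:
        est = apply_inverse(W, avg.data)
        estimates[avg.condition_code] = est
        if not load_only:
            np.save(root / f"source_power_c{avg.condition_code}.npy", est.power)
    ctx["source_estimates"] = estimates
    log.write({"source": {"lam": lam, "shell_cm": shell,
                          "n_locations": model.n_locations}})


def _stage_stats(ctx, params, config, root, log, load_only):
    epochs: EpochSet = ctx.get("repaired", ctx["epochs"])
    flags = ctx.get("flags")
    keep = (
        ~flags.trial_rejected if flags is not None
        else np.ones(epochs.n_trials, bool)
    )
    codes = np.unique(epochs.conditions.code)
    if len(codes) < 2:
        raise RuntimeError("stats stage needs at least two condition codes")
    a = epochs.data[(epochs.conditions.code == codes[0]) & keep]
    b = epochs.data[(epochs.conditions.code == codes[1]) & keep]
    result = pointwise_ttest(a, b, paired=False)
    ctx["statmap"] = result
    if load_only:
        return
    np.save(root / "stats_t.npy", result.stat)
    np.save(root / "stats_p.npy", result.p)
    log.write(
        {
            "stats": {
                "effect": result.effect,
                "df": result.df,
                "n_a": int(a.shape[0]),
                "n_b": int(b.shape[0]),
                "alpha": params.get("alpha", 0.05),
            }
        }
    )


def _stage_tf(ctx, params, config, root, log, load_only):
    from .timefreq import WaveletSpec, tf_power

    epochs: EpochSet = ctx.get("repaired", ctx["epochs"])
    spec = WaveletSpec.linspace(
        params.get("fmin", 4.0),
        params.get("fmax", 40.0),
        params.get("n_freqs", 10),
        fs=epochs.fs,
        width=params.get("width", 7.0),
    )
    result = tf_power(epochs, spec, kind=params.get("kind", "total"))
    ctx["tf"] = result
    if load_only:
        return
    np.save(root / "tf_power.npy", result.power)
    log.write({"tf": {"freqs": list(map(float, result.freqs)),
                      "width": params.get("width", 7.0), "kind": result.kind}})


_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "artifacts": _stage_artifacts,
    "average": _stage_average,
    "source": _stage_source,
    "stats": _stage_stats,
    "tf": _stage_tf,
}
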