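"""Run configuration, dispatch, and run reports shared by all subcommands.

A run is described by a flat, human-editable YAML document: a
``subcommand`` key naming the pipeline, a parameter block for that
pipeline, and common keys (``seed``, ``out``, ``mode``). Unknown keys are
rejected so that typos fail loudly. Defaults are the protocol's values:
15 sib-mating generations, 450 lines with 3 replicate patches each, 200
crosses per type, 220 females per transfer.

Every run writes its artifacts plus a JSON :class:`RunReport` echoing the
config (including the seed of any stochastic step) so results can be
reproduced exactly.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Any, Callable, Mapping, Optional

import yaml

from . import crossing, evolution, genedrop, inbreeding

__all__ = ["RunConfig", "RunReport", "load_config", "dispatch", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file failed parsing or validation."""


_DEFAULTS: dict[str, dict[str, Any]] = {
    "inbreeding": {
        "generations": 15,
        "initial": {"A": 1, "B": 0, "C": 0, "D": 0},
        "threshold": None,
        "statistic": "f",
    },
    "genedrop": {
        "n_lines": 200_000,
        "generations": 15,
        "n_loci": 1,
    },
    "panel": {
        "n_lines": 450,
        "replicates_per_line": 3,
        "generations": 15,
        "failure_prob": None,
        "calibrate_from_survivors": None,
    },
    "design": {
        "kind": "matched-pairs-4",
        "labels": ["A", "B", "C", "D"],
        "crosses_per_type": 200,
        "available": None,
        "census_rule": "minimum",
    },
    "evolve": {
        "history": None,
        "history_file": None,
        "target": 220,
        "replicate": "r1",
        "regime": "regime",
    },
}

_COMMON_KEYS = {"subcommand", "seed", "out", "mode"}


@dataclass(frozen=True)
class RunConfig:
    """A validated run configuration with defaults applied."""

    subcommand: str
    params: dict[str, Any]
    seed: int = 0
    out: Path = Path("haplobreed-out")
    mode: str = "exact-rational"

    def echo(self) -> dict[str, Any]:
        return {
            "subcommand": self.subcommand,
            "seed": self.seed,
            "out": str(self.out),
            "mode": self.mode,
            "params": {k: v for k, v in self.params.items()},
        }


@dataclass
class RunReport:
    """What a run did: config echo, version, timestamps, outputs, warnings."""

    config: dict[str, Any]
    version: str
    started: str
    finished: str = ""
    outputs: list[str] = field(default_factory=list)
    summaries: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "started": self.started,
                "finished": self.finished,
                "outputs": self.outputs,
                "summaries": self.summaries,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        d = json.loads(text)
        return cls(
            config=d["config"],
            version=d["version"],
            started=d["started"],
            finished=d["finished"],
            outputs=d["outputs"],
            summaries=d["summaries"],
            warnings=d["warnings"],
        )


def _version() -> str:
    try:
        return metadata.version("haplobreed")
    except metadata.PackageNotFoundError:  # running from a source tree
        return "0+unknown"


def make_config(raw: Mapping[str, Any]) -> RunConfig:
    """Validate a raw mapping and fill subcommand defaults."""
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    sub = raw.get("subcommand")
    if sub not in _DEFAULTS:
        raise ConfigError(
            f"subcommand: expected one of {sorted(_DEFAULTS)}, got {sub!r}"
        )
    params = dict(_DEFAULTS[sub])
    for key, value in raw.items():
        if key in _COMMON_KEYS:
            continue
        if key not in params:
            raise ConfigError(f"{sub}.{key}: unknown key")
        params[key] = value
    _validate_params(sub, params)
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed: must be an integer, got {seed!r}")
    mode = raw.get("mode", "exact-rational")
    if mode not in ("exact-rational", "floating"):
        raise ConfigError(f"mode: expected exact-rational or floating, got {mode!r}")
    return RunConfig(
        subcommand=sub,
        params=params,
        seed=seed,
        out=Path(raw.get("out", "haplobreed-out")),
        mode=mode,
    )


def _require_positive_int(sub: str, params: Mapping[str, Any], *keys: str) -> None:
    for key in keys:
        v = params[key]
        if not isinstance(v, int) or v < 1:
            raise ConfigError(f"{sub}.{key}: must be a positive integer, got {v!r}")


def _validate_params(sub: str, params: dict[str, Any]) -> None:
    if sub == "inbreeding":
        _require_positive_int(sub, params, "generations")
        initial = params["initial"]
        if not isinstance(initial, Mapping) or set(initial) - set("ABCD"):
            raise ConfigError(f"{sub}.initial: expected a mapping with keys A-D, got {initial!r}")
    elif sub == "genedrop":
        _require_positive_int(sub, params, "n_lines", "generations", "n_loci")
    elif sub == "panel":
        _require_positive_int(sub, params, "n_lines", "replicates_per_line", "generations")
        fp, calib = params["failure_prob"], params["calibrate_from_survivors"]
        if fp is None and calib is None:
            raise ConfigError(f"{sub}: give failure_prob or calibrate_from_survivors")
        if fp is not None and not (0 <= fp <= 1):
            raise ConfigError(f"{sub}.failure_prob: must be in [0, 1], got {fp!r}")
    elif sub == "design":
        if params["kind"] not in ("matched-pairs-4", "round-robin-3"):
            raise ConfigError(f"{sub}.kind: unsupported design {params['kind']!r}")
        _require_positive_int(sub, params, "crosses_per_type")
    elif sub == "evolve":
        _require_positive_int(sub, params, "target")
        if params["history"] is None and params["history_file"] is None:
            raise ConfigError(f"{sub}: give history (inline) or history_file")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if raw is None:
        raise ConfigError(f"{path}: empty config")
    return make_config(raw)


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------


def _run_inbreeding(config: RunConfig, out: Path, report: RunReport) -> None:
    p = config.params
    initial = {k: p["initial"].get(k, 0) for k in "ABCD"}
    dist = inbreeding.CrossTypeDistribution(
        0,
        *(inbreeding._coerce(initial[k], config.mode) for k in "ABCD"),
    )
    traj = inbreeding.iterate_trajectory(dist, p["generations"], mode=config.mode)
    tsv = out / "inbreeding_trajectory.tsv"
    traj.write_tsv(tsv)
    report.outputs.append(str(tsv))
    last = traj.points[-1]
    report.summaries["inbreeding"] = {
        "generations": p["generations"],
        "f_final": float(last.f),
        "f_final_percent": round(100 * float(last.f), 1),
        "p_fully_inbred_final": float(last.p_fully_inbred),
        "p_fully_inbred_final_percent": round(100 * float(last.p_fully_inbred), 1),
    }
    if p["threshold"] is not None:
        gens = inbreeding.generations_to_threshold(
            inbreeding._coerce(p["threshold"], config.mode), p["statistic"], dist, config.mode
        )
        report.summaries["inbreeding"]["generations_to_threshold"] = gens
    js = out / "inbreeding_trajectory.json"
    js.write_text(json.dumps(traj.to_report(), indent=2))
    report.outputs.append(str(js))


def _run_genedrop(config: RunConfig, out: Path, report: RunReport) -> None:
    p = config.params
    gd = genedrop.GeneDropConfig(
        n_lines=p["n_lines"],
        generations=p["generations"],
        n_loci=p["n_loci"],
        seed=config.seed,
    )
    df = genedrop.estimate_inbreeding_mc(gd)
    tsv = out / "genedrop_estimates.tsv"
    df.to_csv(tsv, sep="\t", index=False)
    report.outputs.append(str(tsv))
    last = df.iloc[-1]
    report.summaries["genedrop"] = {
        "seed": config.seed,
        "n_lines": p["n_lines"],
        "f_hat_final": float(last["f_hat"]),
        "f_se_final": float(last["f_se"]),
        "p_fully_inbred_hat_final": float(last["p_fully_inbred_hat"]),
    }


def _run_panel(config: RunConfig, out: Path, report: RunReport) -> None:
    p = config.params
    failure_prob = p["failure_prob"]
    if failure_prob is None:
        failure_prob = genedrop.calibrate_failure_prob(
            p["n_lines"], p["calibrate_from_survivors"], p["generations"],
            p["replicates_per_line"],
        )
        report.summaries["calibrated_failure_prob"] = failure_prob
    panel = genedrop.simulate_line_panel(
        genedrop.LinePanelConfig(
            n_lines=p["n_lines"],
            replicates_per_line=p["replicates_per_line"],
            generations=p["generations"],
            failure_prob=failure_prob,
            seed=config.seed,
        )
    )
    tsv = out / "panel_trajectory.tsv"
    panel.write_tsv(tsv)
    report.outputs.append(str(tsv))
    js = out / "panel_summary.json"
    js.write_text(json.dumps(panel.to_report(), indent=2))
    report.outputs.append(str(js))
    report.summaries["panel"] = {"surviving_lines_final": panel.survivors}


def _run_design(config: RunConfig, out: Path, report: RunReport) -> None:
    p = config.params
    design = crossing.CrossingDesign.from_labels(
        p["kind"], p["labels"], p["crosses_per_type"]
    )
    combos = crossing.enumerate_combinations(design)
    schedule = crossing.build_schedule(design)
    combo_tsv = out / "combinations.tsv"
    mito, balanced = crossing.mito_representation(combos)
    import pandas as pd

    pd.DataFrame(
        {"combination": [c.name for c in combos], "mito_origin": [c.mito_origin for c in combos]}
    ).to_csv(combo_tsv, sep="\t", index=False)
    report.outputs.append(str(combo_tsv))
    sched_tsv = out / "schedule.tsv"
    schedule.write_tsv(sched_tsv)
    report.outputs.append(str(sched_tsv))
    js = out / "design.json"
    design_report: dict[str, Any] = {
        "schedule": schedule.to_report(),
        "combinations": [c.name for c in combos],
        "mito_representation": mito,
        "mito_balanced": balanced,
    }
    if p["available"] is not None:
        census = crossing.founding_census(p["available"], p["census_rule"])
        design_report["census"] = census.to_report()
        report.summaries["census_total"] = census.total
    js.write_text(json.dumps(design_report, indent=2))
    report.outputs.append(str(js))
    report.summaries["n_combinations"] = len(combos)


def _run_evolve(config: RunConfig, out: Path, report: RunReport) -> None:
    p = config.params
    if p["history"] is not None:
        pairs = [(int(a), int(b)) for a, b in p["history"]]
    else:
        import pandas as pd

        df = pd.read_csv(p["history_file"], sep="\t")
        pairs = list(zip(df["available_current"].astype(int), df["available_backup"].astype(int)))
    history = evolution.track_regime(
        pairs, target=p["target"], replicate=p["replicate"], regime=p["regime"]
    )
    tsv = out / "effective_generations.tsv"
    history.write_tsv(tsv)
    report.outputs.append(str(tsv))
    report.summaries["evolve"] = {
        "chronological_generations": len(history.records),
        "effective_generations_final": history.final_effective,
    }


_PIPELINES: dict[str, Callable[[RunConfig, Path, RunReport], None]] = {
    "inbreeding": _run_inbreeding,
    "genedrop": _run_genedrop,
    "panel": _run_panel,
    "design": _run_design,
    "evolve": _run_evolve,
}


def dispatch(config: RunConfig) -> RunReport:
    """Run the pipeline a config names and write its artifacts and report."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config=config.echo(),
        version=_version(),
        started=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )
    _PIPELINES[config.subcommand](config, out, report)
    report.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
    report_path = out / "run_report.json"
    report.outputs.append(str(report_path))
    report_path.write_text(report.to_json())
    return report
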