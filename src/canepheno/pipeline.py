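"""End-to-end orchestration: simulate or load a trial, run the requested
analysis stages in dependency order, and write CSV outputs plus a combined
Markdown report and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, correlation, diversity, regression, selection
from .heritability import heritability_table
from .io import genotype_means, read_phenotypes, write_phenotypes
from .reference import CHECK_PARENT
from .simulate import TrialDesign, default_config, simulate_trial

#: Stages in dependency order.
STAGES = (
    "simulate", "evaluate", "heritability", "correlate",
    "cluster", "pca-select", "fit-model", "estimate", "report",
)

#: What each stage needs before it can run.
_PREREQUISITES = {
    "evaluate": "table", "heritability": "table", "correlate": "table",
    "cluster": "table", "pca-select": "table", "fit-model": "table",
    "estimate": "table", "report": "table",
}


@dataclass
class PipelineConfig:
    """Configuration of an end-to-end run."""

    out_dir: Path
    input_path: Path | None = None  # None -> simulate
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    k: int = 3
    check_id: str = CHECK_PARENT
    candidates: tuple[str, ...] = ("SN", "SD", "IL", "SH", "B")
    response: str = "SY"
    design: TrialDesign = field(default_factory=TrialDesign)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}; valid stages: {list(STAGES)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the requested stages and return a name -> output-file map.

    All randomness flows from ``config.seed``.  The same configuration and
    seed produce byte-identical numeric outputs, and any stage run standalone
    from a previously written phenotype CSV matches the chained run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in config.stages]
    artifacts: dict[str, Path] = {}

    if "simulate" in stages:
        table = simulate_trial(default_config(), config.design, seed=config.seed)
        artifacts["phenotypes"] = out / "phenotypes.csv"
        write_phenotypes(table, artifacts["phenotypes"])
    elif config.input_path is not None:
        table = read_phenotypes(config.input_path)
    else:
        needing = [s for s in stages if _PREREQUISITES.get(s) == "table"]
        if needing:
            raise ValueError(
                f"stage(s) {needing} need a phenotype table: run the 'simulate' stage "
                "or provide input_path"
            )
        table = None

    means = genotype_means(table) if table is not None else None
    summary = None

    if "evaluate" in stages:
        summary = diversity.summarize_table(table)
        artifacts["summary"] = out / "summary.csv"
        summary.to_csv(artifacts["summary"], index=False, float_format="%.6g")

    if "heritability" in stages:
        varcomp = heritability_table(table)
        artifacts["varcomp"] = out / "varcomp.csv"
        varcomp.to_csv(artifacts["varcomp"], index=False, float_format="%.6g")

    if "correlate" in stages:
        corr = correlation.correlate(means)
        artifacts["corr"] = out / "corr.csv"
        corr.long_format().to_csv(artifacts["corr"], index=False, float_format="%.6g")

    if "cluster" in stages:
        membership = diversity.membership_standardize(means)
        clusters = correlation.ward_cluster(membership, k=config.k)
        groups = clusters.labels.rename("group").to_frame()
        artifacts["groups"] = out / "groups.csv"
        groups.to_csv(artifacts["groups"])
        profile = correlation.group_profile(clusters.labels, means)
        artifacts["group_profile"] = out / "group_profile.csv"
        profile.to_csv(artifacts["group_profile"], float_format="%.6g")

    if "pca-select" in stages:
        scored = selection.pca_select(means, check_id=config.check_id)
        artifacts["selection"] = out / "selection.csv"
        scored.table.to_csv(artifacts["selection"], float_format="%.6g")

    model = None
    if "fit-model" in stages:
        model = regression.stepwise_select(
            means[config.response], means[list(config.candidates)]
        )
        artifacts["model"] = out / "model.json"
        payload = {
            "response": model.response,
            "terms": model.summary_frame().round(10).to_dict(orient="index"),
            "dropped": list(model.dropped),
            "r2": model.r2,
            "r2_adj": model.r2_adj,
            "aic": model.aic,
            "nobs": model.nobs,
            "selection_trace": model.selection_trace,
        }
        artifacts["model"].write_text(json.dumps(payload, indent=2, allow_nan=True))

    if "estimate" in stages:
        est = regression.published_equation(means["SN"], means["SD"], means["B"], means["SH"])
        frame = pd.DataFrame({"SY_estimated": est, "SY_measured": means["SY"]})
        artifacts["estimates"] = out / "estimates.csv"
        frame.to_csv(artifacts["estimates"], float_format="%.6g")

    if "report" in stages:
        artifacts["report"] = out / "report.md"
        artifacts["report"].write_text(_render_report(config, table, summary, artifacts))

    manifest = {
        "canepheno": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stages": stages,
        "inputs": (
            {str(config.input_path): _sha256(Path(config.input_path))}
            if config.input_path
            else {}
        ),
        "outputs": {name: _sha256(path) for name, path in artifacts.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = manifest_path
    return artifacts


def _render_report(
    config: PipelineConfig,
    table: pd.DataFrame | None,
    summary: pd.DataFrame | None,
    artifacts: dict[str, Path],
) -> str:
    lines = ["# Trial evaluation report", ""]
    if table is not None:
        n_gen = table["genotype"].nunique()
        envs = sorted(table["environment"].unique())
        reps = table["replicate"].nunique()
        lines += [
            f"- genotypes: {n_gen}",
            f"- environments: {', '.join(map(str, envs))}",
            f"- replicates: {reps}",
            f"- seed: {config.seed}",
            "",
        ]
    if summary is not None:
        lines += ["## Trait summary", "", summary.round(3).to_markdown(index=False), ""]
    lines += ["## Outputs", ""]
    lines += [f"- {name}: {path.name}" for name, path in artifacts.items()]
    lines.append("")
    return "\n".join(lines)
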