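"""Stage orchestration: simulate/assemble -> edge models -> summaries -> reports.

Every stage logs its wall time and writes long-format tables keyed by
edge_id; a JSON manifest ties outputs to the exact configuration.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import cwas, summary
from .cohort import CohortDataset, load_cohort
from .config import RunConfig, file_hash, write_manifest
from .groups import fit_group_edge_anova, integration_group_anova
from .integration import (
    cortical_integration,
    fit_integration_model,
    roc_percentile_sweep,
)
from .simulate import SimulationConfig, simulate_cohort, simulate_two_group

logger = logging.getLogger(__name__)


def _stage(name, stages, fn, *args, **kwargs):
    start = time.perf_counter()
    result = fn(*args, **kwargs)
    elapsed = time.perf_counter() - start
    stages.append({"stage": name, "seconds": round(elapsed, 4)})
    logger.info("stage %-16s %7.2fs", name, elapsed)
    return result


def run_simulate(config: RunConfig) -> Path:
    """Generate a cohort per config.simulate and write it to outdir/cohort."""
    sim_kwargs = dict(config.simulate)
    planted = [tuple(e) for e in sim_kwargs.pop("planted_edges", [])]
    group_shifts = [tuple(e) for e in sim_kwargs.pop("group_shifts", [])]
    sim = SimulationConfig(
        seed=sim_kwargs.pop("seed", config.seed),
        planted_edges=tuple(planted),
        **sim_kwargs,
    )
    if config.mode == "group":
        dataset, truth = simulate_two_group(sim, group_shifts=tuple(group_shifts))
    else:
        dataset, truth = simulate_cohort(sim)
    cohort_dir = Path(config.outdir) / "cohort"
    dataset.write(cohort_dir)
    truth.to_json(cohort_dir / "truth.json")
    return cohort_dir


def run_pipeline(config: RunConfig, dataset: CohortDataset | None = None) -> dict:
    """Full analysis on an assembled cohort; returns output paths.

    Longitudinal mode: edge-wise delta model -> row-wise BH -> network
    frequency + hub scores -> integration model -> ROC sweep. Group mode:
    edge-wise group ANOVA -> row-wise BH -> integration group ANOVA.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    inputs: dict = {}

    if dataset is None:
        config.validate_paths()
        if config.cohort_dir is None:
            raise ValueError("no cohort: set cohort_dir or pass a dataset")
        cohort_dir = Path(config.cohort_dir)
        for f in sorted(cohort_dir.glob("*.tsv")):
            inputs[f.name] = file_hash(f)
        dataset = _stage("load_cohort", stages, load_cohort, cohort_dir)

    scheme = dataset.scheme
    targets = scheme.ids_by_name(config.target_rois)
    outputs: dict[str, str] = {}

    if config.mode == "group":
        result = _stage(
            "group_edge_anova",
            stages,
            fit_group_edge_anova,
            dataset,
            q=config.q,
        )
        path = outdir / "group_edge_results.tsv"
        result.to_frame().to_csv(path, sep="\t", index=False)
        outputs["group_edge_results"] = str(path)

        integ = _stage(
            "integration_anova", stages, integration_group_anova, dataset, targets
        )
        path = outdir / "integration_group.json"
        path.write_text(
            json.dumps(
                {
                    "target_rois": config.target_rois,
                    "F": float(integ.f[0]),
                    "p": float(integ.p[0]),
                    "df_num": integ.df_num,
                    "df_den": integ.df_den,
                    "direction": float(integ.direction[0]),
                },
                indent=2,
            )
        )
        outputs["integration_group"] = str(path)
    else:
        spec = cwas.delta_model_spec(standardize=config.standardize)
        results = _stage("edge_models", stages, cwas.fit_edge_models, dataset, spec)
        results = _stage("rowwise_bh", stages, cwas.rowwise_bh, results, config.q)
        path = outdir / "edge_results.tsv"
        results.to_long_frame().to_csv(path, sep="\t", index=False)
        outputs["edge_results"] = str(path)

        freq = _stage("network_frequency", stages, summary.network_frequency, results)
        path = outdir / "network_frequency.tsv"
        freq.to_tsv(path)
        outputs["network_frequency"] = str(path)

        hubs = _stage("hub_scores", stages, summary.hub_scores, results)
        path = outdir / "hub_scores.tsv"
        hubs.to_csv(path, sep="\t", index=False)
        outputs["hub_scores"] = str(path)

        profile = _stage(
            "cortical_integration", stages, cortical_integration, dataset, targets
        )
        report = _stage(
            "integration_model",
            stages,
            fit_integration_model,
            profile,
            dataset,
            config.standardize,
        )
        path = outdir / "integration_model.json"
        path.write_text(
            json.dumps(
                {"target_rois": config.target_rois, **report.to_dict()}, indent=2
            )
        )
        outputs["integration_model"] = str(path)

        # ROC of the sign-aligned integration-change score
        sign = np.sign(report.beta[report.terms.index("mean_delta")]) or 1.0
        roc = _stage(
            "roc_sweep",
            stages,
            roc_percentile_sweep,
            sign * profile.mean_delta,
            dataset.symptoms_tp2,
            tuple(config.percentiles),
        )
        path = outdir / "roc_sweep.tsv"
        roc.to_csv(path, sep="\t", index=False)
        outputs["roc_sweep"] = str(path)

    write_manifest(outdir, config, stages, inputs)
    outputs["manifest"] = str(outdir / "manifest.json")
    return outputs
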