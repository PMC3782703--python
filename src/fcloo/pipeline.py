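"""End-to-end orchestration: simulate -> classify -> evaluate.

A :class:`RunConfig` captures every knob of a run (generator conditions,
subset rules, threshold mode, significance levels, seed).  ``run_pipeline``
executes the stages, writes delimited artifact tables plus a JSON manifest
(stage parameters, input hashes, timings, per-stage counts) into a run
directory, and is deterministic for a fixed seed: score tables are
byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import loo_scores, per_connection_loo
from .cohort import CohortDataset, impute_handedness, phenotypes_to_frame, write_phenotypes
from .evaluation import (
    behavior_correlations,
    evaluate,
    per_site_accuracy,
    site_accuracy_analysis,
    threshold_scores,
)
from .preprocess import retained_volume_stats
from .simulate import GroundTruth, SimParams, simulate_cohort

logger = logging.getLogger("fcloo.pipeline")

#: p-value thresholds used for connection-subset sweeps.
DEFAULT_ALPHAS = (0.01, 0.001, 0.0001, 0.00001)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    sim: SimParams = field(default_factory=SimParams)
    subset_alphas: tuple[float, ...] = DEFAULT_ALPHAS
    include_all_connections: bool = True
    threshold_mode: str = "zero"  # "zero" | "roc"
    fdr_q: float = 0.05
    site_adjust: str = "harmonize"
    write_matrices: bool = False
    seed: int | None = None  # overrides sim.seed when set

    def resolved_sim(self) -> SimParams:
        if self.seed is None:
            return self.sim
        return dataclasses.replace(self.sim, seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim_raw = raw.pop("sim", {}) or {}
        for key in ("baseline_strength_range", "age_range", "handedness_probs"):
            if key in sim_raw and isinstance(sim_raw[key], list):
                sim_raw[key] = tuple(sim_raw[key])
        if isinstance(raw.get("subset_alphas"), list):
            raw["subset_alphas"] = tuple(raw["subset_alphas"])
        return cls(sim=SimParams(**sim_raw), **raw)


def show_defaults() -> str:
    """All default configuration values, as YAML."""
    return yaml.safe_dump(dataclasses.asdict(RunConfig()), sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run simulate -> classify -> evaluate and write artifacts.

    Returns the manifest dict.  A stage failure raises with the failing stage
    named; artifacts written up to that point are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {"stages": {}, "config": dataclasses.asdict(config)}
    try:
        # ---- simulate ---------------------------------------------------
        t0 = time.perf_counter()
        params = config.resolved_sim()
        dataset, truth = simulate_cohort(params)
        dataset = CohortDataset(
            phenotypes=impute_handedness(dataset.phenotypes),
            matrices=dataset.matrices,
            rois=dataset.rois,
            single_site_ok=dataset.single_site_ok,
        )
        write_phenotypes(dataset.phenotypes, out / "phenotypes.tsv")
        pd.DataFrame(truth.affected_pairs, columns=["roi_i", "roi_j"]).to_csv(
            out / "ground_truth_affected.tsv", sep="\t", index=False
        )
        (out / "ground_truth_meta.json").write_text(
            json.dumps(
                {
                    "n_affected": int(truth.affected.size),
                    "coefficients": truth.coefficients,
                    "severity_mean_autism": float(
                        truth.severity[truth.severity > 0].mean()
                    )
                    if (truth.severity > 0).any()
                    else 0.0,
                },
                indent=2,
            )
        )
        if config.write_matrices:
            from .cohort import write_cohort_matrices

            write_cohort_matrices(dataset, out / "matrices")
        retention = retained_volume_stats(dataset.phenotypes)
        logger.info(
            "simulate: n=%d R=%d, %.1f%% subjects retained >50%% of volumes",
            dataset.n_subjects,
            dataset.n_rois,
            100 * retention.fraction_over_half,
        )
        manifest["stages"]["simulate"] = {
            "seconds": time.perf_counter() - t0,
            "n_subjects": dataset.n_subjects,
            "n_rois": dataset.n_rois,
            "fraction_over_half_retained": retention.fraction_over_half,
            "inputs": {},
            "params": dataclasses.asdict(params),
        }

        # ---- classify ---------------------------------------------------
        t0 = time.perf_counter()
        pre = per_connection_loo(dataset, site_adjust=config.site_adjust)
        rules: list = []
        if config.include_all_connections:
            rules.append("all")
        rules.extend(("p", a) for a in config.subset_alphas)
        score_tables: dict[str, pd.DataFrame] = {}
        for rule in rules:
            results = loo_scores(dataset, subset_rule=rule, precomputed=pre)
            name = results[0].subset
            df = pd.DataFrame(
                {
                    "subject_id": [r.subject_id for r in results],
                    "score": [r.score for r in results],
                    "predicted": [r.predicted for r in results],
                    "actual": [r.actual for r in results],
                    "subset": [r.subset for r in results],
                    "flagged": [r.flagged for r in results],
                }
            )
            fname = f"scores_{name.replace('<', '_lt_')}.tsv"
            df.to_csv(out / fname, sep="\t", index=False, float_format="%.17g")
            score_tables[name] = df
            if rule != "all":
                mean_sel = float(np.mean([(pre.pvals[s] < rule[1]).sum() for s in range(pre.n_subjects)]))
                logger.info("classify %s: mean selected connections %.1f", name, mean_sel)
        manifest["stages"]["classify"] = {
            "seconds": time.perf_counter() - t0,
            "rules": list(score_tables),
            "inputs": {"phenotypes.tsv": _sha256(out / "phenotypes.tsv")},
        }

        # ---- evaluate ---------------------------------------------------
        t0 = time.perf_counter()
        labels = np.array([p.diagnosis for p in dataset.phenotypes])
        sites = np.array([p.site for p in dataset.phenotypes])
        eval_rows = []
        for name, df in score_tables.items():
            scores = df["score"].to_numpy()
            preds, thr, _ = threshold_scores(scores, labels, mode=config.threshold_mode)
            res = evaluate(preds, labels, threshold=thr, threshold_mode=config.threshold_mode)
            eval_rows.append(
                {
                    "subset": name,
                    "threshold_mode": res.threshold_mode,
                    "threshold": res.threshold,
                    "n": res.n,
                    "n_correct": res.n_correct,
                    "accuracy": res.accuracy,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "binomial_p": res.binomial_p,
                }
            )
        eval_df = pd.DataFrame(eval_rows)
        eval_df.to_csv(out / "evaluation.tsv", sep="\t", index=False, float_format="%.17g")

        all_name = "all" if "all" in score_tables else next(iter(score_tables))
        all_scores = score_tables[all_name]["score"].to_numpy()
        behav = behavior_correlations(all_scores, dataset.phenotypes)
        behav.to_csv(out / "behavior_correlations.tsv", sep="\t", index=False, float_format="%.17g")
        site_df = per_site_accuracy(all_scores, labels, sites)
        vols = (
            phenotypes_to_frame(dataset.phenotypes)
            .groupby("site")["n_volumes_acquired"]
            .mean()
            .reindex(site_df["site"])
            .to_numpy()
        )
        site_df["mean_volumes"] = vols
        site_df.to_csv(out / "site_accuracy.tsv", sep="\t", index=False, float_format="%.17g")
        site_corr = (
            site_accuracy_analysis(
                site_df["accuracy"].to_numpy(), vols, site_df["n"].to_numpy()
            )
            if len(site_df) >= 3
            else None
        )
        manifest["stages"]["evaluate"] = {
            "seconds": time.perf_counter() - t0,
            "rows": len(eval_rows),
            "site_correlations": site_corr,
            "inputs": {
                f"scores_{n.replace('<', '_lt_')}.tsv": _sha256(
                    out / f"scores_{n.replace('<', '_lt_')}.tsv"
                )
                for n in score_tables
            },
        }
        for row in eval_rows:
            logger.info(
                "evaluate %s: accuracy %.3f (binomial p %.3g)",
                row["subset"],
                row["accuracy"],
                row["binomial_p"],
            )
    except Exception as exc:
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "simulate"
        logger.error("pipeline failed after stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage after {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
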