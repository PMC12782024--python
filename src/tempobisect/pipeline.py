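"""End-to-end pipeline: design -> simulate -> fit -> group models -> ROI
association, with a run manifest for reproducibility bookkeeping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as _cohort
from . import inference, io, neuro, psychometrics
from .cohort import CohortSpec, GroupSpec, default_cohort_spec


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    seed: int
    out_dir: str
    cohort: CohortSpec | None = None  # None -> published default pattern
    n_blocks: int = 8
    cross_block_constraint: bool = False
    fit_family: str = "scaled_normal"
    contrast_families: tuple[str, ...] = (
        "category×diagnosis", "category×valence", "diagnosis main",
    )
    holm: bool = False
    roi_regions: tuple[str, ...] = _cohort.DEFAULT_ROI_FAMILY
    roi_noise_sd: float = 0.4
    fwe_method: str = "permutation_maxT"
    n_perm: int = 2000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrast_families"] = list(self.contrast_families)
        d["roi_regions"] = list(self.roi_regions)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        d = yaml.safe_load(path.read_text())
        if "seed" not in d or d["seed"] is None:
            raise ConfigError("config must declare a seed")
        cohort_d = d.pop("cohort", None)
        spec = None
        if cohort_d:
            groups = {
                g: GroupSpec(v["n"], dict(v["bp"]), dict(v["wr"]))
                for g, v in cohort_d.pop("groups").items()
            }
            spec = CohortSpec(groups=groups, **cohort_d)
        d["contrast_families"] = tuple(d.get("contrast_families", ()))
        d["roi_regions"] = tuple(d.get("roi_regions", _cohort.DEFAULT_ROI_FAMILY))
        return cls(cohort=spec, **d)


@dataclass
class RunManifest:
    config_hash: str
    stages: dict[str, dict] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # file -> sha256

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write all result tables under ``out_dir``.

    Reruns with the same config and seed produce byte-identical CSVs
    (timestamps live only in the manifest).  Any stage failure aborts with
    the stage named; outputs written so far are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config))
    spec = config.cohort or default_cohort_spec(seed=config.seed)
    spec.seed = config.seed
    spec.n_blocks = config.n_blocks

    def stage(name: str):
        manifest.stages[name] = {"t_start": time.time()}
        return manifest.stages[name]

    def write(df: pd.DataFrame, fname: str, columns=None) -> None:
        path = out / fname
        io.write_table(df, path, columns)
        manifest.outputs[fname] = _sha256(path)

    try:
        s = stage("simulate")
        trial_log, covariates, _ = _cohort.simulate_cohort(spec)
        ratings = _cohort.simulate_valence_ratings(spec)
        s.update(n_participants=covariates.shape[0], n_trials=trial_log.shape[0])
        write(trial_log, "trial_log.csv", io.TRIAL_LOG_COLUMNS)
        write(covariates, "covariates.csv", io.COVARIATE_COLUMNS)
        write(ratings, "valence_ratings.csv")

        s = stage("fit")
        mapping = psychometrics.reassign_valence(ratings)
        relabelled = psychometrics.apply_valence_mapping(trial_log, mapping)
        metrics = psychometrics.participant_metrics(relabelled, family=config.fit_family)
        n_failed = int((~metrics["fit_ok"]).sum())
        s.update(n_fits=metrics.shape[0], n_failed=n_failed,
                 n_reassigned=int(mapping["reassigned"].sum()))
        write(metrics, "metrics.csv", io.METRICS_COLUMNS)

        s = stage("screen")
        screen_cols = ["group", "mood", "hearing", "musical_background",
                       "training_score", "tone_duration_score",
                       "sound_recognition_score"]
        present = [c for c in screen_cols if c in covariates.columns]
        screen = inference.screen_confounders(covariates[present])
        s.update(n_flagged=int(screen["include_as_covariate"].sum()))
        write(screen, "confound_screen.csv")

        s = stage("group_models")
        # listwise exclusion: drop participants with any failed condition fit
        ok_pid = metrics.groupby("participant_id")["fit_ok"].all()
        usable = metrics[metrics["participant_id"].map(ok_pid)].copy()
        s.update(n_excluded_participants=int((~ok_pid).sum()))
        summaries = {}
        contrasts_rows = []
        for response in ("bp", "log_wr"):
            model = inference.fit_mixed_model(usable, response)
            summaries[response] = {
                "converged": model.converged,
                "random_intercept_var": model.random_intercept_var,
                "residual_var": model.residual_var,
                "fixed_effects": model.fixed_effects.to_dict("records")
                if model.converged else [],
            }
            if model.converged:
                for fam in config.contrast_families:
                    for c in inference.posthoc_contrasts(model, fam, holm=config.holm):
                        contrasts_rows.append(
                            {"response": response, "family": fam,
                             "contrast": c.description, "estimate": c.estimate,
                             "z": c.z, "p": c.p}
                        )
        (out / "group_models.json").write_text(
            json.dumps(summaries, indent=2,
                       default=lambda o: o.item() if hasattr(o, "item") else str(o))
        )
        manifest.outputs["group_models.json"] = _sha256(out / "group_models.json")
        write(pd.DataFrame(contrasts_rows), "contrasts.csv")
        patient_means = (
            usable[usable["group"] != "controls"]
            .groupby("participant_id", as_index=False)
            .agg(group=("group", "first"), mean_bp=("bp", "mean"), mean_wr=("wr", "mean"))
            .merge(
                covariates[
                    ["participant_id", "mmse", "digit_span_forward",
                     "digit_span_reverse", "matrices"]
                ],
                on="participant_id",
            )
        )
        corrs = inference.exploratory_correlations(patient_means)
        write(corrs, "correlations.csv")

        s = stage("neuro")
        deltas = neuro.build_signed_differences(usable)
        write(deltas, "signed_differences.csv", io.DELTA_COLUMNS)
        roi = _cohort.simulate_roi_volumes(
            covariates, deltas, noise_sd=config.roi_noise_sd,
            regions=config.roi_regions, seed=config.seed,
        )
        write(roi, "roi_volumes.csv")
        assoc_all = []
        for cond in sorted(deltas["condition"].unique()):
            assoc_all.append(
                neuro.run_association(
                    roi, deltas, cond, regions=config.roi_regions,
                    method=config.fwe_method, n_perm=config.n_perm,
                    seed=config.seed,
                )
            )
        write(pd.concat(assoc_all, ignore_index=True), "associations.csv",
              io.ASSOC_COLUMNS)
        s.update(n_conditions=len(assoc_all))
    except Exception as exc:
        failed = [k for k, v in manifest.stages.items() if "t_end" not in v]
        raise RuntimeError(
            f"pipeline stage {failed[-1] if failed else '?'} failed: {exc}"
        ) from exc
    finally:
        for v in manifest.stages.values():
            v.setdefault("t_end", time.time())
    manifest.to_json(out / "manifest.json")
    return manifest
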