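"""End-to-end orchestration: simulate -> behavior -> decode -> neuro-behavioral
regression -> cluster statistics, with JSON configuration, a run manifest,
and fixed-seed reproducibility.

Each stage writes plain-text/HDF5 artifacts under the output directory and
records checksums and wall times in ``manifest.json``; re-running an
unchanged configuration reproduces identical checksums for deterministic
stages.
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

from . import __version__, behavior, cluster_stats, decoding, io, model_selection, neurobehav
from .errors import ConfigError, DataError
from .synthetic import GenParams, SourceEpochs, SourceGrid, SubjectDataset, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    gen: GenParams = field(default_factory=GenParams)
    out_dir: str = "avrecal_out"
    n_folds: int = 6
    window_ms: float = 60.0
    step_ms: float = 10.0
    decode_crop_ms: tuple[float, float] | None = (-100.0, 500.0)
    n_permutations: int = 200
    min_cluster_size: int = 6
    connectivity: int = 26
    cluster_alpha: float = 0.05
    t_threshold_p: float = 0.01
    pxp_samples: int = 100_000
    seed: int = 0
    stages: tuple[str, ...] = ("behavior", "decode", "neurobehav", "clusters")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["gen"] = json.loads(self.gen.to_json())
        return json.dumps(d, indent=2, default=float)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        try:
            d = json.loads(text)
            d["gen"] = GenParams.from_json(json.dumps(d.get("gen", {})))
            if d.get("decode_crop_ms") is not None:
                d["decode_crop_ms"] = tuple(d["decode_crop_ms"])
            if "stages" in d:
                d["stages"] = tuple(d["stages"])
            return cls(**d)
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigError(f"invalid pipeline config: {exc}") from exc

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


class RunManifest:
    def __init__(self, config: PipelineConfig):
        self.data = {
            "config_hash": config.config_hash,
            "package_version": __version__,
            "files": {},
            "wall_times_s": {},
        }

    def add_file(self, stage: str, path: Path) -> None:
        self.data["files"][str(path.name)] = {"stage": stage, "sha256": io.sha256_of(path)}

    def time_stage(self, stage: str, seconds: float) -> None:
        self.data["wall_times_s"][stage] = round(seconds, 3)

    def write(self, out_dir: Path) -> Path:
        return io.write_json(self.data, out_dir / "manifest.json")


def crop_epochs(epochs: SourceEpochs, t_min: float, t_max: float) -> SourceEpochs:
    sel = (epochs.time_ms >= t_min) & (epochs.time_ms <= t_max)
    return SourceEpochs(
        data=epochs.data[:, :, sel],
        time_ms=epochs.time_ms[sel],
        grid=epochs.grid,
        trial_index=epochs.trial_index,
        subject=epochs.subject,
    )


def run_simulate(config: PipelineConfig, include_epochs: bool = True) -> Path:
    """Generate a cohort on disk: per-subject trial TSVs, epoch HDF5 files,
    the generator parameters, and a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config)
    t0 = time.perf_counter()
    cohort = generate_cohort(config.gen, include_epochs=include_epochs)
    trials = pd.concat([d.trials for d in cohort], ignore_index=True)
    p = io.write_trials_tsv(trials, out / "trials.tsv")
    manifest.add_file("simulate", p)
    (out / "gen_params.json").write_text(config.gen.to_json())
    manifest.add_file("simulate", out / "gen_params.json")
    if include_epochs:
        for d in cohort:
            for name, ep in (("av", d.epochs_av), ("a", d.epochs_a)):
                p = io.write_epochs_h5(ep, out / f"epochs_sub{d.subject_id:02d}_{name}.h5")
                manifest.add_file("simulate", p)
    manifest.time_stage("simulate", time.perf_counter() - t0)
    manifest.write(out)
    return out


def behavioral_bundle(trials: pd.DataFrame, config: PipelineConfig, rng: np.random.Generator) -> dict:
    """Full behavioral analysis of a trial table (used by run_behavior_only
    and run_full)."""
    ve = behavior.compute_ve(trials)
    vae = behavior.compute_vae(trials)
    battery = model_selection.behavioral_model_selection(trials, n_samples=config.pxp_samples, rng=rng)
    dissoc = behavior.select_dissociation_trials(trials)
    dissoc_vae = vae[vae["trial"].isin(dissoc["trial"]) & vae["subject"].isin(dissoc["subject"])]
    results = {
        "ve_tests": behavior.discrepancy_bias_tests(ve).to_dict(orient="records"),
        "vae_tests": behavior.discrepancy_bias_tests(vae).to_dict(orient="records"),
        "dissociation_vae_tests": behavior.discrepancy_bias_tests(dissoc_vae).to_dict(orient="records"),
        "model_selection": {k: v.to_dict() for k, v in battery.items()},
        "mi3_fit": _fit_summary(model_selection.fit_mixed(model_selection.ModelSpec.named("mi3"), ve)),
        "mr3_fit": _fit_summary(model_selection.fit_mixed(model_selection.ModelSpec.named("mr3"), vae)),
    }
    return {"results": results, "ve": ve, "vae": vae}


def _fit_summary(fit: model_selection.FitResult) -> dict:
    return {
        "betas": fit.betas,
        "t_values": fit.t_values,
        "dof": fit.dof,
        "loglik": fit.loglik,
        "bic": fit.bic,
        "aic": fit.aic,
        "n_obs": fit.n_obs,
    }


def run_behavior_only(config: PipelineConfig, trial_table_path: str | Path) -> dict:
    """Behavioral bundle from an on-disk trial table TSV."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = io.read_trials_tsv(trial_table_path)
    rng = np.random.default_rng(config.seed)
    t0 = time.perf_counter()
    bundle = behavioral_bundle(trials, config, rng)
    manifest = RunManifest(config)
    p = io.write_json(bundle["results"], out / "behavior_results.json")
    manifest.add_file("behavior", p)
    for name in ("ve", "vae"):
        path = out / f"{name}_bias.tsv"
        bundle[name].to_csv(path, sep="\t", index=False)
        manifest.add_file("behavior", path)
    manifest.time_stage("behavior", time.perf_counter() - t0)
    manifest.write(out)
    return bundle["results"]


def run_decode(config: PipelineConfig, cohort_dir: str | Path) -> Path:
    """Stage-isolated decoding: read a simulated cohort from disk, write
    per-subject AUC maps and trial projections."""
    cohort_dir = Path(cohort_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = io.read_trials_tsv(cohort_dir / "trials.tsv")
    manifest = RunManifest(config)
    t0 = time.perf_counter()
    for subject, sub_trials in trials.groupby("subject"):
        epochs_av = io.read_epochs_h5(cohort_dir / f"epochs_sub{subject:02d}_av.h5")
        epochs_a = io.read_epochs_h5(cohort_dir / f"epochs_sub{subject:02d}_a.h5")
        dataset = SubjectDataset(
            subject_id=int(subject), trials=sub_trials.reset_index(drop=True),
            epochs_av=epochs_av, epochs_a=epochs_a, ground_truth=pd.DataFrame(), params=config.gen,
        )
        decoded = decode_subject(dataset, config, np.random.default_rng([config.seed, 7, int(subject)]))
        arrays = {}
        for var, (dmap, proj) in decoded.items():
            arrays[f"auc_{var}"] = dmap.auc
            arrays[f"proj_{var}"] = proj.y
            arrays[f"trials_{var}"] = proj.trial_index
        arrays["time_ms"] = next(iter(decoded.values()))[0].time_ms
        p = io.write_arrays_h5(out / f"decode_sub{subject:02d}.h5", arrays, {"subject": int(subject)})
        manifest.add_file("decode", p)
    manifest.time_stage("decode", time.perf_counter() - t0)
    manifest.write(out)
    return out


_MODEL_KEYS = {"eq4": ("A_AV", "V_AV", "VE"), "eq5": ("prev_A_AV", "prev_V_AV", "VAE")}


def run_neurobehav(config: PipelineConfig, cohort_dir: str | Path, decode_dir: str | Path) -> Path:
    """Stage-isolated neuro-behavioral regression: read decode outputs and
    the trial table, write per-subject beta maps for eq4/eq5."""
    cohort_dir, decode_dir = Path(cohort_dir), Path(decode_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = io.read_trials_tsv(cohort_dir / "trials.tsv")
    manifest = RunManifest(config)
    t0 = time.perf_counter()
    ve = behavior.compute_ve(trials)
    vae = behavior.compute_vae(trials)
    bias_tables = {"VE": ve, "VAE": vae}
    for subject in sorted(trials["subject"].unique()):
        arrays, _ = io.read_arrays_h5(decode_dir / f"decode_sub{subject:02d}.h5")
        out_arrays = {"time_ms": arrays["time_ms"]}
        for model, (key_a, key_b, bias_kind) in _MODEL_KEYS.items():
            proj_a = decoding.TrialProjections(
                y=arrays[f"proj_{key_a}"], time_ms=arrays["time_ms"],
                trial_index=arrays[f"trials_{key_a}"], fold=np.zeros(len(arrays[f"trials_{key_a}"]), int),
            )
            proj_b = decoding.TrialProjections(
                y=arrays[f"proj_{key_b}"], time_ms=arrays["time_ms"],
                trial_index=arrays[f"trials_{key_b}"], fold=proj_a.fold,
            )
            bias_sub = bias_tables[bias_kind]
            bias_sub = bias_sub[bias_sub["subject"] == subject]
            bmap = neurobehav.bias_regression(proj_a, proj_b, bias_sub, model, subject=int(subject))
            out_arrays[f"betas_{model}"] = bmap.betas
        p = io.write_arrays_h5(out / f"betas_sub{subject:02d}.h5", out_arrays, {"subject": int(subject)})
        manifest.add_file("neurobehav", p)
    manifest.time_stage("neurobehav", time.perf_counter() - t0)
    manifest.write(out)
    return out


def run_clusters(config: PipelineConfig, neurobehav_dir: str | Path) -> Path:
    """Stage-isolated cluster inference on the stored eq4/eq5 beta maps."""
    neurobehav_dir = Path(neurobehav_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = sorted(neurobehav_dir.glob("betas_sub*.h5"))
    if not files:
        raise DataError(f"no beta maps found under {neurobehav_dir}")
    manifest = RunManifest(config)
    t0 = time.perf_counter()
    grid = SourceGrid(config.gen.grid_shape, config.gen.voxel_spacing)
    loaded = [io.read_arrays_h5(f)[0] for f in files]
    time_axis = loaded[0]["time_ms"]
    tcrit = cluster_stats.parametric_threshold(len(loaded) - 1, config.t_threshold_p)
    results = {}
    for model in _MODEL_KEYS:
        stack = np.stack([d[f"betas_{model}"] for d in loaded])  # (S, V, W, 3)
        for j, term in enumerate(("beta_a", "beta_v"), start=1):
            course = np.abs(
                np.nan_to_num(stack[:, :, :, j].mean(axis=0) / (stack[:, :, :, j].std(axis=0, ddof=1) + 1e-12))
            ) * np.sqrt(len(loaded))
            times, _ = decoding.select_peaks(course, time_axis)
            w_peak = int(np.argmin(np.abs(time_axis - times[0])))
            effects = stack[:, :, w_peak, j]
            cs, _, _ = cluster_stats.cluster_inference(
                effects, grid,
                cluster_stats.PermutationScheme(config.n_permutations, config.seed + 2, "t"),
                threshold=tcrit, connectivity=config.connectivity,
                min_size=config.min_cluster_size, timepoint_ms=float(time_axis[w_peak]),
            )
            results[f"{model}:{term}"] = cs.to_dict(grid)
    p = io.write_json(results, out / "clusters.json")
    manifest.add_file("clusters", p)
    manifest.time_stage("clusters", time.perf_counter() - t0)
    manifest.write(out)
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _stimulus_variables(d: SubjectDataset) -> dict[str, tuple[str, np.ndarray]]:
    """(trial type, per-epoch stimulus values) for each decoded variable."""
    av = d.trials[d.trials["type"] == "AV"]
    paired = behavior.attach_pair_stimuli(d.trials)
    return {
        "A_AV": ("AV", av["A_loc"].to_numpy()),
        "V_AV": ("AV", av["V_loc"].to_numpy()),
        "A_A": ("A", paired["A_loc"].to_numpy()),
        "prev_A_AV": ("A", paired["A_AV"].to_numpy()),
        "prev_V_AV": ("A", paired["V_AV"].to_numpy()),
    }


def decode_subject(
    d: SubjectDataset,
    config: PipelineConfig,
    rng: np.random.Generator,
    variables: tuple[str, ...] = ("A_AV", "V_AV", "A_A", "prev_A_AV", "prev_V_AV"),
) -> dict[str, tuple[decoding.DecoderMap, decoding.TrialProjections]]:
    """Searchlight decoding of every requested variable for one subject."""
    spec = decoding.SearchlightSpec(window_ms=config.window_ms, step_ms=config.step_ms)
    epochs = {"AV": d.epochs_av, "A": d.epochs_a}
    if config.decode_crop_ms is not None:
        epochs = {k: crop_epochs(v, *config.decode_crop_ms) for k, v in epochs.items()}
    out = {}
    stim = _stimulus_variables(d)
    for var in variables:
        ttype, values = stim[var]
        labels, include = decoding.binarize_locations(values, "stimulus")
        dmap, proj = decoding.crossval_decode(
            epochs[ttype], labels, include, spec=spec, n_folds=config.n_folds, rng=rng, variable=var
        )
        out[var] = (dmap, proj)
    return out


def run_full(config: PipelineConfig) -> dict:
    """Run every stage on a freshly generated synthetic cohort and return
    (and write) the results bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config)
    rng = np.random.default_rng(config.seed)
    results: dict = {}

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        cohort = generate_cohort(config.gen, include_epochs=True)
        trials = pd.concat([d.trials for d in cohort], ignore_index=True)
        io.write_trials_tsv(trials, out / "trials.tsv")
        manifest.add_file(stage, out / "trials.tsv")
        manifest.time_stage(stage, time.perf_counter() - t0)

        stage = "behavior"
        t0 = time.perf_counter()
        bundle = behavioral_bundle(trials, config, rng)
        results["behavior"] = bundle["results"]
        io.write_json(bundle["results"], out / "behavior_results.json")
        manifest.add_file(stage, out / "behavior_results.json")
        manifest.time_stage(stage, time.perf_counter() - t0)

        stage = "decode"
        t0 = time.perf_counter()
        per_subject = [decode_subject(d, config, np.random.default_rng([config.seed, 7, d.subject_id])) for d in cohort]
        grid = cohort[0].epochs_a.grid
        variables = list(per_subject[0])
        auc_stack = {
            var: np.stack([ps[var][0].auc for ps in per_subject]) for var in variables
        }  # (S, V, W)
        time_axis = per_subject[0][variables[0]][0].time_ms
        peaks = {}
        for var in variables:
            group_auc = auc_stack[var].mean(axis=0)
            times, flag = decoding.select_peaks(group_auc, time_axis)
            peaks[var] = {"times_ms": times.tolist(), "endpoint_flag": bool(flag)}
        results["decoding"] = {
            "peaks": peaks,
            "mean_auc_max": {var: float(auc_stack[var].mean(axis=0).max()) for var in variables},
        }
        manifest.time_stage(stage, time.perf_counter() - t0)

        stage = "clusters"
        t0 = time.perf_counter()
        scheme = cluster_stats.PermutationScheme(
            n_permutations=config.n_permutations, seed=config.seed + 1, statistic="mean"
        )
        auc_clusters: dict[str, cluster_stats.ClusterSet] = {}
        for var in variables:
            w_peak = int(np.argmin(np.abs(time_axis - peaks[var]["times_ms"][0])))
            effects = auc_stack[var][:, :, w_peak] - 0.5
            cs, _, thr = cluster_stats.cluster_inference(
                effects, grid, scheme, threshold="auc99",
                connectivity=config.connectivity, min_size=config.min_cluster_size,
                timepoint_ms=float(time_axis[w_peak]),
            )
            auc_clusters[var] = cs
        results["auc_clusters"] = {
            var: cs.to_dict(grid) for var, cs in auc_clusters.items()
        }
        manifest.time_stage(stage, time.perf_counter() - t0)

        stage = "neurobehav"
        t0 = time.perf_counter()
        tcrit = cluster_stats.parametric_threshold(len(cohort) - 1, config.t_threshold_p)
        beta_clusters: dict[str, cluster_stats.ClusterSet] = {}
        group_tables: dict[str, dict] = {}
        for model, (key_a, key_b, bias_kind) in {
            "eq4": ("A_AV", "V_AV", "ve"),
            "eq5": ("prev_A_AV", "prev_V_AV", "vae"),
        }.items():
            maps = []
            for d, ps in zip(cohort, per_subject):
                bias_tab = bundle[bias_kind]
                bias_sub = bias_tab[bias_tab["subject"] == d.subject_id]
                maps.append(
                    neurobehav.bias_regression(ps[key_a][1], ps[key_b][1], bias_sub, model, subject=d.subject_id)
                )
            gt_map = neurobehav.group_level(maps)
            group_tables[model] = {"df": gt_map.df}
            for j, term in enumerate(gt_map.terms[1:], start=1):
                course = np.abs(gt_map.t[:, :, j]).astype(float)
                times, _ = decoding.select_peaks(course, time_axis)
                w_peak = int(np.argmin(np.abs(time_axis - times[0])))
                effects = np.stack([m.betas[:, w_peak, j] for m in maps])
                decode_var = {"Y_A_AV": "A_AV", "Y_V_AV": "V_AV", "Y_prev_A_AV": "prev_A_AV", "Y_prev_V_AV": "prev_V_AV"}[term]
                mask = cluster_stats.apriori_mask(auc_clusters[decode_var], grid.n_voxels, config.cluster_alpha) \
                    if "V_AV" not in term else None  # full brain for the visual regressor
                cs, _, _ = cluster_stats.cluster_inference(
                    effects, grid,
                    cluster_stats.PermutationScheme(config.n_permutations, config.seed + 2, "t"),
                    threshold=tcrit, connectivity=config.connectivity,
                    min_size=config.min_cluster_size, timepoint_ms=float(time_axis[w_peak]), mask=mask,
                )
                beta_clusters[f"{model}:{term}"] = cs
        results["beta_clusters"] = {k: cs.to_dict(grid) for k, cs in beta_clusters.items()}
        overlap_input = {
            k: cs.significant(config.cluster_alpha) for k, cs in beta_clusters.items() if cs.significant(config.cluster_alpha)
        }
        if len(overlap_input) >= 2:
            results["overlap_voxels"] = {
                "n": int(cluster_stats.overlap_map(overlap_input, grid.n_voxels).sum())
            }
        manifest.time_stage(stage, time.perf_counter() - t0)

        io.write_json(
            {k: v for k, v in results.items()},
            out / "results.json",
        )
        manifest.add_file("bundle", out / "results.json")
        manifest.write(out)
    except (DataError, ConfigError):
        raise
    except Exception as exc:  # preserve partial outputs, name the stage
        manifest.write(out)
        raise DataError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
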