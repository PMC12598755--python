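"""End-to-end orchestration: simulate -> match -> train/predict per modality
-> delta report -> classify -> stability.

A run is fully described by a :class:`RunConfig` (YAML-serializable) and is
reproducible from (config, package version).  The matched obese and
normal-weight control groups are held out from every training stage; models
are trained on the remaining pool (normal-weight and overweight participants,
which widens the training age/BMI variability), mirroring the study design.
Each run emits a comparison table shaped like a published group-comparison
table (rows: modality x age scope), a metrics JSON, a stability CSV and a
manifest with the config hash and per-file checksums.
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

from . import io as bio
from .classify import ClassifierGrid, bootstrap_stability, cv_classify, rank_weights
from .connectivity import (
    extract_pair_vector,
    make_parcellation,
    partition_pairs,
)
from .inference import DEFAULT_STRATA, delta_report
from .matching import MatchConstraints, match_controls
from .model import (
    BrainAgeModel,
    HyperparameterGrid,
    apply_bias_correction,
    evaluate,
    permutation_test,
    predict,
    tune_and_fit,
)
from .synthetic import (
    DEFAULT_NETWORK_SIZES,
    Cohort,
    EffectSpec,
    generate_cohort,
    generate_connectivity,
    generate_dwi_features,
    generate_gm_features,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "build_features"]

DWI_MODALITIES = ("fa", "md", "ad", "rd")
PACKAGE_VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML round-trippable."""

    seed: int = 0
    out_dir: str = "results/run"
    # cohort
    n_pool: int = 600
    obese_fraction: float = 0.18
    overweight_fraction: float = 0.30
    # injected obesity effect (brain-age acceleration, years)
    accel_years: float = 3.0
    accel_window: tuple[float, float] | None = None
    gm_noise_sd: float = 0.1
    dwi_noise_sd: float = 0.03
    n_rois: int = 48
    # connectivity
    network_sizes: tuple[int, ...] = DEFAULT_NETWORK_SIZES
    n_timepoints: int = 261
    # matching
    max_age_diff: float = 5.0
    max_education_diff: int = 1
    n_pairs_max: int | None = 83
    # modelling
    modalities: tuple[str, ...] = ("gm", "fa", "md", "ad", "rd", "intra", "inter")
    k_folds: int = 10
    alpha_values: tuple[float, ...] = (0.001, 0.25, 0.5, 0.75, 0.99)
    n_lambdas: int = 100
    pc_step: int = 5
    pc_max: int = 60
    n_perm: int = 200  # reduced demo default; 1000 for a full run
    # classification
    classify_modalities: tuple[str, ...] | str = "auto"
    classifier_repeats: int = 10
    classifier_tolerances: tuple[float, ...] = ClassifierGrid().tolerance_values
    classifier_n_c: int = 30
    n_boot: int = 200  # reduced demo default; 1000 for a full run

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("network_sizes", "modalities", "alpha_values",
                    "classifier_tolerances"):
            d[key] = list(d[key])
        if isinstance(d["classify_modalities"], tuple):
            d["classify_modalities"] = list(d["classify_modalities"])
        if d["accel_window"] is not None:
            d["accel_window"] = list(d["accel_window"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key in ("network_sizes", "modalities", "alpha_values",
                    "classifier_tolerances"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if isinstance(kwargs.get("classify_modalities"), list):
            kwargs["classify_modalities"] = tuple(kwargs["classify_modalities"])
        if kwargs.get("accel_window") is not None:
            kwargs["accel_window"] = tuple(kwargs["accel_window"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    started_at: float
    finished_at: float
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _derive_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def build_features(cohort: Cohort, config: RunConfig) -> dict[str, pd.DataFrame]:
    """Feature tables for every configured modality, for the whole cohort."""
    out: dict[str, pd.DataFrame] = {}
    gm_effect = EffectSpec(
        accel_years=config.accel_years,
        accel_window=config.accel_window,
        noise_sd=config.gm_noise_sd,
    )
    if "gm" in config.modalities:
        out["gm"] = generate_gm_features(
            cohort, n_rois=config.n_rois, effect=gm_effect,
            seed=_derive_seed(config.seed, "gm"),
        )
    dwi_wanted = [m for m in config.modalities if m in DWI_MODALITIES]
    if dwi_wanted:
        dwi_effect = EffectSpec(accel_years=0.0, noise_sd=config.dwi_noise_sd)
        tables = generate_dwi_features(
            cohort, n_rois=config.n_rois, effect=dwi_effect,
            seed=_derive_seed(config.seed, "dwi"),
        )
        for m in dwi_wanted:
            out[m] = tables[m.upper()]
    if "intra" in config.modalities or "inter" in config.modalities:
        parcellation = make_parcellation(config.network_sizes)
        partition = partition_pairs(parcellation)
        conn_effect = EffectSpec(
            accel_years=config.accel_years, accel_window=config.accel_window,
        )
        matrices = generate_connectivity(
            cohort, parcellation, effect=conn_effect,
            seed=_derive_seed(config.seed, "conn"),
            n_timepoints=config.n_timepoints,
        )
        for which in ("intra", "inter"):
            if which not in config.modalities:
                continue
            vectors = np.stack(
                [extract_pair_vector(matrices[pid], partition, which)
                 for pid in cohort.ids]
            )
            pairs = getattr(partition, f"{which}_pairs")
            cols = [f"{which}_{i:03d}_{j:03d}" for i, j in pairs]
            frame = pd.DataFrame(vectors, columns=cols)
            frame.insert(0, "id", cohort.ids)
            out[which] = frame
    return out


def _grid_for(modality: str, config: RunConfig, n_train: int) -> HyperparameterGrid:
    lambdas = np.logspace(-5, 5, config.n_lambdas)
    n_pcs = None
    if modality in ("intra", "inter"):
        cap = min(config.pc_max, n_train - n_train // config.k_folds - 1)
        n_pcs = HyperparameterGrid.pc_grid(cap, step=config.pc_step)
    return HyperparameterGrid(
        alpha_values=config.alpha_values,
        lambda_values=lambdas,
        n_pcs_values=n_pcs,
    )


def run_pipeline(config: RunConfig) -> tuple[RunManifest, dict]:
    """Execute all stages in order; see the module docstring.

    Returns the manifest and an in-memory results dict (models, prediction
    frames, report and classifier outputs).  A stage failure raises with the
    stage named; partial outputs already written are retained.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    stage_seconds: dict[str, float] = {}
    outputs: dict[str, str] = {}
    results: dict = {}

    def _run_stage(name, fn):
        t0 = time.time()
        try:
            value = fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stage_seconds[name] = time.time() - t0
        logger.info("stage %s finished in %.1fs", name, stage_seconds[name])
        return value

    def _write(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        outputs[name] = _sha256(path)
        return path

    # --- simulate ---------------------------------------------------------
    def _simulate():
        cohort = generate_cohort(
            config.n_pool, config.obese_fraction,
            seed=_derive_seed(config.seed, "cohort"),
            overweight_fraction=config.overweight_fraction,
        )
        _write("cohort.csv", lambda p: bio.write_cohort(cohort, p))
        return cohort

    cohort = _run_stage("simulate", _simulate)

    # --- match ------------------------------------------------------------
    def _match():
        table = cohort.table
        cases = table[table["bmi_class"] == "obese"]
        candidates = table[table["bmi_class"] == "normal"]
        constraints = MatchConstraints(
            max_age_diff=config.max_age_diff,
            max_education_diff=config.max_education_diff,
        )
        res = match_controls(cases, candidates, constraints)
        if config.n_pairs_max is not None:
            res.pairs = res.pairs[: config.n_pairs_max]
        _write("pairs.csv", lambda p: res.to_frame().to_csv(p, index=False))
        _write(
            "exclusions.csv",
            lambda p: pd.DataFrame({"case_id": res.excluded_cases}).to_csv(
                p, index=False
            ),
        )
        return res

    match_result = _run_stage("match", _match)
    results["match"] = match_result
    case_ids = set(match_result.case_ids)
    control_ids = set(match_result.control_ids)
    held_out = case_ids | control_ids
    # unmatched obese are excluded from the analysis entirely
    obese_ids = set(cohort.table.loc[cohort.table["bmi_class"] == "obese", "id"])
    train_mask = ~cohort.table["id"].isin(held_out | obese_ids)
    results["n_train"] = int(train_mask.sum())

    # --- features ---------------------------------------------------------
    features = _run_stage("features", lambda: build_features(cohort, config))

    # --- train / predict per modality ------------------------------------
    table = cohort.table.set_index("id")
    report_frames = []
    metrics: dict[str, dict] = {}
    models: dict[str, BrainAgeModel] = {}
    deltas: dict[str, dict[str, pd.DataFrame]] = {}

    def _train_modality(modality: str):
        feats = features[modality]
        tr = feats[feats["id"].isin(cohort.table.loc[train_mask, "id"])]
        ages_tr = table.loc[tr["id"], "age"].to_numpy()
        grid = _grid_for(modality, config, len(tr))
        model = tune_and_fit(
            tr, ages_tr, grid, k=config.k_folds,
            seed=_derive_seed(config.seed, f"folds-{modality}"),
            modality=modality,
        )
        models[modality] = model
        _write(f"model_{modality}.json", model.save)

        group_frames = {}
        for group, ids in (("NWc", match_result.control_ids),
                           ("O", match_result.case_ids)):
            sub = feats[feats["id"].isin(ids)]
            ages = table.loc[sub["id"], "age"].to_numpy()
            pred = predict(model, sub)
            res = apply_bias_correction(model, pred, ages, ids=sub["id"].to_numpy())
            group_frames[group] = res.to_frame()
            r2, mae = evaluate(res)
            metrics.setdefault(modality, {})[group] = {"r2": r2, "mae": mae}
        deltas[modality] = group_frames
        both = pd.concat(
            [f.assign(group=g) for g, f in group_frames.items()],
            ignore_index=True,
        )
        _write(f"deltas_{modality}.csv", lambda p: both.to_csv(p, index=False))

        rep = delta_report(
            group_frames["NWc"]["age"].to_numpy(),
            group_frames["NWc"]["corrected_delta"].to_numpy(),
            group_frames["O"]["age"].to_numpy(),
            group_frames["O"]["corrected_delta"].to_numpy(),
            strata=DEFAULT_STRATA,
            modality=modality,
        )
        report_frames.append(rep)

        if config.n_perm > 0:
            test_feats = feats[feats["id"].isin(held_out)]
            test_ages = table.loc[test_feats["id"], "age"].to_numpy()
            perm = permutation_test(
                tr, ages_tr, test_feats, test_ages, model,
                n_perm=config.n_perm,
                seed=_derive_seed(config.seed, f"perm-{modality}"),
            )
            metrics[modality]["permutation_p"] = perm.p_value
            metrics[modality]["observed_mae"] = perm.observed_mae

    for modality in config.modalities:
        _run_stage(f"train-{modality}", lambda m=modality: _train_modality(m))

    report = pd.concat(report_frames, ignore_index=True)
    _write("delta_report.csv", lambda p: report.to_csv(p, index=False))
    results.update(models=models, deltas=deltas, report=report)

    # --- classify ---------------------------------------------------------
    if config.classify_modalities == "auto":
        classify_mods = tuple(
            m for m in config.modalities
            if float(
                report.query("modality == @m and scope == 'lifespan'")["p"].iloc[0]
            ) < 0.05
        )
    else:
        classify_mods = tuple(config.classify_modalities)

    classifier_results = {}
    stability_frames = []
    grid = ClassifierGrid(
        tolerance_values=config.classifier_tolerances,
        c_values=np.logspace(-4, 4, config.classifier_n_c),
    )

    def _classify_modality(modality: str):
        feats = features[modality]
        ordered_ids = match_result.control_ids + match_result.case_ids
        sub = feats.set_index("id").loc[ordered_ids].reset_index()
        demo = table.loc[sub["id"]]
        X = sub.copy()
        X.insert(1, "age", demo["age"].to_numpy())
        X.insert(2, "sex_male", (demo["sex"] == "male").astype(int).to_numpy())
        y = np.array(
            [0] * len(match_result.control_ids) + [1] * len(match_result.case_ids)
        )
        res = cv_classify(
            X, y, grid, k=config.k_folds, repeats=config.classifier_repeats,
            seed=_derive_seed(config.seed, f"classify-{modality}"),
        )
        classifier_results[modality] = res

        # modal selected combo across repeats x folds, for the bootstrap
        sel = res.selected.groupby(["tolerance", "C"]).size().idxmax()
        tol, C = float(sel[0]), float(sel[1])
        if config.n_boot >= 100:
            stab = bootstrap_stability(
                X.drop(columns=["id"]), y, tolerance=tol, C=C,
                n_boot=config.n_boot,
                seed=_derive_seed(config.seed, f"boot-{modality}"),
            )
            ranked = rank_weights(stab).assign(modality=modality)
            stability_frames.append(ranked)

    for modality in classify_mods:
        _run_stage(f"classify-{modality}", lambda m=modality: _classify_modality(m))

    if stability_frames:
        stability = pd.concat(stability_frames, ignore_index=True)
        _write("stability.csv", lambda p: stability.to_csv(p, index=False))
        results["stability"] = stability
    results["classifiers"] = classifier_results

    metrics_out = {
        mod: metrics.get(mod, {}) for mod in config.modalities
    }
    for mod, res in classifier_results.items():
        metrics_out.setdefault(mod, {})["classifier"] = res.summary()
    _write(
        "metrics.json",
        lambda p: Path(p).write_text(json.dumps(metrics_out, indent=2)),
    )
    results["metrics"] = metrics_out

    config_path = out_dir / "config.yaml"
    config.to_yaml(config_path)
    outputs["config.yaml"] = _sha256(config_path)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        package_version=PACKAGE_VERSION,
        started_at=started,
        finished_at=time.time(),
        outputs=outputs,
        stage_seconds=stage_seconds,
    )
    manifest.to_json(out_dir / "manifest.json")
    results["manifest"] = manifest
    return manifest, results
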