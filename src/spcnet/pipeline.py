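"""End-to-end experiment pipeline: phantom cohort -> preprocessing ->
label fusion -> cross-validated training -> ensemble prediction ->
lesion extraction -> evaluation.

Two entry points:

* :func:`run_experiment` — in-memory, returns the evaluation reports;
  used by tests and the acceptance script.
* :func:`run_pipeline` — staged, artifact-per-stage on disk, resumable;
  backs the command-line interface.

All randomness flows from one global seed via named substreams (phantom,
folds, model init, augmentation), so a rerun with the same configuration is
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .evaluation import (
    CLASS_NAMES,
    combine_predictions,
    per_lesion_eval,
    per_patient_eval,
    per_pixel_eval,
    pick_thresholds,
    radiologist_as_prediction,
    save_thresholds,
)
from .labels import GradeMap, SoftLabelVolume, fuse_labels
from .lesions import DEFAULT_CLOSING_RADII_MM, MIN_LESION_VOLUME_MM3
from .model import (
    ModelConfig,
    ProbabilityVolume,
    load_checkpoint,
    predict_case,
    save_checkpoint,
)
from .phantom import PhantomParams, StudyCase, generate_cohort
from .preprocess import (
    DEFAULT_PERCENTILES,
    HistogramLandmarks,
    crop_around_prostate,
    learn_landmarks,
    preprocess_case,
    resample_to_grid,
)
from .training import PreparedCase, TrainConfig, make_folds, train_fold
from .volume import ImageVolume

__all__ = [
    "PipelineConfig",
    "prepare_case",
    "prepare_cases",
    "learn_cohort_landmarks",
    "train_cross_validation",
    "run_experiment",
    "run_pipeline",
]

log = logging.getLogger("spcnet")


@dataclass
class PipelineConfig:
    """Single configuration object for a full experiment run.

    Nested dataclass fields hold per-stage parameters; the global ``seed``
    drives every stochastic stage through named substreams.
    """

    seed: int = 0
    n_train_cases: int = 20
    n_test_cases: int = 8
    phantom: PhantomParams = field(default_factory=PhantomParams)
    target_in_plane_mm: float = 0.29
    crop_px: int = 224
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    closing_radii_mm: tuple[float, float] = DEFAULT_CLOSING_RADII_MM
    min_volume_mm3: float = MIN_LESION_VOLUME_MM3
    significance_rule: str = "1pct"
    benign_threshold: float = 0.95

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(_to_plain(asdict(self)), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "phantom" in kwargs and isinstance(kwargs["phantom"], dict):
            ph = dict(kwargs["phantom"])
            for k in ("class_mix", "grid", "lesion_volume_lognormal", "n_lesions_range"):
                if k in ph:
                    ph[k] = tuple(ph[k])
            if "contrast" in ph:
                ph["contrast"] = {k: tuple(v) for k, v in ph["contrast"].items()}
            kwargs["phantom"] = PhantomParams(**ph)
        if "model" in kwargs and isinstance(kwargs["model"], dict):
            kwargs["model"] = ModelConfig(**kwargs["model"])
        if "train" in kwargs and isinstance(kwargs["train"], dict):
            tr = dict(kwargs["train"])
            if "rotation_range_deg" in tr:
                tr["rotation_range_deg"] = tuple(tr["rotation_range_deg"])
            kwargs["train"] = TrainConfig(**tr)
        for k in ("percentiles", "closing_radii_mm"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# case preparation
# ---------------------------------------------------------------------------


def _resample_grade_map(gm: GradeMap, target_mm: float) -> GradeMap:
    factor = gm.in_plane_spacing_mm / target_mm
    if abs(factor - 1.0) < 1e-9:
        return GradeMap(gm.data.copy(), target_mm, gm.slice_spacing_mm)
    data = ndimage.zoom(
        gm.data, (1.0, factor, factor), order=0, mode="nearest", grid_mode=True
    )
    return GradeMap(data, target_mm, gm.slice_spacing_mm)


def learn_cohort_landmarks(
    cases: list[StudyCase],
    target_in_plane_mm: float,
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
) -> dict[str, HistogramLandmarks]:
    """Learn the frozen per-sequence landmarks from a training cohort (on the
    resampled grid, in-gland voxels only)."""
    vols: dict[str, list] = {"t2w": [], "adc": []}
    for case in cases:
        mask = resample_to_grid(case.prostate_mask, target_in_plane_mm)
        vols["t2w"].append((resample_to_grid(case.t2w, target_in_plane_mm), mask))
        vols["adc"].append((resample_to_grid(case.adc, target_in_plane_mm), mask))
    return {
        seq: learn_landmarks(vols[seq], seq, percentiles) for seq in ("t2w", "adc")
    }


def prepare_case(
    case: StudyCase,
    landmarks: dict[str, HistogramLandmarks],
    target_in_plane_mm: float,
    crop_px: int,
) -> tuple[PreparedCase, ImageVolume]:
    """Run the preprocessing chain and fuse labels for one case.

    Returns the model-ready case plus the cropped radiologist outline (kept
    separate because it is an evaluation input, not training data)."""
    out = preprocess_case(
        case.t2w,
        case.adc,
        case.prostate_mask,
        landmarks,
        target_in_plane_mm,
        crop_px,
        extra_masks={
            "pathologist_mask": case.pathologist_mask,
            "radiologist_outline": case.radiologist_outline,
        },
    )
    gm = _resample_grade_map(case.grade_map, target_in_plane_mm)
    gm_vol = ImageVolume(
        gm.data.astype(np.float64), target_in_plane_mm, gm.slice_spacing_mm
    )
    mask_r = resample_to_grid(case.prostate_mask, target_in_plane_mm)
    gm_cropped = crop_around_prostate(gm_vol, mask_r, crop_px)
    grade_map = GradeMap(
        gm_cropped.data.astype(np.int8), target_in_plane_mm, gm.slice_spacing_mm
    )
    labels = fuse_labels(grade_map, out["pathologist_mask"], out["prostate_mask"])
    prepared = PreparedCase(
        case_id=case.case_id,
        t2w=out["t2w"].data,
        adc=out["adc"].data,
        gland=out["prostate_mask"].data.astype(bool),
        labels=labels,
        cohort_tag=case.cohort_tag,
    )
    return prepared, out["radiologist_outline"]


def prepare_cases(
    cases: list[StudyCase],
    landmarks: dict[str, HistogramLandmarks],
    target_in_plane_mm: float,
    crop_px: int,
) -> tuple[list[PreparedCase], dict[str, ImageVolume]]:
    prepared, outlines = [], {}
    for case in cases:
        p, outline = prepare_case(case, landmarks, target_in_plane_mm, crop_px)
        prepared.append(p)
        outlines[case.case_id] = outline
    return prepared, outlines


# ---------------------------------------------------------------------------
# cross-validated training and ensembling
# ---------------------------------------------------------------------------


def train_cross_validation(
    train_cases: list[PreparedCase],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[list, dict[str, int], list[dict], list[ProbabilityVolume]]:
    """Patient-level k-fold cross-validation.

    Returns (fold models, fold assignment, fold histories, out-of-fold
    validation predictions aligned with ``train_cases``)."""
    folds = make_folds([c.case_id for c in train_cases], train_cfg.n_folds, train_cfg.seed)
    models, histories = [], []
    oof: dict[str, ProbabilityVolume] = {}
    for fold in range(train_cfg.n_folds):
        tr = [c for c in train_cases if folds[c.case_id] != fold]
        va = [c for c in train_cases if folds[c.case_id] == fold]
        fold_model_cfg = dataclasses.replace(
            model_cfg, seed=int(np.random.default_rng([model_cfg.seed, fold]).integers(2**31))
        )
        fold_train_cfg = dataclasses.replace(
            train_cfg, seed=int(np.random.default_rng([train_cfg.seed, 7, fold]).integers(2**31))
        )
        model, history = train_fold(tr, va, fold_model_cfg, fold_train_cfg)
        models.append(model)
        histories.append(history)
        for case in va:
            oof[case.case_id] = predict_case(
                model,
                case.t2w,
                case.adc,
                case.labels.in_plane_spacing_mm,
                case.labels.slice_spacing_mm,
            )
        log.info("fold %d: train loss %s", fold, history["train_loss"])
    oof_list = [oof[c.case_id] for c in train_cases]
    return models, folds, histories, oof_list


def predict_ensemble(
    models: list, cases: list[PreparedCase]
) -> list[ProbabilityVolume]:
    return [
        predict_case(
            models,
            c.t2w,
            c.adc,
            c.labels.in_plane_spacing_mm,
            c.labels.slice_spacing_mm,
        )
        for c in cases
    ]


# ---------------------------------------------------------------------------
# in-memory experiment
# ---------------------------------------------------------------------------


def run_experiment(config: PipelineConfig) -> dict:
    """Full experiment in memory; returns a dict of evaluation reports.

    Generates a training cohort and an independent test cohort, learns the
    preprocessing landmarks on the training cohort only, trains the
    cross-validation ensemble, freezes per-class thresholds on the pooled
    out-of-fold validation predictions, and evaluates the ensemble on the
    held-out cohort at pixel, lesion, and patient level, including the
    radiologist comparison and the combined score."""
    ph_train = dataclasses.replace(
        config.phantom, seed=config.seed, n_cases=config.n_train_cases
    )
    ph_test = dataclasses.replace(
        config.phantom, seed=config.seed + 1, n_cases=config.n_test_cases
    )
    train_raw, _ = generate_cohort(ph_train)
    test_raw, _ = generate_cohort(ph_test)

    landmarks = learn_cohort_landmarks(
        train_raw, config.target_in_plane_mm, config.percentiles
    )
    train_cases, _ = prepare_cases(
        train_raw, landmarks, config.target_in_plane_mm, config.crop_px
    )
    test_cases, test_outlines = prepare_cases(
        test_raw, landmarks, config.target_in_plane_mm, config.crop_px
    )

    model_cfg = dataclasses.replace(
        config.model, input_size_px=config.crop_px, seed=config.seed
    )
    train_cfg = dataclasses.replace(config.train, seed=config.seed)
    models, folds, histories, oof = train_cross_validation(
        train_cases, model_cfg, train_cfg
    )
    thresholds = pick_thresholds(train_cases, oof)

    predictions = predict_ensemble(models, test_cases)
    lesion_kw = dict(
        benign_threshold=config.benign_threshold,
        closing_radii_mm=config.closing_radii_mm,
        min_volume_mm3=config.min_volume_mm3,
        cohort_tag="test",
    )
    results = {
        "thresholds": thresholds,
        "fold_assignment": folds,
        "histories": histories,
        "pixel": per_pixel_eval(test_cases, predictions, thresholds, "test"),
        "lesion_all": per_lesion_eval(
            test_cases,
            [p.cancer_probability() for p in predictions],
            thresholds["cancer"],
            mode="all",
            **lesion_kw,
        ),
        "lesion_cs": per_lesion_eval(
            test_cases,
            [p.probs[2] for p in predictions],
            thresholds["aggressive"],
            mode="cs",
            significance_rule=config.significance_rule,
            **lesion_kw,
        ),
        "patient": per_patient_eval(
            test_cases,
            predictions,
            thresholds["aggressive"],
            config.significance_rule,
            config.closing_radii_mm,
            config.min_volume_mm3,
        ),
    }

    radio_preds = [
        radiologist_as_prediction(test_outlines[c.case_id]) for c in test_cases
    ]
    results["lesion_cs_radiologist"] = per_lesion_eval(
        test_cases,
        [p.probs[2] for p in radio_preds],
        0.5,
        mode="cs",
        significance_rule=config.significance_rule,
        **lesion_kw,
    )
    combined = [
        combine_predictions(m, r)[2] for m, r in zip(predictions, radio_preds)
    ]
    results["lesion_cs_combined"] = per_lesion_eval(
        test_cases,
        combined,
        thresholds["aggressive"],
        mode="cs",
        significance_rule=config.significance_rule,
        **lesion_kw,
    )
    results["models"] = models
    results["train_cases"] = train_cases
    results["test_cases"] = test_cases
    results["predictions"] = predictions
    return results


# ---------------------------------------------------------------------------
# staged, resumable pipeline on disk
# ---------------------------------------------------------------------------

_STAGES = ("phantom", "prepare", "train", "predict", "evaluate")


def _marker(out_dir: Path, stage: str) -> Path:
    return out_dir / stage / ".done"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log_checksums(out_dir: Path, stage: str) -> None:
    record_path = out_dir / "checksums.json"
    record = json.loads(record_path.read_text()) if record_path.exists() else {}
    stage_dir = out_dir / stage
    record[stage] = {
        str(p.relative_to(out_dir)): _sha256(p)
        for p in sorted(stage_dir.rglob("*"))
        if p.is_file() and p.name != ".done"
    }
    record_path.write_text(json.dumps(record, indent=1))


def _require_stage(out_dir: Path, stage: str) -> None:
    stage_dir = out_dir / stage
    has_content = stage_dir.exists() and any(
        p.is_file() and p.name != ".done" for p in stage_dir.rglob("*")
    )
    if not (_marker(out_dir, stage).exists() and has_content):
        raise FileNotFoundError(
            f"missing upstream artifact: stage '{stage}' has not completed in "
            f"{out_dir}; run it first (spcnet run-all or spcnet {stage})"
        )


def _save_prepared(path: Path, case: PreparedCase, outline: ImageVolume) -> None:
    np.savez_compressed(
        path,
        t2w=case.t2w,
        adc=case.adc,
        gland=case.gland,
        label_channels=case.labels.as_channels(),
        outline=outline.data,
        in_plane_mm=case.labels.in_plane_spacing_mm,
        slice_mm=case.labels.slice_spacing_mm,
        cohort_tag=np.frombuffer(case.cohort_tag.encode(), dtype=np.uint8),
    )


def _load_prepared(path: Path) -> tuple[PreparedCase, ImageVolume]:
    with np.load(path) as d:
        in_plane = float(d["in_plane_mm"])
        slice_mm = float(d["slice_mm"])
        labels = SoftLabelVolume.from_channels(d["label_channels"], in_plane, slice_mm)
        case = PreparedCase(
            case_id=path.stem,
            t2w=d["t2w"],
            adc=d["adc"],
            gland=d["gland"],
            labels=labels,
            cohort_tag=bytes(d["cohort_tag"]).decode(),
        )
        outline = ImageVolume(d["outline"], in_plane, slice_mm, is_mask=True)
    return case, outline


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, resume: bool = True
) -> Path:
    """Execute all stages, writing versioned artifacts under ``out_dir``.

    With ``resume=True`` a stage whose completion marker exists is skipped,
    so deleting one stage's directory regenerates only it and its
    downstream stages."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    (out_dir / "seed.txt").write_text(str(config.seed))

    # --- stage: phantom ----------------------------------------------------
    if not (resume and _marker(out_dir, "phantom").exists()):
        stage = out_dir / "phantom"
        ph_train = dataclasses.replace(
            config.phantom, seed=config.seed, n_cases=config.n_train_cases
        )
        ph_test = dataclasses.replace(
            config.phantom, seed=config.seed + 1, n_cases=config.n_test_cases
        )
        generate_cohort(ph_train, stage / "train")
        generate_cohort(ph_test, stage / "test")
        _marker(out_dir, "phantom").touch()
        _log_checksums(out_dir, "phantom")
        log.info("stage phantom done")

    # --- stage: prepare ------------------------------------------------------
    if not (resume and _marker(out_dir, "prepare").exists()):
        _require_stage(out_dir, "phantom")
        stage = out_dir / "prepare"
        stage.mkdir(parents=True, exist_ok=True)
        train_raw = _read_cohort(out_dir / "phantom" / "train")
        test_raw = _read_cohort(out_dir / "phantom" / "test")
        landmarks = learn_cohort_landmarks(
            train_raw, config.target_in_plane_mm, config.percentiles
        )
        for seq, lm in landmarks.items():
            lm.to_yaml(stage / f"landmarks_{seq}.yaml")
        for split, raw in (("train", train_raw), ("test", test_raw)):
            (stage / split).mkdir(exist_ok=True)
            for case in raw:
                prepared, outline = prepare_case(
                    case, landmarks, config.target_in_plane_mm, config.crop_px
                )
                _save_prepared(stage / split / f"{case.case_id}.npz", prepared, outline)
        _marker(out_dir, "prepare").touch()
        _log_checksums(out_dir, "prepare")
        log.info("stage prepare done")

    # --- stage: train --------------------------------------------------------
    if not (resume and _marker(out_dir, "train").exists()):
        _require_stage(out_dir, "prepare")
        stage = out_dir / "train"
        stage.mkdir(parents=True, exist_ok=True)
        train_cases = [
            _load_prepared(p)[0]
            for p in sorted((out_dir / "prepare" / "train").glob("*.npz"))
        ]
        model_cfg = dataclasses.replace(
            config.model, input_size_px=config.crop_px, seed=config.seed
        )
        train_cfg = dataclasses.replace(config.train, seed=config.seed)
        models, folds, histories, oof = train_cross_validation(
            train_cases, model_cfg, train_cfg
        )
        for i, m in enumerate(models):
            save_checkpoint(m, stage / f"fold{i}.npz")
        (stage / "folds.json").write_text(json.dumps(folds, indent=1))
        pd.DataFrame(
            [
                {"fold": i, "epoch": e, "train_loss": l}
                for i, h in enumerate(histories)
                for e, l in enumerate(h["train_loss"])
            ]
        ).to_csv(stage / "history.csv", index=False)
        thresholds = pick_thresholds(train_cases, oof)
        save_thresholds(thresholds, stage / "thresholds.yaml")
        _marker(out_dir, "train").touch()
        _log_checksums(out_dir, "train")
        log.info("stage train done")

    # --- stage: predict ------------------------------------------------------
    if not (resume and _marker(out_dir, "predict").exists()):
        _require_stage(out_dir, "train")
        stage = out_dir / "predict"
        stage.mkdir(parents=True, exist_ok=True)
        models = [
            load_checkpoint(p) for p in sorted((out_dir / "train").glob("fold*.npz"))
        ]
        for p in sorted((out_dir / "prepare" / "test").glob("*.npz")):
            case, _ = _load_prepared(p)
            prob = predict_case(
                models,
                case.t2w,
                case.adc,
                case.labels.in_plane_spacing_mm,
                case.labels.slice_spacing_mm,
            )
            np.savez_compressed(stage / p.name, probs=prob.probs)
        _marker(out_dir, "predict").touch()
        _log_checksums(out_dir, "predict")
        log.info("stage predict done")

    # --- stage: evaluate -----------------------------------------------------
    if not (resume and _marker(out_dir, "evaluate").exists()):
        _require_stage(out_dir, "predict")
        from .evaluation import load_thresholds  # local to avoid cycle confusion

        stage = out_dir / "evaluate"
        stage.mkdir(parents=True, exist_ok=True)
        thresholds = load_thresholds(out_dir / "train" / "thresholds.yaml")
        cases, predictions, radio = [], [], []
        for p in sorted((out_dir / "prepare" / "test").glob("*.npz")):
            case, outline = _load_prepared(p)
            cases.append(case)
            radio.append(radiologist_as_prediction(outline))
            with np.load(out_dir / "predict" / p.name) as d:
                predictions.append(
                    ProbabilityVolume(
                        d["probs"],
                        case.labels.in_plane_spacing_mm,
                        case.labels.slice_spacing_mm,
                    )
                )
        lesion_kw = dict(
            benign_threshold=config.benign_threshold,
            closing_radii_mm=config.closing_radii_mm,
            min_volume_mm3=config.min_volume_mm3,
            cohort_tag="test",
        )
        reports = {
            "pixel": per_pixel_eval(cases, predictions, thresholds, "test"),
            "lesion_all": per_lesion_eval(
                cases,
                [p.cancer_probability() for p in predictions],
                thresholds["cancer"],
                mode="all",
                **lesion_kw,
            ),
            "lesion_cs": per_lesion_eval(
                cases,
                [p.probs[2] for p in predictions],
                thresholds["aggressive"],
                mode="cs",
                significance_rule=config.significance_rule,
                **lesion_kw,
            ),
        }
        patient = per_patient_eval(
            cases,
            predictions,
            thresholds["aggressive"],
            config.significance_rule,
            config.closing_radii_mm,
            config.min_volume_mm3,
        )
        from .evaluation import case_ground_truth_lesions

        lesion_rows = []
        for case in cases:
            for l in case_ground_truth_lesions(
                case, config.closing_radii_mm, config.min_volume_mm3
            ):
                lesion_rows.append(
                    {
                        "case_id": case.case_id,
                        "lesion_id": l.lesion_id,
                        "volume_mm3": l.volume_mm3,
                        "aggressive_fraction": l.aggressive_fraction,
                        "significant_at_1pct": l.significant_at_1pct,
                        "significant_at_5pct": l.significant_at_5pct,
                    }
                )
        pd.DataFrame(
            lesion_rows,
            columns=[
                "case_id",
                "lesion_id",
                "volume_mm3",
                "aggressive_fraction",
                "significant_at_1pct",
                "significant_at_5pct",
            ],
        ).to_csv(stage / "lesions.csv", index=False)
        payload = {k: r.to_json_dict() for k, r in reports.items()}
        payload["patient"] = patient.as_dict()
        (stage / "reports.json").write_text(json.dumps(payload, indent=1))
        rows = []
        for name, rep in reports.items():
            for entry, vals in rep.entries.items():
                rows.append({"report": name, "entry": entry, **vals})
        rows.append({"report": "patient", "entry": config.significance_rule,
                     **patient.as_dict()})
        pd.DataFrame(rows).to_csv(stage / "reports.csv", index=False)
        _marker(out_dir, "evaluate").touch()
        _log_checksums(out_dir, "evaluate")
        log.info("stage evaluate done")

    return out_dir


def _read_cohort(cohort_dir: Path) -> list[StudyCase]:
    """Rehydrate phantom StudyCases from a cohort directory written by
    :func:`spcnet.phantom.generate_cohort`."""
    from .phantom import StudyCase as SC
    from .volume import read_volume

    cases = []
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    tags = dict(zip(manifest["case_id"], manifest["cohort_tag"]))
    for d in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        t2w = read_volume(d / "t2w.nii.gz")
        gm_vol = read_volume(d / "grade_map.nii.gz")
        gm = GradeMap(
            np.rint(gm_vol.data).astype(np.int8),
            gm_vol.in_plane_spacing_mm,
            gm_vol.slice_spacing_mm,
        )
        cases.append(
            SC(
                case_id=d.name,
                t2w=t2w,
                adc=read_volume(d / "adc.nii.gz"),
                prostate_mask=read_volume(d / "prostate_mask.nii.gz", is_mask=True),
                grade_map=gm,
                pathologist_mask=read_volume(d / "pathologist_mask.nii.gz", is_mask=True),
                radiologist_outline=read_volume(
                    d / "radiologist_outline.nii.gz", is_mask=True
                ),
                cohort_tag=str(tags[d.name]),
            )
        )
    return cases
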