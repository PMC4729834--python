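"""End-to-end orchestration of the label-free cell-cycle workflow.

``run_pipeline`` drives the full chain on one population —
simulate (optional) -> reshape/montage -> segment -> profile -> train and
cross-validate -> Watson fit — writing every intermediate artifact plus a
run report with artifact hashes, so identical (config, seed) runs are
byte-reproducible. ``demo_block_experiment`` is the synthetic analogue of a
mitotic-block study: train the DNA regressor on an untreated, stained
population, score an unstained blocked population, and compare the Watson
G2/M fractions of the two predicted DNA distributions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import boost, watson
from .features import feature_manifest, profile_population
from .montage import build_montages, split_montage
from .segment import SegmentationParams
from .synth import PopulationConfig, generate_population, write_population

logger = logging.getLogger("cytocycle")

__all__ = ["RunConfig", "run_pipeline", "demo_block_experiment", "prepare_profiles"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (one YAML file end to end)."""

    seed: int = 0
    outdir: str = "cytocycle_run"
    population: dict = field(default_factory=dict)  # PopulationConfig overrides
    tile: int = 55
    grid: int = 15
    segmentation: dict = field(default_factory=dict)  # SegmentationParams overrides
    cv_folds: int = 10
    lsboost: dict = field(default_factory=lambda: {"M": 150})
    rusboost: dict = field(default_factory=lambda: {"M": 60})
    n_bins: int = 128
    merge_post_prophase: bool = False
    write_images: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def prepare_profiles(records, tile: int = 55, seg_params: Optional[SegmentationParams] = None,
                     seed: int = 0, grid: int = 15):
    """Reshape through montages, split back, segment and profile.

    Running the montage build/split round trip (rather than reshaping each
    record directly) exercises the exact image path the batch workflow
    uses; the index map guarantees tiles come back to the right cells.
    Returns ``(features, stain, qc)`` as from
    :func:`~cytocycle.features.profile_population`.
    """
    channels = ["brightfield", "darkfield"] + (
        ["stain"] if all(r.stain is not None for r in records) else []
    )
    with warnings.catch_warnings():
        # darkfield speckle fills the frame; cropping it is by design
        warnings.simplefilter("ignore", UserWarning)
        montages = build_montages(records, grid=grid, tile=tile, channels=channels, seed=seed)
    tiles = {ch: dict(t for m in montages[ch] for t in split_montage(m)) for ch in channels}
    reshaped = []
    for rec in records:
        new = type(rec)(
            cell_id=rec.cell_id,
            brightfield=tiles["brightfield"][rec.cell_id],
            darkfield=tiles["darkfield"][rec.cell_id],
            stain=tiles["stain"][rec.cell_id] if "stain" in tiles else None,
            truth=rec.truth,
        )
        reshaped.append(new)
    return profile_population(reshaped, seg_params or SegmentationParams())


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic workflow and write a run report.

    Stages: simulate -> montage round trip -> segment -> profile ->
    10-fold CV of the DNA regression and the phase classification ->
    Watson fit of the measured stain histogram. Artifacts (feature table,
    truth, QC, models, report) are written under ``config.outdir``; the
    report carries a SHA-256 per artifact for reproducibility audits.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- simulate -------------------------------------------------------
    try:
        pop_cfg = PopulationConfig(seed=config.seed, **config.population)
        records, truth = generate_population(pop_cfg)
        if config.write_images:
            write_population(records, truth, out / "population")
        truth.to_csv(out / "truth.csv", index=False)
        report["stages"]["simulate"] = {"n_cells": len(records)}
        logger.info("simulated %d cells", len(records))
    except Exception as exc:  # noqa: BLE001 - stage attribution
        fail("simulate", exc)

    # --- montage/segment/profile ---------------------------------------
    try:
        seg_params = SegmentationParams(**config.segmentation)
        features, stain, qc = prepare_profiles(
            records, tile=config.tile, seg_params=seg_params, seed=config.seed, grid=config.grid
        )
        features.to_csv(out / "features.csv")
        qc.to_csv(out / "qc.csv", index=False)
        n_discard = int((~qc["kept"]).sum())
        report["stages"]["profile"] = {
            "n_kept": len(features),
            "n_discarded": n_discard,
            "discard_reasons": qc.loc[~qc["kept"], "reasons"].value_counts().to_dict(),
            "manifest_version": feature_manifest().version,
        }
        logger.info("profiled %d cells (%d discarded)", len(features), n_discard)
    except Exception as exc:  # noqa: BLE001
        fail("profile", exc)

    # --- machine learning ----------------------------------------------
    try:
        tt = truth.set_index("cell_id").loc[features.index]
        y_dna = stain.loc[features.index].to_numpy()
        reg_report = boost.cross_validate(
            features,
            y_dna,
            k=config.cv_folds,
            task="regression",
            seed=config.seed,
            params=boost.LSBoostParams(**config.lsboost),
        )
        labels = boost.merge_phase_labels(
            tt["phase"], merge_post_prophase=config.merge_post_prophase
        )
        clf_report = boost.cross_validate(
            features,
            labels,
            k=config.cv_folds,
            task="classification",
            seed=config.seed,
            params=boost.RUSBoostParams(**config.rusboost),
        )
        (out / "cv_regression.json").write_text(reg_report.to_json())
        (out / "cv_classification.json").write_text(clf_report.to_json())
        clf_report.confusion.to_csv(out / "confusion.csv")
        report["stages"]["learn"] = {
            "dna_pearson_r_mean": reg_report.mean,
            "dna_pearson_r_sd": reg_report.sd,
            "phase_tpr_mean": clf_report.mean,
            "phase_tpr_sd": clf_report.sd,
        }
        logger.info("10-fold CV: DNA r=%.3f, TPR=%s", reg_report.mean, clf_report.mean)
    except Exception as exc:  # noqa: BLE001
        fail("learn", exc)

    # --- cell-cycle fractions ------------------------------------------
    try:
        fit = watson.watson_fractions(y_dna, n_bins=config.n_bins)
        fit.components_frame().to_csv(out / "watson_components.csv", index=False)
        report["stages"]["cellcycle"] = {
            "fractions": fit.fractions,
            "cv_g1": fit.cv_g1,
            "warnings": list(fit.warnings),
        }
    except Exception as exc:  # noqa: BLE001
        fail("cellcycle", exc)

    # --- report with artifact hashes ------------------------------------
    report["artifacts"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv")) if p.is_file()
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def demo_block_experiment(
    seed: int = 0,
    n_cells: int = 2000,
    block_shift: float = 0.15,
    lsboost_params: Optional[boost.LSBoostParams] = None,
    rusboost_params: Optional[boost.RUSBoostParams] = None,
    n_bins: int = 128,
    with_classifier: bool = True,
    population_overrides: Optional[dict] = None,
) -> dict:
    """Synthetic mitotic-block experiment on predicted DNA content.

    Generates an untreated stained population and a blocked *unstained*
    population, trains the DNA regressor on the untreated cells (stain as
    ground truth), predicts the DNA content of both populations with that
    single model, Watson-fits the two predicted histograms and reports the
    G2/M shift. Optionally also cross-validates the phase classifier on
    the untreated cells with metaphase/anaphase/telophase merged, the
    grouping appropriate when late mitotic phases are sparse.
    """
    overrides = population_overrides or {}
    cfg_ctrl = PopulationConfig(n_cells=n_cells, seed=seed, **overrides)
    cfg_block = PopulationConfig(
        n_cells=n_cells, seed=seed + 1, block_shift=block_shift, with_stain=False, **overrides
    )
    rec_c, truth_c = generate_population(cfg_ctrl)
    rec_b, truth_b = generate_population(cfg_block)

    feats_c, stain_c, _ = prepare_profiles(rec_c, seed=seed)
    feats_b, _, _ = prepare_profiles(rec_b, seed=seed + 1)

    y = stain_c.loc[feats_c.index].to_numpy()
    params = lsboost_params or boost.LSBoostParams(M=100)
    # control predictions are out-of-fold (10-fold CV): in-sample
    # predictions are artificially sharp and would bias the control
    # fractions relative to the genuinely out-of-sample blocked arm
    reg = boost.cross_validate(
        feats_c, y, k=10, task="regression", seed=seed, params=params
    )
    pred_c = reg.predictions.to_numpy(float)
    model = boost.fit_lsboost(feats_c, y, params, seed=seed,
                              manifest_version=feature_manifest().version)
    pred_b = model.predict(feats_b)

    fit_c = watson.watson_fractions(pred_c, n_bins=n_bins, source="predicted")
    fit_b = watson.watson_fractions(pred_b, n_bins=n_bins, source="predicted")
    delta = {ph: fit_b.fractions[ph] - fit_c.fractions[ph] for ph in ("G1", "S", "G2M")}

    result = {
        "control_fractions": fit_c.fractions,
        "blocked_fractions": fit_b.fractions,
        "delta": delta,
        "delta_g2m": delta["G2M"],
        "block_shift": block_shift,
        "n_cells": n_cells,
        "seed": seed,
    }
    if with_classifier:
        labels = boost.merge_phase_labels(
            truth_c.set_index("cell_id").loc[feats_c.index, "phase"], merge_post_prophase=True
        )
        clf = boost.cross_validate(
            feats_c,
            labels,
            k=10,
            task="classification",
            seed=seed,
            params=rusboost_params or boost.RUSBoostParams(M=60),
        )
        result["phase_tpr_mean"] = clf.mean
        result["phase_tpr_sd"] = clf.sd
    return result
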