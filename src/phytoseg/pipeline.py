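"""End-to-end orchestration of the detection pipeline.

A run executes: feature stack -> feature selection -> per-arm segmentation
and learning -> metric tables. The four experimental arms are

* ``single_index_ths`` — each selected index segmented directly by each
  thresholder;
* ``bwo_index_ths`` — a BWO-fused index learned per thresholder, then
  segmented by it;
* ``majority_vote`` — plain per-pixel majority over the nine base masks;
* ``bwo_weighted_vote`` — BWO-trained integer replication vote over the nine
  base masks.

Every random draw flows from one top-level seed, fanned out to per-stage
child seeds by stable hashing of the stage name, so reconfiguring one stage
does not perturb the draws of another.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import metrics
from .ensemble import BWOVoteEnsemble, majority_vote
from .fusion import FusedIndexSegmenter
from .indices import ALL_FEATURES, compute_stack
from .io import BinaryMask, Region, read_ground_truth, read_rgb, write_mask
from .selection import build_feature_table, ccia_select, correlation_matrix, rf_importance
from .synthetic import SceneConfig, generate_scene
from .thresholding import METHODS, ThresholdParams, segment

logger = logging.getLogger(__name__)

ARMS = ("single_index_ths", "bwo_index_ths", "majority_vote", "bwo_weighted_vote")
VALID_N = (5, 10, 15, 20, 27)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON round-trippable)."""

    scene_path: str | None = None
    truth_path: str | None = None
    scene: SceneConfig | None = None  # synthetic scene when no paths given
    region: tuple[int, int, int, int] = (0, 0, 128, 128)
    selection: str = "rfvi"  # "rfvi" | "ccia"
    n_features: int = 5
    methods: tuple[str, ...] = METHODS
    arms: tuple[str, ...] = ARMS
    bwo_pop: int = 50
    bwo_iters: int = 50
    max_rows: int = 20000
    rf_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features not in VALID_N:
            raise ValueError(f"n_features must be one of {VALID_N}")
        if self.selection not in ("rfvi", "ccia"):
            raise ValueError("selection must be 'rfvi' or 'ccia'")
        bad = [a for a in self.arms if a not in ARMS]
        if bad or not self.arms:
            raise ValueError(f"invalid arms {bad}; choose from {ARMS}")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown thresholders {bad}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "scene" in raw and raw["scene"] is not None:
            raw["scene"] = SceneConfig(**raw["scene"])
        for key in ("region", "methods", "arms"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (seed ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def run(config: RunConfig, outdir) -> pd.DataFrame:
    """Execute all configured arms; write masks, models, metrics and a
    manifest under ``outdir``; return the metrics table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.scene_path is not None:
        logger.info("loading scene %s", config.scene_path)
        image = read_rgb(config.scene_path)
        truth = read_ground_truth(config.truth_path)
    else:
        scene_cfg = config.scene or SceneConfig(seed=child_seed(config.seed, "scene"))
        if scene_cfg.seed is None:
            scene_cfg = dataclasses.replace(scene_cfg, seed=child_seed(config.seed, "scene"))
        logger.info("generating synthetic scene %dx%d", scene_cfg.height, scene_cfg.width)
        image, truth = generate_scene(scene_cfg)
    region = Region(*config.region)
    region.check_within(image.shape)

    # --- stack and selection ---------------------------------------------
    logger.info("computing %d-feature stack", len(ALL_FEATURES))
    stack = compute_stack(image)
    table = build_feature_table(
        stack, truth, region, max_rows=config.max_rows,
        seed=child_seed(config.seed, "table"),
    )
    if config.selection == "rfvi":
        ranker = rf_importance(table, trees=config.rf_trees,
                               seed=child_seed(config.seed, "rf"))
        selected = list(ranker.top_k(config.n_features))
        pd.DataFrame(
            {"feature": ranker.ranking_,
             "importance": sorted(ranker.importances_, reverse=True)}
        ).to_csv(outdir / "importance.csv", index=False)
    else:
        matrix = correlation_matrix(table)
        selected, trace = ccia_select(matrix, table.names, k=config.n_features)
        selected = list(selected)
        pd.DataFrame(trace, columns=["dropped", "partner", "abs_rho"]).to_csv(
            outdir / "ccia_trace.csv", index=False
        )
    logger.info("selected features (%s): %s", config.selection, selected)

    sub = stack.subset(selected)
    truth_region = BinaryMask(truth.array[region.slices])

    rows: list[dict] = []

    def add_row(arm: str, method: str, pred_full: BinaryMask, extra=None):
        cm = metrics.confusion(pred_full, truth)
        row = {"arm": arm, "method": method, **metrics.all_metrics(cm)}
        if extra:
            row.update(extra)
        rows.append(row)

    # --- arm: single-index thresholding ----------------------------------
    if "single_index_ths" in config.arms:
        for name in selected:
            plane = stack.plane(name)
            for m in config.methods:
                pred = segment(plane, ThresholdParams(method=m))
                add_row("single_index_ths", m, pred, {"feature": name})

    # --- arm: per-thresholder fused index ---------------------------------
    fused_masks_full: dict[str, BinaryMask] = {}
    fused_masks_region: dict[str, BinaryMask] = {}
    need_votes = bool({"majority_vote", "bwo_weighted_vote"} & set(config.arms))
    if "bwo_index_ths" in config.arms or need_votes:
        for m in config.methods:
            logger.info("fitting fused index for %s", m)
            model = FusedIndexSegmenter(
                features=selected, method=m, pop_size=config.bwo_pop,
                iters=config.bwo_iters,
                random_state=child_seed(config.seed, f"fuse-{m}"),
            )
            model.fit(sub, truth, region)
            model.save(outdir / f"fused_{m}.json")
            pred = model.predict(stack.subset(selected))
            fused_masks_full[m] = pred
            fused_masks_region[m] = BinaryMask(pred.array[region.slices])
            if "bwo_index_ths" in config.arms:
                add_row("bwo_index_ths", m, pred,
                        {"training_csi": model.training_csi_})
            write_mask(pred, outdir / f"mask_bwo_{m}.png")

    # --- voting arms -------------------------------------------------------
    if need_votes:
        base_full = [fused_masks_full[m] for m in config.methods]
        base_region = [fused_masks_region[m] for m in config.methods]
        if "majority_vote" in config.arms:
            pred = majority_vote(base_full)
            add_row("majority_vote", "all", pred)
            write_mask(pred, outdir / "mask_majority.png")
        if "bwo_weighted_vote" in config.arms:
            ens = BWOVoteEnsemble(
                pop_size=config.bwo_pop, iters=config.bwo_iters,
                random_state=child_seed(config.seed, "ensemble"),
            )
            ens.fit(base_region, truth_region)
            ens.save(outdir / "ensemble.json")
            pred = ens.predict(base_full)
            add_row("bwo_weighted_vote", "all", pred,
                    {"training_csi": ens.training_csi_})
            write_mask(pred, outdir / "mask_ensemble.png")

    table_df = pd.DataFrame(rows)
    table_df.to_csv(outdir / "metrics.csv", index=False)
    manifest = {
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "selected_features": selected,
        "n_rows": len(table_df),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("wrote %d metric rows to %s", len(table_df), outdir)
    return table_df
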