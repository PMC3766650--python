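"""End-to-end orchestration: synthetic cohorts -> preprocessing -> coherency
and SHG metrics -> group statistics, reproducing the four quantitative
contrasts between wild-type (WT) and MMP13-knockout (KO) tumor boundaries:
higher collagen I IF, lower coherency, higher normalized B_SHG and lower F/B
in KO.

Every run is fully determined by its configuration (one global seed fans out
to per-FOV seeds via a spawn-key counter scheme).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import coherency as coh
from . import ratiometrics as rm
from . import stacks as st
from . import stats as gs
from . import synthetic as syn

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Image-analysis parameters applied identically to all groups."""

    gradient_sigma_px: float = 1.0
    window_sigma_px: float = 2.0
    if_threshold_mode: str = "quantile:0.95"
    fb_threshold_mode: str = "quantile:0.95"
    background_mode: str = "scalar"  # "scalar" blank mean | "image" closed-shutter MIP


@dataclass
class RunConfig:
    """Full replication-run configuration; serializable alongside outputs."""

    seed: int = 1
    n_wt: int = 16
    n_ko: int = 14
    wt_overrides: Dict[str, object] = field(default_factory=dict)
    ko_overrides: Dict[str, object] = field(default_factory=dict)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: Optional[str] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _subtract(image: st.ProjectedImage, blank: st.ZStack, mode: str) -> st.ProjectedImage:
    if mode == "image":
        return st.subtract_background_image(image, st.max_project(blank))
    background = st.estimate_background(st.max_project(blank))
    return st.subtract_background(image, background)


def process_bundle(
    bundle: syn.SceneBundle,
    cfg: AnalysisConfig,
    fov_id: str = "",
    group: str = "",
    animal: str = "",
) -> rm.ChannelPairMetrics:
    """All per-FOV metrics for an in-memory scene bundle.

    Projects each channel, subtracts the blank background, then computes mean
    IF intensity, mean coherency of the IF image, normalized B_SHG (IF-mask
    gated) and the mean F/B ratio (B_SHG-mask gated).
    """
    if_img = _subtract(st.max_project(bundle.if_stack), bundle.blank_stack, cfg.background_mode)
    b_img = _subtract(st.max_project(bundle.bshg_stack), bundle.blank_stack, cfg.background_mode)
    f_img = None
    if bundle.fshg_stack is not None:
        f_img = _subtract(st.max_project(bundle.fshg_stack), bundle.blank_stack, cfg.background_mode)

    metrics = rm.compute_pair_metrics(
        if_img, b_img, f_img,
        if_threshold_mode=cfg.if_threshold_mode,
        fb_threshold_mode=cfg.fb_threshold_mode,
        fov_id=fov_id, group=group, animal=animal,
    )
    tensor = coh.structure_tensor(if_img, cfg.gradient_sigma_px, cfg.window_sigma_px)
    metrics.mean_coherency = coh.coherency_map(tensor).mean_c
    logger.info(
        "fov=%s group=%s mean_if=%.3f mean_c=%.4f nbshg=%s fb=%s",
        fov_id, group, metrics.mean_if, metrics.mean_coherency,
        metrics.normalized_bshg, metrics.mean_fb_ratio,
    )
    return metrics


def cohort_metrics(
    group: str,
    n_fovs: int,
    seed: int,
    cfg: AnalysisConfig,
    include_fshg: bool = True,
    **overrides,
) -> pd.DataFrame:
    """Simulate one cohort and measure every FOV; one row per FOV."""
    bundles = syn.make_cohort(group, n_fovs, seed, include_fshg=include_fshg, **overrides)
    rows = []
    for i, bundle in enumerate(bundles):
        m = process_bundle(bundle, cfg, fov_id=f"{group}_{i:03d}", group=group,
                           animal=f"{group}_a{i % 4}")
        rows.append(dataclasses.asdict(m))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Manifest-driven processing (file-based path used by the CLI and scripts)
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["fov_id", "group", "animal", "slide", "channel", "path"]


def write_cohort(
    bundles: List[syn.SceneBundle],
    out_dir: Path,
    cohort: str,
    animal_cycle: int = 4,
) -> pd.DataFrame:
    """Write a cohort's stacks as TIFFs plus JSON sidecars; returns manifest
    rows. One blank acquisition per slide (= cohort) serves all its FOVs.

    Filenames follow ``{cohort}/{fov:03d}_{channel}.tif``.
    """
    out_dir = Path(out_dir)
    rows = []
    for i, bundle in enumerate(bundles):
        fov_id = f"{cohort}_{i:03d}"
        animal = f"{cohort}_a{i % animal_cycle}"
        stack_map = {"IF": bundle.if_stack, "BSHG": bundle.bshg_stack}
        if bundle.fshg_stack is not None:
            stack_map["FSHG"] = bundle.fshg_stack
        if i == 0:
            stack_map["BLANK"] = bundle.blank_stack
        for name, stack in stack_map.items():
            path = out_dir / cohort / f"{i:03d}_{name}.tif"
            st.write_stack(stack, path)
            rows.append(dict(fov_id=fov_id, group=cohort, animal=animal,
                             slide=cohort, channel=name, path=str(path)))
        sidecar = out_dir / cohort / f"{i:03d}_params.json"
        sidecar.write_text(json.dumps({
            "params": bundle.params.to_dict(),
            "truth_summary": {
                "n_fiber_pixels": int(bundle.truth.fiber_mask.sum()),
                "per_fiber_width_um": bundle.truth.per_fiber_width_um,
                "per_fiber_orientation_rad": bundle.truth.per_fiber_orientation_rad,
            },
        }, indent=1))
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def metrics_from_manifest(manifest: pd.DataFrame, cfg: AnalysisConfig,
                          pixel_size_um: float = syn.DEFAULT_PIXEL_SIZE_UM) -> pd.DataFrame:
    """Per-FOV metrics from a file manifest.

    The manifest maps each FOV to its channel TIFFs; one BLANK row per slide
    provides the background for all FOVs of that slide. FOVs with missing
    channels are reported with the corresponding metric absent; the pipeline
    continues.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")

    blanks: Dict[str, st.ZStack] = {}
    for slide, sub in manifest[manifest["channel"] == "BLANK"].groupby("slide"):
        blanks[slide] = st.read_stack(sub.iloc[0]["path"], st.Channel.BLANK, pixel_size_um)

    rows = []
    fov_rows = manifest[manifest["channel"] != "BLANK"]
    for fov_id, sub in fov_rows.groupby("fov_id", sort=True):
        slide = sub.iloc[0]["slide"]
        if slide not in blanks:
            logger.error("fov=%s: no BLANK acquisition for slide %s; skipped", fov_id, slide)
            continue
        blank = blanks[slide]
        paths = dict(zip(sub["channel"], sub["path"]))
        try:
            if_stack = st.read_stack(paths["IF"], st.Channel.IF, pixel_size_um)
            b_stack = st.read_stack(paths["BSHG"], st.Channel.BSHG, pixel_size_um)
        except (KeyError, st.StackFormatError) as exc:
            logger.error("fov=%s: unreadable required channel (%s); skipped", fov_id, exc)
            continue
        f_stack = None
        if "FSHG" in paths:
            try:
                f_stack = st.read_stack(paths["FSHG"], st.Channel.FSHG, pixel_size_um)
            except st.StackFormatError as exc:
                logger.error("fov=%s: unreadable FSHG (%s); F/B absent", fov_id, exc)

        bundle = syn.SceneBundle(
            if_stack=if_stack, bshg_stack=b_stack, fshg_stack=f_stack,
            blank_stack=blank, truth=None, params=None,
        )
        m = process_bundle(bundle, cfg, fov_id=fov_id,
                           group=sub.iloc[0]["group"], animal=sub.iloc[0]["animal"])
        rows.append(dataclasses.asdict(m))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Replication run
# ---------------------------------------------------------------------------

#: metric -> expected direction of the KO - WT difference
EXPECTED_DIRECTIONS = {
    "mean_if": "greater",
    "mean_coherency": "less",
    "normalized_bshg": "greater",
    "mean_fb_ratio": "less",
}


def run_replication(config: RunConfig) -> dict:
    """Simulate WT and KO cohorts, measure every FOV, and test the four
    group contrasts.

    Returns a JSON-serializable report with per-group summaries, unpaired
    t-test and Mann-Whitney results per metric, and a direction flag per
    contrast. If the two presets resolve to identical scene parameters the
    report flags a null contrast instead of asserting directions.
    """
    cfg = config.analysis
    wt = cohort_metrics("WT", config.n_wt, config.seed, cfg, **config.wt_overrides)
    ko = cohort_metrics("KO", config.n_ko, config.seed + 1, cfg, **config.ko_overrides)

    wt_params = syn.preset_params("WT", seed=0, **config.wt_overrides)
    ko_params = syn.preset_params("KO", seed=0, **config.ko_overrides)
    null_contrast = wt_params == ko_params

    report: dict = {
        "config": config.to_dict(),
        "unit_of_analysis": "FOV",
        "null_contrast": bool(null_contrast),
        "metrics": {},
    }
    all_directions_hold = True
    for metric, direction in EXPECTED_DIRECTIONS.items():
        a = wt[metric].dropna().tolist()
        b = ko[metric].dropna().tolist()
        s_wt, s_ko = gs.summarize(a, "WT"), gs.summarize(b, "KO")
        t_res = gs.t_unpaired(a, b)
        mw_res = gs.mann_whitney(a, b)
        delta = s_ko.mean - s_wt.mean
        holds = (delta > 0) if direction == "greater" else (delta < 0)
        all_directions_hold &= bool(holds and t_res.p_value < 0.05)
        report["metrics"][metric] = {
            "WT": {"n": s_wt.n, "mean": s_wt.mean, "sem": s_wt.sem},
            "KO": {"n": s_ko.n, "mean": s_ko.mean, "sem": s_ko.sem},
            "expected_direction_ko_vs_wt": direction,
            "direction_holds": bool(holds),
            "t_unpaired": {"statistic": t_res.statistic, "p_value": t_res.p_value, "df": t_res.df},
            "mann_whitney": {"statistic": mw_res.statistic, "p_value": mw_res.p_value,
                             "method": mw_res.detail},
        }
    report["all_directions_hold"] = bool(all_directions_hold and not null_contrast)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "replication_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        pd.concat([wt, ko], ignore_index=True).to_csv(out / "fov_metrics.csv", index=False)
        (out / "run_config.json").write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))
    return report
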