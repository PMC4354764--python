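"""End-to-end pipeline: simulate → segment → quantify → evaluate.

``run_pipeline`` executes the whole chain for a simulated (or pre-loaded)
cohort and writes the cohort table, one ROC report per kinetic parameter
(both pathways), and a text summary of the curve-type malignancy rule.
All randomness flows from one seed, so a rerun with the same config
produces byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .errors import PipelineError, TiccadError
from .evaluation import (
    BENIGN,
    MALIGNANT,
    LabeledScores,
    confusion_metrics,
    dice_coefficient,
    malignancy_from_type,
    optimal_cutoff,
    roc_row,
)
from .kinetics import PARAM_NAMES, compute_params, extract_mean_curve, pixelwise_maps
from .phantom import PhantomSpec, SimulatedCase, simulate_cohort
from .segmentation import SegmentationConfig, segment_lesion

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run; every key has a default."""

    n_benign: int = 30
    n_malignant: int = 30
    seed: int = 42
    sigma: float = 0.05
    jitter: float = 0.05
    noise: str = "gaussian"
    background_fraction: float = 0.2
    post_phase_index: int = 3
    se_size: int = 4
    histogram_bins: int = 256
    slope_lower: float = -10.0
    slope_upper: float = 10.0
    slope_cutoff_override: float | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a ``key = value`` config file; unknown keys are rejected."""
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise TiccadError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise TiccadError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float) or default is None:
                kwargs[key] = float(val) if val.lower() != "none" else None
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(
            sigma=self.sigma,
            jitter=self.jitter,
            noise=self.noise,
            background_fraction=self.background_fraction,
        )

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            post_phase_index=self.post_phase_index,
            se_size=self.se_size,
            histogram_bins=self.histogram_bins,
        )


def process_case(case: SimulatedCase, cfg: RunConfig) -> tuple[list[dict], float]:
    """Segment one case and compute both parameter pathways.

    Returns the two cohort rows (mean-curve and region-mean pathways) and
    the Dice overlap of the segmentation against the truth mask.
    """
    roi_mask = tio.rasterize_roi(case.roi, case.series.shape)
    lesion = segment_lesion(case.series, roi_mask, cfg.segmentation_config())
    dice = dice_coefficient(lesion.data, case.lesion_mask.data)
    mean_curve = extract_mean_curve(case.series, lesion)
    p_mean = compute_params(mean_curve, cfg.slope_lower, cfg.slope_upper)
    maps = pixelwise_maps(case.series, lesion, cfg.slope_lower, cfg.slope_upper)
    rows = []
    for pathway, params in (("mean_curve", p_mean), ("region_mean", maps.region_means)):
        row = {"case_id": case.series.case_id, "label": case.label, "pathway": pathway}
        row.update(params.as_dict())
        row["tic_type"] = params.tic_type
        rows.append(row)
    return rows, dice


def evaluate_cohort(cohort: pd.DataFrame, param: str, pathway: str):
    """ROC analysis of one kinetic parameter for one pathway."""
    sub = cohort[cohort["pathway"] == pathway]
    ls = LabeledScores.from_arrays(sub[param].to_numpy(float), sub["label"].to_numpy())
    return optimal_cutoff(ls)


def rule_metrics(cohort: pd.DataFrame, pathway: str):
    """Confusion metrics of the curve-type rule (II/III → malignant)."""
    sub = cohort[cohort["pathway"] == pathway]
    defined = sub[sub["tic_type"].notna()]
    n_undefined = len(sub) - len(defined)
    if n_undefined:
        logger.warning("%d cases with undefined TIC type excluded", n_undefined)
    calls = [malignancy_from_type(t) for t in defined["tic_type"]]
    return confusion_metrics(calls, defined["label"].to_numpy())


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run (files are written separately)."""

    cohort: pd.DataFrame
    dice: dict[str, float]
    roc: dict[tuple[str, str], object]
    rule: dict[str, object]
    n_failed: int

    @property
    def mean_dice(self) -> float:
        return float(np.mean(list(self.dice.values())))


def run_cohort(cfg: RunConfig, cases: list[SimulatedCase] | None = None) -> PipelineResult:
    """Run segmentation + quantification + evaluation over a cohort."""
    if cases is None:
        cases = simulate_cohort(
            cfg.n_benign, cfg.n_malignant, seed=cfg.seed, pspec=cfg.phantom_spec()
        )
    rows: list[dict] = []
    dice: dict[str, float] = {}
    n_failed = 0
    for case in cases:
        try:
            case_rows, d = process_case(case, cfg)
        except TiccadError as exc:
            logger.warning("case %s skipped: %s", case.series.case_id, exc)
            n_failed += 1
            continue
        rows.extend(case_rows)
        dice[case.series.case_id] = d
    if not rows:
        raise PipelineError("every case failed")
    cohort = pd.DataFrame(rows, columns=list(tio.COHORT_COLUMNS))
    roc = {
        (param, pathway): evaluate_cohort(cohort, param, pathway)
        for pathway in ("mean_curve", "region_mean")
        for param in PARAM_NAMES
    }
    rule = {pathway: rule_metrics(cohort, pathway) for pathway in ("mean_curve", "region_mean")}
    return PipelineResult(cohort=cohort, dice=dice, roc=roc, rule=rule, n_failed=n_failed)


def _summary_text(cfg: RunConfig, result: PipelineResult) -> str:
    lines = []
    lines.append("ROC analysis per kinetic parameter")
    for pathway in ("mean_curve", "region_mean"):
        lines.append(f"\n[{pathway}]")
        header = f"{'param':<10}{'AUC':>7}{'SE':>8}{'95% CI':>17}{'criterion':>14}{'sens%':>8}{'spec%':>8}{'acc%':>8}"
        lines.append(header)
        for param in PARAM_NAMES:
            r = result.roc[(param, pathway)]
            crit = ("> " if r.direction == "gt" else "<= ") + f"{r.cutoff:.4g}"
            lines.append(
                f"{param:<10}{r.auc:>7.3f}{r.se:>8.4f}"
                f"{'(' + format(r.ci95[0], '.3f') + ',' + format(r.ci95[1], '.3f') + ')':>17}"
                f"{crit:>14}{r.sensitivity:>8.2f}{r.specificity:>8.2f}{r.accuracy:>8.2f}"
            )
    lines.append("\nCurve-type rule (type II/III called malignant)")
    for pathway in ("mean_curve", "region_mean"):
        cm = result.rule[pathway]
        lines.append(
            f"{pathway:<12} sensitivity {cm.sensitivity:.2f}%  "
            f"specificity {cm.specificity:.2f}%  accuracy {cm.accuracy:.2f}%"
        )
    if cfg.slope_cutoff_override is not None:
        c = cfg.slope_cutoff_override
        sub = result.cohort[result.cohort["pathway"] == "mean_curve"]
        calls = np.where(sub["si_slope"].to_numpy(float) <= c, MALIGNANT, BENIGN)
        cm = confusion_metrics(calls, sub["label"].to_numpy())
        lines.append(
            f"slope<= {c:g} rule (mean_curve): sensitivity {cm.sensitivity:.2f}%  "
            f"specificity {cm.specificity:.2f}%  accuracy {cm.accuracy:.2f}%"
        )
    lines.append(f"\nmean segmentation Dice vs truth: {result.mean_dice:.4f}")
    lines.append(f"cases failed: {result.n_failed}")
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: RunConfig, out_dir: str | Path, cases=None) -> PipelineResult:
    """Run the full chain and write cohort.csv, roc_<param>.csv and summary.txt."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = run_cohort(cfg, cases=cases)
    tio.write_cohort(result.cohort, out_dir / "cohort.csv")
    for param in PARAM_NAMES:
        df = pd.DataFrame(
            [
                roc_row(param, pathway, result.roc[(param, pathway)])
                for pathway in ("mean_curve", "region_mean")
            ]
        )
        tio.write_roc(df, out_dir / f"roc_{param}.csv")
    (out_dir / "summary.txt").write_text(_summary_text(cfg, result))
    return result
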