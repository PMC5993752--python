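"""End-to-end orchestration: configuration, analysis, reporting, selftest.

``analyze`` chains the stages — channel separation, matched-filter
segmentation of the green channel, ODR computation, segment extraction,
diameter/tortuosity measurement, artery/vein classification, AVR — and
returns a report whose every number is traceable to the stage parameters
recorded in its provenance.  ``end_to_end_selftest`` generates a synthetic
scene with known truth, analyses it, and scores mask Dice, label accuracy,
and diameter/tortuosity/AVR recovery against the generator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .av import VesselSegment, classify_av, extract_segments, odr_map
from .channels import FundusImage, read_image, write_image
from .errors import DegenerateInputError, IncompleteReportError
from .metrics import AVReport, avr, measure_segments
from .segmentation import (
    DEFAULT_SIGMAS,
    SegmentationParams,
    VesselMask,
    segment_vessels,
)
from .synthetic import (
    LABEL_ARTERY,
    LABEL_BACKGROUND,
    LABEL_VEIN,
    GroundTruth,
    RenderSpec,
    VesselTreeSpec,
    generate_vessel_tree,
    render_fundus,
)

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "SelftestResult",
    "analyze",
    "end_to_end_selftest",
    "dice_coefficient",
    "label_accuracy",
]


@dataclass
class PipelineConfig:
    """Every stage parameter of the pipeline, round-trippable through YAML."""

    pixel_pitch_um: float = 16.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    min_segment_length_px: int = 30
    odr_threshold: str | float = "otsu"  # "otsu" or a fixed float
    g_floor: float = 1.0
    refine_by_width: bool = True
    pairing_radius_px: float = 40.0
    parallel_tol_deg: float = 30.0
    refine_margin: float = 0.15
    length_weighted_avr: bool = False
    rounding_decimals: int = 1
    seed: int = 0
    tree: VesselTreeSpec = field(default_factory=VesselTreeSpec)
    render: RenderSpec = field(default_factory=RenderSpec)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segmentation"]["sigmas"] = [float(s) for s in d["segmentation"]["sigmas"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "segmentation" in d:
            seg = dict(d["segmentation"])
            if "sigmas" in seg:
                seg["sigmas"] = tuple(float(s) for s in seg["sigmas"])
            d["segmentation"] = SegmentationParams(**seg)
        if "tree" in d:
            t = dict(d["tree"])
            for k in ("artery_diameter_range_um", "vein_diameter_range_um"):
                if k in t:
                    t[k] = tuple(t[k])
            d["tree"] = VesselTreeSpec(**t)
        if "render" in d:
            r = dict(d["render"])
            for k in ("background_rgb_means", "artery_rgb", "vein_rgb"):
                if k in r:
                    r[k] = tuple(r[k])
            d["render"] = RenderSpec(**r)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class AnalysisReport:
    """Result of one end-to-end analysis run."""

    status: str  # "ok" | "no-vessels" | "single-class"
    av_report: AVReport | None
    segments: list[VesselSegment]
    odr_threshold: float | None
    provenance: dict
    mask: VesselMask | None = None

    def segments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "segment_id": s.segment_id,
                    "label": s.label,
                    "mean_odr": s.mean_odr,
                    "mean_diameter_um": s.mean_diameter_um,
                    "tortuosity": s.tortuosity,
                    "n_centerline_px": s.n_points,
                }
                for s in self.segments
            ]
        )

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "av_report": self.av_report.to_dict() if self.av_report else None,
            "odr_threshold": self.odr_threshold,
            "n_segments": len(self.segments),
            "segments": self.segments_frame().to_dict(orient="records"),
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def analyze(
    image: FundusImage | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Run the full quantitative analysis on a fundus image.

    Accepts an in-memory :class:`FundusImage` or a path (the configured
    pixel pitch is attached when reading from disk).  When ``out_dir`` is
    given, writes mask PNG, A/V overlay PNG, per-segment CSV and the
    report JSON there.  Deterministic for a fixed image + config.
    """
    config = config or PipelineConfig()
    if not isinstance(image, FundusImage):
        image = read_image(image, pixel_pitch_um=config.pixel_pitch_um)

    try:
        mask = segment_vessels(image.green, config.segmentation)
    except DegenerateInputError:
        # featureless image (e.g. constant): nothing to segment
        mask = VesselMask(
            pixels=np.zeros(image.shape, dtype=bool),
            provenance={"threshold_method": "otsu", "threshold_value": None,
                        "note": "degenerate input, no vessels found"},
        )
    provenance = {
        "software_version": __version__,
        "pixel_pitch_um": image.pixel_pitch_um,
        "segmentation": dict(mask.provenance),
        "min_segment_length_px": config.min_segment_length_px,
        "g_floor": config.g_floor,
        "odr_threshold_mode": config.odr_threshold,
        "rounding_decimals": config.rounding_decimals,
    }

    segments = extract_segments(mask, min_length_px=config.min_segment_length_px)
    status = "ok"
    av_report = None
    threshold = None
    if not segments:
        status = "no-vessels"
    else:
        odr = odr_map(image.red, image.green, mask, g_floor=config.g_floor)
        measure_segments(segments, mask, image.pixel_pitch_um)
        segments, threshold = classify_av(
            segments,
            odr,
            threshold=config.odr_threshold,
            refine=config.refine_by_width,
            pairing_radius_px=config.pairing_radius_px,
            parallel_tol_deg=config.parallel_tol_deg,
            refine_margin=config.refine_margin,
        )
        try:
            av_report = avr(
                segments,
                rounding_decimals=config.rounding_decimals,
                length_weighted=config.length_weighted_avr,
            )
        except IncompleteReportError:
            status = "single-class"
    provenance["odr_threshold_value"] = threshold

    report = AnalysisReport(
        status=status,
        av_report=av_report,
        segments=segments,
        odr_threshold=threshold,
        provenance=provenance,
        mask=mask,
    )
    if out_dir is not None:
        _write_artifacts(report, image, mask, Path(out_dir))
    return report


_LABEL_COLORS = {"artery": (255, 0, 0), "vein": (0, 255, 255), "unknown": (255, 255, 0)}


def _write_artifacts(
    report: AnalysisReport, image: FundusImage, mask: VesselMask, out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    import imageio.v3 as iio

    iio.imwrite(out_dir / "mask.png", (mask.pixels * np.uint8(255)))
    overlay = np.clip(image.pixels, 0, 255).astype(np.uint8).copy()
    for seg in report.segments:
        color = _LABEL_COLORS[seg.label]
        overlay[seg.centerline[:, 0], seg.centerline[:, 1]] = color
    iio.imwrite(out_dir / "overlay.png", overlay)
    report.segments_frame().to_csv(out_dir / "segments.csv", index=False)
    (out_dir / "report.json").write_text(report.to_json())


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def label_accuracy(segments: list[VesselSegment], truth: GroundTruth) -> float:
    """Fraction of classified segments whose label matches the ground truth.

    Each extracted segment is matched to the truth by the majority
    ground-truth class along its centerline; segments whose centerline
    falls mostly on background (spurious detections) are excluded.
    """
    codes = {LABEL_ARTERY: "artery", LABEL_VEIN: "vein"}
    n_ok = n_tot = 0
    for seg in segments:
        gt = truth.label_map[seg.centerline[:, 0], seg.centerline[:, 1]]
        on_vessel = gt != LABEL_BACKGROUND
        if on_vessel.mean() < 0.5:
            continue
        counts = np.bincount(gt[on_vessel], minlength=3)
        true_label = codes[int(np.argmax(counts[1:])) + 1]
        n_tot += 1
        n_ok += seg.label == true_label
    return n_ok / n_tot if n_tot else float("nan")


@dataclass
class SelftestResult:
    passed: bool
    metrics: dict
    failures: list[str]
    thresholds: dict


# recovery thresholds the selftest asserts on a default synthetic scene
SELFTEST_THRESHOLDS = {
    "dice_min": 0.7,
    "label_accuracy_min": 0.95,
    "diameter_rel_err_max": 0.10,
    "tortuosity_rel_err_max": 0.05,
    "avr_abs_err_max": 0.08,
}


def end_to_end_selftest(
    seed: int = 1, config: PipelineConfig | None = None
) -> SelftestResult:
    """Simulate a default scene, analyse it, and score recovery vs truth."""
    config = config or PipelineConfig()
    config.segmentation.sigmas = tuple(config.segmentation.sigmas)
    tree = dataclasses.replace(config.tree, seed=seed)
    render = dataclasses.replace(config.render, seed=seed + 1)
    image, truth = render_fundus(generate_vessel_tree(tree), render)
    report = analyze(image, config)

    failures: list[str] = []
    metrics: dict = {"status": report.status, "n_segments": len(report.segments)}

    metrics["dice"] = dice_coefficient(report.mask.pixels, truth.mask)
    if metrics["dice"] < SELFTEST_THRESHOLDS["dice_min"]:
        failures.append("segmentation_dice")

    if report.status != "ok" or report.av_report is None:
        failures.append("pipeline_status")
        return SelftestResult(False, metrics, failures, dict(SELFTEST_THRESHOLDS))

    metrics["label_accuracy"] = label_accuracy(report.segments, truth)
    if not metrics["label_accuracy"] >= SELFTEST_THRESHOLDS["label_accuracy_min"]:
        failures.append("label_accuracy")

    rep = report.av_report
    for cls, measured in (
        ("artery", rep.mean_artery_diameter_um),
        ("vein", rep.mean_vein_diameter_um),
    ):
        true = truth.class_mean_diameter_um(cls)
        rel = abs(measured - true) / true
        metrics[f"{cls}_diameter_um"] = measured
        metrics[f"{cls}_diameter_true_um"] = true
        metrics[f"{cls}_diameter_rel_err"] = rel
        if rel > SELFTEST_THRESHOLDS["diameter_rel_err_max"]:
            failures.append(f"{cls}_diameter_recovery")

    for cls, measured in (
        ("artery", rep.mean_artery_tortuosity),
        ("vein", rep.mean_vein_tortuosity),
    ):
        true = truth.class_mean_tortuosity(cls)
        rel = abs(measured - true) / true
        metrics[f"{cls}_tortuosity"] = measured
        metrics[f"{cls}_tortuosity_true"] = true
        metrics[f"{cls}_tortuosity_rel_err"] = rel
        if rel > SELFTEST_THRESHOLDS["tortuosity_rel_err_max"]:
            failures.append(f"{cls}_tortuosity_recovery")

    true_avr = truth.class_mean_diameter_um("artery") / truth.class_mean_diameter_um("vein")
    metrics["avr"] = rep.avr
    metrics["avr_true"] = true_avr
    if abs(rep.avr - true_avr) > SELFTEST_THRESHOLDS["avr_abs_err_max"]:
        failures.append("avr_recovery")

    return SelftestResult(not failures, metrics, failures, dict(SELFTEST_THRESHOLDS))
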