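"""End-to-end pipeline and directory-level evaluation.

``run_pipeline`` chains the stages on one frame: enhancement → pixel
classification → polygon extraction → overlay rendering, writing the
overlay PNG, the polygon JSON and the segmentation-map PNG.

``run_evaluation`` pairs predicted and ground-truth mask directories by
filename, reduces every pair to malignant/benign per-image outcomes
and per-class Dice, aggregates confusion counts, and writes a CSV/JSON
report with sensitivity, precision and F-score in percent (4 decimal
places). Subsets tagged by pre-processing version in the filename
(``*_original.png`` etc.) can be reported separately.
"""

from __future__ import annotations

import csv
import logging
import time
from pathlib import Path

import numpy as np

from . import imgio
from .config import PipelineConfig
from .metrics import (ConfusionCounts, categorize_image, dice, format_percent,
                      prf, tally)
from .nnet import ReferenceNet, predict
from .polygons import render_overlay, segmap_to_polygons
from .enhance import enhance_pipeline
from .scheme import DEFAULT_SCHEME, ClassScheme

log = logging.getLogger(__name__)


def run_pipeline(image_path: str | Path, model, cfg: PipelineConfig,
                 out_dir: str | Path,
                 scheme: ClassScheme = DEFAULT_SCHEME) -> dict:
    """Process one frame end to end; returns the artifact paths.

    ``model`` is anything satisfying the model contract (a callable
    from (N, H, W, 3) standardized input to (N, H, W, 7) scores), e.g.
    a :class:`~cystoseg.nnet.ReferenceNet` or a loaded checkpoint.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = Path(image_path).stem
    timings = {}

    t0 = time.perf_counter()
    img = imgio.load_image(image_path)
    display, model_input = enhance_pipeline(img, cfg.enhance)
    timings["enhance"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    _, seg = predict(model, model_input)
    timings["predict"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    polys, diag = segmap_to_polygons(seg, cfg.polygons)
    overlay = render_overlay(display, polys, scheme)
    timings["postprocess"] = time.perf_counter() - t0

    paths = {"overlay": str(out / f"{stem}_overlay.png"),
             "mask": str(out / f"{stem}_mask.png"),
             "polygons": str(out / f"{stem}_polygons.json")}
    imgio.save_image(paths["overlay"], overlay)
    imgio.save_mask(paths["mask"], seg)
    imgio.save_json(paths["polygons"],
                    {"polygons": [p.to_json(scheme) for p in polys],
                     "noise_chains": diag.n_noise_chains,
                     "noise_pixels": diag.n_noise_pixels})
    for stage, dt in timings.items():
        log.info("%s: %s %.1f ms", stem, stage, 1e3 * dt)
    return paths


def load_model(path: str | Path) -> ReferenceNet:
    return ReferenceNet.load(path)


# -- evaluation ------------------------------------------------------------

def evaluate_pairs(pairs, scheme: ClassScheme = DEFAULT_SCHEME) -> dict:
    """Evaluate (pred mask, truth mask) array pairs.

    Returns confusion counts for the malignant and benign categories,
    their precision/recall/F in percent, and the mean of the per-image
    mean Dice coefficients.
    """
    mal_outcomes, ben_outcomes, dices = [], [], []
    for pred, truth in pairs:
        m, b = categorize_image(pred, truth, scheme)
        mal_outcomes.append(m)
        ben_outcomes.append(b)
        dices.append(dice(pred, truth).mean)
    result = {"n_images": len(dices),
              "mean_dice": float(np.mean(dices)) if dices else float("nan")}
    for cat, outcomes in (("malignant", mal_outcomes), ("benign", ben_outcomes)):
        counts = tally(outcomes, cat)
        precision, recall, f_score = prf(counts)
        result[cat] = {"tp": counts.tp, "tn": counts.tn,
                       "fp": counts.fp, "fn": counts.fn,
                       "sensitivity": recall, "precision": precision,
                       "f_score": f_score}
    return result


def _version_tag(name: str) -> str:
    stem = Path(name).stem
    for tag in ("original", "filtered", "sharpened", "enhanced"):
        if stem.endswith("_" + tag):
            return tag
    return "untagged"


def run_evaluation(pred_dir: str | Path, truth_dir: str | Path,
                   report_csv: str | Path | None = None,
                   report_json: str | Path | None = None,
                   by_version: bool = False,
                   scheme: ClassScheme = DEFAULT_SCHEME) -> dict:
    """Evaluate matching mask files from two directories.

    Files are paired by identical name; unmatched files are listed and
    skipped with a warning. With ``by_version`` the report additionally
    breaks the counts out per pre-processing version tag, mirroring the
    per-subset analysis of enhancement benefit.
    """
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    pred_files = {p.name: p for p in sorted(pred_dir.glob("*.png"))}
    truth_files = {p.name: p for p in sorted(truth_dir.glob("*.png"))}
    common = sorted(pred_files.keys() & truth_files.keys())
    skipped = sorted(pred_files.keys() ^ truth_files.keys())
    if skipped:
        log.warning("run_evaluation: %d unmatched files skipped: %s",
                    len(skipped), skipped[:10])
    loaded = [(name, imgio.load_mask(pred_files[name]),
               imgio.load_mask(truth_files[name])) for name in common]
    report = {"all": evaluate_pairs([(p, t) for _, p, t in loaded], scheme),
              "skipped": skipped}
    if by_version:
        subsets: dict[str, list] = {}
        for name, p, t in loaded:
            subsets.setdefault(_version_tag(name), []).append((p, t))
        report["by_version"] = {tag: evaluate_pairs(pairs, scheme)
                                for tag, pairs in sorted(subsets.items())}
    if report_json is not None:
        imgio.save_json(report_json, report)
    if report_csv is not None:
        _write_csv(report, report_csv)
    return report


def _write_csv(report: dict, path: str | Path) -> None:
    rows = [("all", report["all"])]
    for tag, sub in report.get("by_version", {}).items():
        rows.append((tag, sub))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subset", "category", "tp", "tn", "fp", "fn",
                         "sensitivity", "precision", "f_score", "mean_dice"])
        for tag, sub in rows:
            for cat in ("malignant", "benign"):
                c = sub[cat]
                writer.writerow([tag, cat, c["tp"], c["tn"], c["fp"], c["fn"],
                                 format_percent(c["sensitivity"]),
                                 format_percent(c["precision"]),
                                 format_percent(c["f_score"]),
                                 f"{sub['mean_dice']:.4f}"])
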