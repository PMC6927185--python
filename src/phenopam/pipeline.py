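"""Directory-level processing: tidy phenotype table, QC report, time-lapse.

``process_directory`` walks a directory of instrument exports, segments
every stack, extracts per-plant YII and NPQ for every induction step plus
one calibrated area per plant, joins genotypes, and writes one tidy
long-format CSV (one value per row) with the QC flags attached to every
record.  Files with malformed names are skipped and logged, never fatal.
``qc_report`` renders a storyboard-style markdown report (completeness,
QC flags, per-phenotype timeseries); ``timelapse`` compiles false-colour
GIF animations per tray group with genotype annotations.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config_maps import (
    FilenameParseError,
    FrameRole,
    GenotypeMap,
    load_frame_map,
    load_genotype_map,
    parse_filename,
)
from .phenotypes import (
    Parameter,
    npq,
    plant_area,
    plant_value,
    render_false_color,
    yii,
    fvfm,
)
from .segmentation import (
    ROILayout,
    SegmentationParams,
    make_roi_grid,
    render_overlay,
    segment_frame,
)
from .stack_io import CalibrationSpec, read_stack

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "process_directory", "qc_report", "timelapse"]

TIDY_COLUMNS = [
    "treatment",
    "date",
    "sample_id",
    "roi",
    "genotype",
    "parameter",
    "induction_step",
    "value",
    "qc_complete",
    "qc_independent",
]


@dataclass
class RunConfig:
    """Everything one processing run needs; echoed into the output directory."""

    indir: Path
    outdir: Path
    frame_map_path: Path
    genotype_map_path: Path
    pixel_resolution: float = 0.2  # mm per pixel
    roi_rows: int = 2
    roi_cols: int = 4
    roi_origin: tuple[float, float] = (120.0, 85.0)
    roi_spacing: tuple[float, float] = (220.0, 156.0)
    roi_radius: float = 60.0
    image_shape: tuple[int, int] = (480, 640)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    strict: bool = True
    save_overlays: bool = True
    signal_floor: float | str = "auto"
    seed: int = 0  # reserved for stochastic extensions; processing is deterministic

    def __post_init__(self) -> None:
        self.indir = Path(self.indir)
        self.outdir = Path(self.outdir)
        self.frame_map_path = Path(self.frame_map_path)
        self.genotype_map_path = Path(self.genotype_map_path)

    def layout(self) -> ROILayout:
        return make_roi_grid(
            self.roi_rows,
            self.roi_cols,
            self.roi_origin,
            self.roi_spacing,
            self.roi_radius,
            self.image_shape,
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        d["segmentation"] = {
            "frame_role": self.segmentation.frame_role.value,
            "nbins": self.segmentation.nbins,
            "min_object_px": self.segmentation.min_object_px,
            "max_hole_px": self.segmentation.max_hole_px,
        }
        return json.dumps(d, indent=2, sort_keys=True)


def _setup_run_logger(outdir: Path) -> logging.Logger:
    run_logger = logging.getLogger(f"phenopam.run.{outdir}")
    run_logger.setLevel(logging.INFO)
    run_logger.propagate = True
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (outdir / "processing.log").resolve()
        for h in run_logger.handlers
    ):
        fh = logging.FileHandler(outdir / "processing.log")
        fh.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        run_logger.addHandler(fh)
    return run_logger


def process_directory(cfg: RunConfig) -> pd.DataFrame:
    """Process every parsable stack under ``cfg.indir`` into a tidy table.

    Emits, per plant per measurement, YII and NPQ at every induction step
    plus one ``area_mm2`` record, each row carrying the genotype and the
    two QC flags of its ROI; writes ``phenotypes.csv``, per-image mask
    overlays, a line-per-file processing log and the echoed configuration.
    """
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.json").write_text(cfg.to_json())
    log = _setup_run_logger(outdir)

    fmap = load_frame_map(cfg.frame_map_path)
    layout = cfg.layout()
    gmap = load_genotype_map(cfg.genotype_map_path, n_roi=layout.n_roi)
    cal = CalibrationSpec(pixel_resolution=cfg.pixel_resolution)
    if cfg.save_overlays:
        (outdir / "overlays").mkdir(exist_ok=True)

    files = sorted(
        p for p in cfg.indir.iterdir() if p.suffix.lower() in (".tif", ".tiff")
    )
    n_steps = fmap.n_induction_steps
    records: list[tuple] = []
    n_processed = 0
    for path in files:
        try:
            mid = parse_filename(path.name)
        except FilenameParseError as exc:
            log.error("SKIP %s: %s", path.name, exc)
            continue
        stack = read_stack(path, fmap, measurement_id=mid)
        seg = segment_frame(
            stack.get_frame(cfg.segmentation.frame_role), layout, cfg.segmentation
        )
        genotypes = [
            gmap.lookup(mid.sample_id, pos, strict=cfg.strict)
            for pos in range(1, layout.n_roi + 1)
        ]
        fm = stack.get_frame(FrameRole.Fm)
        step_imgs = []
        for step in range(1, n_steps + 1):
            fp = stack.get_frame(FrameRole.Fprime, step)
            fmp = stack.get_frame(FrameRole.Fmprime, step)
            step_imgs.append(
                (
                    step,
                    yii(fp, fmp, seg.foreground, step, cfg.signal_floor),
                    npq(fm, fmp, seg.foreground, step, cfg.signal_floor),
                )
            )
        for pos in range(1, layout.n_roi + 1):
            pmask = seg.roi_masks[pos - 1]
            flags = seg.flags[pos - 1]
            base = (
                mid.treatment,
                mid.date.isoformat(),
                mid.sample_id,
                pos,
                genotypes[pos - 1],
            )
            tail = (flags.complete, flags.independent)
            for step, yimg, nimg in step_imgs:
                records.append(base + ("YII", step, plant_value(yimg, pmask)) + tail)
                records.append(base + ("NPQ", step, plant_value(nimg, pmask)) + tail)
            records.append(
                base
                + ("area_mm2", None, plant_area(seg.pixel_counts[pos - 1], cal))
                + tail
            )
        if cfg.save_overlays:
            overlay = render_overlay(
                stack.get_frame(cfg.segmentation.frame_role), seg, layout
            )
            iio.imwrite(outdir / "overlays" / f"{path.stem}.png", overlay)
        n_processed += 1
        log.info(
            "OK %s: threshold=%s fg_px=%d unassigned=%d flags=%s",
            path.name,
            seg.threshold,
            int(seg.foreground.sum()),
            seg.n_unassigned_components,
            [(f.complete, f.independent) for f in seg.flags],
        )
    if n_processed == 0:
        raise RuntimeError(f"no parsable stack files found in {cfg.indir}")

    table = pd.DataFrame(records, columns=TIDY_COLUMNS)
    table = table.sort_values(
        ["date", "sample_id", "roi", "parameter", "induction_step"],
        na_position="first",
    ).reset_index(drop=True)
    table["induction_step"] = table["induction_step"].astype("Int64")
    table.to_csv(outdir / "phenotypes.csv", index=False)
    log.info("DONE %d files -> %d records", n_processed, len(table))
    return table


# ---------------------------------------------------------------------------
# QC report


def _timeseries_panels(table: pd.DataFrame, outdir: Path) -> list[tuple[str, str]]:
    """Line and bar timeseries per phenotype, grouped genotype x treatment.

    YII/NPQ are summarised at their final induction step (steady state).
    Returns (title, png filename) pairs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = []
    last_step = table["induction_step"].max()
    for param in ("area_mm2", "YII", "NPQ"):
        sub = table[table["parameter"] == param]
        if param != "area_mm2":
            sub = sub[sub["induction_step"] == last_step]
        sub = sub.dropna(subset=["value"])
        grouped = (
            sub.groupby(["date", "genotype", "treatment"])["value"].mean().reset_index()
        )
        for kind in ("line", "bar"):
            fig, ax = plt.subplots(figsize=(7, 4))
            if grouped.empty:
                ax.text(0.5, 0.5, "no data", ha="center", va="center")
            else:
                dates = sorted(grouped["date"].unique())
                combos = sorted(
                    grouped.groupby(["genotype", "treatment"]).groups.keys()
                )
                width = 0.8 / max(len(combos), 1)
                for i, (geno, trt) in enumerate(combos):
                    g = grouped[
                        (grouped["genotype"] == geno) & (grouped["treatment"] == trt)
                    ].set_index("date")["value"]
                    ys = [g.get(d, np.nan) for d in dates]
                    label = f"{geno}/{trt}"
                    if kind == "line":
                        ax.plot(range(len(dates)), ys, marker="o", label=label)
                    else:
                        ax.bar(
                            np.arange(len(dates)) + i * width, ys, width=width,
                            label=label,
                        )
                ax.set_xticks(range(len(dates)))
                ax.set_xticklabels(dates, rotation=45, ha="right", fontsize=7)
                ax.legend(fontsize=6)
            unit = " (mm²)" if param == "area_mm2" else ""
            suffix = f" @ step {last_step}" if param != "area_mm2" else ""
            ax.set_title(f"{param}{unit}{suffix} — {kind}")
            fig.tight_layout()
            fname = f"timeseries_{param}_{kind}.png"
            fig.savefig(outdir / fname, dpi=90)
            plt.close(fig)
            panels.append((f"{param} {kind} plot", fname))
    return panels


def qc_report(
    table: pd.DataFrame, outdir: str | Path, title: str = "Post-processing QC report"
) -> Path:
    """Storyboard report: data completeness, QC flags, phenotype timeseries.

    Written as ``report.md`` plus PNG panels in ``outdir``.
    """
    if table.empty:
        raise ValueError("tidy table is empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts = table.groupby(["date", "sample_id"]).size().unstack(fill_value=0)
    expected = counts.values.max()
    lines = [f"# {title}", "", "## 1. Data completeness", ""]
    lines.append("Measurement x tray matrix (✓ complete, ✗ missing/short):")
    lines.append("")
    header = "| date | " + " | ".join(str(c) for c in counts.columns) + " |"
    lines.append(header)
    lines.append("|" + "---|" * (len(counts.columns) + 1))
    all_dates = sorted(table["date"].unique())
    all_trays = list(counts.columns)
    for d in all_dates:
        row = [str(d)]
        for t in all_trays:
            n = counts.loc[d, t] if (d in counts.index and t in counts.columns) else 0
            row.append("✓" if n == expected else f"✗ ({n})")
        lines.append("| " + " | ".join(row) + " |")
    lines.append("")

    lines += ["## 2. QC flags", ""]
    flagged = table[~table["qc_complete"] | ~table["qc_independent"]]
    if flagged.empty:
        lines.append("No QC flags were activated: every plant was completely "
                     "imaged and remained independent.")
    else:
        bad = (
            flagged.groupby(["date", "sample_id", "roi"])[
                ["qc_complete", "qc_independent"]
            ]
            .first()
            .reset_index()
        )
        lines.append("| date | tray | roi | complete | independent |")
        lines.append("|---|---|---|---|---|")
        for _, r in bad.iterrows():
            lines.append(
                f"| {r['date']} | {r['sample_id']} | {r['roi']} | "
                f"{r['qc_complete']} | {r['qc_independent']} |"
            )
        lines.append("")
        lines.append(
            "A False value invalidates that plant's records at that time point "
            "and motivates their removal from downstream analysis."
        )
    lines.append("")

    lines += ["## 3. Phenotype timeseries", ""]
    for caption, fname in _timeseries_panels(table, outdir):
        lines.append(f"### {caption}")
        lines.append("")
        lines.append(f"![{caption}]({fname})")
        lines.append("")

    report = outdir / "report.md"
    report.write_text("\n".join(lines), encoding="utf-8")
    return report


# ---------------------------------------------------------------------------
# Time-lapse animations


def _annotate(rgb: np.ndarray, layout: ROILayout, labels: Sequence[str]) -> np.ndarray:
    from PIL import Image, ImageDraw

    im = Image.fromarray(rgb)
    draw = ImageDraw.Draw(im)
    for (r0, c0), text in zip(layout.centers, labels):
        y = max(0, int(r0 - layout.radius - 12))
        x = max(0, int(c0 - 4 * len(text)))
        draw.text((x, y), text, fill=(255, 255, 255))
    return np.asarray(im)


def timelapse(
    cfg: RunConfig,
    parameter: str = "NPQ",
    induction_step: Optional[int] = None,
    group_size: int = 2,
    fps: float = 2.0,
) -> list[Path]:
    """False-colour GIF time-lapse per tray group (default: pairs of trays).

    Frames run in date order on a colour scale fixed across the whole
    animation; each ROI is annotated with its genotype.  A date missing for
    part of a group is skipped with a log note; a single remaining time
    point degrades to a one-frame still with a warning.
    """
    param = Parameter(parameter)
    fmap = load_frame_map(cfg.frame_map_path)
    layout = cfg.layout()
    gmap = load_genotype_map(cfg.genotype_map_path, n_roi=layout.n_roi)
    if induction_step is None:
        induction_step = 1 if param is Parameter.FvFm else fmap.n_induction_steps

    stacks_by_tray: dict[str, dict[str, Path]] = {}
    for path in sorted(cfg.indir.iterdir()):
        if path.suffix.lower() not in (".tif", ".tiff"):
            continue
        try:
            mid = parse_filename(path.name)
        except FilenameParseError:
            continue
        stacks_by_tray.setdefault(mid.sample_id, {})[mid.date.isoformat()] = path

    trays = sorted(stacks_by_tray)
    groups = [trays[i : i + group_size] for i in range(0, len(trays), group_size)]
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for group in groups:
        dates = sorted(set.union(*(set(stacks_by_tray[t]) for t in group)))
        frames = []
        for d in dates:
            if any(d not in stacks_by_tray[t] for t in group):
                logger.info("timelapse: date %s missing for part of group %s; skipped", d, group)
                continue
            tiles = []
            for tray in group:
                stack = read_stack(stacks_by_tray[tray][d], fmap)
                seg = segment_frame(
                    stack.get_frame(cfg.segmentation.frame_role), layout,
                    cfg.segmentation,
                )
                if param is Parameter.FvFm:
                    img = fvfm(
                        stack.get_frame(FrameRole.Fo),
                        stack.get_frame(FrameRole.Fm),
                        seg.foreground,
                        cfg.signal_floor,
                    )
                elif param is Parameter.YII:
                    img = yii(
                        stack.get_frame(FrameRole.Fprime, induction_step),
                        stack.get_frame(FrameRole.Fmprime, induction_step),
                        seg.foreground,
                        induction_step,
                        cfg.signal_floor,
                    )
                else:
                    img = npq(
                        stack.get_frame(FrameRole.Fm),
                        stack.get_frame(FrameRole.Fmprime, induction_step),
                        seg.foreground,
                        induction_step,
                        cfg.signal_floor,
                    )
                rgb = render_false_color(img)
                labels = [
                    gmap.lookup(tray, pos, strict=False)
                    for pos in range(1, layout.n_roi + 1)
                ]
                tiles.append(_annotate(rgb, layout, labels))
            frames.append(np.hstack(tiles))
        if not frames:
            logger.warning("timelapse: no complete date for group %s; skipped", group)
            continue
        if len(frames) == 1:
            logger.warning(
                "timelapse: single time point for group %s; emitting a still", group
            )
        out = cfg.outdir / f"timelapse_{param.value}_{'_'.join(group)}.gif"
        iio.imwrite(out, frames, duration=int(1000 / fps), loop=0)
        outputs.append(out)
    return outputs
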