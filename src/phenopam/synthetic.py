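"""Ground-truthed synthetic IMAGING-PAM scenes and experiments.

The generator inverts the phenotype equations: given a prescribed Fv/Fm,
per-step YII and NPQ trajectories and a dark level Fo for each plant, it
computes the fluorescence levels every frame must hold,

    Fm   = Fo / (1 - Fv/Fm)
    Fm'_t = Fm / (1 + NPQ_t)
    F'_t  = Fm'_t (1 - YII_t)

renders disk- or rosette-shaped plants at ROI grid positions into a
multi-frame stack with the instrument's frame order, adds clipped Gaussian
noise, and emits a ground-truth table of every prescribed value.  Defect
injection (border-clipped plants, merged neighbours) exercises the QC
flags.  Frames hold integer counts, so arbitrary float prescriptions are
realised to quantisation accuracy; :func:`exact_trajectories` builds
prescriptions from integer fluorescence levels that are realised exactly.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config_maps import (
    FrameMap,
    FrameRole,
    GenotypeMap,
    MeasurementID,
    default_frame_map,
    format_filename,
    write_frame_map,
    write_genotype_map,
)
from .segmentation import ROILayout, make_roi_grid
from .stack_io import FluorescenceStack, write_stack

__all__ = [
    "SyntheticPlantSpec",
    "BorderClip",
    "Merge",
    "SyntheticSceneSpec",
    "render_scene",
    "exact_trajectories",
    "make_experiment",
    "default_layout",
    "GENOTYPE_BASELINES",
]


@dataclass(frozen=True)
class SyntheticPlantSpec:
    """Ground-truth description of one simulated plant."""

    roi_position: int
    center: tuple[float, float]  # (row, col)
    radius: float
    fo_level: float
    fvfm_true: float
    yii_trajectory: tuple[float, ...]  # YII_1 == fvfm_true (dark-adapted)
    npq_trajectory: tuple[float, ...]  # NPQ_1 == 0
    genotype: str = "WT"
    n_lobes: int = 0  # 0 = disk; k >= 3 = rosette of k elliptical lobes

    def __post_init__(self) -> None:
        if not 0.0 < self.fvfm_true < 1.0:
            raise ValueError(f"fvfm_true must be in (0, 1), got {self.fvfm_true}")
        if len(self.yii_trajectory) != len(self.npq_trajectory):
            raise ValueError("YII and NPQ trajectories must have equal length")
        if abs(self.npq_trajectory[0]) > 1e-9:
            raise ValueError("NPQ at step 1 must be 0 (dark-adapted first pair)")
        if abs(self.yii_trajectory[0] - self.fvfm_true) > 1e-9:
            raise ValueError("YII at step 1 must equal fvfm_true (dark-adapted)")
        if any(v < 0 for v in self.npq_trajectory):
            raise ValueError("NPQ values must be >= 0")
        if any(not 0 <= v <= 1 for v in self.yii_trajectory):
            raise ValueError("YII values must be in [0, 1]")

    @property
    def fm_level(self) -> float:
        return self.fo_level / (1.0 - self.fvfm_true)


@dataclass(frozen=True)
class BorderClip:
    """Defect: the named plant is shifted so its rosette runs off frame."""

    roi: int


@dataclass(frozen=True)
class Merge:
    """Defect: a bridge of foreground pixels joins two neighbouring plants."""

    roi_a: int
    roi_b: int


@dataclass
class SyntheticSceneSpec:
    """Full description of one simulated tray measurement."""

    plants: list[SyntheticPlantSpec]
    layout: ROILayout
    image_shape: tuple[int, int] = (480, 640)
    background_level: float = 200.0
    absorptivity_level: float = 1000.0
    noise_sd: float = 0.0
    texture_sd: float = 0.04  # multiplicative leaf texture (lognormal sd)
    defects: list[BorderClip | Merge] = field(default_factory=list)
    seed: int = 0
    dtype: str = "uint16"
    heterogeneity: float = 0.0  # radial Fv/Fm falloff, for false-colour demos


def _plant_mask(
    spec: SyntheticPlantSpec, shape: tuple[int, int], center: tuple[float, float]
) -> np.ndarray:
    """Disk (n_lobes=0) or rosette (union of k elliptical lobes)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = center
    if spec.n_lobes < 3:
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= spec.radius**2
    mask = np.zeros(shape, dtype=bool)
    r = spec.radius
    for j in range(spec.n_lobes):
        th = 2 * math.pi * j / spec.n_lobes
        lr, lc = r0 + 0.55 * r * math.sin(th), c0 + 0.55 * r * math.cos(th)
        # lobe: ellipse with long axis pointing outward
        u = (rr - lr) * math.sin(th) + (cc - lc) * math.cos(th)
        v = -(rr - lr) * math.cos(th) + (cc - lc) * math.sin(th)
        mask |= (u / (0.55 * r)) ** 2 + (v / (0.33 * r)) ** 2 <= 1.0
    mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= (0.45 * r) ** 2
    return mask


def _frame_levels(spec: SyntheticPlantSpec, fmap: FrameMap, absorptivity: float) -> list[float]:
    """Fluorescence level of this plant in every frame, in frame order."""
    fm = spec.fm_level
    levels: list[float] = []
    for e in fmap.entries:
        if e.role is FrameRole.Fo:
            levels.append(spec.fo_level)
        elif e.role is FrameRole.Fm:
            levels.append(fm)
        elif e.role in (FrameRole.RedAbs, FrameRole.NIRAbs):
            levels.append(absorptivity)
        else:
            t = e.induction_step - 1
            fmp = fm / (1.0 + spec.npq_trajectory[t])
            levels.append(fmp if e.role is FrameRole.Fmprime else fmp * (1.0 - spec.yii_trajectory[t]))
    return levels


def render_scene(
    spec: SyntheticSceneSpec,
    frame_map: Optional[FrameMap] = None,
    measurement_id: Optional[MeasurementID] = None,
) -> tuple[FluorescenceStack, pd.DataFrame]:
    """Render one scene into a stack plus its ground-truth table.

    The ground truth holds one row per plant per prescribed quantity:
    Fv/Fm, YII and NPQ at every induction step, and the rendered plant
    area in pixels (exact by construction).
    """
    if frame_map is None:
        frame_map = default_frame_map(len(spec.plants[0].yii_trajectory))
    n_steps = frame_map.n_induction_steps
    for p in spec.plants:
        if len(p.yii_trajectory) != n_steps:
            raise ValueError(
                f"plant at roi {p.roi_position}: trajectory length "
                f"{len(p.yii_trajectory)} != {n_steps} induction steps"
            )
    if measurement_id is None:
        measurement_id = MeasurementID("synthetic", _dt.date(2019, 9, 1), "tray1")

    dtype = np.dtype(spec.dtype)
    h, w = spec.image_shape
    clip_rois = {d.roi for d in spec.defects if isinstance(d, BorderClip)}
    merges = [d for d in spec.defects if isinstance(d, Merge)]

    plant_masks: dict[int, np.ndarray] = {}
    centers: dict[int, tuple[float, float]] = {}
    for p in spec.plants:
        center = p.center
        if p.roi_position in clip_rois:
            # shift toward the nearest image edge, keeping the centre inside
            # the ROI circle so the clipped plant still claims its ROI
            r0, c0 = center
            edges = [(r0, ("r", 0)), (h - 1 - r0, ("r", h - 1)),
                     (c0, ("c", 0)), (w - 1 - c0, ("c", w - 1))]
            _, (axis, edge) = min(edges)
            roi_r = spec.layout.radius
            if axis == "r":
                shift = min(roi_r - 1, abs(edge - r0) - 1)
                center = (r0 + math.copysign(shift, edge - r0), c0)
                reach = abs(edge - center[0])
            else:
                shift = min(roi_r - 1, abs(edge - c0) - 1)
                center = (r0, c0 + math.copysign(shift, edge - c0))
                reach = abs(edge - center[1])
            mask = _plant_mask(p, spec.image_shape, center)
            if reach >= p.radius:
                # plant still short of the edge: extend a leaf to the border
                rr, cc = np.ogrid[:h, :w]
                half = max(2.0, 0.3 * p.radius)
                if axis == "r":
                    lo, hi = sorted((center[0], float(edge)))
                    mask |= (np.abs(cc - center[1]) <= half) & (rr >= lo) & (rr <= hi)
                else:
                    lo, hi = sorted((center[1], float(edge)))
                    mask |= (np.abs(rr - center[0]) <= half) & (cc >= lo) & (cc <= hi)
        else:
            mask = _plant_mask(p, spec.image_shape, center)
        plant_masks[p.roi_position] = mask
        centers[p.roi_position] = center

    bridge_masks: list[tuple[np.ndarray, int]] = []
    for m in merges:
        (r1, c1), (r2, c2) = centers[m.roi_a], centers[m.roi_b]
        n = int(math.hypot(r2 - r1, c2 - c1)) * 2 + 1
        rs = np.linspace(r1, r2, n)
        cs = np.linspace(c1, c2, n)
        bm = np.zeros(spec.image_shape, dtype=bool)
        for rr_, cc_ in zip(rs, cs):
            rl, cl = int(round(rr_)), int(round(cc_))
            bm[max(0, rl - 1) : rl + 2, max(0, cl - 1) : cl + 2] = True
        bridge_masks.append((bm, m.roi_a))

    n_frames = len(frame_map)
    frames = np.full((n_frames, h, w), spec.background_level, dtype=float)
    het_fields: dict[int, np.ndarray] = {}
    if spec.heterogeneity > 0:
        rr, cc = np.ogrid[:h, :w]
        for p in spec.plants:
            r0, c0 = centers[p.roi_position]
            d = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2) / max(p.radius, 1.0)
            het_fields[p.roi_position] = np.clip(d, 0, 1) ** 2

    levels_by_roi = {
        p.roi_position: _frame_levels(p, frame_map, spec.absorptivity_level)
        for p in spec.plants
    }
    rng = np.random.default_rng(spec.seed)
    for p in spec.plants:
        mask = plant_masks[p.roi_position]
        levels = levels_by_roi[p.roi_position]
        # multiplicative per-pixel leaf texture, identical in every frame:
        # scales Fo, Fm, F', Fm' together, so ratio parameters are untouched
        if spec.texture_sd > 0:
            tex = np.exp(rng.normal(0.0, spec.texture_sd, int(mask.sum())))
        else:
            tex = 1.0
        for i in range(n_frames):
            frames[i][mask] = levels[i] * tex
        if p.roi_position in het_fields:
            # radial Fv/Fm falloff: scale Fm (and Fm'/F' identically) down
            # toward the rim so ratio images show structure
            scale = 1.0 - spec.heterogeneity * het_fields[p.roi_position][mask]
            for i, e in enumerate(frame_map.entries):
                if e.role not in (FrameRole.Fo, FrameRole.RedAbs, FrameRole.NIRAbs):
                    frames[i][mask] = spec.background_level + (
                        levels[i] - spec.background_level
                    ) * scale
    for bm, src_roi in bridge_masks:
        levels = levels_by_roi[src_roi]
        for i in range(n_frames):
            frames[i][bm] = levels[i]

    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)
    dmax = np.iinfo(dtype).max
    frames = np.clip(np.rint(frames), 0, dmax).astype(dtype)
    if frame_map.first_pair_is_dark_adapted and len(frames) >= 6:
        # the export repeats the dark-adapted pair as frames 5/6: copies,
        # not re-measurements, so the step-1 identities hold exactly
        frames[4] = frames[0]
        frames[5] = frames[1]

    stack = FluorescenceStack(id=measurement_id, frames=frames, frame_map=frame_map)

    rows: list[dict] = []
    for p in spec.plants:
        base = {
            "roi": p.roi_position,
            "genotype": p.genotype,
            "treatment": measurement_id.treatment,
            "date": measurement_id.date.isoformat(),
            "sample_id": measurement_id.sample_id,
        }
        rows.append(base | {"parameter": "FvFm", "induction_step": None, "value": p.fvfm_true})
        for t in range(n_steps):
            rows.append(base | {"parameter": "YII", "induction_step": t + 1, "value": p.yii_trajectory[t]})
            rows.append(base | {"parameter": "NPQ", "induction_step": t + 1, "value": p.npq_trajectory[t]})
        rows.append(
            base
            | {
                "parameter": "area_px",
                "induction_step": None,
                "value": float(plant_masks[p.roi_position].sum()),
            }
        )
    return stack, pd.DataFrame(rows)


def exact_trajectories(
    n_steps: int, rng: Optional[np.random.Generator] = None
) -> tuple[float, float, tuple[float, ...], tuple[float, ...]]:
    """(fo_level, fvfm, yii_trajectory, npq_trajectory) built from integer
    fluorescence levels, so the rendered integer frames realise the
    prescribed ratios exactly (no quantisation error)."""
    rng = rng or np.random.default_rng(0)
    fo, fm = 800, 4000
    fvfm = (fm - fo) / fm  # 0.8
    # Fm' drawn from divisors of Fm so every level is an exact integer
    fmp_choices = [3200, 2500, 2000, 1600, 1250, 1000]
    yii_list, npq_list = [fvfm], [0.0]
    for _ in range(n_steps - 1):
        fmp = int(rng.choice(fmp_choices))
        # F' as an integer fraction of Fm'
        fp = int(rng.choice([fmp // 2, fmp // 4, (3 * fmp) // 4]))
        yii_list.append((fmp - fp) / fmp)
        npq_list.append((fm - fmp) / fmp)
    return float(fo), fvfm, tuple(yii_list), tuple(npq_list)


def default_layout(image_shape: tuple[int, int] = (480, 640)) -> ROILayout:
    """2 x 4 grid of 60-px ROIs on a 480 x 640 frame (8 pots per tray)."""
    return make_roi_grid(
        n_rows=2,
        n_cols=4,
        origin=(120, 85),
        spacing=(220, 156),
        radius=60,
        image_shape=image_shape,
    )


#: genotype-specific baselines: (Fv/Fm, steady-state YII, saturating NPQ)
GENOTYPE_BASELINES: dict[str, tuple[float, float, float]] = {
    "WT": (0.80, 0.50, 2.0),
    "kea3": (0.78, 0.44, 2.6),
    "vccn1": (0.79, 0.48, 1.8),
    "stn7": (0.76, 0.40, 2.2),
}


def _smooth_trajectories(
    fvfm: float, yii_ss: float, npq_max: float, n_steps: int, rng: np.random.Generator
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Saturating induction kinetics with small seeded wiggle."""
    steps = np.arange(n_steps, dtype=float)
    yii = yii_ss + (fvfm - yii_ss) * np.exp(-steps / 2.5)
    npq = npq_max * (1.0 - np.exp(-steps / 3.0))
    yii[1:] += rng.normal(0, 0.01, n_steps - 1)
    npq[1:] += rng.normal(0, 0.03, n_steps - 1)
    yii = np.clip(yii, 0.02, 0.98)
    npq = np.clip(npq, 0.0, None)
    yii[0], npq[0] = fvfm, 0.0
    return tuple(yii.tolist()), tuple(npq.tolist())


def make_experiment(
    outdir: str | Path,
    n_trays: int = 6,
    plants_per_tray: int = 8,
    n_days: int = 11,
    n_steps: int = 15,
    seed: int = 0,
    genotypes: Sequence[str] = ("WT", "kea3", "vccn1", "stn7"),
    layout: Optional[ROILayout] = None,
    noise_sd: float = 80.0,
    start_date: _dt.date = _dt.date(2019, 9, 1),
    defects: Optional[dict[tuple[str, int], list[BorderClip | Merge]]] = None,
) -> tuple[Path, ROILayout]:
    """Simulate a full screening campaign and write the pipeline's inputs.

    One stack per tray per day (filenames ``treatment-YYYYMMDD-trayN.tif``),
    the two metadata maps, and ``ground_truth.csv``.  Trays split half and
    half between ``control`` and ``fluc`` treatments; genotypes cycle over
    ROI positions; plant radii grow linearly with day so area trends are
    monotone; per-day trajectories are seeded smooth processes around
    genotype baselines.  ``defects`` maps (sample_id, day_index) to defect
    lists.  The same seed reproduces the directory bit for bit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = layout or default_layout()
    if plants_per_tray > layout.n_roi:
        raise ValueError(
            f"layout holds {layout.n_roi} plants, requested {plants_per_tray}"
        )
    rng = np.random.default_rng(seed)
    fmap = default_frame_map(n_steps)
    write_frame_map(fmap, outdir / "pimframes_map.csv")

    gmap = GenotypeMap()
    tray_ids = [f"tray{i + 1}" for i in range(n_trays)]
    for ti, tray in enumerate(tray_ids):
        for pos in range(1, plants_per_tray + 1):
            geno = genotypes[(ti * plants_per_tray + pos - 1) % len(genotypes)]
            gmap.entries[(tray, pos)] = geno
    write_genotype_map(gmap, outdir / "genotype_map.csv")

    # per-plant statics drawn once so day-to-day change is smooth
    plant_static: dict[tuple[str, int], dict] = {}
    for tray in tray_ids:
        for pos in range(1, plants_per_tray + 1):
            geno = gmap.entries[(tray, pos)]
            f0, yss, nmax = GENOTYPE_BASELINES.get(geno, (0.79, 0.46, 2.0))
            plant_static[(tray, pos)] = {
                "fvfm0": float(np.clip(f0 + rng.normal(0, 0.008), 0.55, 0.92)),
                "yii_ss": float(np.clip(yss + rng.normal(0, 0.02), 0.1, 0.9)),
                "npq_max": float(max(0.2, nmax + rng.normal(0, 0.1))),
                "fo": float(rng.integers(700, 950)),
                "r0": float(rng.uniform(8.0, 10.5)),
                "growth": float(rng.uniform(1.1, 1.6)),
                "phase": float(rng.uniform(0, 2 * math.pi)),
                "n_lobes": int(rng.choice([0, 5, 6, 7])),
            }

    gt_frames: list[pd.DataFrame] = []
    half = (n_trays + 1) // 2
    for day in range(n_days):
        date = start_date + _dt.timedelta(days=day)
        for ti, tray in enumerate(tray_ids):
            treatment = "control" if ti < half else "fluc"
            plants = []
            for pos in range(1, plants_per_tray + 1):
                st = plant_static[(tray, pos)]
                fvfm_d = float(
                    np.clip(
                        st["fvfm0"]
                        - (0.004 if treatment == "fluc" else 0.0) * day
                        + 0.004 * math.sin(2 * math.pi * day / max(n_days, 2) + st["phase"]),
                        0.3,
                        0.95,
                    )
                )
                npq_mult = 1.2 if treatment == "fluc" else 1.0
                yii_t, npq_t = _smooth_trajectories(
                    fvfm_d, st["yii_ss"], st["npq_max"] * npq_mult, n_steps, rng
                )
                plants.append(
                    SyntheticPlantSpec(
                        roi_position=pos,
                        center=layout.centers[pos - 1],
                        radius=st["r0"] + st["growth"] * day,
                        fo_level=st["fo"],
                        fvfm_true=fvfm_d,
                        yii_trajectory=yii_t,
                        npq_trajectory=npq_t,
                        genotype=gmap.entries[(tray, pos)],
                        n_lobes=st["n_lobes"],
                    )
                )
            scene = SyntheticSceneSpec(
                plants=plants,
                layout=layout,
                image_shape=layout.image_shape,
                noise_sd=noise_sd,
                defects=(defects or {}).get((tray, day), []),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            mid = MeasurementID(treatment=treatment, date=date, sample_id=tray)
            stack, gt = render_scene(scene, fmap, mid)
            write_stack(stack, outdir / format_filename(mid))
            gt_frames.append(gt)
    pd.concat(gt_frames, ignore_index=True).to_csv(
        outdir / "ground_truth.csv", index=False
    )
    return outdir, layout
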