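"""Seeded generator of labeled cell tables and rendered smear images.

The generator emulates the statistical structure a vaginal smear presents to
the flowchart classifier: per-class diameter ranges from the comparative
literature, nucleus-area distributions matching the published measurement of
cornified-cell nuclei (mean 57.7 µm², SD 13.8 µm²), cornification-line
counts per class, and stage-dependent class mixtures.  Rendered images are
a deliberately simple surrogate for digitized slides: flat-shaded cells on a
bright background, high-contrast nuclei, thin dark cornification creases,
and optional erythrocyte/neutrophil clutter — enough structure to exercise
segmentation and morphometry end to end, with per-pixel ground truth.

A ``margin`` keeps generated features away from the classifier's decision
boundaries so that ground-truth labels are exactly recoverable; set the
margins to zero to stress boundary behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy import stats
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.morphology import erosion, disk as disk_selem

from .cell_model import (
    CellClass,
    CellRecord,
    ClassifierConfig,
    NucleusState,
    ValidationError,
)

__all__ = [
    "GeneratorConfig",
    "RenderConfig",
    "LabeledCellTable",
    "SmearImage",
    "PlacementError",
    "STAGES",
    "generate_cell_table",
    "render_smear",
]

STAGES = ("anestrus", "proestrus", "estrus", "early_diestrus")


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap at the requested
    density; carries the number of cells that did fit."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could not place {requested} cells without overlap; "
            f"achieved {achieved} — enlarge the canvas or reduce the count"
        )
        self.requested = requested
        self.achieved = achieved


def _default_diameter_ranges() -> dict[CellClass, tuple[float, float]]:
    return {
        CellClass.PARABASAL: (10.0, 20.0),
        CellClass.INTERMEDIATE: (20.0, 50.0),
        CellClass.SUPERFICIAL: (30.0, 75.0),
        CellClass.SQUAMOUS: (30.0, 75.0),
    }


def _default_nucleus_area() -> dict[CellClass, tuple[float, float, float]]:
    # (mean, sd, lower truncation) in µm²; intermediate truncated at the
    # classifier threshold so generated intermediates are consistent with it
    return {
        CellClass.PARABASAL: (60.0, 10.0, 1.0),
        CellClass.INTERMEDIATE: (95.0, 15.0, 79.5),
        CellClass.SUPERFICIAL: (57.7, 13.8, 0.0),
        CellClass.SQUAMOUS: (45.0, 12.0, 1.0),  # eroded remnant, when present
    }


def _default_line_probs() -> dict[CellClass, dict[int, float]]:
    # parabasal cells never show cornification (validation measurements of
    # 200 sub-20 µm cells found none); intermediates show at most one line
    return {
        CellClass.PARABASAL: {0: 1.0},
        CellClass.INTERMEDIATE: {0: 0.6, 1: 0.4},
        CellClass.SUPERFICIAL: {2: 0.35, 3: 0.3, 4: 0.2, 5: 0.15},
        CellClass.SQUAMOUS: {2: 0.35, 3: 0.3, 4: 0.2, 5: 0.15},
    }


def _default_state_probs() -> dict[CellClass, dict[NucleusState, float]]:
    return {
        CellClass.PARABASAL: {NucleusState.DEMARCATED: 1.0},
        CellClass.INTERMEDIATE: {NucleusState.DEMARCATED: 1.0},
        CellClass.SUPERFICIAL: {NucleusState.DEMARCATED: 1.0},
        CellClass.SQUAMOUS: {NucleusState.ABSENT: 0.9, NucleusState.ERODED: 0.1},
    }


def _default_stage_mixtures() -> dict[str, dict[CellClass, float]]:
    return {
        "anestrus": {
            CellClass.PARABASAL: 0.7,
            CellClass.INTERMEDIATE: 0.3,
            CellClass.SUPERFICIAL: 0.0,
            CellClass.SQUAMOUS: 0.0,
        },
        "proestrus": {
            CellClass.PARABASAL: 0.2,
            CellClass.INTERMEDIATE: 0.4,
            CellClass.SUPERFICIAL: 0.35,
            CellClass.SQUAMOUS: 0.05,
        },
        "estrus": {
            CellClass.PARABASAL: 0.0,
            CellClass.INTERMEDIATE: 0.0,
            CellClass.SUPERFICIAL: 0.3,
            CellClass.SQUAMOUS: 0.7,
        },
        "early_diestrus": {
            CellClass.PARABASAL: 0.2,
            CellClass.INTERMEDIATE: 0.4,
            CellClass.SUPERFICIAL: 0.3,
            CellClass.SQUAMOUS: 0.1,
        },
    }


def _default_distractor_rates() -> dict[str, tuple[float, float]]:
    # (erythrocytes, neutrophils) per epithelial cell: proestrus smears carry
    # heavy erythrocyte influx, early diestrus a neutrophil influx
    return {
        "anestrus": (0.2, 0.1),
        "proestrus": (2.0, 0.05),
        "estrus": (0.5, 0.0),
        "early_diestrus": (0.3, 1.0),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Per-class feature priors and stage mixtures for the generator.

    ``margin_um`` / ``margin_area_um2`` are exclusion buffers around the
    classifier's diameter and nuclear-area decision boundaries: with the
    defaults, no generated cell sits closer than 1 µm to the 20 µm diameter
    cut-off or closer than 3 µm² to the 79.5 µm² intermediate threshold.
    """

    diameter_ranges: dict[CellClass, tuple[float, float]] = field(
        default_factory=_default_diameter_ranges
    )
    nucleus_area: dict[CellClass, tuple[float, float, float]] = field(
        default_factory=_default_nucleus_area
    )
    line_probs: dict[CellClass, dict[int, float]] = field(default_factory=_default_line_probs)
    state_probs: dict[CellClass, dict[NucleusState, float]] = field(
        default_factory=_default_state_probs
    )
    stage_mixtures: dict[str, dict[CellClass, float]] = field(
        default_factory=_default_stage_mixtures
    )
    distractor_rates: dict[str, tuple[float, float]] = field(
        default_factory=_default_distractor_rates
    )
    margin_um: float = 1.0
    margin_area_um2: float = 3.0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self) -> None:
        if self.margin_um < 0 or self.margin_area_um2 < 0:
            raise ValidationError("margin: must be >= 0")
        for stage, mix in self.stage_mixtures.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"stage_mixtures[{stage}]: proportions sum to {total}, expected 1"
                )
        for cls, (lo, hi) in self.diameter_ranges.items():
            if not (0 < lo < hi):
                raise ValidationError(f"diameter_ranges[{cls.value}]: degenerate range ({lo}, {hi})")

    def effective_diameter_range(self, cls: CellClass) -> tuple[float, float]:
        """Diameter range after applying the boundary margin."""
        lo, hi = self.diameter_ranges[cls]
        cut = self.classifier.parabasal_max_diameter_um
        if cls is CellClass.PARABASAL:
            hi = min(hi, cut - self.margin_um)
        else:
            lo = max(lo, cut + self.margin_um)
        if not lo < hi:
            raise ValidationError(
                f"diameter range for {cls.value} collapses under margin {self.margin_um}"
            )
        return lo, hi

    def effective_area_truncation(self, cls: CellClass) -> float:
        """Lower truncation of the nucleus-area prior after the margin."""
        _, _, lower = self.nucleus_area[cls]
        if cls is CellClass.INTERMEDIATE:
            lower = max(lower, self.classifier.intermediate_min_nucleus_area_um2
                        + self.margin_area_um2)
        return lower


@dataclass
class LabeledCellTable:
    """Generated cell records with their ground-truth classes."""

    records: list[CellRecord]
    labels: list[CellClass]
    stage: str

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValidationError("records and labels must have equal length")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[CellRecord, CellClass]]:
        return iter(zip(self.records, self.labels))

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for rec, lab in self:
            rows.append(
                {
                    "cell_id": rec.cell_id,
                    "diameter_um": rec.diameter_um,
                    "cornification_lines": rec.cornification_lines,
                    "nucleus_area_um2": rec.nucleus_area_um2,
                    "nucleus_state": rec.nucleus_state.value,
                    "true_class": lab.value,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id",
                "diameter_um",
                "cornification_lines",
                "nucleus_area_um2",
                "nucleus_state",
                "true_class",
            ],
        )


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lower: float, size: int = 1) -> np.ndarray:
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cell_table(
    stage: str,
    n: int,
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> LabeledCellTable:
    """Draw ``n`` labeled cells for an estrous-cycle stage.

    Class labels follow the stage's configured mixture; features are drawn
    from the per-class priors with the margin buffers applied, so that with
    the default margins the flowchart classifier recovers every label.
    Reproducible for a fixed seed.
    """
    if config is None:
        config = GeneratorConfig()
    if stage not in config.stage_mixtures:
        raise ValidationError(
            f"stage: unknown stage {stage!r}; valid stages: {sorted(config.stage_mixtures)}"
        )
    if n < 0:
        raise ValidationError("n: must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    mix = config.stage_mixtures[stage]
    classes = list(CellClass)
    probs = np.array([mix.get(c, 0.0) for c in classes])
    records: list[CellRecord] = []
    labels: list[CellClass] = []
    width = max(4, len(str(max(n, 1))))
    drawn = rng.choice(len(classes), size=n, p=probs) if n else np.array([], dtype=int)
    for i, ci in enumerate(drawn):
        cls = classes[int(ci)]
        lo, hi = config.effective_diameter_range(cls)
        diameter = float(rng.uniform(lo, hi))

        line_probs = config.line_probs[cls]
        line_vals = sorted(line_probs)
        lines = int(rng.choice(line_vals, p=[line_probs[v] for v in line_vals]))

        state_probs = config.state_probs[cls]
        states = sorted(state_probs, key=lambda s: s.value)
        state = rng.choice([s.value for s in states], p=[state_probs[s] for s in states])
        state = NucleusState(str(state))

        if state is NucleusState.ABSENT:
            area = None
        else:
            mean, sd, _ = config.nucleus_area[cls]
            lower = config.effective_area_truncation(cls)
            area = float(_trunc_normal(rng, mean, sd, lower)[0])
            # keep the nucleus geometrically inside the cell footprint
            max_area = 0.45 * math.pi * (diameter / 2.0) ** 2
            area = min(area, max_area)
        records.append(
            CellRecord(
                cell_id=f"c{i + 1:0{width}d}",
                diameter_um=diameter,
                cornification_lines=lines,
                nucleus_area_um2=area,
                nucleus_state=state,
            )
        )
        labels.append(cls)
    return LabeledCellTable(records=records, labels=labels, stage=stage)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderConfig:
    """Appearance and geometry of the rendered smear.

    Intensities are normalized to [0, 1]; the defaults give strongly
    demarcated nuclei (Michelson contrast ~0.44 against cytoplasm) and
    weakly visible eroded remnants (~0.08).
    """

    microns_per_pixel: float = 0.5
    canvas_px: Optional[tuple[int, int]] = None  # (rows, cols); None = auto
    background: float = 0.92
    cytoplasm: float = 0.65
    nucleus_intensity: float = 0.25
    eroded_intensity: float = 0.55
    line_intensity: float = 0.35
    line_width_px: float = 2.0
    noise_sigma: float = 0.01
    border_margin_um: float = 5.0
    cell_gap_um: float = 2.0
    n_erythrocytes: int = 0
    n_neutrophils: int = 0
    max_retries: int = 3000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValidationError("microns_per_pixel: must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma: must be >= 0")


@dataclass
class SmearImage:
    """Rendered smear: raster, scale, per-pixel ground-truth mask, legend.

    Mask value 0 is background; value ``i`` marks the pixels of the cell
    described by ``legend[i]`` (epithelial cells only — distractor clutter
    is never in the mask).
    """

    pixels: np.ndarray
    microns_per_pixel: float
    mask: Optional[np.ndarray] = None
    legend: Optional[dict[int, dict]] = None

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValidationError("microns_per_pixel: must be > 0")
        if self.mask is not None and self.mask.shape != self.pixels.shape[:2]:
            raise ValidationError("mask: dimensions must equal the raster dimensions")


def _auto_canvas(radii_px: np.ndarray, border_px: float) -> tuple[int, int]:
    if radii_px.size == 0:
        return (256, 256)
    area = float(np.sum(np.pi * (radii_px + 4) ** 2))
    side = int(math.ceil(math.sqrt(area / 0.22))) + 2 * int(border_px) + 1
    side = max(side, int(4 * radii_px.max() + 2 * border_px + 8))
    return (side, side)


def _place_centers(
    rng: np.random.Generator,
    radii_px: np.ndarray,
    shape: tuple[int, int],
    border_px: float,
    gap_px: float,
    max_retries: int,
) -> np.ndarray:
    """Non-overlapping centers by rejection sampling, largest first."""
    order = np.argsort(-radii_px, kind="stable")
    centers = np.full((len(radii_px), 2), np.nan)
    placed_r: list[float] = []
    placed_c: list[np.ndarray] = []
    for idx in order:
        r = radii_px[idx]
        lo_r, hi_r = border_px + r, shape[0] - border_px - r
        lo_c, hi_c = border_px + r, shape[1] - border_px - r
        if lo_r >= hi_r or lo_c >= hi_c:
            raise PlacementError(len(radii_px), len(placed_r))
        ok = False
        for _ in range(max_retries):
            cand = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
            if placed_c:
                d = np.linalg.norm(np.array(placed_c) - cand, axis=1)
                if np.any(d < np.array(placed_r) + r + gap_px):
                    continue
            centers[idx] = cand
            placed_r.append(r + 0.0)
            placed_c.append(cand)
            ok = True
            break
        if not ok:
            raise PlacementError(len(radii_px), len(placed_r))
    return centers


def _cell_outline(
    rng: np.random.Generator, a_px: float, b_px: float, cornified: bool
) -> np.ndarray:
    """Vertices (local frame, unrotated) of the cell outline.

    The outline always contains the points (±a, 0), so the maximum caliper
    diameter of the drawn region equals 2a (all other vertices lie inside
    the bounding ellipse).  Cornified cells get an angular polygon, others a
    smooth ellipse.
    """
    if cornified:
        m = int(rng.integers(7, 11))
        inner = np.sort(rng.uniform(0.12, math.pi - 0.12, size=m // 2 - 1))
        lower = np.sort(rng.uniform(math.pi + 0.12, 2 * math.pi - 0.12,
                                    size=m - m // 2 - 1))
        angles = np.concatenate(([0.0], inner, [math.pi], lower))
        shrink = rng.uniform(0.85, 1.0, size=angles.size)
        shrink[angles == 0.0] = 1.0
        shrink[angles == math.pi] = 1.0
    else:
        angles = np.linspace(0, 2 * math.pi, 72, endpoint=False)
        shrink = np.ones_like(angles)
        shrink[(angles != 0.0) & (np.abs(angles - math.pi) > 1e-9)] = 1.0
    x = a_px * np.cos(angles) * shrink
    y = b_px * np.sin(angles) * shrink
    return np.stack([x, y], axis=1)


def render_smear(
    table: LabeledCellTable,
    config: Optional[RenderConfig] = None,
) -> SmearImage:
    """Render a labeled cell table into a grayscale smear image.

    Each cell is drawn as a filled region whose longest axis equals its
    diameter in pixels: an angular polygon when it shows at least two
    cornification lines, a smooth ellipse otherwise.  Demarcated nuclei are
    dark disks of the record's nuclear area, eroded nuclei low-contrast
    disks, absent nuclei are omitted.  Cornification lines are thin dark
    creases parallel to the long axis, placed clear of the nucleus.
    Erythrocyte and neutrophil clutter is added on request but never enters
    the ground-truth mask.  Identical inputs and seed give a byte-identical
    raster and mask.
    """
    if config is None:
        config = RenderConfig()
    rng = np.random.default_rng(config.seed)
    mpp = config.microns_per_pixel

    radii_px = np.array([r.diameter_um / (2 * mpp) for r in table.records])
    border_px = config.border_margin_um / mpp
    shape = config.canvas_px or _auto_canvas(radii_px, border_px)
    img = np.full(shape, config.background, dtype=np.float64)
    mask = np.zeros(shape, dtype=np.int32)
    legend: dict[int, dict] = {}

    if len(table) > 0:
        centers = _place_centers(
            rng, radii_px, shape, border_px, config.cell_gap_um / mpp, config.max_retries
        )
        for i, (rec, label) in enumerate(table):
            _draw_cell(img, mask, i + 1, rec, centers[i], rng, config)
            legend[i + 1] = {"cell_id": rec.cell_id, "true_class": label.value}

    _draw_distractors(img, mask, rng, config)

    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return SmearImage(pixels=img, microns_per_pixel=mpp, mask=mask, legend=legend)


def _draw_cell(
    img: np.ndarray,
    mask: np.ndarray,
    region_id: int,
    rec: CellRecord,
    center: np.ndarray,
    rng: np.random.Generator,
    config: RenderConfig,
) -> None:
    mpp = config.microns_per_pixel
    a = rec.diameter_um / (2 * mpp)
    aspect = float(rng.uniform(0.75, 0.95))
    b = a * aspect
    theta = float(rng.uniform(0, math.pi))
    cornified = rec.cornification_lines >= 2

    verts = _cell_outline(rng, a, b, cornified)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    pts = verts @ rot.T + center[::-1]  # verts are (x, y); center is (row, col)
    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=img.shape)
    img[rr, cc] = config.cytoplasm + float(rng.uniform(-0.015, 0.015))
    mask[rr, cc] = region_id

    # work on a local patch around the cell from here on
    r0, c0 = int(rr.min()), int(cc.min())
    local = np.zeros((int(rr.max()) - r0 + 1, int(cc.max()) - c0 + 1), dtype=bool)
    local[rr - r0, cc - c0] = True

    # nucleus at the cell center, clipped to the interior
    nucleus_r_px = 0.0
    if rec.nucleus_state is not NucleusState.ABSENT and rec.nucleus_area_um2:
        nucleus_r_px = math.sqrt(rec.nucleus_area_um2 / math.pi) / mpp
        nr, nc = draw_disk((center[0], center[1]), nucleus_r_px, shape=img.shape)
        keep = local[nr - r0, nc - c0]
        nr, nc = nr[keep], nc[keep]
        intensity = (
            config.nucleus_intensity
            if rec.nucleus_state is NucleusState.DEMARCATED
            else config.eroded_intensity
        )
        img[nr, nc] = intensity

    # cornification creases: chords parallel to the long axis, clear of the
    # nucleus, clipped to an eroded interior so they never touch the rim
    if rec.cornification_lines >= 1:
        interior = erosion(local, disk_selem(2))
        offsets = _line_offsets(
            rec.cornification_lines, nucleus_r_px, b, spacing=3.5 / (mpp / 0.5)
        )
        if offsets:
            rows, cols = np.nonzero(interior)
            rel = np.stack([cols + c0 - center[1], rows + r0 - center[0]], axis=1)
            # perpendicular coordinate in the rotated cell frame
            perp = rel @ np.array([-math.sin(theta), math.cos(theta)])
            for o in offsets:
                sel = np.abs(perp - o) <= config.line_width_px / 2.0
                img[rows[sel] + r0, cols[sel] + c0] = config.line_intensity


def _line_offsets(
    n_lines: int, nucleus_r_px: float, b_px: float, spacing: float
) -> list[float]:
    """Perpendicular chord offsets that avoid the nucleus band and stay
    within 85% of the cell's half-width; at most ``n_lines`` of them."""
    base = nucleus_r_px + 3.0 if nucleus_r_px > 0 else 3.0
    limit = 0.85 * b_px
    offsets: list[float] = []
    j = 0
    while len(offsets) < n_lines:
        o = base + spacing * (j // 2)
        if o > limit:
            break
        offsets.append(o if j % 2 == 0 else -o)
        j += 1
    return offsets


def _draw_distractors(
    img: np.ndarray, mask: np.ndarray, rng: np.random.Generator, config: RenderConfig
) -> None:
    """Erythrocytes (small pale-centered disks) and neutrophils (clusters of
    tiny dark lobes), placed on free background, never entering the mask."""
    mpp = config.microns_per_pixel
    h, w = img.shape

    def free_spot(radius_px: float) -> Optional[tuple[float, float]]:
        for _ in range(200):
            r0 = rng.uniform(radius_px + 2, h - radius_px - 2)
            c0 = rng.uniform(radius_px + 2, w - radius_px - 2)
            rr, cc = draw_disk((r0, c0), radius_px + 2, shape=img.shape)
            # clear of cells and of previously drawn clutter, so distractors
            # never merge into clumps that could pass the debris filter
            if not np.any(mask[rr, cc]) and np.all(img[rr, cc] >= config.background - 0.02):
                return (r0, c0)
        return None

    ery_r = 3.0 / mpp  # ~6 µm diameter
    for _ in range(config.n_erythrocytes):
        spot = free_spot(ery_r)
        if spot is None:
            continue
        rr, cc = draw_disk(spot, ery_r, shape=img.shape)
        img[rr, cc] = 0.55
        rr, cc = draw_disk(spot, ery_r * 0.45, shape=img.shape)
        img[rr, cc] = 0.75  # biconcave pale center

    lobe_r = 1.5 / mpp
    for _ in range(config.n_neutrophils):
        spot = free_spot(4.5 / mpp)
        if spot is None:
            continue
        n_lobes = int(rng.integers(3, 5))
        for _ in range(n_lobes):
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, 2.0 / mpp)
            rr, cc = draw_disk(
                (spot[0] + rad * math.sin(ang), spot[1] + rad * math.cos(ang)),
                lobe_r,
                shape=img.shape,
            )
            img[rr, cc] = 0.35
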