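"""Morphometric measurement of cells from smear images.

Turns a rendered (or otherwise acquired) grayscale smear into the feature
table the flowchart classifier consumes: per cell, the maximum caliper
(Feret) diameter in µm, the nuclear area in µm² with its qualitative state,
and the number of cornification lines.

Segmentation is deliberately classical: global intensity thresholding,
8-connected components, then the exclusion rules of the measurement
protocol — debris below a minimum size, regions touching the image border,
and low-solidity regions (the overlap proxy) are dropped and logged.
Inside each cell the nucleus is recovered as the largest compact dark blob
(a binary opening removes thin creases first) and its demarcation is judged
by Michelson contrast against the surrounding cytoplasm.  Cornification
lines are the remaining thin dark structures, skeletonized, merged when
collinear, and counted if long enough relative to the cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import dilation, disk as disk_selem, opening, skeletonize

from .cell_model import CellRecord, NucleusState, ValidationError
from .synthetic_smear import SmearImage

__all__ = [
    "MorphometryConfig",
    "SegmentedCell",
    "ExclusionLog",
    "segment_cells",
    "measure_cell",
    "measure_smear",
]


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunable measurement parameters.

    ``min_cell_diameter_um`` sets the debris floor (a region must be at
    least as large as a disk of this diameter).  ``dark_delta`` is how far
    below the cytoplasm's median intensity a pixel must fall to count as
    nuclear/crease material; ``demarcation_contrast`` is the Michelson
    contrast separating a demarcated from an eroded nucleus.  Lines shorter
    than ``min_line_fraction`` of the Feret diameter are ignored as noise.
    """

    min_cell_diameter_um: float = 8.0
    max_solidity_deficit: float = 0.2  # solidity < 0.8 flags overlap
    dark_delta: float = 0.06
    demarcation_contrast: float = 0.2
    min_nucleus_area_um2: float = 10.0
    nucleus_opening_radius_um: float = 1.5
    min_line_fraction: float = 0.25
    collinear_angle_deg: float = 15.0
    equivalent_circle_diameter: bool = False

    @property
    def min_cell_area_um2(self) -> float:
        return math.pi * (self.min_cell_diameter_um / 2.0) ** 2


@dataclass
class SegmentedCell:
    """One connected foreground region with its exclusion flags."""

    region_id: int
    slice_rc: tuple[slice, slice]
    mask: np.ndarray  # boolean patch within slice_rc
    centroid: tuple[float, float]
    area_px: int
    touches_border: bool
    overlapping: bool

    @property
    def excluded(self) -> bool:
        return self.touches_border or self.overlapping


@dataclass
class ExclusionLog:
    """Counts of regions dropped at segmentation time."""

    debris: int = 0
    boundary: int = 0
    overlap: int = 0
    kept: int = 0


def _to_gray(image: Union[SmearImage, np.ndarray]) -> np.ndarray:
    pixels = image.pixels if isinstance(image, SmearImage) else np.asarray(image)
    if pixels.ndim == 3:
        # luminance conversion for RGB input
        pixels = pixels @ np.array([0.2126, 0.7152, 0.0722])
    pixels = pixels.astype(np.float64)
    if pixels.max() > 1.0:
        pixels = pixels / (65535.0 if pixels.max() > 255 else 255.0)
    return pixels


def _resolve_scale(
    image: Union[SmearImage, np.ndarray], microns_per_pixel: Optional[float]
) -> float:
    if microns_per_pixel is not None:
        if microns_per_pixel <= 0:
            raise ValidationError("microns_per_pixel: must be > 0")
        return microns_per_pixel
    if isinstance(image, SmearImage):
        return image.microns_per_pixel
    raise ValidationError("microns_per_pixel: required for a raw raster")


def segment_cells(
    image: Union[SmearImage, np.ndarray],
    microns_per_pixel: Optional[float] = None,
    config: Optional[MorphometryConfig] = None,
    include_flagged: bool = False,
) -> list[SegmentedCell]:
    """Find candidate cell regions in a smear image.

    Foreground is everything darker than the automatic (Otsu) threshold;
    8-connected components smaller than the debris floor are discarded, and
    border-touching or low-solidity (overlapping) regions are flagged and —
    unless ``include_flagged`` — dropped.  A blank image yields an empty
    list.
    """
    cells, _ = _segment_with_log(image, microns_per_pixel, config)
    if include_flagged:
        return cells
    return [c for c in cells if not c.excluded]


def _segment_with_log(
    image: Union[SmearImage, np.ndarray],
    microns_per_pixel: Optional[float],
    config: Optional[MorphometryConfig],
) -> tuple[list[SegmentedCell], ExclusionLog]:
    if config is None:
        config = MorphometryConfig()
    mpp = _resolve_scale(image, microns_per_pixel)
    gray = _to_gray(image)
    log = ExclusionLog()

    if gray.size == 0 or float(gray.max() - gray.min()) < 0.05:
        return [], log  # blank: no usable intensity structure

    thresh = threshold_otsu(gray)
    foreground = gray < thresh
    labels = cc_label(foreground, connectivity=2)
    min_area_px = config.min_cell_area_um2 / mpp**2

    cells: list[SegmentedCell] = []
    h, w = gray.shape
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            log.debris += 1
            continue
        rmin, cmin, rmax, cmax = prop.bbox
        touches = rmin == 0 or cmin == 0 or rmax == h or cmax == w
        overlapping = prop.solidity < 1.0 - config.max_solidity_deficit
        if touches:
            log.boundary += 1
        elif overlapping:
            log.overlap += 1
        else:
            log.kept += 1
        cells.append(
            SegmentedCell(
                region_id=prop.label,
                slice_rc=prop.slice,
                mask=prop.image.copy(),
                centroid=tuple(prop.centroid),
                area_px=int(prop.area),
                touches_border=touches,
                overlapping=overlapping,
            )
        )
    return cells, log


def measure_cell(
    cell: SegmentedCell,
    image: Union[SmearImage, np.ndarray],
    microns_per_pixel: Optional[float] = None,
    config: Optional[MorphometryConfig] = None,
    cell_id: Optional[str] = None,
) -> CellRecord:
    """Measure one segmented region into a CellRecord.

    Diameter is the maximum Feret (caliper) diameter of the region times the
    scale (equivalent-circle diameter on request).  The nucleus is the
    largest dark blob surviving a binary opening that removes thin creases;
    its state is ABSENT when no blob clears the minimum-area floor, ERODED
    when its contrast against the cytoplasm falls below the demarcation
    threshold, DEMARCATED otherwise.  Cornification lines are thin dark
    ridge components, merged when collinear, counted when at least a quarter
    of the Feret diameter long.
    """
    if config is None:
        config = MorphometryConfig()
    mpp = _resolve_scale(image, microns_per_pixel)
    gray = _to_gray(image)

    sl = cell.slice_rc
    if (
        sl[0].start < 0
        or sl[1].start < 0
        or sl[0].stop > gray.shape[0]
        or sl[1].stop > gray.shape[1]
    ):
        raise ValidationError("cell: region lies outside the image bounds")
    patch = gray[sl]
    m = cell.mask

    prop = regionprops(m.astype(np.uint8))[0]
    if config.equivalent_circle_diameter:
        diameter_px = prop.equivalent_diameter_area
    else:
        diameter_px = prop.feret_diameter_max
    diameter_um = float(diameter_px * mpp)

    values = patch[m]
    cyto_med = float(np.median(values))
    dark = m & (patch < cyto_med - config.dark_delta)

    open_r = max(1, round(config.nucleus_opening_radius_um / mpp))
    blobs = opening(dark, disk_selem(open_r))
    blob_labels = cc_label(blobs, connectivity=2)
    nucleus_mask = None
    if blob_labels.max() > 0:
        sizes = np.bincount(blob_labels.ravel())[1:]
        best = int(np.argmax(sizes)) + 1
        if sizes[best - 1] * mpp**2 >= config.min_nucleus_area_um2:
            seed = blob_labels == best
            # the opening shaves the blob boundary; recover the full dark
            # component the seed belongs to, bounded by a dilation of the
            # seed so attached creases can never inflate the area
            dark_labels = cc_label(dark, connectivity=2)
            comp_ids = np.unique(dark_labels[seed])
            component = np.isin(dark_labels, comp_ids[comp_ids > 0])
            nucleus_mask = component & dilation(seed, disk_selem(open_r + 1))

    if nucleus_mask is None:
        state = NucleusState.ABSENT
        area = None
    else:
        area = float(nucleus_mask.sum() * mpp**2)
        nuc_med = float(np.median(patch[nucleus_mask]))
        cyto_pixels = m & ~dark
        cyto_ref = float(np.median(patch[cyto_pixels])) if cyto_pixels.any() else cyto_med
        denom = cyto_ref + nuc_med
        contrast = (cyto_ref - nuc_med) / denom if denom > 0 else 0.0
        state = (
            NucleusState.DEMARCATED
            if contrast >= config.demarcation_contrast
            else NucleusState.ERODED
        )

    lines = _count_lines(dark, nucleus_mask, diameter_px, config)

    return CellRecord(
        cell_id=cell_id if cell_id is not None else f"region_{cell.region_id}",
        diameter_um=diameter_um,
        cornification_lines=lines,
        nucleus_area_um2=area,
        nucleus_state=state,
    )


def _count_lines(
    dark: np.ndarray,
    nucleus_mask: Optional[np.ndarray],
    feret_px: float,
    config: MorphometryConfig,
) -> int:
    """Count thin dark ridge structures, excluding the nucleus blob."""
    ridges = dark.copy()
    if nucleus_mask is not None:
        ridges &= ~dilation(nucleus_mask, disk_selem(2))
    if not ridges.any():
        return 0
    skel = skeletonize(ridges)
    labels = cc_label(skel, connectivity=2)
    n = labels.max()
    if n == 0:
        return 0

    segments = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        pts = np.stack([rr, cc], axis=1).astype(np.float64)
        length = len(rr)
        if length < 3:
            continue
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
        proj = centered @ direction
        p0 = pts[np.argmin(proj)]
        p1 = pts[np.argmax(proj)]
        segments.append({"len": length, "dir": direction, "ends": (p0, p1)})

    segments = _merge_collinear(segments, config.collinear_angle_deg)
    min_len = config.min_line_fraction * feret_px
    return sum(1 for s in segments if s["len"] >= min_len)


def _merge_collinear(segments: list[dict], angle_tol_deg: float) -> list[dict]:
    """Merge pairs of skeleton segments that are nearly collinear and close,
    as happens when one crease is interrupted (e.g. by the nucleus)."""
    merged = True
    segs = list(segments)
    while merged and len(segs) > 1:
        merged = False
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                a, b = segs[i], segs[j]
                cosang = abs(float(np.dot(a["dir"], b["dir"])))
                if cosang < math.cos(math.radians(angle_tol_deg)):
                    continue
                gap = min(
                    np.linalg.norm(pa - pb) for pa in a["ends"] for pb in b["ends"]
                )
                span = a["len"] + b["len"]
                if gap > max(12.0, 0.6 * span):
                    continue
                # lateral offset of b's midpoint from a's line
                mid_b = (b["ends"][0] + b["ends"][1]) / 2
                mid_a = (a["ends"][0] + a["ends"][1]) / 2
                rel = mid_b - mid_a
                lateral = abs(rel[0] * a["dir"][1] - rel[1] * a["dir"][0])
                if lateral > 4.0:
                    continue
                ends = [*a["ends"], *b["ends"]]
                d = a["dir"]
                proj = [float(np.dot(e, d)) for e in ends]
                p0 = ends[int(np.argmin(proj))]
                p1 = ends[int(np.argmax(proj))]
                segs[i] = {"len": a["len"] + b["len"] + gap, "dir": d, "ends": (p0, p1)}
                del segs[j]
                merged = True
                break
            if merged:
                break
    return segs


def measure_smear(
    image: Union[SmearImage, np.ndarray],
    microns_per_pixel: Optional[float] = None,
    config: Optional[MorphometryConfig] = None,
) -> tuple[list[CellRecord], ExclusionLog]:
    """Segment and measure every retained cell of a smear.

    Returns the records together with the exclusion log (debris, boundary
    and overlap counts).  When the image carries a ground-truth mask, each
    record's ``cell_id`` is taken from the legend entry of the mask region
    it overlaps most, so measured records can be matched back to generated
    ground truth.
    """
    if config is None:
        config = MorphometryConfig()
    cells, log = _segment_with_log(image, microns_per_pixel, config)

    mask = image.mask if isinstance(image, SmearImage) else None
    legend = image.legend if isinstance(image, SmearImage) else None

    records: list[CellRecord] = []
    for cell in cells:
        if cell.excluded:
            continue
        cell_id = None
        if mask is not None and legend:
            overlap = mask[cell.slice_rc][cell.mask]
            overlap = overlap[overlap > 0]
            if overlap.size:
                gt_id = int(np.bincount(overlap).argmax())
                if gt_id in legend:
                    cell_id = legend[gt_id]["cell_id"]
        records.append(measure_cell(cell, image, microns_per_pixel, config, cell_id=cell_id))
    return records, log
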