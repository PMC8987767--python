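"""File formats: cell-table CSV, ratings CSV, configs, images, reports.

The cell-table schema is strict: columns ``cell_id, diameter_um,
cornification_lines, nucleus_area_um2, nucleus_state`` (plus an optional
``true_class``).  An absent nucleus area is an *empty* field — 0 is a legal
measurement and must never collide with absence, so "NaN"/"null"/"NA"
literals are rejected with a named-column error.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .cell_model import CellClass, CellRecord, ClassifierConfig, NucleusState, ValidationError
from .synthetic_smear import LabeledCellTable, SmearImage

__all__ = [
    "CELL_TABLE_COLUMNS",
    "read_cell_table",
    "write_cell_table",
    "read_ratings",
    "write_rating_matrix",
    "load_classifier_config",
    "write_image",
    "read_image",
    "write_mask",
    "report_to_json",
    "RunManifest",
    "write_manifest",
]

CELL_TABLE_COLUMNS = [
    "cell_id",
    "diameter_um",
    "cornification_lines",
    "nucleus_area_um2",
    "nucleus_state",
]

_NA_LITERALS = {"nan", "na", "n/a", "null", "none", "<na>"}


def read_cell_table(path: Union[str, Path]) -> tuple[list[CellRecord], Optional[list[CellClass]]]:
    """Read a cell-table CSV; returns records and, when a ``true_class``
    column is present, the ground-truth labels."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cell table {path}: missing columns {missing}")

    records: list[CellRecord] = []
    for idx, row in df.iterrows():
        area_raw = row["nucleus_area_um2"].strip()
        if area_raw.lower() in _NA_LITERALS:
            raise ValidationError(
                f"cell table {path} row {idx}: nucleus_area_um2 must be an empty "
                f"field when absent, not the literal {area_raw!r}"
            )
        area = None if area_raw == "" else _parse_float(area_raw, "nucleus_area_um2", idx, path)
        state_raw = row["nucleus_state"].strip().lower()
        try:
            state = NucleusState(state_raw)
        except ValueError:
            raise ValidationError(
                f"cell table {path} row {idx}: nucleus_state must be one of "
                f"{[s.value for s in NucleusState]}, got {state_raw!r}"
            ) from None
        records.append(
            CellRecord(
                cell_id=row["cell_id"],
                diameter_um=_parse_float(row["diameter_um"], "diameter_um", idx, path),
                cornification_lines=_parse_int(
                    row["cornification_lines"], "cornification_lines", idx, path
                ),
                nucleus_area_um2=area,
                nucleus_state=state,
            )
        )

    labels = None
    if "true_class" in df.columns:
        labels = []
        for idx, raw in df["true_class"].items():
            try:
                labels.append(CellClass(raw.strip().lower()))
            except ValueError:
                raise ValidationError(
                    f"cell table {path} row {idx}: unknown true_class {raw!r}"
                ) from None
    return records, labels


def _parse_float(raw: str, column: str, idx, path) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(
            f"cell table {path} row {idx}: {column} must be numeric, got {raw!r}"
        ) from None


def _parse_int(raw: str, column: str, idx, path) -> int:
    try:
        return int(raw)
    except ValueError:
        raise ValidationError(
            f"cell table {path} row {idx}: {column} must be an integer, got {raw!r}"
        ) from None


def write_cell_table(
    records: Sequence[CellRecord],
    path: Union[str, Path],
    labels: Optional[Sequence[CellClass]] = None,
    classes: Optional[Sequence[CellClass]] = None,
) -> None:
    """Write records to CSV; absent nucleus areas become empty fields.

    ``labels`` adds a ``true_class`` column, ``classes`` a ``predicted_class``
    column.
    """
    rows = []
    for i, rec in enumerate(records):
        row = {
            "cell_id": rec.cell_id,
            "diameter_um": rec.diameter_um,
            "cornification_lines": rec.cornification_lines,
            "nucleus_area_um2": "" if rec.nucleus_area_um2 is None else rec.nucleus_area_um2,
            "nucleus_state": rec.nucleus_state.value,
        }
        if labels is not None:
            row["true_class"] = labels[i].value
        if classes is not None:
            row["predicted_class"] = classes[i].value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labeled_table(path: Union[str, Path], stage: str = "unknown") -> LabeledCellTable:
    records, labels = read_cell_table(path)
    if labels is None:
        raise ValidationError(f"cell table {path}: no true_class column")
    return LabeledCellTable(records=records, labels=labels, stage=stage)


def read_ratings(path: Union[str, Path]) -> pd.DataFrame:
    """Read a long-format ratings CSV (subject_id, rater_id, category)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["subject_id", "rater_id", "category"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"ratings table {path}: missing columns {missing}")
    return df[expected]


def write_rating_matrix(matrix, path: Union[str, Path]) -> None:
    """Export a RatingMatrix as CSV with a category header row."""
    pd.DataFrame(matrix.counts, columns=list(matrix.categories)).to_csv(path, index=False)


def load_classifier_config(path: Union[str, Path]) -> ClassifierConfig:
    """Load classifier thresholds from a YAML or JSON file mirroring the
    ClassifierConfig field names; unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if data is None:
        return ClassifierConfig()
    if not isinstance(data, dict):
        raise ValidationError(f"config {path}: expected a mapping")
    valid = {f.name for f in dataclasses.fields(ClassifierConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValidationError(f"config {path}: unknown keys {sorted(unknown)}")
    if "cornified_min_lines" in data:
        data["cornified_min_lines"] = int(data["cornified_min_lines"])
    return ClassifierConfig(**data)


def write_image(image: SmearImage, path: Union[str, Path], bit_depth: int = 8) -> None:
    """Write the raster as PNG/TIFF, 8-bit or 16-bit grayscale."""
    path = Path(path)
    arr = np.clip(image.pixels, 0.0, 1.0)
    if bit_depth == 8:
        Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)
    elif bit_depth == 16:
        data = (arr * 65535).round().astype(np.uint16)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, data)
        else:
            Image.fromarray(data).save(path)  # 16-bit grayscale PNG
    else:
        raise ValidationError(f"bit_depth: must be 8 or 16, got {bit_depth}")


def read_image(
    path: Union[str, Path], microns_per_pixel: Optional[float] = None
) -> SmearImage:
    """Read a PNG/TIFF smear image.  The scale comes from the argument or a
    ``<image>.scale.json`` sidecar with a ``microns_per_pixel`` key."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path))
    else:
        arr = np.asarray(Image.open(path))
    arr = arr.astype(np.float64)
    if arr.max() > 255:
        arr = arr / 65535.0
    elif arr.max() > 1.0:
        arr = arr / 255.0
    if microns_per_pixel is None:
        sidecar = path.with_suffix(path.suffix + ".scale.json")
        if sidecar.exists():
            microns_per_pixel = json.loads(sidecar.read_text())["microns_per_pixel"]
        else:
            raise ValidationError(
                f"image {path}: no scale given and no sidecar {sidecar.name} found"
            )
    return SmearImage(pixels=arr, microns_per_pixel=float(microns_per_pixel))


def write_mask(image: SmearImage, path: Union[str, Path]) -> None:
    """Write the ground-truth mask as 16-bit integer PNG/TIFF plus a legend
    JSON alongside."""
    if image.mask is None:
        raise ValidationError("image: no ground-truth mask to write")
    path = Path(path)
    data = image.mask.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        Image.fromarray(data).save(path)  # 16-bit integer PNG
    legend_path = path.with_suffix(path.suffix + ".legend.json")
    legend_path.write_text(json.dumps(image.legend or {}, indent=2))


def report_to_json(report, path: Optional[Union[str, Path]] = None) -> str:
    """Serialize a report dataclass (calibration, agreement, stage call) to
    JSON, converting arrays and enums to plain types."""

    def default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if hasattr(obj, "value"):
            return obj.value
        raise TypeError(f"cannot serialize {type(obj)}")

    if dataclasses.is_dataclass(report) and not isinstance(report, type):
        payload = dataclasses.asdict(
            report,
            dict_factory=lambda items: {
                (k.value if hasattr(k, "value") else k): v for k, v in items
            },
        )
    else:
        payload = report
    text = json.dumps(payload, indent=2, default=default)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass
class RunManifest:
    """Record of one CLI run, sufficient to reproduce its outputs."""

    command: str
    config: dict
    seed: Optional[int]
    inputs: list[str]
    outputs: list[str]
    package_version: str
    timestamp: str


def write_manifest(
    command: str,
    config: dict,
    seed: Optional[int],
    inputs: Sequence[Union[str, Path]],
    outputs: Sequence[Union[str, Path]],
    path: Union[str, Path],
) -> RunManifest:
    from . import __version__

    manifest = RunManifest(
        command=command,
        config=config,
        seed=seed,
        inputs=[str(p) for p in inputs],
        outputs=[str(p) for p in outputs],
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    Path(path).write_text(report_to_json(manifest))
    return manifest
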