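"""File formats shared across the pipeline.

Plates travel as long-format CSV (``well,sample_id,group,dilution,time_h,
fluorescence_au``; UTF-8, '.' decimal separator); images as 16-bit
grayscale TIFF with a JSON ground-truth/metadata sidecar; tabular results
as TSV whose first line is a ``#`` comment carrying provenance (seed and
configuration hash), so every output can be traced to the run that wrote
it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

PLATE_COLUMNS = ["well", "sample_id", "group", "dilution", "time_h", "fluorescence_au"]


def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"plate table lacks columns: {sorted(missing)}")
    plate[PLATE_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    plate = pd.read_csv(path, comment="#")
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"{path}: plate CSV lacks columns: {sorted(missing)}")
    return plate


def write_table(
    table: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a TSV, optionally preceded by one ``#`` provenance line."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def save_image(path: str | Path, image: np.ndarray, sidecar: dict | None = None) -> None:
    """Write a uint16 TIFF (single- or multi-channel) plus a JSON sidecar."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))
    if sidecar is not None:
        Path(path).with_suffix(".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True), encoding="utf-8"
        )


def load_image(path: str | Path) -> tuple[np.ndarray, dict | None]:
    image = tifffile.imread(path)
    sidecar_path = Path(path).with_suffix(".json")
    sidecar = (
        json.loads(sidecar_path.read_text(encoding="utf-8"))
        if sidecar_path.exists()
        else None
    )
    return image, sidecar


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8"
    )
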