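"""CSV / JSON / YAML readers and writers for the pipeline's file formats.

Formats (all plain text):

* neuron coordinates — ``animal_id,group,x_um,y_um``, one row per neuron;
* ROI contour — ``x_um,y_um`` ordered vertices, closing edge implicit;
* freezing — long format ``animal_id,group,phase,percent_freezing``;
* matrices — row-major CSV without header (one file per map);
* configuration — JSON or YAML by file extension.

Floats are written with a fixed format so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .behavior import FreezingRecord, records_to_frame
from .topography import CountMatrix, NeuronMap, RoiContour

FLOAT_FMT = "%.6f"


def write_neuron_maps(maps: Sequence[NeuronMap], path: str | Path) -> None:
    rows = []
    for m in maps:
        for x, y in m.coordinates:
            rows.append({"animal_id": m.animal_id, "group": m.group, "x_um": x, "y_um": y})
    df = pd.DataFrame(rows, columns=["animal_id", "group", "x_um", "y_um"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_neuron_maps(path: str | Path) -> list[NeuronMap]:
    df = pd.read_csv(path)
    need = {"animal_id", "group", "x_um", "y_um"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    maps = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=False):
        maps.append(
            NeuronMap(
                animal_id=str(animal),
                group=str(group),
                coordinates=sub[["x_um", "y_um"]].to_numpy(dtype=float),
            )
        )
    return maps


def write_roi(roi: RoiContour, path: str | Path) -> None:
    pd.DataFrame(roi.vertices, columns=["x_um", "y_um"]).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_roi(path: str | Path) -> RoiContour:
    df = pd.read_csv(path)
    need = {"x_um", "y_um"}
    if need - set(df.columns):
        raise ValueError(f"{path}: ROI file needs columns x_um,y_um")
    return RoiContour(df[["x_um", "y_um"]].to_numpy(dtype=float))


def write_freezing(records: Iterable[FreezingRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_freezing(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"animal_id", "group", "phase", "percent_freezing"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_matrix(values: np.ndarray, path: str | Path) -> None:
    """Row-major matrix CSV without header; NaN for undefined entries."""
    np.savetxt(path, np.asarray(values, dtype=float), delimiter=",", fmt=FLOAT_FMT)


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    np.savetxt(path, matrix.counts, delimiter=",", fmt="%d")


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML configuration mapping (extension-dispatched)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
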