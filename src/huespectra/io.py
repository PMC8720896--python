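"""CSV/JSON readers and writers for spectra, PQS points and datasets.

Dialect is fixed to avoid locale drift: comma separator, '.' decimal,
UTF-8, mandatory header row.  Spectrum CSVs round-trip losslessly (values
are written with 17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import FitReport, RegressionDataset
from .spectra import HueSpectrum

__all__ = [
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_pqs_csv",
    "read_dataset_csv",
    "write_dataset_csv",
    "write_fit_report",
]

_DEG_COLUMNS = [f"deg_{d}" for d in range(1, 361)]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_spectrum_csv(spectrum: HueSpectrum, path: str | Path) -> Path:
    """Write one spectrum as 360 ``degree,value`` rows plus a JSON sidecar
    (threshold, n_included, total_pixels, normalization, crop range)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("degree,value\n")
        for d, v in zip(range(1, 361), spectrum.values):
            fh.write(f"{d},{v:.17g}\n")
    meta = {
        "threshold": spectrum.threshold_used,
        "n_included": spectrum.n_included,
        "total_pixels": spectrum.total_pixels,
        "normalization": spectrum.normalization,
        "crop_range": list(spectrum.crop_range) if spectrum.crop_range else None,
        "aggregate": spectrum.aggregate,
    }
    _sidecar(path).write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n", encoding="utf-8")
    return path


def read_spectrum_csv(path: str | Path) -> HueSpectrum:
    """Read a spectrum written by :func:`write_spectrum_csv`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["degree", "value"] or len(df) != 360:
        raise ValueError(f"{path}: expected 360 'degree,value' rows")
    values = np.zeros(360)
    values[df["degree"].to_numpy() - 1] = df["value"].to_numpy()
    meta_path = _sidecar(path)
    meta = json.loads(meta_path.read_text(encoding="utf-8")) if meta_path.exists() else {}
    return HueSpectrum(
        values=values,
        n_included=meta.get("n_included", float("nan")),
        threshold_used=meta.get("threshold", float("nan")),
        total_pixels=meta.get("total_pixels", 0),
        normalization=meta.get("normalization", "included"),
        crop_range=tuple(meta["crop_range"]) if meta.get("crop_range") else None,
        aggregate=meta.get("aggregate", False),
    )


def write_matrix_csv(ids: list[str], spectra: list[HueSpectrum], path: str | Path) -> Path:
    """Combined matrix: one row per image, columns id, deg_1..deg_360."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id," + ",".join(_DEG_COLUMNS) + "\n")
        for sid, spec in zip(ids, spectra):
            fh.write(sid + "," + ",".join(f"{v:.17g}" for v in spec.values) + "\n")
    return path


def read_matrix_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a combined spectra matrix; returns (ids, n x 360 array)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["id"] + _DEG_COLUMNS:
        raise ValueError(f"{path}: malformed spectra matrix; expected columns id, deg_1..deg_360")
    values = df[_DEG_COLUMNS].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(values)):
        rows, cols = np.where(~np.isfinite(values))
        raise ValueError(f"{path}: non-numeric value at row {rows[0] + 1}, column {_DEG_COLUMNS[cols[0]]}")
    return df["id"].astype(str).tolist(), values


def write_pqs_csv(rows: list[dict], path: str | Path) -> Path:
    """PQS results: id, lo, hi, pqs_x, pqs_y, area (NA + reason when undefined)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id,lo,hi,pqs_x,pqs_y,area,note\n")
        for r in rows:
            if r.get("undefined"):
                fh.write(f"{r['id']},{r['lo']},{r['hi']},NA,NA,NA,{r['note']}\n")
            else:
                fh.write(
                    f"{r['id']},{r['lo']},{r['hi']},{r['x']:.17g},{r['y']:.17g},{r['area']:.17g},\n"
                )
    return path


def write_dataset_csv(data: RegressionDataset, path: str | Path) -> Path:
    """One row per sample: id, response, then the predictor columns."""
    path = Path(path)
    names = data.feature_names or tuple(f"col{i}" for i in range(data.n_features))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id," + data.response_name + "," + ",".join(names) + "\n")
        for sid, y, row in zip(data.ids, data.response, data.predictors):
            fh.write(f"{sid},{y:.17g}," + ",".join(f"{v:.17g}" for v in row) + "\n")
    return path


def read_dataset_csv(path: str | Path) -> RegressionDataset:
    """Read a regression dataset: columns id, <response>, predictors..."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 3 or df.columns[0] != "id":
        raise ValueError(f"{path}: expected columns id, response, then predictors")
    return RegressionDataset(
        predictors=df.iloc[:, 2:].to_numpy(dtype=np.float64),
        response=df.iloc[:, 1].to_numpy(dtype=np.float64),
        ids=tuple(df["id"].astype(str)),
        feature_names=tuple(df.columns[2:]),
        response_name=df.columns[1],
    )


def write_fit_report(report: FitReport, path: str | Path, extra: dict | None = None) -> Path:
    """Serialize a FitReport (plus optional run metadata) as sorted JSON."""
    path = Path(path)
    payload = report.to_dict()
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n", encoding="utf-8")
    return path
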