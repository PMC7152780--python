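"""Plain-text readers and writers for traces, carpets, curves and tables.

Formats: intensity traces are 2-column delimited text (time_ms, intensity);
carpets add one intensity column per pixel; correlation curves are
(lag_ms, G) with provenance in '#'-prefixed header lines; fit tables are
TSV via pandas; bead images are 16-bit grayscale TIFF.  All writers use
full double precision so that read(write(x)) round-trips losslessly.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import tifffile

from .traces import CorrelationCurve, IntensityTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_carpet",
    "read_carpet",
    "write_curve",
    "read_curve",
    "write_fit_table",
    "read_fit_table",
    "write_bead_image",
    "read_bead_image",
    "write_manifest",
]

_FMT = "%.17g"


def write_trace(path, trace: IntensityTrace) -> None:
    header = "time_ms\tintensity"
    meta = json.dumps(
        {"sampling_interval_ms": trace.sampling_interval, **_jsonable(trace.metadata)}
    )
    np.savetxt(
        path,
        np.column_stack([trace.times, trace.values]),
        fmt=_FMT,
        delimiter="\t",
        header=f"{meta}\n{header}",
    )


def read_trace(path) -> IntensityTrace:
    meta = _read_header_json(path)
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    dt = meta.pop(
        "sampling_interval_ms",
        float(np.median(np.diff(data[:, 0]))) if len(data) > 1 else 1.0,
    )
    return IntensityTrace(data[:, 0], data[:, 1], dt, meta)


def write_carpet(path, pixels: list[IntensityTrace]) -> None:
    if not pixels:
        raise ValueError("empty carpet")
    cols = [pixels[0].times] + [p.values for p in pixels]
    header = "time_ms\t" + "\t".join(f"pixel_{i}" for i in range(len(pixels)))
    meta = json.dumps({"sampling_interval_ms": pixels[0].sampling_interval})
    np.savetxt(
        path,
        np.column_stack(cols),
        fmt=_FMT,
        delimiter="\t",
        header=f"{meta}\n{header}",
    )


def read_carpet(path) -> list[IntensityTrace]:
    meta = _read_header_json(path)
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    dt = meta.get(
        "sampling_interval_ms",
        float(np.median(np.diff(data[:, 0]))) if len(data) > 1 else 1.0,
    )
    return [
        IntensityTrace(data[:, 0], data[:, j], dt, {"pixel": j - 1})
        for j in range(1, data.shape[1])
    ]


def write_curve(path, curve: CorrelationCurve) -> None:
    meta = json.dumps(_jsonable(curve.provenance))
    cols = [curve.lags, curve.values]
    header = "lag_ms\tG"
    if curve.n_samples_per_lag is not None:
        cols.append(curve.n_samples_per_lag)
        header += "\tn_samples"
    np.savetxt(
        path,
        np.column_stack(cols),
        fmt=_FMT,
        delimiter="\t",
        header=f"{meta}\n{header}",
    )


def read_curve(path) -> CorrelationCurve:
    prov = _read_header_json(path)
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    n = data[:, 2] if data.shape[1] > 2 else None
    return CorrelationCurve(data[:, 0], data[:, 1], n, prov)


def write_fit_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FMT)


def read_fit_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bead_image(path, image: np.ndarray) -> None:
    """Write a grayscale image as 16-bit TIFF (values clipped to uint16)."""
    img = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, img)


def read_bead_image(path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale TIFF, got shape {img.shape}")
    return img


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _read_header_json(path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        try:
            return json.loads(first[1:].strip())
        except json.JSONDecodeError:
            return {}
    return {}
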