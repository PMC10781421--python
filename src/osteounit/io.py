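"""File-format helpers for the command-line interface.

Curves travel as CSV (``time_s, stress_kPa`` or raw
``time_s, force_N, displacement_um``); images as single-channel TIFF/PNG;
volumes as multi-page 8-bit TIFF with nonzero = bone; phantom truths as JSON
sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .relaxation import LoadingProtocol, RelaxationCurve, compute_stress_strain


def write_curve_csv(path, curve: RelaxationCurve) -> None:
    pd.DataFrame({"time_s": curve.time_s,
                  "stress_kPa": curve.stress_kPa}).to_csv(path, index=False)


def read_curve_csv(path, protocol: LoadingProtocol,
                   applied_strain: float | None = None) -> RelaxationCurve:
    """Load a relaxation record.

    A ``stress_kPa`` column is taken as an already-converted hold trace; a
    ``force_N``/``displacement_um`` pair is converted via
    :func:`compute_stress_strain`.
    """
    df = pd.read_csv(path)
    if "stress_kPa" in df.columns:
        return RelaxationCurve(
            time_s=df["time_s"].to_numpy(),
            stress_kPa=df["stress_kPa"].to_numpy(),
            applied_strain=(applied_strain if applied_strain is not None
                            else protocol.target_strain),
            protocol=protocol,
        )
    if {"force_N", "displacement_um"} <= set(df.columns):
        return compute_stress_strain(df["time_s"], df["force_N"],
                                     df["displacement_um"], protocol)
    raise ValueError(
        f"{path}: need either a stress_kPa column or force_N + displacement_um"
    )


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        from imageio import v3 as iio
        iio.imwrite(path, image)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        from imageio import v3 as iio
        img = iio.imread(path)
    if img.ndim == 3 and img.shape[-1] in (3, 4):  # RGB(A) -> luminance
        img = img[..., :3].mean(axis=-1)
    return np.asarray(img)


def write_volume(path, volume: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(volume, dtype=np.uint8))


def read_volume(path) -> np.ndarray:
    vol = tifffile.imread(path)
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page TIFF stack")
    return vol


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder,
                                     sort_keys=True) + "\n")
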