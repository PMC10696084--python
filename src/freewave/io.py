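"""Readers and writers for the pipeline's on-disk artifacts.

Raw k-space goes to an NPZ container with a JSON sidecar describing shapes,
timing and conventions; PMU traces to two-column CSV; images to NIfTI;
delay tables to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputError
from .gating import PmuTrace
from .phantom import COMPARTMENTS, KSpaceSeries

__all__ = [
    "save_kspace",
    "load_kspace",
    "save_pmu_csv",
    "load_pmu_csv",
    "save_nifti",
    "load_nifti",
    "save_label_map",
    "save_json",
]

_SIDECAR_CONVENTIONS = {
    "kspace_convention": "DC at array center, unitary (ortho) DFT",
    "frequency_encode_axis": "last",
}


def save_kspace(path, series: KSpaceSeries, seed: int | None = None) -> None:
    """Write a k-space series as NPZ plus a ``.json`` sidecar."""
    path = Path(path)
    np.savez(
        path,
        data=series.data,
        timestamps_ms=series.timestamps_ms,
        pe_order=series.pe_order,
    )
    sidecar = {
        "shape": list(series.data.shape),
        "axes": ["repetition", "line_slot", "frequency_encode", "coil"],
        "tr_ms": series.tr_ms,
        "seed": seed,
        **_SIDECAR_CONVENTIONS,
    }
    save_json(path.with_suffix(".json"), sidecar)


def load_kspace(path) -> KSpaceSeries:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as f:
        return KSpaceSeries(
            data=f["data"],
            timestamps_ms=f["timestamps_ms"],
            tr_ms=float(sidecar["tr_ms"]),
            pe_order=f["pe_order"],
        )


def save_pmu_csv(path, trace: PmuTrace) -> None:
    pd.DataFrame(
        {"time_ms": trace.sample_time_ms, "value_ms": trace.value_ms}
    ).to_csv(path, index=False)


def load_pmu_csv(path) -> PmuTrace:
    """Read a two-column (time_ms, value_ms) CSV; a header row is optional."""
    first = pd.read_csv(path, nrows=1, header=None)
    has_header = isinstance(first.iloc[0, 0], str)
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 2:
        raise InputError("PMU CSV needs two columns (time_ms, value_ms)")
    return PmuTrace(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def save_nifti(path, array: np.ndarray, pixdim_mm: float = 1.0) -> None:
    """Write a 2-D or 3-D array as NIfTI (identity-scaled affine)."""
    arr = np.asarray(array)
    affine = np.diag([pixdim_mm, pixdim_mm, pixdim_mm, 1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.float64), affine), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_label_map(path, label_map: np.ndarray, legend_path=None) -> None:
    """Write an integer label map as NIfTI with a JSON compartment legend."""
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(label_map.astype(np.int16), affine), str(path))
    if legend_path is not None:
        save_json(legend_path, {str(i): name for i, name in enumerate(COMPARTMENTS)})


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
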