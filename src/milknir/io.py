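"""Delimited-text persistence for spectra sets, designs and models.

A spectra set is stored as two UTF-8 CSV files with '.' decimals and header
rows: ``<name>_spectra.csv`` (first column ``row_id``, remaining columns
wavelength-labelled absorbances) and ``<name>_meta.csv`` (row-id keyed
metadata).  Study designs and run configurations round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .synthetic import Composition, DeviceProfile, SampleDesign, SpectraSet

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "design_to_yaml",
    "design_from_yaml",
    "device_from_dict",
    "device_to_dict",
    "write_json",
]


def write_spectra_csv(spectra: SpectraSet, prefix: Union[str, Path]) -> tuple:
    """Write ``<prefix>_spectra.csv`` and ``<prefix>_meta.csv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spec_path = prefix.with_name(prefix.name + "_spectra.csv")
    meta_path = prefix.with_name(prefix.name + "_meta.csv")
    cols = [f"{w:.6g}" for w in spectra.wavelengths]
    df = pd.DataFrame(spectra.absorbance, columns=cols)
    df.insert(0, "row_id", np.arange(len(df)))
    df.to_csv(spec_path, index=False)
    meta = spectra.meta.copy()
    meta.insert(0, "row_id", np.arange(len(meta)))
    meta.to_csv(meta_path, index=False)
    return spec_path, meta_path


def read_spectra_csv(prefix: Union[str, Path]) -> SpectraSet:
    """Read a spectra set written by :func:`write_spectra_csv`."""
    prefix = Path(prefix)
    spec_path = prefix.with_name(prefix.name + "_spectra.csv")
    meta_path = prefix.with_name(prefix.name + "_meta.csv")
    df = pd.read_csv(spec_path)
    meta = pd.read_csv(meta_path)
    df = df.sort_values("row_id")
    meta = meta.sort_values("row_id").drop(columns="row_id").reset_index(drop=True)
    wavelengths = np.array([float(c) for c in df.columns[1:]])
    return SpectraSet(wavelengths, df.iloc[:, 1:].to_numpy(float), meta)


def design_to_yaml(design: SampleDesign, path: Union[str, Path]) -> None:
    data = dataclasses.asdict(design)
    data["adulterants"] = list(design.adulterants)
    data["fraud_levels"] = [float(f) for f in design.fraud_levels]
    data["blending_modes"] = list(design.blending_modes)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf8")


def design_from_yaml(path: Union[str, Path]) -> SampleDesign:
    data = yaml.safe_load(Path(path).read_text(encoding="utf8"))
    comp = data.pop("composition", None)
    kwargs = dict(data)
    if comp is not None:
        kwargs["composition"] = Composition(**comp)
    for key in ("adulterants", "fraud_levels", "blending_modes"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SampleDesign(**kwargs)


def device_to_dict(device: DeviceProfile) -> dict:
    d = dataclasses.asdict(device)
    d["artifact_kinds"] = sorted(device.artifact_kinds)
    return d


def device_from_dict(data: dict) -> DeviceProfile:
    data = dict(data)
    data["artifact_kinds"] = frozenset(data.get("artifact_kinds", ()))
    return DeviceProfile(**data)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(data: dict, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(data, indent=2, sort_keys=True,
                               cls=_NumpyEncoder) + "\n", encoding="utf8")
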