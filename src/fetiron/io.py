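"""Dataset readers/writers and run-configuration handling.

All on-disk formats are plain delimited text: a block of ``#``-prefixed
metadata lines (``# key = value`` or ``# meta: {json}``), one header
line naming the columns, then comma-separated numeric rows.  Columns
are header-keyed, so order does not matter.  Malformed rows are
reported with their line number.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .datasets import KineticTrace, NMRDDataset, O17Dataset
from .speciation import TitrationDataset

__all__ = [
    "read_dataset",
    "write_dataset",
    "RunConfig",
    "load_config",
    "DatasetFormatError",
]

#: required columns per dataset kind
_COLUMNS = {
    "nmrd": ("frequency_MHz", "r1_mM_s"),
    "o17": ("temperature_K", "R2r_s", "dOmega_r_rad_s"),
    "titration": ("pH", "observable"),
    "trace": ("time_s", "absorbance"),
}


class DatasetFormatError(ValueError):
    """A dataset file violates its format; the message names the line."""


def _parse_table(path: Path) -> tuple[dict[str, Any], dict[str, np.ndarray]]:
    meta: dict[str, Any] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("meta:"):
                    meta.update(json.loads(body[5:]))
                elif "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        meta[key.strip()] = json.loads(val.strip())
                    except json.JSONDecodeError:
                        meta[key.strip()] = val.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                continue
            cells = [c.strip() for c in line.split(",")]
            if len(cells) != len(header):
                raise DatasetFormatError(
                    f"{path}:{lineno}: expected {len(header)} cells, got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise DatasetFormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if header is None:
        raise DatasetFormatError(f"{path}: no header line found")
    data = np.array(rows, dtype=float) if rows else np.empty((0, len(header)))
    return meta, {name: data[:, i] for i, name in enumerate(header)}


def read_dataset(path: str | Path, kind: str):
    """Read a typed dataset from a delimited-text file.

    ``kind`` is one of nmrd / o17 / titration / trace.
    """
    path = Path(path)
    if kind not in _COLUMNS:
        raise ValueError(f"unknown dataset kind {kind!r}")
    meta, cols = _parse_table(path)
    missing = [c for c in _COLUMNS[kind] if c not in cols]
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {missing} for kind {kind!r}")

    if kind == "nmrd":
        return NMRDDataset(
            freq_MHz=cols["frequency_MHz"],
            temperature_K=float(meta.get("temperature_K", 298.15)),
            r1=cols["r1_mM_s"],
            sigma=cols.get("sigma"),
            label=str(meta.get("label", path.stem)),
        )
    if kind == "o17":
        return O17Dataset(
            temperature_K=cols["temperature_K"],
            R2r=cols["R2r_s"],
            dOmega_r=cols["dOmega_r_rad_s"],
            B0_T=float(meta.get("B0_T", 11.74)),
            sigma_R2r=cols.get("sigma_R2r"),
            sigma_dOmega_r=cols.get("sigma_dOmega_r"),
            label=str(meta.get("label", path.stem)),
        )
    if kind == "titration":
        eps = meta.get("molar_absorptivities", {})
        eps = {
            sp: {float(w): float(e) for w, e in tbl.items()} for sp, tbl in eps.items()
        }
        return TitrationDataset(
            pH=cols["pH"],
            observable=cols["observable"],
            observable_kind=meta.get("observable_kind", "absorbance"),
            total_Fe=float(meta.get("total_Fe", 0.0)),
            total_L=float(meta.get("total_L", 0.0)),
            wavelength=meta.get("wavelength"),
            molar_absorptivities=eps,
            path_length=float(meta.get("path_length", 1.0)),
            sigma=cols.get("sigma"),
        )
    return KineticTrace(
        times_s=cols["time_s"],
        absorbance=cols["absorbance"],
        conditions={k: meta[k] for k in ("pH", "cdta_M", "fe_M", "tiron_M") if k in meta},
        label=str(meta.get("label", path.stem)),
    )


def write_dataset(dataset, path: str | Path) -> None:
    """Write a dataset in the delimited-text format read_dataset parses."""
    path = Path(path)
    lines: list[str] = []
    if isinstance(dataset, NMRDDataset):
        meta = {"temperature_K": dataset.temperature_K, "label": dataset.label}
        lines.append(f"# meta: {json.dumps(meta)}")
        cols = ["frequency_MHz", "r1_mM_s"] + (["sigma"] if dataset.sigma is not None else [])
        lines.append(",".join(cols))
        for i in range(len(dataset)):
            row = [dataset.freq_MHz[i], dataset.r1[i]]
            if dataset.sigma is not None:
                row.append(dataset.sigma[i])
            lines.append(",".join(f"{v:.10g}" for v in row))
    elif isinstance(dataset, O17Dataset):
        meta = {"B0_T": dataset.B0_T, "label": dataset.label}
        lines.append(f"# meta: {json.dumps(meta)}")
        lines.append("temperature_K,R2r_s,dOmega_r_rad_s")
        for i in range(len(dataset)):
            lines.append(
                f"{dataset.temperature_K[i]:.10g},{dataset.R2r[i]:.10g},{dataset.dOmega_r[i]:.10g}"
            )
    elif isinstance(dataset, TitrationDataset):
        meta = {
            "observable_kind": dataset.observable_kind,
            "total_Fe": dataset.total_Fe,
            "total_L": dataset.total_L,
            "wavelength": dataset.wavelength,
            "path_length": dataset.path_length,
            "molar_absorptivities": dataset.molar_absorptivities,
        }
        lines.append(f"# meta: {json.dumps(meta)}")
        lines.append("pH,observable")
        for i in range(dataset.pH.size):
            lines.append(f"{dataset.pH[i]:.10g},{dataset.observable[i]:.10g}")
    elif isinstance(dataset, KineticTrace):
        meta = {"label": dataset.label, **dataset.conditions}
        lines.append(f"# meta: {json.dumps(meta)}")
        lines.append("time_s,absorbance")
        for i in range(len(dataset)):
            lines.append(f"{dataset.times_s[i]:.10g},{dataset.absorbance[i]:.10g}")
    else:
        raise TypeError(f"cannot serialise {type(dataset).__name__}")
    path.write_text("\n".join(lines) + "\n")


_CONFIG_KEYS = {
    "task",
    "inputs",
    "fixture",
    "free",
    "fixed",
    "seed",
    "out",
    "options",
}


@dataclass
class RunConfig:
    """Validated run configuration for CLI tasks.

    Unknown keys in the source file are rejected so that typos fail
    loudly rather than silently falling back to defaults.
    """

    task: str
    inputs: list[str] = field(default_factory=list)
    fixture: str = "FeL2"
    free: list[str] = field(default_factory=list)
    fixed: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    out: str | None = None
    options: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    raw = json.loads(Path(path).read_text())
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "task" not in raw:
        raise ValueError("config must declare a task")
    return RunConfig(**raw)
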