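"""Readers and writers for the platform's plain-text formats.

Every writer/reader pair is a bijection on valid objects (write-then-
read reproduces the in-memory object).  Formats:

* FASTA — target oligo sets (Biopython-backed).
* mask CSV — either sparse ``row,col`` pairs (header ``row,col``) or a
  dense 0/1 matrix with no header.
* schedule JSONL — one instance per line:
  ``{"row": r, "offset": o, "blocks": [...], "t_charge_ns": t}``.
* waveform CSV — ``time_s,voltage_V``.
* census CSV — ``t_s,chamber_row,chamber_col,area_um2,confined``.

Malformed records raise :class:`FormatError` carrying the line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from .addressing import ArrayGeometry, Instance, Schedule

if TYPE_CHECKING:  # pragma: no cover
    from .dynamics import Waveform

__all__ = [
    "FormatError",
    "write_manifest",
    "read_fasta_records",
    "write_fasta_records",
    "read_mask_csv",
    "write_mask_csv",
    "read_schedule_jsonl",
    "write_schedule_jsonl",
    "read_waveform_csv",
    "write_waveform_csv",
    "write_census_csv",
    "read_census_csv",
]


class FormatError(ValueError):
    """Malformed input file; message includes the offending line number."""


# ---------------------------------------------------------------- FASTA

def read_fasta_records(path) -> list[tuple[str, str]]:
    """(description, sequence) pairs; CRLF and LF files parse identically."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.description, str(rec.seq)))
    return records


def write_fasta_records(path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ------------------------------------------------------------- mask CSV

def write_mask_csv(path, mask: np.ndarray, dense: bool = False) -> None:
    """Sparse ``row,col`` list by default; ``dense=True`` writes a 0/1 matrix."""
    mask = np.asarray(mask, dtype=bool)
    if dense:
        np.savetxt(path, mask.astype(np.int8), fmt="%d", delimiter=",")
    else:
        rows, cols = np.nonzero(mask)
        with open(path, "w") as fh:
            fh.write("row,col\n")
            for r, c in zip(rows, cols):
                fh.write(f"{r},{c}\n")


def read_mask_csv(path, geometry: ArrayGeometry) -> np.ndarray:
    """Auto-detects sparse (``row,col`` header) vs dense 0/1 layout."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.strip().replace(" ", "") == "row,col":
        mask = np.zeros((geometry.n_rows, geometry.n_cols), dtype=bool)
        with open(path) as fh:
            next(fh)
            for lineno, line in enumerate(fh, start=2):
                line = line.strip()
                if not line:
                    continue
                try:
                    r_s, c_s = line.split(",")
                    r, c = int(r_s), int(c_s)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: expected 'row,col'") from exc
                if not (0 <= r < geometry.n_rows and 0 <= c < geometry.n_cols):
                    raise FormatError(f"{path}:{lineno}: site ({r},{c}) out of range")
                mask[r, c] = True
        return mask
    dense = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    if dense.shape != (geometry.n_rows, geometry.n_cols):
        raise FormatError(
            f"{path}: dense mask shape {dense.shape} != "
            f"({geometry.n_rows}, {geometry.n_cols})"
        )
    return dense.astype(bool)


# -------------------------------------------------------- schedule JSONL

def write_schedule_jsonl(path, schedule: Schedule) -> None:
    with open(path, "w") as fh:
        for inst in schedule.instances:
            fh.write(
                json.dumps(
                    {
                        "row": inst.row,
                        "offset": inst.offset,
                        "blocks": sorted(inst.blocks),
                        "t_charge_ns": inst.t_charge_ns,
                    }
                )
                + "\n"
            )


def read_schedule_jsonl(path) -> Schedule:
    instances = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                instances.append(
                    Instance(
                        row=int(obj["row"]),
                        offset=int(obj["offset"]),
                        blocks=frozenset(int(b) for b in obj["blocks"]),
                        t_charge_ns=float(obj["t_charge_ns"]),
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad instance record") from exc
    t_default = instances[0].t_charge_ns if instances else 80.0
    return Schedule(instances=instances, t_charge_default_ns=t_default)


# ---------------------------------------------------------- waveform CSV

def write_waveform_csv(path, wf: "Waveform") -> None:
    with open(path, "w") as fh:
        fh.write("time_s,voltage_V\n")
        for t, v in zip(wf.times, wf.voltages):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def read_waveform_csv(path) -> "Waveform":
    from .dynamics import Waveform

    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return Waveform(times=data[:, 0], voltages=data[:, 1])


# ------------------------------------------------------------ census CSV

def write_census_csv(path, history: list[tuple[float, np.ndarray]]) -> None:
    """Census time series: one row per (time, chamber)."""
    with open(path, "w") as fh:
        fh.write("t_s,chamber_row,chamber_col,area_um2\n")
        for t, areas in history:
            areas = np.asarray(areas)
            for (r, c), a in np.ndenumerate(areas):
                fh.write(f"{float(t)!r},{r},{c},{float(a)!r}\n")


def read_census_csv(path) -> list[tuple[float, np.ndarray]]:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for t, grp in df.groupby("t_s", sort=True):
        nr = int(grp["chamber_row"].max()) + 1
        nc = int(grp["chamber_col"].max()) + 1
        areas = np.zeros((nr, nc))
        areas[grp["chamber_row"], grp["chamber_col"]] = grp["area_um2"]
        out.append((float(t), areas))
    return out


# --------------------------------------------------------------- manifest

def write_manifest(out_dir, config=None, seed: int | None = None) -> None:
    """Write a machine-readable run manifest (config hash, seed, versions)
    beside a command's outputs, so any run can be reproduced exactly."""
    import hashlib
    import platform

    import numpy
    import scipy

    from . import __version__

    cfg_text = ""
    if config is not None:
        import yaml

        cfg_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "synthchip": __version__,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
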