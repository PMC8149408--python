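"""On-disk format for simulated series batches.

A batch is a directory of CSV files (``series_000.csv`` ...), one per
series, with header ``t,x1,...,xN``, plus a JSON sidecar
(``seriesset.json``) carrying the generating parameters, the simulation
protocol (the likelihood needs dt) and the per-series seeds.  Floats are
serialized with 17 significant digits so that write-then-read reproduces
the state arrays bit for bit.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .exceptions import NonUniformGridError, SeriesFormatError
from .params import ModelParams
from .simulate import SeriesSet, SimulationConfig

__all__ = ["write_series", "read_series", "SIDECAR_NAME"]

SIDECAR_NAME = "seriesset.json"


def _series_filename(i: int) -> str:
    return f"series_{i:03d}.csv"


def write_series(directory: str | Path, series_set: SeriesSet) -> list[Path]:
    """Write one CSV per series plus the JSON sidecar; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = series_set.n
    header = "t," + ",".join(f"x{i + 1}" for i in range(n))
    paths = []
    for i in range(series_set.n_series):
        path = directory / _series_filename(i)
        data = np.column_stack([series_set.times, series_set.states[i]])
        np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.17g")
        paths.append(path)
    sidecar = {
        "format": "glca-seriesset-v1",
        "n_alternatives": n,
        "n_series": series_set.n_series,
        "params": series_set.params_used.to_dict(),
        "config": series_set.config_used.to_dict(),
        "seed_per_series": list(series_set.seed_per_series),
        "files": [p.name for p in paths],
    }
    sidecar_path = directory / SIDECAR_NAME
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return paths + [sidecar_path]


def _read_csv(path: Path, n_expected: int) -> tuple[np.ndarray, np.ndarray]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SeriesFormatError(f"{path}: empty file") from None
        if header[0] != "t" or len(header) != n_expected + 1:
            raise SeriesFormatError(
                f"{path}: header must be t,x1..x{n_expected}, got {','.join(header)}"
            )
        times, states = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n_expected + 1:
                raise SeriesFormatError(
                    f"{path}: line {lineno}: expected {n_expected + 1} fields, "
                    f"got {len(row)}"
                )
            try:
                values = [float(v) for v in row]
            except ValueError as exc:
                raise SeriesFormatError(f"{path}: line {lineno}: {exc}") from None
            times.append(values[0])
            states.append(values[1:])
    t = np.asarray(times)
    diffs = np.diff(t)
    if t.size < 2 or diffs[0] <= 0 or not np.allclose(diffs, diffs[0], rtol=1e-6):
        raise NonUniformGridError(f"{path}: time column is not a uniform grid")
    return t, np.asarray(states)


def read_series(directory: str | Path) -> SeriesSet:
    """Read a series batch written by :func:`write_series`.

    The sidecar is mandatory: without it the grid spacing and model
    dimension cannot be trusted, and the likelihood would be undefined.
    """
    directory = Path(directory)
    sidecar_path = directory / SIDECAR_NAME
    if not sidecar_path.exists():
        raise SeriesFormatError(
            f"missing sidecar {sidecar_path}; dt and parameters are required"
        )
    sidecar = json.loads(sidecar_path.read_text())
    n = int(sidecar["n_alternatives"])
    params = ModelParams.from_dict(sidecar["params"])
    config = SimulationConfig.from_dict(sidecar["config"])
    if params.n != n:
        raise SeriesFormatError(
            f"sidecar inconsistent: n_alternatives={n} but params have N={params.n}"
        )
    times_ref = None
    states = []
    for name in sidecar["files"]:
        t, x = _read_csv(directory / name, n)
        if times_ref is None:
            times_ref = t
        elif t.shape != times_ref.shape or not np.array_equal(t, times_ref):
            raise SeriesFormatError(f"{name}: time grid differs from other series")
        states.append(x)
    if times_ref is None:
        raise SeriesFormatError(f"{directory}: sidecar lists no series files")
    return SeriesSet(
        times=times_ref,
        states=np.stack(states),
        params_used=params,
        config_used=config,
        seed_per_series=tuple(int(s) for s in sidecar.get("seed_per_series", [])),
    )
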