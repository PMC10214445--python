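"""File formats: observables CSV, contour CSV, wrap-time CSV, extended XYZ.

Every file written carries a comment header with the package version and
the resolved seed so any artifact can be traced back to its run.
"""

from __future__ import annotations

import json
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import ObservableSeries, WrapState

_VALID_STATES = {s.value for s in WrapState}

OBSERVABLE_COLUMNS = ["time", "theta_deg", "d", "z", "f1", "f2", "state"]


def _header(seed) -> str:
    from . import __version__
    return f"# vesiwrap {__version__} seed={seed}\n"


def _read_csv_with_header(path: Path) -> tuple[pd.DataFrame, int]:
    """Read a CSV skipping leading '#' comment lines; returns (df, n_skipped)."""
    lines = Path(path).read_text().splitlines(keepends=True)
    n_skip = 0
    for ln in lines:
        if ln.startswith("#"):
            n_skip += 1
        else:
            break
    body = "".join(lines[n_skip:])
    df = pd.read_csv(StringIO(body))
    return df, n_skip


def write_observables(series: ObservableSeries, path, seed="unknown") -> None:
    """Write an observable series as CSV with a provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = series.to_dataframe()
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, index=False, lineterminator="\n")


def read_observables(path) -> ObservableSeries:
    """Read an observable series; malformed rows raise with a line number."""
    path = Path(path)
    df, n_skip = _read_csv_with_header(path)
    missing = [c for c in OBSERVABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return ObservableSeries(time=np.empty(0), theta=np.empty(0),
                                d=np.empty(0), z=np.empty(0),
                                f1=np.empty(0), f2=np.empty(0),
                                state=np.empty(0, dtype=object))
    for i, tok in enumerate(df["state"]):
        if str(tok) not in _VALID_STATES:
            # +2: header line of the CSV body plus 1-based indexing
            raise ValueError(
                f"{path}:{n_skip + i + 2}: invalid state token {tok!r}")
    num = df[OBSERVABLE_COLUMNS[:-1]]
    if num.isna().any().any():
        bad = int(num.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}:{n_skip + bad + 2}: malformed numeric field")
    return ObservableSeries.from_dataframe(df)


def write_contours(series, path, seed="unknown") -> None:
    """Contour series as CSV: one row per frame, one column per angle."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    m = series.radii.shape[1]
    df = pd.DataFrame(series.radii,
                      columns=[f"r{k}" for k in range(m)])
    df.insert(0, "frame", np.arange(series.radii.shape[0]))
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write(f"# frame_interval={series.frame_interval}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_contours(path):
    from .flicker import ContourSeries
    path = Path(path)
    interval = 1.0
    for ln in open(path):
        if ln.startswith("# frame_interval="):
            interval = float(ln.split("=", 1)[1])
        if not ln.startswith("#"):
            break
    df, _ = _read_csv_with_header(path)
    radii = df[[c for c in df.columns if c.startswith("r")]].to_numpy(dtype=float)
    return ContourSeries(radii=radii, frame_interval=interval)


def write_wraptime(df: pd.DataFrame, path, seed="unknown") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, index=False, lineterminator="\n")


def read_wraptime(path) -> pd.DataFrame:
    df, _ = _read_csv_with_header(path)
    if "sigma" not in df.columns or "time" not in df.columns:
        raise ValueError(f"{path}: wrap-time table needs 'sigma' and 'time' columns")
    return df


def write_json(obj: dict, path, seed="unknown") -> None:
    """JSON artifact (fit results, transition tables) with provenance keys."""
    from . import __version__
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_vesiwrap_version": __version__, "_seed": seed, **obj}
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")


# ---------------------------------------------------------------------------
# extended XYZ (positions + normals + species), one block per frame

def write_extxyz(path, frames, seed="unknown", append: bool = False) -> None:
    """Write simulation snapshots as extended XYZ.

    ``frames`` is an iterable of dicts with keys ``species`` (list of
    str), ``positions`` (N, 3), optional ``normals`` (N, 3), optional
    ``time`` and ``box``.  Normals default to zero for species without
    orientation.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for fr in frames:
            pos = np.asarray(fr["positions"], dtype=float)
            n = pos.shape[0]
            nrm = np.asarray(fr.get("normals", np.zeros_like(pos)), dtype=float)
            species = fr["species"]
            comment = (f'Properties=species:S:1:pos:R:3:normal:R:3 '
                       f'Time={fr.get("time", 0.0)} seed={seed}')
            if "box" in fr and fr["box"] is not None:
                L = float(fr["box"])
                comment += (f' Lattice="{L} 0 0 0 {L} 0 0 0 {L}"')
            fh.write(f"{n}\n{comment}\n")
            for k in range(n):
                fh.write(f"{species[k]} "
                         f"{pos[k, 0]:.8g} {pos[k, 1]:.8g} {pos[k, 2]:.8g} "
                         f"{nrm[k, 0]:.8g} {nrm[k, 1]:.8g} {nrm[k, 2]:.8g}\n")


def read_extxyz(path) -> list[dict]:
    """Read extended-XYZ frames written by :func:`write_extxyz`."""
    frames = []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            comment = fh.readline()
            time = 0.0
            box = None
            for tok in comment.split():
                if tok.startswith("Time="):
                    time = float(tok.split("=")[1])
            if 'Lattice="' in comment:
                lat = comment.split('Lattice="')[1].split('"')[0].split()
                box = float(lat[0])
            species, pos, nrm = [], [], []
            for _ in range(n):
                parts = fh.readline().split()
                species.append(parts[0])
                pos.append([float(x) for x in parts[1:4]])
                nrm.append([float(x) for x in parts[4:7]])
            frames.append({"species": species,
                           "positions": np.asarray(pos),
                           "normals": np.asarray(nrm),
                           "time": time, "box": box})
    return frames
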