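"""Reading and writing landmark datasets, accuracy maps and colored meshes.

Supported input dialects:

* wide CSV — one row per specimen: ``specimen_id, sex, population,
  x_1, y_1, z_1, ...`` (optionally ``replicate_of``);
* long CSV — one row per point: ``specimen_id, point_id, x, y, z`` with a
  metadata sidecar CSV (``specimen_id, sex, population, replicate_of``);
* Rohlf TPS — ``LM3=n`` blocks of ``x y z`` lines with ``ID=`` records,
  metadata from a sidecar CSV;
* 3D Slicer markups fcsv — a directory of one ``.fcsv`` per specimen plus a
  ``metadata.csv`` sidecar. Slicer writes either RAS or LPS coordinates
  depending on version; the declared system is honored and converted to the
  requested one (never silently mixed).

All internal indexing is 0-based; 1-based file conventions are converted at
the boundary. Coordinates are millimetres. Missing coordinates are rejected,
not imputed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AccuracyMap, LandmarkConfiguration, SpecimenSet, Triangulation
from .errors import ParseError, SchemaError

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "write_accuracy_map",
    "read_accuracy_map_csv",
    "write_ply",
]


# ----------------------------------------------------------------- metadata IO

def _read_metadata(path: Path) -> pd.DataFrame | None:
    if path is None or not Path(path).exists():
        return None
    df = pd.read_csv(path, dtype=str)
    if "specimen_id" not in df.columns:
        raise SchemaError(f"metadata file {path} lacks a specimen_id column")
    return df.set_index("specimen_id")


def _meta_lookup(meta: pd.DataFrame | None, sid: str, column: str):
    if meta is None or column not in getattr(meta, "columns", ()):
        return None
    if sid not in meta.index:
        return None
    val = meta.loc[sid, column]
    if isinstance(val, pd.Series):
        val = val.iloc[0]
    if pd.isna(val) or val == "":
        return None
    return str(val)


def _assemble(blocks: dict[str, np.ndarray], point_ids, meta: pd.DataFrame | None) -> SpecimenSet:
    sids = list(blocks)
    counts = {sid: b.shape[0] for sid, b in blocks.items()}
    first = counts[sids[0]]
    for sid, n in counts.items():
        if n != first:
            raise SchemaError(
                f"specimen {sid!r} has {n} points but {sids[0]!r} has {first}"
            )
    return SpecimenSet(
        coords=np.stack([blocks[s] for s in sids]),
        specimen_ids=tuple(sids),
        sex=tuple(_meta_lookup(meta, s, "sex") for s in sids),
        population=tuple(_meta_lookup(meta, s, "population") for s in sids),
        replicate_of=tuple(_meta_lookup(meta, s, "replicate_of") for s in sids),
        point_ids=tuple(point_ids),
    )


# --------------------------------------------------------------------- readers

def read_landmarks(path, format: str, metadata=None, coordinate_system: str = "RAS") -> SpecimenSet:
    """Read a landmark dataset into a SpecimenSet.

    ``format`` is one of ``csv`` (wide or long, auto-detected), ``tps`` or
    ``fcsv`` (a directory of Slicer markup files). ``metadata`` optionally
    points at a sidecar CSV; by default a ``<name>.metadata.csv`` or
    ``metadata.csv`` next to the input is used when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path, metadata)
    if format == "tps":
        return _read_tps(path, metadata)
    if format == "fcsv":
        return _read_fcsv_dir(path, metadata, coordinate_system)
    raise ValueError(f"unknown landmark format {format!r} (expected csv, tps or fcsv)")


def _default_sidecar(path: Path) -> Path | None:
    for candidate in (path.with_suffix(".metadata.csv"), path.parent / "metadata.csv",
                      path / "metadata.csv" if path.is_dir() else path):
        if candidate is not None and candidate.is_file() and candidate != path:
            return candidate
    return None


def _read_csv(path: Path, metadata) -> SpecimenSet:
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"specimen_id", "point_id", "x", "y", "z"} <= cols:
        return _read_long_csv(df, path, metadata)
    if "specimen_id" in cols and any(c.startswith("x_") for c in df.columns):
        return _read_wide_csv(df, path)
    raise SchemaError(
        f"{path}: not a recognized wide (x_1,y_1,z_1,...) or long (point_id,x,y,z) landmark CSV"
    )


def _read_wide_csv(df: pd.DataFrame, path: Path) -> SpecimenSet:
    suffixes = []
    for c in df.columns:
        if c.startswith("x_"):
            suffixes.append(c[2:])
    for s in suffixes:
        for axis in ("y", "z"):
            if f"{axis}_{s}" not in df.columns:
                raise SchemaError(f"{path}: missing column {axis}_{s}")
    coord_cols = [f"{axis}_{s}" for s in suffixes for axis in "xyz"]
    try:
        values = df[coord_cols].to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric coordinate ({exc})") from exc
    if np.isnan(values).any():
        row = int(np.nonzero(np.isnan(values).any(axis=1))[0][0])
        raise SchemaError(
            f"{path}: missing coordinate for specimen {df['specimen_id'].iloc[row]!r}"
        )
    coords = values.reshape(len(df), len(suffixes), 3)
    def col(name):
        if name in df.columns:
            return tuple(None if pd.isna(v) else str(v) for v in df[name])
        return (None,) * len(df)
    return SpecimenSet(
        coords=coords,
        specimen_ids=tuple(str(s) for s in df["specimen_id"]),
        sex=col("sex"),
        population=col("population"),
        replicate_of=col("replicate_of"),
        point_ids=tuple(suffixes),
    )


def _read_long_csv(df: pd.DataFrame, path: Path, metadata) -> SpecimenSet:
    meta = _read_metadata(Path(metadata)) if metadata else _read_metadata(_default_sidecar(path))
    try:
        df[["x", "y", "z"]].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric coordinate ({exc})") from exc
    blocks: dict[str, np.ndarray] = {}
    point_ids = None
    for sid, grp in df.groupby("specimen_id", sort=False):
        pids = tuple(str(p) for p in grp["point_id"])
        if point_ids is None:
            point_ids = pids
        elif pids != point_ids:
            raise SchemaError(f"{path}: specimen {sid!r} has a different point scheme")
        blocks[str(sid)] = grp[["x", "y", "z"]].to_numpy(dtype=float)
    return _assemble(blocks, point_ids, meta)


def _read_tps(path: Path, metadata) -> SpecimenSet:
    meta = _read_metadata(Path(metadata)) if metadata else _read_metadata(_default_sidecar(path))
    blocks: dict[str, np.ndarray] = {}
    current: list[list[float]] | None = None
    expected = 0
    pending_rows: list[list[float]] = []
    pending_id: str | None = None

    def flush(line_no):
        nonlocal pending_rows, pending_id, expected
        if expected == 0 and not pending_rows:
            return
        if len(pending_rows) != expected:
            raise ParseError(
                f"{path}: block {pending_id or len(blocks)} has {len(pending_rows)} of {expected} points",
                line=line_no,
            )
        sid = pending_id if pending_id is not None else f"specimen_{len(blocks)}"
        blocks[sid] = np.asarray(pending_rows, dtype=float)
        pending_rows = []
        pending_id = None
        expected = 0

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                flush(line_no)
                try:
                    expected = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ParseError(f"{path}: bad LM3 count {line!r}", line=line_no) from exc
            elif upper.startswith("ID="):
                pending_id = line.split("=", 1)[1].strip()
            elif upper.startswith(("IMAGE=", "SCALE=", "COMMENT=")):
                continue
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError(f"{path}: expected 3 coordinates, got {line!r}", line=line_no)
                try:
                    pending_rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise ParseError(f"{path}: non-numeric coordinate {line!r}", line=line_no) from exc
    flush(None)
    if not blocks:
        raise ParseError(f"{path}: no LM3 blocks found")
    n = next(iter(blocks.values())).shape[0]
    point_ids = tuple(f"p{i}" for i in range(n))
    return _assemble(blocks, point_ids, meta)


def _read_fcsv(path: Path, coordinate_system: str) -> tuple[list[str], np.ndarray]:
    declared = None
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "CoordinateSystem" in line:
                    declared = line.split("=")[-1].strip().split()[-1].upper()
                continue
            parts = line.split(",")
            if len(parts) < 4:
                raise ParseError(f"{path}: short fcsv row", line=line_no)
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric coordinate {parts[1:4]}", line=line_no) from exc
            label = parts[11] if len(parts) > 11 and parts[11] else f"p{len(rows)}"
            labels.append(label)
            rows.append(xyz)
    coords = np.asarray(rows, dtype=float)
    declared = declared or coordinate_system.upper()
    target = coordinate_system.upper()
    if declared not in ("RAS", "LPS") or target not in ("RAS", "LPS"):
        raise SchemaError(f"{path}: unsupported coordinate system {declared!r}")
    if declared != target:
        coords = coords * np.array([-1.0, -1.0, 1.0])  # LPS <-> RAS flips x and y
    return labels, coords


def _read_fcsv_dir(path: Path, metadata, coordinate_system: str) -> SpecimenSet:
    if path.is_file():
        files = [path]
    else:
        files = sorted(p for p in path.iterdir() if p.suffix == ".fcsv")
    if not files:
        raise SchemaError(f"{path}: no .fcsv files found")
    meta = _read_metadata(Path(metadata)) if metadata else _read_metadata(
        path / "metadata.csv" if path.is_dir() else _default_sidecar(path)
    )
    blocks: dict[str, np.ndarray] = {}
    point_ids = None
    for f in files:
        labels, coords = _read_fcsv(f, coordinate_system)
        sid = f.stem
        if point_ids is None:
            point_ids = tuple(labels)
        blocks[sid] = coords
    return _assemble(blocks, point_ids, meta)


# --------------------------------------------------------------------- writers

def write_landmarks(specimens: SpecimenSet, path, format: str = "csv") -> None:
    """Write a SpecimenSet (wide ``csv``, ``csv-long`` + sidecar, or ``tps`` +
    sidecar). Round-trips through read_landmarks to <= 1e-9 mm."""
    path = Path(path)
    if format == "csv":
        _write_wide_csv(specimens, path)
    elif format == "csv-long":
        _write_long_csv(specimens, path)
        _write_metadata_sidecar(specimens, path.with_suffix(".metadata.csv"))
    elif format == "tps":
        _write_tps(specimens, path)
        _write_metadata_sidecar(specimens, path.with_suffix(".metadata.csv"))
    else:
        raise ValueError(f"unknown landmark format {format!r}")


def _write_metadata_sidecar(specimens: SpecimenSet, path: Path) -> None:
    pd.DataFrame(
        {
            "specimen_id": specimens.specimen_ids,
            "sex": specimens.sex,
            "population": specimens.population,
            "replicate_of": specimens.replicate_of,
        }
    ).to_csv(path, index=False)


def _write_wide_csv(specimens: SpecimenSet, path: Path) -> None:
    data = {
        "specimen_id": specimens.specimen_ids,
        "sex": specimens.sex,
        "population": specimens.population,
        "replicate_of": specimens.replicate_of,
    }
    flat = specimens.coords
    for j, pid in enumerate(specimens.point_ids):
        for a, axis in enumerate("xyz"):
            data[f"{axis}_{pid}"] = flat[:, j, a]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def _write_long_csv(specimens: SpecimenSet, path: Path) -> None:
    rows = []
    for i, sid in enumerate(specimens.specimen_ids):
        for j, pid in enumerate(specimens.point_ids):
            x, y, z = specimens.coords[i, j]
            rows.append((sid, pid, x, y, z))
    pd.DataFrame(rows, columns=["specimen_id", "point_id", "x", "y", "z"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def _write_tps(specimens: SpecimenSet, path: Path) -> None:
    with open(path, "w") as fh:
        for i, sid in enumerate(specimens.specimen_ids):
            fh.write(f"LM3={specimens.n_points}\n")
            for x, y, z in specimens.coords[i]:
                fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
            fh.write(f"ID={sid}\n")


# ------------------------------------------------------------------ map output

def _coolwarm_colors(values: np.ndarray) -> np.ndarray:
    """Map values linearly from [min, max] to a cool->warm ramp as uchar RGB.

    A constant map sits at the middle of the ramp."""
    from matplotlib import colormaps

    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    lo = np.nanmin(v) if finite.any() else 0.0
    hi = np.nanmax(v) if finite.any() else 1.0
    if hi - lo <= 1e-300:
        t = np.full_like(v, 0.5)
    else:
        t = (v - lo) / (hi - lo)
    t = np.where(np.isfinite(t), t, 0.5)
    rgba = colormaps["coolwarm"](t)
    return (rgba[:, :3] * 255).round().astype(np.uint8)


def write_ply(path, coords: np.ndarray, faces: np.ndarray, rgb: np.ndarray) -> None:
    """Write an ASCII PLY mesh with per-vertex uchar RGB colors."""
    coords = np.asarray(coords, dtype=float)
    faces = np.asarray(faces, dtype=int)
    rgb = np.asarray(rgb, dtype=np.uint8)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(coords)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for (x, y, z), (r, g, b) in zip(coords, rgb):
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {r} {g} {b}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_accuracy_map(
    accuracy_map: AccuracyMap,
    consensus,
    faces: Triangulation,
    out_csv,
    out_ply=None,
) -> None:
    """Write an accuracy map as a tidy CSV and (optionally) a colored PLY mesh.

    The CSV has one row per point (point_id, acc_total, acc_F, acc_M, space);
    the PLY colors each vertex by acc_total on a cool->warm ramp scaled to
    the map's [min, max]."""
    coords = consensus.coords if isinstance(consensus, LandmarkConfiguration) else np.asarray(consensus, dtype=float)
    n = coords.shape[0]
    if accuracy_map.n_points != n:
        raise SchemaError(
            f"map covers {accuracy_map.n_points} points but consensus has {n}"
        )
    pids = accuracy_map.point_ids or tuple(f"p{i}" for i in range(n))
    pd.DataFrame(
        {
            "point_id": pids,
            "acc_total": accuracy_map.acc_total,
            "acc_F": accuracy_map.acc_F,
            "acc_M": accuracy_map.acc_M,
            "space": accuracy_map.space,
        }
    ).to_csv(out_csv, index=False, float_format="%.9g")
    if out_ply is not None:
        faces.validate_against(n)
        rgb = _coolwarm_colors(accuracy_map.acc_total)
        write_ply(out_ply, coords, faces.faces, rgb)


def read_accuracy_map_csv(path) -> pd.DataFrame:
    """Read back an accuracy-map CSV (round-trip of write_accuracy_map)."""
    return pd.read_csv(path)
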