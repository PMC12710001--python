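"""Point-cloud and configuration file I/O.

PLY support covers ASCII and binary little-endian vertex-only files with
arbitrary scalar vertex properties, so part labels (``part``) and skeleton
masks (``is_skeleton``) survive round trips.  XYZ files are whitespace-
delimited triples, one point per line.  Species profiles are stored as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .skeleton import LeafSkeleton, SpeciesProfile

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "read_xyz",
    "write_xyz",
    "write_skeleton_ply",
    "read_skeleton_ply",
    "load_profile",
    "save_profile",
    "PlyParseError",
]

_PLY_TYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}
_INV_TYPES = {"i1": "char", "u1": "uchar", "i2": "short", "u2": "ushort",
              "i4": "int", "u4": "uint", "f4": "float", "f8": "double"}


class PlyParseError(ValueError):
    """Malformed PLY header or body."""


def _parse_header(fh) -> tuple[str, int, list[tuple[str, str]], int]:
    """Returns (format, vertex count, [(name, numpy dtype code)], header bytes)."""
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise PlyParseError("not a PLY file (missing 'ply' magic)")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    line_no = 1
    while True:
        raw = fh.readline()
        if not raw:
            raise PlyParseError("unexpected end of header")
        line_no += 1
        line = raw.decode("ascii", errors="replace").strip()
        if not line or line.startswith("comment"):
            continue
        tok = line.split()
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise PlyParseError(f"line {line_no}: list properties unsupported for vertices")
            if tok[1] not in _PLY_TYPES:
                raise PlyParseError(f"line {line_no}: unknown property type {tok[1]!r}")
            props.append((tok[2], _PLY_TYPES[tok[1]]))
        elif tok[0] == "end_header":
            break
    if fmt not in ("ascii", "binary_little_endian"):
        raise PlyParseError(f"unsupported PLY format {fmt!r}")
    if n_vertex is None:
        raise PlyParseError("no vertex element in header")
    for needed in ("x", "y", "z"):
        if needed not in [p[0] for p in props]:
            raise PlyParseError(f"vertex element lacks property {needed!r}")
    return fmt, n_vertex, props, fh.tell()


def read_point_cloud(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read a PLY or XYZ file.

    Returns (points (N, 3) float64, extra vertex properties by name).
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        return read_xyz(path), {}
    with open(path, "rb") as fh:
        fmt, n, props, _ = _parse_header(fh)
        if fmt == "ascii":
            names = [p[0] for p in props]
            rows = []
            for i in range(n):
                line = fh.readline()
                if not line:
                    raise PlyParseError(f"vertex {i}: file truncated (expected {n} vertices)")
                vals = line.split()
                if len(vals) != len(props):
                    raise PlyParseError(
                        f"vertex {i}: expected {len(props)} values, got {len(vals)}")
                rows.append([float(v) for v in vals])
            data = {name: np.array([r[j] for r in rows]) for j, name in enumerate(names)}
            for (name, code) in props:
                data[name] = data[name].astype(np.dtype("<" + code))
        else:
            dtype = np.dtype([(name, "<" + code) for name, code in props])
            buf = fh.read(dtype.itemsize * n)
            if len(buf) < dtype.itemsize * n:
                raise PlyParseError(f"binary body truncated (expected {n} vertices)")
            rec = np.frombuffer(buf, dtype=dtype, count=n)
            data = {name: rec[name].copy() for name, _ in props}
    points = np.column_stack([data.pop("x"), data.pop("y"), data.pop("z")]).astype(float)
    return points, data


def write_point_cloud(points: np.ndarray, path, properties: dict[str, np.ndarray] | None = None,
                      binary: bool = True) -> None:
    """Write a PLY (default binary little-endian) or, by extension, XYZ file."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        write_xyz(points, path)
        return
    points = np.asarray(points, dtype=float)
    properties = properties or {}
    cols: list[tuple[str, np.ndarray]] = [
        ("x", points[:, 0]), ("y", points[:, 1]), ("z", points[:, 2]),
    ]
    for name, arr in properties.items():
        arr = np.asarray(arr)
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        cols.append((name, arr))

    header = ["ply",
              f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {len(points)}"]
    codes = []
    for name, arr in cols:
        code = np.dtype(arr.dtype).str.lstrip("<>=|")
        if code not in _INV_TYPES:
            arr = arr.astype(float)
            code = "f8"
        codes.append(code)
        header.append(f"property {_INV_TYPES[code]} {name}")
    header.append("end_header")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            rec = np.empty(len(points), dtype=np.dtype(
                [(name, "<" + code) for (name, _), code in zip(cols, codes)]))
            for (name, arr), code in zip(cols, codes):
                rec[name] = arr.astype("<" + code)
            fh.write(rec.tobytes())
        else:
            arrays = [arr for _, arr in cols]
            for i in range(len(points)):
                vals = []
                for arr, code in zip(arrays, codes):
                    v = arr[i]
                    vals.append(repr(float(v)) if code.startswith("f") else str(int(v)))
                fh.write((" ".join(vals) + "\n").encode("ascii"))


def read_xyz(path) -> np.ndarray:
    """Whitespace-delimited XYZ; blank lines are ignored."""
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: expected 3 coordinates")
            rows.append([float(v) for v in parts[:3]])
    return np.asarray(rows, dtype=float)


def write_xyz(points: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(points, dtype=float), fmt="%.17g")


def write_skeleton_ply(skeleton: LeafSkeleton, path, sidecar: dict | None = None,
                       binary: bool = False) -> None:
    """Labeled skeleton PLY (per-vertex integer ``part``) + JSON sidecar."""
    write_point_cloud(skeleton.points, path,
                      {"part": skeleton.part_labels.astype(np.int32)}, binary=binary)
    if sidecar is not None:
        import json

        Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_skeleton_ply(path) -> LeafSkeleton:
    points, props = read_point_cloud(path)
    if "part" not in props:
        raise PlyParseError("skeleton PLY lacks the 'part' vertex property")
    return LeafSkeleton(points=points, part_labels=props["part"].astype(int))


def load_profile(path) -> SpeciesProfile:
    """Species profile from YAML: name, length_scale_range, width_factor_range,
    has_petiole.  The width rule is interval-valued: s_w ~ U(f_lo*s_l, f_hi*s_l)."""
    cfg = yaml.safe_load(Path(path).read_text())
    f_lo, f_hi = cfg["width_factor_range"]
    return SpeciesProfile(
        name=cfg["name"],
        length_scale_range=tuple(cfg["length_scale_range"]),
        width_scale_rule=lambda sl: (f_lo * sl, f_hi * sl),
        has_petiole=bool(cfg["has_petiole"]),
    )


def save_profile(profile: SpeciesProfile, path) -> None:
    lo = profile.length_scale_range[0]
    w_lo, w_hi = profile.width_scale_rule(lo)
    Path(path).write_text(yaml.safe_dump({
        "name": profile.name,
        "length_scale_range": list(profile.length_scale_range),
        "width_factor_range": [w_lo / lo, w_hi / lo],
        "has_petiole": profile.has_petiole,
        "gmm_modes": profile.gmm_modes,
    }))
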