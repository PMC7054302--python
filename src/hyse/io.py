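"""ENVI-style on-disk I/O for hypercubes, label rasters and spectral libraries.

The on-disk standard is the plain ENVI pair: a text ``.hdr`` header next to a
raw binary file, with the three standard interleaves (BSQ, BIL, BIP). The
header axes map onto the in-memory convention as ``lines = x``,
``samples = y``, ``bands = lam``. Wavelengths are mandatory for hypercubes
and stored in the header; free-form metadata and label legends travel in JSON
sidecars (``<file>.meta.json`` / ``<file>.legend.json``).

Only the subset of the ENVI dialect needed here is implemented; vendor
formats (SPE, camera SDK streams) are out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from .types import CalibrationFrames, Hypercube, LabelMap, ReferenceLibrary, SpectralClass


class EnviFormatError(ValueError):
    """A missing, malformed or inconsistent ENVI header/binary pair."""


_DTYPE_TO_ENVI = {
    np.dtype(np.uint8): 1,
    np.dtype(np.int16): 2,
    np.dtype(np.int32): 3,
    np.dtype(np.float32): 4,
    np.dtype(np.float64): 5,
    np.dtype(np.uint16): 12,
    np.dtype(np.uint32): 13,
}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


def _header_path(path: Path) -> Path:
    return path.with_name(path.name + ".hdr")


def _format_header(fields: dict[str, Any]) -> str:
    lines = ["ENVI"]
    for key, value in fields.items():
        if isinstance(value, (list, tuple, np.ndarray)):
            inner = ", ".join(repr(float(v)) if isinstance(v, (float, np.floating)) else str(v) for v in value)
            lines.append(f"{key} = {{ {inner} }}")
        else:
            lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


def _parse_header(text: str, path: Path) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError(f"{path}: missing ENVI magic line")
    body = text.lstrip()[len("ENVI") :]
    fields: dict[str, str] = {}
    while True:
        eq = body.find("=")
        if eq < 0:
            break
        key = body[:eq].strip().lower()
        rest = body[eq + 1 :]
        if rest.lstrip().startswith("{"):
            start = rest.find("{")
            end = rest.find("}", start)
            if end < 0:
                raise EnviFormatError(f"{path}: unterminated brace value for {key!r}")
            value = rest[start + 1 : end]
            body = rest[end + 1 :]
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl < 0 else nl
            value = rest[:nl]
            body = rest[nl + 1 :] if nl < len(rest) else ""
        if key:
            fields[key] = value.strip()
    return fields


def _require(fields: dict[str, str], key: str, path: Path) -> str:
    if key not in fields:
        raise EnviFormatError(f"{path}: header field {key!r} is missing")
    return fields[key]


def write_hypercube(
    cube: Hypercube,
    path: str | Path,
    interleave: str = "bsq",
    dtype: np.dtype | type | None = None,
) -> Path:
    """Write ``cube`` as an ENVI header + raw binary pair; returns the data path.

    ``dtype`` defaults to float32 for floating cubes and the array's own dtype
    for integer (raw-count) cubes. Two writes of the same cube are
    byte-identical.
    """
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"interleave must be one of {_INTERLEAVES}")
    if dtype is None:
        dtype = cube.data.dtype if np.issubdtype(cube.data.dtype, np.integer) else np.float32
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_TO_ENVI:
        raise ValueError(f"unsupported on-disk dtype {dtype}")

    nx, ny, nl = cube.shape
    arr = np.ascontiguousarray(cube.data, dtype=dtype)
    if interleave == "bsq":  # (bands, lines, samples)
        disk = arr.transpose(2, 0, 1)
    elif interleave == "bil":  # (lines, bands, samples)
        disk = arr.transpose(0, 2, 1)
    else:  # bip: (lines, samples, bands)
        disk = arr

    fields = {
        "description": "{ hyse hypercube }",
        "samples": ny,
        "lines": nx,
        "bands": nl,
        "header offset": 0,
        "file type": "ENVI Standard",
        "data type": _DTYPE_TO_ENVI[dtype],
        "interleave": interleave,
        "byte order": 0,
        "wavelength units": "nm",
        "wavelength": [float(w) for w in cube.wavelengths],
    }
    _header_path(path).write_text(_format_header(fields))
    with open(path, "wb") as fh:
        fh.write(np.ascontiguousarray(disk).tobytes())
    if cube.meta:
        meta_path = path.with_name(path.name + ".meta.json")
        meta_path.write_text(json.dumps(_jsonable(cube.meta), indent=1, sort_keys=True))
    return path


def read_hypercube(path: str | Path) -> Hypercube:
    """Read an ENVI pair back into the in-memory ``(x, y, lam)`` convention."""
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        raise EnviFormatError(f"{hdr}: header file not found")
    if not path.exists():
        raise EnviFormatError(f"{path}: binary file not found")
    fields = _parse_header(hdr.read_text(), hdr)

    ny = int(_require(fields, "samples", hdr))
    nx = int(_require(fields, "lines", hdr))
    nl = int(_require(fields, "bands", hdr))
    code = int(_require(fields, "data type", hdr))
    interleave = _require(fields, "interleave", hdr).lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"{hdr}: unknown interleave {interleave!r}")
    if code not in _ENVI_TO_DTYPE:
        raise EnviFormatError(f"{hdr}: unsupported data type code {code}")
    if "wavelength" not in fields:
        raise EnviFormatError(f"{hdr}: header field 'wavelength' is missing (mandatory)")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].split(",") if tok.strip()]
    )
    if len(wavelengths) != nl:
        raise EnviFormatError(
            f"{hdr}: wavelength list length {len(wavelengths)} != bands {nl}"
        )
    dtype = _ENVI_TO_DTYPE[code]
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != nx * ny * nl:
        raise EnviFormatError(
            f"{path}: binary holds {raw.size} values, header declares {nx * ny * nl} "
            f"(lines={nx}, samples={ny}, bands={nl})"
        )
    if interleave == "bsq":
        data = raw.reshape(nl, nx, ny).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(nx, nl, ny).transpose(0, 2, 1)
    else:
        data = raw.reshape(nx, ny, nl)

    meta: dict[str, Any] = {}
    meta_path = path.with_name(path.name + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    return Hypercube(np.ascontiguousarray(data), wavelengths, meta)


def write_label_map(label_map: LabelMap, path: str | Path) -> Path:
    """Store a label map as a single-band int32 ENVI raster + JSON legend."""
    path = Path(path)
    nx, ny = label_map.shape
    fields = {
        "description": "{ hyse label map }",
        "samples": ny,
        "lines": nx,
        "bands": 1,
        "header offset": 0,
        "file type": "ENVI Standard",
        "data type": _DTYPE_TO_ENVI[np.dtype(np.int32)],
        "interleave": "bsq",
        "byte order": 0,
    }
    _header_path(path).write_text(_format_header(fields))
    with open(path, "wb") as fh:
        fh.write(np.ascontiguousarray(label_map.labels, dtype=np.int32).tobytes())
    legend_path = path.with_name(path.name + ".legend.json")
    legend_path.write_text(
        json.dumps({str(k): v for k, v in label_map.legend.items()}, indent=1, sort_keys=True)
    )
    return path


def read_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        raise EnviFormatError(f"{hdr}: header file not found")
    fields = _parse_header(hdr.read_text(), hdr)
    ny = int(_require(fields, "samples", hdr))
    nx = int(_require(fields, "lines", hdr))
    code = int(_require(fields, "data type", hdr))
    raw = np.fromfile(path, dtype=_ENVI_TO_DTYPE[code])
    if raw.size != nx * ny:
        raise EnviFormatError(f"{path}: binary size does not match header")
    legend_path = path.with_name(path.name + ".legend.json")
    if not legend_path.exists():
        raise EnviFormatError(f"{legend_path}: legend sidecar not found")
    legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
    return LabelMap(raw.reshape(nx, ny).astype(np.int64), legend)


def write_calibration(cal: CalibrationFrames, path: str | Path) -> Path:
    """Store white/dark frames as a 2-band float32 ENVI raster (white first)."""
    path = Path(path)
    white = np.atleast_2d(cal.white)
    stack = np.stack([white, np.broadcast_to(cal.dark, white.shape)])
    fields = {
        "description": "{ hyse calibration frames: band 0 white, band 1 dark }",
        "samples": stack.shape[2],
        "lines": stack.shape[1],
        "bands": 2,
        "header offset": 0,
        "file type": "ENVI Standard",
        "data type": _DTYPE_TO_ENVI[np.dtype(np.float32)],
        "interleave": "bsq",
        "byte order": 0,
    }
    _header_path(path).write_text(_format_header(fields))
    with open(path, "wb") as fh:
        fh.write(np.ascontiguousarray(stack, dtype=np.float32).tobytes())
    return path


def read_calibration(path: str | Path) -> CalibrationFrames:
    path = Path(path)
    fields = _parse_header(_header_path(path).read_text(), _header_path(path))
    ny = int(_require(fields, "samples", path))
    nx = int(_require(fields, "lines", path))
    raw = np.fromfile(path, dtype=np.float32)
    if raw.size != 2 * nx * ny:
        raise EnviFormatError(f"{path}: binary size does not match header")
    stack = raw.reshape(2, nx, ny).astype(np.float64)
    return CalibrationFrames(white=stack[0], dark=stack[1])


def write_library(library: ReferenceLibrary, path: str | Path) -> Path:
    """Serialize a reference-spectrum library to JSON."""
    path = Path(path)
    doc = {
        "wavelengths": [float(w) for w in library.wavelengths],
        "background_label": library.background_label,
        "classes": [
            {
                "name": c.name,
                "rgb": [int(v) for v in c.rgb],
                "spectrum": [float(v) for v in c.spectrum],
            }
            for c in library.classes
        ],
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_library(path: str | Path) -> ReferenceLibrary:
    doc = json.loads(Path(path).read_text())
    classes = [
        SpectralClass(c["name"], np.array(c["spectrum"]), tuple(c["rgb"]))
        for c in doc["classes"]
    ]
    return ReferenceLibrary(
        np.array(doc["wavelengths"]), classes, doc.get("background_label", 18)
    )


def _jsonable(obj: Any) -> Any:
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
    return obj
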