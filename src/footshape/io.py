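"""Readers and writers: STL surfaces, landmark XML, shape-model containers.

Units are millimetres everywhere (STL itself carries no units).

Landmark XML schema (defined by this package)::

    <landmarks subject="S01" segment="first_metatarsal">
      <landmark name="TL" x="12.3" y="4.5" z="-6.7"/>
      ...
    </landmarks>

Multiple segments for one subject may be wrapped in a ``<subject>`` root::

    <subject id="S01">
      <landmarks segment="first_metatarsal">...</landmarks>
      <landmarks segment="calcaneus">...</landmarks>
    </subject>

Shape-model container: a NumPy ``.npz`` archive with a format-version
marker, the mean vector, mode matrix, eigenvalues and JSON metadata.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .geometry import GeometryError, TriangleMesh

__all__ = [
    "LandmarkFile",
    "StlParseError",
    "LandmarkSchemaError",
    "ModelFormatError",
    "read_stl",
    "write_stl",
    "read_landmarks",
    "write_landmarks",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class StlParseError(ValueError):
    """Malformed STL file; carries the byte offset where parsing failed."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)


class LandmarkSchemaError(ValueError):
    """Landmark XML violates the documented schema."""


class ModelFormatError(ValueError):
    """Shape-model container unreadable or version-incompatible."""


@dataclass
class LandmarkFile:
    """Named anatomical landmark coordinates for one subject/segment."""

    subject: str
    segment: str
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for name, xyz in self.landmarks.items():
            arr = np.asarray(xyz, dtype=float).reshape(3)
            if not np.isfinite(arr).all():
                raise LandmarkSchemaError(f"landmark {name!r} has non-finite coordinates")
            clean[str(name)] = arr
        self.landmarks = clean

    def coordinates(self, names) -> np.ndarray:
        """Stack the coordinates of ``names`` in order; missing name raises."""
        missing = [n for n in names if n not in self.landmarks]
        if missing:
            raise LandmarkSchemaError(
                f"landmark(s) {missing} not present in file for subject "
                f"{self.subject!r} segment {self.segment!r}"
            )
        return np.vstack([self.landmarks[n] for n in names])


# ---------------------------------------------------------------------------
# STL

_BIN_HEADER = 80
_BIN_TRI = 50  # 12 floats * 4 bytes + 2-byte attribute


def _validate_binary_stl(path: Path) -> None:
    size = path.stat().st_size
    if size < _BIN_HEADER + 4:
        raise StlParseError("file too short for a binary STL header", offset=size)
    with open(path, "rb") as fh:
        fh.seek(_BIN_HEADER)
        (count,) = struct.unpack("<I", fh.read(4))
    expected = _BIN_HEADER + 4 + count * _BIN_TRI
    if size != expected:
        raise StlParseError(
            f"declared triangle count {count} implies {expected} bytes "
            f"but file has {size}",
            offset=min(size, expected),
        )
    if count == 0:
        raise StlParseError("binary STL declares zero triangles", offset=_BIN_HEADER)


def _weld_exact(vertices: np.ndarray, faces: np.ndarray):
    """Deduplicate vertices by exact coordinate match, preserving first
    occurrence order."""
    uniq, index, inverse = np.unique(
        vertices, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(index)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    remap = rank[inverse.ravel()]
    return uniq[order], remap[faces]


def read_stl(path, label: str | None = None, side: str = "none") -> TriangleMesh:
    """Read an ASCII or binary STL file into a :class:`TriangleMesh`.

    Vertices are welded by exact coordinate match.  Binary files are
    validated against the declared triangle count before parsing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        head = fh.read(5)
    is_ascii = head.startswith(b"solid")
    if is_ascii:
        # an ASCII file must contain a "facet" token; otherwise treat as
        # binary whose header merely begins with "solid"
        text_probe = path.read_bytes()[:2048]
        if b"facet" not in text_probe:
            is_ascii = False
    if not is_ascii:
        _validate_binary_stl(path)
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise StlParseError(f"unparseable STL: {exc}", offset=0) from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise StlParseError("STL contains no triangles (empty solid)", offset=_BIN_HEADER)
    verts = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    uniq, remapped = _weld_exact(verts, faces)
    return TriangleMesh(uniq, remapped, label=label, side=side)


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write a mesh as STL.  ``dialect`` is ``"binary"`` (bit-exact
    round-trip) or ``"ascii"``."""
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"dialect must be binary or ascii, got {dialect!r}")
    if len(mesh.faces) == 0:
        raise GeometryError("refusing to write an empty mesh")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tm = mesh.to_trimesh()
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    data = trimesh.exchange.export.export_mesh(tm, None, file_type=file_type)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# landmark XML

from xml.etree import ElementTree as ET  # noqa: E402


def _parse_landmarks_element(el, subject: str) -> LandmarkFile:
    segment = el.get("segment")
    if segment is None:
        raise LandmarkSchemaError("<landmarks> element missing 'segment' attribute")
    seen: dict[str, np.ndarray] = {}
    for lm in el.findall("landmark"):
        name = lm.get("name")
        if name is None:
            raise LandmarkSchemaError("<landmark> element missing 'name' attribute")
        if name in seen:
            raise LandmarkSchemaError(f"duplicate landmark name {name!r}")
        coords = []
        for axis in ("x", "y", "z"):
            val = lm.get(axis)
            if val is None:
                raise LandmarkSchemaError(
                    f"landmark {name!r} missing coordinate attribute {axis!r}"
                )
            coords.append(float(val))
        seen[name] = np.array(coords)
    return LandmarkFile(subject=subject, segment=segment, landmarks=seen)


def read_landmarks(path) -> list[LandmarkFile]:
    """Read a landmark XML file.

    Returns one :class:`LandmarkFile` per segment (a file may carry several
    segments under a ``<subject>`` root).
    """
    tree = ET.parse(path)
    root = tree.getroot()
    if root.tag == "landmarks":
        subject = root.get("subject")
        if subject is None:
            raise LandmarkSchemaError("<landmarks> root missing 'subject' attribute")
        return [_parse_landmarks_element(root, subject)]
    if root.tag == "subject":
        subject = root.get("id")
        if subject is None:
            raise LandmarkSchemaError("<subject> root missing 'id' attribute")
        out = [_parse_landmarks_element(el, subject) for el in root.findall("landmarks")]
        if not out:
            raise LandmarkSchemaError("<subject> root contains no <landmarks> elements")
        segs = [f.segment for f in out]
        if len(set(segs)) != len(segs):
            raise LandmarkSchemaError("duplicate segment in landmark file")
        return out
    raise LandmarkSchemaError(f"unexpected root element <{root.tag}>")


def write_landmarks(files: LandmarkFile | list[LandmarkFile], path) -> None:
    """Write landmark files to XML (single <landmarks> root for one segment,
    <subject> root for several).  Coordinates use repr-precision floats, so
    round-trips are exact to better than 1e-12."""
    if isinstance(files, LandmarkFile):
        files = [files]
    if not files:
        raise LandmarkSchemaError("nothing to write")
    subjects = {f.subject for f in files}
    if len(subjects) != 1:
        raise LandmarkSchemaError("one landmark file per subject")

    def fill(el, lf):
        for name, xyz in lf.landmarks.items():
            ET.SubElement(el, "landmark", name=name,
                          x=repr(float(xyz[0])), y=repr(float(xyz[1])),
                          z=repr(float(xyz[2])))

    if len(files) == 1:
        root = ET.Element("landmarks", subject=files[0].subject,
                          segment=files[0].segment)
        fill(root, files[0])
    else:
        root = ET.Element("subject", id=files[0].subject)
        for lf in files:
            el = ET.SubElement(root, "landmarks", segment=lf.segment)
            fill(el, lf)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tree.write(path, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# shape-model container


def save_model(model, path) -> None:
    """Save a fitted :class:`~footshape.model.PointDistributionModel` to a
    versioned ``.npz`` container (lossless)."""
    from .model import PointDistributionModel  # local import avoids cycle

    if not isinstance(model, PointDistributionModel):
        raise TypeError("save_model expects a PointDistributionModel")
    model._check_fitted()
    meta = {
        "segment": model.segment_,
        "n_training": int(model.n_training_),
        "landmark_indices": {k: int(v) for k, v in (model.landmark_indices_ or {}).items()},
    }
    np.savez(
        path,
        format_version=np.array(MODEL_FORMAT_VERSION),
        mean=model.mean_,
        components=model.components_,
        eigenvalues=model.eigenvalues_,
        total_variance=np.array(model._total_variance),
        faces=model.faces_ if model.faces_ is not None else np.zeros((0, 3), np.int64),
        metadata=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path):
    """Load a shape model saved by :func:`save_model`."""
    from .model import PointDistributionModel

    try:
        with np.load(path) as data:
            if "format_version" not in data:
                raise ModelFormatError("not a footshape model container")
            version = int(data["format_version"])
            if version != MODEL_FORMAT_VERSION:
                raise ModelFormatError(
                    f"container version {version} not supported "
                    f"(expected {MODEL_FORMAT_VERSION})"
                )
            meta = json.loads(bytes(data["metadata"]).decode())
            faces = data["faces"]
            model = PointDistributionModel._from_arrays(
                mean=data["mean"],
                components=data["components"],
                eigenvalues=data["eigenvalues"],
                n_training=meta["n_training"],
                segment=meta["segment"],
                landmark_indices=meta["landmark_indices"] or None,
                faces=faces if len(faces) else None,
                total_variance=float(data["total_variance"]),
            )
    except (OSError, ValueError, KeyError) as exc:
        if isinstance(exc, ModelFormatError):
            raise
        raise ModelFormatError(f"cannot read model container: {exc}") from exc
    return model
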