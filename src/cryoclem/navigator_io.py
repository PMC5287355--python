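"""Navigator-file coordinate exchange.

The EM control software stores selected points, polygons and map images in
plain-text "navigator" files written in the autodoc dialect: a version
header line, then ``[Item = label]`` sections of ``Key = value`` lines.
This module reads and writes that dialect losslessly — every key is kept
verbatim in ``raw_fields``, so fields this package does not interpret
survive a read/write round trip byte-identically — and converts annotation
lists (positions of interest and grid reference landmarks) from the FM side
into navigator point items, optionally mapping them through an FM->EM
transform first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import Point2D, Transform2D

__all__ = [
    "NavigatorItem",
    "AnnotationList",
    "read_navigator",
    "write_navigator",
    "export_annotations",
    "NAV_VERSION",
]

NAV_VERSION = "2.00"

_TYPE_TO_KIND = {0: "point", 1: "polygon", 2: "map"}
_KIND_TO_TYPE = {v: k for k, v in _TYPE_TO_KIND.items()}

POI_GROUP_ID = 11
GRID_REF_GROUP_ID = 21


def _fmt(v: float) -> str:
    """Floats with up to 6 significant digits, integers without decimals."""
    if float(v) == int(v):
        return str(int(v))
    return f"{float(v):.6g}"


@dataclass
class NavigatorItem:
    """One record of a navigator file.

    ``raw_fields`` is the ordered list of ``(key, value-string)`` pairs
    exactly as read; parsed attributes (``stage``, ``kind`` ...) are views
    onto it.  Writing emits ``raw_fields`` verbatim, which is what makes
    the round trip lossless for keys this package does not model.
    """

    item_id: str
    kind: str = "point"
    stage: Point2D = Point2D(0.0, 0.0)
    stage_z: float = 0.0
    registration_group: int = 0
    map_file: str | None = None
    map_scale_matrix: np.ndarray | None = None
    raw_fields: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in _KIND_TO_TYPE:
            raise ValueError(f"unknown item kind {self.kind!r}")
        if self.kind == "map" and not self.map_file:
            raise ValueError("map items require map_file")
        if not self.raw_fields:
            self.raw_fields = self._default_fields()

    def _default_fields(self) -> list[tuple[str, str]]:
        fields = [
            ("Type", str(_KIND_TO_TYPE[self.kind])),
            (
                "StageXYZ",
                f"{_fmt(self.stage.x)} {_fmt(self.stage.y)} {_fmt(self.stage_z)}",
            ),
            ("GroupID", str(self.registration_group)),
        ]
        if self.map_file:
            fields.append(("MapFile", self.map_file))
        if self.map_scale_matrix is not None:
            m = np.asarray(self.map_scale_matrix, dtype=float).ravel()
            fields.append(("MapScaleMat", " ".join(_fmt(v) for v in m)))
        return fields


class NavigatorParseError(ValueError):
    pass


def _parse_item(label: str, lines: list[tuple[int, str]]) -> NavigatorItem:
    raw: list[tuple[str, str]] = []
    kind = "point"
    stage = Point2D(0.0, 0.0)
    stage_z = 0.0
    group = 0
    map_file = None
    map_scale = None
    for lineno, line in lines:
        if "=" not in line:
            raise NavigatorParseError(f"line {lineno}: expected 'Key = value', got {line!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        val = val.strip()
        raw.append((key, val))
        try:
            if key == "Type":
                kind = _TYPE_TO_KIND.get(int(val), "point")
            elif key == "StageXYZ":
                parts = [float(p) for p in val.split()]
                stage = Point2D(parts[0], parts[1])
                stage_z = parts[2] if len(parts) > 2 else 0.0
            elif key == "GroupID":
                group = int(val)
            elif key == "MapFile":
                map_file = val
            elif key == "MapScaleMat":
                vals = [float(p) for p in val.split()]
                map_scale = np.array(vals[:4], dtype=float).reshape(2, 2)
        except (ValueError, IndexError) as exc:
            if isinstance(exc, NavigatorParseError):
                raise
            raise NavigatorParseError(
                f"line {lineno}: cannot parse {key} value {val!r}"
            ) from exc
    return NavigatorItem(
        item_id=label,
        kind=kind,
        stage=stage,
        stage_z=stage_z,
        registration_group=group,
        map_file=map_file,
        map_scale_matrix=map_scale,
        raw_fields=raw,
    )


def read_navigator(path: str | Path) -> list[NavigatorItem]:
    """Parse a navigator file into :class:`NavigatorItem` records.

    The first non-blank line must be the ``AdocVersion`` header; malformed
    section bodies raise with the offending line number.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    idx = 0
    while idx < len(lines) and not lines[idx].strip():
        idx += 1
    if idx >= len(lines) or not lines[idx].strip().startswith("AdocVersion"):
        raise NavigatorParseError("missing AdocVersion header line")
    idx += 1

    items: list[NavigatorItem] = []
    current_label: str | None = None
    current_lines: list[tuple[int, str]] = []
    for lineno in range(idx, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.startswith("["):
            if current_label is not None:
                items.append(_parse_item(current_label, current_lines))
            if not (line.endswith("]") and "=" in line):
                raise NavigatorParseError(
                    f"line {lineno + 1}: malformed section header {line!r}"
                )
            head, _, label = line[1:-1].partition("=")
            if head.strip() != "Item":
                raise NavigatorParseError(
                    f"line {lineno + 1}: expected [Item = ...], got {line!r}"
                )
            current_label = label.strip()
            current_lines = []
        else:
            if current_label is None:
                raise NavigatorParseError(
                    f"line {lineno + 1}: data line outside any [Item] section"
                )
            current_lines.append((lineno + 1, line))
    if current_label is not None:
        items.append(_parse_item(current_label, current_lines))
    return items


def write_navigator(
    items: list[NavigatorItem], path: str | Path, version: str = NAV_VERSION
) -> None:
    """Write items in input order; an empty list produces a header-only file."""
    out = [f"AdocVersion = {version}", ""]
    for item in items:
        out.append(f"[Item = {item.item_id}]")
        for key, val in item.raw_fields:
            out.append(f"{key} = {val}")
        out.append("")
    Path(path).write_text("\n".join(out).rstrip("\n") + "\n")


@dataclass
class AnnotationList:
    """FM-side annotations: targets for acquisition and grid-wide landmarks."""

    pois: list[tuple[str, Point2D, str]] = field(default_factory=list)  # label, point, channel
    grid_refs: list[tuple[str, Point2D]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for group in (
            [label for label, *_ in self.pois],
            [label for label, _ in self.grid_refs],
        ):
            if len(group) != len(set(group)):
                raise ValueError("annotation labels must be unique within a list")

    def to_tsv(self, path: str | Path) -> None:
        rows = ["label\tx\ty\tkind\tchannel"]
        for label, p, ch in self.pois:
            rows.append(f"{label}\t{p.x:.6f}\t{p.y:.6f}\tpoi\t{ch}")
        for label, p in self.grid_refs:
            rows.append(f"{label}\t{p.x:.6f}\t{p.y:.6f}\tgrid_ref\t")
        Path(path).write_text("\n".join(rows) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationList":
        pois, refs = [], []
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            label, x, y, kind, channel = (line.split("\t") + [""])[:5]
            p = Point2D(float(x), float(y))
            if kind == "poi":
                pois.append((label, p, channel))
            else:
                refs.append((label, p))
        return cls(pois=pois, grid_refs=refs)


def export_annotations(
    annotations: AnnotationList,
    transform: Transform2D | None = None,
) -> list[NavigatorItem]:
    """Convert an annotation list to navigator point items.

    POIs go into one registration group and grid references into another,
    so the EM side can treat landmark registration points and acquisition
    targets differently.  When ``transform`` is given it must map the
    annotation frame to EM stage coordinates, and all points are mapped
    through it; otherwise coordinates pass through unchanged.  Stage Z
    defaults to 0 — eucentric height is set at the instrument.
    """

    def _map(p: Point2D) -> Point2D:
        if transform is None:
            return p
        return transform.apply_point(p)

    items: list[NavigatorItem] = []
    for label, p, _channel in annotations.pois:
        items.append(
            NavigatorItem(
                item_id=label,
                kind="point",
                stage=_map(p),
                registration_group=POI_GROUP_ID,
            )
        )
    for label, p in annotations.grid_refs:
        items.append(
            NavigatorItem(
                item_id=label,
                kind="point",
                stage=_map(p),
                registration_group=GRID_REF_GROUP_ID,
            )
        )
    return items
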