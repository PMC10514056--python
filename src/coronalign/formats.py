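"""Readers and writers for QuickNII-compatible alignment files.

Two dialects are supported:

* **quicknii-json** — ``{"name": ..., "target": ..., "slices": [{"filename",
  "nr", "width", "height", "anchoring": [ox,oy,oz,ux,uy,uz,vx,vy,vz]}]}``.
* **quicknii-xml** — ``<series name=...>`` containing ``<slice>`` elements
  whose ``anchoring`` attribute is an ampersand-joined ``key=value`` string
  (``ox=...&oy=...&...``), keys in canonical order.

The QuickNII ``nr`` (section number) attribute is mapped onto
``SectionAnchor.cutting_index``; when writing a section without a cutting
index, ``nr`` falls back to the 1-based position in the series.
"""

from __future__ import annotations

import json
from pathlib import Path

from lxml import etree

from .anchoring import ANCHORING_FIELDS, DEFAULT_TARGET, SectionAnchor, SeriesAlignment

__all__ = ["FormatError", "read_series", "write_series", "DIALECTS"]

DIALECTS = ("quicknii-json", "quicknii-xml")


class FormatError(ValueError):
    """An alignment file does not conform to the named dialect."""


def _detect_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "quicknii-json"
    if suffix == ".xml":
        return "quicknii-xml"
    raise FormatError(
        f"cannot infer dialect from extension {suffix!r} of {path}; pass dialect explicitly"
    )


def _slice_label(index: int, filename) -> str:
    return f"slice {index}" + (f" ({filename!r})" if filename else "")


def _parse_number(value, field: str, where: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(f"{where}: non-numeric {field}={value!r}") from None


def _parse_int(value, field: str, where: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise FormatError(f"{where}: non-integer {field}={value!r}") from None


def read_series(path, dialect: str | None = None) -> SeriesAlignment:
    """Read a series alignment, auto-detecting the dialect from the extension."""
    path = Path(path)
    dialect = dialect or _detect_dialect(path)
    if dialect == "quicknii-json":
        return _read_json(path)
    if dialect == "quicknii-xml":
        return _read_xml(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_series(series: SeriesAlignment, path, dialect: str | None = None) -> None:
    """Write a series alignment; numbers keep full float precision."""
    path = Path(path)
    dialect = dialect or _detect_dialect(path)
    if dialect == "quicknii-json":
        _write_json(series, path)
    elif dialect == "quicknii-xml":
        _write_xml(series, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _read_json(path: Path) -> SeriesAlignment:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from None
    if not isinstance(doc, dict) or "slices" not in doc:
        raise FormatError(f"{path}: missing top-level 'slices' array")
    sections = []
    for k, item in enumerate(doc["slices"]):
        where = _slice_label(k, item.get("filename"))
        for key in ("filename", "width", "height", "anchoring"):
            if key not in item:
                raise FormatError(f"{path}: {where}: missing field {key!r}")
        anchoring = item["anchoring"]
        if len(anchoring) != 9:
            raise FormatError(
                f"{path}: {where}: anchoring has {len(anchoring)} components, expected 9"
            )
        comps = [_parse_number(c, f"anchoring[{n}]", where) for n, c in enumerate(anchoring)]
        nr = _parse_int(item["nr"], "nr", where) if "nr" in item else None
        sections.append(
            SectionAnchor.from_components(
                str(item["filename"]),
                comps,
                width=_parse_int(item["width"], "width", where),
                height=_parse_int(item["height"], "height", where),
                cutting_index=nr,
            )
        )
    return SeriesAlignment(
        name=str(doc.get("name", path.stem)),
        sections=sections,
        target=str(doc.get("target", DEFAULT_TARGET)),
    )


def _nr(section: SectionAnchor, position: int) -> int:
    return section.cutting_index if section.cutting_index is not None else position + 1


def _write_json(series: SeriesAlignment, path: Path) -> None:
    doc = {
        "name": series.name,
        "target": series.target,
        "slices": [
            {
                "filename": s.filename,
                "nr": _nr(s, k),
                "width": s.width,
                "height": s.height,
                "anchoring": [getattr(s, f) for f in ANCHORING_FIELDS],
            }
            for k, s in enumerate(series.sections)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _parse_anchoring_string(text: str, where: str) -> list[float]:
    pairs = {}
    for token in text.split("&"):
        if "=" not in token:
            raise FormatError(f"{where}: malformed anchoring token {token!r}")
        key, _, value = token.partition("=")
        pairs[key.strip()] = value
    missing = [f for f in ANCHORING_FIELDS if f not in pairs]
    if missing:
        raise FormatError(f"{where}: anchoring string omits {', '.join(missing)}")
    return [_parse_number(pairs[f], f, where) for f in ANCHORING_FIELDS]


def _read_xml(path: Path) -> SeriesAlignment:
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: not valid XML: {exc}") from None
    if root.tag != "series":
        raise FormatError(f"{path}: root element is <{root.tag}>, expected <series>")
    sections = []
    for k, elem in enumerate(root.iter("slice")):
        where = _slice_label(k, elem.get("filename"))
        for attr in ("filename", "width", "height", "anchoring"):
            if elem.get(attr) is None:
                raise FormatError(f"{path}: {where}: missing attribute {attr!r}")
        comps = _parse_anchoring_string(elem.get("anchoring"), f"{path}: {where}")
        nr = elem.get("nr")
        sections.append(
            SectionAnchor.from_components(
                elem.get("filename"),
                comps,
                width=_parse_int(elem.get("width"), "width", where),
                height=_parse_int(elem.get("height"), "height", where),
                cutting_index=_parse_int(nr, "nr", where) if nr is not None else None,
            )
        )
    return SeriesAlignment(
        name=root.get("name", path.stem),
        sections=sections,
        target=root.get("target", DEFAULT_TARGET),
    )


def _write_xml(series: SeriesAlignment, path: Path) -> None:
    root = etree.Element("series", name=series.name, target=series.target)
    for k, s in enumerate(series.sections):
        anchoring = "&".join(f"{f}={getattr(s, f)!r}" for f in ANCHORING_FIELDS)
        etree.SubElement(
            root,
            "slice",
            filename=s.filename,
            nr=str(_nr(s, k)),
            width=str(s.width),
            height=str(s.height),
            anchoring=anchoring,
        )
    etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True, encoding="utf-8")
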