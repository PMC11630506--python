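"""Data model for the supported Gosling-grammar subset.

A specification is a JSON tree of *views* (grouping nodes that may carry
shared properties and an arrangement) and *tracks* (leaves binding a
dataset to a mark plus visual channels).  Properties set on a view apply
to every descendant track unless overridden closer to the track;
normalization resolves that inheritance and fills grammar defaults so that
every track is flat and fully specified.

The closed vocabularies below cover the marks and channels the chart-type
rules and the natural-language maps know about.  Other channels sometimes
seen in the wild (x1, x1e, y1, stroke, opacity, size) are parsed and
retained verbatim but only described generically; unknown properties are
kept and flagged, never fatal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterator

MARKS = ("point", "line", "bar", "rect", "rule", "triangle", "text", "area", "circle")
CHANNELS = ("x", "xe", "y", "ye", "row", "color", "text")
EXTRA_CHANNELS = ("x1", "x1e", "y1", "stroke", "opacity", "size")
FIELD_TYPES = ("genomic", "quantitative", "nominal")
LAYOUTS = ("linear", "circular")
ARRANGEMENTS = ("vertical", "horizontal", "parallel", "serial")

#: properties a view passes down to descendant tracks
INHERITABLE = ("layout", "assembly", "data", "static", "width", "height")

#: grammar defaults applied when neither the track nor any ancestor sets a value
DEFAULTS: dict[str, Any] = {
    "layout": "linear",
    "assembly": "hg38",
    "arrangement": "vertical",
    "alignment": "stack",
    "static": False,
}

_KNOWN_PROPS = frozenset(
    ("mark", "data", "layout", "arrangement", "alignment", "assembly", "title",
     "subtitle", "width", "height", "static", "views", "tracks")
    + CHANNELS + EXTRA_CHANNELS
)


class SpecError(ValueError):
    """Malformed or empty specification."""


class SpecValidationError(SpecError):
    """A structurally valid spec that violates a grammar invariant."""


@dataclass(frozen=True)
class ChannelBinding:
    """One visual channel: either a data field of a declared type, or a literal value."""

    channel_name: str
    field: str | None = None
    field_type: str | None = None
    value: Any = None

    def __post_init__(self) -> None:
        if self.field is not None and self.value is not None:
            raise SpecValidationError(
                f"channel {self.channel_name!r} binds both a field and a value"
            )
        if self.field is not None and self.field_type is None and self.channel_name != "text":
            raise SpecValidationError(
                f"channel {self.channel_name!r} binds field {self.field!r} without a type"
            )

    @property
    def is_axis(self) -> bool:
        return self.field is not None


@dataclass
class RawSpec:
    """A parsed, unresolved specification tree plus parser bookkeeping."""

    root: dict[str, Any]
    unknown_props: list[tuple[str, str]] = field(default_factory=list)

    def track_leaves(self) -> list[dict[str, Any]]:
        return list(_iter_tracks(self.root))


@dataclass
class NormalizedTrack:
    """A fully resolved track: every property has a value after normalization."""

    track_id: int
    mark: str
    channels: dict[str, ChannelBinding]
    layout: str
    assembly: str
    data_ref: str | None = None
    title: str | None = None
    overlay_group: int | None = None
    width: int | None = None
    height: int | None = None
    static: bool = False
    extra: dict[str, Any] = field(default_factory=dict)

    def channel(self, name: str) -> ChannelBinding | None:
        return self.channels.get(name)

    def axis_type(self, name: str) -> str | None:
        """field_type of a channel when it is field-bound, else None."""
        ch = self.channels.get(name)
        return ch.field_type if ch is not None and ch.is_axis else None


@dataclass
class NormalizedSpec:
    """Flat track list plus the residual arrangement tree.

    The arrangement tree records how views arrange their children:
    ``{"arrangement": ..., "children": [...]}`` with ``{"track": id}``
    leaves.  Track order equals document order of the raw spec.
    """

    tracks: list[NormalizedTrack]
    arrangement_tree: dict[str, Any]
    global_title: str | None = None

    def to_raw(self) -> RawSpec:
        """Re-express this normalized spec as an explicit raw spec.

        Normalizing the result reproduces this spec (idempotence).
        """
        by_id = {t.track_id: t for t in self.tracks}

        def node_to_raw(node: dict[str, Any]) -> dict[str, Any]:
            if "track" in node:
                return _track_to_raw(by_id[node["track"]])
            children = node.get("children", [])
            leaf_ids = [c["track"] for c in children if "track" in c]
            groups = {by_id[i].overlay_group for i in leaf_ids}
            if (children and len(leaf_ids) == len(children) and len(groups) == 1
                    and groups != {None}):
                return {
                    "arrangement": node.get("arrangement", DEFAULTS["arrangement"]),
                    "alignment": "overlay",
                    "tracks": [_track_to_raw(by_id[i]) for i in leaf_ids],
                }
            return {
                "arrangement": node.get("arrangement", DEFAULTS["arrangement"]),
                "views": [node_to_raw(c) for c in children],
            }

        root = node_to_raw(self.arrangement_tree)
        if self.global_title is not None:
            root["title"] = self.global_title
        return RawSpec(root)


def _track_to_raw(t: NormalizedTrack) -> dict[str, Any]:
    raw: dict[str, Any] = {"mark": t.mark, "layout": t.layout, "assembly": t.assembly,
                           "static": t.static}
    if t.data_ref is not None:
        raw["data"] = t.data_ref
    if t.title is not None:
        raw["title"] = t.title
    if t.width is not None:
        raw["width"] = t.width
    if t.height is not None:
        raw["height"] = t.height
    for name, ch in t.channels.items():
        if ch.is_axis:
            d: dict[str, Any] = {"field": ch.field}
            if ch.field_type is not None:
                d["type"] = ch.field_type
            raw[name] = d
        else:
            raw[name] = {"value": ch.value}
    raw.update(t.extra)
    return raw


def _is_track(node: dict[str, Any]) -> bool:
    return "mark" in node


def _iter_tracks(node: dict[str, Any]) -> Iterator[dict[str, Any]]:
    if _is_track(node):
        yield node
        return
    for child in node.get("views", []) + node.get("tracks", []):
        yield from _iter_tracks(child)


def parse_spec(text: str | dict[str, Any]) -> RawSpec:
    """Parse a JSON specification document into a :class:`RawSpec`.

    Unknown properties are retained and flagged in ``unknown_props`` as
    ``(json-path, property)`` pairs.  A document without any track is
    rejected.
    """
    if isinstance(text, dict):
        root = text
    else:
        try:
            root = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SpecError(f"malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}") from exc
    if not isinstance(root, dict):
        raise SpecError("specification root must be a JSON object")
    spec = RawSpec(root)
    if not spec.track_leaves():
        raise SpecError("specification contains no track")

    def flag_unknown(node: dict[str, Any], path: str) -> None:
        for key in node:
            if key not in _KNOWN_PROPS:
                spec.unknown_props.append((path, key))
        for i, child in enumerate(node.get("views", [])):
            flag_unknown(child, f"{path}/views/{i}")
        for i, child in enumerate(node.get("tracks", [])):
            if isinstance(child, dict) and not _is_track(child):
                flag_unknown(child, f"{path}/tracks/{i}")

    flag_unknown(root, "$")
    return spec


def _parse_channel(name: str, raw: Any) -> ChannelBinding:
    if not isinstance(raw, dict):
        return ChannelBinding(name, value=raw)
    if "field" in raw and "value" in raw:
        raise SpecValidationError(f"channel {name!r} defines both a field and a value")
    return ChannelBinding(
        name,
        field=raw.get("field"),
        field_type=raw.get("type"),
        value=raw.get("value"),
    )


def _data_ref(data: Any) -> str | None:
    if data is None:
        return None
    if isinstance(data, str):
        return data
    if isinstance(data, dict):
        return data.get("url") or data.get("id") or json.dumps(data, sort_keys=True)
    return str(data)


def normalize_spec(raw: RawSpec | NormalizedSpec,
                   defaults: dict[str, Any] | None = None) -> NormalizedSpec:
    """Resolve view inheritance and defaults into flat, fully-specified tracks.

    A property set on a view applies to all descendant tracks unless a
    nearer view or the track itself overrides it; whatever remains unset is
    filled from ``defaults`` (the grammar defaults by default).  Tracks of
    an ``alignment: overlay`` view share an ``overlay_group``.  The
    operation is idempotent: normalizing an already-normalized spec is a
    no-op.
    """
    if isinstance(raw, NormalizedSpec):
        raw = raw.to_raw()
    table = dict(DEFAULTS)
    if defaults:
        table.update(defaults)

    tracks: list[NormalizedTrack] = []
    counter = {"track": 0, "group": 0}

    def resolve_track(node: dict[str, Any], inherited: dict[str, Any],
                      overlay_group: int | None) -> dict[str, Any]:
        merged = dict(inherited)
        merged.update({k: v for k, v in node.items() if k in INHERITABLE})
        channels: dict[str, ChannelBinding] = {}
        extra: dict[str, Any] = {}
        for key, val in node.items():
            if key in CHANNELS:
                channels[key] = _parse_channel(key, val)
            elif key not in _KNOWN_PROPS:
                extra[key] = val
            elif key in EXTRA_CHANNELS:
                extra[key] = val
        track = NormalizedTrack(
            track_id=counter["track"],
            mark=node.get("mark", ""),
            channels=channels,
            layout=merged.get("layout", table["layout"]),
            assembly=merged.get("assembly", table["assembly"]),
            data_ref=_data_ref(merged.get("data")),
            title=node.get("title"),
            overlay_group=overlay_group,
            width=merged.get("width"),
            height=merged.get("height"),
            static=bool(merged.get("static", table["static"])),
            extra=extra,
        )
        tracks.append(track)
        counter["track"] += 1
        return {"track": track.track_id}

    def resolve_view(node: dict[str, Any], inherited: dict[str, Any]) -> dict[str, Any]:
        merged = dict(inherited)
        merged.update({k: v for k, v in node.items() if k in INHERITABLE})
        alignment = node.get("alignment", table["alignment"])
        children_raw = node.get("views", []) + node.get("tracks", [])
        overlay_group: int | None = None
        track_children = [c for c in children_raw if _is_track(c)]
        if alignment == "overlay" and len(track_children) > 1:
            overlay_group = counter["group"]
            counter["group"] += 1
        children = []
        for child in children_raw:
            if _is_track(child):
                children.append(resolve_track(child, merged, overlay_group))
            else:
                children.append(resolve_view(child, merged))
        return {
            "arrangement": node.get("arrangement", table["arrangement"]),
            "children": children,
        }

    root = raw.root
    if _is_track(root):
        tree = {"arrangement": table["arrangement"],
                "children": [resolve_track(root, {}, None)]}
    else:
        tree = resolve_view(root, {})
    return NormalizedSpec(tracks=tracks, arrangement_tree=tree,
                          global_title=root.get("title"))


@dataclass(frozen=True)
class Issue:
    """One validation finding, naming the offending track and property."""

    track_id: int | None
    prop: str
    message: str


def validate_spec(spec: NormalizedSpec) -> list[Issue]:
    """Check grammar invariants on a normalized spec; issues are data, not errors."""
    issues: list[Issue] = []
    for t in spec.tracks:
        if t.mark not in MARKS:
            issues.append(Issue(t.track_id, "mark", f"mark {t.mark!r} is not in the mark vocabulary"))
        if t.layout not in LAYOUTS:
            issues.append(Issue(t.track_id, "layout", f"layout {t.layout!r} must be linear or circular"))
        if not t.assembly:
            issues.append(Issue(t.track_id, "assembly", "assembly is unresolved"))
        for name, ch in t.channels.items():
            if ch.field is None and ch.value is None:
                issues.append(Issue(t.track_id, name, f"channel {name!r} binds neither field nor value"))
            if ch.is_axis and ch.field_type is not None and ch.field_type not in FIELD_TYPES:
                issues.append(Issue(t.track_id, name, f"channel {name!r} has unknown type {ch.field_type!r}"))

    known_ids = {t.track_id for t in spec.tracks}
    seen: list[int] = []

    def walk(node: dict[str, Any]) -> None:
        if "track" in node:
            seen.append(node["track"])
            return
        if node.get("arrangement") not in ARRANGEMENTS:
            issues.append(Issue(None, "arrangement",
                                f"arrangement {node.get('arrangement')!r} is not recognised"))
        for child in node.get("children", []):
            walk(child)

    walk(spec.arrangement_tree)
    for tid in seen:
        if tid not in known_ids:
            issues.append(Issue(tid, "arrangement_tree", f"arrangement tree references missing track {tid}"))
    return issues
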