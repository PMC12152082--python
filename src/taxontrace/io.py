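"""Reading and writing collections of taxon sets.

Two boundary formats:

* plain text, UTF-8, one taxon set per line with comma-separated labels;
  ``#`` starts a comment; an optional header line
  ``universe: a,b,c,...`` declares X explicitly (default: the union of
  all member sets);
* JSON: ``{"taxa": [...], "sets": [[...], ...]}``.

Writing then reading a collection reproduces it exactly (member sets in
canonical order under the universe's label order).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .combinatorics import TaxonSetCollection, TaxonUniverse

__all__ = ["loads", "dumps", "read_collection", "write_collection"]

log = logging.getLogger(__name__)


class CollectionFormatError(ValueError):
    """Malformed collection input, reported with its line number."""


def _loads_text(text: str) -> TaxonSetCollection:
    universe: TaxonUniverse | None = None
    sets: list[list[str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("universe:"):
            if universe is not None:
                raise CollectionFormatError(
                    f"line {lineno}: duplicate universe declaration"
                )
            labels = [
                t.strip() for t in line.split(":", 1)[1].split(",")
            ]
            labels = [t for t in labels if t]
            if not labels:
                raise CollectionFormatError(
                    f"line {lineno}: empty universe declaration"
                )
            try:
                universe = TaxonUniverse(tuple(labels))
            except ValueError as exc:
                raise CollectionFormatError(
                    f"line {lineno}: {exc}"
                ) from None
            continue
        members = [t.strip() for t in line.split(",")]
        if any(not t for t in members):
            raise CollectionFormatError(
                f"line {lineno}: empty taxon label"
            )
        sets.append(members)
    try:
        coll = TaxonSetCollection.from_iterables(sets, universe)
    except ValueError as exc:
        raise CollectionFormatError(str(exc)) from None
    _warn_duplicates(coll)
    return coll


def _loads_json(text: str) -> TaxonSetCollection:
    data = json.loads(text)
    universe = None
    if data.get("taxa"):
        universe = TaxonUniverse(tuple(str(t) for t in data["taxa"]))
    coll = TaxonSetCollection.from_iterables(
        [[str(t) for t in y] for y in data.get("sets", [])], universe
    )
    _warn_duplicates(coll)
    return coll


def _warn_duplicates(coll: TaxonSetCollection) -> None:
    if len(set(coll.sets)) != len(coll.sets):
        log.warning(
            "collection contains duplicate member sets; induced tuples "
            "are unaffected"
        )


def loads(text: str) -> TaxonSetCollection:
    """Parse either format (JSON when the payload starts with '{')."""
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return _loads_json(text)
    return _loads_text(text)


def dumps(coll: TaxonSetCollection, fmt: str = "text") -> str:
    """Serialize a collection in the text (default) or JSON format."""
    if fmt == "json":
        return json.dumps(
            {
                "taxa": list(coll.universe.labels),
                "sets": [
                    list(coll.universe.sort_labels(y)) for y in coll.sets
                ],
            },
            indent=2,
        )
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}")
    lines = ["universe: " + ",".join(coll.universe.labels)]
    for y in coll.sets:
        lines.append(",".join(coll.universe.sort_labels(y)))
    return "\n".join(lines) + "\n"


def read_collection(path: str | Path) -> TaxonSetCollection:
    return loads(Path(path).read_text(encoding="utf-8"))


def write_collection(
    coll: TaxonSetCollection, path: str | Path, fmt: str = "text"
) -> None:
    Path(path).write_text(dumps(coll, fmt), encoding="utf-8")
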