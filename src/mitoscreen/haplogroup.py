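"""Simplified mtDNA haplogroup assignment by marker-set matching.

A haplogroup is scored as the fraction of its defining markers present in a
sample's variant set; candidates are ranked by descending score with
lexicographic tie-breaking. This deliberately flat model (no phylogenetic
tree walking, no back-mutations) is enough to check set concordance of a
sample with a named lineage; it does not reproduce full tree-based callers.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .reference import ValidationError
from .variants import Variant

__all__ = ["MarkerDB", "load_marker_db", "match_haplogroup"]

MarkerKey = tuple[int, str, str]


@dataclass(frozen=True)
class MarkerDB:
    """Map from haplogroup name to its set of defining variants."""

    entries: dict[str, frozenset[MarkerKey]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("empty marker database")
        for name, markers in self.entries.items():
            if not markers:
                raise ValidationError(f"haplogroup {name!r} has an empty marker set")


def load_marker_db(source) -> MarkerDB:
    """Load a marker DB from JSON ({haplogroups: {name: [{position, ref, alt}]}})
    or TSV (haplogroup, position, ref, alt)."""
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        path = str(source)
        source = open(source, "rt")
        close = True
    else:
        path = getattr(source, "name", "")
    try:
        if path.endswith(".json"):
            doc = json.load(source)
            groups = doc.get("haplogroups", doc)
            entries = {
                name: frozenset(
                    (int(m["position"]), m["ref"].upper(), m["alt"].upper())
                    for m in markers
                )
                for name, markers in groups.items()
                if not name.startswith("_")
            }
        else:
            reader = csv.DictReader(
                (ln for ln in source if not ln.startswith("#")), delimiter="\t"
            )
            entries_mut: dict[str, set[MarkerKey]] = {}
            for row in reader:
                entries_mut.setdefault(row["haplogroup"], set()).add(
                    (int(row["position"]), row["ref"].upper(), row["alt"].upper())
                )
            entries = {k: frozenset(v) for k, v in entries_mut.items()}
    finally:
        if close:
            source.close()
    return MarkerDB(entries=entries)


def _as_keys(variants: Iterable[Variant | MarkerKey]) -> set[MarkerKey]:
    keys = set()
    for v in variants:
        if isinstance(v, Variant):
            keys.add((v.position, v.ref, v.alt))
        else:
            pos, ref, alt = v
            keys.add((int(pos), ref.upper(), alt.upper()))
    return keys


def match_haplogroup(
    variants: Sequence[Variant | MarkerKey], marker_db: MarkerDB
) -> list[tuple[str, float]]:
    """Rank haplogroups by marker concordance with a sample's variant set.

    Score = |defining markers present| / |defining markers|, in [0, 1].
    Returns all haplogroups sorted by descending score, ties broken
    lexicographically by name.
    """
    present = _as_keys(variants)
    scored = [
        (name, len(markers & present) / len(markers))
        for name, markers in marker_db.entries.items()
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored
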