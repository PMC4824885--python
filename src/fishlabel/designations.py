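"""Commercial designation table and menu-label normalization.

EU member states publish lists of authorized commercial designations:
each sale name maps to the species that may legally be sold under it,
at species, genus ("umbrella"), or family rank. A sample is mislabelled
when its molecular identification falls outside the admissible set for
the name on the menu.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .taxa import TaxonRecord, TaxonRegistry

PATTERN_TYPES = ("species", "genus", "family")


def _canon(name: str) -> str:
    """Canonical form of a commercial name: case-folded, whitespace
    collapsed."""
    return re.sub(r"\s+", " ", name.strip().casefold())


@dataclass(frozen=True)
class DesignationEntry:
    """One commercial name with its admissible taxon patterns.

    ``patterns`` is a tuple of ``(pattern_type, value)`` pairs where
    pattern_type is ``species`` (exact binomial), ``genus`` or
    ``family``. At least one pattern is required.
    """

    commercial_name: str
    patterns: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"{self.commercial_name!r}: no admissible patterns")
        for ptype, _ in self.patterns:
            if ptype not in PATTERN_TYPES:
                raise ValueError(f"unknown pattern_type {ptype!r}")

    def admits(self, taxon: TaxonRecord) -> bool:
        """True if ``taxon`` may legally be sold under this name."""
        for ptype, value in self.patterns:
            if ptype == "species" and taxon.scientific_name == value:
                return True
            if ptype == "genus" and taxon.genus == value:
                return True
            if ptype == "family" and taxon.family == value:
                return True
        return False

    def admissible_taxa(self, registry: TaxonRegistry) -> set[TaxonRecord]:
        """Expand the patterns against a registry of known taxa."""
        out: set[TaxonRecord] = set()
        for ptype, value in self.patterns:
            if ptype == "species":
                rec = registry.get(value)
                if rec is not None:
                    out.add(rec)
            elif ptype == "genus":
                out |= registry.in_genus(value)
            else:
                out |= registry.in_family(value)
        return out


class DesignationTable:
    """Mapping of canonical commercial names to designation entries.

    Lookups are total: an unknown name returns ``None`` rather than
    raising, so adjudication can apply its unlisted-name policy.
    """

    def __init__(self, entries: Iterable[DesignationEntry] = ()) -> None:
        self._entries: dict[str, DesignationEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: DesignationEntry) -> None:
        key = _canon(entry.commercial_name)
        if key in self._entries:
            raise ValueError(f"duplicate commercial_name: {entry.commercial_name!r}")
        self._entries[key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def lookup(self, name: str) -> DesignationEntry | None:
        """Find the entry for a commercial name, or ``None`` if the name
        is not listed. Tries the canonical form, then a space-free
        variant (so menu spellings like "King Fish" hit "kingfish")."""
        key = _canon(name)
        entry = self._entries.get(key)
        if entry is None:
            entry = self._entries.get(key.replace(" ", ""))
        if entry is None and " " in key:
            # also try matching a listed name ignoring its own spaces
            squashed = key.replace(" ", "")
            for k, e in self._entries.items():
                if k.replace(" ", "") == squashed:
                    return e
        return entry

    def admissible_species(
        self, name: str, registry: TaxonRegistry
    ) -> set[TaxonRecord] | None:
        """Admissible taxa for a commercial name, or ``None`` when the
        name is not listed (explicit not-listed result, not an error)."""
        entry = self.lookup(name)
        if entry is None:
            return None
        return entry.admissible_taxa(registry)


def load_designations(path: str | Path) -> DesignationTable:
    """Read a designation table.

    Format: TSV with header ``commercial_name, pattern_type, patterns``;
    ``patterns`` holds one or more values of the stated type separated by
    ``;`` (e.g. ``bluefin tuna / species / Thunnus thynnus;Thunnus
    orientalis;Thunnus maccoyii``). Duplicate commercial names and
    unknown pattern types are errors.
    """
    table = DesignationTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["commercial_name", "pattern_type", "patterns"]
        if header != expected:
            raise ValueError(f"{path}: expected columns {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            name, ptype, patterns = fields
            if ptype not in PATTERN_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown pattern_type {ptype!r}")
            entry = DesignationEntry(
                commercial_name=_canon(name),
                patterns=tuple((ptype, p.strip()) for p in patterns.split(";") if p.strip()),
            )
            table.add(entry)
    return table


def write_designations(table: DesignationTable, path: str | Path) -> None:
    """Serialize a table in the format :func:`load_designations` reads.

    Each entry must use a single pattern type (true of the packaged and
    generated tables); mixed-type entries cannot be represented in one
    row and raise a ``ValueError``.
    """
    with open(path, "w") as fh:
        fh.write("commercial_name\tpattern_type\tpatterns\n")
        for entry in table:
            types = {ptype for ptype, _ in entry.patterns}
            if len(types) != 1:
                raise ValueError(
                    f"{entry.commercial_name!r}: mixed pattern types not serializable"
                )
            values = ";".join(v for _, v in entry.patterns)
            fh.write(f"{entry.commercial_name}\t{types.pop()}\t{values}\n")


@dataclass(frozen=True)
class NormalizedLabel:
    """Decomposition of a raw menu label.

    ``base_name`` is the commercial name to adjudicate against;
    ``species_claim`` is a more specific listed designation the menu
    explicitly committed to (e.g. "yellowfin tuna"); qualifiers that do
    not resolve to a listed designation (preparation, habitat) are kept
    as ``preparation_tags`` and ignored for adjudication.
    """

    base_name: str
    species_claim: str | None
    preparation_tags: tuple[str, ...]

    @property
    def adjudication_name(self) -> str:
        return self.species_claim if self.species_claim is not None else self.base_name


def normalize_label(label_raw: str, table: DesignationTable) -> NormalizedLabel:
    """Split a printed menu label into base name, optional species
    claim, and preparation tags.

    A parenthetical or trailing qualifier is a species claim iff
    "<qualifier> <base>" or "<qualifier>" alone is a listed designation;
    otherwise it is treated as preparation. For an inline multi-word
    label with no parenthetical, trailing words are stripped one at a
    time until a listed designation is found ("flying fish eggs" ->
    base "flying fish", tag "eggs").
    """
    if not label_raw or not label_raw.strip():
        raise ValueError("label_raw must be non-empty")
    raw = _canon(label_raw)

    qualifiers: list[str] = []
    m = re.search(r"\((.*?)\)", raw)
    base = raw
    if m:
        qualifiers = [q.strip() for q in m.group(1).split(",") if q.strip()]
        base = _canon(re.sub(r"\(.*?\)", " ", raw))

    tags: list[str] = []
    if table.lookup(base) is None and " " in base:
        words = base.split()
        for cut in range(len(words) - 1, 0, -1):
            candidate = " ".join(words[:cut])
            if table.lookup(candidate) is not None:
                tags.extend(words[cut:])
                base = candidate
                break

    entry = table.lookup(base)
    if entry is not None:
        base = entry.commercial_name  # canonical listed spelling

    claim: str | None = None
    for q in qualifiers:
        combined = f"{q} {base}"
        if table.lookup(combined) is not None:
            claim = combined
        elif table.lookup(q) is not None:
            claim = q
        else:
            tags.append(q)
    return NormalizedLabel(base, claim, tuple(tags))
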