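"""Taxonomic records and the conservation-status vocabulary.

A :class:`TaxonRecord` is the unit of identification throughout the
package: reference barcodes point at one, candidate sets contain them,
and verdicts compare sets of them against a designation table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


class IUCNStatus(str, enum.Enum):
    """IUCN Red List categories used for conservation tallies."""

    critically_endangered = "critically_endangered"
    endangered = "endangered"
    vulnerable = "vulnerable"
    near_threatened = "near_threatened"
    least_concern = "least_concern"
    data_deficient = "data_deficient"
    not_assessed = "not_assessed"


@dataclass(frozen=True)
class TaxonRecord:
    """A species with its placement, trade names and Red List status.

    Parameters
    ----------
    scientific_name
        Binomial, ``"Genus species"``. The genus field must equal its
        first token.
    family
        Family name, used by family-rank designation patterns.
    accepted_common_names
        Non-empty tuple of market/common names; the first entry is the
        primary reporting name.
    iucn_status
        Red List category; defaults to ``not_assessed``.
    """

    scientific_name: str
    family: str
    accepted_common_names: tuple[str, ...]
    iucn_status: IUCNStatus = IUCNStatus.not_assessed

    def __post_init__(self) -> None:
        parts = self.scientific_name.split()
        if len(parts) < 2:
            raise ValueError(
                f"scientific_name must be a binomial: {self.scientific_name!r}"
            )
        if not self.accepted_common_names:
            raise ValueError(f"{self.scientific_name}: no accepted common names")

    @property
    def genus(self) -> str:
        return self.scientific_name.split()[0]

    @property
    def common_name(self) -> str:
        """Primary reporting name."""
        return self.accepted_common_names[0]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.scientific_name


class TaxonRegistry:
    """Lookup table of known taxa, keyed by scientific name.

    Genus- and family-rank designation patterns are expanded against
    this registry, so it should contain every taxon a reference library
    or audit fixture mentions.
    """

    def __init__(self, taxa: Iterable[TaxonRecord] = ()) -> None:
        self._by_name: dict[str, TaxonRecord] = {}
        for t in taxa:
            self.add(t)

    def add(self, taxon: TaxonRecord) -> None:
        if taxon.scientific_name in self._by_name:
            raise ValueError(f"duplicate taxon: {taxon.scientific_name}")
        self._by_name[taxon.scientific_name] = taxon

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[TaxonRecord]:
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def get(self, name: str) -> TaxonRecord | None:
        return self._by_name.get(name)

    def __getitem__(self, name: str) -> TaxonRecord:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"taxon not in registry: {name!r}") from None

    def resolve(self, name: str) -> TaxonRecord:
        """Return the record for ``name``, registering a bare-bones one
        (family unknown, status not_assessed) if it is absent.

        Used when parsing user-supplied match lists that may mention
        taxa outside the packaged table; the synthesized record carries
        its binomial as its only common name.
        """
        rec = self._by_name.get(name)
        if rec is None:
            rec = TaxonRecord(name, "incertae-sedis", (name,))
            self._by_name[name] = rec
        return rec

    def in_genus(self, genus: str) -> set[TaxonRecord]:
        return {t for t in self if t.genus == genus}

    def in_family(self, family: str) -> set[TaxonRecord]:
        return {t for t in self if t.family == family}


def load_taxa(path: str | Path) -> TaxonRegistry:
    """Read a taxon table (TSV: scientific_name, family, common_names
    pipe-separated, iucn_status) into a registry."""
    registry = TaxonRegistry()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["scientific_name", "family", "common_names", "iucn_status"]
        if header != expected:
            raise ValueError(f"{path}: expected columns {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            name, family, commons, status = fields
            registry.add(
                TaxonRecord(
                    scientific_name=name,
                    family=family,
                    accepted_common_names=tuple(commons.split("|")),
                    iucn_status=IUCNStatus(status),
                )
            )
    return registry
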