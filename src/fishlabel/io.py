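"""Sequence records, FASTA I/O and sample sheets.

Reference FASTA headers follow the dialect ``id|Genus_species|marker``,
e.g. ``ref001|Thunnus_albacares|coi_full``. Markers are ``coi_full``
(~655 bp barcode), ``coi_mini`` (short internal fragment) or ``cytb``
(fallback gene); queries are only compared against references of a
compatible marker class (COI with COI, cytb with cytb).
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxa import TaxonRecord, TaxonRegistry

IUPAC_NUCLEOTIDES = frozenset("ACGTNRYSWKMBDHV")


class Marker(str, enum.Enum):
    coi_full = "coi_full"
    coi_mini = "coi_mini"
    cytb = "cytb"

    @property
    def gene(self) -> str:
        """Marker class used for comparability (COI vs cytb)."""
        return "cytb" if self is Marker.cytb else "coi"


def clean_sequence(seq: str) -> str:
    """Uppercase, map U->T, and validate against the IUPAC alphabet."""
    s = seq.strip().upper().replace("U", "T")
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - IUPAC_NUCLEOTIDES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class BarcodeRecord:
    """One reference barcode: an identifier, its taxon, marker and
    sequence (uppercase IUPAC nucleotides)."""

    record_id: str
    taxon: TaxonRecord
    marker: Marker
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_sequence(self.sequence))


_HEADER_RE = re.compile(r"^(?P<id>[^|]+)\|(?P<taxon>[^|]+)\|(?P<marker>[^|]+)$")


def read_fasta(path: str | Path, registry: TaxonRegistry | None = None) -> list[BarcodeRecord]:
    """Parse a reference FASTA with ``id|Genus_species|marker`` headers.

    Sequences are uppercased and U is mapped to T. Taxa are resolved
    against ``registry`` (one is created if not given, synthesizing
    records for unknown names). A malformed header raises a
    ``ValueError`` naming the offending entry; an empty file returns an
    empty list with a warning.
    """
    registry = registry if registry is not None else TaxonRegistry()
    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        m = _HEADER_RE.match(entry.description.split()[0])
        if m is None:
            raise ValueError(
                f"{path}: malformed FASTA header {entry.description!r}; "
                "expected 'id|Genus_species|marker'"
            )
        try:
            marker = Marker(m.group("marker"))
        except ValueError:
            raise ValueError(
                f"{path}: unknown marker {m.group('marker')!r} in header "
                f"{entry.description!r}"
            ) from None
        record_id = m.group("id")
        if record_id in seen:
            raise ValueError(f"{path}: duplicate record_id {record_id!r}")
        seen.add(record_id)
        taxon = registry.resolve(m.group("taxon").replace("_", " "))
        records.append(
            BarcodeRecord(record_id, taxon, marker, clean_sequence(str(entry.seq)))
        )
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: list[BarcodeRecord], path: str | Path) -> None:
    """Write records in the same header dialect ``read_fasta`` parses."""
    out = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.record_id}|{r.taxon.scientific_name.replace(' ', '_')}|{r.marker.value}",
            description="",
        )
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


@dataclass
class QuerySample:
    """One purchased sample: its menu label and either a sequence to
    identify or a precomputed ranked match list (fixture mode).

    Exactly one of ``sequence`` / ``match_list`` must be present.
    Oral claims from waiting staff are recorded but, by policy, never
    used in the mislabelling calculation.
    """

    sample_id: str
    city: str
    label_raw: str
    oral_claim: str | None = None
    sequence: str | None = None
    match_list: "object | None" = None  # MatchList; untyped to avoid cycle
    marker: Marker = Marker.coi_full

    def __post_init__(self) -> None:
        if not self.label_raw or not self.label_raw.strip():
            raise ValueError(f"{self.sample_id}: label_raw must be non-empty")
        if (self.sequence is None) == (self.match_list is None):
            raise ValueError(
                f"{self.sample_id}: exactly one of sequence or match_list required"
            )
        if self.sequence is not None:
            self.sequence = clean_sequence(self.sequence)


def load_sample_sheet(path: str | Path) -> list[QuerySample]:
    """Read a delimited sample sheet (TSV, header row) with columns
    sample_id, city, label, optional oral_claim, sequence, marker."""
    samples: list[QuerySample] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("sample_id", "city", "label", "sequence"):
            if col not in idx:
                raise ValueError(f"{path}: missing column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")

            def get(col: str) -> str | None:
                i = idx.get(col)
                if i is None or i >= len(fields):
                    return None
                return fields[i] or None

            samples.append(
                QuerySample(
                    sample_id=fields[idx["sample_id"]],
                    city=fields[idx["city"]],
                    label_raw=fields[idx["label"]],
                    oral_claim=get("oral_claim"),
                    sequence=get("sequence"),
                    marker=Marker(get("marker") or "coi_full"),
                )
            )
    return samples
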