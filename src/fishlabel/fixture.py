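"""Packaged reference audit: 115 sushi samples from six UK cities.

The bundled table transcribes a published restaurant audit: for every
sample it records the city, the menu label, the marker that finally
yielded a sequence, the ranked reference-database matches with percent
identities, the reported common name, Red List status, and the printed
mislabelling verdict. It contains no sequences - samples carry
precomputed match lists - and serves as the ground truth the
adjudication and reporting stages must reproduce end to end.

Known transcription notes: one sample (KU168656) prints a 100%
*Thunnus albacares* match but the reported name "Bigeye tuna"; both
are stored as printed, and the verdict (not mislabelled) is invariant
to the discrepancy under the tuna umbrella designation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .designations import DesignationTable, load_designations
from .identify import MatchHit, MatchList
from .io import Marker, QuerySample
from .taxa import IUCNStatus, TaxonRegistry, load_taxa

_AUDIT_SHA256 = "7335c1b2e1ba9a8d49894dd889b7aab529f321c31baec7254fed956f04eaf831"


def _data_path(name: str) -> Path:
    return Path(resources.files("fishlabel").joinpath("data", name))


def load_default_taxa() -> TaxonRegistry:
    """Registry of the taxa the packaged audit and designation table
    reference, with Red List statuses."""
    return load_taxa(_data_path("taxa.tsv"))


def load_default_designations() -> DesignationTable:
    """Commercial designation table covering the audited sale names
    (umbrella genus terms, species claims, family terms)."""
    return load_designations(_data_path("designations.tsv"))


@dataclass(frozen=True)
class FixtureSample:
    sample: QuerySample
    expected_mislabelled: bool
    expected_accepted_name: str
    expected_iucn_status: IUCNStatus


@dataclass(frozen=True)
class AuditFixture:
    """The packaged audit with its expected outcomes."""

    samples: tuple[FixtureSample, ...]
    registry: TaxonRegistry
    designations: DesignationTable

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def query_samples(self) -> list[QuerySample]:
        return [fs.sample for fs in self.samples]

    @property
    def expected_verdicts(self) -> dict[str, bool]:
        return {fs.sample.sample_id: fs.expected_mislabelled for fs in self.samples}


def _parse_matches(text: str, registry: TaxonRegistry, floor: float = 90.0) -> MatchList:
    hits = []
    for part in text.split(";"):
        name, _, ident = part.rpartition(":")
        hits.append(MatchHit(registry.resolve(name.strip()), float(ident), name.strip()))
    return MatchList(tuple(hits), floor=floor)


def load_paper_fixture() -> AuditFixture:
    """Load the packaged 115-sample audit.

    Verifies the packaged file against a recorded checksum, then parses
    each row into a :class:`QuerySample` carrying a precomputed
    :class:`MatchList` plus the expected verdict, reported name and
    Red List status.
    """
    path = _data_path("uk_sushi_audit.tsv")
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _AUDIT_SHA256:
        raise RuntimeError(
            f"packaged audit table checksum mismatch ({digest}); "
            "the data file appears corrupted"
        )
    registry = load_default_taxa()
    designations = load_default_designations()
    samples: list[FixtureSample] = []
    lines = raw.decode().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    expected_header = [
        "sample_id",
        "city",
        "sold_as",
        "marker",
        "matches",
        "accepted_common_name",
        "iucn_status",
        "expected_mislabelled",
    ]
    if header != expected_header:
        raise RuntimeError("packaged audit table has unexpected columns")
    for line in lines[1:]:
        sid, city, sold_as, marker, matches, accepted, status, mis = line.split("\t")
        qs = QuerySample(
            sample_id=sid,
            city=city,
            label_raw=sold_as,
            match_list=_parse_matches(matches, registry),
            marker=Marker(marker),
        )
        samples.append(
            FixtureSample(
                sample=qs,
                expected_mislabelled={"YES": True, "NO": False}[mis],
                expected_accepted_name=accepted,
                expected_iucn_status=IUCNStatus(status),
            )
        )
    if len(samples) != 115:
        raise RuntimeError(f"expected 115 samples, found {len(samples)}")
    return AuditFixture(tuple(samples), registry, designations)
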