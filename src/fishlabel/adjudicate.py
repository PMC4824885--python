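"""Per-sample mislabelling decisions.

A sample is mislabelled when the set of species in its molecular
candidate tier shares no member with the set of species admissible
under the commercial name on the menu. Umbrella designations (e.g.
"tuna" covering all *Thunnus*) make any member species a legal match;
an explicit species claim on the menu ("Tuna (Yellowfin)") narrows the
admissible set to that claim. Names absent from the official list but
scientifically valid for the identified species (e.g. "black cod" for
*Anoplopoma fimbria*, listed only as "sablefish") are accepted as
misapplied market nomenclature rather than mislabelling, with a
warning. Oral statements by staff are recorded but never change a
verdict.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .designations import DesignationTable, NormalizedLabel, _canon, normalize_label
from .identify import CandidateSet, Resolution
from .io import QuerySample
from .taxa import TaxonRecord, TaxonRegistry


class Rationale(str, enum.Enum):
    match_umbrella = "match_umbrella"
    match_species_claim = "match_species_claim"
    substitution = "substitution"
    label_not_listed = "label_not_listed"
    synonym_accepted = "synonym_accepted"
    unidentifiable = "unidentifiable"


class Flag(str, enum.Enum):
    oral_claim_recorded = "oral_claim_recorded"
    nomenclature_warning = "nomenclature_warning"


@dataclass(frozen=True)
class NomenclaturePolicy:
    """Audit-wide policy knobs.

    ``accept_scientific_synonyms``: a label missing from the official
    list but present among the identified species' accepted common
    names is not mislabelling (default, mirroring the sablefish /
    black-cod reasoning). ``treat_unlisted_label_as_mislabelled``:
    strict mode for labels that resolve to nothing at all.
    """

    accept_scientific_synonyms: bool = True
    treat_unlisted_label_as_mislabelled: bool = False


@dataclass(frozen=True)
class Verdict:
    """The decision for one sample, with the evidence that produced it."""

    sample_id: str
    city: str
    label: NormalizedLabel
    candidate_taxa: frozenset[TaxonRecord]
    resolution: Resolution
    accepted_common_name: str
    admissible_taxa: frozenset[TaxonRecord]
    mislabelled: bool
    rationale: Rationale
    flags: frozenset[Flag] = frozenset()

    @property
    def category(self) -> str:
        """Aggregation key: the normalized base commercial name."""
        return self.label.base_name


# Within a tied multi-species tier the reported name follows market
# convention: the commercially dominant species lends its name to the
# group (a tier of tied Thunnus hits containing T. albacares is
# reported as "Yellowfin tuna"). Only report text depends on this,
# never the verdict boolean.
REPORTING_PRIORITY = (
    "Thunnus albacares",
    "Thunnus alalunga",
    "Thunnus thynnus",
    "Thunnus obesus",
)


def reporting_taxon(candidates: CandidateSet) -> TaxonRecord | None:
    if not candidates.taxa:
        return None
    def key(t: TaxonRecord) -> tuple[int, str]:
        try:
            pri = REPORTING_PRIORITY.index(t.scientific_name)
        except ValueError:
            pri = len(REPORTING_PRIORITY)
        return (pri, t.scientific_name)
    return min(candidates.taxa, key=key)


def accepted_name_of(candidates: CandidateSet) -> str:
    """Reporting common name of a candidate set ("unidentified" when
    empty)."""
    taxon = reporting_taxon(candidates)
    return taxon.common_name if taxon is not None else "unidentified"


def adjudicate(
    sample: QuerySample,
    candidates: CandidateSet,
    table: DesignationTable,
    policy: NomenclaturePolicy = NomenclaturePolicy(),
    registry: TaxonRegistry | None = None,
) -> Verdict:
    """Compare the molecular candidate tier against the admissible set
    for the menu label and return a :class:`Verdict`.

    The admissible set comes from the species claim when the label
    carries one, otherwise from the base commercial name. Unresolvable
    identifications yield an ``unidentifiable`` verdict that reporting
    excludes from rate denominators.
    """
    label = normalize_label(sample.label_raw, table)
    registry = registry if registry is not None else TaxonRegistry(
        t for t in candidates.taxa
    )
    flags: set[Flag] = set()

    if candidates.resolution is Resolution.none:
        verdict = Verdict(
            sample_id=sample.sample_id,
            city=sample.city,
            label=label,
            candidate_taxa=frozenset(),
            resolution=candidates.resolution,
            accepted_common_name="unidentified",
            admissible_taxa=frozenset(),
            mislabelled=False,
            rationale=Rationale.unidentifiable,
            flags=frozenset(flags),
        )
        return handle_oral_claim(sample, verdict)

    entry = table.lookup(label.adjudication_name)
    if entry is not None:
        admissible = frozenset(entry.admissible_taxa(registry))
        overlap = any(entry.admits(t) for t in candidates.taxa)
        mislabelled = not overlap
        if overlap:
            rationale = (
                Rationale.match_species_claim
                if label.species_claim is not None
                else Rationale.match_umbrella
            )
        else:
            rationale = Rationale.substitution
    else:
        admissible = frozenset()
        synonym = policy.accept_scientific_synonyms and any(
            label.adjudication_name in map(_canon, t.accepted_common_names)
            for t in candidates.taxa
        )
        if synonym:
            mislabelled = False
            rationale = Rationale.synonym_accepted
            flags.add(Flag.nomenclature_warning)
        else:
            mislabelled = policy.treat_unlisted_label_as_mislabelled
            rationale = Rationale.label_not_listed
            flags.add(Flag.nomenclature_warning)

    verdict = Verdict(
        sample_id=sample.sample_id,
        city=sample.city,
        label=label,
        candidate_taxa=frozenset(candidates.taxa),
        resolution=candidates.resolution,
        accepted_common_name=accepted_name_of(candidates),
        admissible_taxa=admissible,
        mislabelled=mislabelled,
        rationale=rationale,
        flags=frozenset(flags),
    )
    return handle_oral_claim(sample, verdict)


def handle_oral_claim(sample: QuerySample, verdict: Verdict) -> Verdict:
    """Record an oral claim as a flag; the verdict boolean never
    changes (oral information is excluded from substitution rates)."""
    if sample.oral_claim:
        return replace(
            verdict, flags=verdict.flags | {Flag.oral_claim_recorded}
        )
    return verdict
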