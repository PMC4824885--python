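"""Percent-identity identification against a local reference library.

This replaces remote reference-database queries with an exhaustive
local search: every query is aligned against every marker-compatible
reference record, the best identity per species is kept, species are
ranked by identity above a floor (default 90%), and the top tier of
tied best hits forms the molecular candidate set used for adjudication.

Alignment and the identity statistic
------------------------------------
Pairwise alignment uses affine gap scoring (match +1, mismatch -1, gap
open -5, gap extend -2). Two modes are supported:

``semi_global`` (default)
    The query must align end to end but the reference's ends are free,
    so a ~166 bp mini-barcode nests inside a ~655 bp reference without
    terminal-gap penalty.
``global``
    Terminal gaps on both sequences are penalized; the statistic is
    symmetric under argument swap.

Percent identity is ``100 * identical aligned positions / aligned
columns``, where the column count runs from the first to the last
aligned residue pair (terminal gap columns excluded, internal gap
columns included). ``N`` and other ambiguity codes never count as
identical. Among alignments of equal optimal score, the one maximizing
the match count and then minimizing the column count defines the
statistic, making results reproducible bit for bit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator

from .io import BarcodeRecord, Marker, QuerySample, clean_sequence
from .taxa import TaxonRecord

# --------------------------------------------------------------------------
# alignment kernel

_P = 1 << 21  # field width for (score, matches, columns) key packing
_CMAX = _P - 1
_NEG = np.int64(-(1 << 62))

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGTNRYSWKMBDHV"):
    _ENCODE[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("non-nucleotide characters in sequence")
    return arr


@njit(cache=True)
def _gotoh_key(x, y, match, mismatch, gap_open, gap_extend, semi_global):
    """Best packed (score, matches, columns) key over alignments with at
    least one aligned residue pair. Keys order lexicographically by
    score desc, matches desc, columns asc."""
    n = x.shape[0]
    m = y.shape[0]
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)

    open_delta = np.int64(gap_open) * _P * _P - 1
    ext_delta = np.int64(gap_extend) * _P * _P - 1

    best = _NEG
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # leading terminal region: query prefix always penalized,
            # reference prefix free only in semi-global mode
            lead = np.int64(0)
            gq = i - 1
            if gq > 0:
                lead += gap_open + gap_extend * (gq - 1)
            gr = j - 1
            if gr > 0 and not semi_global:
                lead += gap_open + gap_extend * (gr - 1)
            start = lead * _P * _P + _CMAX  # zero columns encode as CMAX

            prev = start
            if M[i - 1, j - 1] > prev:
                prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
            a = x[i - 1]
            b = y[j - 1]
            if a == b and a < 4:
                M[i, j] = prev + (np.int64(match) * _P + 1) * _P - 1
            else:
                M[i, j] = prev + np.int64(mismatch) * _P * _P - 1

            # internal gaps (gap-gap adjacency disallowed: X extends M/X,
            # Y extends M/Y only)
            vx = M[i - 1, j] + open_delta
            if X[i - 1, j] + ext_delta > vx:
                vx = X[i - 1, j] + ext_delta
            X[i, j] = vx
            vy = M[i, j - 1] + open_delta
            if Y[i, j - 1] + ext_delta > vy:
                vy = Y[i, j - 1] + ext_delta
            Y[i, j] = vy

            # trailing terminal region after ending at aligned pair (i,j)
            trail = np.int64(0)
            gq = n - i
            if gq > 0:
                trail += gap_open + gap_extend * (gq - 1)
            gr = m - j
            if gr > 0 and not semi_global:
                trail += gap_open + gap_extend * (gr - 1)
            cand = M[i, j] + trail * _P * _P
            if cand > best:
                best = cand
    return best


def _decode(key: int) -> tuple[int, int, int]:
    cpart = key % _P
    rest = key // _P
    matches = rest % _P
    score = rest // _P
    return int(score), int(matches), int(_CMAX - cpart)


class AlignmentMode(str, enum.Enum):
    global_ = "global"
    semi_global = "semi_global"


@dataclass(frozen=True)
class AlignmentScoring:
    """Integer alignment scores; gap of length g costs open + (g-1)*extend."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -5
    gap_extend: int = -2


def alignment_stats(
    query_seq: str,
    ref_seq: str,
    mode: str = "semi_global",
    scoring: AlignmentScoring = AlignmentScoring(),
) -> tuple[int, int, int]:
    """(score, matched columns, aligned columns) of the optimal alignment."""
    mode = AlignmentMode(mode)
    x = _encode(clean_sequence(query_seq))
    y = _encode(clean_sequence(ref_seq))
    key = _gotoh_key(
        x,
        y,
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
        mode is AlignmentMode.semi_global,
    )
    return _decode(int(key))


def pairwise_identity(
    query_seq: str,
    ref_seq: str,
    mode: str = "semi_global",
    scoring: AlignmentScoring = AlignmentScoring(),
) -> float:
    """Percent identity of the optimal pairwise alignment, in [0, 100]."""
    q = clean_sequence(query_seq)
    r = clean_sequence(ref_seq)
    mode = AlignmentMode(mode)
    # exact containment shortcut: the optimal alignment is forced
    if q == r or (mode is AlignmentMode.semi_global and q in r):
        if set(q) <= set("ACGT"):
            return 100.0
    score, matches, cols = alignment_stats(q, r, mode.value, scoring)
    if cols == 0:
        return 0.0
    return 100.0 * matches / cols


# --------------------------------------------------------------------------
# match lists and candidate sets


@dataclass(frozen=True)
class MatchHit:
    """Best hit for one species: its identity and the reference record
    that produced it."""

    taxon: TaxonRecord
    identity: float
    record_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity out of range: {self.identity}")


@dataclass(frozen=True)
class MatchList:
    """Ranked per-species hits, identity descending, all >= floor.

    Ties are ordered lexicographically by scientific name so ranking is
    deterministic.
    """

    hits: tuple[MatchHit, ...]
    floor: float = 90.0

    def __post_init__(self) -> None:
        seen = set()
        for a, b in zip(self.hits, self.hits[1:]):
            if a.identity < b.identity:
                raise ValueError("hits must be sorted by identity descending")
        for h in self.hits:
            if h.identity < self.floor:
                raise ValueError(f"hit below floor: {h}")
            if h.taxon.scientific_name in seen:
                raise ValueError(f"duplicate species in MatchList: {h.taxon}")
            seen.add(h.taxon.scientific_name)

    def __len__(self) -> int:
        return len(self.hits)

    @property
    def best_identity(self) -> float | None:
        return self.hits[0].identity if self.hits else None


class Resolution(str, enum.Enum):
    species = "species"
    genus_ambiguous = "genus_ambiguous"
    family_ambiguous = "family_ambiguous"
    none = "none"


@dataclass(frozen=True)
class CandidateSet:
    """The top tier of tied best hits: the molecular identification."""

    taxa: frozenset[TaxonRecord]
    tier_identity: float | None
    resolution: Resolution

    def __post_init__(self) -> None:
        if (self.resolution is Resolution.none) != (len(self.taxa) == 0):
            raise ValueError("resolution none iff empty candidate set")
        if self.resolution is Resolution.species and len(self.taxa) != 1:
            raise ValueError("species resolution requires exactly one taxon")


def top_tier(matches: MatchList, tier_epsilon: float = 0.0) -> CandidateSet:
    """All species within ``tier_epsilon`` of the best identity.

    With the default epsilon of 0 only exact ties at the maximum form
    the candidate set; a 99.85% runner-up behind a 100% hit is excluded.
    """
    if tier_epsilon < 0:
        raise ValueError("tier_epsilon must be >= 0")
    if not matches.hits:
        return CandidateSet(frozenset(), None, Resolution.none)
    best = matches.hits[0].identity
    taxa = frozenset(h.taxon for h in matches.hits if h.identity >= best - tier_epsilon)
    if len(taxa) == 1:
        res = Resolution.species
    elif len({t.genus for t in taxa}) == 1:
        res = Resolution.genus_ambiguous
    else:
        res = Resolution.family_ambiguous
    return CandidateSet(taxa, best, res)


@dataclass(frozen=True)
class SpeciesCall:
    """A species-level call under the congeneric-disambiguation
    criteria: unique top match, margin over the runner-up, and optional
    tree/multi-library concordance."""

    taxon: TaxonRecord | None
    unique_top_match: bool
    margin_over_next: bool
    tree_concordant: bool | None = None
    multi_library_concordant: bool | None = None


def species_level_call(
    matches: MatchList,
    margin_delta: float = 0.3,
    tree_check: bool | None = None,
    concordance: bool | None = None,
) -> SpeciesCall:
    """Assign a species only when the top match is unique, leads the
    runner-up by at least ``margin_delta`` percentage points, and any
    supplied tree/concordance evidence agrees."""
    if not matches.hits:
        return SpeciesCall(None, False, False, tree_check, concordance)
    best = matches.hits[0]
    unique = len(matches.hits) == 1 or matches.hits[1].identity < best.identity
    margin = (
        len(matches.hits) == 1
        or (best.identity - matches.hits[1].identity) >= margin_delta
    )
    ok = unique and margin
    if tree_check is not None:
        ok = ok and tree_check
    if concordance is not None:
        ok = ok and concordance
    return SpeciesCall(best.taxon if ok else None, unique, margin, tree_check, concordance)


# --------------------------------------------------------------------------
# estimator


class BarcodeIdentifier(BaseEstimator):
    """Reference-library barcode classifier.

    Fit on a list of :class:`BarcodeRecord`; predict ranks every query
    against all marker-compatible references by percent identity and
    returns candidate sets of tied best species.

    Parameters
    ----------
    floor : float, default 90.0
        Minimum percent identity for a hit to be reported (inclusive).
    tier_epsilon : float, default 0.0
        Width of the top tier: species within this many percentage
        points of the best identity join the candidate set.
    margin_delta : float, default 0.3
        Lead (percentage points) over the runner-up required for a
        species-level call.
    k : int, default 10
        Maximum number of species reported per query.
    mode : str, default "semi_global"
        Alignment mode; see :func:`pairwise_identity`.
    scoring : AlignmentScoring
        Integer alignment scores.

    Attributes
    ----------
    library_ : list of BarcodeRecord
        The fitted reference records.
    species_ : list of str
        Sorted scientific names present in the library.
    """

    def __init__(
        self,
        floor: float = 90.0,
        tier_epsilon: float = 0.0,
        margin_delta: float = 0.3,
        k: int = 10,
        mode: str = "semi_global",
        scoring: AlignmentScoring = AlignmentScoring(),
    ) -> None:
        self.floor = floor
        self.tier_epsilon = tier_epsilon
        self.margin_delta = margin_delta
        self.k = k
        self.mode = mode
        self.scoring = scoring

    # sklearn-style validation happens in fit
    def fit(self, X: list[BarcodeRecord], y=None) -> "BarcodeIdentifier":
        library = list(X)
        if not library:
            raise ValueError("reference library must be non-empty")
        ids = [r.record_id for r in library]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record_id in reference library")
        self.library_ = library
        self.species_ = sorted({r.taxon.scientific_name for r in library})
        self._cache: dict[tuple[str, str], MatchList] = {}
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "library_"):
            raise RuntimeError("BarcodeIdentifier is not fitted")

    def rank(self, query_seq: str, marker: Marker = Marker.coi_full) -> MatchList:
        """Ranked per-species best identities for one query sequence."""
        self._check_fitted()
        seq = clean_sequence(query_seq)
        key = (seq, Marker(marker).gene)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        best: dict[str, tuple[float, str]] = {}
        for rec in self.library_:
            if rec.marker.gene != Marker(marker).gene:
                continue
            ident = pairwise_identity(seq, rec.sequence, self.mode, self.scoring)
            name = rec.taxon.scientific_name
            if name not in best or ident > best[name][0]:
                best[name] = (ident, rec.record_id)
        taxa = {r.taxon.scientific_name: r.taxon for r in self.library_}
        hits = [
            MatchHit(taxa[name], ident, rid)
            for name, (ident, rid) in best.items()
            if ident >= self.floor
        ]
        hits.sort(key=lambda h: (-h.identity, h.taxon.scientific_name))
        result = MatchList(tuple(hits[: self.k]), floor=self.floor)
        self._cache[key] = result
        return result

    def predict_candidates(self, X) -> list[CandidateSet]:
        """Top-tier candidate set for each query (sequence string or
        QuerySample)."""
        self._check_fitted()
        out = []
        for q in X:
            if isinstance(q, QuerySample):
                if q.match_list is not None:
                    matches = q.match_list
                else:
                    matches = self.rank(q.sequence, q.marker)
            else:
                matches = self.rank(q)
            out.append(top_tier(matches, self.tier_epsilon))
        return out

    def predict(self, X) -> np.ndarray:
        """Species-level call per query; "unidentified" where the
        criteria are not met."""
        self._check_fitted()
        calls = []
        for q in X:
            seq = q.sequence if isinstance(q, QuerySample) else q
            marker = q.marker if isinstance(q, QuerySample) else Marker.coi_full
            call = species_level_call(self.rank(seq, marker), self.margin_delta)
            calls.append(call.taxon.scientific_name if call.taxon else "unidentified")
        return np.asarray(calls, dtype=object)


def rank_matches(
    query: QuerySample | str,
    library: list[BarcodeRecord],
    floor: float = 90.0,
    k: int = 10,
    mode: str = "semi_global",
    scoring: AlignmentScoring = AlignmentScoring(),
) -> MatchList:
    """Functional wrapper over :class:`BarcodeIdentifier.rank`."""
    ident = BarcodeIdentifier(floor=floor, k=k, mode=mode, scoring=scoring).fit(library)
    if isinstance(query, QuerySample):
        return ident.rank(query.sequence, query.marker)
    return ident.rank(query)
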