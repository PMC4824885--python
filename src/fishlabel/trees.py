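"""Distance trees for corroborating identifications.

A neighbor-joining tree over reference barcodes (plus the query) gives
an independent, topology-based check on a percent-identity call: the
query should attach nearest to, and within the subtree spanned by, the
records of the species it was assigned to.
"""

from __future__ import annotations

import io as _io

import dendropy
import numpy as np

from .identify import AlignmentScoring, pairwise_identity
from .io import BarcodeRecord
from .taxa import TaxonRecord

_QUERY_LABEL = "__query__"


def p_distance_matrix(
    records: list[BarcodeRecord],
    extra_seqs: dict[str, str] | None = None,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> tuple[np.ndarray, list[str]]:
    """Symmetric p-distance matrix, d = 1 - identity/100.

    Each pair is aligned semi-globally with the shorter sequence as the
    query, so mini-barcodes nest inside full-length references and the
    matrix stays symmetric. A sequence without any unambiguous base is
    unalignable and raises a ``ValueError``.
    """
    named = [(r.record_id, r.sequence) for r in records]
    if extra_seqs:
        named += list(extra_seqs.items())
    if len(named) < 2:
        raise ValueError("need at least two sequences")
    for name, seq in named:
        if not set(seq) & set("ACGT"):
            raise ValueError(f"{name}: no unambiguous bases; unalignable")
    n = len(named)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = named[i][1], named[j][1]
            if (len(a), named[i][0]) > (len(b), named[j][0]):
                a, b = b, a  # shorter (then lexicographically first id) as query
            ident = pairwise_identity(a, b, "semi_global", scoring)
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    return d, [name for name, _ in named]


def _format_length(x: float) -> str:
    return f"{x:.10g}"


def nj_tree(distance_matrix: np.ndarray, leaf_names: list[str]) -> str:
    """Neighbor-joining tree as an unrooted Newick string.

    Standard Saitou-Nei agglomeration. Determinism: ties in the
    Q-matrix are broken by the smallest (i, j) index pair in the
    current node order. Negative branch lengths are clamped to zero
    with the deficit transferred to the sister edge, preserving the
    pair's summed length.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 leaves")
    if len(leaf_names) != n:
        raise ValueError("leaf_names length must match matrix size")
    if (d < -1e-12).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")

    d = d.copy()
    frags = [_escape(name) for name in leaf_names]
    while d.shape[0] > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) among Q minima
        best = np.inf
        bi = bj = -1
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < best - 1e-12:
                    best = q[i, j]
                    bi, bj = i, j
        li = 0.5 * d[bi, bj] + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = d[bi, bj] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new_frag = f"({frags[bi]}:{_format_length(li)},{frags[bj]}:{_format_length(lj)})"
        du = 0.5 * (d[bi, :] + d[bj, :] - d[bi, bj])
        keep = [k for k in range(m) if k not in (bi, bj)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = du[keep]
        d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        frags = [frags[k] for k in keep] + [new_frag]

    # final three-point formulas
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    lengths = [la, lb, lc]
    for i in range(3):
        if lengths[i] < 0:
            lengths[(i + 1) % 3] += lengths[i]
            lengths[i] = 0.0
    return (
        f"({frags[0]}:{_format_length(lengths[0])},"
        f"{frags[1]}:{_format_length(lengths[1])},"
        f"{frags[2]}:{_format_length(lengths[2])});"
    )


def _escape(name: str) -> str:
    if any(c in name for c in "(),:;"):
        raise ValueError(f"leaf name contains Newick metacharacters: {name!r}")
    return name.replace(" ", "_")


def tree_placement_check(
    query_seq: str,
    candidate: TaxonRecord,
    library: list[BarcodeRecord],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> bool:
    """True iff the query's placement in the NJ tree supports
    ``candidate``.

    The query's nearest leaf by patristic distance must be a record of
    the candidate species; when the candidate has two or more records,
    the query must additionally fall inside the subtree spanned by
    those records (assessed with the tree rooted at the first
    non-candidate reference leaf).
    """
    cand_ids = {
        r.record_id for r in library if r.taxon.scientific_name == candidate.scientific_name
    }
    if not cand_ids:
        raise ValueError(f"candidate {candidate} has no records in the library")
    other_species = {
        r.taxon.scientific_name
        for r in library
        if r.taxon.scientific_name != candidate.scientific_name
    }
    if len(other_species) < 2:
        raise ValueError("library must contain at least two non-candidate species")

    d, names = p_distance_matrix(library, {_QUERY_LABEL: query_seq}, scoring)
    newick = nj_tree(d, names)
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    qt = taxa[_QUERY_LABEL]
    nearest = min(
        (t for t in tree.taxon_namespace if t is not qt),
        key=lambda t: (pdm.patristic_distance(qt, t), t.label),
    )
    if nearest.label not in cand_ids:
        return False
    if len(cand_ids) < 2:
        return True

    outgroup = sorted(
        t.label for t in tree.taxon_namespace if t.label not in cand_ids | {_QUERY_LABEL}
    )[0]
    og_leaf = tree.find_node_with_taxon_label(outgroup)
    tree.reroot_at_edge(og_leaf.edge, update_bipartitions=True)
    mrca = tree.mrca(taxon_labels=sorted(cand_ids))
    clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return _QUERY_LABEL in clade
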