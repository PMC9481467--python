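"""Phylogenetic placement of cluster representatives.

Representatives are threaded onto the reference template alignment
(NAST-style: the query is pairwise-aligned to its nearest reference and
mapped into template coordinates, dropping query-specific insertions), columns
failing a 30% conservation filter are masked, pairwise p-distances are
computed on the remaining columns, and a neighbor-joining tree is built
jointly over the representatives and the selected type strains.

The NJ implementation is the classic Saitou–Nei agglomeration on the
Q-criterion with deterministic tie-breaking and non-negative branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .align import global_align, pairwise_identity
from .seq_io import ReferenceDB, SeqRecord

GAP_CHARS = ("-", ".")


class IncomparablePairError(ValueError):
    """Two rows share no comparable (both ungapped, unmasked) columns."""


@dataclass
class TemplateAlignment:
    """Rows on a shared column system plus a kept/dropped column mask."""

    ids: list[str]
    rows: list[str]
    column_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.column_mask is not None and self.rows:
            if len(self.column_mask) != len(self.rows[0]):
                raise ValueError("mask length != alignment length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class PlacementParams:
    """Knobs of the placement stage.

    min_conservation: modal-residue frequency a column must reach among its
        non-gap characters (the 30% conservation filter).
    min_occupancy: minimum non-gap fraction per column; template-threaded
        queries have ragged ends that otherwise produce gap-rich columns.
    knn_refs: references kept per query (union over queries) for the joint
        tree, nearest first by identity.
    """

    min_conservation: float = 0.30
    min_occupancy: float = 0.50
    knn_refs: int = 10


def align_to_template(
    query: SeqRecord, refdb: ReferenceDB, nearest_accession: str | None = None
) -> str:
    """Thread a query onto the reference template coordinates.

    The query is globally aligned to its nearest reference (by identity,
    ties to the smaller accession) and the pairwise alignment is transferred
    onto the template: query bases pairing with reference bases land in that
    reference's template columns, deletions leave gaps, and query insertions
    relative to the template are dropped.
    """
    if len(refdb) == 0:
        raise ValueError("empty reference database")
    entries = [e for e in refdb if e.aligned_seq]
    if not entries:
        raise ValueError("reference database has no aligned_seq entries")
    if nearest_accession is None:
        scored = sorted(
            ((-pairwise_identity(query.seq, e.seq), e.accession) for e in entries),
        )
        nearest_accession = scored[0][1]
    ref = refdb.by_accession(nearest_accession)
    tmpl_len = len(ref.aligned_seq)
    # ungapped reference position -> template column
    ref_cols = [i for i, c in enumerate(ref.aligned_seq) if c not in GAP_CHARS]
    aa, ar = global_align(query.seq, ref.seq)
    out = ["-"] * tmpl_len
    ri = 0
    for qc, rc in zip(aa, ar):
        if rc != "-":
            if qc != "-":
                out[ref_cols[ri]] = qc
            ri += 1
        # qc consumed against a reference gap: insertion, dropped
    return "".join(out)


def conservation_filter(
    alignment: TemplateAlignment,
    min_conservation: float = 0.30,
    min_occupancy: float = 0.50,
) -> np.ndarray:
    """Column mask: keep columns whose modal residue frequency (among non-gap
    characters) reaches ``min_conservation`` and whose non-gap fraction
    reaches ``min_occupancy``.  All-gap columns are dropped."""
    if len(alignment.rows) < 2:
        raise ValueError("conservation filter needs >= 2 rows")
    mat = np.array([list(r) for r in alignment.rows])
    n_rows, n_cols = mat.shape
    mask = np.zeros(n_cols, dtype=bool)
    nongap = ~np.isin(mat, GAP_CHARS)
    occupancy = nongap.sum(axis=0)
    for j in range(n_cols):
        occ = occupancy[j]
        if occ == 0 or occ / n_rows < min_occupancy:
            continue
        col = mat[nongap[:, j], j]
        _, counts = np.unique(col, return_counts=True)
        if counts.max() / occ >= min_conservation:
            mask[j] = True
    return mask


def p_distance(row_a: str, row_b: str, mask: np.ndarray | None = None) -> float:
    """Uncorrected distance: mismatches / columns non-gap in both rows."""
    a = np.frombuffer(row_a.encode(), dtype="S1")
    b = np.frombuffer(row_b.encode(), dtype="S1")
    if len(a) != len(b):
        raise ValueError("rows have unequal lengths")
    keep = ~(np.isin(a, [b"-", b"."]) | np.isin(b, [b"-", b"."]))
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    n = int(keep.sum())
    if n == 0:
        raise IncomparablePairError("rows overlap on zero comparable columns")
    return float((a[keep] != b[keep]).sum() / n)


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Q-criterion agglomeration; when several pairs minimize Q within 1e-12 the
    lexicographically smallest label pair joins (internal nodes carry the
    smallest leaf label beneath them for comparison).  Negative branch
    lengths are clamped to zero with the deficit moved to the sister branch.
    The returned tree is unrooted (trifurcating root node).
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    d = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=name) for name in labels]
    tags = list(labels)  # smallest leaf label beneath each working node

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if q[i, j] <= qmin + 1e-12:
                    key = tuple(sorted((tags[i], tags[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # distances from the new node to the rest
        dnew = (d[i, :] + d[j, :] - d[i, j]) / 2
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.empty((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = np.maximum(dnew[keep], 0.0)
        d2[-1, -1] = 0.0
        d = d2
        new_tag = min(tags[i], tags[j])
        nodes = [nodes[k] for k in keep] + [parent]
        tags = [tags[k] for k in keep] + [new_tag]

    # resolve the final three branches with the three-point formulas
    order = sorted(range(3), key=lambda k: tags[k])
    a, b, c = order
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = d[a, b] - la
    lc = d[a, c] - la
    la, lb, lc = _clamp_triple(la, lb, lc)
    for node, length in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = length
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _clamp_triple(la: float, lb: float, lc: float) -> tuple[float, float, float]:
    vals = [la, lb, lc]
    for i in range(3):
        if vals[i] < 0:
            deficit = vals[i]
            vals[i] = 0.0
            # spread the deficit over the sisters, largest first
            j = int(np.argmax(vals))
            vals[j] = max(vals[j] + deficit, 0.0)
    return tuple(vals)


def build_distance_matrix(alignment: TemplateAlignment) -> DistanceMatrix:
    """All-pairs p-distances on the masked columns."""
    mask = alignment.column_mask
    n = len(alignment.ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                mat[i, j] = mat[j, i] = p_distance(
                    alignment.rows[i], alignment.rows[j], mask
                )
            except IncomparablePairError as exc:
                raise IncomparablePairError(
                    f"incomparable pair: {alignment.ids[i]} vs {alignment.ids[j]}"
                ) from exc
    return DistanceMatrix(mat, ids=alignment.ids)


def build_joint_tree(
    otu_reps: list[SeqRecord],
    refdb: ReferenceDB,
    params: PlacementParams | None = None,
    identities: dict[str, dict[str, float]] | None = None,
) -> TreeNode:
    """Joint NJ tree over OTU representatives and selected type strains.

    Per query the ``knn_refs`` nearest references (by identity) are kept and
    the union used; each query is threaded onto the template via its nearest
    reference.  Columns are masked by the conservation filter before the
    distance computation.  ``identities`` may supply precomputed
    query -> {accession: identity} maps to avoid re-alignment.
    """
    params = params or PlacementParams()
    entries = [e for e in refdb if e.aligned_seq]
    if not entries:
        raise ValueError("reference database has no aligned_seq entries")

    selected: set[str] = set()
    nearest: dict[str, str] = {}
    for rep in otu_reps:
        if identities is not None and rep.id in identities:
            ranked = sorted(
                ((-v, acc) for acc, v in identities[rep.id].items())
            )
        else:
            ranked = sorted(
                ((-pairwise_identity(rep.seq, e.seq), e.accession) for e in entries)
            )
        take = [acc for _, acc in ranked[: params.knn_refs]]
        selected.update(take)
        nearest[rep.id] = take[0]
    if not otu_reps:
        selected = {e.accession for e in entries}

    ref_entries = [e for e in entries if e.accession in selected]
    ids = [e.accession for e in ref_entries]
    rows = [e.aligned_seq for e in ref_entries]
    for rep in otu_reps:
        ids.append(rep.id)
        rows.append(align_to_template(rep, refdb, nearest_accession=nearest[rep.id]))

    aln = TemplateAlignment(ids=ids, rows=rows)
    aln.column_mask = conservation_filter(
        aln, params.min_conservation, params.min_occupancy
    )
    dm = build_distance_matrix(aln)
    return nj_tree(dm)
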