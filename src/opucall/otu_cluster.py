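"""Dereplication and greedy centroid clustering at the species threshold.

Filtered reads are collapsed to unique sequences with aggregated counts and
clustered greedily, most-abundant first, against existing centroids at 98.7%
identity — the boundary commonly taken to discriminate bacterial species on
full-length 16S rRNA.  The most frequent read of each cluster is its
representative.

``cluster_equivalence_oracle`` recomputes the same greedy semantics with
exhaustive all-pairs alignment and no prefilter; it exists to prove the
production path's prefilter admissible on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import kmer_set, pairwise_identity
from .seq_io import SeqRecord

SPECIES_THRESHOLD = 0.987


@dataclass(frozen=True)
class IdentityParams:
    """Identity threshold and prefilter settings.

    threshold: cluster-membership identity floor (>= comparison).
    kmer_size: word size of the candidate prefilter.  The prefilter may only
        skip a candidate it can prove below threshold; sharing zero k-mers at a
        high threshold is the only such proof used.
    band: optional alignment band width (reserved; full DP is used).
    """

    threshold: float = SPECIES_THRESHOLD
    kmer_size: int = 8
    band: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")


@dataclass
class Otu:
    """A cluster of unique reads with its representative."""

    otu_id: str
    members: list[SeqRecord]
    identities: list[float] = field(default_factory=list)

    @property
    def representative(self) -> SeqRecord:
        return max(self.members, key=lambda r: (r.count, _neg_id(r.id)))

    @property
    def total_count(self) -> int:
        return sum(m.count for m in self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


class _NegStr(str):
    """Inverts string comparison so max() breaks count ties by smallest id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


def _neg_id(s: str) -> _NegStr:
    return _NegStr(s)


def dereplicate(records: list[SeqRecord]) -> list[SeqRecord]:
    """Merge exact-sequence duplicates, summing counts.

    Output is sorted by count descending, then id ascending; the retained id
    of each unique is the lexicographically smallest member id, so the result
    is independent of input order.
    """
    by_seq: dict[str, tuple[str, int]] = {}
    for r in records:
        if r.seq in by_seq:
            prev_id, prev_count = by_seq[r.seq]
            by_seq[r.seq] = (min(prev_id, r.id), prev_count + r.count)
        else:
            by_seq[r.seq] = (r.id, r.count)
    uniques = [
        SeqRecord(id=uid, seq=seq, count=count)
        for seq, (uid, count) in by_seq.items()
    ]
    uniques.sort(key=lambda r: (-r.count, r.id))
    return uniques


def greedy_cluster(
    uniques: list[SeqRecord], params: IdentityParams | None = None
) -> list[Otu]:
    """Greedy centroid clustering of dereplicated uniques.

    Uniques are processed in their (count desc, id asc) order; each is
    assigned to the *first-founded* centroid it matches at >= threshold,
    otherwise it founds a new centroid.  Centroids are therefore pairwise
    below threshold at founding time.
    """
    params = params or IdentityParams()
    t, k = params.threshold, params.kmer_size
    centroids: list[SeqRecord] = []
    centroid_kmers: list[frozenset] = []
    otus: list[Otu] = []
    for u in uniques:
        u_kmers = kmer_set(u.seq, k) if t > 0.9 else None
        assigned = False
        for idx, c in enumerate(centroids):
            if u_kmers is not None and not (u_kmers & centroid_kmers[idx]):
                # zero shared k-mers at a high threshold: provably below it
                continue
            ident = pairwise_identity(u.seq, c.seq)
            if ident >= t:
                otus[idx].members.append(u)
                otus[idx].identities.append(ident)
                assigned = True
                break
        if not assigned:
            centroids.append(u)
            centroid_kmers.append(kmer_set(u.seq, k))
            otus.append(
                Otu(otu_id=f"OTU_{len(otus) + 1:05d}", members=[u], identities=[1.0])
            )
    return otus


def cluster_equivalence_oracle(
    uniques: list[SeqRecord], params: IdentityParams | None = None
) -> list[Otu]:
    """Greedy clustering by exhaustive alignment; verification oracle.

    Same semantics as :func:`greedy_cluster` with every candidate centroid
    aligned (no prefilter, no shortcut).  Limited to 50 uniques.
    """
    if len(uniques) > 50:
        raise ValueError("oracle limited to <= 50 uniques")
    params = params or IdentityParams()
    centroids: list[SeqRecord] = []
    otus: list[Otu] = []
    for u in uniques:
        assigned = False
        for idx, c in enumerate(centroids):
            aa_ident = _full_identity(u.seq, c.seq)
            if aa_ident >= params.threshold:
                otus[idx].members.append(u)
                otus[idx].identities.append(aa_ident)
                assigned = True
                break
        if not assigned:
            centroids.append(u)
            otus.append(
                Otu(otu_id=f"OTU_{len(otus) + 1:05d}", members=[u], identities=[1.0])
            )
    return otus


def _full_identity(a: str, b: str) -> float:
    # identical to pairwise_identity but never short-circuits
    from .align import global_align, identity_from_alignment

    return identity_from_alignment(*global_align(a, b))
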