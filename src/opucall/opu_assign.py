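"""From placed OTUs to OPUs: cultured species, potentially new species, or
potentially new higher taxa.

The decision rule follows the operational-phylogenetic-unit convention for
full-length 16S: a representative at or above 98.7% identity to a type strain
is the corresponding cultured species; an independent lineage placed inside a
clear genus (a clade whose reference leaves are unanimous in genus) below the
species threshold is a potentially new species of that genus; anything deeper
is a potentially new higher taxon, anchored at the deepest rank whose clade
is taxonomically unanimous and whose rank-level identity floor is met.  The
rank floors are the canonical 16S identity minima per rank (94.5 / 86.5 /
82.0 / 78.5 / 75.0 for genus / family / order / class / phylum) and act as an
automated surrogate for manual tree inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

from skbio import TreeNode

from .align import pairwise_identity
from .otu_cluster import Otu, SPECIES_THRESHOLD
from .seq_io import ReferenceDB, SeqRecord

CULTURED_SPECIES = "CULTURED_SPECIES"
NEW_SPECIES = "NEW_SPECIES"
NEW_TAXON = "NEW_TAXON"

CATEGORIES = (CULTURED_SPECIES, NEW_SPECIES, NEW_TAXON)


@dataclass(frozen=True)
class RankThresholds:
    """Identity floors per rank (strictly decreasing with rank height)."""

    genus: float = 0.945
    family: float = 0.865
    order: float = 0.820
    class_: float = 0.785
    phylum: float = 0.750

    def __post_init__(self) -> None:
        seq = (self.genus, self.family, self.order, self.class_, self.phylum)
        if any(a <= b for a, b in zip(seq, seq[1:])):
            raise ValueError("rank floors must strictly decrease with rank height")

    def at(self, rank: str) -> float:
        return getattr(self, "class_" if rank == "class" else rank)


@dataclass(frozen=True)
class Classification:
    category: str
    anchor_rank: str  # species / genus / family / order / class / phylum
    anchor_taxon: str
    nearest_type_strain: str
    nearest_identity: float


@dataclass
class Opu:
    """A merged operational phylogenetic unit."""

    opu_id: str
    member_otu_ids: list[str]
    category: str
    anchor_rank: str
    anchor_taxon: str
    nearest_type_strain: str
    nearest_identity: float
    total_count: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == CULTURED_SPECIES and self.nearest_identity < SPECIES_THRESHOLD:
            raise ValueError("cultured species requires identity >= 0.987")
        if self.category == NEW_SPECIES and self.anchor_rank != "genus":
            raise ValueError("new species must be anchored at genus rank")


def nearest_type_strain(
    rep: SeqRecord,
    refdb: ReferenceDB,
    identities: dict[str, float] | None = None,
) -> tuple[str, float]:
    """Best-matching reference by identity; ties to the smaller accession."""
    if len(refdb) == 0:
        raise ValueError("empty reference database")
    if identities is None:
        identities = reference_identities(rep, refdb)
    best = sorted(((-v, acc) for acc, v in identities.items()))[0]
    return best[1], -best[0]


def reference_identities(rep: SeqRecord, refdb: ReferenceDB) -> dict[str, float]:
    return {e.accession: pairwise_identity(rep.seq, e.seq) for e in refdb}


def _root_for_clades(tree: TreeNode) -> TreeNode:
    """Deterministic rooted copy used for clade membership tests."""
    try:
        return tree.root_at_midpoint()
    except Exception:
        return tree.copy()


def classify_otu(
    rep: SeqRecord,
    placement: TreeNode,
    refdb: ReferenceDB,
    thresholds: RankThresholds | None = None,
    identities: dict[str, float] | None = None,
    rooted: TreeNode | None = None,
) -> Classification:
    """Classify one representative from its identity and tree position.

    Rules, in priority order: (1) identity >= 98.7% to a type strain is that
    cultured species regardless of placement; (2) placement inside a clade
    whose references are unanimous in genus, with identity above the genus
    floor, is a potentially new species of that genus; (3) otherwise the
    deepest unanimous higher rank meeting its identity floor anchors a
    potentially new taxon; (4) failing everything, the phylum of the nearest
    reference anchors an "Unclassified" placeholder.
    """
    thresholds = thresholds or RankThresholds()
    acc, ident = nearest_type_strain(rep, refdb, identities)
    nearest_entry = refdb.by_accession(acc)
    if ident >= SPECIES_THRESHOLD:
        return Classification(
            CULTURED_SPECIES, "species", nearest_entry.species_name, acc, ident
        )

    rooted = rooted if rooted is not None else _root_for_clades(placement)
    accs = {e.accession for e in refdb}
    tip = None
    for t in rooted.tips():
        if t.name == rep.id:
            tip = t
            break
    if tip is None:
        raise ValueError(f"representative {rep.id!r} is not a leaf of the placement")

    # smallest ancestral clade containing at least one reference leaf
    clade_refs: list[str] = []
    node = tip.parent
    while node is not None:
        clade_refs = [t.name for t in node.tips() if t.name in accs]
        if clade_refs:
            break
        node = node.parent
    entries = [refdb.by_accession(a) for a in clade_refs]

    if entries:
        genera = {e.lineage.genus for e in entries}
        if len(genera) == 1 and ident >= thresholds.genus:
            return Classification(NEW_SPECIES, "genus", genera.pop(), acc, ident)
        for rank in ("family", "order", "class", "phylum"):
            names = {e.lineage.at(rank) for e in entries}
            if len(names) == 1 and ident >= thresholds.at(rank):
                return Classification(NEW_TAXON, rank, names.pop(), acc, ident)
    return Classification(
        NEW_TAXON,
        "phylum",
        f"Unclassified {nearest_entry.lineage.phylum}",
        acc,
        ident,
    )


def merge_otus_to_opus(
    classified: list[tuple[Otu, Classification]],
    placement: TreeNode,
    refdb: ReferenceDB,
) -> list[Opu]:
    """Merge classified OTUs into OPUs.

    OTUs merge iff they share category and anchor (and nearest species when
    cultured) and their representative leaves — together with the anchor's
    own reference leaf, when cultured — form a connected subtree of the
    placement: the clade spanned by the candidate leaves contains no leaf
    outside the candidate group.  Distinct lineages inside one genus thus
    stay separate OPUs (their parent strains sit between them), while
    clustering-granularity splits of one species rejoin.  Merging is a
    transitive closure over pairwise tests; OPU ids follow total-count order.
    """
    rooted = _root_for_clades(placement)
    tips = {t.name: t for t in rooted.tips()}

    n = len(classified)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    def group_key(c: Classification):
        key = (c.category, c.anchor_rank, c.anchor_taxon)
        if c.category == CULTURED_SPECIES:
            key += (c.nearest_type_strain,)
        return key

    groups: dict[tuple, list[int]] = {}
    for i, (_, cls) in enumerate(classified):
        groups.setdefault(group_key(cls), []).append(i)

    for key, members in groups.items():
        if len(members) < 2:
            continue
        cls0 = classified[members[0]][1]
        allowed = {
            classified[i][0].representative.id for i in members if
            classified[i][0].representative.id in tips
        }
        if cls0.category == CULTURED_SPECIES and cls0.nearest_type_strain in tips:
            allowed.add(cls0.nearest_type_strain)
        for ai in range(len(members)):
            for aj in range(ai + 1, len(members)):
                i, j = members[ai], members[aj]
                leaves = [
                    tips[name]
                    for name in (
                        classified[i][0].representative.id,
                        classified[j][0].representative.id,
                    )
                    if name in tips
                ]
                if cls0.category == CULTURED_SPECIES:
                    if cls0.nearest_type_strain in tips:
                        leaves.append(tips[cls0.nearest_type_strain])
                if len(leaves) < 2:
                    continue
                lca = rooted.lowest_common_ancestor(leaves)
                if all(t.name in allowed for t in lca.tips()):
                    union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    merged = []
    for members in clusters.values():
        otus = [classified[i][0] for i in members]
        clss = [classified[i][1] for i in members]
        lead = max(
            range(len(otus)),
            key=lambda k: (otus[k].total_count, clss[k].nearest_identity),
        )
        merged.append(
            dict(
                member_otu_ids=sorted(o.otu_id for o in otus),
                category=clss[lead].category,
                anchor_rank=clss[lead].anchor_rank,
                anchor_taxon=clss[lead].anchor_taxon,
                nearest_type_strain=clss[lead].nearest_type_strain,
                nearest_identity=clss[lead].nearest_identity,
                total_count=sum(o.total_count for o in otus),
            )
        )
    merged.sort(key=lambda m: (-m["total_count"], m["member_otu_ids"][0]))
    return [
        Opu(opu_id=f"OPU_{k + 1:04d}", **m) for k, m in enumerate(merged)
    ]


def category_tally(opus: list[Opu]) -> dict:
    """Counts and read shares per category."""
    if not opus:
        raise ValueError("no OPUs to tally")
    counts = {c: 0 for c in CATEGORIES}
    reads = {c: 0 for c in CATEGORIES}
    for o in opus:
        counts[o.category] += 1
        reads[o.category] += o.total_count
    total_reads = sum(reads.values())
    return {
        "cultured": counts[CULTURED_SPECIES],
        "new_species": counts[NEW_SPECIES],
        "new_taxon": counts[NEW_TAXON],
        "unknown_fraction": (counts[NEW_SPECIES] + counts[NEW_TAXON]) / len(opus),
        "read_share": {
            "cultured": reads[CULTURED_SPECIES] / total_reads if total_reads else 0.0,
            "new_species": reads[NEW_SPECIES] / total_reads if total_reads else 0.0,
            "new_taxon": reads[NEW_TAXON] / total_reads if total_reads else 0.0,
        },
    }
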