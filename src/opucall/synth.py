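"""Synthetic data with ground truth: reference databases, communities with
planted cultured / novel-species / novel-lineage taxa, error-bearing CCS-like
reads, chimeras, contaminants, and genomes with planted resistance genes.

The generator is substitution-only along the reference hierarchy, so every
reference sequence shares the template coordinate system (aligned_seq == seq)
and every planted identity is exact by construction: mutating k of L positions
realizes identity (L - k) / L.  Novel identities avoid a margin around the
98.7% species boundary so recovery tests are not threshold-flaky; a boundary
preset exists for tests that want sequences exactly at the threshold.

Reads carry the 27F/1492R primers, random orientation, i.i.d. per-base errors
at the CCS-like rate 1.1e-4 (80% substitutions, 10% insertions, 10%
deletions), two-parent chimeras with uniform breakpoints, and contaminant
taxa shared between every sample and the negative control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .opu_assign import CULTURED_SPECIES, NEW_SPECIES, NEW_TAXON, Opu
from .preprocess import FWD_PRIMER_27F, REV_PRIMER_1492R
from .seq_io import Lineage, RefEntry, ReferenceDB, SeqRecord, revcomp

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    Identity ranges steer planted novelty: novel species sit inside a genus
    below the species boundary; novel lineages sit below genus-level identity
    to every type strain.  Both ranges keep a safety margin around the
    0.987 boundary (the generator rejects ranges intersecting
    [0.982, 0.992]).  ``richness_mean``/``richness_sd`` shape per-sample OPU
    richness (truncated normal, >= 1); ``max_prevalence`` caps taxon
    occupancy so that no core taxon exists under the defaults.
    """

    seed: int = 0
    # reference hierarchy
    n_phyla: int = 2
    families_per_phylum: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 3
    amplicon_len: int = 1450
    # read model
    per_base_error: float = 0.00011
    chimera_rate: float = 0.02
    contaminant_taxa: int = 2
    contaminant_read_fraction: float = 0.04
    novel_species_identity_range: tuple[float, float] = (0.95, 0.975)
    novel_taxon_identity_range: tuple[float, float] = (0.78, 0.92)
    # community
    n_samples: int = 20
    n_cultured: int = 16
    n_new_species: int = 9
    n_new_taxon: int = 5
    richness_mean: float = 49.17
    richness_sd: float = 35.66
    max_prevalence: float = 0.60
    depth_mean: float = 120.0
    depth_sd: float = 60.0
    control_depth: int = 60
    abundance_sigma: float = 1.2

    def __post_init__(self) -> None:
        for lo, hi in (self.novel_species_identity_range, self.novel_taxon_identity_range):
            if not (0 < lo <= hi < 1):
                raise ValueError("identity ranges must lie in (0, 1)")
        if self.per_base_error < 0:
            raise ValueError("error rate must be >= 0")
        margin = (0.982, 0.992)
        lo, hi = self.novel_species_identity_range
        if lo < margin[1] and hi > margin[0]:
            raise ValueError(
                "novel_species_identity_range intersects the species-boundary "
                f"margin {margin}; use boundary_stress() deliberately"
            )

    @classmethod
    def survey_scale(cls, seed: int = 0) -> "SimParams":
        """Cohort shaped to a real ocular-surface survey: 196 samples,
        richness 49.17 +/- 35.66 OPUs per sample, a heavy low-prevalence
        tail, and no taxon above 60% prevalence."""
        return cls(
            seed=seed,
            n_phyla=4,
            families_per_phylum=3,
            genera_per_family=3,
            species_per_genus=6,
            n_samples=196,
            n_cultured=160,
            n_new_species=120,
            n_new_taxon=40,
            depth_mean=6017.0,
            depth_sd=4434.0,
        )

    @classmethod
    def boundary_stress(cls, seed: int = 0) -> "SimParams":
        """Novel species planted exactly at the 98.7% boundary."""
        p = cls(seed=seed)
        object.__setattr__(p, "novel_species_identity_range", (0.987, 0.987))
        return p


@dataclass(frozen=True)
class TaxonTruth:
    name: str
    category: str  # CULTURED_SPECIES / NEW_SPECIES / NEW_TAXON
    nearest_type_strain: str
    target_identity: float
    seq: str
    anchor_truth: str = ""  # species (cultured) / genus (new species) / phylum
    is_contaminant: bool = False


@dataclass
class Community:
    taxa: list[TaxonTruth]
    composition: pd.DataFrame  # taxa x samples relative weights (0 = absent)
    sample_ids: list[str]

    @property
    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": t.name,
                    "true_category": t.category,
                    "nearest_type_strain": t.nearest_type_strain,
                    "target_identity": t.target_identity,
                    "is_contaminant": t.is_contaminant,
                }
                for t in self.taxa
            ]
        ).set_index("name")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate_positions(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    for p in positions:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def mutate_to_identity(
    parent: str, target_identity: float, rng: np.random.Generator | int
) -> str:
    """Derive a sequence at an exact identity to its parent.

    Substitutes round(L * (1 - target)) distinct positions (no indels, no
    back-mutation), so the realized gapless identity is exactly
    round(L * target) / L.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if not (0.5 < target_identity <= 1):
        raise ValueError("target identity must be in (0.5, 1]")
    L = len(parent)
    k = int(round(L * (1 - target_identity)))
    if k == 0:
        return parent
    positions = rng.choice(L, size=k, replace=False)
    return _mutate_positions(parent, positions, rng)


def _hamming_identity(a: str, b: str) -> float:
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((x == y).mean())


# ---------------------------------------------------------------------------
# Reference database

def simulate_reference_db(params: SimParams) -> tuple[ReferenceDB, TreeNode]:
    """Hierarchical type-strain database with its generating tree.

    Sequences evolve by substitution along a rank hierarchy (phylum ->
    family -> genus -> species; one class and order per phylum) with
    divergence budgets chosen so realized within-genus type-strain identities
    fall in [0.945, 0.982] and between-genus identities stay below 0.945.
    The realized identities are audited post-generation and the database is
    resampled (up to 100 attempts) until the constraints hold.
    """
    last_err = None
    for attempt in range(100):
        rng = np.random.default_rng([params.seed, 7, attempt])
        refdb, tree = _build_reference_db(params, rng)
        ok, last_err = _audit_reference_db(refdb)
        if ok:
            return refdb, tree
    raise RuntimeError(
        "could not satisfy reference identity constraints after 100 resamples "
        f"({last_err}); loosen the hierarchy divergences or sequence length"
    )


def _build_reference_db(
    params: SimParams, rng: np.random.Generator
) -> tuple[ReferenceDB, TreeNode]:
    L = params.amplicon_len
    root_seq = _random_seq(L, rng)
    entries: list[RefEntry] = []
    root = TreeNode(name=None)
    acc_counter = 0
    d_phylum, d_family, d_genus = 0.10, 0.035, 0.025
    for p in range(1, params.n_phyla + 1):
        phylum = f"Phylum{p}"
        p_seq = mutate_to_identity(root_seq, 1 - d_phylum, rng)
        p_node = TreeNode(name=None, length=d_phylum)
        root.append(p_node)
        for f in range(1, params.families_per_phylum + 1):
            family = f"Family{p}.{f}"
            f_seq = mutate_to_identity(p_seq, 1 - d_family, rng)
            f_node = TreeNode(name=None, length=d_family)
            p_node.append(f_node)
            for g in range(1, params.genera_per_family + 1):
                genus = f"Genus{p}.{f}.{g}"
                g_seq = mutate_to_identity(f_seq, 1 - d_genus, rng)
                g_node = TreeNode(name=None, length=d_genus)
                f_node.append(g_node)
                # disjoint mutation sets within a genus keep pairwise
                # identities exactly 1 - (d_i + d_j)
                div = rng.uniform(0.009, 0.0185, size=params.species_per_genus)
                counts = [int(round(L * d)) for d in div]
                pool = rng.permutation(L)
                offset = 0
                for s in range(1, params.species_per_genus + 1):
                    acc_counter += 1
                    accession = f"TS{acc_counter:04d}"
                    k = counts[s - 1]
                    positions = pool[offset : offset + k]
                    offset += k
                    seq = _mutate_positions(g_seq, positions, rng)
                    species = f"{genus} sp{s}"
                    entries.append(
                        RefEntry(
                            accession=accession,
                            species_name=species,
                            lineage=Lineage(
                                genus=genus,
                                family=family,
                                order=f"Order{p}",
                                class_=f"Class{p}",
                                phylum=phylum,
                            ),
                            seq=seq,
                            aligned_seq=seq,
                        )
                    )
                    g_node.append(TreeNode(name=accession, length=k / L))
    return ReferenceDB(entries), root


def _audit_reference_db(refdb: ReferenceDB) -> tuple[bool, str | None]:
    entries = list(refdb)
    for i, a in enumerate(entries):
        for b in entries[i + 1 :]:
            ident = _hamming_identity(a.seq, b.seq)
            same_genus = a.lineage.genus == b.lineage.genus
            if same_genus and not (0.945 <= ident <= 0.982):
                return False, f"within-genus identity {ident:.4f} ({a.accession}, {b.accession})"
            if not same_genus and ident >= 0.945:
                return False, f"between-genus identity {ident:.4f} ({a.accession}, {b.accession})"
    return True, None


# ---------------------------------------------------------------------------
# Community

def simulate_community(refdb: ReferenceDB, params: SimParams) -> Community:
    """Plant taxa with known truth categories and sample their occupancy.

    Cultured taxa are type strains verbatim; novel species derive from a
    parent strain at an identity inside ``novel_species_identity_range``
    (re-sampled until the parent stays the nearest strain); novel lineages
    derive from internal ancestors at ``novel_taxon_identity_range`` and are
    audited to sit below genus-level identity (94.5%) to every strain.
    Occupancy targets the per-sample richness distribution and caps every
    taxon at ``max_prevalence``; within-sample abundances are lognormal.
    """
    rng = np.random.default_rng([params.seed, 11])
    entries = list(refdb)
    if params.n_cultured + params.contaminant_taxa > len(entries):
        raise ValueError("not enough type strains for cultured + contaminant taxa")
    order = rng.permutation(len(entries))
    cultured = [entries[i] for i in order[: params.n_cultured]]
    contam = [
        entries[i]
        for i in order[params.n_cultured : params.n_cultured + params.contaminant_taxa]
    ]

    taxa: list[TaxonTruth] = []
    for e in cultured:
        taxa.append(
            TaxonTruth(
                name=f"sim|cultured|{e.accession}",
                category=CULTURED_SPECIES,
                nearest_type_strain=e.accession,
                target_identity=1.0,
                seq=e.seq,
                anchor_truth=e.species_name,
            )
        )

    lo, hi = params.novel_species_identity_range
    parents = [entries[i] for i in rng.choice(len(entries), params.n_new_species, replace=False)]
    for idx, parent in enumerate(parents, 1):
        target = rng.uniform(lo, hi)
        for _ in range(50):
            seq = mutate_to_identity(parent.seq, target, rng)
            others = [
                _hamming_identity(seq, e.seq)
                for e in entries
                if e.accession != parent.accession
            ]
            if max(others) < _hamming_identity(seq, parent.seq):
                break
        taxa.append(
            TaxonTruth(
                name=f"sim|new_species|{idx}",
                category=NEW_SPECIES,
                nearest_type_strain=parent.accession,
                target_identity=round(
                    round(len(parent.seq) * target) / len(parent.seq), 6
                ),
                seq=seq,
                anchor_truth=parent.lineage.genus,
            )
        )

    lo_t, hi_t = params.novel_taxon_identity_range
    # ancestral reconstruction by consensus of a phylum's strains stands in
    # for the (unkept) ancestor sequences
    phyla = sorted({e.lineage.phylum for e in entries})
    for idx in range(1, params.n_new_taxon + 1):
        phylum = phyla[int(rng.integers(len(phyla)))]
        members = [e for e in entries if e.lineage.phylum == phylum]
        anc = _consensus([m.seq for m in members])
        target = rng.uniform(lo_t, hi_t)
        for _ in range(50):
            seq = mutate_to_identity(anc, target, rng)
            idents = {e.accession: _hamming_identity(seq, e.seq) for e in entries}
            if max(idents.values()) < 0.945:
                break
        nearest = min(sorted(idents), key=lambda a: (-idents[a], a))
        taxa.append(
            TaxonTruth(
                name=f"sim|new_taxon|{idx}",
                category=NEW_TAXON,
                nearest_type_strain=nearest,
                target_identity=round(max(idents.values()), 6),
                seq=seq,
                anchor_truth=phylum,
            )
        )

    for e in contam:
        taxa.append(
            TaxonTruth(
                name=f"sim|contaminant|{e.accession}",
                category=CULTURED_SPECIES,
                nearest_type_strain=e.accession,
                target_identity=1.0,
                seq=e.seq,
                anchor_truth=e.species_name,
                is_contaminant=True,
            )
        )

    sample_ids = [f"S{i + 1:03d}" for i in range(params.n_samples)]
    community_taxa = [t for t in taxa if not t.is_contaminant]
    T, n = len(community_taxa), params.n_samples
    # heavy-tailed occupancy weights; a per-taxon quota enforces the
    # prevalence cap by construction while samples draw toward the target
    # richness as long as quota remains
    weights = rng.lognormal(0.0, 1.5, size=T)
    cap = max(int(np.floor(params.max_prevalence * n)), 1)
    quota = np.full(T, cap)
    occupancy = np.zeros((T, n), dtype=bool)
    for j in range(n):
        r = int(np.clip(round(rng.normal(params.richness_mean, params.richness_sd)), 1, T))
        for _ in range(r):
            avail = np.flatnonzero((quota > 0) & ~occupancy[:, j])
            if len(avail) == 0:
                break
            w = weights[avail] / weights[avail].sum()
            pick = int(avail[rng.choice(len(avail), p=w)])
            occupancy[pick, j] = True
            quota[pick] -= 1
        if not occupancy[:, j].any():  # quota exhausted everywhere
            occupancy[int(np.argmin(occupancy.sum(axis=1))), j] = True

    abund = np.where(
        occupancy, rng.lognormal(0.0, params.abundance_sigma, size=occupancy.shape), 0.0
    )
    abund = abund / np.maximum(abund.sum(axis=0), 1e-300)
    composition = pd.DataFrame(
        abund, index=[t.name for t in community_taxa], columns=sample_ids
    )
    return Community(taxa=taxa, composition=composition, sample_ids=sample_ids)


def _consensus(seqs: list[str]) -> str:
    mat = np.array([list(s) for s in seqs])
    out = []
    for j in range(mat.shape[1]):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        out.append(sorted(zip(-counts, vals))[0][1])
    return "".join(out)


# ---------------------------------------------------------------------------
# Reads

def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. per-base errors: 80% substitutions, 10% insertions, 10%
    deletions."""
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = sorted(rng.choice(len(seq), size=n_err, replace=False), reverse=True)
    chars = list(seq)
    for p in positions:
        u = rng.random()
        if u < 0.8:
            choices = [b for b in "ACGT" if b != chars[p]]
            chars[p] = choices[rng.integers(3)]
        elif u < 0.9:
            chars.insert(p, str(rng.choice(BASES)))
        else:
            del chars[p]
    return "".join(chars)


def simulate_reads(
    community: Community, params: SimParams
) -> tuple[dict[str, list[SeqRecord]], pd.DataFrame]:
    """Emit per-sample reads (primers attached, random orientation) and the
    per-read truth table.

    Chimeras combine two taxa present in the same sample at a uniform
    breakpoint; contaminant reads are injected into every biological sample
    and make up the entire negative-control sample ``CTRL``.
    """
    rng = np.random.default_rng([params.seed, 13])
    taxon_seq = {t.name: t.seq for t in community.taxa}
    contaminants = [t for t in community.taxa if t.is_contaminant]
    sigma2 = np.log(1 + (params.depth_sd / params.depth_mean) ** 2)
    mu = np.log(params.depth_mean) - sigma2 / 2

    samples: dict[str, list[SeqRecord]] = {}
    truth_rows = []
    read_counter = 0

    def emit(sample_id: str, insert: str, source: str, is_chimera: bool,
             parents: str, breakpoint: int | None, is_contaminant: bool) -> SeqRecord:
        nonlocal read_counter
        read_counter += 1
        read_id = f"read{read_counter:07d}"
        seq = FWD_PRIMER_27F + _apply_errors(insert, params.per_base_error, rng) \
            + revcomp(REV_PRIMER_1492R)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        truth_rows.append(
            {
                "read_id": read_id,
                "sample_id": sample_id,
                "source_taxon": source,
                "is_chimera": is_chimera,
                "parents": parents,
                "breakpoint": breakpoint if breakpoint is not None else -1,
                "is_contaminant": is_contaminant,
            }
        )
        return SeqRecord(id=read_id, seq=seq)

    for sample_id in community.sample_ids:
        comp = community.composition[sample_id]
        present = comp[comp > 0]
        depth = max(10, int(round(rng.lognormal(mu, np.sqrt(sigma2)))))
        n_contam = int(round(depth * params.contaminant_read_fraction)) if contaminants else 0
        reads: list[SeqRecord] = []
        probs = (present / present.sum()).to_numpy()
        names = list(present.index)
        for _ in range(depth):
            if len(names) >= 2 and rng.random() < params.chimera_rate:
                ia, ib = rng.choice(len(names), size=2, replace=False, p=probs)
                a_seq, b_seq = taxon_seq[names[ia]], taxon_seq[names[ib]]
                L = min(len(a_seq), len(b_seq))
                bp = int(rng.integers(1, L))
                reads.append(
                    emit(
                        sample_id,
                        a_seq[:bp] + b_seq[bp:],
                        names[ia],
                        True,
                        f"{names[ia]};{names[ib]}",
                        bp,
                        False,
                    )
                )
            else:
                t = names[int(rng.choice(len(names), p=probs))]
                reads.append(emit(sample_id, taxon_seq[t], t, False, "", None, False))
        for _ in range(n_contam):
            t = contaminants[int(rng.integers(len(contaminants)))]
            reads.append(emit(sample_id, t.seq, t.name, False, "", None, True))
        samples[sample_id] = reads

    control_reads = []
    if contaminants:
        for _ in range(params.control_depth):
            t = contaminants[int(rng.integers(len(contaminants)))]
            control_reads.append(emit("CTRL", t.seq, t.name, False, "", None, True))
    samples["CTRL"] = control_reads

    truth = pd.DataFrame(truth_rows).set_index("read_id")
    return samples, truth


# ---------------------------------------------------------------------------
# Genomes with planted resistance genes

def simulate_genome(
    gene_db: list[SeqRecord],
    n_genes: int,
    background_len: int,
    mutation_rate: float,
    seed: int,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """One contig of random background with ``n_genes`` genes inserted at
    recorded loci and strands, each mutated by substitution at
    ``mutation_rate``."""
    if not gene_db:
        raise ValueError("empty gene database")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(gene_db), size=n_genes, replace=n_genes > len(gene_db))
    genes = [gene_db[int(i)] for i in picks]
    longest = max(len(g.seq) for g in genes) if genes else 0
    if longest > background_len:
        raise ValueError("gene longer than background")
    background = _random_seq(background_len, rng)
    # non-overlapping slots
    slots = []
    attempt = 0
    while len(slots) < n_genes and attempt < 1000:
        attempt += 1
        g = genes[len(slots)]
        start = int(rng.integers(0, background_len - len(g.seq) + 1))
        if all(start + len(g.seq) <= s or start >= e for s, e, _, _ in slots):
            slots.append((start, start + len(g.seq), g, "+-"[int(rng.integers(2))]))
    if len(slots) < n_genes:
        raise ValueError("could not place genes without overlap")
    slots.sort()
    contig = list(background)
    rows = []
    for start, end, gene, strand in slots:
        seq = gene.seq
        k = int(round(len(seq) * mutation_rate))
        if k:
            seq = _mutate_positions(seq, rng.choice(len(seq), size=k, replace=False), rng)
        if strand == "-":
            seq = revcomp(seq)
        contig[start:end] = list(seq)
        rows.append(
            {
                "gene_id": gene.id,
                "start": start,
                "end": end,
                "strand": strand,
                "n_mutations": k,
            }
        )
    contigs = [SeqRecord(id="contig1", seq="".join(contig))]
    return contigs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recovery evaluation

def evaluate_recovery(
    opus: list[Opu],
    rep_seqs: dict[str, str],
    community: Community,
    refdb: ReferenceDB | None = None,
) -> dict:
    """Match predicted OPUs to truth taxa and score category recovery.

    A truth taxon is recovered by the OPU whose representative is nearest to
    its amplicon at >= 98.7% identity; recovery requires the planted category
    and, for cultured and new-species taxa, the planted anchor.  Contaminant
    taxa are excluded (the pipeline is supposed to remove them).
    """
    from .align import pairwise_identity
    from .otu_cluster import SPECIES_THRESHOLD

    truth = [t for t in community.taxa if not t.is_contaminant]
    confusion: dict[tuple[str, str], int] = {}
    correct = 0
    anchor_correct = 0
    matched = 0
    for t in truth:
        best_opu, best_ident = None, 0.0
        for o in opus:
            rep = rep_seqs[o.opu_id]
            ident = 1.0 if rep == t.seq else (
                _hamming_identity(rep, t.seq) if len(rep) == len(t.seq) else None
            )
            if ident is None:
                ident = pairwise_identity(rep, t.seq)
            if ident > best_ident:
                best_opu, best_ident = o, ident
        if best_opu is None or best_ident < SPECIES_THRESHOLD:
            confusion[(t.category, "MISSED")] = confusion.get((t.category, "MISSED"), 0) + 1
            continue
        matched += 1
        confusion[(t.category, best_opu.category)] = (
            confusion.get((t.category, best_opu.category), 0) + 1
        )
        cat_ok = best_opu.category == t.category
        if cat_ok:
            correct += 1
            anchor_correct += int(_anchor_ok(best_opu, t, refdb))
    n = len(truth)
    return {
        "n_taxa": n,
        "n_matched": matched,
        "n_category_correct": correct,
        "category_accuracy": correct / n if n else 0.0,
        "anchor_accuracy": anchor_correct / n if n else 0.0,
        "opu_count_error": len(opus) - n,
        "confusion": confusion,
    }


def _anchor_ok(opu: Opu, taxon: TaxonTruth, refdb: ReferenceDB | None) -> bool:
    if taxon.category in (CULTURED_SPECIES, NEW_SPECIES):
        return opu.anchor_taxon == taxon.anchor_truth
    # new higher taxon: the anchor (whatever rank it resolved at) must sit
    # inside the source phylum
    anchor = opu.anchor_taxon.removeprefix("Unclassified ")
    if anchor == taxon.anchor_truth:
        return True
    if refdb is None:
        return True
    for e in refdb:
        if anchor in (
            e.lineage.genus,
            e.lineage.family,
            e.lineage.order,
            e.lineage.class_,
            e.lineage.phylum,
        ):
            return e.lineage.phylum == taxon.anchor_truth
    return False
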