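"""Antibiotic resistance gene screening of assembled genomes.

Genes are searched against contigs by local (Smith–Waterman) alignment on
both strands; a hit is reported when nucleotide identity over the aligned
columns reaches the similarity threshold (default 80%) and the aligned gene
span covers at least the coverage threshold (default 70%) of the full gene
length — the ResFinder-style convention.  Summaries report per-strain gene
counts, the fraction of strains carrying at least one gene, and per-genus
means.

The alignment kernel is a numba-compiled affine-gap Smith–Waterman with full
traceback; scoring defaults to +2/-3 match/mismatch and 5 + 2k for a gap of
length k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seq_io import SeqRecord, revcomp


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5  # a gap of length k costs gap_open + gap_extend * k
    gap_extend: int = 2


@dataclass(frozen=True)
class LocalHit:
    score: float
    identity: float
    q_span: tuple[int, int]  # 0-based half-open, query coordinates
    s_span: tuple[int, int]  # subject coordinates on the forward strand
    strand: str


@dataclass(frozen=True)
class ResGeneHit:
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid hit coordinates")
        if not (0 <= self.identity <= 1):
            raise ValueError("identity outside [0, 1]")
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage outside (0, 1]")


_ENCODE = np.full(128, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=False)
def _sw_kernel(q, s, match, mismatch, gap_first, gap_ext):  # pragma: no cover
    m, n = len(q), len(s)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -10**9, dtype=np.int32)  # gap in query (left)
    F = np.full((m + 1, n + 1), -10**9, dtype=np.int32)  # gap in subject (up)
    # packed pointers: bits 0-1 H-source (0 stop, 1 diag, 2 E, 3 F),
    # bit 2 E came from E, bit 3 F came from F
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_first
            e_ext = E[i, j - 1] - gap_ext
            if e_ext > e_open:
                E[i, j] = e_ext
                ptr[i, j] |= 4
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - gap_first
            f_ext = F[i - 1, j] - gap_ext
            if f_ext > f_open:
                F[i, j] = f_ext
                ptr[i, j] |= 8
            else:
                F[i, j] = f_open
            sub = match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) else mismatch
            diag = H[i - 1, j - 1] + sub
            h, src = 0, 0
            if diag > h:
                h, src = diag, 1
            if E[i, j] > h:
                h, src = E[i, j], 2
            if F[i, j] > h:
                h, src = F[i, j], 3
            H[i, j] = h
            ptr[i, j] |= src
            if h > best:
                best, bi, bj = h, i, j
    # traceback
    i, j = bi, bj
    matches = 0
    columns = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        p = ptr[i, j]
        if state == 0:
            src = p & 3
            if src == 0:
                break
            if src == 1:
                columns += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            came_from_e = p & 4
            j -= 1
            state = 1 if came_from_e else 0
        else:
            columns += 1
            came_from_f = p & 8
            i -= 1
            state = 2 if came_from_f else 0
    return best, i, bi, j, bj, matches, columns


def local_align(
    query: str, subject: str, scoring: Scoring | None = None
) -> LocalHit:
    """Best local alignment of a gene against a contig, both strands.

    Returns score, identity over aligned columns, and the spans on the query
    and on the forward strand of the subject.  Ties prefer the + strand.
    """
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    scoring = scoring or Scoring()
    q = _encode(query)
    gap_first = scoring.gap_open + scoring.gap_extend
    best: LocalHit | None = None
    for strand, subj in (("+", subject), ("-", revcomp(subject))):
        s = _encode(subj)
        score, qb, qe, sb, se, matches, columns = _sw_kernel(
            q, s, scoring.match, scoring.mismatch, gap_first, scoring.gap_extend
        )
        if strand == "-":
            sb, se = len(subject) - se, len(subject) - sb
        identity = matches / columns if columns else 0.0
        hit = LocalHit(
            score=float(score),
            identity=identity,
            q_span=(qb, qe),
            s_span=(sb, se),
            strand=strand,
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


def scan_genome(
    contigs: list[SeqRecord],
    gene_db: list[SeqRecord],
    min_identity: float = 0.80,
    min_coverage: float = 0.70,
    scoring: Scoring | None = None,
) -> list[ResGeneHit]:
    """Screen contigs for resistance genes at the identity/coverage gates.

    One best alignment is taken per (gene, contig, strand); passing hits to
    the same gene with loci overlapping >= 50% are deduplicated keeping the
    best score.
    """
    if not gene_db:
        raise ValueError("empty gene database")
    hits: list[ResGeneHit] = []
    for gene in gene_db:
        gene_hits: list[ResGeneHit] = []
        for contig in contigs:
            for strand, subj in (("+", contig.seq), ("-", revcomp(contig.seq))):
                q = _encode(gene.seq)
                s = _encode(subj)
                sc = scoring or Scoring()
                score, qb, qe, sb, se, matches, columns = _sw_kernel(
                    q, s, sc.match, sc.mismatch, sc.gap_open + sc.gap_extend,
                    sc.gap_extend,
                )
                if columns == 0:
                    continue
                if strand == "-":
                    sb, se = len(contig.seq) - se, len(contig.seq) - sb
                identity = matches / columns
                coverage = (qe - qb) / len(gene.seq)
                if identity >= min_identity and coverage >= min_coverage:
                    gene_hits.append(
                        ResGeneHit(
                            gene_id=gene.id,
                            contig_id=contig.id,
                            start=sb,
                            end=se,
                            strand=strand,
                            identity=identity,
                            coverage=coverage,
                            score=float(score),
                        )
                    )
        hits.extend(_dedupe(gene_hits))
    return hits


def _overlap_frac(a: ResGeneHit, b: ResGeneHit) -> float:
    if a.contig_id != b.contig_id:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return inter / min(a.end - a.start, b.end - b.start)


def _dedupe(gene_hits: list[ResGeneHit]) -> list[ResGeneHit]:
    kept: list[ResGeneHit] = []
    for hit in sorted(gene_hits, key=lambda h: (-h.score, h.contig_id, h.start)):
        if all(_overlap_frac(hit, k) < 0.5 for k in kept):
            kept.append(hit)
    return kept


@dataclass
class ResgeneSummary:
    per_strain: dict[str, list[str]]
    strain_gene_counts: dict[str, int]
    fraction_with_hits: float
    percent_with_hits: float  # rounded half-up, 1 decimal
    per_genus_mean: dict[str, float]


def summarize_resistance(
    hits_per_strain: dict[str, list[ResGeneHit]],
    strain_to_genus: dict[str, str],
) -> ResgeneSummary:
    """Per-strain gene lists, carrier fraction, and per-genus means."""
    from .profile_stats import round_half_up

    unmapped = set(hits_per_strain) - set(strain_to_genus)
    if unmapped:
        raise ValueError(f"strains without a genus: {sorted(unmapped)}")
    per_strain = {
        s: sorted({h.gene_id for h in hits}) for s, hits in hits_per_strain.items()
    }
    counts = {s: len(g) for s, g in per_strain.items()}
    n = len(per_strain)
    with_hits = sum(1 for c in counts.values() if c > 0)
    genus_counts: dict[str, list[int]] = {}
    for strain, c in counts.items():
        genus_counts.setdefault(strain_to_genus[strain], []).append(c)
    return ResgeneSummary(
        per_strain=per_strain,
        strain_gene_counts=counts,
        fraction_with_hits=with_hits / n if n else 0.0,
        percent_with_hits=round_half_up(100 * with_hits / n, 1) if n else 0.0,
        per_genus_mean={g: sum(v) / len(v) for g, v in genus_counts.items()},
    )
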