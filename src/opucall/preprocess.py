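"""Read-level QC: primer trimming, length window, chimera and contaminant
removal.

The stack mirrors a full-length 16S CCS workflow: reads carry the 27F/1492R
universal primers, are orientation-ambiguous, must fall in the 1,200–1,600 bp
window after trimming, and may be two-parent PCR chimeras.  Contaminants are
recognized post-clustering by matching cluster representatives against
clusters derived from negative-control samples at the species threshold.

Chimera detection is a deterministic two-parent, single-breakpoint model in
the UCHIME-denovo tradition: candidates are the more abundant unique reads of
the same sample; a read is called chimeric when some two-parent mosaic
explains it markedly better than any single parent does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .align import kmer_set, pairwise_identity, query_match_profile
from .otu_cluster import Otu
from .seq_io import SeqRecord, revcomp

FWD_PRIMER_27F = "AGAGTTTGATCCTGGCTCAG"
REV_PRIMER_1492R = "TACGACTTAACCCCAATCGC"


@dataclass(frozen=True)
class QcParams:
    """QC thresholds.

    min_len/max_len bound the primer-trimmed read length (inclusive).
    chimera_min_div is the minimum divergence both from the best single parent
    and between the two putative parents; chimera_score_min is the two-segment
    model identity a mosaic must reach.  contaminant_identity is the species
    threshold used to match sample clusters to control clusters.
    """

    fwd_primer: str = FWD_PRIMER_27F
    rev_primer: str = REV_PRIMER_1492R
    max_primer_mismatch: int = 2
    min_len: int = 1200
    max_len: int = 1600
    primer_window: int = 30
    chimera_min_div: float = 0.03
    chimera_score_min: float = 0.99
    chimera_min_gain: float = 0.002
    chimera_top_k: int = 4
    chimera_shortlist: int = 8
    contaminant_identity: float = 0.987

    def __post_init__(self) -> None:
        if not (0 < self.min_len < self.max_len):
            raise ValueError("need 0 < min_len < max_len")
        if not self.fwd_primer or not self.rev_primer:
            raise ValueError("primers must be non-empty")


@dataclass
class QcReport:
    """Per-sample outcome bookkeeping; every input read lands in exactly one
    of the five outcome buckets."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    OUTCOMES = ("primer_fail", "length_fail", "chimera", "contaminant", "passed")

    def add(self, sample: str, outcome: str, n: int = 1) -> None:
        if outcome not in self.OUTCOMES:
            raise ValueError(f"unknown outcome {outcome!r}")
        row = self.counts.setdefault(sample, {k: 0 for k in self.OUTCOMES})
        row[outcome] += n

    def input_count(self, sample: str) -> int:
        row = self.counts.get(sample, {})
        return sum(row.values())

    def pass_fraction(self, sample: str | None = None) -> float:
        rows = (
            [self.counts[sample]] if sample is not None else list(self.counts.values())
        )
        total = sum(sum(r.values()) for r in rows)
        passed = sum(r["passed"] for r in rows)
        return passed / total if total else 0.0


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _find_primer(
    seq: str, primer: str, starts: Iterable[int], max_mm: int
) -> int | None:
    """Best-scoring primer start among candidate offsets, or None."""
    p = len(primer)
    best: tuple[int, int] | None = None
    for start in starts:
        if start < 0 or start + p > len(seq):
            continue
        mm = _hamming(seq[start : start + p], primer)
        if mm <= max_mm and (best is None or mm < best[0]):
            best = (mm, start)
    return None if best is None else best[1]


def trim_primers(record: SeqRecord, params: QcParams | None = None) -> SeqRecord | None:
    """Locate both primers, auto-detect orientation, and return the insert.

    The forward primer must start within the first ``primer_window`` bases
    (Hamming distance <= max_primer_mismatch, no indels), and the reverse
    complement of the reverse primer must end within the last
    ``primer_window`` bases.  If the forward orientation fails, the reverse
    complement of the whole read is tried.  Returns None (REJECT) when no
    orientation works.
    """
    params = params or QcParams()
    rev_rc = revcomp(params.rev_primer)
    w = params.primer_window
    for seq in (record.seq, revcomp(record.seq)):
        # forward primer fully within the first w bases
        fwd_at = _find_primer(
            seq,
            params.fwd_primer,
            range(0, w - len(params.fwd_primer) + 1),
            params.max_primer_mismatch,
        )
        if fwd_at is None:
            continue
        # revcomp of the reverse primer fully within the last w bases
        rev_at = _find_primer(
            seq,
            rev_rc,
            range(len(seq) - w, len(seq) - len(rev_rc) + 1),
            params.max_primer_mismatch,
        )
        if rev_at is None:
            continue
        fwd_end = fwd_at + len(params.fwd_primer)
        if rev_at <= fwd_end:
            continue
        return record.with_seq(seq[fwd_end:rev_at])
    return None


def filter_length(
    records: Iterable[SeqRecord], params: QcParams | None = None
) -> tuple[list[SeqRecord], int]:
    """Keep reads with min_len <= length <= max_len (inclusive bounds)."""
    params = params or QcParams()
    kept, rejected = [], 0
    for r in records:
        if params.min_len <= len(r.seq) <= params.max_len:
            kept.append(r)
        else:
            rejected += 1
    return kept, rejected


@dataclass(frozen=True)
class ChimeraVerdict:
    verdict: str  # CHIMERIC or CLEAN
    best_parents: tuple[str, str] | None
    breakpoint: int | None
    model_identity: float
    best_single_identity: float

    @property
    def is_chimeric(self) -> bool:
        return self.verdict == "CHIMERIC"


def detect_chimera(
    query: SeqRecord,
    candidates: Sequence[SeqRecord],
    params: QcParams | None = None,
) -> ChimeraVerdict:
    """Two-parent single-breakpoint chimera test.

    Candidates must be more abundant than the query (abundance-ordered
    reference set, de novo convention).  The top-k candidates by identity are
    paired in both orders; for each pair (A, B) every breakpoint b is scored
    as the fraction of query bases matching A before b and B from b on, using
    per-base match profiles from the two pairwise alignments.  The call is
    CHIMERIC iff the best two-segment identity reaches ``chimera_score_min``,
    exceeds the best single-parent identity by at least ``chimera_min_gain``
    (a read its best single parent already explains gains nothing from a
    mosaic), and the two parents diverge by at least ``chimera_min_div``.

    The reported breakpoint is the midpoint of the optimal-score plateau:
    between two diverged parents the mosaic score is flat between the
    divergent sites flanking the true junction, so only that plateau — not a
    single base — is identifiable.
    """
    params = params or QcParams()
    if len(candidates) < 2:
        raise ValueError("detect_chimera needs at least 2 candidates")

    # shortlist by shared k-mers to bound alignment work, then rank by identity
    qk = kmer_set(query.seq)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-len(qk & kmer_set(candidates[i].seq)), i),
    )[: params.chimera_shortlist]
    idents: list[tuple[float, int]] = []
    profiles: dict[int, np.ndarray] = {}
    for i in order:
        prof = np.array(query_match_profile(query.seq, candidates[i].seq))
        profiles[i] = prof
        idents.append((prof.mean(), i))
    idents.sort(key=lambda t: (-t[0], t[1]))
    best_single = idents[0][0]
    top = [i for _, i in idents[: params.chimera_top_k]]

    L = len(query.seq)
    prefix = {i: np.concatenate([[0], np.cumsum(profiles[i])]) for i in top}
    pair_scores: list[tuple[float, int, int, int]] = []
    for ia in top:
        for ib in top:
            if ia == ib:
                continue
            pref_a, pref_b = prefix[ia], prefix[ib]
            # score(b) = matches to A in [0, b) + matches to B in [b, L)
            scores = (pref_a[1:L] + (pref_b[-1] - pref_b[1:L])) / L
            score = float(scores.max())
            plateau = np.flatnonzero(scores >= score - 1e-12)
            bp = int((plateau[0] + plateau[-1]) // 2) + 1
            pair_scores.append((score, ia, ib, bp))
    pair_scores.sort(key=lambda t: (-t[0], t[1], t[2]))
    best_model, best_pair, best_bp = 0.0, None, None
    if pair_scores:
        score, ia, ib, bp = pair_scores[0]
        best_model = score
        best_pair = (candidates[ia].id, candidates[ib].id)
        best_bp = bp

    verdict = "CLEAN"
    for score, ia, ib, bp in pair_scores:
        if score < params.chimera_score_min:
            break
        if score - best_single < params.chimera_min_gain:
            continue
        div_ok = (
            pairwise_identity(candidates[ia].seq, candidates[ib].seq)
            <= 1 - params.chimera_min_div
        )
        if div_ok:
            verdict = "CHIMERIC"
            best_model = score
            best_pair = (candidates[ia].id, candidates[ib].id)
            best_bp = bp
            break
    return ChimeraVerdict(
        verdict=verdict,
        best_parents=best_pair,
        breakpoint=best_bp,
        model_identity=best_model,
        best_single_identity=float(best_single),
    )


def flag_chimeras(
    uniques: Sequence[SeqRecord], params: QcParams | None = None
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """De novo chimera pass over dereplicated uniques of one sample.

    Each unique is tested against the strictly more abundant uniques seen
    before it; the first two uniques are never testable and are kept.
    Returns (clean, chimeric).
    """
    params = params or QcParams()
    clean: list[SeqRecord] = []
    chimeric: list[SeqRecord] = []
    for i, u in enumerate(uniques):
        cands = [c for c in uniques[:i] if c.count > u.count]
        if len(cands) < 2:
            clean.append(u)
            continue
        if detect_chimera(u, cands, params).is_chimeric:
            chimeric.append(u)
        else:
            clean.append(u)
    return clean, chimeric


def remove_contaminants(
    otus: Sequence[Otu],
    control_otus: Sequence[Otu],
    params: QcParams | None = None,
) -> tuple[list[Otu], list[Otu]]:
    """Drop OTUs whose representative matches any control-cluster
    representative at >= contaminant_identity."""
    params = params or QcParams()
    kept, removed = [], []
    control_reps = [c.representative.seq for c in control_otus]
    for otu in otus:
        rep = otu.representative.seq
        if any(
            pairwise_identity(rep, c) >= params.contaminant_identity
            for c in control_reps
        ):
            removed.append(otu)
        else:
            kept.append(otu)
    return list(kept), list(removed)
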