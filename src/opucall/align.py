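"""Global pairwise alignment and count-based identity.

The identity measure underlying every threshold in the pipeline (the 98.7%
species boundary, rank floors, contaminant matching) is computed on a global
alignment; the columns occupied by terminal gaps are excluded from the
identity denominator, while internal gap columns count as non-matching
columns.  Terminal gaps are penalized during the alignment search like any
other gap: leaving them free makes a short spurious end-overlap the optimum
for divergent pairs, which would report a meaningless identity of 1.
Alignment search scoring is match +1, mismatch -2, gap open -10 (first gap
column), gap extend -1; identity itself is count-based, not score-based.

The dynamic program is scikit-bio's ``pair_align`` (affine-gap Gotoh with free
end gaps); this module owns the scoring convention and the identity semantics
layered on the returned path.
"""

from __future__ import annotations

from skbio.alignment import pair_align

MATCH = 1.0
MISMATCH = -2.0
# skbio charges open + ext*k for a k-column gap; (9, 1) therefore prices the
# first gap column at 10 and each subsequent one at 1.
GAP_OPEN = 9.0
GAP_EXT = 1.0


def global_align(a: str, b: str) -> tuple[str, str]:
    """Global alignment; returns the two gapped rows."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    res = pair_align(
        a,
        b,
        mode="global",
        sub_score=(MATCH, MISMATCH),
        gap_cost=(GAP_OPEN, GAP_EXT),
        free_ends=False,
        max_paths=1,
        atol=0,
    )
    aa, ab = res.paths[0].to_aligned((a, b))
    return aa, ab


def _core_span(aa: str, ab: str) -> tuple[int, int]:
    """Column span once terminal-gap columns of either row are stripped."""
    start = max(
        len(aa) - len(aa.lstrip("-")),
        len(ab) - len(ab.lstrip("-")),
    )
    end = min(len(aa.rstrip("-")), len(ab.rstrip("-")))
    return start, end


def identity_from_alignment(aa: str, ab: str) -> float:
    """matches / aligned columns, excluding terminal-gap columns."""
    start, end = _core_span(aa, ab)
    if end <= start:
        return 0.0
    matches = sum(
        1 for x, y in zip(aa[start:end], ab[start:end]) if x == y and x != "-"
    )
    return matches / (end - start)


def pairwise_identity(a: str, b: str) -> float:
    """Identity of two unaligned sequences in [0, 1].

    Identical inputs short-circuit to 1.0; everything else goes through the
    full alignment.  Arguments are ordered canonically before aligning: when
    several alignments tie on score their identities can differ marginally,
    and the canonical order makes the reported value symmetric.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    if b < a:
        a, b = b, a
    return identity_from_alignment(*global_align(a, b))


def query_match_profile(query: str, parent: str) -> list[int]:
    """Per-query-position match indicator against ``parent``.

    Aligns ``query`` to ``parent`` and marks, for every query base, whether it
    sits in a match column of the alignment.  Used by the chimera model to
    score two-segment mosaics without re-aligning at every breakpoint.
    """
    aa, ab = global_align(query, parent)
    profile = []
    for x, y in zip(aa, ab):
        if x != "-":
            profile.append(1 if x == y else 0)
    return profile


def kmer_set(seq: str, k: int = 8) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))
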