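"""Community profiling over the OPU x sample table.

Relative abundance is reads of an OPU over total reads per sample; prevalence
is the fraction of samples where an OPU is present (>= 1 read after all
filters, configurable floor); prevalence is binned in twenty 5% intervals and
OPUs split into an extremely-low-prevalence group (< 15% of samples) and a
medium group.  A core-microbiota test asks whether any OPU exceeds a 60%
prevalence cutoff.  Alpha diversity uses the Shannon index (natural log) and
the bias-corrected Chao1 estimator; paired left/right-eye comparisons use the
Wilcoxon signed-rank test.  Annotation summaries reproduce origin-category,
human-subsite, and infection-history percentages from a species annotation
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seq_io import SampleManifest

LOW_PREVALENCE_CUTOFF = 0.15
CORE_CUTOFF = 0.60
N_BINS = 20

ORIGIN_CATEGORIES = ("environment", "human", "plant", "animal", "food", "other")
HUMAN_SUBSITES = (
    "oral and upper respiratory tract",
    "blood",
    "intestinal and fecal",
    "infected wounds and abscesses",
    "skin",
    "clinical effusion",
    "eyes",
    "uterus and vagina",
    "other clinical samples",
)


def round_half_up(x: float, digits: int) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# OPU table and prevalence

def build_opu_table(per_sample_counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    """OPU x sample integer count table from per-sample OPU read counts.

    ``per_sample_counts``: sample_id -> {opu_id: reads}.  Duplicate
    contributions to a cell sum; missing cells are 0.
    """
    table = pd.DataFrame(per_sample_counts).fillna(0).astype(int)
    table = table.reindex(sorted(table.index), axis=0)
    table = table.reindex(sorted(table.columns), axis=1)
    return table


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample normalization: OPU reads / total reads; columns sum to 1."""
    totals = table.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return table / totals


@dataclass
class PrevalenceProfile:
    """Per-OPU prevalence with 5% bins and LOW/MEDIUM grouping.

    Bins partition [0, 1] into 20 left-closed intervals [0, 0.05), ...,
    [0.95, 1.0] (the final bin is closed).  LOW means prevalence strictly
    below the cutoff (default 15% of samples).
    """

    per_opu: pd.DataFrame  # index opu, columns: prevalence, bin, group
    per_bin: pd.DataFrame  # index bin, columns: opu_count, read_share
    n_samples: int
    cutoff: float

    @property
    def low_count(self) -> int:
        return int((self.per_opu["group"] == "LOW").sum())

    @property
    def medium_count(self) -> int:
        return int((self.per_opu["group"] == "MEDIUM").sum())

    def group_read_share(self, table: pd.DataFrame) -> dict[str, float]:
        total = table.values.sum()
        low = table.loc[self.per_opu.index[self.per_opu["group"] == "LOW"]].values.sum()
        return {"LOW": low / total, "MEDIUM": 1 - low / total}


def prevalence_bin(prevalence: float) -> int:
    """Index of the 5% interval; the final bin [0.95, 1.0] is closed."""
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence outside [0, 1]")
    return min(int(prevalence / 0.05), N_BINS - 1)


def prevalence_profile(
    table: pd.DataFrame,
    cutoff: float = LOW_PREVALENCE_CUTOFF,
    presence_floor: int = 1,
) -> PrevalenceProfile:
    """Prevalence, bin, and LOW/MEDIUM group per OPU, plus per-bin totals."""
    n = table.shape[1]
    if n < 1:
        raise ValueError("need at least one sample")
    presence = (table >= presence_floor).sum(axis=1)
    prev = presence / n
    bins = prev.map(prevalence_bin)
    group = np.where(prev < cutoff, "LOW", "MEDIUM")
    per_opu = pd.DataFrame(
        {"prevalence": prev, "bin": bins, "group": group}, index=table.index
    )
    reads = table.sum(axis=1)
    total_reads = reads.sum()
    per_bin = pd.DataFrame(
        {
            "opu_count": per_opu.groupby("bin").size(),
            "read_share": reads.groupby(bins).sum() / (total_reads or 1),
        }
    ).reindex(range(N_BINS), fill_value=0)
    per_bin["read_share"] = per_bin["read_share"].astype(float).fillna(0.0)
    return PrevalenceProfile(per_opu=per_opu, per_bin=per_bin, n_samples=n, cutoff=cutoff)


def core_microbiota_test(
    profile: PrevalenceProfile, core_cutoff: float = CORE_CUTOFF
) -> list[str]:
    """OPUs at or above the core prevalence cutoff; empty means no core."""
    sel = profile.per_opu["prevalence"] >= core_cutoff
    return list(profile.per_opu.index[sel])


# ---------------------------------------------------------------------------
# Alpha diversity

def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i over nonzero proportions."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("negative counts")
    if c.sum() == 0:
        raise ValueError("all-zero count vector")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def paired_wilcoxon(left_values, right_values) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped; ties receive average ranks.  The exact
    tie-aware null distribution (dynamic program over sign assignments) is
    used for n <= 25 retained pairs, the normal approximation with tie
    correction and continuity correction above.  Returns
    {statistic, p_value, n_used}; statistic is min(W+, W-).
    """
    left = np.asarray(left_values, dtype=float)
    right = np.asarray(right_values, dtype=float)
    if left.shape != right.shape:
        raise ValueError("paired vectors must have equal length")
    diff = left - right
    diff = diff[diff != 0]
    n = len(diff)
    if n == 0:
        import warnings

        warnings.warn("all paired differences are zero; p = 1.0")
        return {"statistic": 0.0, "p_value": 1.0, "n_used": 0}
    ranks = sps.rankdata(np.abs(diff))
    w_plus = float(ranks[diff > 0].sum())
    w_minus = float(ranks[diff < 0].sum())
    w = min(w_plus, w_minus)
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w)
    else:
        mean = n * (n + 1) / 4
        # tie correction on the variance
        t_adj = 0.0
        _, counts = np.unique(ranks, return_counts=True)
        t_adj = (counts**3 - counts).sum() / 48
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24 - t_adj)
        z = (w - mean + 0.5) / sd  # continuity-corrected, lower tail
        p = min(1.0, 2 * sps.norm.cdf(z))
    return {"statistic": w, "p_value": float(p), "n_used": n}


def _exact_signed_rank_p(ranks: np.ndarray, w: float) -> float:
    """Exact two-sided p via the distribution of W- over all 2^n sign
    assignments, computed by convolution on doubled (integer) ranks."""
    r2 = np.rint(ranks * 2).astype(int)
    total = r2.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: len(dist) - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w * 2))
    p = 2 * dist[: w2 + 1].sum()
    return min(1.0, float(p))


# ---------------------------------------------------------------------------
# Group prevalence and richness

def group_prevalence(
    table: pd.DataFrame,
    manifest: SampleManifest,
    group_field: str = "age_group",
    high_cutoff: float = CORE_CUTOFF,
    presence_floor: int = 1,
) -> dict[str, dict]:
    """Within-group OPU prevalence, per-sample richness, and the
    high-prevalence list (strictly above ``high_cutoff``)."""
    sample_group = {}
    for row in manifest.samples:
        sample_group[row.sample_id] = getattr(row, group_field)
    unknown = [s for s in table.columns if s not in sample_group]
    if unknown:
        raise ValueError(f"samples not mapped to a group: {unknown}")
    out: dict[str, dict] = {}
    for group in sorted(set(sample_group.values())):
        cols = [s for s in table.columns if sample_group[s] == group]
        sub = table[cols]
        presence = sub >= presence_floor
        prev = presence.sum(axis=1) / len(cols)
        richness = presence.sum(axis=0)
        high = prev[prev > high_cutoff]
        out[group] = {
            "n_samples": len(cols),
            "mean_opus": float(richness.mean()),
            "sd_opus": float(richness.std(ddof=1)) if len(cols) > 1 else 0.0,
            "high_prevalence": {
                opu: float(p) for opu, p in high.sort_values(ascending=False).items()
            },
            "prevalence": prev,
        }
    return out


# ---------------------------------------------------------------------------
# Annotation summaries

@dataclass
class AnnotationTable:
    """species -> origin category, human subsite, infection-history flag."""

    rows: pd.DataFrame  # index species; columns origin_category, human_subsite, infection

    def __post_init__(self) -> None:
        bad = set(self.rows["origin_category"]) - set(ORIGIN_CATEGORIES)
        if bad:
            raise ValueError(f"unknown origin categories: {sorted(bad)}")
        nonhuman = self.rows[self.rows["origin_category"] != "human"]
        if (nonhuman["human_subsite"].fillna("") != "").any():
            raise ValueError("human_subsite set on a non-human origin")

    @classmethod
    def from_records(cls, records: dict[str, dict]) -> "AnnotationTable":
        df = pd.DataFrame.from_dict(records, orient="index")
        df = df.reindex(columns=["origin_category", "human_subsite", "infection"])
        df["human_subsite"] = df["human_subsite"].fillna("")
        df["infection"] = df["infection"].fillna(False).astype(bool)
        return cls(df)


def summarize_annotations(
    species_list: list[str], annotation: AnnotationTable, percent_digits: int = 2
) -> dict:
    """Origin-category, human-subsite, and infection-history summary.

    Category percentages use the species-list size as denominator; subsite
    percentages use the human-category count.  Percentages are rounded
    half-up to ``percent_digits`` decimals.
    """
    n = len(species_list)
    ann = annotation.rows
    cat_counts = {c: 0 for c in ORIGIN_CATEGORIES}
    sub_counts = {s: 0 for s in HUMAN_SUBSITES}
    infection = 0
    unannotated = 0
    for sp in species_list:
        if sp not in ann.index:
            unannotated += 1
            continue
        row = ann.loc[sp]
        cat_counts[row["origin_category"]] += 1
        if row["origin_category"] == "human" and row["human_subsite"]:
            sub_counts[row["human_subsite"]] += 1
        if bool(row["infection"]):
            infection += 1
    n_human = cat_counts["human"]
    pct = lambda num, den: round_half_up(100 * num / den, percent_digits) if den else 0.0
    return {
        "n_species": n,
        "unannotated": unannotated,
        "categories": {
            c: {"count": cat_counts[c], "percent": pct(cat_counts[c], n)}
            for c in ORIGIN_CATEGORIES
        },
        "human_subsites": {
            s: {"count": sub_counts[s], "percent": pct(sub_counts[s], n_human)}
            for s in HUMAN_SUBSITES
        },
        "infection": {"count": infection, "percent": pct(infection, n)},
    }
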