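"""End-to-end orchestration: reads -> QC -> OTUs -> placement -> OPUs.

Chimera screening runs per sample on dereplicated uniques (de novo
convention) before pooling; clustering pools all biological samples; control
samples are clustered separately and used to strip contaminant OTUs; the
surviving representatives are placed in a joint NJ tree with the reference
type strains and classified into OPUs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from skbio import TreeNode

from .opu_assign import (
    Classification,
    Opu,
    RankThresholds,
    classify_otu,
    merge_otus_to_opus,
    reference_identities,
    _root_for_clades,
)
from .otu_cluster import IdentityParams, Otu, dereplicate, greedy_cluster
from .phylo_place import PlacementParams, build_joint_tree
from .preprocess import QcParams, QcReport, filter_length, flag_chimeras, \
    remove_contaminants, trim_primers
from .profile_stats import build_opu_table
from .seq_io import ReferenceDB, SeqRecord


@dataclass
class PipelineResult:
    qc_report: QcReport
    otus: list[Otu]
    removed_otus: list[Otu]
    control_otus: list[Otu]
    tree: TreeNode
    classified: list[tuple[Otu, Classification]]
    opus: list[Opu]
    opu_table: pd.DataFrame
    rep_seqs: dict[str, str]  # opu_id -> representative sequence


def run_pipeline(
    samples: dict[str, list[SeqRecord]],
    refdb: ReferenceDB,
    control_samples: tuple[str, ...] = ("CTRL",),
    qc_params: QcParams | None = None,
    id_params: IdentityParams | None = None,
    placement_params: PlacementParams | None = None,
    thresholds: RankThresholds | None = None,
) -> PipelineResult:
    qc_params = qc_params or QcParams()
    id_params = id_params or IdentityParams()
    report = QcReport()

    # per-sample QC and chimera screening on dereplicated uniques
    clean_uniques: dict[str, list[SeqRecord]] = {}
    for sample_id, reads in samples.items():
        passed: list[SeqRecord] = []
        for read in reads:
            trimmed = trim_primers(read, qc_params)
            if trimmed is None:
                report.add(sample_id, "primer_fail")
                continue
            kept, _ = filter_length([trimmed], qc_params)
            if not kept:
                report.add(sample_id, "length_fail")
                continue
            passed.append(kept[0])
        uniques = dereplicate(passed)
        clean, chimeric = flag_chimeras(uniques, qc_params)
        for u in chimeric:
            report.add(sample_id, "chimera", u.count)
        clean_uniques[sample_id] = clean

    # pooled clustering (biological samples); controls clustered separately
    biological = [s for s in samples if s not in control_samples]
    seq_counts: dict[str, dict[str, int]] = {}
    pooled: list[SeqRecord] = []
    for sample_id in biological:
        for u in clean_uniques[sample_id]:
            seq_counts.setdefault(u.seq, {})[sample_id] = (
                seq_counts.get(u.seq, {}).get(sample_id, 0) + u.count
            )
            pooled.append(u)
    uniques = dereplicate(pooled)
    otus = greedy_cluster(uniques, id_params)

    control_pool = [
        u for s in control_samples if s in clean_uniques for u in clean_uniques[s]
    ]
    control_otus = greedy_cluster(dereplicate(control_pool), id_params)
    for s in control_samples:
        for u in clean_uniques.get(s, []):
            report.add(s, "passed", u.count)

    kept_otus, removed_otus = remove_contaminants(otus, control_otus, qc_params)

    def per_sample(otu: Otu) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in otu.members:
            for sample_id, c in seq_counts.get(m.seq, {}).items():
                out[sample_id] = out.get(sample_id, 0) + c
        return out

    for otu in removed_otus:
        for sample_id, c in per_sample(otu).items():
            report.add(sample_id, "contaminant", c)
    for otu in kept_otus:
        for sample_id, c in per_sample(otu).items():
            report.add(sample_id, "passed", c)

    # placement and classification
    reps = [o.representative for o in kept_otus]
    identities = {r.id: reference_identities(r, refdb) for r in reps}
    tree = build_joint_tree(reps, refdb, placement_params, identities=identities)
    rooted = _root_for_clades(tree)
    classified = [
        (
            otu,
            classify_otu(
                otu.representative,
                tree,
                refdb,
                thresholds,
                identities=identities[otu.representative.id],
                rooted=rooted,
            ),
        )
        for otu in kept_otus
    ]
    opus = merge_otus_to_opus(classified, tree, refdb)

    # OPU x sample table
    otu_by_id = {o.otu_id: o for o in kept_otus}
    counts: dict[str, dict[str, int]] = {s: {} for s in biological}
    rep_seqs: dict[str, str] = {}
    for opu in opus:
        members = [otu_by_id[i] for i in opu.member_otu_ids]
        lead = max(members, key=lambda o: o.total_count)
        rep_seqs[opu.opu_id] = lead.representative.seq
        for otu in members:
            for sample_id, c in per_sample(otu).items():
                counts[sample_id][opu.opu_id] = counts[sample_id].get(opu.opu_id, 0) + c
    table = build_opu_table(counts)

    return PipelineResult(
        qc_report=report,
        otus=kept_otus,
        removed_otus=removed_otus,
        control_otus=control_otus,
        tree=tree,
        classified=classified,
        opus=opus,
        opu_table=table,
        rep_seqs=rep_seqs,
    )
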