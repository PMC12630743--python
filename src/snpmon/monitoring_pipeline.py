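"""End-to-end monitoring season: QC -> species -> sex -> individuals -> kinship.

The stage order follows the annual workflow: negative-control check and
duplicate consensus first, pass/fail per sample, species assignment of the
passing genotypes against pooled reference groups, genetic sexing,
allele-match clustering into unique individuals, and parentage among the
recovered individuals.  Suspicious samples are flagged for analyst scrutiny
— single-occurrence individuals, samples near the pass threshold, sex
conflicts, urine samples — and never silently discarded: contamination is a
judgement call that belongs to a human.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    CAT_X_SEX,
    CAT_Y_SEX,
    CHROM_AUTOSOME,
    MISSING,
    GenotypeTable,
    MarkerInfo,
    SampleRecord,
    call_alleles,
    write_report,
)
from .individual_match import MatchConfig, cluster_individuals, consensus_table
from .parentage import ParentageConfig, assign_parents, assignments_frame
from .panel_design import minor_allele_frequency
from .replicate_qc import QCConfig, run_qc
from .sex_caller import SexConfig, sex_table
from .species_assign import ReferenceSet, assign, build_reference_set

log = logging.getLogger("snpmon.pipeline")


@dataclass
class PipelineConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    sex: SexConfig = field(default_factory=SexConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    parentage: ParentageConfig = field(default_factory=ParentageConfig)
    wolf_group: str = "wolf_dog"  # reference group containing the target species
    near_threshold_margin: float = 0.05
    seed: int = 0


@dataclass
class MonitoringResult:
    reports: dict[str, pd.DataFrame]
    qc_report: object
    cluster_result: object

    def write(self, out_dir: str | Path) -> list[Path]:
        return write_report(self.reports, out_dir)


def reference_allele_freqs(
    refset: ReferenceSet, group: str
) -> dict[str, dict[str, float]]:
    """Smoothed per-marker allele frequencies of one reference group."""
    out = {}
    for mid in refset.marker_ids:
        c, t = refset.counts[group][mid]
        p = (c + 0.5) / (t + 1.0)
        counted = refset.counted_allele[mid]
        # the registered pair is (other, counted) lexicographically
        labels = sorted(
            {a for call in refset.table.marker_calls(mid) if call != MISSING
             for a in call_alleles(call)}
        )
        other = next((x for x in labels if x != counted), counted)
        out[mid] = {counted: p, other: 1.0 - p}
    return out


def female_x_frequencies(
    reference_table: GenotypeTable,
    markers: Sequence[MarkerInfo],
    sex_of: Mapping[str, str],
) -> dict[str, float]:
    """Expected-heterozygosity inputs for sexing: female MAF per X marker."""
    x_ids = [m.marker_id for m in markers if m.category == CAT_X_SEX]
    females = [s for s in reference_table.sample_ids if sex_of.get(s) == "FEMALE"]
    sub = reference_table.subset(sample_ids=females, marker_ids=x_ids)
    return {
        mid: float(minor_allele_frequency(sub.marker_calls(mid)))
        for mid in x_ids
    }


def run_monitoring(
    genotypes: GenotypeTable,
    samples: Sequence[SampleRecord],
    markers: Sequence[MarkerInfo],
    refset: ReferenceSet,
    x_freqs: Mapping[str, float],
    config: PipelineConfig | None = None,
) -> MonitoringResult:
    """Run every stage in order and assemble the season's report bundle.

    Reports: ``pass_table`` (per physical sample: call rate, pass flag),
    ``pass_by_material``, ``assignments`` (posterior per group, best group,
    confirmatory-panel flag for the wolf/dog group), ``sex_calls``,
    ``clusters`` (sample -> individual), ``parentage``, ``scrutiny`` and
    ``replicate_mismatches``.  Every threshold applied is logged.
    """
    cfg = config or PipelineConfig()
    by_cat = {m.marker_id: m.category for m in markers if m.marker_id in
              set(genotypes.marker_ids)}
    x_ids = [m for m, c in by_cat.items() if c == CAT_X_SEX]
    y_ids = [m for m, c in by_cat.items() if c == CAT_Y_SEX]
    y_id = y_ids[0] if y_ids else None
    autosomal = [m.marker_id for m in markers
                 if m.chrom_class == CHROM_AUTOSOME
                 and m.marker_id in set(genotypes.marker_ids)]

    # --- QC: NTC check, consensus, pass filter -----------------------------
    log.info("QC: pass call-rate %.2f, NTC max calls %d",
             cfg.qc.sample_pass_callrate, cfg.qc.ntc_max_calls)
    qc = run_qc(genotypes, samples, cfg.qc, markers)
    consensus = qc.consensus
    assert consensus is not None
    material_of = {}
    for r in samples:
        material_of.setdefault(r.replicate_group, r.material)
        material_of[r.sample_id] = r.material
    pass_table = pd.DataFrame(
        {
            "sample": qc.sample_call_rate.index,
            "material": [material_of.get(s, "unknown")
                         for s in qc.sample_call_rate.index],
            "call_rate": qc.sample_call_rate.values,
            "passed": qc.sample_pass.reindex(qc.sample_call_rate.index).values,
        }
    )
    passing = [s for s in consensus.sample_ids if bool(qc.sample_pass.get(s))]
    passing_table = consensus.subset(sample_ids=passing)

    # --- species assignment -------------------------------------------------
    assignments = pd.DataFrame(
        columns=["sample", *refset.groups, "best_group", "confirmatory_panel"]
    )
    wolf_samples: list[str] = []
    if passing:
        res = assign(passing_table.subset(marker_ids=[m for m in autosomal
                                                      if m in set(refset.marker_ids)]),
                     refset)
        assignments = res.posteriors.copy()
        assignments.insert(0, "sample", assignments.index)
        assignments["best_group"] = res.best_group
        # wolves, dogs and putative hybrids all go to the confirmatory panel
        assignments["confirmatory_panel"] = res.best_group == cfg.wolf_group
        assignments = assignments.reset_index(drop=True)
        wolf_samples = [
            s for s, g in res.best_group.items() if g == cfg.wolf_group
        ]

    # --- sexing -------------------------------------------------------------
    sex_calls = sex_table(passing_table, x_ids, y_id, dict(x_freqs), cfg.sex)

    # --- individual identification ------------------------------------------
    wolf_table = passing_table.subset(sample_ids=wolf_samples)
    cluster_res = cluster_individuals(wolf_table, cfg.match)
    log.info("matching: min_overlap %d, threshold %d%s",
             cfg.match.min_overlap, cluster_res.threshold_used,
             " (fallback)" if cluster_res.threshold_was_fallback else "")
    clusters = pd.DataFrame(
        [{"sample": s, "individual_id": i}
         for s, i in cluster_res.assignment.items()],
        columns=["sample", "individual_id"],
    )

    # --- parentage among recovered individuals ------------------------------
    ind_table = consensus_table(cluster_res, autosomal)
    sex_by_sample = dict(zip(sex_calls["sample_id"], sex_calls["call"]))
    sex_of_ind: dict[str, str] = {}
    for c in cluster_res.clusters:
        calls = {sex_by_sample.get(s) for s in c.member_sample_ids}
        calls.discard(None)
        calls.discard("UNCERTAIN")
        sex_of_ind[c.individual_id] = calls.pop() if len(calls) == 1 else "UNKNOWN"
    freqs = reference_allele_freqs(refset, cfg.wolf_group)
    par = assign_parents(ind_table, ind_table, sex_of_ind, freqs, cfg.parentage)
    parentage = assignments_frame(par)

    # --- scrutiny flags ------------------------------------------------------
    scrutiny_rows = []
    counts = clusters["individual_id"].value_counts() if len(clusters) else {}
    for c in cluster_res.clusters:
        if len(c.member_sample_ids) == 1:
            scrutiny_rows.append(
                {"sample": c.member_sample_ids[0],
                 "reason": "single-occurrence individual"}
            )
    for row in pass_table.itertuples(index=False):
        thr = cfg.qc.threshold_for(row.material)
        if row.passed and row.call_rate < thr + cfg.near_threshold_margin:
            scrutiny_rows.append(
                {"sample": row.sample, "reason": "near pass threshold"}
            )
    for row in sex_calls.itertuples(index=False):
        if row.conflict_flag:
            scrutiny_rows.append(
                {"sample": row.sample_id, "reason": "sex conflict"}
            )
    for s in passing:
        if material_of.get(s) == "urine":
            scrutiny_rows.append(
                {"sample": s, "reason": "urine sample (contamination risk)"}
            )
    for s in qc.ntc_flags:
        scrutiny_rows.append({"sample": s, "reason": "NTC up"})
    scrutiny = pd.DataFrame(scrutiny_rows, columns=["sample", "reason"])
    scrutiny = scrutiny.sort_values(["sample", "reason"]).reset_index(drop=True)

    reports = {
        "pass_table": pass_table,
        "pass_by_material": qc.pass_by_material,
        "assignments": assignments,
        "sex_calls": sex_calls,
        "clusters": clusters,
        "parentage": parentage,
        "scrutiny": scrutiny,
        "replicate_mismatches": qc.group_mismatches.rename_axis("group")
        .reset_index(name="n_mismatches"),
    }
    return MonitoringResult(reports=reports, qc_report=qc, cluster_result=cluster_res)
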