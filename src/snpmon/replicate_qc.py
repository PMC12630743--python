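"""Replicate QC: amplification success, duplicate consensus, pass thresholds,
and error rates against known reference genotypes.

Scat samples are genotyped in duplicate because faecal DNA is degraded;
replicates of one physical sample share a ``replicate_group`` and are merged
into a consensus genotype where any disagreement is recoded as missing.
Error rates against an independent reference (e.g. an array genotype of the
same animal) count an allelic mismatch when one call is heterozygous and the
other homozygous, or when the two calls are opposite homozygotes — one
mismatch per locus.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    CAT_Y_SEX,
    MISSING,
    GenotypeTable,
    MarkerInfo,
    SampleRecord,
)


@dataclass
class QCConfig:
    """Pass thresholds for monitoring samples.

    ``sample_pass_callrate`` is the default minimum fraction of panel
    markers that must yield a call; per-material overrides allow stricter
    rules for high-quality tissue.  ``ntc_max_calls`` is how many markers a
    no-template control may amplify before the run is flagged.
    """

    sample_pass_callrate: float = 0.80
    per_material_callrate: dict[str, float] = field(default_factory=dict)
    ntc_max_calls: int = 0
    consensus_before_pass: bool = True

    def __post_init__(self) -> None:
        vals = [self.sample_pass_callrate, *self.per_material_callrate.values()]
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError("call-rate thresholds must lie in [0, 1]")

    def threshold_for(self, material: str) -> float:
        return self.per_material_callrate.get(material, self.sample_pass_callrate)


@dataclass
class QCReport:
    sample_call_rate: pd.Series
    marker_call_rate: pd.Series
    sample_pass: pd.Series
    pass_by_material: pd.DataFrame
    overall_pass_pct: int
    group_mismatches: pd.Series
    consensus: GenotypeTable | None = None
    ntc_flags: list[str] = field(default_factory=list)


def amplification_success(
    table: GenotypeTable,
    samples: Sequence[SampleRecord] | None = None,
    markers: Sequence[MarkerInfo] | None = None,
    sex_calls: Mapping[str, str] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Per-sample and per-marker call-rate fractions.

    When marker metadata and sex calls are supplied, the Y marker is removed
    from female denominators: a female's empty Y assay is biology, not a
    failed reaction.
    """
    if table.n_samples == 0 or table.n_markers == 0:
        raise ValueError("amplification success undefined for an empty table")
    called = table.calls != MISSING
    y_cols = (
        [j for j, m in enumerate(table.marker_ids)
         if any(mk.marker_id == m and mk.category == CAT_Y_SEX for mk in markers)]
        if markers else []
    )
    per_sample = {}
    for i, sid in enumerate(table.sample_ids):
        cols = np.ones(table.n_markers, dtype=bool)
        if y_cols and sex_calls and sex_calls.get(sid) == "FEMALE":
            cols[y_cols] = False
        per_sample[sid] = float(called[i, cols].mean())
    per_marker = pd.Series(
        called.mean(axis=0), index=table.marker_ids, name="call_rate"
    )
    return pd.Series(per_sample, name="call_rate"), per_marker


def duplicate_consensus(
    table: GenotypeTable, samples: Sequence[SampleRecord]
) -> tuple[GenotypeTable, pd.Series]:
    """Merge replicate groups into consensus genotypes.

    Per locus within a group: if every non-missing replicate agrees the call
    is kept; any disagreement is recoded as MISSING and counted as one
    mismatch; all-missing stays missing.  Groups of size one pass through.
    Consensus rows are named by replicate group, ordered by first appearance.
    """
    group_of = {r.sample_id: r.replicate_group for r in samples}
    groups: dict[str, list[int]] = defaultdict(list)
    order: list[str] = []
    for i, sid in enumerate(table.sample_ids):
        g = group_of.get(sid, sid)
        if g not in groups:
            order.append(g)
        groups[g].append(i)

    calls = np.full((len(order), table.n_markers), MISSING, dtype=object)
    mismatches = {}
    for gi, g in enumerate(order):
        rows = groups[g]
        n_mm = 0
        for j in range(table.n_markers):
            seen = {table.calls[i, j] for i in rows} - {MISSING}
            if len(seen) == 1:
                calls[gi, j] = seen.pop()
            elif len(seen) > 1:
                n_mm += 1  # disagreement -> missing
        mismatches[g] = n_mm
    consensus = GenotypeTable(order, list(table.marker_ids), calls)
    return consensus, pd.Series(mismatches, name="mismatches")


def pass_filter(
    call_rates: pd.Series,
    samples: Sequence[SampleRecord],
    config: QCConfig | None = None,
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Pass/fail per sample plus a per-material summary.

    ``call_rates`` may be indexed by sample id or by replicate group
    (consensus mode).  Returns the boolean series, a material summary with
    ``n_pass``/``n_total``/``pct``, and the overall percentage rounded to
    the nearest integer.
    """
    cfg = config or QCConfig()
    material_of: dict[str, str] = {}
    for r in samples:
        if r.is_control:
            continue
        material_of[r.sample_id] = r.material
        material_of.setdefault(r.replicate_group, r.material)

    passes = {}
    mat_counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for key, rate in call_rates.items():
        mat = material_of.get(str(key), "unknown")
        ok = bool(rate >= cfg.threshold_for(mat))
        passes[key] = ok
        mat_counts[mat][0] += int(ok)
        mat_counts[mat][1] += 1

    rows = [
        {"material": m, "n_pass": c[0], "n_total": c[1],
         "pct": round(100 * c[0] / c[1]) if c[1] else 0}
        for m, c in sorted(mat_counts.items())
    ]
    summary = pd.DataFrame(rows, columns=["material", "n_pass", "n_total", "pct"])
    total = int(summary["n_total"].sum())
    overall = round(100 * int(summary["n_pass"].sum()) / total) if total else 0
    return pd.Series(passes, name="pass"), summary, overall


def overall_pass_pct(counts: Sequence[tuple[int, int]]) -> int:
    """Overall pass percentage from per-material (n_pass, n_total) counts."""
    n_pass = sum(p for p, _ in counts)
    n_total = sum(t for _, t in counts)
    if n_total == 0:
        return 0
    return round(100 * n_pass / n_total)


def check_negative_controls(
    table: GenotypeTable,
    samples: Sequence[SampleRecord],
    config: QCConfig | None = None,
) -> list[str]:
    """Flag negative controls with more amplified markers than allowed ("NTC up")."""
    cfg = config or QCConfig()
    flags = []
    ids = set(table.sample_ids)
    for r in samples:
        if r.is_control == "NEGATIVE" and r.sample_id in ids:
            n_calls = int(np.sum(table.sample_calls(r.sample_id) != MISSING))
            if n_calls > cfg.ntc_max_calls:
                flags.append(r.sample_id)
    return flags


@dataclass
class ErrorRateResult:
    n_comparisons: int
    n_mismatches: int
    n_panel_missing: int
    per_marker_missing: pd.Series
    mismatch_rate: float


def _is_mismatch(panel_call: str, ref_call: str) -> bool:
    from .genotype_io import call_alleles

    pa = call_alleles(panel_call)
    ra = call_alleles(ref_call)
    het_p = pa[0] != pa[1]
    het_r = ra[0] != ra[1]
    if het_p != het_r:
        return True  # het vs hom
    if not het_p and pa[0] != ra[0]:
        return True  # opposite homozygotes
    return het_p and set(pa) != set(ra)


def error_rate_vs_reference(
    panel_table: GenotypeTable, reference_table: GenotypeTable
) -> ErrorRateResult:
    """Allelic-mismatch accounting against trusted reference genotypes.

    Comparisons run over shared samples and markers where the reference call
    is non-missing; each such locus contributes exactly one comparison.
    Panel-missing loci are tallied separately (they are dropouts, not
    errors) regardless of the reference call.
    """
    shared_s = [s for s in panel_table.sample_ids if s in set(reference_table.sample_ids)]
    shared_m = [m for m in panel_table.marker_ids if m in set(reference_table.marker_ids)]
    if not shared_m or not shared_s:
        raise ValueError("no shared samples/markers between panel and reference")
    p = panel_table.subset(shared_s, shared_m)
    r = reference_table.subset(shared_s, shared_m)

    n_comp = n_mm = n_missing = 0
    miss_per_marker = Counter()
    for i in range(len(shared_s)):
        for j, mid in enumerate(shared_m):
            pc, rc = p.calls[i, j], r.calls[i, j]
            if pc == MISSING:
                n_missing += 1
                miss_per_marker[mid] += 1
                continue
            if rc == MISSING:
                continue
            n_comp += 1
            if _is_mismatch(pc, rc):
                n_mm += 1
    per_marker = pd.Series(
        {m: miss_per_marker.get(m, 0) for m in shared_m}, name="n_missing"
    )
    return ErrorRateResult(
        n_comparisons=n_comp,
        n_mismatches=n_mm,
        n_panel_missing=n_missing,
        per_marker_missing=per_marker,
        mismatch_rate=n_mm / n_comp if n_comp else float("nan"),
    )


def run_qc(
    table: GenotypeTable,
    samples: Sequence[SampleRecord],
    config: QCConfig | None = None,
    markers: Sequence[MarkerInfo] | None = None,
) -> QCReport:
    """Convenience wrapper: NTC check, consensus, call rates and pass filter."""
    cfg = config or QCConfig()
    ntc_flags = check_negative_controls(table, samples, cfg)
    analysed = table.subset(
        sample_ids=[s for s in table.sample_ids
                    if not any(r.sample_id == s and r.is_control for r in samples)]
    )
    consensus, mismatches = duplicate_consensus(analysed, samples)
    target = consensus if cfg.consensus_before_pass else analysed
    sample_cr, marker_cr = amplification_success(target, samples, markers)
    passes, by_material, overall = pass_filter(sample_cr, samples, cfg)
    return QCReport(
        sample_call_rate=sample_cr,
        marker_call_rate=marker_cr,
        sample_pass=passes,
        pass_by_material=by_material,
        overall_pass_pct=overall,
        group_mismatches=mismatches,
        consensus=consensus,
        ntc_flags=ntc_flags,
    )
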