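"""Marker-selection cascade for building a monitoring SNP panel.

The cascade mirrors standard array-QC practice: per-sample and per-marker
call-rate filters, windowed LD pruning on genotype-dosage r^2, an exact
Hardy-Weinberg screen, then category-specific rules — fixed differences
(F_ST = 1) for species-diagnostic markers, a minimum MAF for the
individual-ID markers, and sex-split MAF criteria for X markers (variable in
females, near-monomorphic in males, which carry a single X).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    ATTRITION_REASONS,
    CAT_HIGH_MAF,
    CAT_WOLF_DOG,
    CAT_WOLF_JACKAL,
    CAT_X_SEX,
    CAT_Y_SEX,
    CHROM_AUTOSOME,
    CHROM_X,
    MISSING,
    GenotypeTable,
    MarkerInfo,
    call_alleles,
    is_het,
)


@dataclass
class SelectionConfig:
    """Thresholds of the selection cascade.

    Defaults follow common PLINK-style QC settings: samples below 85% call
    rate and markers below 90% are dropped; LD pruning scans 50-marker
    windows in steps of 5 removing one of each pair with r^2 > 0.2; the
    design-stage HWE screen uses alpha = 0.001 and the validation stage
    0.05; individual-ID markers must keep MAF >= 0.3.
    """

    sample_callrate_min: float = 0.85
    marker_callrate_min: float = 0.90
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.2
    hwe_alpha: float = 0.001
    hwe_alpha_validation: float = 0.05
    maf_min: float = 0.3
    female_x_maf_range: tuple[float, float] = (0.125, 0.333)
    male_x_maf_max: float = 0.005
    pid_threshold: float = 1e-4
    n_high_maf_subsample: int | None = None  # e.g. 145 of 990 candidates

    def __post_init__(self) -> None:
        for name in ("sample_callrate_min", "marker_callrate_min", "ld_r2_max",
                     "hwe_alpha", "hwe_alpha_validation", "maf_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.ld_window >= self.ld_step >= 1:
            raise ValueError("need ld_window >= ld_step >= 1")


@dataclass
class LocusStats:
    marker_id: str
    call_rate: float
    maf: float
    hwe_p: float
    counts: tuple[int, int, int, int]  # n_hom1, n_het, n_hom2, n_missing
    fst: dict[tuple[str, str], float] = field(default_factory=dict)
    monomorphic: bool = False


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Exact two-sided HWE test conditional on the observed allele counts.

    Sums, over every heterozygote count compatible with the allele totals
    (same parity as the minor-allele count), the conditional probabilities
    that do not exceed the observed configuration's probability.  The
    conditional probability of ``h`` heterozygotes is proportional to
    ``2**h * N! / (n_AA! * h! * n_BB!)``.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n == 0:
        raise ValueError("HWE test undefined for zero genotypes")
    n_a = 2 * n_AA + n_AB
    n_b = 2 * n_BB + n_AB
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = n - hets - homs_rare  # carries the (2N - rare) common alleles
    # log of 2^h * N! / (hr! h! hc!) up to the shared N! constant
    from scipy.special import gammaln

    logp = (
        hets * math.log(2.0)
        - gammaln(homs_rare + 1)
        - gammaln(hets + 1)
        - gammaln(homs_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_AB][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Locus statistics
# ---------------------------------------------------------------------------


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int, int, list[str]]:
    labels = sorted({a for c in col if c != MISSING for a in call_alleles(c)})
    n_miss = int(np.sum(col == MISSING))
    if not labels:
        return 0, 0, 0, n_miss, labels
    a = labels[0]
    n_hom1 = n_het = n_hom2 = 0
    for c in col:
        if c == MISSING:
            continue
        x, y = call_alleles(c)
        if x != y:
            n_het += 1
        elif x == a:
            n_hom1 += 1
        else:
            n_hom2 += 1
    return n_hom1, n_het, n_hom2, n_miss, labels


def minor_allele_frequency(col: np.ndarray) -> float:
    """MAF from observed allele counts, ignoring missing; NaN if no calls."""
    n_hom1, n_het, n_hom2, _n_miss, labels = _genotype_counts(col)
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return float("nan")
    p = (2 * n_hom1 + n_het) / (2 * n)
    return min(p, 1 - p)


def compute_locus_stats(
    table: GenotypeTable,
    markers: Sequence[MarkerInfo] | None = None,
    population_labels: Mapping[str, str] | None = None,
    fst_pairs: Sequence[tuple[str, str]] = (),
) -> list[LocusStats]:
    """Call rate, MAF, exact-HWE p and optional per-pair F_ST for each marker."""
    out = []
    for mid in table.marker_ids:
        col = table.marker_calls(mid)
        n_hom1, n_het, n_hom2, n_miss, labels = _genotype_counts(col)
        n_called = n_hom1 + n_het + n_hom2
        call_rate = n_called / len(col) if len(col) else 0.0
        if n_called == 0:
            stats = LocusStats(mid, 0.0, float("nan"), float("nan"),
                               (0, 0, 0, n_miss), monomorphic=True)
            out.append(stats)
            continue
        p = (2 * n_hom1 + n_het) / (2 * n_called)
        maf = min(p, 1 - p)
        hwe_p = hwe_exact_test(n_hom1, n_het, n_hom2)
        stats = LocusStats(
            mid, call_rate, maf, hwe_p,
            (n_hom1, n_het, n_hom2, n_miss),
            monomorphic=(maf == 0.0),
        )
        if population_labels is not None:
            for pa, pb in fst_pairs:
                stats.fst[(pa, pb)] = fst_locus(table, population_labels, pa, pb, mid)
        out.append(stats)
    return out


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of minor-allele dosages.

    Computed over jointly non-missing samples; NaN when either marker has
    zero variance there (treated downstream as "not linked").
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < 2:
        return float("nan")
    a, b = a[mask], b[mask]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return float("nan")
    cov = float(np.mean((a - a.mean()) * (b - b.mean())))
    return cov * cov / (va * vb)


def ld_prune(
    table: GenotypeTable,
    marker_order: Sequence[str] | None = None,
    config: SelectionConfig | None = None,
) -> list[str]:
    """Windowed LD pruning: drop one marker from every high-r^2 pair.

    A window of ``ld_window`` markers slides in steps of ``ld_step`` along
    map order; within a window every remaining pair with r^2 above
    ``ld_r2_max`` loses its lower-MAF member (ties drop the later marker),
    repeated until the window is clean.
    """
    cfg = config or SelectionConfig()
    order = list(marker_order) if marker_order is not None else list(table.marker_ids)
    dos, _ = table.dosage_matrix(order)
    maf = {m: minor_allele_frequency(table.marker_calls(m)) for m in order}
    removed: set[str] = set()

    n = len(order)
    start = 0
    while start < n:
        window = [i for i in range(start, min(start + cfg.ld_window, n))
                  if order[i] not in removed]
        changed = True
        while changed:
            changed = False
            for ii in range(len(window)):
                i = window[ii]
                if order[i] in removed:
                    continue
                for jj in range(ii + 1, len(window)):
                    j = window[jj]
                    if order[j] in removed:
                        continue
                    r2 = ld_r2(dos[:, i], dos[:, j])
                    if not np.isnan(r2) and r2 > cfg.ld_r2_max:
                        mi, mj = order[i], order[j]
                        # drop the less informative member; tie -> later map position
                        drop = mj if (maf[mj] < maf[mi] or maf[mj] == maf[mi]) else mi
                        removed.add(drop)
                        changed = True
        if start + cfg.ld_window >= n:
            break
        start += cfg.ld_step
    return [m for m in order if m not in removed]


# ---------------------------------------------------------------------------
# F_ST (Weir & Cockerham two-population theta)
# ---------------------------------------------------------------------------


def fst_locus(
    table: GenotypeTable,
    labels: Mapping[str, str],
    pop_a: str,
    pop_b: str,
    marker_id: str,
) -> float:
    """Weir-Cockerham variance-components theta for one locus, two populations.

    Handles unequal sample sizes; returns 1.0 at a fixed difference and NaN
    when the locus is monomorphic across both populations together.
    """
    col = table.marker_calls(marker_id)
    stats = []
    for pop in (pop_a, pop_b):
        idx = [i for i, s in enumerate(table.sample_ids) if labels.get(s) == pop]
        calls = [col[i] for i in idx if col[i] != MISSING]
        if not calls:
            return float("nan")
        labels_here = sorted({a for c in calls for a in call_alleles(c)})
        stats.append((calls, labels_here))

    all_labels = sorted({a for calls, _ in stats for c in calls for a in call_alleles(c)})
    if len(all_labels) < 2:
        return float("nan")
    counted = all_labels[-1]

    n_i, p_i, h_i = [], [], []
    for calls, _ in stats:
        n = len(calls)
        dos = [sum(a == counted for a in call_alleles(c)) for c in calls]
        het = [1 if is_het(c) else 0 for c in calls]
        n_i.append(n)
        p_i.append(sum(dos) / (2 * n))
        h_i.append(sum(het) / n)

    r = 2
    n_i = np.asarray(n_i, dtype=float)
    p_i = np.asarray(p_i)
    h_i = np.asarray(h_i)
    n_bar = n_i.mean()
    if n_bar <= 1:
        return float("nan")
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return float(a / denom)


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------


@dataclass
class PanelSelection:
    selected: dict[str, list[str]]  # category -> marker ids
    attrition: pd.DataFrame  # reason x category counts
    passing_samples: list[str]
    rejected: dict[str, list[str]]  # marker -> reasons


def _attrition_frame(
    rejected: Mapping[str, list[str]],
    category_of: Mapping[str, str],
    extra_reasons: Sequence[str] = (),
) -> pd.DataFrame:
    reasons = list(ATTRITION_REASONS) + [
        r for r in extra_reasons if r not in ATTRITION_REASONS
    ]
    cats = [CAT_HIGH_MAF, CAT_X_SEX, CAT_Y_SEX, CAT_WOLF_DOG, CAT_WOLF_JACKAL]
    counts = pd.DataFrame(0, index=reasons, columns=cats)
    for mid, rs in rejected.items():
        cat = category_of.get(mid, CAT_HIGH_MAF)
        for reason in rs:
            if reason not in counts.index:
                counts.loc[reason] = 0
            counts.loc[reason, cat] += 1
    counts.insert(0, "reason", counts.index)
    return counts.reset_index(drop=True)


def select_panel(
    table: GenotypeTable,
    markers: Sequence[MarkerInfo],
    config: SelectionConfig | None = None,
    population_labels: Mapping[str, str] | None = None,
    sex_labels: Mapping[str, str] | None = None,
    diagnostic_pairs: Mapping[str, tuple[str, str]] | None = None,
    external_flags: Mapping[str, Sequence[str]] | None = None,
    focal_population: str = "wolf",
    rng: np.random.Generator | None = None,
) -> PanelSelection:
    """Run the full selection cascade and build a Table-1-style attrition report.

    Order of operations: sample call-rate filter; marker call-rate filter
    (complete failure reported as "No amplification", partial as "Low
    amplification"); LD prune and exact-HWE screen on the individual-ID
    (high-MAF) candidates within the focal population — pooling divergent
    species would manufacture spurious LD and Wahlund-style HWE failure at
    exactly the diagnostic markers the panel needs; then category rules
    (diagnostic markers need theta = 1 between their species pair; high-MAF
    markers need MAF >= maf_min; X markers need female MAF inside the
    configured range and male MAF below the ceiling).  A marker can be
    rejected for several reasons at once and is counted once per reason.
    ``external_flags`` lets the caller merge wet-lab rejection reasons
    ("NTC up", "Readability") into the same report.
    """
    cfg = config or SelectionConfig()
    rng = rng or np.random.default_rng(0)
    diagnostic_pairs = diagnostic_pairs or {
        CAT_WOLF_DOG: ("wolf", "dog"),
        CAT_WOLF_JACKAL: ("wolf", "jackal"),
    }
    by_id = {m.marker_id: m for m in markers}
    category_of = {m.marker_id: m.category for m in markers}
    rejected: dict[str, list[str]] = {}

    def reject(mid: str, reason: str) -> None:
        rejected.setdefault(mid, []).append(reason)

    for mid, flags in (external_flags or {}).items():
        for reason in flags:
            reject(mid, reason)

    # PAR-flagged X markers are unusable for sexing and leave the pool first
    for m in markers:
        if m.par_flag:
            reject(m.marker_id, "PAR")

    # 1. sample call-rate filter
    if table.n_samples and table.n_markers:
        rates = 1.0 - np.mean(table.calls == MISSING, axis=1)
    else:
        rates = np.zeros(table.n_samples)
    passing_samples = [
        s for s, r in zip(table.sample_ids, rates) if r >= cfg.sample_callrate_min
    ]
    sub = table.subset(sample_ids=passing_samples)

    # 2. marker call-rate filter
    alive: list[str] = []
    for mid in sub.marker_ids:
        if mid in rejected:
            continue
        col = sub.marker_calls(mid)
        rate = float(np.mean(col != MISSING)) if len(col) else 0.0
        if rate == 0.0:
            reject(mid, "No amplification")
        elif rate < cfg.marker_callrate_min:
            reject(mid, "Low amplification")
        else:
            alive.append(mid)

    # LD/HWE/MAF screens run on the focal population when labels are given
    if population_labels is not None:
        focal_ids = [s for s in passing_samples
                     if population_labels.get(s) == focal_population]
        focal = sub.subset(sample_ids=focal_ids) if focal_ids else sub
    else:
        focal = sub

    # 3. LD prune the individual-ID candidates (map order)
    id_markers = [m for m in alive
                  if by_id[m].chrom_class == CHROM_AUTOSOME
                  and by_id[m].category == CAT_HIGH_MAF]
    id_markers.sort(key=lambda m: (by_id[m].position, m))
    kept = set(ld_prune(focal, id_markers, cfg))
    for mid in id_markers:
        if mid not in kept:
            reject(mid, "LD")
    alive = [m for m in alive if m not in rejected]

    # 4. HWE screen (high-MAF autosomals; hemizygous males break HWE on X)
    for mid in alive:
        if by_id[mid].category != CAT_HIGH_MAF:
            continue
        n1, nh, n2, _, labels = _genotype_counts(focal.marker_calls(mid))
        if n1 + nh + n2 == 0:
            continue
        if hwe_exact_test(n1, nh, n2) < cfg.hwe_alpha:
            reject(mid, "Deviation from HW")
    alive = [m for m in alive if m not in rejected]

    # 5. category rules
    selected: dict[str, list[str]] = {
        CAT_HIGH_MAF: [], CAT_WOLF_DOG: [], CAT_WOLF_JACKAL: [],
        CAT_X_SEX: [], CAT_Y_SEX: [],
    }
    females = males = None
    if sex_labels:
        females = [s for s in passing_samples if sex_labels.get(s) == "FEMALE"]
        males = [s for s in passing_samples if sex_labels.get(s) == "MALE"]

    for mid in alive:
        cat = category_of[mid]
        if cat == CAT_HIGH_MAF:
            maf = minor_allele_frequency(focal.marker_calls(mid))
            if np.isnan(maf) or maf < cfg.maf_min:
                reject(mid, "Low MAF")
            else:
                selected[cat].append(mid)
        elif cat in diagnostic_pairs:
            if population_labels is None:
                reject(mid, "No labels")
                continue
            pa, pb = diagnostic_pairs[cat]
            theta = fst_locus(sub, population_labels, pa, pb, mid)
            if np.isnan(theta) or theta < 1.0 - 1e-9:
                reject(mid, "Not diagnostic")
            else:
                selected[cat].append(mid)
        elif cat == CAT_X_SEX:
            if females is None or males is None:
                reject(mid, "No sex labels")
                continue
            f_maf = minor_allele_frequency(
                sub.subset(sample_ids=females).marker_calls(mid)
            )
            m_maf = minor_allele_frequency(
                sub.subset(sample_ids=males).marker_calls(mid)
            )
            lo, hi = cfg.female_x_maf_range
            if np.isnan(f_maf) or not (lo <= f_maf <= hi):
                reject(mid, "Low MAF")
            elif not np.isnan(m_maf) and m_maf > cfg.male_x_maf_max:
                reject(mid, "Male X heterozygosity")
            else:
                selected[cat].append(mid)
        elif cat == CAT_Y_SEX:
            selected[cat].append(mid)

    # optional seeded random subsample of the high-MAF pool (e.g. 145 of 990)
    n_sub = cfg.n_high_maf_subsample
    pool = selected[CAT_HIGH_MAF]
    if n_sub is not None and len(pool) > n_sub:
        chosen = rng.choice(len(pool), size=n_sub, replace=False)
        selected[CAT_HIGH_MAF] = [pool[i] for i in sorted(chosen)]

    attrition = _attrition_frame(
        rejected, category_of,
        extra_reasons=sorted({r for rs in rejected.values() for r in rs}),
    )
    return PanelSelection(
        selected=selected,
        attrition=attrition,
        passing_samples=passing_samples,
        rejected=rejected,
    )
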