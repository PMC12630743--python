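"""Species identification: PCA projection and likelihood assignment to pooled
reference groups.

Queries are assigned with a conditional genotype-likelihood model: each
group's allele frequencies are posterior means under a symmetric
Dirichlet(1/2, 1/2) prior on its allele counts, a sample's log-likelihood in
a group sums log HWE genotype probabilities over its called loci, and
posteriors follow from equal group priors.  The Dirichlet smoothing keeps
every genotype possible, so a single discordant locus cannot veto a group.
Reference-group membership can be restricted by externally supplied ancestry
coefficients (individuals below the Q threshold are excluded, mirroring how
admixed references are dropped before assignment).

Genetically distant non-target species (bear, lynx, moose) are not handled
here: their samples barely amplify and are removed by the QC pass filter
before assignment is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeTable, call_alleles


@dataclass
class ReferenceSet:
    """Per-group allele counts plus the genotypes they came from."""

    groups: list[str]
    marker_ids: list[str]
    counted_allele: dict[str, str]
    # counts[group][marker] = (count of counted allele, total called alleles)
    counts: dict[str, dict[str, tuple[int, int]]]
    members: dict[str, list[str]]
    table: GenotypeTable
    q_threshold: float = 0.85
    excluded: list[str] = field(default_factory=list)


def build_reference_set(
    table: GenotypeTable,
    group_labels: Mapping[str, str],
    ancestry_q: Mapping[str, float] | None = None,
    q_threshold: float = 0.85,
) -> ReferenceSet:
    """Pool labelled reference genotypes into per-group allele counts.

    Samples with an ancestry coefficient below ``q_threshold`` are excluded
    from the counts (and from membership) but reported in ``excluded``.
    """
    excluded = []
    keep: dict[str, str] = {}
    for sid in table.sample_ids:
        if sid not in group_labels:
            continue
        if ancestry_q is not None and ancestry_q.get(sid, 1.0) < q_threshold:
            excluded.append(sid)
            continue
        keep[sid] = group_labels[sid]
    groups = sorted(set(keep.values()))

    counted: dict[str, str] = {}
    for mid in table.marker_ids:
        labels = sorted(
            {a for c in table.marker_calls(mid) if c != MISSING
             for a in call_alleles(c)}
        )
        counted[mid] = labels[-1] if labels else "B"

    counts: dict[str, dict[str, tuple[int, int]]] = {g: {} for g in groups}
    members: dict[str, list[str]] = {g: [] for g in groups}
    for g in groups:
        members[g] = [s for s, gg in keep.items() if gg == g]
    for mid in table.marker_ids:
        col = table.marker_calls(mid)
        for g in groups:
            c = t = 0
            for s in members[g]:
                call = col[table.sample_ids.index(s)]
                if call == MISSING:
                    continue
                a, b = call_alleles(call)
                c += (a == counted[mid]) + (b == counted[mid])
                t += 2
            counts[g][mid] = (c, t)
    return ReferenceSet(
        groups=groups,
        marker_ids=list(table.marker_ids),
        counted_allele=counted,
        counts=counts,
        members=members,
        table=table,
        q_threshold=q_threshold,
        excluded=excluded,
    )


@dataclass
class AssignmentResult:
    posteriors: pd.DataFrame  # samples x groups, rows sum to 1
    log_likelihoods: pd.DataFrame
    best_group: pd.Series
    n_loci_used: pd.Series


def _locus_loglik(dosage: int, p: float) -> float:
    if dosage == 2:
        return math.log(p * p)
    if dosage == 1:
        return math.log(2 * p * (1 - p))
    return math.log((1 - p) * (1 - p))


def _smoothed_freq(count: int, total: int) -> float:
    # posterior mean under Dirichlet(1/2, 1/2)
    return (count + 0.5) / (total + 1.0)


def assign(
    query_table: GenotypeTable,
    refset: ReferenceSet,
    adjust: Mapping[str, dict[str, tuple[int, int]]] | None = None,
) -> AssignmentResult:
    """Assign each query sample to the most likely reference group.

    ``adjust`` subtracts (count, total) pairs from a group's counts before
    scoring — the hook leave-one-out validation uses to remove a sample's
    own contribution.  A fully missing query gets a flat posterior.
    """
    shared = [m for m in query_table.marker_ids if m in set(refset.marker_ids)]
    if not shared:
        raise ValueError("query and reference share no markers")

    loglik = np.zeros((query_table.n_samples, len(refset.groups)))
    n_used = np.zeros(query_table.n_samples, dtype=int)
    for i, sid in enumerate(query_table.sample_ids):
        for mid in shared:
            call = query_table.get(sid, mid)
            if call == MISSING:
                continue
            a, b = call_alleles(call)
            counted = refset.counted_allele[mid]
            dosage = (a == counted) + (b == counted)
            n_used[i] += 1
            for k, g in enumerate(refset.groups):
                c, t = refset.counts[g][mid]
                if adjust and mid in adjust.get(g, {}):
                    dc, dt = adjust[g][mid]
                    c, t = c - dc, t - dt
                loglik[i, k] += _locus_loglik(dosage, _smoothed_freq(c, t))

    post = np.zeros_like(loglik)
    for i in range(len(post)):
        if n_used[i] == 0:
            post[i, :] = 1.0 / len(refset.groups)
        else:
            z = loglik[i] - loglik[i].max()
            w = np.exp(z)
            post[i, :] = w / w.sum()

    posteriors = pd.DataFrame(
        post, index=query_table.sample_ids, columns=refset.groups
    )
    return AssignmentResult(
        posteriors=posteriors,
        log_likelihoods=pd.DataFrame(
            loglik, index=query_table.sample_ids, columns=refset.groups
        ),
        best_group=posteriors.idxmax(axis=1),
        n_loci_used=pd.Series(n_used, index=query_table.sample_ids),
    )


def leave_one_out_self_assignment(refset: ReferenceSet) -> pd.Series:
    """Per-group fraction of reference members assigned back to their group.

    Each member's alleles are subtracted from its own group's counts before
    it is scored, so a sample never supports itself.  Groups with a single
    member are skipped with a warning.
    """
    rates = {}
    for g in refset.groups:
        members = refset.members[g]
        if len(members) < 2:
            warnings.warn(f"group {g!r} has {len(members)} member(s); skipped")
            continue
        correct = 0
        for sid in members:
            adjust: dict[str, dict[str, tuple[int, int]]] = {g: {}}
            for mid in refset.marker_ids:
                call = refset.table.get(sid, mid)
                if call == MISSING:
                    continue
                a, b = call_alleles(call)
                counted = refset.counted_allele[mid]
                d = (a == counted) + (b == counted)
                adjust[g][mid] = (d, 2)
            res = assign(refset.table.subset(sample_ids=[sid]), refset, adjust=adjust)
            if res.best_group.iloc[0] == g:
                correct += 1
        rates[g] = correct / len(members)
    return pd.Series(rates, name="loo_self_assignment")


def pca_project(
    reference_table: GenotypeTable,
    query_table: GenotypeTable | None = None,
    n_components: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame | None, np.ndarray]:
    """Principal components of reference dosages, with queries projected on.

    Dosages are mean-centred per marker with missing values imputed to the
    reference marker mean; axes come from an SVD of the centred reference
    matrix only, so queries cannot distort the space they are judged in.
    Returns (reference coordinates, query coordinates or None,
    explained-variance fractions).
    """
    if reference_table.n_samples < 2:
        raise ValueError("PCA needs at least two reference samples")
    ref_dos, m_ids = reference_table.dosage_matrix()
    all_missing = np.all(np.isnan(ref_dos), axis=0)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} marker(s) with no reference calls"
        )
        keep = ~all_missing
        ref_dos = ref_dos[:, keep]
        m_ids = [m for m, k in zip(m_ids, keep) if k]

    means = np.nanmean(ref_dos, axis=0)
    ref_c = np.where(np.isnan(ref_dos), 0.0, ref_dos - means)
    u, s, vt = np.linalg.svd(ref_c, full_matrices=False)
    k = min(n_components, len(s))
    total_var = (s**2).sum()
    explained = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    ref_coords = pd.DataFrame(
        ref_c @ vt[:k].T, index=reference_table.sample_ids, columns=cols
    )

    query_coords = None
    if query_table is not None:
        # dosage coding must match the reference's counted alleles
        q = query_table.subset(marker_ids=[m for m in m_ids
                                           if m in set(query_table.marker_ids)])
        q_dos = np.full((q.n_samples, len(m_ids)), np.nan)
        ref_labels = {m: sorted({a for c in reference_table.marker_calls(m)
                                 if c != MISSING for a in call_alleles(c)})
                      for m in m_ids}
        for j, mid in enumerate(m_ids):
            if mid not in set(q.marker_ids):
                continue
            labels = ref_labels[mid]
            counted = labels[-1] if labels else "B"
            col = q.marker_calls(mid)
            for i, call in enumerate(col):
                if call == MISSING:
                    continue
                a, b = call_alleles(call)
                q_dos[i, j] = (a == counted) + (b == counted)
        q_c = np.where(np.isnan(q_dos), 0.0, q_dos - means)
        query_coords = pd.DataFrame(
            q_c @ vt[:k].T, index=query_table.sample_ids, columns=cols
        )
    return ref_coords, query_coords, explained
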