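"""Mendelian-exclusion and likelihood-ratio parentage, plus pedigree inbreeding.

Parentage here is a desk-scale exclusion + LOD scheme rather than a full
likelihood sibship reconstruction: candidates are screened by the number of
Mendelian-incompatible loci they would force (with an allowance scaled to
the genotyping error rate), survivors are ranked by a transmission
log-likelihood ratio, and a posterior over the surviving parent hypotheses
under (near-)equal priors serves as the assignment confidence.  Pedigree
inbreeding coefficients come from the classic recursive kinship function:
an individual's F equals the kinship of its parents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeTable, call_alleles


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Parent links: ``parents[id] = (sire_id_or_None, dam_id_or_None)``."""

    parents: dict[str, tuple[str | None, str | None]]
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # every named parent exists as an individual (implicitly a founder)
        for child, (sire, dam) in list(self.parents.items()):
            for p in (sire, dam):
                if p is not None and p not in self.parents:
                    self.parents[p] = (None, None)
        self._depths = self._topological_depths()
        for child, (sire, dam) in self.parents.items():
            if sire and self.sex.get(sire) == "FEMALE":
                raise PedigreeError(f"sire {sire} of {child} is recorded FEMALE")
            if dam and self.sex.get(dam) == "MALE":
                raise PedigreeError(f"dam {dam} of {child} is recorded MALE")

    def _topological_depths(self) -> dict[str, int]:
        depths: dict[str, int] = {}

        def depth(i: str, stack: tuple[str, ...]) -> int:
            if i in stack:
                raise PedigreeError(f"pedigree cycle through {i}")
            if i in depths:
                return depths[i]
            sire, dam = self.parents[i]
            d = 0
            for p in (sire, dam):
                if p is not None:
                    d = max(d, depth(p, stack + (i,)) + 1)
            depths[i] = d
            return d

        for i in self.parents:
            depth(i, ())
        return depths

    @property
    def individuals(self) -> list[str]:
        return sorted(self.parents, key=lambda i: (self._depths[i], i))

    def is_founder(self, i: str) -> bool:
        return self.parents[i] == (None, None)


def kinship(pedigree: Pedigree, a: str | None, b: str | None,
            _memo: dict | None = None) -> float:
    """Recursive kinship phi(a, b); founders unrelated and non-inbred.

    phi(a, a) = (1 + F_a) / 2 and phi(a, b) = [phi(sire_a, b) +
    phi(dam_a, b)] / 2 where a is the deeper individual; a missing parent
    contributes zero (treated as an unrelated, non-inbred founder).
    """
    if a is None or b is None:
        return 0.0
    memo = _memo if _memo is not None else {}
    key = (a, b) if a <= b else (b, a)
    if key in memo:
        return memo[key]
    if a == b:
        sire, dam = pedigree.parents[a]
        val = 0.5 * (1.0 + kinship(pedigree, sire, dam, memo))
    else:
        # recurse through the deeper individual's parents
        da, db = pedigree._depths[a], pedigree._depths[b]
        x, y = (a, b) if da >= db else (b, a)
        sire, dam = pedigree.parents[x]
        val = 0.5 * (
            kinship(pedigree, sire, y, memo) + kinship(pedigree, dam, y, memo)
        )
    memo[key] = val
    return val


def pedigree_inbreeding(pedigree: Pedigree) -> dict[str, float]:
    """F per individual: the kinship of its parents (0 for founders)."""
    memo: dict = {}
    out = {}
    for i in pedigree.individuals:
        sire, dam = pedigree.parents[i]
        out[i] = kinship(pedigree, sire, dam, memo)
    return out


# ---------------------------------------------------------------------------
# Exclusion and LOD
# ---------------------------------------------------------------------------


@dataclass
class ParentageConfig:
    """Error allowance and candidate-set policy.

    ``error_rate`` is the assumed per-locus genotyping error (the LOD model
    mixes Mendelian transmission with a population-frequency draw at this
    rate); ``max_incompatible`` defaults to ceil(2 * error_rate * n_loci) so
    true parents survive exclusion at the assumed error rate.
    ``prob_parent_present`` is the prior probability that a true parent is
    among the candidates, carried as prior odds against the "parent absent"
    hypothesis.
    """

    error_rate: float = 0.01
    max_incompatible: int | None = None
    prob_parent_present: float = 0.9
    min_confidence: float = 0.8
    max_pair_candidates: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if not 0 < self.prob_parent_present <= 1:
            raise ValueError("prob_parent_present must lie in (0, 1]")

    def incompat_tolerance(self, n_loci: int) -> int:
        if self.max_incompatible is not None:
            return self.max_incompatible
        return math.ceil(2 * self.error_rate * n_loci)


def _transmit_prob(allele: str, parent_call: str) -> float:
    a, b = call_alleles(parent_call)
    if a == b:
        return 1.0 if allele == a else 0.0
    return 0.5 if allele in (a, b) else 0.0


def mendel_incompatibilities(
    offspring_calls: Mapping[str, str],
    parent_calls: Mapping[str, str],
    other_parent_calls: Mapping[str, str] | None = None,
) -> tuple[int, int]:
    """(incompatible loci, shared called loci) for a dyad or trio.

    Dyad: a locus is incompatible when offspring and candidate share no
    allele.  Trio: incompatible when no gamete pair from the two candidates
    can produce the offspring genotype.
    """
    n_bad = n_shared = 0
    for mid, oc in offspring_calls.items():
        if oc == MISSING:
            continue
        pc = parent_calls.get(mid, MISSING)
        if pc == MISSING:
            continue
        qc = None
        if other_parent_calls is not None:
            qc = other_parent_calls.get(mid, MISSING)
            if qc == MISSING:
                qc = None
        n_shared += 1
        x, y = call_alleles(oc)
        if qc is None:
            if not (set((x, y)) & set(call_alleles(pc))):
                n_bad += 1
        else:
            ok = (
                _transmit_prob(x, pc) * _transmit_prob(y, qc)
                + _transmit_prob(y, pc) * _transmit_prob(x, qc)
            ) > 0
            if not ok:
                n_bad += 1
    if n_shared == 0:
        raise ValueError("no shared called loci between offspring and candidate(s)")
    return n_bad, n_shared


def _hwe_prob(call: str, freqs: Mapping[str, float]) -> float:
    x, y = call_alleles(call)
    px = freqs.get(x, 0.0)
    py = freqs.get(y, 0.0)
    return px * px if x == y else 2 * px * py


def _mendel_prob(
    call: str,
    parent_call: str,
    other_parent_call: str | None,
    freqs: Mapping[str, float],
) -> float:
    x, y = call_alleles(call)
    if other_parent_call is None:
        # one transmitted allele, the other drawn from the population
        if x == y:
            return _transmit_prob(x, parent_call) * freqs.get(x, 0.0)
        return (
            _transmit_prob(x, parent_call) * freqs.get(y, 0.0)
            + _transmit_prob(y, parent_call) * freqs.get(x, 0.0)
        )
    if x == y:
        return _transmit_prob(x, parent_call) * _transmit_prob(x, other_parent_call)
    return (
        _transmit_prob(x, parent_call) * _transmit_prob(y, other_parent_call)
        + _transmit_prob(y, parent_call) * _transmit_prob(x, other_parent_call)
    )


def parentage_lod(
    offspring_calls: Mapping[str, str],
    parent_calls: Mapping[str, str],
    freqs: Mapping[str, Mapping[str, float]],
    error_rate: float = 0.01,
    other_parent_calls: Mapping[str, str] | None = None,
) -> float:
    """log10 likelihood ratio of parenthood over an unrelated HWE draw.

    Per locus: P_obs = (1 - eps) * P(offspring | candidate transmission) +
    eps * P(offspring | HWE), against the null P(offspring | HWE); summed
    over loci called in offspring and candidate(s).  With eps = 0 an
    incompatible locus sends the LOD to -inf, recovering pure exclusion.
    """
    lod = 0.0
    for mid, oc in offspring_calls.items():
        if oc == MISSING or mid not in freqs:
            continue
        pc = parent_calls.get(mid, MISSING)
        if pc == MISSING:
            continue
        qc = None
        if other_parent_calls is not None:
            qc = other_parent_calls.get(mid, MISSING)
            if qc == MISSING:
                qc = None
        p_null = _hwe_prob(oc, freqs[mid])
        if p_null <= 0:
            continue  # allele unseen in the frequency table: uninformative
        p_mendel = _mendel_prob(oc, pc, qc, freqs[mid])
        p_obs = (1 - error_rate) * p_mendel + error_rate * p_null
        if p_obs == 0.0:
            return float("-inf")
        lod += math.log10(p_obs / p_null)
    return lod


@dataclass
class ParentAssignment:
    offspring_id: str
    sire_id: str | None
    dam_id: str | None
    lod: float
    confidence: float
    n_incompatible: int
    note: str = ""


def assign_parents(
    offspring_table: GenotypeTable,
    candidate_table: GenotypeTable,
    sex_of: Mapping[str, str],
    freqs: Mapping[str, Mapping[str, float]],
    config: ParentageConfig | None = None,
) -> list[ParentAssignment]:
    """Best parent pair (or single parent, or none) per offspring.

    All genotyped males are potential fathers and all females potential
    mothers; unknown-sex candidates enter both sets.  Candidates failing the
    dyad exclusion tolerance are dropped; the surviving single parents
    (capped at the top ``max_pair_candidates`` per side by dyad LOD) are
    combined into pairs, trio-excluded pairs are dropped, and the hypothesis
    with the highest total LOD wins.  Confidence is the posterior of the
    winning hypothesis where each "parent present" hypothesis shares the
    ``prob_parent_present`` prior mass and the no-parent hypothesis (LOD 0)
    takes the rest.  Ties break on higher shared-locus count, then
    lexicographic ids.
    """
    cfg = config or ParentageConfig()
    out = []
    cand_calls = {
        s: dict(zip(candidate_table.marker_ids, candidate_table.sample_calls(s)))
        for s in candidate_table.sample_ids
    }
    for off in offspring_table.sample_ids:
        oc = dict(zip(offspring_table.marker_ids, offspring_table.sample_calls(off)))
        n_loci = sum(1 for v in oc.values() if v != MISSING)
        tol = cfg.incompat_tolerance(n_loci)

        mothers, fathers = [], []
        for cid in candidate_table.sample_ids:
            if cid == off:
                continue
            try:
                bad, shared = mendel_incompatibilities(oc, cand_calls[cid])
            except ValueError:
                continue
            if bad > tol:
                continue
            lod = parentage_lod(oc, cand_calls[cid], freqs, cfg.error_rate)
            sex = sex_of.get(cid)
            entry = (cid, lod, bad, shared)
            if sex != "MALE":
                mothers.append(entry)
            if sex != "FEMALE":
                fathers.append(entry)
        mothers.sort(key=lambda e: (-e[1], -e[3], e[0]))
        fathers.sort(key=lambda e: (-e[1], -e[3], e[0]))
        mothers = mothers[: cfg.max_pair_candidates]
        fathers = fathers[: cfg.max_pair_candidates]

        # hypotheses: (sire, dam, lod, n_incompatible, n_shared)
        hyps: list[tuple[str | None, str | None, float, int, int]] = [
            (None, None, 0.0, 0, 0)
        ]
        for cid, lod, bad, shared in fathers:
            hyps.append((cid, None, lod, bad, shared))
        for cid, lod, bad, shared in mothers:
            hyps.append((None, cid, lod, bad, shared))
        for fid, flod, fbad, fsh in fathers:
            for mid_, mlod, mbad, msh in mothers:
                if fid == mid_:
                    continue
                try:
                    bad, shared = mendel_incompatibilities(
                        oc, cand_calls[fid], cand_calls[mid_]
                    )
                except ValueError:
                    continue
                if bad > tol:
                    continue
                lod = parentage_lod(
                    oc, cand_calls[fid], freqs, cfg.error_rate,
                    other_parent_calls=cand_calls[mid_],
                )
                hyps.append((fid, mid_, lod, bad, shared))

        # posterior over hypotheses; no-parent carries the absent-parent prior
        finite = [h for h in hyps if math.isfinite(h[2])]
        n_present = max(1, len(finite) - 1)
        weights = []
        for sire, dam, lod, _, _ in finite:
            prior = (
                (1 - cfg.prob_parent_present)
                if (sire is None and dam is None)
                else cfg.prob_parent_present / n_present
            )
            weights.append((sire, dam, lod, prior))
        max_lod = max(w[2] for w in weights)
        zs = [p * (10.0 ** (lod - max_lod)) for _, _, lod, p in weights]
        total = sum(zs)
        posts = [z / total for z in zs]

        best_i = max(
            range(len(weights)),
            key=lambda i: (
                weights[i][2],
                -(weights[i][0] is None) - (weights[i][1] is None),
                str(weights[i][0]), str(weights[i][1]),
            ),
        )
        sire, dam, lod, _ = weights[best_i]
        bad = next(h[3] for h in hyps if h[0] == sire and h[1] == dam)
        note = "unassigned" if sire is None and dam is None else (
            "single-parent" if sire is None or dam is None else ""
        )
        out.append(
            ParentAssignment(
                offspring_id=off, sire_id=sire, dam_id=dam, lod=lod,
                confidence=posts[best_i], n_incompatible=bad, note=note,
            )
        )
    return out


def assignments_frame(assignments: Sequence[ParentAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"offspring_id": a.offspring_id, "sire_id": a.sire_id or "",
             "dam_id": a.dam_id or "", "lod": a.lod,
             "confidence": a.confidence, "n_incompatible": a.n_incompatible,
             "note": a.note}
            for a in assignments
        ],
        columns=["offspring_id", "sire_id", "dam_id", "lod", "confidence",
                 "n_incompatible", "note"],
    )
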