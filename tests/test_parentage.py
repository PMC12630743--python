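"""Mendelian exclusion, parentage LOD and pedigree inbreeding."""

import math

import numpy as np
import pytest

from snpmon.genotype_io import MISSING
from snpmon.parentage import (
    ParentageConfig,
    Pedigree,
    PedigreeError,
    assign_parents,
    kinship,
    mendel_incompatibilities,
    parentage_lod,
    pedigree_inbreeding,
)
from snpmon.synthetic_data import (
    SimConfig,
    make_markers,
    random_family_pedigree,
    simulate_frequencies,
    simulate_individuals,
)

from conftest import table_from_rows


# ---------------------------------------------------------------------------
# Exclusion
# ---------------------------------------------------------------------------


def test_dyad_compatibility_rules():
    assert mendel_incompatibilities({"m": "A/G"}, {"m": "A/A"}) == (0, 1)
    assert mendel_incompatibilities({"m": "G/G"}, {"m": "A/A"}) == (1, 1)


def test_trio_exclusion_by_gamete_enumeration():
    # two A/A parents cannot produce an A/G offspring
    assert mendel_incompatibilities(
        {"m": "A/G"}, {"m": "A/A"}, {"m": "A/A"}
    ) == (1, 1)
    # A/G x A/G can produce anything
    assert mendel_incompatibilities(
        {"m": "G/G"}, {"m": "A/G"}, {"m": "A/G"}
    ) == (0, 1)


def test_no_shared_loci_is_error():
    with pytest.raises(ValueError):
        mendel_incompatibilities({"m": MISSING}, {"m": "A/A"})


# ---------------------------------------------------------------------------
# LOD
# ---------------------------------------------------------------------------

FREQS_HALF = {"m": {"A": 0.5, "G": 0.5}}


def test_lod_single_locus_closed_form():
    """Offspring identical to candidate at one p=0.5 locus matches hand math."""
    eps = 0.01
    # het offspring, het parent: P(A/G | parent A/G) = 0.5*0.5 + 0.5*0.5 = 0.5
    p_null = 0.5
    p_mendel = 0.5
    expect = math.log10(((1 - eps) * p_mendel + eps * p_null) / p_null)
    got = parentage_lod({"m": "A/G"}, {"m": "A/G"}, FREQS_HALF, eps)
    assert got == pytest.approx(expect, abs=1e-12)
    # hom offspring, hom parent: P(A/A | A/A) = 1 * 0.5; null = 0.25
    expect2 = math.log10(((1 - eps) * 0.5 + eps * 0.25) / 0.25)
    got2 = parentage_lod({"m": "A/A"}, {"m": "A/A"}, FREQS_HALF, eps)
    assert got2 == pytest.approx(expect2, abs=1e-12)


def test_lod_zero_error_incompatible_is_minus_infinity():
    lod = parentage_lod({"m": "G/G"}, {"m": "A/A"}, FREQS_HALF, 0.0)
    assert lod == float("-inf")


@pytest.fixture(scope="module")
def trio_simulation():
    cfg = SimConfig(seed=21)
    markers = [m for m in make_markers(cfg) if m.category == "HIGH_MAF"]
    rng = np.random.default_rng(21)
    freqs = simulate_frequencies(cfg, rng)
    ped, sex_of = random_family_pedigree(30, 20, rng)
    pop = {i: "wolf" for i in ped.parents}
    truth = simulate_individuals(freqs, ped, pop, sex_of, markers, rng)
    freq_dicts = {
        m.marker_id: {"G": float(freqs.loc[m.marker_id, "wolf"]),
                      "A": 1 - float(freqs.loc[m.marker_id, "wolf"])}
        for m in markers
    }
    return ped, sex_of, truth, freq_dicts


def test_true_parents_score_positive_unrelated_negative(trio_simulation):
    ped, sex_of, truth, freqs = trio_simulation
    offspring = [i for i in ped.parents if not ped.is_founder(i)]
    founders = [i for i in ped.parents if ped.is_founder(i)]
    n_pos = n_neg = n_unrel = n_unrel_neg = 0
    for off in offspring:
        oc = dict(zip(truth.marker_ids, truth.sample_calls(off)))
        sire, dam = ped.parents[off]
        for parent in (sire, dam):
            pc = dict(zip(truth.marker_ids, truth.sample_calls(parent)))
            n_pos += 1
            if parentage_lod(oc, pc, freqs, 0.01) > 0:
                n_neg += 1
        unrelated = [f for f in founders if f not in (sire, dam)][:2]
        for u in unrelated:
            uc = dict(zip(truth.marker_ids, truth.sample_calls(u)))
            n_unrel += 1
            if parentage_lod(oc, uc, freqs, 0.01) < 0:
                n_unrel_neg += 1
    assert n_neg / n_pos >= 0.99
    assert n_unrel_neg / n_unrel >= 0.95


# ---------------------------------------------------------------------------
# Pedigree inbreeding
# ---------------------------------------------------------------------------


def grandfather_granddaughter_pedigree():
    return Pedigree(
        {
            "GF": (None, None), "A": (None, None), "C": (None, None),
            "B": ("GF", "A"),       # daughter of GF
            "G": ("C", "B"),        # granddaughter of GF
            "H": ("GF", "G"),       # grandfather x granddaughter
        },
        sex={"GF": "MALE", "A": "FEMALE", "C": "MALE",
             "B": "FEMALE", "G": "FEMALE", "H": "FEMALE"},
    )


def test_founder_inbreeding_zero():
    ped = grandfather_granddaughter_pedigree()
    f = pedigree_inbreeding(ped)
    assert f["GF"] == 0.0 and f["A"] == 0.0


def test_grandfather_granddaughter_offspring():
    f = pedigree_inbreeding(grandfather_granddaughter_pedigree())
    assert f["H"] == pytest.approx(0.125)


def test_full_sib_offspring_and_inbred_line():
    ped = Pedigree(
        {
            "p": (None, None), "q": (None, None),
            "s1": ("p", "q"), "s2": ("p", "q"),
            "kid": ("s1", "s2"),
        },
        sex={"p": "MALE", "q": "FEMALE", "s1": "MALE", "s2": "FEMALE"},
    )
    assert pedigree_inbreeding(ped)["kid"] == pytest.approx(0.25)

    # four-generation within-line matings push F past 0.2:
    # I is a father-daughter son (GF x B); K pairs him with H
    base = grandfather_granddaughter_pedigree()
    parents = dict(base.parents) | {"I": ("GF", "B"), "K": ("I", "H")}
    sexes = dict(base.sex) | {"I": "MALE", "K": "FEMALE"}
    f = pedigree_inbreeding(Pedigree(parents, sex=sexes))
    assert f["I"] == pytest.approx(0.25)
    assert f["K"] == pytest.approx(9 / 32)  # hand path-counting: 0.28125
    assert max(f.values()) >= 0.2


def test_pedigree_cycle_raises():
    with pytest.raises(PedigreeError):
        Pedigree({"a": ("b", None), "b": ("a", None)})


def test_parent_sex_consistency_enforced():
    with pytest.raises(PedigreeError):
        Pedigree({"kid": ("mum", "dad")},
                 sex={"mum": "FEMALE", "dad": "MALE"})


def test_kinship_matches_gene_dropping(rng):
    """Recursive F agrees with Monte-Carlo gene dropping."""
    ped = grandfather_granddaughter_pedigree()
    expect = pedigree_inbreeding(ped)["H"]
    n = 200_000
    alleles = {}
    next_id = 0
    for ind in ped.individuals:
        sire, dam = ped.parents[ind]
        if sire is None and dam is None:
            a = np.full(n, next_id); next_id += 1
            b = np.full(n, next_id); next_id += 1
            alleles[ind] = (a, b)
        else:
            pa = alleles[sire]
            ma = alleles[dam]
            pick_p = rng.integers(2, size=n)
            pick_m = rng.integers(2, size=n)
            alleles[ind] = (
                np.where(pick_p == 0, pa[0], pa[1]),
                np.where(pick_m == 0, ma[0], ma[1]),
            )
    ibd = np.mean(alleles["H"][0] == alleles["H"][1])
    se = math.sqrt(expect * (1 - expect) / n)
    assert abs(ibd - expect) < 4 * se


def test_kinship_symmetric_psd():
    ped = grandfather_granddaughter_pedigree()
    ids = ped.individuals
    memo = {}
    K = np.array([[kinship(ped, a, b, memo) for b in ids] for a in ids])
    assert np.allclose(K, K.T)
    assert np.linalg.eigvalsh(K).min() > -1e-10


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------


def test_assign_parents_full_recovery_on_complete_genotypes(trio_simulation):
    ped, sex_of, truth, freqs = trio_simulation
    offspring = [i for i in ped.parents if not ped.is_founder(i)]
    res = assign_parents(
        truth.subset(sample_ids=offspring), truth, sex_of, freqs,
        ParentageConfig(error_rate=0.0),
    )
    correct = 0
    for a in res:
        sire, dam = ped.parents[a.offspring_id]
        if a.sire_id == sire and a.dam_id == dam:
            correct += 1
    assert correct == len(offspring)


def test_missing_parent_never_yields_confident_wrong_pair(trio_simulation):
    ped, sex_of, truth, freqs = trio_simulation
    offspring = [i for i in ped.parents if not ped.is_founder(i)][:8]
    for off in offspring:
        sire, dam = ped.parents[off]
        candidates = truth.subset(
            sample_ids=[s for s in truth.sample_ids if s != sire]
        )
        res = assign_parents(
            truth.subset(sample_ids=[off]), candidates, sex_of, freqs,
            ParentageConfig(error_rate=0.01),
        )
        (a,) = res
        if a.confidence >= 0.8 and a.sire_id and a.dam_id:
            assert a.dam_id == dam  # never a confidently wrong pair


def test_empty_candidate_set_leaves_all_unassigned(trio_simulation):
    ped, sex_of, truth, freqs = trio_simulation
    off = [i for i in ped.parents if not ped.is_founder(i)][:3]
    empty = truth.subset(sample_ids=[])
    res = assign_parents(truth.subset(sample_ids=off), empty, sex_of, freqs)
    assert all(a.sire_id is None and a.dam_id is None for a in res)
    assert all(a.note == "unassigned" for a in res)
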