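"""Synthetic genotype datasets with the structure the monitoring pipeline expects.

The generator emulates a five-population canid system — wolf and dog close
together, golden jackal / red fox / raccoon dog as a distant group — using
the Balding-Nichols model: each population's allele frequency at a marker is
a Beta(p0(1-F)/F, (1-p0)(1-F)/F) draw around an ancestral frequency p0,
where F controls divergence.  The default panel composition is 81 high-MAF
autosomal markers (ancestral MAF uniform on 0.292-0.5), two wolf-jackal and
three wolf-dog diagnostic markers fixed for opposite alleles between their
species pair, nine X markers (ancestral MAF 0.125-0.333) and one
presence/absence Y marker.

Individuals descend from a pedigree (founders in HWE, offspring receiving
one allele per parent; sons take their single X from the dam); observed
samples add material-specific missingness, allelic dropout (het seen as
hom) and false alleles, scat samples are genotyped in duplicate, and urine
samples can be two-individual mixtures whose calls are the union of the
donors' alleles.  Genetically distant non-target species (bear/lynx/moose)
appear only as near-total amplification failures, which is how they present
on a canid assay.  Identical configuration and seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    CAT_HIGH_MAF,
    CAT_WOLF_DOG,
    CAT_WOLF_JACKAL,
    CAT_X_SEX,
    CAT_Y_SEX,
    CHROM_AUTOSOME,
    CHROM_X,
    CHROM_Y,
    MISSING,
    Y_DETECTED,
    GenotypeTable,
    MarkerInfo,
    SampleRecord,
    make_call,
)
from .parentage import Pedigree

WOLF_CLADE = ("wolf", "dog")
DISTANT_CLADE = ("jackal", "fox", "raccoon_dog")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    fst: float  # Balding-Nichols divergence from its clade's frequency
    n_individuals: int
    clade: str = "wolf_clade"


@dataclass(frozen=True)
class ErrorModel:
    """Per-call corruption rates for one sample material.

    ``degraded_rate`` is the fraction of physical samples whose DNA is too
    poor for reliable genotyping; a degraded sample's per-call missing rate
    is drawn uniformly from ``degraded_missing_range`` instead of
    ``missing_rate``.  Whole-sample failure, not independent per-call
    dropout, is what drives the material pass-rate ordering in real
    monitoring data (tissue > scat > urine > hair).
    """

    missing_rate: float
    dropout_rate: float  # het observed as a random hom
    false_allele_rate: float
    degraded_rate: float = 0.0
    degraded_missing_range: tuple[float, float] = (0.3, 0.95)

    def __post_init__(self) -> None:
        for r in (self.missing_rate, self.dropout_rate,
                  self.false_allele_rate, self.degraded_rate):
            if not 0 <= r <= 1:
                raise ValueError(f"error rate {r} outside [0, 1]")


#: material-specific defaults: tissue is near-perfect, scat worse, urine and
#: hair worst — the DNA quantity/purity ordering of non-invasive materials.
#: scat per-call error rates are calibrated so duplicate genotyping shows
#: ~0.001 mismatches per marker and mismatches in ~5% of replicate groups,
#: the repeatability level observed for microfluidic scat genotyping
DEFAULT_ERROR_MODELS: dict[str, ErrorModel] = {
    "tissue": ErrorModel(0.01, 0.0002, 0.00005, degraded_rate=0.0),
    "blood": ErrorModel(0.01, 0.0002, 0.00005, degraded_rate=0.0),
    "saliva": ErrorModel(0.05, 0.002, 0.0005, degraded_rate=0.05),
    "scat": ErrorModel(0.05, 0.0008, 0.0002, degraded_rate=0.12),
    "urine": ErrorModel(0.10, 0.01, 0.002, degraded_rate=0.33),
    "hair": ErrorModel(0.12, 0.02, 0.003, degraded_rate=0.5),
    "unknown": ErrorModel(0.10, 0.005, 0.001, degraded_rate=0.1),
}


@dataclass(frozen=True)
class SimConfig:
    n_high_maf: int = 81
    n_wolf_jackal: int = 2
    n_wolf_dog: int = 3
    n_x: int = 9
    n_y: int = 1
    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("wolf", 0.03, 40, clade="wolf_clade"),
        PopulationSpec("dog", 0.08, 40, clade="wolf_clade"),
        PopulationSpec("jackal", 0.05, 10, clade="distant"),
        PopulationSpec("fox", 0.05, 10, clade="distant"),
        PopulationSpec("raccoon_dog", 0.05, 10, clade="distant"),
    )
    #: divergence of each clade's shared frequency from the ancestral p0;
    #: the distant canids cluster together, far from the wolf/dog pair
    clade_fst: Mapping[str, float] = field(
        default_factory=lambda: {"wolf_clade": 0.0, "distant": 0.30}
    )
    maf_range: tuple[float, float] = (0.292, 0.500)
    #: Beta shape of the ancestral MAF draw over maf_range; markers enter a
    #: monitoring panel because they were ascertained for the highest MAF, so
    #: the density rises toward 0.5 (shape (1.74, 1) puts the mean at 0.424)
    maf_shape: tuple[float, float] = (1.74, 1.0)
    x_maf_range: tuple[float, float] = (0.125, 0.333)
    error_models: Mapping[str, ErrorModel] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_MODELS)
    )
    n_replicates: Mapping[str, int] = field(default_factory=lambda: {"scat": 2})
    contamination_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie inside (0, 0.5]")
        if not 0 <= self.contamination_rate <= 1:
            raise ValueError("contamination_rate outside [0, 1]")
        for p in self.populations:
            if p.fst != 0 and not (0 < p.fst < 1):
                raise ValueError(f"population {p.name}: F={p.fst} outside [0, 1)")
        for c, f in self.clade_fst.items():
            if f != 0 and not (0 < f < 1):
                raise ValueError(f"clade {c}: F={f} outside [0, 1)")

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]


@dataclass
class TruthSet:
    """Ground truth for every emitted sample."""

    individual_of_sample: dict[str, str]
    species_of_individual: dict[str, str]
    sex_of_individual: dict[str, str]
    pedigree: Pedigree | None
    replicate_group_of_sample: dict[str, str]
    contamination: dict[str, tuple[str, str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Markers and frequencies
# ---------------------------------------------------------------------------


def make_markers(config: SimConfig) -> list[MarkerInfo]:
    markers = []
    pos = 0
    for k in range(config.n_high_maf):
        pos += 1_000_000
        markers.append(MarkerInfo(f"HM_{k + 1:03d}", CHROM_AUTOSOME, pos,
                                  ("A", "G"), CAT_HIGH_MAF))
    for k in range(config.n_wolf_jackal):
        pos += 1_000_000
        markers.append(MarkerInfo(f"WJ_{k + 1:02d}", CHROM_AUTOSOME, pos,
                                  ("A", "G"), CAT_WOLF_JACKAL))
    for k in range(config.n_wolf_dog):
        pos += 1_000_000
        markers.append(MarkerInfo(f"WD_{k + 1:02d}", CHROM_AUTOSOME, pos,
                                  ("A", "G"), CAT_WOLF_DOG))
    for k in range(config.n_x):
        markers.append(MarkerInfo(f"X_{k + 1:02d}", CHROM_X,
                                  (k + 1) * 1_000_000, ("A", "G"), CAT_X_SEX))
    for k in range(config.n_y):
        markers.append(MarkerInfo(f"Y_{k + 1:02d}", CHROM_Y,
                                  (k + 1) * 1_000_000, ("Y", "Y"), CAT_Y_SEX))
    return markers


def balding_nichols(p0: float, fst: float, rng: np.random.Generator) -> float:
    """One Balding-Nichols draw: Beta around p0 with divergence fst."""
    if fst == 0:
        return p0
    if not 0 < fst < 1:
        raise ValueError(f"F must lie in (0, 1), got {fst}")
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    return float(rng.beta(a, b))


def simulate_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-population frequency of the counted ('G') allele per marker.

    High-MAF and X markers get a shared ancestral frequency p0, one
    Balding-Nichols draw per clade around p0 (divergence ``clade_fst``),
    and one draw per population around its clade frequency (divergence
    ``PopulationSpec.fst``).  The hierarchy makes the distant canids cluster
    together, well away from the wolf/dog pair, while wolves and dogs stay
    close.  Diagnostic markers are fixed 1 vs 0 between their species pair
    (the wolf clade carries the wolf allele at wolf-jackal markers;
    non-pair populations sit at 0.5 for wolf-dog markers).  The Y row is a
    presence marker and is set to 1.
    """
    rng = rng or np.random.default_rng(config.seed)
    markers = make_markers(config)
    clades = sorted({p.clade for p in config.populations})
    rows = {}

    def hierarchical_draw(p0: float) -> dict[str, float]:
        clade_p = {
            c: balding_nichols(p0, float(config.clade_fst.get(c, 0.0)), rng)
            for c in clades
        }
        return {
            p.name: balding_nichols(clade_p[p.clade], p.fst, rng)
            for p in config.populations
        }

    lo, hi = config.maf_range
    for m in markers:
        if m.category == CAT_HIGH_MAF:
            p0 = lo + (hi - lo) * float(rng.beta(*config.maf_shape))
            rows[m.marker_id] = hierarchical_draw(p0)
        elif m.category == CAT_X_SEX:
            rows[m.marker_id] = hierarchical_draw(
                float(rng.uniform(*config.x_maf_range))
            )
        elif m.category == CAT_WOLF_JACKAL:
            rows[m.marker_id] = {
                p.name: 1.0 if p.name in WOLF_CLADE else 0.0
                for p in config.populations
            }
        elif m.category == CAT_WOLF_DOG:
            rows[m.marker_id] = {
                p.name: (1.0 if p.name == "wolf" else
                         0.0 if p.name == "dog" else 0.5)
                for p in config.populations
            }
        else:  # Y presence marker
            rows[m.marker_id] = {p.name: 1.0 for p in config.populations}
    return pd.DataFrame.from_dict(rows, orient="index")[config.population_names]


# ---------------------------------------------------------------------------
# Individuals
# ---------------------------------------------------------------------------


def _founder_alleles(
    m: MarkerInfo, p_g: float, sex: str, rng: np.random.Generator
) -> tuple[str, ...]:
    a_lo, a_hi = sorted(m.alleles)

    def draw() -> str:
        return a_hi if rng.random() < p_g else a_lo

    if m.chrom_class == CHROM_Y:
        return (Y_DETECTED,) if sex == "MALE" else ()
    if m.chrom_class == CHROM_X and sex == "MALE":
        return (draw(),)
    return (draw(), draw())


def _alleles_to_call(alleles: tuple[str, ...], chrom_class: str) -> str:
    if chrom_class == CHROM_Y:
        return Y_DETECTED if alleles else MISSING
    if len(alleles) == 1:  # hemizygous male X reported as a homozygote
        return make_call(alleles[0], alleles[0])
    return make_call(alleles[0], alleles[1])


def simulate_individuals(
    freqs: pd.DataFrame,
    pedigree: Pedigree,
    population_of: Mapping[str, str],
    sex_of: Mapping[str, str],
    markers: Sequence[MarkerInfo],
    rng: np.random.Generator,
) -> GenotypeTable:
    """True genotypes for every pedigree individual.

    Founders are drawn from HWE at their population's frequencies;
    offspring receive one allele from each parent (sons take their only X
    from the dam and the Y from the sire).  Missing parents are replaced by
    a population draw.
    """
    alleles: dict[str, dict[str, tuple[str, ...]]] = {}
    for ind in pedigree.individuals:  # topological order
        sex = sex_of[ind]
        pop = population_of[ind]
        sire, dam = pedigree.parents[ind]
        geno: dict[str, tuple[str, ...]] = {}
        for m in markers:
            p_g = float(freqs.loc[m.marker_id, pop])
            if pedigree.is_founder(ind):
                geno[m.marker_id] = _founder_alleles(m, p_g, sex, rng)
                continue

            def gamete(parent: str | None) -> str:
                if parent is None:
                    a_lo, a_hi = sorted(m.alleles)
                    return a_hi if rng.random() < p_g else a_lo
                pa = alleles[parent][m.marker_id]
                return pa[int(rng.integers(len(pa)))]

            if m.chrom_class == CHROM_Y:
                geno[m.marker_id] = (Y_DETECTED,) if sex == "MALE" else ()
            elif m.chrom_class == CHROM_X:
                if sex == "MALE":
                    geno[m.marker_id] = (gamete(dam),)  # maternal X only
                else:
                    geno[m.marker_id] = (gamete(sire), gamete(dam))
            else:
                geno[m.marker_id] = (gamete(sire), gamete(dam))
        alleles[ind] = geno

    ids = list(pedigree.individuals)
    by_class = {m.marker_id: m.chrom_class for m in markers}
    calls = np.array(
        [[_alleles_to_call(alleles[i][m.marker_id], by_class[m.marker_id])
          for m in markers] for i in ids],
        dtype=object,
    ).reshape(len(ids), len(markers))
    return GenotypeTable(ids, [m.marker_id for m in markers], calls)


# ---------------------------------------------------------------------------
# Observation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplePlan:
    sample_id: str
    individual_id: str
    material: str
    replicate_group: str


def _corrupt_call(
    call: str, m: MarkerInfo, em: ErrorModel, rng: np.random.Generator,
    missing_rate: float | None = None,
) -> str:
    miss = em.missing_rate if missing_rate is None else missing_rate
    if m.chrom_class == CHROM_Y:
        if call == Y_DETECTED and rng.random() < miss:
            return MISSING
        return call
    if rng.random() < miss:
        return MISSING
    if call == MISSING:
        return MISSING
    from .genotype_io import call_alleles, is_het

    a, b = call_alleles(call)
    if a != b and rng.random() < em.dropout_rate:
        keep = a if rng.random() < 0.5 else b
        return make_call(keep, keep)
    if rng.random() < em.false_allele_rate:
        lo, hi = sorted(m.alleles)
        flip_first = rng.random() < 0.5
        if flip_first:
            a = hi if a == lo else lo
        else:
            b = hi if b == lo else lo
        return make_call(a, b)
    return call


def _mix_calls(call_a: str, call_b: str, m: MarkerInfo) -> str:
    """Union-of-alleles collapse for a two-individual mixture."""
    from .genotype_io import call_alleles

    if m.chrom_class == CHROM_Y:
        return Y_DETECTED if Y_DETECTED in (call_a, call_b) else MISSING
    pool: list[str] = []
    for c in (call_a, call_b):
        if c != MISSING:
            pool.extend(call_alleles(c))
    if not pool:
        return MISSING
    uniq = sorted(set(pool))[:2]  # biallelic truncation
    return make_call(uniq[0], uniq[-1])


def corrupt_samples(
    truth: GenotypeTable,
    plan: Sequence[SamplePlan],
    markers: Sequence[MarkerInfo],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeTable, list[SampleRecord], dict[str, tuple[str, str]]]:
    """Apply the material error model (and urine contamination) to a plan.

    Each planned sample copies its individual's true genotype, urine samples
    become a two-donor mixture with probability ``contamination_rate``
    (union of alleles per locus, Y detected if either donor is male), then
    per-call missingness / allelic dropout / false alleles are applied at
    that material's rates.  Returns the observed table, sample records and
    the contamination map (sample -> ordered donor pair).
    """
    by_id = {m.marker_id: m for m in markers}
    marker_ids = list(truth.marker_ids)
    calls = np.full((len(plan), len(marker_ids)), MISSING, dtype=object)
    records = []
    contamination: dict[str, tuple[str, str]] = {}
    inds = list(truth.sample_ids)

    # DNA quality is a property of the physical extract, so replicates of one
    # sample share their (possibly degraded) per-call missing rate
    miss_of_group: dict[str, float] = {}
    for i, sp in enumerate(plan):
        em = config.error_models.get(sp.material, DEFAULT_ERROR_MODELS["unknown"])
        if sp.replicate_group not in miss_of_group:
            if rng.random() < em.degraded_rate:
                miss_of_group[sp.replicate_group] = float(
                    rng.uniform(*em.degraded_missing_range)
                )
            else:
                miss_of_group[sp.replicate_group] = em.missing_rate
        miss = miss_of_group[sp.replicate_group]
        base = dict(zip(marker_ids, truth.sample_calls(sp.individual_id)))
        if (
            sp.material == "urine"
            and len(inds) > 1
            and rng.random() < config.contamination_rate
        ):
            others = [x for x in inds if x != sp.individual_id]
            donor = others[int(rng.integers(len(others)))]
            donor_calls = dict(zip(marker_ids, truth.sample_calls(donor)))
            base = {
                mid: _mix_calls(base[mid], donor_calls[mid], by_id[mid])
                for mid in marker_ids
            }
            contamination[sp.sample_id] = (sp.individual_id, donor)
        for j, mid in enumerate(marker_ids):
            calls[i, j] = _corrupt_call(base[mid], by_id[mid], em, rng, miss)
        records.append(
            SampleRecord(
                sample_id=sp.sample_id,
                material=sp.material,
                replicate_group=sp.replicate_group,
            )
        )
    table = GenotypeTable([sp.sample_id for sp in plan], marker_ids, calls)
    return table, records, contamination


# ---------------------------------------------------------------------------
# Whole-dataset conveniences
# ---------------------------------------------------------------------------


def unrelated_pedigree(
    names: Sequence[str], sexes: Mapping[str, str]
) -> Pedigree:
    return Pedigree({n: (None, None) for n in names}, sex=dict(sexes))


def random_family_pedigree(
    n_founders: int,
    n_offspring: int,
    rng: np.random.Generator,
    prefix: str = "W",
) -> tuple[Pedigree, dict[str, str]]:
    """Founders plus offspring of random male x female founder/descendant pairs."""
    sex_of: dict[str, str] = {}
    parents: dict[str, tuple[str | None, str | None]] = {}
    ids: list[str] = []
    for k in range(n_founders):
        ind = f"{prefix}_F{k + 1:03d}"
        sex_of[ind] = "MALE" if rng.random() < 0.5 else "FEMALE"
        parents[ind] = (None, None)
        ids.append(ind)
    for k in range(n_offspring):
        males = [i for i in ids if sex_of[i] == "MALE"]
        females = [i for i in ids if sex_of[i] == "FEMALE"]
        ind = f"{prefix}_O{k + 1:03d}"
        sire = males[int(rng.integers(len(males)))] if males else None
        dam = females[int(rng.integers(len(females)))] if females else None
        sex_of[ind] = "MALE" if rng.random() < 0.5 else "FEMALE"
        parents[ind] = (sire, dam)
        ids.append(ind)
    return Pedigree(parents, sex=sex_of), sex_of


def simulate_reference_dataset(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeTable, list[MarkerInfo], dict[str, str], dict[str, str], pd.DataFrame]:
    """Unrelated reference individuals from every configured population.

    Returns (true genotypes, markers, population label per sample, sex per
    sample, per-population frequencies).  Reference genotypes are clean
    (tissue-grade truth) — corruption belongs to the monitoring samples.
    """
    rng = rng or np.random.default_rng(config.seed)
    markers = make_markers(config)
    freqs = simulate_frequencies(config, rng)
    names: list[str] = []
    pop_of: dict[str, str] = {}
    sex_of: dict[str, str] = {}
    for p in config.populations:
        for k in range(p.n_individuals):
            ind = f"{p.name}_{k + 1:03d}"
            names.append(ind)
            pop_of[ind] = p.name
            sex_of[ind] = "MALE" if rng.random() < 0.5 else "FEMALE"
    ped = unrelated_pedigree(names, sex_of)
    table = simulate_individuals(freqs, ped, pop_of, sex_of, markers, rng)
    return table, markers, pop_of, sex_of, freqs


#: the material mix of one real monitoring season (scat, urine, tissue, hair)
SEASON_MATERIAL_MIX: tuple[tuple[str, int], ...] = (
    ("scat", 188), ("urine", 74), ("tissue", 16), ("hair", 4),
)


def simulate_season(
    config: SimConfig | None = None,
    n_individuals: int = 140,
    material_mix: Sequence[tuple[str, int]] = SEASON_MATERIAL_MIX,
    n_founders: int = 60,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeTable, list[SampleRecord], TruthSet, list[MarkerInfo], pd.DataFrame]:
    """One synthetic monitoring season.

    ``n_individuals`` wolves (founders plus family-line offspring, so
    parentage has something to find) are sampled under the configured
    material mix; every individual receives at least one sample and the
    remainder are spread at random, so a few animals accumulate many
    samples.  Scat samples are emitted in duplicate per the replicate
    policy.  Returns observed genotypes, sample records, the truth set,
    markers, and the frequency table.
    """
    cfg = config or SimConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    markers = make_markers(cfg)
    freqs = simulate_frequencies(cfg, rng)

    ped, sex_of = random_family_pedigree(
        n_founders, max(0, n_individuals - n_founders), rng
    )
    inds = list(ped.individuals)
    pop_of = {i: "wolf" for i in inds}
    truth_table = simulate_individuals(freqs, ped, pop_of, sex_of, markers, rng)

    materials = [m for m, n in material_mix for _ in range(n)]
    rng.shuffle(materials)
    n_samples = len(materials)
    owners = list(inds)
    if n_samples > len(inds):
        extra = rng.choice(len(inds), size=n_samples - len(inds), replace=True)
        owners += [inds[i] for i in extra]
    rng.shuffle(owners)
    owners = owners[:n_samples]

    plan: list[SamplePlan] = []
    rep_group_of: dict[str, str] = {}
    ind_of: dict[str, str] = {}
    for k, (mat, ind) in enumerate(zip(materials, owners)):
        group = f"S{k + 1:04d}"
        n_rep = cfg.n_replicates.get(mat, 1)
        for r in range(n_rep):
            sid = group if n_rep == 1 else f"{group}_r{r + 1}"
            plan.append(SamplePlan(sid, ind, mat, group))
            rep_group_of[sid] = group
            ind_of[sid] = ind

    observed, records, contamination = corrupt_samples(
        truth_table, plan, markers, cfg, rng
    )
    records = [
        SampleRecord(
            sample_id=r.sample_id, material=r.material,
            replicate_group=r.replicate_group,
        )
        for r in records
    ]
    truth = TruthSet(
        individual_of_sample=ind_of,
        species_of_individual={i: "wolf" for i in inds},
        sex_of_individual=dict(sex_of),
        pedigree=ped,
        replicate_group_of_sample=rep_group_of,
        contamination=contamination,
    )
    return observed, records, truth, markers, freqs
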