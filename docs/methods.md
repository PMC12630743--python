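# Methods

This note documents the models, defaults and numerical choices behind
`snpmon`, and what the synthetic-data generator does and does not emulate.

## Data model

Genotypes are unordered biallelic allele pairs normalised to a canonical
string (`A/G` ≡ `G/A`); missing is the empty string. The Y marker is a
presence/absence assay stored as a detected call or missing — an endpoint
array cannot distinguish "female, no Y" from "male, failed reaction" at a
single locus, so absence of Y is only ever *evidence* for female, never
proof. Hemizygous male X calls arrive as homozygous-looking calls, exactly
as genotyping arrays report them. Supported formats are PLINK text PED/MAP
and a long sample × assay × call CSV as exported by array scoring software;
the long-format schema (`sample_id, assay_id, allele1, allele2`, with
`No Call` and `NTC` tokens) is an assumption documented here because vendor
export schemas vary.

## Panel design

The selection cascade runs: per-sample call-rate filter (default ≥ 0.85),
per-marker call-rate filter (≥ 0.90; complete failure is reported as "No
amplification", partial as "Low amplification"), windowed LD pruning
(window 50, step 5, r² > 0.2 drops the lower-MAF member; ties drop the
later map position), an exact HWE screen (design α = 0.001), then category
rules: diagnostic markers require a fixed difference (Weir–Cockerham
θ = 1) between their species pair; individual-ID markers require
MAF ≥ 0.3; X markers require female MAF in 0.125–0.333 and male MAF ≤
0.005 (a male X marker showing heterozygotes is mis-mapped or
pseudoautosomal). The LD and HWE screens run on the focal population only:
pooling divergent species would manufacture Wahlund-effect HWE failure and
cross-species LD at exactly the diagnostic markers the panel needs.
Markers can be rejected for several reasons at once and are counted once
per reason in the attrition report, which also accepts externally supplied
wet-lab reasons ("NTC up", "Readability") that no statistical filter can
produce.

r² is computed on genotype dosages (0/1/2), not EM-phased haplotypes — a
deliberate simplification: the panel is designed to be unlinked, where the
two estimators agree. The HWE test is the exact conditional test (sum of
probabilities ≤ the observed configuration's, over heterozygote counts of
matching parity), computed in log space with a 1 + 10⁻¹² relative guard on
the ≤ comparison so equal-probability support points are never dropped to
floating-point noise. F_ST is the two-population Weir–Cockerham
variance-components θ, NaN when the locus is monomorphic overall.

## Replicate QC

Scat DNA is degraded, so scat samples are genotyped in duplicate.
Consensus per locus: all non-missing replicates agree → keep the call; any
disagreement → missing plus one counted mismatch; all missing → missing.
Consensus is computed before the pass filter (both orders are supported;
after-consensus is the default because the duplicate exists precisely to
rescue borderline samples). The pass threshold is a per-material call-rate
cutoff, default 0.80 for all materials — the exact operational cutoff of a
monitoring program is a policy choice, so it is configuration, not code.
Error rates against a trusted reference count one allelic mismatch per
locus where one call is heterozygous and the other homozygous, or the two
are opposite homozygotes; panel-missing loci are tallied separately as
dropouts, not errors. The Y marker is removed from female call-rate
denominators so females are not penalised for expected Y absence.

## Species assignment

Reference groups pool labelled genotypes (optionally filtered by supplied
ancestry coefficients, default threshold Q ≥ 0.85). Group allele
frequencies are posterior means under a symmetric Dirichlet(1/2, 1/2)
prior, so no genotype ever has zero likelihood; a sample's log-likelihood
per group sums log HWE genotype probabilities over called loci, and
posteriors use equal group priors. Leave-one-out validation subtracts each
member's alleles from its own group's counts before scoring it. PCA
centres per-marker dosages on the reference means, imputes missing to the
mean, and projects queries onto axes computed from the reference only.
Genetically distant non-target species (bear, lynx, moose) are handled
upstream: their samples barely amplify on a canid assay and fail the QC
pass filter before assignment.

## Sexing

The X statistic is the method-of-moments homozygosity excess
F = (O_hom − E_hom)/(L − E_hom), with E_hom = Σ(1 − 2pq) from reference
*female* allele frequencies (no small-sample correction: the reference set
is treated as the population). Defaults: MALE needs Y detected and
F ≥ 0.8 (or F undefined); FEMALE needs Y absent and F ≤ 0.2; at least 5
typed X markers. A detected Y whose X statistic fails to confirm a male is
flagged as conflicting indicators — a single male cannot be heterozygous
on the X — which is the signature of male+female cross-contamination in
over-marked urine. The flag rule is deliberately broader than "F in the
female zone": with nine X markers of modest MAF, a mixture's homozygote
count regularly lands between the male and female zones, and only the
positive-confirmation rule catches ≥ 95% of mixtures. Females homozygous
at every X marker (common in inbred packs) are indistinguishable from
males with a failed Y reaction; they come out UNCERTAIN, never
FEMALE-by-default, and `tune_thresholds` reports them as the irreducible
conflict set when tuning against known sexes (grid search maximising
called fraction subject to zero mis-calls; ties prefer the widest
UNCERTAIN band).

## Individual identification

Samples are compared by allele mismatches over jointly called loci; a pair
is linkable when it overlaps at ≥ 79 loci (the practical floor for robust
identification) and mismatches at ≤ 16 loci, or at a data-driven threshold:
the midpoint of the widest empty gap (minimum width 3) between the
same-individual mode near zero and the different-individual mass in the
mismatch histogram, falling back to the configured default when no such
gap exists. Connected components under single linkage are the individuals
— transitive identity is the monitoring semantics, and the threshold
controls the chaining risk. Consensus genotypes use per-locus majority
with ties recoded missing, consistent with the replicate rule. Identity
statistics deliberately understate the practical marker requirement: PID
and PIDsib assume an ideal HWE population, while real monitoring data add
inbreeding, dropout and missingness, which is why the pipeline requires
~79 overlapping loci although PIDsib says ~18–19 suffice.

## Parentage and inbreeding

Parentage is an exclusion + LOD scheme, a desk-scale substitute for
full-likelihood sibship tools (which are explicitly not reimplemented).
Dyads are excluded when offspring and candidate share no allele at more
than ⌈2εL⌉ loci (ε defaults to 0.01, the conventional per-locus error
assumption); trios when no gamete combination can produce the offspring.
The LOD per locus is log₁₀ of [(1−ε)·P(offspring | transmission) +
ε·P(offspring | HWE)] over P(offspring | HWE); at ε = 0 this collapses to
pure exclusion (−∞ at any incompatible locus). The best pair among
sex-compatible candidates (unknown-sex candidates enter both sides, the
top 8 per side by dyad LOD form the pair pool) wins; confidence is the
posterior over surviving hypotheses where the no-parent hypothesis carries
prior mass 1 − 0.9 ("probability parents are in the data" re-expressed as
prior odds). A known limitation of pairwise parentage without age data: an
offspring's own child is dyad-compatible by symmetry, and with a nonzero
error allowance a child-plus-true-parent trio can occasionally outscore
the true pair; with complete error-free genotypes and ε = 0, exclusion
removes such trios and recovery is exact in simulation. Pedigree
inbreeding uses the classic recursion φ(a,a) = (1+F_a)/2,
φ(a,b) = [φ(sire_a,b)+φ(dam_a,b)]/2 with founders unrelated and
non-inbred; missing parents count as unrelated founders.

## Synthetic data: what it emulates, and what it does not

Allele frequencies follow a hierarchical Balding–Nichols model: an
ancestral frequency p0 per marker, one Beta draw per *clade* around p0
(wolf/dog clade F = 0, distant-canid clade F = 0.30), then one draw per
population around its clade frequency (wolf 0.03, dog 0.08,
jackal/fox/raccoon dog 0.05). The hierarchy makes the three distant
species cluster together, far from the wolf/dog pair, while wolves and
dogs stay close — the structure a canid assay ascertained on dogs actually
shows. Ancestral MAF for the 81 individual-ID markers is drawn from a
Beta(1.74, 1) scaled to 0.292–0.500: panels are built from markers
*ascertained for the highest MAF*, so the density rises toward 0.5 and the
mean sits at 0.424; measured sample MAFs average slightly lower because
estimates near 0.5 fold downward. X-marker MAF is uniform on 0.125–0.333.
Diagnostic markers are fixed 1 vs 0 between their species pair.

Individuals descend from explicit pedigrees (founders in HWE; offspring
take one allele per parent; sons take their single X from the dam and the
Y from the sire). The observation model applies, per material: a per-call
missing rate, an allelic dropout rate (heterozygote observed as a random
homozygote), and a false-allele rate — plus a *degraded-sample* fraction
whose missing rate is drawn from 0.3–0.95, shared by all replicates of the
physical extract, because DNA quality is a property of the sample, not the
reaction. Scat per-call error rates are calibrated so duplicate
genotyping reproduces the observed repeatability of microfluidic scat
genotyping (~0.001 mismatches per marker; mismatching duplicates in
roughly 5–10% of passing groups); the remaining material rates are free
parameters chosen to reproduce the qualitative pass ordering
tissue > scat > urine > hair and are documented in
`synthetic_data.DEFAULT_ERROR_MODELS`. Urine samples become two-donor
mixtures with probability 0.05 (union of alleles truncated to a biallelic
call; Y detected if either donor is male). Distant non-canid species are
emulated purely as near-total amplification failure, which is how they
present on a canid assay.

The generator does **not** emulate: linkage or recombination (markers are
unlinked by design, matching a post-pruning panel), ascertainment bias
beyond the clade structure, genotype-intensity/cluster-scoring artefacts,
population substructure within wolves, or age structure. Passing tests
therefore demonstrate correctness of the algorithms under the stated
error model, not field performance on any real population.

Default problem sizes (a 282-sample season from 140 individuals, a
110–200-member reference set, 36 unrelated individuals for identity
statistics, 20-founder/25-offspring pedigrees) were chosen as typical
one-season workloads for this kind of monitoring program; all are
configuration, and identical configuration plus seed reproduces identical
datasets byte for byte.

## Pipeline policy choices

The season pipeline never deletes suspect data: contaminated-looking,
single-occurrence, near-threshold and urine samples are written to a
scrutiny list for the analyst, because discarding is a judgement call.
Samples assigned to the wolf/dog group are exported for confirmatory
genotyping on a dedicated wolf–dog panel rather than classified further —
PCA separates dogs from wolves, but hybrid-generation classification needs
markers this panel does not carry. All thresholds actually applied are
logged.
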