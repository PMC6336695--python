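# Methods

`famseg` reimplements a two-armed variant-discovery analysis for multiplex
families sequenced by whole-exome sequencing: a *conventional* arm that
prioritises rare, predicted-deleterious variants carried by probands, and a
*co-segregation* arm that scores every proband-carried variant by two-point
parametric linkage with the disease phenotype. Because the motivating study
design (four multiplex families ascertained through probands with severe
left-sided cardiovascular malformations) has no public genotype data, the
package ships a synthetic cohort generator that reproduces the statistical
structure of such a cohort, so every stage is runnable and testable from a
seed alone.

## Quality control

QC operates at two levels, in a fixed cascade whose order is part of the
contract (per-reason counts depend on it):

1. **Genotype blanking.** A call is blanked (genotype set missing; depth and
   quality untouched) unless 20X ≤ DP ≤ 250X and GQ ≥ 20. Missing DP/GQ
   counts as failing.
2. **Site filters**, first-fail reason recorded: *indel* (ref/alt length
   difference after multiallelic decomposition), *low call rate* (< 80%
   non-missing), *excess alt carriers* (alt called in strictly more than 30%
   of individuals — a joint-calling artifact signature in a small related
   cohort), *non-autosome*.

Both the call rate and the carrier fraction use **all sequenced
individuals** as denominator, not non-missing calls; the 30% rule is
deliberately strict ("more than"). These choices are configurable
(`QcThresholds`).

## Conventional arm (RVIS)

A variant is a *rare variant with informatics support* when

- every population panel reporting it has minor-allele frequency ≤ 1%
  (panel alt frequencies are folded to `min(f, 1−f)` first; a variant
  unobserved in all panels counts as rare),
- its CADD-Phred score is ≥ 20 (a missing score is not support), and
- at least one proband carries the alt allele.

Sub-reports mirror the usual triage of such a list: sharing across probands
at variant level and at gene level (families can share a gene without
sharing a variant), stop-gain and ClinVar-pathogenic subsets, proband
homozygotes, and nested MAF tiers (≤1%, ≤0.1%, ≤0.01%).

## Co-segregation arm (two-point linkage)

### Model

The disease model is dominant with reduced penetrance: disease allele
frequency 0.01, penetrance 0.8 for carriers (one or two copies), phenocopy
rate 0 for non-carriers — all four numbers configurable (`DiseaseModel`).
Unknown phenotypes contribute a factor of 1. Each variant is treated as a
biallelic marker; its founder allele frequency comes either from the
annotation panels (mean over present panels) or, by default, from a
pseudocounted founder estimate `(alt+1)/(2·called+2)` clamped to
[0.001, 0.999] — founder counts in four families are sparse, hence the
pseudocount.

The likelihood is the standard two-locus pedigree likelihood: each
individual carries an ordered diplotype (paternal and maternal haplotype,
each pairing a disease allele with a marker allele; 16 states), founders
draw from Hardy–Weinberg with linkage equilibrium between the loci,
non-founders from Mendelian transmission with recombination fraction θ, and
evidence enters through penetrance factors and marker-genotype indicators.
The two-point LOD is `log10 L(θ) − log10 L(1/2)`, evaluated on a θ grid
(default 0 to 0.5 in steps of 0.01; the large simulation benchmarks use a
0.05-step grid — at that resolution the ranking of variants, which is what
those benchmarks measure, is unchanged while the scan is 5× cheaper).

### Evaluation

Loop-free pedigrees are evaluated by Elston–Stewart peeling over nuclear
units with a single pivot each, vectorised across variants and θ values and
normalised per message with a running log-scale (no underflow at realistic
family sizes). Pedigrees with marriage loops fall back to a full
contraction of the diplotype factor graph (≤ 10–12 members). Both paths are
exposed and are cross-checked against each other — and, at tiny sizes,
against a literal 16^n summation written from first principles in the test
suite. Mendelian-impossible marker configurations are reported as a
distinct skip reason, never as numeric −∞ in output tables.

### Cumulative LOD and classification

Per-variant evidence is combined across families by **summing the per-θ
curves and then maximising over θ** (summing per-family maxima attained at
different θ overstates evidence; that simpler policy is available as
`sum-of-maxima`). θ ties break toward smaller θ. Classification:
*cosegregating* at cumulative LOD ≥ 1.0, *suggestive* ≥ 0.5, *excluded*
when the cumulative LOD **at θ = 0** is < −2 (the maximised LOD is pinned
≥ 0 because every curve is 0 at θ = 1/2, so exclusion must be judged at
tight linkage, the classical convention), else *neutral*.

### Theoretical maximum LOD

`theoretical_max_lod` answers "what could a perfect marker show in this
family?": it assigns disease-allele carriers by a greedy parsimonious
dominant closure (all affecteds carry; every carrier non-founder is given a
carrier parent, preferring affected, then unknown-phenotype parents;
unaffected parents are inadmissible at full penetrance), constructs a
private fully co-segregating marker (carriers heterozygous, everyone else
homozygous reference), and evaluates the LOD with founder phase clamped.
With phase known, every meiosis from a carrier parent contributes exactly
log10 2 at θ = 0, so the bound equals
`(#children of carrier parents) · log10 2` and dominates the phase-unknown
LOD a real biallelic marker can reach on the same data. A family whose
affecteds cannot be explained by any dominant assignment (affected child of
two unaffected parents at penetrance 1) raises an error suggesting a
phenocopy rate > 0.

A worked contrast that matters for interpretation: a bare nuclear family
with an affected doubly-heterozygous parent and k affected het children
reaches only `log10(1 / (2(1−q)·2^−k + q))` (≈ 0.589 for k = 3, q = 0.01)
because the parent's phase is unknown and a homozygous-carrier parent
cannot be excluded; the textbook `k·log10 2` requires the transmitting
parent's phase and heterozygosity to be certain, e.g. through a typed
unaffected grandparent. The closed-form tests use that phase-anchored
construction.

## Synthetic cohort generator

The generator inverts the analysis model. Defaults reproduce the motivating
study profile; all are configurable (`SimulationConfig`).

**Pedigrees.** Four families of 18/16/10/8 members (52 total), three
generations, built as a founder-couple spine with married-in founders and
child counts drawn to hit the target size exactly. Three of the four
families are *bilineal*: a second founder couple whose child marries into
the main line, so disease can enter through two lines of descent.

**Gene drop and phenotypes.** The causal variant is dropped through the
founders and transmitted Mendelianly; affection is sampled from the disease
model (penetrance 0.8 by default); the family is re-dropped until it
reaches its per-family affected target (4/5/5/3 ≈ the 22/31/50/38% disease
fractions of the profile), emulating the ascertainment that selects
multiplex families; one randomly chosen affected member per family is the
proband. In *table-matching mode* the sampled affection is replaced by
exactly the per-family target count (carriers first), giving the fixed
52-member / 17-affected profile for report fixtures.

**The causal variant is common but line-borne.** By default the causal
variant has population (panel) frequency 0.2 and a benign CADD score (5,
intronic) — the profile of variants that co-segregate in practice — but its
founder origin is controlled: only the disease-line founders carry it
(heterozygous), other founders are homozygous reference
(`CausalVariantSpec.cosegregating=True`). This is deliberate. An honestly
Hardy–Weinberg-dropped allele at frequency 0.2 makes ~36% of founders
carriers; in an ascertained family most founders then carry it, the marker
loses all linkage information, and the variant would in any case exceed the
30%-carrier artifact filter and never reach the scan. A variant that both
*survives QC* and *fully co-segregates* in such a cohort is, by
implication, one that entered each family through its disease lines —
which is what the generator builds. Setting ``cosegregating=False``
restores the plain Hardy–Weinberg drop (with bilineal families still
introducing the allele through both lines).

**Background variants.** 250 rare (log-uniform frequency in [1e-5, 0.01])
and 250 common (uniform in (0.01, 0.5]) sites per cohort by default,
dropped independently per family through Hardy–Weinberg founders; 5% of
background sites receive a deleterious score (CADD drawn in [20.5, 45],
stop-gain/missense/splice), the rest a benign one ([0.1, 19.5]); a small
fraction of deleterious rare sites get ClinVar pathogenic classes.

**Sequencing layer.** Depth is gamma-Poisson around 60X (shape 8), GQ is
truncated normal (80 ± 15, capped at 99), 2% of calls are missing, and
background genotypes suffer 0.1% random errors. `noise_free_sequencing()`
disables all of this for benchmarks that require clean transmission.

**Planted QC violations and exact ground truth.** A configured number of
sites deliberately violate each QC rule (50 indels, 30 low-call-rate, 20
excess-carrier, 10 non-autosomal by default), labeled in a truth table.
So that truth labels propagate *exactly* through QC and RVIS, the generator
enforces margin separation: blanked-plus-missing calls on non-planted sites
are capped below the call-rate threshold; background sites are
rejection-sampled (re-drop, then frequency halving) to stay at or below the
30%-carrier threshold (this thins the upper tail of the common-frequency
range and slightly lowers realised common-variant frequencies — a
deliberate trade of tail realism for label exactness); panel-frequency
jitter (multiplicative log-normal, σ = 0.15, emulating database/sample
divergence) is clipped to the rare/common side of the 1% boundary;
deleteriousness scores avoid the CADD-20 boundary; very rare variants
(frequency < 1e-4) are absent from each panel with probability 0.5; the
causal and planted-artifact sites carry their constructed genotypes
verbatim; and proband-carrier truth is recorded from the genotypes as
emitted (after blanking). The causal variant's own QC fate is recorded
honestly: if its observed carrier fraction exceeds 30% the truth table says
so.

### What the generator does and does not emulate

It reproduces family structure, Mendelian transmission, reduced penetrance,
ascertainment, sequencing noise at the genotype level, and
database-divergent annotations. It does **not** emulate linkage
disequilibrium between sites, read-level errors, mapping artifacts,
consequence–gene structure on a real genome, population stratification, or
relatedness across families. Tests passing on synthetic cohorts therefore
demonstrate the *pipeline's* correctness and the *statistical* behaviour of
the two arms under the stated model — not performance on real exomes.

## Numerical and degenerate-input choices

- All likelihoods in log10; per-message normalisation with a running
  log-scale; impossible configurations propagate as −inf internally and as
  explicit flags externally.
- `MarkerModel` rejects frequencies of exactly 0 or 1 (monomorphic markers
  are uninformative; exclude upstream).
- Empty C-SV sets report fractions of 0 by convention.
- θ grids must contain both 0 and 0.5; LOD(0.5) = 0 is asserted to 1e-9 on
  construction.
- Peeling requires loop-free pedigrees; loops are accepted at parse time,
  rejected only when a peeling order is requested, and handled by
  enumeration up to 12 members.
- Multiallelic VCF records are decomposed into one biallelic record per alt
  allele; the per-sample depth and quality are shared across the split
  records.

## Known limitations

- The 30%-carrier artifact filter and a common, truly population-frequent
  co-segregating variant are in tension: in a 52-member ascertained cohort
  such a variant often exceeds the filter. The discovery benchmark therefore
  measures the co-segregation arm on proband-carried variants directly;
  on real data a practitioner should be aware that this filter can remove
  exactly the common co-segregating candidates the linkage arm is designed
  to find.
- The greedy parsimonious carrier assignment is not guaranteed globally
  minimal on heavily bilineal pedigrees; the theoretical maximum it yields
  is then an upper bound for the assignment found, not the global optimum.
- Cumulative LOD assumes locus homogeneity across families under the
  shared model; no admixture/heterogeneity test is provided.
- X-linked models, multipoint linkage, liability classes, and CNVs are out
  of scope.
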