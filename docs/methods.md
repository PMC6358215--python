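# Methods

## The inheritance model

`drivesim` models the transmission genetics of CRISPR homing gene drives in
*Drosophila melanogaster* crosses, covering three architectures: a standard
homing drive (construct carries Cas9, gRNA and a dsRed marker), a split
drive (gRNA element at the target locus, Cas9 on an unlinked EGFP-marked
autosomal insertion), and synthetic-target drives that home into an
engineered EGFP gene. Each fly is a two-locus genotype: the target locus
(alleles `WILD`, `DRIVE`, `R1`, `R2`; X-linked or autosomal, males
hemizygous when X-linked) and the autosomal support locus (`CAS9` or
`ABSENT`).

Events occur in the causal order of a cross:

1. **Germline homing at gametogenesis.** In an exact drive/wild
   heterozygote with an available Cas9 source, the wild-type allele becomes
   `DRIVE` with probability *c* (sex-specific: `c_f`, `c_m`), a resistance
   allele with probability *r* (`r_f`, `r_m`), and stays wild otherwise;
   one of the two alleles is then transmitted uniformly. The drive
   transmission rate from a het parent is therefore (1 + *c*)/2 and the
   conversion efficiency is recovered as 2*p* − 1 from the dsRed fraction
   *p*. Resistance and drive homologs are never cut (their target site is
   destroyed). Any other genotype transmits Mendelianly.
2. **Fertilization.** The support locus segregates independently; fathers
   pass their X-linked target allele to daughters only.
3. **Early-embryo cutting.** Only when the mother deposited *both* Cas9 and
   gRNA (derived purely from her genotype: gRNA iff she carries a drive
   allele, Cas9 iff she carries any genomic Cas9 source), each wild-type
   zygotic allele is independently converted to resistance with
   probability `e_cut` or mosaically cut with probability `e_mosaic`
   (phenotype-visible, allele state unchanged and still convertible in the
   next generation's germline). Embryo cutting never produces drive
   alleles: homology-directed repair is assumed unavailable at that stage.

New resistance alleles are `R1` (function-preserving) with probability
`r1_fraction`, else `R2`. `r1_fraction` is a free parameter (default 0):
r1 formation is observed qualitatively but not rate-quantified, and allele
sequence diversity is not modelled.

**Cas9 carryover.** An individual with no genomic Cas9 whose own egg
received maternal Cas9 may retain enough protein for germline homing. The
model is deliberately two-level: a per-individual Bernoulli switch
`p_active` (default 15/16, matching the observed all-or-nothing pattern
in which one of sixteen exposed females showed no conversion), then
per-allele rates `c_carry`/`r_carry` replacing *c*/*r* when active.
Carryover has strictly one-generation memory — deposition into the next
egg is recomputed from genotype alone — so carryover effects vanish in
grandprogeny, a property the test suite checks by chaining three
generations.

## Genotype → phenotype

Markers are taken as fully penetrant and scorable: dsRed ⇔ ≥1 drive allele.
A recessive body-colour marker (yellow; *cinnabar*/*white* are handled
through the same channel since their recessive markers are genetically
isomorphic for every estimator here) shows when no functional target allele
remains; mosaic body/eye categories are emitted post-classification — the
≥50%-eye-coverage scoring rule is treated as already applied. For split
systems the EGFP channel reports carriage of the Cas9 supporting element;
for synthetic targets it reports the state of the target alleles
(full/mosaic/none). Fitness and viability differences between phenotype
classes are not modelled.

## Estimators and their pinned conventions

Estimators consume pooled phenotype counts (pooling across crosses before
estimation; a delete-one-cross jackknife SE is available as a secondary
uncertainty to flag between-female overdispersion). Denominators are pinned
per cross design:

* conversion efficiency — dsRed fraction over **all offspring** for
  maternal transmission and autosomal targets; **daughters only** for
  paternal X-linked transmission.
* embryo r2 (yellow readout) — full-yellow dsRed daughters / dsRed
  daughters. Mosaic-yellow daughters stay in the denominator only.
* embryo r2 (EGFP readout) — EGFP-none among dsRed progeny; **daughters
  only at X-linked targets**, because a dsRed son carries no paternal
  allele and would read as EGFP-none regardless of embryo activity.
* germline r2 from sons — 2 × (yellow non-dsRed sons)/(all sons), valid
  only when the mother deposits no Cas9 (no embryo cutting in that
  generation); the factor 2 accounts for sons sampling one of the mother's
  two germline products.

Uncertainty: binomial SE and Wilson 95% score intervals (efficiencies are
linear transforms, so SE and interval double). The published "±" convention
is not stated; neither quantity claims to reproduce it numerically.

Fisher's exact test (two-sided) is computed by hypergeometric enumeration,
summing all tables with fixed margins whose probability does not exceed the
observed table's (relative tie tolerance 1e−7; an all-zero table returns
p = 1 by convention). The test suite checks it exhaustively against exact
integer enumeration for every table with total ≤ 30 and against an
independent library implementation.

## Synthetic data and what passing tests show

The simulator doubles as the package's data generator. Its default
experiment scale — 40 crosses × 100 offspring, 50 replicates, master seed
split into per-cross substreams `(seed, cross index)` — gives standard
errors comparable to the published ±1–5% while keeping any recovery run
under a minute on one CPU. Defaults of `DriveParams` are the split-yellow
system (c_f = 0.74, e_cut = 0.74, p_active = 15/16, c_carry = 0.54); the
carryover-only cross uses c_carry = 0.38, r_carry = 0.12.

The generator emulates phenotype-count experiments faithfully at the level
of Mendelian segregation, homing, deposition gating and carryover, but not
several features of real data: brood-size variation and viability effects
(offspring counts are fixed per cross; the binomial SE understates real
overdispersion — hence the jackknife diagnostic), sex-ratio noise beyond
binomial 1:1, scoring error (markers perfectly penetrant), stage-resolved
germline timing (pre-gonial vs meiotic resistance formation is collapsed
into one germline outcome distribution, since no stage-resolved rates
exist), and sequence-level allele diversity. Parameter-recovery tests
therefore demonstrate estimator correctness *under the model*, not
robustness to these real-data features.

## Numerical choices

* All probabilities validated on construction (`c + r ≤ 1`,
  `e_cut + e_mosaic ≤ 1`, everything in [0, 1]).
* Efficiencies are never clamped: sub-Mendelian estimates come out
  negative by design.
* Zero denominators raise `UndefinedEstimateError` rather than returning
  NaN.
* Wilson bounds are clamped to exact 0/1 at the k = 0 / k = n boundaries
  where the closed form is exact but floating arithmetic is not; the Fisher
  p snaps to exactly 1 when the enumerated mass is complete up to float
  summation error.
* Recovery tolerance policy is 3 empirical SE of the replicate mean (not a
  fixed percentage), so checks stay valid if replicate counts are changed.

## Known limitations

Single-gRNA drives only; no multi-generation population/cage dynamics; no
fitness costs or off-target cutting. The two published anomalies — fully
yellow females that nonetheless converted, and the mechanism behind
location-specific embryo-cut differences — are not modelled. The
remainder fraction in the carryover-only cross (wild-type alleles that
were neither converted nor cut) is treated as 1 − c_carry − r_carry
without an independent check.
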