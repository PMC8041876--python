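# Methods

## Gene-content classification

KIR typing at presence/absence resolution yields, per subject, a flag
for each of 16 loci.  The **AA** genotype requires all nine A-genotype
loci present (3DL3, 2DL3, 2DL1, 2DP1, 3DP1, 2DL4, 3DL1, 2DS4, 3DL2)
*and* every B-specific locus absent (2DL2, 2DL5, 2DS1, 2DS2, 2DS3,
2DS5, 3DS1); everything else is **Bx**.  The rule partitions any cohort,
which the suite checks as a property over random profiles.

The linked clusters are scored as conjunctions: **C4** = 2DS2 ∧ 2DL2 ∧
2DS3 ∧ 2DL5, **T4** = 3DS1 ∧ 2DS5 ∧ 2DS1 ∧ 2DL5.  Presence/absence
typing does not resolve 2DL5A (telomeric) from 2DL5B (centromeric), so
both tests consult the single collapsed 2DL5 flag.  This is a stated
approximation: a subject carrying 2DL5B together with the three
telomeric T4 genes on another haplotype would be scored T4-positive
even though the bona fide cluster is split across haplotypes.

Profiles missing a framework gene (3DL3, 3DP1, 2DL4, 3DL2) are retained
and flagged *atypical* rather than dropped; with physical material such
profiles would be re-typed, which an in-silico pipeline cannot do.
When a framework-gene column is absent from an input file entirely the
gene is imputed present (framework genes ride on essentially all
haplotypes) and a warning is logged.

The genotype catalog assigns one record per distinct 16-bit pattern.
Published genotype numberings are cohort-specific, so the package ships
a pattern→identifier map only for the canonical AA pattern ("#40", the
one pattern whose gene content is unambiguous in prose); all other
patterns receive systematic IDs G1, G2, … in descending order of total
count, ties broken by ascending big-endian value of the pattern string.

## Ligand epitope assignment

Allele names are normalised to 2-field molecular resolution
(`C*04:01`); serologic names are rejected because sequencing-based
typing produces molecular names.  Epitopes come from a packaged
reference table: HLA-C alleles are C1 (Asn80) or C2 (Lys80); HLA-B
alleles are Bw4 or Bw6 by their residue 77–83 motif, with B*46:01 and
B*73:01 additionally carrying C1 (Val76 + Asn80); A*03/A*11 set the
A3/A11 flag.  Bw4-bearing HLA-A allotypes (A*23/24/25/32) count toward
Bw4 only under `include_hla_a_bw4` (default off — ligand studies of
this design typically score Bw4 on HLA-B, and the available denominators
cannot settle the question, so the choice is exposed as configuration).

The sequence-calling mode emulates bidirectional exon-2 sequencing: the
reverse read is reverse-complemented, both reads are matched
(IUPAC-ambiguity-aware substring) against the exon-2 library of the
locus-specific amplification group, and every consistent allele is
returned.  One amplification dialect is modelled: B*73:01 carries
reverse-primer-site mutations that defeat the HLA-B PCR but is amplified
by the HLA-C reaction, so locus-B calls never contain B*73:01 while
locus-C calls may.  Reads that each match reference alleles but share
none are an error (discordant chromatograms); reads matching nothing
yield an empty call with a warning.

The packaged reference is **synthetic**: real allele names and real
epitope assignments over constructed exon-2 backbones, with the
epitope-determining codons (76, 77–83, 80) faithful and the remainder
deterministic filler.  It contains ~15–25 alleles per locus, restricted
to allotypes whose epitope assignment is textbook-unambiguous.  A
translation oracle in the test suite recomputes every label from the
sequences independently.  Consequences: sequence *identity* is
meaningful only within this library (matching against real reads is out
of scope), and epitope-null or low-expression variants (e.g. C*04:09N)
are absent — the unknown-allele policy (error, or warn-and-skip) governs
anything outside the set.

## Combinations

The 12 tabulated receptor+ligand combinations are conjunctions of gene
presence, gene absence (rows marked "−"), and epitope positivity.  Flags
are tri-state: a combination is *not evaluable* for a subject untyped at
any HLA locus it references, and such subjects leave the row's
denominator — this is what makes per-row denominators vary (256, 233,
125 in a 278-control arm at realistic typing completeness).  The row
"2DL2+2DL3+C1+" is read literally (both genes required) by default; the
alternative reading (either C1 receptor) is available as
`c1_pair_mode="either"` since the row label is genuinely ambiguous.

## Association statistics

* **Fisher exact, two-tailed, point-probability rule**: conditioning on
  both margins, p is the sum of hypergeometric probabilities of all
  tables no more probable than the observed one.  Log-space
  computation; a relative slack of 1e-7 on log-probabilities absorbs
  floating-point error on exact ties.  The suite proves equality
  (1e-12) with an exact-rational enumeration oracle for all tables with
  row margins ≤ 12 and cross-checks against an independent library
  implementation on random tables.
* **Odds ratio** OR = ad/bc with the **Woolf logit CI**,
  exp(ln OR ± z·√(1/a+1/b+1/c+1/d)).  z = 1.96 by default (matching the
  convention of the published tables it reproduces); `z=None` selects
  the exact normal quantile.  Any zero cell triggers the
  Haldane–Anscombe +0.5 correction on all four cells, flagged on the
  result; two zero cells on a diagonal leave the OR undefined (error).
* **No multiple-testing correction** by default, matching the reporting
  convention of single-cohort immunogenetic scans; a Bonferroni
  annotation column is available.

Cases of unknown stage are stored under the label `case` and pooled
into the "all cases" contrast only; early/advanced contrasts use their
own labels.  (The three-label scheme of the cohort schema is thereby
extended by one label, the minimal way to honour varying stage
completeness.)

### Reproduction of published values

All published odds ratios and CI bounds that are arithmetically
consistent with their own printed counts are reproduced exactly at
printed precision (22 ORs, including the Haldane-corrected genotype#1
advanced row).  Comparisons allow one unit in the last printed digit
because the source mixes rounding and truncation (e.g. a CI bound of
1.1957 printed as 1.19, an OR of 4.179 printed as 4.18).  Known
discrepancies are *not* reproduced and are flagged in the fixture
data instead:

* several combination-row percentages contradict their printed
  fractions, and the combination ORs (2.98, 2.6, 3.04, 0.46…) trace to
  the percentages rather than the counts;
* the 3DS1 advanced OR printed as 2.88 computes to 2.78 from its counts
  (probable erratum);
* a handful of printed p-values (genotype#1 0.07/0.015, genotype#42
  0.02, AA/Bx advanced 0.003, 2DP1 0.0003) match a Wald logit test, not
  Fisher; all count-consistent Fisher p's reproduce at printed
  precision under truncation rendering.

## Synthetic cohorts

Subjects are diploid draws from a haplotype pool; a profile is the
union of two haplotypes, so gene linkage within haplotypes (C4/T4
motifs) survives by construction.  The default pool is one A haplotype
(frequency 0.53) plus seven B variants carrying full or partial
centromeric/telomeric B motifs, tuned once so the control arm echoes
the modelled study's margins: AA ≈ 28.1% (0.53²), C4 carriage ≈ 33.5%,
T4 ≈ 21.6%.  These frequencies are illustrative, not inferential — the
pool encodes no measured linkage disequilibrium and the B-variant split
is a plausible guess, which is also why partial-motif haplotypes can
complement each other in trans at low probability.

Ligand epitopes are Bernoulli per chromosome — P(C1) = P(C2) = 0.5 per
HLA-C chromosome, P(Bw4) = 0.4 per HLA-B, P(A3/A11) = 0.225 per HLA-A —
giving carrier rates near the modelled control arm (C2 ≈ 75%, Bw4 ≈
64%, A3/A11 ≈ 40%).  Per-locus missingness (C 8%, B 16%, A 55%) mirrors
that study's typing completeness; untyped loci clear their flags.
Ligand draws are independent of KIR, which real cohorts satisfy only
approximately (KIR and HLA segregate on different chromosomes).  In
`allele` mode the simulator draws concrete allele names consistent with
the sampled epitope state (excluding the C1-bearing HLA-B exceptions so
flags stay faithful), letting the ligand-assignment stage run end to
end.

**Case-arm enrichment.**  The joint distribution over (diploid KIR
pattern × ligand state) atoms is enumerated exactly (≤ ~600 atoms for
the default pool).  Enrichment exponentially tilts this distribution:
atom probabilities are multiplied by ∏ w_m over the markers the atom
carries, and the weights are solved jointly (`scipy.optimize.root`,
residual tolerance 1e-8) so each marker's tilted carrier probability
hits the odds implied by its target OR against the untilted control
distribution.  Joint solving matters because markers overlap (every T4
carrier is Bx); single-marker tilts composed naively would overshoot.
Cases are then sampled categorically from the tilted atoms —
equivalent in distribution to rejection sampling against the tilt, but
exact and loop-free.  A target is declared unreachable (error before
sampling) when the control-arm carrier probability is 0 or 1.

What passing simulation-based tests shows: the pipeline's estimators
recover known odds ratios at realistic and large sample sizes, with
Woolf CIs achieving nominal coverage.  What it does not show: behaviour
under real linkage disequilibrium between KIR and HLA, allele-frequency
structure beyond the ligand groups, genotyping error, or stage
misclassification — none of which the generator emulates.

## Problem sizes and numerical choices

Point-estimate recovery is checked at 5,000 subjects per arm (binomial
error on a log-OR at this n is ~±0.06, comfortably inside the stated
bands); CI coverage uses 100 replicates at 1,000 per arm.  The Fisher
enumeration oracle covers all ~8,000 tables with both row margins ≤ 12.
Catalog ID ties are broken deterministically; association panels are
pure functions of their inputs (the suite asserts bit-identical
reruns).  Rendering in result tables follows the published convention:
percentages to 1 decimal, OR/CI to 2 decimals, half-away-from-zero.

## Known limitations

* Gene-content resolution only: no KIR allele typing, copy number, or
  haplotype phase; 2DL5A/B collapsed as above.
* The ligand reference is a closed synthetic library; novel-allele
  detection and SBT ambiguity-string handling are out of scope.
* No covariate adjustment or regression modelling — the statistics are
  deliberately the marginal 2×2 battery of the study design modelled.
* Genotype-catalog numbering beyond the canonical AA pattern cannot be
  reconstructed from published prose (the original catalog is graphical),
  so it is systematic rather than published numbering.
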