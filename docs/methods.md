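# Methods

This note documents the models and estimators implemented in `popdiv`,
the defaults chosen where a convention had to be fixed, and what the
synthetic-data generator does and does not emulate.

## Data model and conventions

Genotypes are stored as a sites × samples matrix of unordered diploid
allele-index pairs; a partially missing call (`./1`) is treated as fully
missing. Phase separators (`|` vs `/`) are read but ignored: every
statistic in the package (allele-count π, PIC, composite dosage r²) is
phase-free, so phasing quality never enters the results. Sites are kept
sorted by (chromosome, position); multi-allelic records survive parsing
untouched and are only reduced by the simple filter.

Coordinates are 0-based half-open internally; conversion to/from the
1-based conventions of VCF and GFF3 happens exactly once, at the parse
and serialise boundaries. This is load-bearing for window and flank
arithmetic, and the test suite exercises the conversion on a 1 bp exon,
where off-by-one errors cannot hide.

## Filters

* **Simple filter** — keep biallelic polymorphic SNPs. "More than two
  alleles" is counted over {REF} ∪ observed alleles, so a site whose
  two observed alleles are both ALTs counts three and is removed; this
  keeps REF equal to the genome base at every retained site, which the
  annotation stage relies on. Retained sites are recoded so the single
  observed ALT is allele 1.
* **Core filter** — missing rate ≤ 10%, heterozygosity rate ≤ 10%,
  MAF ≥ 2%, all inclusive as printed and all configurable. Rates are
  computed from integer counts (missing over all samples, het and MAF
  over called samples only) so comparisons at the printed boundaries
  (a site missing in exactly 10% of samples) are exact rather than
  float-dependent. The heterozygosity denominator is *called* samples;
  with the ≤ 10% missingness bound the distinction is small, but it had
  to be fixed one way and is tested as documented.
* **Mutated in all** — missing rate strictly < 10% and every genotyped
  call carrying at least one ALT allele. "Carrying a mutation" includes
  heterozygotes, since the contrast is with the reference state, not
  with homozygosity; a `hom_alt_only` flag provides the stricter
  reading.

## Nucleotide diversity

Each non-missing allele call is one sampled sequence of frequency 1/n.
The default per-site estimator is the average pairwise difference
*without replacement*,

    π_site = Σ_{u<v} c_u c_v / C(n, 2) = (n² − Σ c²) / (n (n − 1)),

equal to 2p̂q̂·n/(n−1) at a biallelic site — the convention of the
standard windowed-π tools. The plain with-replacement form
Σ xᵢxⱼπᵢⱼ = 1 − Σp̂² is available as `estimator="raw"` since the formula
is often quoted that way. Missing calls are excluded per site
(pairwise-complete alleles), never imputed.

Windowed π sums per-site values inside a window and divides by the
window length in bp, matching the per-bp 10⁻³ scale on which such
studies tabulate π. The default window is 100 kb sliding by 10 kb;
because a 10 kb step implies overlap while the same sources sometimes
say "non-overlapping", both modes are exposed (`step=None` tiles) and
the pipeline records which was used rather than guessing silently. A
population's π is the unweighted mean over windows, and sub-population
values are computed on the sub-population's columns only, with
sub-population-specific allele counts (not global counts restricted to
a window set — the alternative reading; this one is documented and
tested). Empty windows contribute π = 0.

## PIC

    PIC_l = 1 − Σ_u p_u² − Σ_u Σ_{v>u} 2 p_u² p_v²,

evaluated from observed allele frequencies; the cross term is computed
as (Σp²)² − Σp⁴. The population PIC is the unweighted mean over all
loci with at least one called genotype; in a filtered core set every
locus is polymorphic, so no monomorphic-locus dilution arises there
(a property the tests assert), while sub-population values may include
loci monomorphic *within* the sub-population, which enter as PIC = 0.
Heterozygous calls contribute one copy of each allele; diploid
sequences are the units of both π and PIC.

## LD decay

r² is the squared Pearson correlation of per-sample ALT dosages over
pairwise-complete samples (composite LD): phase is not trusted in
scope, and genotype-based r² is the standard fallback when phasing is
external. Pairs with fewer than two complete samples or a monomorphic
site within the complete subset are undefined and skipped. Only
same-chromosome pairs within `max_dist` (default 1 Mb) contribute.

The decay curve is a plain distance-binned mean (default 1 kb bins; no
loess — smoothing would make the estimator non-deterministic to
reproduce and is left to presentation). The half-decay distance uses
the first populated bin's mean as the "maximum" level — the simplest
reading of "half of the maximum" — and interpolates linearly between
bin midpoints for the first crossing of half that level; a
`reference="global_max"` option exists. A flat curve yields an
undefined half-decay with a diagnostic, never an exception.
Sub-population curves are only computed for sub-populations with at
least 20 samples (configurable): below that, composite-r² noise and
upward bias make the estimate unreliable, so the pipeline warns and
skips.

Finite panels inflate r² by roughly 1/N additively; at N = 100 diploids
this shifts the recovered half-decay of an exp(−d/L) process a few
percent above L·ln 2, which is visible in the worked example and well
inside the ±15% recovery band the acceptance tests use.

## Variant annotation

Region precedence is exonic > UTR > intronic > upstream/downstream >
intergenic when a site touches features of several genes (sources
reporting one label per site rarely state their precedence; this one is
a documented choice). Up/downstream are a 5 kb flank measured from the
start codon (upstream) or stop codon (downstream), strand-aware.

Coding effects use the standard nuclear code, one transcript per gene,
no alternative start codons. Indels are left-aligned against the
reference before classification, since VCF permits equivalent
representations. SNPs compare reference vs mutated codon translations;
a change in codon 1 destroying ATG is start_lost (the
"initiator_codon_variant" of some annotators). In-frame indels are
*conservative* when codon-boundary aligned and *disruptive* otherwise
(the disruptive classes are implemented for completeness and reported
separately). Frameshifts re-translate the shifted ORF and attach
secondary start_lost / stop_gained / stop_lost consequences when the
recomputed ORF loses its start, truncates early, or loses its stop.
A deletion bridging the coding spans of two genes is a gene fusion,
"bidirectional" when the strands differ. Impact grades: HIGH for
stop/start disruption, frameshift and fusion; MODERATE for missense and
in-frame indels; LOW for synonymous.

Genes whose CDS length is not divisible by 3 are flagged and skipped
rather than mistranslated.

## Synthetic data

The generator produces the statistical structure the estimators assume,
not sequencing realism — no read simulation, demography, selection or
recombination graphs.

* **Frequency laws**: fixed p; uniform; neutral SFS with
  P(count = i) ∝ 1/i over 1…2N−1.
* **Genotypes**: independent Bernoulli(p) alleles (HWE), with an
  inbreeding-style heterozygote deficit F copying the first gamete with
  probability F, and MCAR missingness. `exact_frequency=True` instead
  deals exactly round(2N·p) ALT alleles at random among the 2N allele
  slots — random mating *conditioned on the realised sample frequency*.
  Under that conditioning π_site equals 2p(1−p)·2N/(2N−1) in closed
  form, which is the target the recovery tests check; under plain
  binomial sampling the estimator is instead unbiased for 2p(1−p), and
  that is tested separately. The distinction matters at the ~1% level
  and is easy to conflate.
* **LD haplotypes**: a symmetric two-state Markov chain along each
  haplotype copies the previous allele with probability (1+ρ)/2,
  ρ = exp(−Δd/2L). Correlations telescope, giving allele correlation
  exp(−d/2L) and dosage r²(d) ≈ exp(−d/L) — an analytically known decay
  target, which is what the LD stage needs; a coalescent simulator
  would be more realistic but has no closed-form curve to recover.
  Diploids pair consecutive haplotypes (random mating), with the same
  F-style autozygosity available for inbred panels.
* **Toy genome**: two-exon genes with UTRs on both strands, designed
  codons at the implant positions, and one variant per effect class
  (synonymous, missense, stop_gained, stop_lost, start_lost,
  frameshift, conservative inframe insertion/deletion) per strand, plus
  a deletion fusing an opposite-strand gene pair. Implant designs are
  redrawn until every indel is already in canonical left-aligned VCF
  form, so the ledger coordinates are representation-stable. Every
  implant appears exactly once in the VCF and once in the truth ledger.

All randomness flows from a single seed; outputs are byte-identical
across runs.

## Pipeline defaults and problem sizes

The pipeline's simulation mode emulates a 181-accession cultivar panel:
five breeding-era sub-populations of 12/8/7/90/64 samples with year
bins SA 1963–1980, SB 1983–1988, SC 1991–2000, SD 2001–2010,
SE 2011–2017 (the bins are configurable — published sources are not
always internally consistent about the later boundaries, so the
tabulated bins are the default). The genome is represented at desk
scale: two 1 Mb chromosomes, ~3000 SNP sites, 12 single-exon genes per
chromosome, LD length scale 100 kb, 2% missingness, F = 0.95
(self-pollinating lines are nearly homozygous — with HWE heterozygosity
the ≤ 10% het filter would empty the core set, which is itself a useful
reminder of what that filter encodes). Substitutions are
transition-biased at p_ts = 1.89/2.89 so the simulated genome-wide
ts/tv ratio is ≈ 1.89, typical of such panels. These sizes keep a full
run near ten seconds while leaving every estimator in its asymptotic
regime; they are scale models, not attempts to reproduce any real
panel's absolute counts.

Determinism: all stage randomness derives from the config seed; the
provenance hash excludes the output directory, so re-running the same
analysis into a different folder is byte-identical.

## What passing tests do and do not show

The generator draws sites independently (except the LD chain), uses
MCAR missingness and a single transcript per gene. Real panels have
linked selection, structured missingness correlated with depth, paralog
collapse and multi-transcript genes — so passing recovery tests shows
the estimators are correct *under the stated models*, not that a real
study's absolute numbers would be reproduced. Headline values of any
particular cohort (total SNP counts, Table-level π/PIC, half-decay
distances of a specific population) depend on data that is not part of
this package.

## Known limitations

* Effect annotation handles one ALT per call path (the first ALT in
  multi-allelic records) and skips splice-site and regulatory classes.
* Insertions are classified only when flanked by CDS on both sides;
  indels spanning exon boundaries fall back to length-based frameshift
  logic.
* The subpopulation LD guard (≥ 20 samples) is a heuristic, not a
  variance estimate.
* `population_pi` weights all windows equally, including sparsely
  covered chromosome ends.
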