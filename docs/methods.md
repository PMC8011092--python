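# Methods

## Problem and approach

Molecular autopsy of sudden unexplained death (SUD) applies post-mortem
exome sequencing to decedents in whom autopsy, toxicology and histology
found no cause of death.  The central difficulty is variant interpretation:
an exome yields tens of thousands of called variants with no presenting
clinical phenotype to steer interpretation.  phenopanel implements a
phenotype-driven alternative to fixed gene panels: a small set of seed
terms from the Human Phenotype Ontology (HPO) — by default *arrhythmia*
(HP:0011675), *sudden cardiac death* (HP:0001645), *status epilepticus*
(HP:0002133) and *apnea* (HP:0002104) — induces a **virtual gene panel**
through the ontology's is-a structure and gene-phenotype annotations, and
a staged filter funnel reduces the exome to a handful of ranked candidate
variants per case.

The funnel stages, in order:

1. **quality** — read depth and genotype quality thresholds;
2. **population frequency** — gnomAD allele frequency below a dominant
   cutoff, with a relaxed cutoff for homozygous (or potentially
   compound-heterozygous) genotypes in recessive-context genes;
3. **functional impact** — missense, stop gained/lost, frameshift,
   splice donor/acceptor, in-frame insertion;
4. **known-benign exclusion** — discard variants ClinVar/LOVD classify as
   benign or likely benign ("conflicting interpretations" is *not*
   benign);
5. **panel intersection** — keep variants in virtual-panel genes; genes
   outside the panel can be *rescued* when their phenotype-similarity
   score ranks in the configured top percentile;
6. **mode of inheritance** — single heterozygous hits in recessive-only
   genes are dropped; two hits in one recessive gene are flagged
   *possible compound het* (single-proband data cannot phase them);
7. **classification and ranking** — ACMG 5-tier class from the variant's
   criteria string, then a deterministic sort (tier, inheritance verdict,
   number of exact seed matches, similarity score, position).

## Virtual panel construction

Ontologies are parsed from an OBO 1.2 subset (`id`, `name`, `is_a` with
trailing-comment stripping, `alt_id`, `is_obsolete`); only is-a edges are
traversed, other relationship types are counted and ignored, and obsolete
terms are excluded from traversal.  Gene-phenotype annotations follow the
genes_to_phenotype TSV dialect (configurable column names); alt ids resolve
to primary ids and rows citing unknown or obsolete terms are skipped and
counted.  By the true-path rule a gene's *propagated* annotation set is the
ancestor closure of its direct set.  A gene joins the panel when a direct
annotation lies in a seed's descendant closure (equivalently: the seed
appears in the gene's propagated set — the equivalence is asserted in
tests), and per-gene provenance records every (seed, matched term) pair.
Gene symbols are stored case-preserved and matched case-insensitively.

Release-dependent panel sizes (per-seed gene counts and their union) are a
property of the annotation release used and are deliberately not asserted
anywhere; the package reports whatever counts the supplied annotation file
induces.

## Phenotype similarity (simscore, a Resnik-BMA analog)

Commercial platforms ship proprietary phenotype-similarity scores; the
formula behind the score this package emulates is not public.  We
implement the standard, well-characterized construction and label outputs
accordingly, claiming no numeric equivalence:

* information content `IC(t) = -ln(n_t / N)` over propagated annotations
  (`n_t` genes reaching term t, `N` annotated genes);
* Resnik term similarity: IC of the most informative common ancestor
  (terms count as their own ancestors here);
* symmetric best-match-average set similarity between the case's term set
  and each gene's **direct** term set;
* dense gene ranks (ties share a rank) and percentiles (fraction of genes
  scoring strictly lower).

Scoring genes by their direct sets and computing IC over propagated sets is
a documented choice.  One consequence worth noting: a gene annotated to the
case's exact term *plus* an unrelated term scores below a gene annotated to
the exact term alone — the unrelated term dilutes the gene-to-case
direction of the average.  Rescue flags out-of-panel variants whose gene
percentile is at least `1 - cutoff`; the default cutoff 0.01 ("highest
range" of the ranking) is configurable.

## Filter thresholds

The source study published no numeric cutoffs.  Defaults are inferred so
that every reported candidate variant passes, and are flagged as inferred:

| parameter | default | rationale |
|---|---|---|
| min depth | 20 | conventional exome QC floor |
| min genotype quality | 20 | conventional |
| max AF, dominant context | 5x10^-4 | largest reported dominant-context AF is 1.465x10^-4 |
| max AF, recessive context | 2x10^-3 | the retained homozygous recessive variant sits at 1.7889x10^-3 |

Missing annotations are never coerced: an absent allele frequency means
"not observed" and passes the frequency stage; absent depth/GQ pass the
quality stage; an unrecognized consequence term is removed conservatively
(configurable).  The compound-het condition in the frequency stage (>= 2
het hits in one gene) is evaluated on the whole sample rather than on the
subset surviving earlier stages, which makes the four first-block
predicates order-independent per record.

## ACMG engine

Criteria strings ("PVS1-m, PM2") parse into criteria with default
strengths (PVS1 very strong; PS1-4 strong; PM1-6 moderate; PP1-5
supporting; BA1 stand-alone benign; BS1-4 strong; BP1-7 supporting) and
optional applied-strength modifiers `-vs/-s/-m/-p`.  Combination follows
the published rules evaluated on *applied* strengths; mixed
pathogenic-and-benign evidence without BA1 yields VUS
(`conflicting_evidence`), an empty or unmatched set yields VUS
(`insufficient_evidence`), and BA1 dominates any conflict.  Two
conventions extend the literal table: criteria counts of >= 2 very-strong
(reachable only through `-vs` upgrades) classify pathogenic, consistent
with point-based equivalents; and benign-side criteria applied at moderate
strength count as supporting (the benign combining rules only define
strong and supporting buckets).  Criteria *assignment* is accepted as
input — deciding PVS1/PM1/PP2 etc. needs transcript, hotspot and
constraint evidence outside scope — except an advisory PM2 helper driven
by allele frequency, which never overrides a provided string (reported
criteria in the reference series disagree with naive frequency-based PM2
in one row, so the printed string always wins).

## Reference case series

`phenopanel.reference` transcribes the 13 reported candidate variants of a
published 16-case SUD cohort (9 adults 23-53 years, 7 infants 4 weeks-9
months): 11 panel hits (9 missense, 2 splice; seed matches 4 arrhythmia /
7 sudden cardiac death / 2 status epilepticus / 1 apnea) and 2
fixed-panel-only variants without an exact seed match.  Variants sharing a
published individual accession are attached to one case, giving 6 infants
and 3 adults with at least one panel candidate.  The published table also
names RANGRF among panel-overlapping genes without a corresponding row;
the transcription follows the rows.  The six adults without candidates
have no published ages; synthetic representative ages inside the stated
range stand in (denominators only).  The engine reproduces all 13 printed
criteria-to-class pairs, including the sole likely-pathogenic call (the
homozygous UPB1 splice-acceptor variant, "PVS1, PM2").

## Simulator

`phenopanel.synthetic` generates cohorts with the statistical structure
the method assumes, at the study's stated conditions: 16 cases (9 adults
uniform 23-53 years, 7 infants uniform 4-39 weeks), Poisson variant counts
with mean 68,947 per sample (tests and CI use 2,000-variant "mini-exomes"
with identical rates), and a first-filter-block pass probability of 0.004
(~276 of 68,947).  Each background variant is constructed either to pass
the whole first block or to fail exactly one designated stage (failure mix
0.75 common allele / 0.17 non-qualifying consequence / 0.05 benign label /
0.03 low quality — frequency is the dominant reducer), so the pass rate is
binomial by construction and calibration is exact in expectation.  Allele
frequencies of rare survivors are absent with probability 0.15 (novel
alleles) or uniform below the dominant cutoff.

Panel-gene hits among survivors occur with probability q = 0.0193, and
genes carry inheritance models with mix 47.5% dominant-only, 12.5%
dominant+recessive, 27.5% recessive-only, 12.5% uncatalogued.  A
background heterozygous survivor is retained by the inheritance stage when
its gene is dominant-capable or uncatalogued (probability r = 0.725), and
additionally when two hets collide in one recessive-only panel gene.  With
S survivors per sample and n_AR recessive-only panel genes, the collision
term is `n_AR * lambda * (1 - exp(-lambda)) / S` with
`lambda = S * q * 0.275 / n_AR`; at full exome scale (S ~ 276, n_AR ~ 16.5)
this adds ~0.05 percentage points.  q solves
`q*r + collision(q) = 4/276 = 1.449%`, the study's reported
panel-plus-inheritance prioritization proportion.  At mini-exome scale the
collision term is negligible and the rate is q*r = 1.40%.

Planted causal variants follow an inheritance scenario: `AD_het`
(heterozygous, novel, splice donor), `AR_hom` (homozygous, AF *between*
the dominant and recessive cutoffs so it survives only through the
recessive relaxation, splice acceptor), `AR_comphet` (two heterozygous
records in one recessive-only gene), and the negative control
`AR_single_het` (expected to be filtered).  Planted consistent variants
carry "PVS1, PM2" (tier 4) and therefore outrank background survivors
(at most tier 3), which is why recovery tests demand rank 1.

What the simulator does **not** emulate: linkage/haplotype structure, real
genome coordinates, annotation errors, multi-gene pleiotropy, trio data,
sample-level quality pathologies, or any correlation between frequency and
consequence.  Passing tests therefore demonstrate the pipeline's logic and
calibration under the assumed generative structure, not performance on
real exomes.

## Numerical and determinism choices

Natural logarithm for IC; similarity ties broken lexicographically by gene
symbol in outputs; candidate ordering is a total order ending in genomic
position; all simulator randomness flows from one integer seed through
`numpy.random.default_rng`, and identical configurations give
byte-identical files.  Multi-allelic VCF sites are split per ALT allele
carried by the genotype; symbolic (CNV-style) ALTs are skipped with a
logged count, mirroring a study design in which no CNV calls survived.
Empty candidate lists are valid findings, not errors.

## Problem sizes used in tests and the acceptance script

Mini-exome samples of 2,000 variants are used for property and calibration
tests (50 samples) and planted-variant recovery (100 single-case cohorts,
scenarios cycled); the acceptance script additionally runs 96 full-scale
(~69k-variant) samples to measure the funnel's exome-scale means.  These
sizes give standard errors comfortably below the tolerances asserted while
keeping the default suite and script in the tens of seconds.

## Known limitations

* The similarity score is an analog, not a reimplementation, of any
  proprietary score; percentile-based rescue is calibrated only in the
  sense of its definition.
* Criteria assignment is not automated; garbage criteria strings yield
  well-defined but meaningless classifications.
* Compound heterozygosity is flagged, never asserted — single-proband
  data cannot phase variants.
* The recessive frequency relaxation requires a gene inheritance context;
  with an empty MOI catalog it never fires.
* Age-compatibility flags need a user-supplied onset map and never remove
  variants.
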