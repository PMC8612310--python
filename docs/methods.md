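# Methods

`sedimeta` re-implements, as a tested library, the descriptive computations
commonly applied to multi-site assembled shotgun metagenomes from marine
sediments: normalized gene-family abundance/diversity matrices, rule-based
detection of detrital (cyanobacterial and eukaryotic) contigs, and per-MAG
characterization statistics. This note records the models, the parameter
choices, and the reasoning behind design decisions that the underlying
description left open.

## Gene-family profiles

For a family *f* at site *s*, with genes *g* of nucleotide length *L_g* bp,
mapped-read count *c_g*, site sequencing depth *R_s* reads and *G_s*
predicted genes:

* **RPM** (reads per million), an abundance measure normalized to gene
  length and dataset size:

  RPM(f, s) = Σ_{g∈f,s} [ c_g / (L_g / 10³) ] / (R_s / 10⁶)

* **GPM** (genes per million), a diversity measure — the number of distinct
  predicted genes annotated to the family per million predicted genes:

  GPM(f, s) = 10⁶ · n_{f,s} / G_s

Choices made where the definitions are verbal rather than algebraic:

* The per-gene reads-per-kilobase terms are computed first and then summed.
  This order is what makes RPM exactly additive over any partition of a
  family's genes, and invariant under jointly rescaling all counts and the
  site depth — both properties are enforced by tests.
* Gene length is the nucleotide span from the gene caller's coordinates
  (1-based inclusive, `end − start + 1`), not protein length: a read-mapping
  normalization needs the length of the mapped template.
* "Different gene homologs" are distinct predicted gene calls carrying the
  family annotation; no identity-threshold clustering is applied, since no
  clustering parameters are defined anywhere and the gene-caller output is
  already the unit of annotation.
* The depth normalizer is the site's **total** read count, configurable in
  the site table; mapped-read totals can be substituted by editing that
  column, as the two conventions differ only by a per-site constant.
* Read counts are taken as given (fractional values from multi-mapping
  resolution are accepted); the package does not define read mapping.
* A family is *present* at a site iff its distinct-gene count exceeds a
  threshold (default 0, i.e. any detection counts). Pathway completeness is
  a conjunction over required families, with rules supplied as data
  (`sedimeta/data/pathway_rules.yaml`); the shipped set covers
  nitrification (amoABC + nxrAB), reverse-DSR sulfide oxidation
  (dsrAB + dsrEFH), sox thiosulfate oxidation (soxZXA), thiosulfate
  reduction (phsA) and anammox (hzoA + hzsA).

## Contig-origin classification

Detrital contigs are flagged from the taxonomy of each gene's single best
hit (highest bit score; ties broken by lower e-value, then lexicographic
subject id, so the choice is deterministic):

* **eukaryotic** ⇔ length > 2000 bp (strict) AND coding density
  < 0.5 genes/kb (strict) AND > 1/2 of hit-bearing genes have eukaryotic
  top hits (strict);
* otherwise **cyanobacterial** ⇔ ≥ 1/2 of hit-bearing genes have
  cyanobacterial top hits (inclusive);
* otherwise **unclassified** (including every contig with no hit-bearing
  genes).

Open points resolved here:

* The strict-vs-inclusive asymmetry ("more than half" eukaryotic, "at least
  half" cyanobacterial) is implemented verbatim; it matters only at exact
  fraction 1/2 and is kept because both wordings are explicit.
* The eukaryotic rule is evaluated first. A gene-poor eukaryotic contig can
  simultaneously show a ≥ 1/2 cyanobacterial fraction among its few hits;
  treating the classes as disjoint with the more specific (three-condition)
  rule first avoids swallowing such contigs into the cyanobacterial class.
* The voting denominator is genes **with at least one hit**, not all genes:
  a fraction over hitless genes is undefined. The same denominator is used
  for both rules, for symmetry. All four thresholds and both taxonomy
  labels are configurable (`ClassifierConfig`, CLI flags).
* Only the top hit per gene votes. Voting over the top *k* hits would need
  a *k* that is nowhere defined; the evidence table (`contig_features`)
  exposes the counts, so alternative voting schemes can be layered on
  without touching the classifier.

## MAG statistics

Per bin: total assembled length, GC% over unambiguous bases only (N's are
excluded from numerator and denominator), gene count, coding density
(10³ · genes / length, genes per kb), completeness *C* and redundancy from
the binning pipeline, and the completion-corrected genome size

  Ŝ = total_length · 100 / C,

undefined (an error) at C ≤ 0, equal to the assembled length at C = 100 and
monotone decreasing in C. The high-quality filter keeps bins with
completeness > 60 and redundancy < 8.7, both strict; the 8.7 contamination
ceiling follows the convention of single-copy-gene redundancy scales.

A MAG poorly represented in reference databases recruits best hits
scattered across many taxa. Per bin, `mean_aai_pct` is the mean percent
identity of its genes' best hits (an AAI proxy) and `n_taxa` the number of
distinct taxon labels among those best hits (one vote per gene; per-hit
counting is an option). `aai_consistency` regresses `n_taxa` on
`mean_aai_pct` by OLS and reports the two-sided t-test on the slope; since
no specific test is canonical for this contrast, a Spearman rank
correlation is reported alongside as a distribution-free cross-check. A
perfectly flat response returns slope 0 with p = 1 rather than the 0/0
t-statistic. At least 3 bins and positive AAI variance are required.

## Synthetic data

The generator emulates the structure such a study presents to the pipeline,
with every record traceable to a planted parameter:

* **Sites and families.** 13 sites by default. Each family has a per-site
  presence probability and, where present, a Poisson number of distinct
  gene calls and an abundance λ defined as the expected RPM contribution
  per gene; read counts are negative binomial with mean
  λ · (L_g/10³) · (R_s/10⁶) and variance μ + αμ² (α = 0.1 by default —
  overdispersion is the norm in metagenome coverage; α = 0 gives Poisson).
  The default family table spans nitrogen and sulfur cycling with sporadic
  presence: ammonia-oxidation genes nearly ubiquitous (p = 0.92),
  nitrite oxidation common (0.70), nitrous-oxide reduction rare (0.08),
  and norB configured as the most abundant family where found — the
  qualitative pattern such surveys report.
* **Detrital contigs.** Planted classes are constructed to *provably*
  satisfy or fail the rules at mislabel rate ε = 0: eukaryotic contigs are
  2.6–8 kb with a single gene (density < 0.4/kb) and a eukaryotic top hit;
  cyanobacterial contigs carry ⌈0.8·n⌉ cyanobacterial top hits; background
  contigs carry ⌊0.3·n⌋ (always < 1/2). ε > 0 randomly re-draws each
  gene's top-hit taxonomy, degrading recovery monotonically.
* **MAGs.** 16 bins by default, true sizes 1.2–4.6 Mb, completeness 61–99%,
  GC 33–56%, coding density 0.68–1.12 genes/kb — ranges typical of
  higher-quality sediment MAGs. Emitted length is size · C/100 (the planted
  size is recorded as the exact inverse of the rounded emitted length, so
  the downstream Ŝ recovers it exactly). Per-bin AAI centers are spread
  over 55–90%; taxon diversity is round(100 − AAI + N(0, 1)) by default
  and realized *exactly* by cycling that many labels over the bin's gene
  hits.
* Sequences are i.i.d. nucleotides at the configured GC; there is no codon
  structure, no phylogenetic signal, and no read-level (FASTQ) simulation.
  Consequently, passing tests demonstrate the correctness of the
  *computations* — normalization arithmetic, rule boundaries, estimator
  inversions, regression recovery — not robustness to assembly artifacts,
  chimeras, or annotation error in real data.

All randomness derives from one integer seed via `numpy.random.SeedSequence`
spawning; a fixed seed reproduces bundles and result trees byte-for-byte
(run manifests record input content hashes, not paths, so reproducibility
is location-independent).

## Problem sizes used in the shipped checks

The acceptance checks run the default 13-site / 16-bin study once end to
end (about 50 MB of generated sequence), 100 random small profiling
instances against a double-loop oracle, 200 randomized invariance cases,
500 planted contigs, and 200 replicates each for the regression-recovery
and dose-response checks — sizes at which every Monte-Carlo tolerance
(5–10%) is comfortably resolved while the whole suite stays fast.

## Known limitations

* GPM counts assembly-derived gene calls, so fragmented assemblies inflate
  it; no length or identity deduplication is attempted.
* The AAI proxy averages best-hit percent identity over genes with hits;
  bins with few annotated genes get noisy values, and no minimum-gene
  threshold is imposed.
* Pathway completeness is binary conjunction; partial-module scoring (as
  KEGG-module tools compute) is out of scope.
* The classifier reads only lengths, gene counts and hit taxonomy; k-mer or
  coverage-based eukaryote detection is out of scope.
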