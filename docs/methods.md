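# Methods

## The analysis

`cladebin` reconstructs draft genomes (MAGs) from a low-diversity holobiont
metagenome and characterizes them taxonomically and quantitatively. The
procedure assumes the community has few members (roughly 5–15), that each
member occupies a distinct region of (GC, coverage, tetranucleotide)
feature space, and that host DNA — present at bacteria-like coverage — is
separable by nucleotide composition. These are exactly the conditions under
which manual inspection of GC-vs-coverage scatter plots has historically
driven holobiont binning; `cladebin` fixes an automated, reproducible
surrogate for that manual step.

### Scaffold features

Each scaffold ≥ 10,000 nt (configurable; shorter scaffolds carry too little
compositional signal) is described by:

- **GC%** — `100·(G+C)/(A+C+G+T)`; ambiguity characters excluded from both
  numerator and denominator.
- **TNF** — frequencies of all overlapping 4-mers, each pooled with its
  reverse complement into 136 canonical classes (16 self-complementary + 120
  pairs), normalized to sum to 1. The k-mer size is configurable; 4 is the
  standard compromise between resolution and sampling noise at 10-kb scale.
- **Coverage** — total aligned bases divided by scaffold length. Using
  aligned bases rather than read counts makes the statistic read-length
  independent; for ungapped end-to-end placements it equals the mean of the
  per-base depth array exactly (a property the test suite checks against a
  brute-force oracle).
- **Paired fraction** — of the records mapped to the scaffold, the fraction
  whose mate also mapped in the same run. Undefined (NaN) when nothing maps;
  screening treats undefined as failing.

Coordinates are 0-based half-open throughout; FASTA/FASTQ identifiers are
truncated at the first whitespace.

### Read mapping

The internal mapper indexes exact k-mers (default k = 16, packed base-4
integers, grouped with one argsort) over the forward strand and seeds each
read (and its reverse complement) at non-overlapping offsets, guaranteeing a
clean seed whenever `(max_mismatches + 1) · k ≤ read length`. Extension is
ungapped over the full read; identity = matches / read length; the best
placement wins, ties broken by lowest (scaffold, position), and tied-best
reads are flagged ambiguous (excluded from abundance). At a 100% identity
floor the contract reduces to exact full-length substring matching, which
makes that mode bit-reproducible. Gapped and clipped alignment are out of
scope: the synthetic error model is substitution-only, and the screening and
abundance statistics are defined on end-to-end placements.

### Binning and screening

Preliminary binning clusters within taxonomy-label groups (labels are
phylum/class rank paths supplied per scaffold; a deliberately pluggable
stand-in for database-driven classification of predicted proteins).
Features are globally standardized (GC, log₁₀ coverage, top-3 TNF principal
components), with each scale floored at typical within-genome noise
(2 GC points, 0.2 log₁₀-fold, 0.02 per PC) so that a community that is one
tight cluster is not inflated to unit variance. DBSCAN (ε = 0.8 in these
units, min_samples = 3) finds clusters per label group; unlabeled scaffolds
and density-noise points attach to the nearest bin centroid within ε, else
stay unbinned. On desk-scale synthetic communities the within-genome
nearest-neighbor distance is ≤ ~0.6 and the between-genome distance within a
shared label is ≥ ~1.0, so the defaults sit in the gap; both knobs are
exposed.

Screening rejects a scaffold from its bin when (checked in this order):

1. paired fraction ≤ 0.90 or undefined — the threshold is strict ("more
   than 90%");
2. |GC − bin median| > 5 points;
3. |log₁₀ coverage − bin median| > 0.5;
4. TNF distance from the bin's componentwise-median centroid exceeds
   `max(q99 of within-bin distances, 3 × median within-bin distance)` —
   the median centroid resists being pulled by the very contaminants under
   test, and the 3×-median floor keeps a clean bin from rejecting its own
   most extreme member (a raw q99 rule would, since the sample maximum
   always exceeds an interpolated 99th percentile);
5. taxonomy label present and different from the bin majority.

`refine` alternates screening (and, in a full deployment, recruitment plus
external re-assembly — pass-through here) until a fixed point or
`max_rounds`; the accepted set never grows, so refinement is monotone.

Completeness and contamination are *simplified* single-copy-marker tallies:
`completeness = 100 · (#families present)/|set|`,
`contamination = 100 · Σ_f max(0, copies_f − 1)/|set|`. Marker collocation,
lineage-specific sets, and the corrections a full marker-based QC tool
applies are intentionally out of scope; the default set is 100 synthetic
families and any family list can be supplied.

### Relatedness and rank calls

AAI is the unweighted mean identity over reciprocal-best-hit protein pairs:
global Needleman–Wunsch/Gotoh alignments under BLOSUM62 with affine gaps
(open 11, extend 1), best hits by alignment score (ties to the smallest
identifier), pairs kept if mutually best with identity ≥ 30% and aligned
coverage ≥ 70% of both proteins; identity counts matches over alignment
columns excluding terminal gaps. A value is reported only when ≥ 20 RBH
pairs support it. 16S identity uses a global nucleotide alignment with free
terminal gaps (match 2 / mismatch −3 / gap −5,−2); internal gap columns
count in the denominator, and spans < 360 nt give an undefined value.

Rank calls use inclusive threshold bands — AAI ≥ 95 species, ≥ 65 genus,
≥ 45 family; below the family band a defined 16S identity ≥ 86.5 keeps the
pair at same-order, otherwise the call is novelty above order. When AAI is
undefined the 16S bands (97 / 94.5 / 86.5) decide alone. Both the AAI-based
and the 16S-based call are recorded side by side, because the two signals
can legitimately disagree (the 16S-based call is the conservative,
downward-revising one). There is no 16S family threshold in the guideline
bands used, so 16S-only calls skip from genus to order granularity.

### Abundance

- *Read recruitment*: reads mapped at 100% identity, unambiguously, to a
  screened bin's scaffolds are counted per taxon. The `classified` metric
  normalizes over classified reads; the `total` metric over all input reads,
  with the remainder reported as unclassified. Reads are not fractionally
  split across bins — ambiguous placements are simply unclassified.
- *Amplicons*: each ASV is matched against the bins' 16S genes by semi-global
  edit distance over the full ASV length (the 360-nt floor applies only to
  environmental full-length-gene searches, not to short amplicons); the best
  group at ≥ 97% identity wins, ties to the lexicographically lower group;
  per-sample shares are computed after dividing by the sample's total reads.
- *Known biases, by construction*: read recruitment under-represents small
  genomes (reads ∝ abundance × genome length), and amplicons over-report
  multi-copy 16S taxa (weights ∝ abundance × copy number). `compare_metrics`
  reports per-taxon differences, a per-sample Spearman rank correlation, and
  flags taxa with multi-copy 16S or atypical genome size as expected
  discordance sources.
- *Environmental matching*: local alignment (+1/−2, gaps −5/−2) with
  filters alignment length ≥ 360 nt, e-value ≤ 1e−7, and tiered identity
  floors (97 species / 95 genus / 90 distant). The e-value uses the
  ungapped Karlin–Altschul form E = K·m·n·e^(−λS) with λ = 1.28, K = 0.46
  (the standard constants for +1/−2 scoring), recorded in the output
  metadata; the filter semantics, not the exact E of any particular BLAST
  build, are the contract.

## The synthetic community generator

The generator emulates the structure of a sponge-holobiont metagenome and is
the ground-truth oracle for every test:

- **Genomes** are i.i.d. nucleotides at per-genome GC targets (default six
  genomes, 200 kb each, GC 30–62%), so genomes are non-homologous outside
  planted loci and binning separability is controlled entirely by the
  configuration. No repeats by default.
- **Planted loci**: 100 single-copy marker families (900 bp, backbone GC)
  and n 16S genes per genome (1500 bp) at evenly spaced, non-overlapping
  positions, 16S copies interleaved across the genome like dispersed rRNA
  operons. 16S copies within a genome differ by 0.3% (≥ 99% identity);
  per-genome templates diverge 8% each from a shared ancestor (~85%
  between-genome identity). The backbone GC is adjusted so the whole genome,
  including the fixed-GC 16S insertions, hits the configured target within
  one point.
- **Host contaminant** (default 10% of community length): a first-order
  Markov chain with strong CpG depletion and AA/TT enrichment — GC ~34%,
  inside the bacterial range — sampled at the median bacterial genome's
  coverage, so only composition separates it.
- **Reads**: pairs allocated ∝ abundance × scaffold length (cell-fraction
  abundances), so genome i's fold coverage is `depth_total × abundance_i`;
  forward–reverse orientation, insert ~ Normal(300, 50) truncated to the
  scaffold; substitution errors at 0.2% per base; constant FASTQ qualities
  (unused downstream). `singleton_rate` is defined as the expected fraction
  of *emitted reads* whose mate was discarded (mates are dropped from
  `2s/(1+s)` of pairs and the pair count inflated by `1+s`), which makes
  both the community paired fraction (1 − s) and the realized depth match
  their nominal values exactly in expectation.
- **Amplicons**: multinomial ASV counts over the planted 16S copies in a
  V4–V5-like window (template positions 515–926), weights ∝ abundance ×
  copy number; ASVs are exact planted subsequences (optional substitution
  model available).
- **Default community**: abundances 60/20/10/6/3.5/0.5% at 20× pooled depth
  — one dominant member, a ~100-fold coverage range, and two genomes sharing
  a class-level label separated by 7 GC points so that within-label
  clustering is actually exercised. Desk-scale sizes (200 kb genomes,
  ~40,000 reads) keep a full pipeline run under a minute; all scales are
  configuration.

What the generator does **not** emulate — and hence what green tests do not
demonstrate about real data: indel and quality-decay error profiles, strain
microdiversity, shared homologous regions between community members,
repeats, plasmids, viral scaffolds, GC-biased coverage, and real rRNA
secondary-structure conservation. The binning margins measured here are
upper bounds on what field data allows.

## Numerical and design notes

- All randomness flows from a single seed; generator sub-stages derive
  seeds as seed + fixed offsets, so every stage is independently
  reproducible and two identically-configured runs are byte-identical
  (checksummed in the run manifest).
- The rarest default genome (0.5% abundance, ~0.1× coverage) is recovered
  by binning (labels + GC carry it) but is legitimately damaged by the
  strict paired-read screen: with ~20–40 mapped reads per scaffold, the
  observed paired fraction often dips below 0.90 by sampling noise alone.
  This is faithful to the screen's definition, and is why screened
  completeness for ultra-rare community members drops while preliminary
  binning recall stays at 1.0.
- Degenerate inputs: zero mapped reads give coverage 0 and undefined paired
  fraction (screen-fail); sequences of only ambiguity characters raise an
  undefined-value error; an all-unlabeled profile table falls back to pure
  density clustering with a warning; a bin emptied by screening is dropped
  with a warning.
- `pair_status` is evaluated against the whole mapping run (a mate mapped to
  a different scaffold still counts as paired), matching how idxstats-style
  flag summaries behave; a same-scaffold-only option exists.
- Protein and nucleotide pairwise alignment are Biopython
  `PairwiseAligner`; ASV matching is edlib in semi-global (infix) mode;
  clustering/PCA are scikit-learn; the AAI test oracle is an independent
  row-vectorized Gotoh dynamic program kept in the test suite.
- Problem sizes in the test and acceptance runs (200-kb genomes, 40k–100k
  reads, 20-protein proteomes of 100–150 aa) were chosen as the smallest
  scales at which the sampling-noise tolerances above are comfortably
  resolvable; every size is a config parameter.

## Known limitations

- The mapper is substitution-only and unsuitable for reads with indels;
  import of externally produced alignments (`read_sam`, via pysam) is
  the escape hatch.
- Marker QC ignores collocation and lineage-specific marker sets; its
  completeness is not comparable to CheckM-style estimates on real MAGs.
- The re-assembly step inside `refine` is a pass-through; the pipeline
  prepares recruited read sets for an external assembler rather than
  assembling.
- AAI ortholog floors (30% identity, 70% coverage) are conventional
  defaults, recorded in output metadata; different services make different
  choices and AAI values shift by a point or two accordingly.
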