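# Methods

## Scope and model

`poolsnp` implements threshold-based variant discovery for *pooled*
sequencing of two closely related species against a shared set of
transcript contigs. There is no genotype-likelihood model anywhere: the
protocol it reproduces is a cascade of explicit count and quality
thresholds, and the package reproduces it as such. Sites are independent;
reads are treated as independent draws from the pool.

Coordinates are 0-based half-open internally; 1-based only in VCF output.
Quality strings are phred+33.

## Read cleaning

Order of operations per read: (1) clip the longest exact 3′ overlap with
an adaptor prefix (minimum 8 bp; a full internal adaptor occurrence clips
from its start), (2) strip trailing `N`s — steps 1–2 repeat to a fixed
point so trimming is idempotent — then (3) discard the read when the mean
phred of the remaining bases is below `min_mean_quality` (default 20), and
(4) discard when shorter than `min_length` (default 15 bp). The quality
rule is a whole-read mean, not a sliding window: the protocol filters
"low-quality sequences by average quality score", and a windowed trimmer
would be a different method. Internal `N`s are retained and simply count
as mismatches during mapping.

## Mapping

Scoring is unit match reward, mismatch cost 2, insertion and deletion cost
3 (linear gaps). A placement is retained when

* similarity = matches / (matches + mismatches + inserted + deleted bases)
  over the aligned region ≥ `min_similarity` (0.80), and
* aligned read bases / read length ≥ `min_length_fraction` (0.50) —
  "length" is read length; the reads are the queries.

Candidate loci come from exact k-mer seeds (k = 12, configurable; the
sensitivity/speed trade-off is ours). Candidate diagonals within 12 bp are
clustered. A diagonal with at most 3 mismatches and no overhang is solved
exactly by a prefix-sum scan for the best gap-free segment; anything else
goes through a banded local Smith–Waterman (Biopython's `PairwiseAligner`,
C implementation) in a ±12 bp window. Each read receives at most one
placement — the highest-scoring one that passes both thresholds, ties
broken by (contig order, start, forward strand) — so pileups never count
one read twice. Reads that fail are written to a FASTA for external
assembly; the pipeline classifies SNPs identically on any contig set
supplied back (no de novo assembler is included).

Consequences worth knowing: a read whose mutations leave no clean 12-mer
cannot be seeded (raise sensitivity by lowering `seed_k`), and in repeat
contexts the gap-free fast path can in principle choose a placement tying
but not equal to the global gapped optimum; the exhaustive-DP agreement
test bounds this empirically on seeded data.

## Pileups

Every observation carries (base, own phred, mean phred of the same read's
bases within ±5 positions with the site excluded, species of origin).
Deletions contribute `-` observations carrying the mean quality of the two
flanking read bases; insertions are recorded in a side channel keyed by
the reference position they precede and never create columns. Species of
origin travels in the read name prefix (`CH|`/`BL|`) or the SAM read
group.

## SNP detection and screening

**Putative stage.** An observation is *qualified* when its own phred ≥ 25
and its surrounding-base mean ≥ 20 (window 5 bp each side, exposed as
`flank_window`; the upstream protocol leaves the window unstated, so it is
a parameter). `N` observations never qualify. A site is a putative variant
when qualified depth ≥ 4 and the most frequent non-reference allele has
qualified count ≥ 2 ("variant frequency of two" is a count, matching "the
minor allele being represented at least twice"). Deletion alleles are
detected under the same thresholds but serve only the clean-flank rule
below; they are never reported as SNPs. Sites whose reference base is not
A/C/G/T are unscorable.

**Reference per view.** The pooled view compares observations to the
contig base. Each species view is compared to the *species consensus*
(most frequent qualified allele, ties to the alphabetically first), which
stands in for the species' own assembly after the three separate
assemblies of the original design are collapsed onto one contig set: a
fixed inter-species difference is then monomorphic within each species
view rather than an apparent intra-specific SNP.

**Screening stage.** A putative SNP is a quality ("filtered") SNP iff

* MAF = minor-allele qualified count / qualified depth ≥ 0.10
  (inclusive). The denominator is qualified depth, i.e. the reads that
  actually assessed the locus;
* no other putative variant of the same view — SNP (pass *or* fail) or
  indel — lies within 15 bp on either side;
* the site is outside repetitive regions. When no repeat BED is supplied,
  a built-in fallback masks homopolymers ≥ 10 bp plus the microsatellite
  finder's tracts (a full repeat annotator is out of scope; masks are
  normally consumed as input);
* exactly two alleles are present, where an allele *exists* only when its
  qualified count reaches the variant-count threshold (2) — a singleton
  observation is below the detector's own evidence bar and is treated as
  noise, not as a third allele. With a literal "any observation is an
  allele" reading, a single stray error would disqualify ~10% of true
  SNPs at 100× depth, which is incompatible with the protocol's reported
  yields at high depth.

The MAF rule applies to all contigs uniformly.

## Classification

Candidate sites are the union of passing positions of the three screened
lists. A species "has an intra-specific SNP" at a site when that view has
a passing call there (a flag allows classifying at the putative level
instead). Categories: 3 when both species do; 1/2 when exactly one does
and the other is covered by ≥ `min_species_depth` (4) reads; 5/6 when the
other is not; 4 when neither does, both are adequately covered, the
pooled view sees a variant, the species consensus alleles differ, and
within-species allele purity is ≥ 0.9 in each (purity implements "no
variation within either species" under sequencing error; set it to 1.0
for the literal rule). Everything else is unclassifiable. Sites present
only in the pooled list are flagged `pooled_only`. Categories 5/6 report
— deliberately without correcting — the coverage-driven underestimation
of shared and inter-specific counts.

## Microsatellites

Maximal perfect tandem repeats with primitive motifs of 2–6 bp;
thresholds 8 repeats (di) / 5 repeats (tri–hexa); mononucleotide runs are
excluded (they go to the fallback repeat mask instead). Tracts containing
`N` are split at the `N`. Overlapping descriptions of one tract collapse
to the shortest primitive motif with maximal extent, and among start
phases preserving the maximal repeat count the one giving the
lexicographically smallest motif is reported — so the reported substring
always equals motif × repeats. Tracts are reported on the given strand
(single-strand convention). Flank sufficiency means ≥ 50 contiguous non-N
bases on each side within the contig (a proxy for primer design room),
measured to the contig ends, not to the nearest other repeat. Compound
tracts separated by ≥ 1 bp are separate hits.

## Synthetic data

The generator emulates the two-pool study design. Individuals are
unrelated, sites are in Hardy–Weinberg with no linkage: each of the 2N
haplotypes carries a planted allele independently with the site's
configured frequency, and the *realized* haplotype frequency is written
back to the truth ledger for scoring. Reads fall uniformly along contigs
(no expression skew — abundance bias in real RNA-seq is a sequencing
artifact orthogonal to the SNP logic and is not modeled), single-end by
default with an optional paired mode.

Per-base phred scores are drawn around a declining profile (default mean
38 at the 5′ end to 28 at the 3′ end, sd 6, clipped to [2, 41]) and
**errors are placed in proportion to the nominal error probability
10^(−q/10)**, normalized so the expected per-read error count equals
`base_error_rate` × read length. This keeps quality scores meaningful —
with quality-independent errors the protocol's quality gates would be
uninformative by construction. Error bases substitute uniformly among the
other three bases; alt alleles of planted SNPs are transitions with
probability 2/3 (the transition excess seen in transcriptome SNP
surveys).

Defaults, chosen once as realistic study conditions where the protocol
itself states none: 47 + 19 diploid individuals; 2 intra-specific SNPs/kb
per species plus 0.2 shared/kb; 1 fixed difference/kb; 0.2 indels/kb
(1–3 bp); 0.3 microsatellite and 0.3 homopolymer tracts per contig; MAF
uniform on {0.10, 0.15, …, 0.50}; 100 bp reads at 100× per species;
0.1% mean base error. Variants are not planted within 10 bp of contig
ends (coverage ramps there). What the generator does **not** model:
expression skew, paralogy/misassembly (PSV/MSV), library chimeras,
quality-correlated indel errors, linkage. Passing recovery tests
therefore show the *rules* are implemented and separable from planted
truth under calibrated error — not that real paralog-rich transcriptomes
would behave as cleanly.

## Validation experiments and sizes

The test suite validates by construction (brute-force oracles) and by
recovery. Problem sizes are chosen to exercise the statistics while
keeping a desk-scale single-CPU run: 1,000 random pileup columns (depths
1–200) for rule-oracle equivalence; exhaustive per-species depth grids
0–8 for classification; a 200-contig (~1 kb each) two-pool experiment at
100× per species and 0.1% error for recovery (the acceptance script
reruns it from scratch at an arbitrary seed); 10,000 random kilobases
plus adversarial boundary constructs for the microsatellite scanner; a
12-contig run at 200× for MAF accuracy. Recovery is scored against
eligible truth records: bi-allelic planted sites with realized minor
frequency ≥ 0.15, no other planted feature within 15 bp, outside planted
tracts — sites that violate these are *expected* to be filtered, which
the false-pass and leakage checks confirm.

## Numerical and tie-break conventions

* Allele order ties break alphabetically (A < C < G < T < `-`);
  consensus ties to the lower base code.
* The MAF boundary is inclusive (0.10 passes); counts are integers so the
  comparison is exact at representable fractions.
* Placement score ties break by (contig order, start, forward strand).
* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); identical config + seed reproduces every
  output file byte for byte, which the manifest's checksums make visible.

## Known limitations

* No PSV/MSV (paralog) detection — the upstream protocol defines no
  algorithm for it; repeat masking and the bi-allelic rule are the only
  defenses.
* The mapper is a minimal faithful stand-in for a commercial assembler's
  read mapping, not a competitive aligner: no gapped seeding, no
  paired-end rescue, no quality-aware scoring.
* Classification of sites absent from both species-level lists relies on
  per-species depths at pooled candidate positions (`pooled_only` flag),
  a choice the original three-assembly design leaves unspecified.
* Indel calls exist only as clean-flank neighbors; indel genotyping and
  reporting are out of scope.
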