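# Methods

`censkim` re-creates, at desk scale, the assembly-free analysis chain used
to characterize centromeric DNA in a monocentric repeat-rich genome such as
that of the red flour beetle: repeats are discovered by graph-based
clustering of low-pass shotgun reads, centromere association is scored by
mapping CenH3 ChIP and input-control reads onto the clusters, satellite
clusters are decomposed into subfamilies, and the cytological observations
(extended metapolycentric centromeres, satellite/CenH3 co-localization on
chromatin fibers) are quantified from 1-D intensity profiles. Every stage
is driven by a synthetic repeatome generator with complete ground truth, so
the pipeline is testable end to end without any external data.

## Synthetic repeatome

A genome spec lists repeat families with a monomer length, genome
fraction, number of subfamilies, maximum subfamily divergence, tandem or
dispersed organization, and a centromeric flag. The default family set
emulates the beetle repeatome: a major satellite (360-bp monomers, five
subfamilies mutually divergent up to 30%, 17% of the genome, centromeric),
a minor euchromatic satellite (180 bp, 0.5%), a rare satellite (73 bp,
0.05%, centromeric), 5S rDNA-like units (192 bp = 119-bp gene + 73-bp
spacer, 0.2%), dispersed retroelement-like copies (1.5 kb, 3%), and short
interstitial (TCAGG)n arrays constrained to 100–400 bp. The default
genome is 2.04 Mb — a 1:100 scale model of a 204-Mb genome — so that 0.2x
coverage with 151-nt reads corresponds to 2,702 reads by the same
count formula that yields 270,200 reads at full scale
(ceiling of coverage x genome length / read length, rounded up to an even
count for paired libraries).

Subfamily consensuses are generated by substituting a random ancestor
monomer at `floor(i/(n-1) * d/2 * L)` random positions for subfamily *i*,
which (a) bounds every pairwise divergence by *d* via the triangle
inequality and (b) gives graded mutual distances — some subfamily pairs
nearly identical, the extreme pair close to *d* — as observed in real
satellite families ("divergent up to" a bound, not equidistant). A
per-copy substitution rate (default 2%) roughens each planted monomer.
Substitutions only: no indel model is attempted, and the alignment layer
relies on this (see below).

Tandem arrays are whole-monomer, head-to-tail, one subfamily per array,
placed without overlap by a free-interval allocator; centromeric families
put 80% of their arrays inside the centromere interval (a centered block
covering 43.5% of the chromosome by default) and 20% immediately flanking
it, emulating satellite arrays that outspread beyond the CenH3 domains.
The 20% spill-over is a free parameter: no measured pericentromere/
centromere array ratio exists for the emulated genome. Dispersed families
are isolated copies placed outside centromeres so that ground truth about
"centromeric" reads stays unambiguous. Everything else is i.i.d. random
sequence. Note that the synthetic centromere interval is therefore mostly
background between arrays; only the planted arrays matter for enrichment,
because occupancy weights attach to arrays, not to the interval.

ChIP and input libraries are drawn position-wise: input read starts are
uniform; ChIP read starts are proportional to a weight that equals the
family's pull-down weight inside *occupied* centromeric arrays and the
background weight elsewhere. Each centromeric array is occupied
independently with probability `occupied_fraction` (default 0.5),
reflecting the observation that CenH3 nucleosomes associate with only a
fraction of the underlying repeat arrays. With the default weight 4 and
occupancy 0.5 on a 17% satellite, the closed-form expected ChIP:input
origin ratio for the major satellite is ~1.7–1.8 — enriched, but below 2,
which is why such a satellite is recovered through the high-abundance
selection criterion rather than the >2-fold criterion (mirroring the
published behaviour of the major satellite clusters).

What the generator does *not* model: sequencing errors beyond an optional
uniform substitution rate, indels, PCR duplicates, GC bias, adapter
contamination, chimeric reads, and any attempt at the real satellite
sequences. Tests passing on this generator demonstrate the correctness of
the analysis logic under the stated statistical structure, not robustness
to real-data artifacts.

## Read preprocessing

Quality filtering keeps reads with ≥ 95% of bases at Phred ≥ 10 (both
comparisons inclusive); trimming truncates to 151 nt from the 3' end and
drops shorter reads so downstream alignment can assume uniform length;
interlacing orders mates a1,a2,b1,b2 and drops a pair whenever either mate
was removed; subsampling draws reads without replacement to hit the target
coverage count, keeping pairs together, and warns outside the 0.01–0.50x
band recommended for read-clustering repeat discovery. Filtering and
trimming are idempotent; subsampling is reproducible from its seed.

## Similarity graph and clustering

Because the divergence model is substitution-only, pairwise similarity is
scored over *ungapped dovetail overlaps*: for each relative shift and both
orientations, identity = matching positions / overlap length, maximized
over shifts with overlap ≥ 55% of the read length; an edge requires
identity ≥ 0.90. These thresholds are the convention of graph-based
repeat-clustering pipelines; the analysis they come from does not state
its own. Candidates are proposed by shared k-mers, with k chosen by a
pigeonhole bound from the thresholds (k = 9 at the defaults): any
qualifying overlap must contain an exact k-run, and — because alignments
are ungapped — that seed proposes the exact shift, so seeding is lossless.
The tests verify the seeded edge set equals an exhaustive all-pairs,
all-shift oracle.

Clusters are connected components with ≥ 2 members, ranked by descending
size (ties: lexicographically smallest member id) and labelled CL1, CL2,
…; remaining reads are singletons. Community detection is deliberately
not used: at desk scale components are sufficient and deterministic. A
cluster's genome proportion is its share of analyzed reads. Annotation
against a reference library and subfamily decomposition assign each member
read to its best reference by semi-global (read-in-reference) alignment
identity computed with edlib; tandem consensuses are tiled so reads
crossing monomer junctions align; ties break to the lexicographically
first label, and a cluster is "unknown" when fewer than half its members
hit anything.

## ChIP enrichment and selection

ChIP and input reads are mapped against the member reads of the top-ranked
clusters with BLASTN-like ungapped bit scores (match +1, mismatch −2,
Karlin–Altschul lambda 1.28, K 0.46, word size 11; threshold default 90,
the middle of the conventional 30/90/150 settings). Each read contributes
at most one hit — to the cluster holding its best-scoring match — so hit
totals are bounded by the library size and ratios are library-size
invariant; score ties go to the more abundant cluster. An optional
candidate cap (evaluate only the targets sharing the most seeds) is a
BLAST-like speed heuristic, disabled wherever exactness is asserted.

Enrichment is the per-cluster ChIP/input hit ratio over equally sized
libraries (unequal libraries are refused unless explicitly scaled per
million reads); a cluster with zero input hits has an undefined ratio,
reported as NA and excluded from means. The mean enrichment is the
arithmetic mean of defined per-cluster ratios (the alternative — ratio of
summed hits — is not used). Selection applies two disjoint criteria
blocks with strict ratio inequalities:
ratio > 1 with ChIP support > 1% of analyzed reads (high-abundance), and
ratio > 2 with support ≥ 0.01% (enriched). A cluster satisfying both is
assigned by a precedence switch, default high-abundance first, matching
the published table's layout. Reported ratios are rounded half-up to two
decimals; full precision is kept internally.

## Cytometry

Profiles are per-position channel intensities along a polyline (the "plot
profile" output of image analysis). Thresholding is either fixed or
isodata — the iterative-intermeans algorithm that ImageJ applies as its
"Default" auto-threshold; presence means intensity strictly above the
threshold (taking the protocol phrase "higher or equal to 0" literally
would mark every pixel present, so it is treated as a wording slip, with
the criterion exposed as a parameter). A flat channel falls back to
strict positivity. Domains are maximal present runs after merging gaps
shorter than `min_gap` and discarding runs shorter than `min_domain`
(defaults 2% and 1% of the chromosome span — free parameters; the source
procedure states none). All extents are edge-inclusive (a one-pixel
domain measures one pixel), which makes the planted geometry recoverable
exactly at zero noise.

Centromere extent is the distance between the *outer* edges of the first
and last centromere-protein domains — inclusive of the outermost domains,
so a single dot-like domain has that domain's extent rather than zero —
relative to the DNA-stain span. Fiber co-localization is co-positive
positions over positions where at least one channel is positive (the
signal-bearing span standing in for "measured fiber length"), which makes
the overlap symmetric and bounded by each channel's fraction. Summaries
report means and sample SDs, excluding failed measurements (no detectable
domain), with SD 0 and a warning at n = 1.

## Expression (CPM)

CPM = hit count / library size x 1e6. Aggregation averages runs within
each biological replicate first, then reports mean and sample SD across
replicates per sample label — replicates, not runs, are the error unit.

## Pipeline and reproducibility

One global seed derives per-stage seeds as SHA-256 of "seed:stage" modulo
2^31, so any stage can be re-run in isolation. WGS simulation runs at
1.25x the target coverage and is randomly subsampled back down, exercising
the preprocessing chain the way oversized real libraries would. The run
manifest records the config snapshot, per-stage seeds and SHA-256
checksums of all artifacts; identical configs produce identical manifests.
On-disk conventions: FASTA genomes, BED (0-based half-open) annotations,
FASTQ (Phred+33) reads, TSV tables and profiles, YAML configs. 1-based
inclusive coordinates are used only when echoing published genomic spans
in documentation.

## Problem sizes used in tests and the acceptance analysis

The packaged analyses run on a 2.04-Mb genome (2,702 WGS reads, 20,000
ChIP and 20,000 input reads), a 500-kb genome for unit fixtures, ≤ 300
reads for the brute-force clustering oracle, 500 reads for subfamily
mixture recovery, and 240 simulated chromosome profiles plus single
synthetic fibers for cytometry recovery. These sizes were chosen as the
smallest at which every recovery target is comfortably identifiable;
published full-scale quantities that depend on the real 204-Mb data
(absolute hit counts, 51.44% clustered fraction, subfamily percentages)
are reproduced as *arithmetic* from their printed inputs, not re-measured.

## Known limitations

* Ungapped alignment is exact only under the substitution-only divergence
  model; indel-rich real reads would need gapped overlap alignment.
* Chance 2-member clusters of overlapping background reads are expected at
  low coverage, and at desk-scale library sizes the 0.01% support
  threshold is only a handful of reads, so the "enriched" block picks up
  small-sample noise clusters alongside genuine signal; the high-abundance
  criterion carries the recovery guarantees.
* The per-cluster enrichment of a centromeric satellite depends on which
  of its arrays the occupancy draw marks occupied; clusters dominated by
  unoccupied arrays legitimately score at or below 1.
* Mapping sensitivity below ~50 matching bases (bit score 90) is limited
  by the word-11 seeding, as in the BLASTN-style tool it models.
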