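# Methods

This note records the models, parameter choices and numerical conventions
behind `ashcomp`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## The setting being modelled

The package targets the comparative analysis of compact fungal genomes with
three properties that shape every algorithm in it: GC content near 50%, very
few repetitive sequences outside the telomeric arrays and a handful of
tandem gene families, and dense single-intron protein-coding genes.  The
sequencing model is early short-read data: 36-base single-end reads at ~35×
and 58-base mate pairs with inserts of 1.6 ± 0.15 kb.  Three genomes are
compared: a reference strain, a second strain whose genome is ~99.9%
identical except for one short introgressed block at ~92% identity, and a
sibling species at ~90% identity whose gene order differs by a few
reciprocal translocations and tandem copy-number changes.

## Synthetic-data generator

`generate_ancestor` draws i.i.d. bases at the configured GC (default 0.52),
flanks every chromosome with ≥3 copies of the 24-base telomeric unit
(reverse-complemented on the right end), and places non-overlapping ORF-like
genes (ATG + stop-free codons + stop) on both strands at `gene_density`
(default 4 genes / 10 kb; genes 450–1350 nt).  A fraction `intron_rate`
(default 0.05) of genes carries one intron of 64–150 nt (mean ≈ 107, the
scale typical of these genomes) built as `GTATGT … TACTAAC … TTTCAG`, so
splice-consensus recovery has a known generator motif.  Tandem arrays are
planted as adjacent gene copies ~2% diverged from each other, sharing a
family label.

**One-sided strain divergence.**  The configured substitution (10⁻³) and
indel (10⁻⁴) rates are *pair* rates: strain A is the reference lineage
(identical to the ancestor) and all events are applied to strain B.  This
reproduces the observed pair identity (10⁻³ → 99.9%) and keeps the planted
truth in reference coordinates, which is what makes precision/recall of 1.0
a meaningful target.  Substitutions are transition-biased
(`transition_fraction`, default 0.63, matching the transition excess such
strain pairs show).  Indel lengths are uniform on 1–5 bases.  Events keep a
minimum spacing (6 bases between substitutions, 12 around indels) and stay
off the telomeric arrays; without spacing, adjacent-event alignment
representations are ambiguous and no caller could match the truth exactly —
the spacing models the fact that at 10⁻³ divergence genuinely overlapping
events are rare.  The introgressed block replaces a 5-kb interval with a
donor haplotype diverged by 8% independent substitutions, making both real
copies equidistant from the donor lineage.

**Species derivation** applies tandem copy-number edits (deleting trailing
copies or inserting diverged duplicates), then `n_translocations` reciprocal
arm exchanges cut at inter-gene midpoints between 1:1-mapped genes (so
flanking-gene reporting is well defined), then genome-wide substitutions at
10%.  Truth breakpoints record the *novel* adjacencies of the derived
genome, the presentation used in translocation tables (gene to the left /
right of the breakpoint in the rearranged genome).

**Reads.**  `simulate_reads` samples read starts uniformly; per-base quality
classes are i.i.d. from the 4-class profile (probabilities
0.02/0.06/0.12/0.80 for classes 0–3, Phred midpoints 5/15/25/35) and
substitution errors are injected at the class rates 0.2/0.05/0.005/0.0005.
Mate pairs are emitted outward-facing (jumping-library convention; an
`innie` switch exists) with spans Normal(1600, 150).  `stratified_reads` is
a second, error-free sampling mode that jitters one start per equal stratum
and always covers the terminal bases; it exists for assembler
reconstruction work, where a >16-base random start gap (unbridgeable at
overlap floor 20) would otherwise make "exactly one contig identical to the
source" unattainable at 20× regardless of algorithm.

What the generator does **not** model: coverage biases at GC extremes,
chimeric mate pairs, structurally complex subtelomeres, paralog families
beyond the planted arrays, and real codon usage.  Tests passing on this
substrate show algorithmic correctness under the stated genome model, not
robustness to those artefacts.

## Assembler

The assembler follows the greedy hash-based design for uniform-length
reads: 2-bit sequence + 2-bit quality packing; collapsing of reads that are
identical or differ only at low-quality bases (consensus base from the
higher-quality read); initial contigs from exact (R−1)/R overlaps; joining
by decreasing overlap to a floor of 20; branch points — ≥2 distinct
extension bases each supported by ≥2 collapsed reads at class ≥2 — block
both extension and joining.  Ambiguous (non-unique) join partners are
skipped, never guessed.  Contig ids are assigned in lexicographic sequence
order and all tie-breaks are deterministic.

Robustness conventions the terse design leaves open, and how they are
resolved here:

* *Low quality* for collapsing is class ≤1 (Phred < 20, the Q20
  convention), exposed as `low_quality_max_class`.
* A divergence whose minority word lacks branch-level support (a lone,
  typically erroneous read) is bypassed in favour of the one well-supported
  continuation; a genuine branch (two supported alleles) still stops
  extension.  The same "one corroborated candidate wins over noise" rule
  applies to join partners.
* A contig that is still a single read remembers its per-base qualities;
  joins extend through such a contig only across its top-quality run, and
  the terminal base of any contig is dropped when it is below top quality —
  the R−1 chain overlap corroborates every interior base but never the
  terminal one.
* Contigs with mean depth < 2 after joining (`min_contig_depth`) are
  dropped as uncorroborated chains of singleton reads, unless they are the
  only output (a single input read still yields its contig).

Known limitation: near-identical tandem copies and the telomeric arrays can
still chimerise joins at short overlaps — the same repeat ambiguity that
makes mate-pair scaffolding necessary in the first place; the scorecard's
`assembly_identity` (exact-substring fraction) surfaces it.

## Scaffolder

Anchoring uses 31-mers unique in the contig and occurring ≤4 times in the
reference (low-multiplicity k-mers are kept so repeat contigs see every
candidate locus), chained per (chromosome, strand, diagonal) by LIS; chains
within 10% of the best give secondary placements.  Mate reads map by unique
31-mers; a link needs ≥3 concordant pairs (`min_links`) whose within-contig
spans fit insert_mean + 3·SD, and estimates its gap as
median(insert_mean − span_a − span_b).  Scaffolds follow reference order;
links decide among candidate loci of multi-placement contigs and set
junction gaps (floored at 1 N); junctions without link support fall back to
reference-implied spacing and are flagged.  Links naming non-facing ends
are ignored at the junction rather than trusted.

## Comparator

Chromosomes are paired by name; anchors are 31-mers unique in both
sequences, chained by LIS.  Inter-anchor spans ≤20 kb are aligned globally
with affine gaps (match +1, mismatch −2, gap open −5, each further gap base
−1; Biopython's `PairwiseAligner` is the engine, and the tests verify its
scores against an independent three-state DP).  Longer spans are reported
unaligned rather than forced.  Each mismatch column is a SNP; each maximal
gap run is one insertion/deletion *event* of its length — the convention
that lets single-base and multi-base indels be tallied separately — and
indels are left-normalised against genome A.  Transitions are
purine↔purine / pyrimidine↔pyrimidine.  Coding classification translates
ref and alt codons in mRNA sense; indels and genes whose CDS length is not
a multiple of 3 are NA.

Identity windows count only columns where both genomes have a base; empty
windows carry `identity=None` rather than 0.  Introgression calling flags
maximal runs of ≥3 windows under 98% identity (merging runs separated by a
single passing window) and refines boundaries to the outermost variants
inside the run; with 1-kb windows this bounds the boundary error by one
window.  The 98%/3-window rule is a package choice: it sits between the
99.9% background and 92% signal with wide margin on both sides, and both
knobs are config-exposed.  Identical-segment detection (gene-conversion
candidates) seeds on shared 31-mers between different chromosomes and
extends exact matches maximally, reporting each segment once
(same-orientation matches; k-mers with >20 occurrences are skipped).

## Synteny and duplications

Breakpoint analysis reduces each genome's gene order to the 1:1-mapped
orthologs (unmapped genes — e.g. members of expanded families — are flagged
and skipped, which is also how up-to-`max_skip` gene losses inside a
conserved adjacency are tolerated).  An adjacency in genome A broken in B
(different chromosome or non-adjacent) is a breakpoint; two breakpoints
whose four arms exchange partners in B form one reciprocal event;
interlinked triples are three-way; chromosome-terminal cases telomeric.
Ancestry: the genome whose adjacency the outgroup preserves is ancestral;
the B-side check uses only *novel* B adjacencies so conserved neighbours
cannot mask the signal; missing flanks give `unclear`.  Tandem arrays are
maximal same-family runs with ≤1 intervening gene (`max_intervening`),
orientation-agnostic; cross-genome comparison falls back to a singleton
census (1 or 0) for families without an array.

## Annotation features

Introns are exon gaps; donor/branch/acceptor contexts are read in mRNA
sense; the branch point is the best match to TACTAAC with ≤1 mismatch.
Consensus matrices cover −3..+6 around the donor, the 7 branch positions,
and −6..+3 around the acceptor, columns normalised to 1.  Convergent
overlaps are opposite-strand span intersections containing both 3′ ends
(CDS ends stand in for transcript ends); intersections containing both 5′
ends are classed `5prime`, others `other`.  Introns under 20 bases are
flagged, not dropped.  Per-class intron counts and means are reported so
either inclusion convention (CDS-only vs all classes) is recoverable.

## Pipeline and problem sizes

`run_all` fans the global seed into independent per-stage streams, writes
every artefact with a content hash into a manifest, and scores each stage
against the planted truth (SNP/indel precision and recall, introgression
boundary error, breakpoint and array recovery, contig count and
exact-substring fraction).  Reruns are bit-identical.

The shipped tests and the acceptance script run at desk scale, chosen to
exercise every code path in minutes on one core: 5-kb genomes for assembler
reconstruction, a 3 × 100 kb strain pair for variant calling, 50 seeded
30-kb replicates for introgression detection, 20 seeded 3 × 30 kb replicates
for synteny recovery, and 200 simulated introns for splice consensus.  The
algorithms carry no scale assumptions beyond memory; the full-genome setting
(7 × ~1.3 Mb) differs only in runtime.
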