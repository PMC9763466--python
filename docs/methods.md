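# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic generator does and does not emulate, and
the known limitations.

## The locus model and coordinates

The analysis window is a single cT-DNA locus plus its plant flanks:
a 200-nt left flank, the 5287-nt cT-DNA, and a 200-nt right flank
(5687 nt). All coordinates are 1-based inclusive on this window, so the
left terminal inverted repeat (IR) spans 201–1148 (948 nt, starting at the
first cT-DNA base), the right IR 4528–5487 (960 nt, ending at the last),
and the genes *acs* (642–1840), *susL* (2677–3657) and *rolB* (4218–4532)
sit on the forward strand with their reading frames anchored at the
interval starts. Conversion to 0-based string indices happens in exactly
one method (`ReferenceMap.seq_index`). The source coordinates print both a
5287-nt and a 5286-nt length for the locus; the package adopts 5287
(the end − start + 1 arithmetic of the printed span).

Two reference sequences exist in a simulation:

* the **ancestral reconstruction** (`build_ancestral_ctdna`): left IR and
  reverse-complemented right IR identical, genes holding open reading
  frames, the locus seated behind a configurable target-site duplication
  (default 8 nt) of the flank;
* the **working reference** (what every analysis stage aligns against):
  the population root *after* the insertion-age substitution load has been
  applied to its repeats. Real analyses reference an extant allele whose
  repeats are already ~90% identical — which is also what makes
  repeat-region reads mappable to the correct copy. Using the
  repeat-identical ancestor as a mapping reference would make every
  repeat-region read ambiguous between the two copies.

## Repeat divergence and dating

Identity of the two repeat copies is computed from an end-free pairwise
alignment of the left copy against the reverse-complemented right copy:
terminal overhang columns (the 12-nt annotation-length difference) are
excluded from the denominator, internal gap columns count as mismatches.
This makes "originally identical" repeats score exactly 100% while
reproducing ~90%-style figures for aged repeats.

Dating inverts the molecular clock: divergence *d* = 1 − identity/100,
age *T* = *d*/μ under the default `paper` convention, or *T* = *d*/(2μ)
under `two_sided` (two copies mutating independently accumulate pairwise
divergence at 2μ per year). The default convention reproduces the printed
arithmetic of the source analysis (9.7% at μ = 6.5×10⁻⁹ → ≈15 Myr); the
two-sided alternative is exposed because standard theory would halve that
age. The generator and the estimator switch conventions together. No
multiple-hit correction is applied by default (`jukes_cantor=True` opts
in). The 95% CI treats the mismatch count as binomial over the aligned
columns (Clopper–Pearson) and propagates the bounds through the formula.

## The synthetic population generator

The generator is first-class, tested code; its defaults are the study
conditions of the bundled analyses.

**Repeat aging.** The total expected repeat divergence is
*D* = μ·T (paper convention; 2μ·T two-sided), with defaults
μ = 6.5×10⁻⁹/site/yr and T = 15×10⁶ yr, i.e. *D* = 0.0975. Each copy
receives a **fixed count** of substitutions at per-site fraction *q*
solved from the two-copy collision model 2q(1−q) + (2/3)q² = *D*, applied
**once at the population root**. All alleles therefore inherit the same
aged repeats — the simplified analogue of real repeats sharing most of
their post-insertion history — and the realized divergence sits at its
expectation instead of fluctuating with a single binomial draw, which
keeps mean-over-alleles recovery tests well calibrated. Lineage
substitutions avoid the repeat intervals, so the repeats carry exactly the
insertion-age signal; per-allele divergence estimates differ only through
alignment estimation (observed spread ≪ 1%, echoing the "remarkably
similar" per-allele identities of real data).

**Genealogy.** Two clades (groups A and B) split at the root, each with
two marker-defined subclades (A1/A2, B1/B2). With
`allele_divergence_range = (d_lo, d_hi)` (default 0.2%–7.3%, the spread of
real allele pairs), per-lineage substitution loads are chosen so a maximal
cross-clade pair diverges by ≈ d_hi over the whole window and a minimal
same-subclade pair by ≈ d_lo: with X = ½·d_hi scaled by the non-repeat
fraction of the window, the clade branch carries 0.6X, the subclade branch
0.1X, and each allele a private load uniform on (½·d_lo scaled, 0.3X).
Substitutions are uniform over the window outside the repeats and outside
marker guard windows.

**Indels.** Clade/subclade markers (a clade-A deletion echoing the
"most frequent deletion defines group A" pattern, subgroup deletions, one
subgroup plant insert) are drawn once; private events are Poisson
(mean 1.2/allele) from a spectrum modeled on the observed catalog:
deletions 3–49 nt (weight 0.45), insertions 3–40 nt (0.20), tandem
duplications 12–20 nt (0.10), plant inserts with a 20–80 nt core behind a
5–10 nt target-site duplication (0.25). Every event is recorded in the
truth table in its canonical left-aligned form; placements are drawn in
the central unique region (window 1160–4510), with substitution-free
normalization windows and a minimum separation of ~12 nt so positions stay
identifiable — including across the two haplotypes of one accession,
because colliding heterozygous gaps cannot be distinguished by short
reads. An empty spectrum disables all indels including markers.

**Accessions.** Each accession is heterozygous with probability 0.58
(≈ the observed paired/unique split) and, if so, cross-clade with
probability 0.5 ("many pairs have one member on each branch"); homozygous
accessions carry one lineage (allele id `*_un`). With probability
`p_rearranged_lineage` (default 1, since the real data contain exactly one
such lineage) an extra early-diverged accession receives the
inverted-center rearrangement: the segment between the repeats is
reverse-complemented and two junction deletions (30–60 and 20–50 nt) are
applied. It is emitted as an assembled allele (`outgroup.fa`), not as
reads: with the palindromic repeat structure, a centrally inverted allele
is globally near-reverse-complementary to the reference and its reads
cannot be consistently oriented by a reference-mapping phaser.

**Reads.** Uniform-start 150-nt reads from both strands at the configured
per-allele coverage (default 30×; Poisson count), with optional uniform
substitution errors (default 0, matching the error-free acceptance
fixtures; no indel errors are simulated). Templates are padded with a
shared 80-nt "outer genomic context" beyond the window so window-edge
positions keep coverage, as they do when reads come from a whole genome.
Read names carry no information about the allele of origin.

What the generator does **not** emulate: sequencing indel errors and
quality-score structure, paired-end inserts, non-uniform coverage,
repetitive plant genomes outside the locus (plant inserts are random
sequence, so partially reconstructable kb-scale repeats do not arise),
gene conversion between the repeats, and recombination after founding.
Passing tests therefore demonstrate the pipeline's correctness under
clean Illumina-like conditions, not robustness to every artifact of real
SRA data.

## Read recruitment and phasing

Recruitment aligns each read (both strands) as an infix of the working
reference. Identity is indel-aware — each mismatch counts 1, each gap run
counts a flat 3 — so reads spanning sizeable indels (the most informative
ones) are kept; the default threshold is 0.85 over ≥100 nt.

All read-level alignment uses edit-distance alignment (edlib) followed by
**affine-gap local realignment** of indel-bearing regions (match +1,
mismatch −1, gap open −4, extend −1): unit-cost optima scatter long indels
across cost-tied mismatch paths, and the realignment restores contiguous
gap runs. Terminal dirty clusters are realigned against a target window
extended 60 nt beyond the original span with free target end-gaps, which
rescues reads whose head or tail crosses a long deletion. Observations are
left-normalized against the reference so equivalent indel placements from
different reads vote together; insertion observations within six columns
(or one insert length) cluster onto the best-supported column.
Edit-dense terminal segments (>2 edits before the first 10-nt match run,
e.g. outer-context overhang at the window boundary) are dropped, as are
the outermost three aligned columns of read ends that stop inside the
window (reads ending at a deletion junction can terminate in a few
coincidentally matching bases).

Variant columns require two alternatives, each with ≥2 supporting reads
and a minor fraction ≥0.2; singleton discrepancies are treated as
sequencing error. "No insertion" votes at an insertion column are only
accepted from reads spanning the longest observed insert plus anchors,
because a read ending inside an insert (e.g. inside a tandem-duplicated
copy) aligns cleanly without it. Reads are partitioned into two groups by
transitive linkage: the best-covered variant column seeds the groups, and
further columns are oriented by votes of already-assigned reads, fixed
only at ≥2 votes with a ≥80% margin (stray votes from junction-misaligned
reads must not flip a column). Adjacent deletion-bearing columns are
harmonized as one physical gap. **Columns no read links to the phased set
carry no phase information; they are joined by reference affinity** (the
reference-matching alternative goes to the same haplotype as every other
reference-matching alternative). This convention is the honest resolution
of an unidentifiable quantity: with 150-nt single-end reads, variants
farther apart than a read length cannot be phased relative to each other.
Consequences: low-divergence allele pairs may be reconstructed as
reference-affine chimeras of the two haplotypes between linkage blocks,
while each variant column still carries its two alternatives on opposite
haplotypes — so indel catalogs, per-event allele counts and group-level
conclusions are unaffected (verified against truth tables), and
byte-exact haplotype recovery holds when one haplotype is reference-like
or divergence is dense enough for linkage.

Each group yields an indel-aware majority consensus (ties prefer the
reference; zero-coverage positions fall back to the reference); variant
columns take their phased symbol by construction, and those sites are
protected through up to two rounds of **polishing** (realigning the
group's reads to the draft and re-voting), which removes residual
alignment-tie artifacts around long gaps. Mean coverage below 10× is
reported `insufficient` (≈45 reads over the window, ~1.2×, is far below
any phasing signal); identical group consensuses collapse to `unique`.

## Indel catalog conventions

Positions are the window coordinate of the last reference base before the
modification, left-aligned (5'-most equivalent placement); equivalent
placements are listed and flagged `ambiguous_boundary`. Deletion sequences
come from the reference, insertions from the allele. Insertions are
re-typed `dupl` when they are k concatenated copies of the adjacent
reference segment (copy number reported) and `plant_insert` when a 3–12 nt
reference k-mer is duplicated across them (the duplicated motif is
reported; in the left-aligned representation the insert *starts* with the
copy of the k-mer that follows the insertion point). Events closer than
3 nt are flagged `compound` rather than force-decomposed; inserts
containing `N` are flagged `partial`. Catalog rows merge on
(position, type, sequence, motif) with `x` = number of carrying alleles
and letter-suffixed labels (`449a`, `449b`) at shared positions.
Hypervariable regions are maximal merges of 15-nt windows containing ≥4
distinct rows.

## Gene disruption scan

Each gene is translated in the frame anchored at its (alignment-lifted)
start. Premature stops are reported at the window coordinate of the stop
codon's **last** base with a 12-nt context ending at that base — the
convention that matches both printed stop positions of the source locus
(1556 and 1538 are third codon positions in frames anchored at the printed
gene starts). Frameshifts are reported where an indel of length ≢ 0 mod 3
falls in the gene; deletions ≥30 nt report `truncation`. Downstream of a
frameshift the scan continues in the shifted frame (an ORF scan of what
the allele actually encodes), and only the first premature stop per gene
is reported.

## Insertion-site reconstruction

Empty and filled sequences are chained by unique 21-mer anchors (longest
colinear subsequence), blocks are maximally extended base-by-base, and
junction gaps become calls: `filled_only` (inserts in the filled site) or
`empty_only` (segments absent from it); gaps on both sides of one junction
are flagged `replacement`. Where a target-site duplication lets both
neighboring blocks claim the same bases, the following block is trimmed so
the duplicated copy joins the insert. Target-site duplications are the
longest 3–15 nt k-mer duplicated at the insert's immediate flanks,
searched over all equivalent insert placements; the reported interval
excludes both motif copies (one copy reads as the ancestral target, one as
its duplication). Terminal inverted repeats are the longest prefix (from
half the insert down to 5 nt) whose reverse complement ends the insert,
allowing a configurable mismatch count. Boundary calls on repetitive
flanks inherit the ambiguity of the sequence itself (a coincidental
flank match can shift a boundary by a base or two).

## Tree and concordance

Alleles are aligned with mafft (deterministic input order), and columns
with >20% gaps are dropped — the reproducible stand-in for manual removal
of indel columns before tree building. Distances are Jukes–Cantor
corrected p-distances with pairwise deletion; the topology is neighbor
joining with nonparametric bootstrap (column resampling, default
100–200 replicates), rooted at the outgroup's attachment node. NJ replaces
the maximum-likelihood engine of the source protocol for desk-scale
determinism; the Newick export allows re-analysis with an external ML
tool. Groups A and B are the two ingroup children of the root; the letter
A goes to the clade richer in the most prevalent marker. Each marker's
home group is its majority group; carriers in the other group are reported
as homoplasy exceptions, and marker-defined sub-sets within the home group
get numbered subgroup labels (A1, B2, ...). Subgroups are defined strictly
by markers — the finer visual subdivisions of real trees have no stated
clade definitions and are not reproduced. Pair spans list each
heterozygous accession's two group labels and the cross-group fraction.

## Problem sizes and determinism

Bundled analyses and tests run at desk scale: populations of 10–60
accessions, coverage 25–50×, 10–200 bootstrap replicates — large enough
for every statistical check (binomial bounds, 3-SE clock checks, ≥95%
phasing recovery over 50 replicates) while keeping the full suite in a few
minutes. Every stage is a pure function of its configuration: a fixed seed
yields byte-identical FASTA/FASTQ/truth files and run directories (no
timestamps are written).

## Known limitations

* Phase between linkage-disconnected variant blocks is assigned by
  reference affinity, not inferred (unidentifiable from the data); see
  above for what this does and does not affect.
* kb-scale repetitive plant inserts — only partially reconstructable in
  real assemblies — are not simulated; `partial` flags exist but are
  exercised only by construction.
* The gene scan assumes forward-strand genes with frames anchored at the
  annotated starts; strand is a property of the feature table, not
  inferred.
* Dating assumes no gene conversion between repeats and no rate variation;
  the convention switch covers the main theoretical ambiguity
  (per-lineage vs two-sided divergence).
* The inverted-center classifier reports junction deletions from alignment
  offsets; their sizes are approximate within the repeat-boundary
  ambiguity of the rearrangement itself.
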