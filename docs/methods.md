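# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `gliascan`, in the order the pipeline runs.

## Synthetic data generator

The generator fabricates the three inputs the pipeline consumes — an
assembly, a per-gene depth table and codon alignments — with exact ground
truth, so every downstream stage can be validated offline.

**Assemblies.** Chromosomes are i.i.d. uniform A/C/G/T background; homology
search must key on the planted genes, not on background realism (wheat's
repeat landscape is deliberately not modeled). Gliadin-like genes are
planted head-to-tail from sublocus anchor positions. Each copy derives from
a single template CDS (~200 codons: signal peptide, Q/P-rich repetitive
domain, two polyglutamine runs, two variable domains, terminal stop) by

* per-site independent substitutions at `substitution_rate`
  (default 0.02 subs/site — copies within a locus are a few percent
  diverged); substitutions keep truth coordinates exact because they never
  change length;
* optional pseudogenization (probability 0.1 by default): exactly one of a
  lost start codon, an internal premature stop, or a 1–2 bp deletion
  (frameshift) — the only length-changing events;
* epitope planting: selected epitope peptides are reverse-translated with a
  fixed codon table and overwrite codons in the repetitive domain *after*
  the substitution step, so planted peptides are always retrievable from
  the truth CDS. A glycine separator codon follows each planted peptide so
  a junction with the Q/P-rich template cannot create a spurious epitope
  occurrence.

The truth table records the final planted sequence, so the `intact_orf`
flag reflects what is actually in the assembly. A consequence worth knowing:
because the template is ~40% Q (CAA, one transition from TAA), chance
substitutions alone pseudogenize roughly half the copies at the 2% rate.
That is not a defect — real gliadin arrays show comparable intact
fractions (about a third to a half of copies) — but small simulations
should budget for it; the bundled toy pipeline config uses 0.015 so that
its 13-copy accession reliably leaves enough intact copies for the
phylogenetic and selection stages.

**Collapsed/heterozygous copies** are simulated purely in the depth table
(normal ≈ median, collapsed ≈ 2×, haplotype-specific ≈ 0.5×, plus Gaussian
noise truncated at zero), not by duplicating sequence — mirroring the fact
that read depth is the only evidence for them in a real assembly. The
default median is 32.23 genome equivalents.

**Codon alignments** evolve down a user tree under GY94 (below). Each site
draws its ω class from the same discretized mixture the inference uses
(M7: K = 10 beta category medians; M8: those plus the ω_s point mass), so
simulation and fitting share one model family and calibration tests carry
no discretization mismatch. Branch lengths are expected substitutions per
codon under the mixture-average rate. States live on the 61 sense codons;
stop codons are unreachable.

## Gene discovery

A deterministic replacement for a BLAST-based search, so results do not
depend on e-value heuristics or database composition:

1. exact k-mer seeds (default length 16, 2-bit packed) from each query are
   located on both strands;
2. co-linear seeds are chained greedily (diagonal drift ≤ 32 bp, genomic
   gap ≤ query length); chains of ≥ 2 seeds define a window (query span
   ± 48 bp);
3. the query is globally aligned to the window with free end gaps on the
   genomic side (match +1, mismatch −1, gap open −4, gap extend −1); the
   aligned genomic span is the candidate interval;
4. hits require identity ≥ 0.90 over the aligned columns and aligned length
   ≥ 300 bp (replacing the tool-specific "e-value = 0" notion with
   reproducible cutoffs); overlapping same-strand hits are merged keeping
   the best score.

A hit is contiguous on the genome by construction, which enforces the
single-exon (intronless) structure of α-gliadins; no intron model exists or
is wanted. Requiring two co-linear seeds suppresses the ~k-mer-rate of
random singleton matches on megabase backgrounds; a true gene at ≤ 5%
divergence retains hundreds of intact 16-mers, so sensitivity is unaffected.

ORF classification never discards: flags (`starts_with_met`,
`has_internal_stop`, `has_terminal_stop`, `frameshifted`) drive downstream
filters. The reported protein covers all complete codons except a terminal
stop; internal stops render as `*`. The divergence filter computes protein
p-distance to the nearest query after global alignment (match +4,
mismatch −1, gap open −10, gap extend −1) and discards above 0.35 — a
level that separates gliadin paralogs from unrelated prolamins; note that
frameshifted pseudogenes routinely exceed it because their translation is
garbled downstream of the indel.

## Locus mapping

Single-linkage clustering of gene midpoints with a gap threshold
(`gap_mb`, default 5): within-array spans are ≤ ~2.4 Mb while genuine
subloci sit ≥ ~6.6 Mb apart, so 5 Mb cleanly separates the regimes.
Raising the threshold can only merge clusters (monotonicity). Names follow
the *Gli-{A,B,D}2* convention with `-1, -2, …` suffixes in coordinate
order when a chromosome has more than one cluster; the subgenome letter is
parsed from the chromosome name, anything unparseable maps to `Un`.
Separations are reported as start-of-later minus end-of-earlier in Mb
(1 decimal, plus integer rounding); overlapping spans report 0 with a
warning. Copies on unanchored scaffolds default to *Gli-D2* (the
literature convention) unless tree clades say otherwise, in which case the
clade's locus wins and a conflict flag is set.

## Epitope profiling

Exact, overlap-aware substring matching (regex lookahead), no wildcards or
deamidation modeling — canonical epitope sequences only. The shipped table
holds the four well-established DQ2.5-glia-α 9-mers (α1a `PFPQPQLPY`, α1b
`PYPQPQLPY`, α2 `PQPQLPYPQ`, α3 `FRPQQPYPQ`) plus the 33-mer; the full
nine-epitope canon varies by source, so the table is a user-supplied TSV
rather than hardcoded. The 33-mer detector reports both the exact substring
count and a composite criterion (≥ 6 overlapping repeat-domain 9-mer hits
within a 33-residue window), since both views appear in practice. Profiles
count *occurrences* per (accession, locus, epitope) and keep zero rows so
absences are visible; a distinct-epitopes-per-gene summary covers the
presence/absence view, as it is genuinely ambiguous which convention a
given published figure uses.

## Phylogenetics

**Codon alignment** is protein-guided: translations are aligned to the most
central sequence (highest total 3-mer similarity) pairwise and merged
once-a-gap-always-a-gap (center-star), then back-projected to codons, so
gaps always occupy whole codons. The scoring constants are fixed and
documented above; no attempt is made to reproduce any particular MSA tool's
output.

**Distances** are K2P with optional gamma rate variation (shape α = 2.25 by
default, matching common practice for gliadin data; α = ∞ gives plain K2P).
Complete deletion at codon granularity is the default; pairwise deletion is
available for gappier data. Saturated pairs (log/power argument ≤ 0)
receive a flagged ceiling distance (5.0) instead of an error because NJ
needs a complete matrix.

**Neighbor joining** is the canonical Saitou–Nei algorithm with the
Q-criterion; ties break on the lowest (row, column) index pair and negative
branch-length estimates clamp to 0 (both logged), making output
platform-deterministic. Bootstrap resamples codon columns with replacement;
support is the percentage of successful replicates containing each original
bipartition (degenerate replicates are skipped and counted).

**Clade membership** treats the tree as rooted at its parse point and
finds maximal subtrees whose informative (non-chrUn) leaves are > 50%
one locus label; leaves disagreeing with their clade's label are flagged as
misplaced copies, and chrUn leaves inherit the clade label (falling back to
the parent's dominant label for label-free subtrees). The > 50% rule means
a heavily skewed label distribution can legitimately absorb the whole tree
into one clade — dominance is relative, not a purity guarantee.

## Selection analysis (M7 vs M8)

**Cleanup** mirrors conservative site-model practice: rows with premature
stops, frameshifts, or no terminal stop are dropped (the terminal stop is
then stripped), all-gap codon columns are removed, and polyglutamine
regions are masked — any run of ≥ 8 consecutive codon columns whose
non-gap residues are ≥ 75% Q/P — because those repeats cannot be aligned
reliably and would generate false positives. Fewer than 3 surviving rows or
10 surviving columns aborts the fit (model unidentifiable). The mask report
maps cleaned column indices back to the original alignment.

**Model.** GY94 rates for single-nucleotide codon changes are
π_j · κ^[transition] · ω^[nonsynonymous]; multi-nucleotide changes are
forbidden. Codon frequencies are F3x4 estimated from the data (with a
small pseudocount). ω varies across sites as M7 = Beta(p, q) discretized
into K = 10 equal-probability categories represented by their medians (the
standard CODEML convention), or M8 = p0·Beta + (1−p0)·{ω_s ≥ 1}. The
generator matrix set is normalized by the mixture-average rate, and input
branch lengths are rescaled by a single free multiplier rather than
re-optimized per branch — a deliberate economy over CODEML that keeps the
optimization low-dimensional; the tree itself is always an input (the NJ
tree serves as fallback), never re-estimated here.

**Fitting.** The likelihood is Felsenstein pruning over the 61 sense-codon
states, with site-pattern compression, per-node rescaling against
underflow, and all ω classes batched into stacked matrix products; the
propagator for each (κ, ω) uses the symmetric eigendecomposition available
for reversible generators. Optimization is bounded L-BFGS-B (bounds:
κ ∈ [0.1, 20], p, q ∈ [0.05, 50], scale ∈ [10⁻³, 50], p0 ∈ [0, 1],
ω_s ∈ [1, 25]) from a default start plus seeded random restarts (default
5 total — the M8 surface is multimodal in (p0, ω_s)); callers testing
M8 against M7 should pass the M7 optimum with p0 = 1 as an extra M8 start,
which guarantees the nesting ℓ(M8) ≥ ℓ(M7) up to optimizer tolerance.
Boundary convergence (e.g. tree scale at 10⁻³ for invariant alignments) is
reported, and a fit where no start converged carries an explicit failure
flag rather than failing silently.

**Test and localization.** 2Δℓ = 2(ℓ₈ − ℓ₇), clamped at 0, is referred to
χ² with 2 degrees of freedom (the standard df for this pair; the true
boundary null is a mixture, so the test is conservative — calibration
simulations show under-rejection, which is the accepted direction). Site
posteriors default to NEB (posterior of the ω_s class at the MLEs); a
coarse-grid BEB that averages posteriors over a (p0, ω_s) grid weighted by
data likelihood — with the remaining parameters held at their MLEs — is
available but not the default, as full BEB integration buys little at the
simulation sizes where the method is validated. Sites with posterior > 0.95
are flagged significant.

**Simulation sizes.** The statistical validation suites use 8-taxon
balanced trees with 0.3-substitution branches: 20 replicates of 300 codons
under M7 for calibration (rejection ≤ 10% at the 5% level) and 20
replicates of 500 codons under M8 (ω_s = 3, 10% positive sites) for power
(≥ 80% rejection; positive sites out-rank beta sites in posterior in
≥ 18/20). These sizes make each fit a few seconds while leaving the tests
statistically sharp.

## Coverage QC

Mean depth per gene (from a per-gene or per-base table; absent bases count
as 0 with a warning) is divided by the genome-wide median gene coverage.
Ratios ≥ 1.5 flag collapsed paralogs, ≤ 0.6 flag haplotype-specific
copies; the thresholds sit between the 1× and 2×/0.5× expectations.
Note the asymmetry of the margins: the haplotype-specific side has only
0.1 × median between expectation (0.5×) and cutoff (0.6×), so reliable
truth recovery requires depth noise below roughly a third of that margin
(σ ≲ 0.033 × median). The toy pipeline sets its simulated noise
accordingly; with noisier depth data, expect borderline 0.5×-copies to be
called normal occasionally rather than the classification to be wrong in
any systematic direction.

## Pipeline and reproducibility

One YAML config drives the stage sequence discover → map-loci → epitopes →
phylo → selection → coverage, each skippable; all randomness flows from one
global seed expanded per stage. Every artifact is a plain-text format
(FASTA/BED/TSV/newick/JSON) and is SHA-256-hashed into `manifest.json`;
identical config + seed reproduces identical hashes. A stage failure writes
a `FAILED` marker and keeps partial outputs.

## What passing tests do and do not show

The synthetic generator validates algorithmic correctness — exact interval
recovery, exact truth bookkeeping, statistical calibration under the very
model the inference assumes. It does not emulate wheat repeat content,
assembly gaps, segmental duplications of whole subloci, alignment
uncertainty from indel-rich evolution, or ONT-specific coverage biases;
performance on real assemblies depends on those factors, and the published
full-genome figures (hundreds of copies across 11 accessions) are outside
desk scale by design.
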