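# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
construction existed.

## Coordinates and gene vocabulary

All coordinates are 0-based half-open on the deposited (+) strand.
Circular wrap-around is encoded as `end > genome length` (never more than
2× the length), keeping one feature per gene; GenBank's 1-based inclusive
convention is translated only at the I/O boundary.  Gene names are
normalized to the canonical 37-gene metazoan vocabulary (13 protein
genes, 22 tRNAs with trnL1/trnL2 and trnS1/trnS2 disambiguated by
anticodon, 2 rRNAs) through an extensible synonym table, because public
annotations are inconsistent across depositors.  Unknown labels are kept
verbatim and flagged rather than dropped.

## Composition and skews

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C) are computed from raw
counts.  Two conventions matter and are fixed as follows: whole-genome
statistics are computed on the deposited (+) strand, while per-gene
statistics are computed on each gene's sense strand, so that grouping
genes by coding strand exposes strand-asymmetric mutation pressure.
IUPAC ambiguity codes are excluded from counts and tallied separately.
A zero denominator returns a null sentinel (`None`), never a fabricated
0 — a sequence with no G or C simply has no GC-skew.  Rounding to three
decimals happens only in report tables; full precision is kept
internally.

## Codon usage

Translation table 5 (invertebrate mitochondrial: AGA/AGG→Ser, ATA→Met,
TGA→Trp; stops TAA/TAG) is the default and leaves 62 sense codons.
Incomplete stop codons — completed by polyadenylation in vivo — are
recognized only when the annotated CDS length mod 3 is 1 or 2 and the
trailing bases are T or TA.

Two synonymous-family conventions are used deliberately:

* **RSCU** families follow the amino acid (Leu 6, Ser 8 codons), the
  MEGA convention, so RSCU values are comparable with the codon-usage
  literature.  Families of unobserved amino acids yield nulls, not 0/0.
* **ENC** families are split by the first two codon positions, giving 13
  two-fold and 9 four-fold families; with Wright's homozygosity
  F̂ = (nΣp̂²−1)/(n−1) per family, class means over families with n ≥ 2,
  and ENC = 13/F̄₂ + 9/F̄₄ capped at 62, ENC ranges over [22, 62].  A
  class with no estimable family is imputed from the other class rescaled
  so uniform usage maps to uniform (F̄₂ = 2F̄₄, capped at 1) and flagged.

The composition-adjusted ENC replaces Wright's homozygosity with the
χ²-based deviation from the codon frequencies expected under a background
base composition, F̂′ = (χ² + n − k)/(k(n−1)): with a uniform background
it reduces exactly to Wright's estimator, and usage exactly proportional
to the background scores as unbiased (ENC = 62).  The background may be
4 overall or 3×4 position-specific base frequencies.

## Gene order

A gene order is a signed circular permutation; representations are
equivalent under rotation and under reflection-with-sign-flip.  The
breakpoint distance counts signed adjacencies of one order absent from
the other, with the adjacency (a, b) identified with (−b, −a); it is a
rotation/reflection-invariant pseudo-metric bounded by the gene count,
verified exhaustively against an independent extremity-set (head/tail)
formulation on small permutations.  The published dissimilarities this
reproduces were computed with rearrangement software whose exact
bookkeeping is not printed; the definition used here is stated precisely
so discrepancies are attributable.  The control region is excluded from
the permutation because its strand is not reliably assignable.  The
pancrustacean ground-pattern order ships as an editable data file; the
family-style template order is a constructed, clearly-labelled synthetic
stand-in satisfying the qualitative constraints described for the group
(conserved cox1..cox3 string, the nad5–nad4L minus-strand block, the
trnA,trnS1,trnN,trnE,trnR string, trnS2+cob beside the control region,
inverted trnT, 21/16 strand split).

## GY94 selection model

The codon model is a 62-state reversible Markov process: rates between
codons differing at one nucleotide are π_j, multiplied by κ for
transitions and by ω for nonsynonymous changes; multi-nucleotide changes
are forbidden.  Codon frequencies are F3x4 (products of position-specific
base frequencies, stops removed, renormalized).  The generator is scaled
so branch lengths are expected substitutions per codon.  P(t) is computed
by symmetrized eigendecomposition (exact for reversible models).

Estimation maximizes the likelihood over log-parameters with bounded
L-BFGS-B and random restarts; bounds t ∈ [1e−6, 50], κ ∈ [0.01, 100],
ω ∈ [1e−4, 20]; site patterns are collapsed before pruning.  Gaps and
ambiguous codons are treated as missing data and marginalized, not
deleted column-wise — this preserves per-gene length but can differ
slightly from implementations that strip incomplete columns.  Identical
sequences give a boundary t̂ and an explicit indeterminate-ω flag rather
than a meaningless ratio.  When an alignment lacks some base at some
codon position entirely, the fitters (only) replace zero positional
frequencies with a pseudo-frequency, with a warning; the plain `f3x4`
accessor reports the exact frequencies.

Recovery behaviour, measured by the acceptance suite: pairwise ω̂ at
2000 codons (true ω ∈ {0.02, 0.1, 0.5}, κ = 2, t = 0.5, 10 replicates)
shows mean bias below 20% of the true value; the one-ratio fit on a
6-taxon simulated tree at 600 codons recovers ω within sampling error.

## Phylogenetic informativeness

Per-site rates are estimated on a fixed rooted ultrametric chronogram
(validated to tolerance 1e−6 × depth) by one-dimensional bounded ML:
the pruning likelihood of a column with branch lengths equal to
chronogram durations × λ, maximized over λ ∈ [0, λ_max] by Brent's
method (tolerance 1e−8; λ_max defaults to 20/tree-depth and sites at the
bound are flagged).  Under HKY, base frequencies are empirical and κ is
estimated once per partition by pooled ML, then fixed for the per-site
optimizations; invariant columns get λ = 0.  The four-state
informativeness ρ(t; λ) = 16λ²t·e^(−4λt) is applied to every partition,
including codon-position partitions, as is standard for profiling
protein-coding genes; its analytic peak at t = 1/(4λ) with height 4λ/e
is asserted in tests.  Net profiles are sums over sites; partition
shares are pointwise fractions of the summed net profiles.  The exact
per-site rate engine used by the original web tools is not reproducible
from their descriptions, so only ordering and share claims — not exact
curves — should be compared.

## RNA structure

Dot-bracket strings parse into nested pair maps; unbalanced brackets
report the offending index and crossing pairs are rejected as
pseudoknots.  A column is conserved iff exactly one non-gap state occurs
and its gap fraction is ≤ 20% (configurable).  Substitutions are
polarized against the column consensus by default — the simplest scheme
consistent with "deduced" changes when no ancestral reconstruction is
published; at stem columns the joint pair states are compared per row:
both sides changed with pairing kept valid (Watson–Crick or GU) is
compensatory, one side changed with pairing kept valid is
hemi-compensatory, pairing broken is mismatch-introducing, and an
invalid consensus pair made valid is mismatch-resolving.  GU wobble
counts as valid pairing throughout.  The accounting identity
`Σ exchanges = unpaired substitutions + Σ sides changed in pair events`
is enforced by tests.

Cloverleaf validation identifies the acceptor stem as the outermost
helix and classifies the hairpins in its multiloop positionally (DHU,
anticodon, TΨC).  A missing DHU or TΨC arm — common in mitochondrial
tRNAs — is reported, not fatal; with two hairpins the missing arm is
inferred from the spacing to the acceptor strands.  Non-canonical stem
pairs such as U-U are listed as mismatches with their positions.

## Noncoding features

The inverted-repeat finder is seed-and-extend: exact 8-mer matches
between the sequence and its reverse complement, extended without gaps
under a +1/−2 match/mismatch score with an X-drop of 8, keeping the
best-scoring endpoints; hits are filtered by arm length, loop length and
arm identity, and redundant descriptions of the same repeat are pruned.
It is ungapped by design — sufficient for the mitochondrial use case of
hairpin-capable palindromes and near-perfect long repeats; indel-riddled
repeats would be under-called, which is documented rather than hidden.
The tandem finder scans each unit length for runs of consecutive units
matching the running consensus at the identity threshold, then
re-anchors the array to the cyclic phase maximizing consensus identity;
units must contain at least two distinct bases so A/T homopolymers in
AT-rich regions are not reported as repeats.  A reported array is
phase-anchored, so a rotation of the planted unit with the same span,
copy number and identity is an equivalent description.

The control-region scan enforces the canonical feature order
TATA < poly-T < (variable region) < poly-A < GANT, with poly-T/poly-A
minima of 10 (observed stretches run 14–15 T and 10–12 A), exact TATA,
degenerate GA-N-T, and stem-loop capability of the variable region
assessed with the inverted-repeat finder.  Because the strand carrying
the replication origin is uncertain, both strands are scanned and the
strand with more ordered features wins; missing features are reported,
never raised.  The GANT motif may lie past the annotated boundary
(embedded in the downstream tRNA gene), so callers can append the
downstream segment.

## Synthetic data: what it emulates, and what it does not

The generator emits circular ~14–15 kb genomes carrying the 37-gene set
in a configurable signed order: protein genes drawn codon-wise from
per-strand base-composition dials (canonical starts, no internal stops,
complete or incomplete stops as configured), tRNAs built from
Watson–Crick-paired cloverleaf templates including the four DHU-less
species, rRNA placeholders padded to realistic lengths with
domain-labelled synthetic reference structures, a control region built
from the five-feature blueprint (optionally with planted hairpins and
tandem arrays), and planted intergenic spacers.  Per-strand composition
defaults (AT% 75, AT-skew −0.02, GC-skew +0.10 on both strands) mirror
the AT-rich, reversed-strand-bias condition observed in the family the
package was built around; gene lengths are realistic invertebrate
values.  Pooled sense-strand skews are steered by a best-of-N redraw
(40 rounds) that lands realized values within about ±0.01 of target —
"rejection polishing" — and every realized quantity is recorded in the
truth bundle, so tests score modules against what was actually planted.

What it does not emulate: sequencing error and read-level artefacts,
among-gene composition heterogeneity beyond the strand dials,
thermodynamically realistic RNA folding (structures are templates, not
folds), selection heterogeneity among sites, and rate variation beyond
the configured partition multipliers.  Passing tests therefore
demonstrate correctness of the statistics and estimators on data obeying
the stated models — not robustness to annotation error or model
violation in field data.

Structured RNA evolution plants substitutions along a tree with separate
loop and stem event rates; each stem event preserves Watson–Crick
pairing with the configured compensation probability, and a full event
log is emitted so the substitution classifier can be scored exactly.
The rearrangement simulator applies transpositions, inversions and
reverse transpositions with a log, supporting the per-operation
breakpoint bounds (≤ 3, ≤ 2, ≤ 3 new breakpoints respectively).

## Problem sizes used in the shipped checks

The test-suite and acceptance script run at sizes chosen to exercise
each estimator meaningfully while keeping a laptop-scale footprint:
1000 random sequences for skew invariants; 100 simulated codon tables
against the brute-force ENC oracle (agreement to 1e−9); exhaustive
breakpoint enumeration at 4 genes plus sampled pairs at 6; GY94 recovery
at 2000 codons × 10 replicates (pairwise) and 600 codons on 6 taxa
(one-ratio); 16-taxon chronograms with 150–180 simulated columns for
rate recovery; and kilobase-scale sequences for the repeat and
control-region scans.

## Known limitations

* One-ratio ω assumes rate constancy across sites and branches; no site
  or branch models are provided.
* The per-site rate estimator fixes κ per partition; sites at the rate
  bound are flagged but still contribute their bounded estimate.
* Consensus polarization of RNA substitutions undercounts parallel
  changes shared by a majority of taxa; a tree-based reconstruction
  would be needed for deep, dense sampling.
* The repeat finders are ungapped; identities are per aligned position
  without indels.
* Breakpoint distance is reported without rearrangement-scenario
  reconstruction; distances from other software may differ by their
  (unpublished) bookkeeping conventions.
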