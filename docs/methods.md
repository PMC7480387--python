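# Methods

This note records the models, conventions and numerical choices behind
`gblreg`, and what the synthetic-data tests do and do not establish.

## Coordinate system

All regulatory positions are *anchored*: signed offsets relative to a gene's
translation start, with −1 the base immediately 5′ of the start codon, +1
the first base of the start codon, and no position 0. Internally anchored
positions map to a gapless ordinal line (−1 → −1, +1 → 0), so interval
lengths, overlaps and displacements are ordinary integer arithmetic even
across the missing zero. For − strand genes "upstream" is the higher
genomic coordinate; every anchored or upstream operation is defined in the
gene's reading orientation, and conversion to genomic coordinates handles
the strand. The convention was validated against the published protection
intervals (e.g. −55..−84 spans 30 nt). All pipeline output tables carry
both anchored and genomic coordinates to prevent convention drift.

## Bipartite promoter model

A promoter is scored as two 13-column additive weight matrices (the −35 and
−10 boxes, consensus hexamer at a configurable 0-based offset within the
13-nt stretch, default 3 ≈ centred) joined by *n* all-zero columns for a
spacer of *n* nucleotides. Null columns contribute exactly 0, so the
combined-matrix score equals the sum of the two window scores at every
offset — a property the tests verify against brute-force enumeration. The
scan enumerates every position × hexamer-spacer combination in the
configured range (default 14–22 nt, which covers all mapped spacers in the
bundled promoter table: 14, 19, 22, 19, 21, 21). Ranking is by total
score; ties break toward the smallest |TSP offset − 10| when a
transcription start is supplied, else toward the 3′-most −10 box. Windows
containing N are skipped rather than scored.

The original class A / class C alignment matrices are not redistributable,
so two clearly labelled synthetic stand-ins ship instead: log-odds-free
consensus matrices built from the σ70-like hexamers (TTGACA / TATAAT), and
matrices learned (pseudo-weight 0.1, uniform background) from the six
experimentally mapped hexamer pairs of the *sfb* cluster. Geometry
(positions, spacers, ranking behaviour) is therefore reproducible with
shipped data; absolute score values are matrix-dependent and are not a
claim of this package.

The TSP offset of a hit is the distance from the −10 hexamer centre (mean
of its two endpoint ordinals, a half-integer for hexamers) to the TSP,
positive upstream.

## Footprint algebra

A footprint pair is two anchored intervals, one per strand. Protection
length is inclusive interval length; strand displacement is the pair of
absolute differences between corresponding edges in genomic order,
summarised as the set of distinct nonzero offsets ({0} when the regions
coincide); overlap is inclusive intersection length. These definitions
reproduce all ten published protection lengths and the published
displacement/overlap summaries from the printed coordinates.

## Operator information model

For *n* aligned width-*w* sites: column frequencies `f_bl`, entropy
`H_l = −Σ_b f_bl log2 f_bl` (0·log 0 = 0), information
`2 − H_l − e(n)`, and `R_sequence = Σ_l` information. The small-sample
correction `e(n)` is computed *exactly* as the expected entropy shortfall
of an *n*-draw uniform multinomial (enumeration over count compositions),
which approaches the familiar 3/(2 ln2 · n) asymptote; it is off by
default because collections of ~10 sites are typically reported
uncorrected, and the flag lets users compare both conventions
(e(10) ≈ 0.247 bits/position, i.e. ~4.4 bits over an 18-nt site).

The IUPAC consensus takes, per column, the minimal code covering all bases
with frequency ≥ `min_freq` (default 0.10, chosen so a single observation
among ten sites qualifies). Dyad symmetry is the fraction of positions
whose IUPAC base set equals the complemented set at the mirrored position;
the published 18-nt operator consensus scores 16/18 under this rule.

Individual information of a window is `Ri = Σ_l [2 + log2 f′(b_l, l)]` with
pseudo-frequencies `f′ = (count + ½)/(n + 2)` so no base has probability
zero; both strands are scanned exhaustively and windows with `Ri ≥ 0` bits
(the conventional threshold) are reported as candidate sites.

Core sites are extracted from footprints by an align-and-refine loop:
protected regions are longer than the operator core (default width 18, the
length of the published consensus), so each window starts at its
protection's centre, a frequency model is built from the current windows,
each window is re-placed to maximise its own Ri, and the loop iterates to a
fixpoint (≤ 50 rounds). Both strands of each pair contribute a site, so
five footprint pairs yield the ten sites a logo is built from. The
operator is modelled as one contiguous 18-mer rather than two half-sites.

## Receptor classification

Isoelectric points solve `net_charge(pH) = 0` by bisection on [0, 14]
(interval tolerance 1e−7, charge tolerance 1e−4), with
Henderson–Hasselbalch terms for D, E, C, Y, H, K, R and the termini. Two
pKa sets ship — a Bjellqvist-style (ExPASy-compatible) default and EMBOSS —
because published pI values rarely state their set; the classification
threshold is pI 7.0 (receptor-like below, pseudo-like at or above,
boundary assigned upward).

Protein distances support p-distance, Poisson and the Kimura protein
correction `d = −ln(1 − p − p²/5)`; "two-parameter" distance settings in
common phylogeny GUIs are ambiguous for proteins, so the Kimura correction
is the default and the model is selectable. Gapped columns are
pairwise-deleted; saturated distances are capped at 10 with a warning.
Neighbor joining is the Saitou–Nei Q-criterion agglomeration with ties
broken by lowest pair index (fully deterministic); on additive matrices it
reproduces the generating tree's path lengths to 1e−9, and its path-length
matrices agree with scikit-bio's independent implementation on random
inputs. Bootstrap resamples alignment columns i.i.d. (flat, single seed),
builds a replicate NJ tree, and reports the percentage of replicates
containing each original bipartition; multiple alignment itself is out of
scope (alignments are inputs).

## qPCR quantification

Standard curves are ordinary least squares of Ct on log10 quantity;
`E = 10^(−1/slope)`; a non-negative slope is an error, while r² below the
threshold (default 0.99) only flags the curve. ΔCt is control − sample, so
the Pfaffl ratio `E_t^ΔCt_t / E_r^ΔCt_r` exceeds 1 when the sample
expresses more than the control. The significance test permutes condition
labels independently within the target and reference gene (replicates are
treated as flat, not nested), uses |log2 ratio| as the statistic, and
applies the +1/(reps+1) correction; it is seeded and vectorised. A single
reference gene is assumed. Operons are the transitive closure of positive
intergenic RT-PCR calls between adjacent same-strand genes; opposite-strand
neighbours are never merged regardless of the call.

## Synthetic data

Background sequence is i.i.d. with GC 0.72 (Streptomyces-like), so
log-odds scanners are exercised off the uniform background; no Markov
structure is simulated. Clusters lay genes left-to-right on the + strand
(600-nt CDS, 600-nt intergenic by default) with valid start/stop codons and
stop-free frames; implants (promoter hexamer pairs with a stated spacer,
PFM-sampled ARE sites, TTA codons) are placed at stated anchored positions
and recorded in a truth table with realised sequences and genomic
coordinates. qPCR tables follow Ct = intercept − log_E(quantity) with
Gaussian noise; treated Ct values encode the configured fold change under
the Pfaffl model, with 3 biological × 3 technical = 9 replicates by
default. Protein families evolve by i.i.d. substitutions on 20 letters
along a supplied Newick tree (per site, mutate with probability
1 − e^(−rate·t) to a uniformly chosen different residue); the evolved
matrix is gap-free and doubles as its own alignment. All generators are
pure functions of (config, seed).

What passing synthetic tests show — and what they do not: they establish
the internal correctness and statistical calibration of each stage
(recovery of implanted signals, exact recovery at zero noise, null
behaviour of the permutation test), but real promoter regions have
correlated composition, overlapping signals and mis-mapped coordinates
that i.i.d. background does not emulate; absolute performance on genomic
sequence is not claimed.

## Problem sizes

The test suite and the acceptance script run the simulations at desk
scale: 100 seeded clusters of 5 kb for ARE-site recovery, 500 seeds for
Pfaffl noise recovery, 500 null datasets × 2,000 permutations for the
randomization-test calibration, 1,000 random sequences for the
combined-matrix equivalence check, and 50 random additive matrices for NJ
recovery — sizes chosen so each property is measured with comfortable
margins while the whole suite stays fast on a single CPU.

## Known limitations

- Absolute promoter scores depend on the stand-in matrices; only geometry
  is a reproducible claim.
- The exact pKa set behind any published pI value is usually unstated;
  agreement beyond ~±0.05 pH units cannot be guaranteed across sets.
- In-silico PCR is exact-match only (no degenerate bases, both primers
  ≥ 15 nt, product length includes both primers).
- The accession-dependent checks (record length, regulator pIs,
  R_sequence from real footprint sites) require the deposited GenBank
  record at `data/MT017918.gb`; it is not redistributed with the package.
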