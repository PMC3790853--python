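# Methods

This note records the models, algorithmic choices and parameter defaults
behind `igcscan`, and what the synthetic-data tests do and do not
establish about behaviour on real genomes.

## Input model and preprocessing

The unit of analysis is a *family*: ≥4 paralogous genomic segments with
a gapless multiple alignment and per-member genomic loci (0-based,
half-open, BED convention; alignment columns are reported 1-based
inclusive in human-facing tables). Filters, applied in order:

1. **Terminal trim.** Leading/trailing columns are dropped until a
   window of 20 consecutive columns (`terminal_window`) is gap-free in
   every member. Alignment ends are where aligner output is least
   trustworthy; the window length is a pragmatic default, configurable.
2. **Identity floor** (`min_identity = 0.88`). A member is removed when
   its *maximum* pairwise identity to every other member falls below the
   floor, computed over columns where neither sequence is gapped. The
   maximum (rather than minimum or mean) keeps any sequence with at
   least one plausible conversion partner: below ~88% identity the
   conversion machinery is essentially inert, so a member with no
   partner above the floor contributes divergence but no signal.
3. **Gap inflation** (`gap_inflation_factor = 0.25`). A member whose
   removal would grow the family's ungapped column count by >25%
   (relative to the count without it) is dropped; applied greedily,
   worst offender first, recomputing after each removal to avoid order
   dependence.
4. **Gap purge.** Every remaining column containing any gap is deleted;
   per-member column→genome maps are updated so every surviving column
   maps to a genomic position in every member.
5. **Size gate.** Families shorter than `min_length = 10 kb` of ungapped
   alignment, or with fewer than 4 members, are rejected (an unrooted
   quartet needs four leaves; short alignments carry too few informative
   sites for the excess test).

**CpG stripping** removes both columns of every dinucleotide that reads
C-then-G on the forward strand in *any* member — the strictest reading,
so no hypermutable position survives in any row. Stripping is a single
pass: columns made adjacent by a removal are not re-examined, which
keeps the operation deterministic and the identity property (CpG-free
input is returned unchanged) exact. Whether one or both columns are
removed, and whether identity is measured on gapped or gap-excluded
columns, are configurable because published practice varies.

## Tree inference

Topologies come from neighbor joining on F84 maximum-likelihood
distances (the Kishino–Hasegawa closed form with frequencies pooled from
each pair), with supports from 100 column-bootstrap replicates: each
internal split's support is the fraction of replicate NJ trees
containing it. Saturated pairs (log argument ≤ 0) are flagged infinite
and abort tree building with the offending pair named.

Full maximum-likelihood tree search is deliberately out of scope: at
the divergences admitted by the identity floor (≤12%), NJ recovers the
topology reliably, and every downstream statistic depends on topology
only. An *ML-lite concordance check* is available
(`phylo.nni_concordance_check`): the fitted model's likelihood on the NJ
topology is compared against every nearest-neighbour-interchange
rearrangement at fixed branch lengths, and a family whose tree loses to
a neighbour is rejected, mirroring the practice of discarding families
where distance and likelihood topologies disagree.

**Support pruning.** While any split's support is below 0.88, one leaf
is removed at random from the canonical (lexicographically smaller) side
of the worst split and the tree rebuilt; a family that would fall below
4 members is rejected with reason `low support`. The random choice is
seeded and reproducible. The 0.88 threshold is an independent
configuration value; its numeric coincidence with the identity floor is
not load-bearing.

## Substitution model and fit

GTR+Γ(4)+I throughout: six exchangeabilities (GT fixed at 1 for
identifiability), empirical base frequencies (counted, not optimised),
discrete-gamma rate classes at category means, and an invariant-site
class. Rate-matrix normalisation fixes one expected substitution per
site per unit branch length; gamma rates are rescaled by 1/(1−p_inv) so
the mixture's mean rate is exactly 1. Transition matrices come from the
reversible eigendecomposition (symmetrise with √π, `eigh`, transform
back), clipped at 0 and row-renormalised against round-off.

The fit maximises the Felsenstein-pruning log-likelihood over compressed
site patterns with L-BFGS-B in transformed coordinates: log
exchangeabilities (bounded e^±4), log α in [0.05, 50], a logistic for
p_inv capped at 0.75, log branch lengths in [1e-7, 5]. The cap on p_inv
keeps the optimiser away from the degenerate all-invariant corner where
the likelihood surface flattens; empirically fitted values sit far
below it. Known Γ+I confounding (α trades off against p_inv on data of
this size) is tolerated because the null simulation needs only the
implied site-rate *distribution*, not the individual parameters.

## The no-exchange null and the excess test

Null replicates are simulated along the fitted tree: each site draws
the invariant class with probability p_inv or a gamma category,
the root draws from π, and each branch applies the GTR transition
matrix for its length times the site rate. Replicate i is seeded from
(seed, i), so any replicate can be regenerated in isolation. Simulated
length equals the observed (possibly CpG-stripped) alignment length so
R-site counts are directly comparable. CpG hypermutability is *not*
simulated in the null — the analysis handles CpG by stripping instead,
and simulating it would double-count the correction.

The family-level statistic is the number of columns reticulate in ≥1
quartet. Uncertainty on the observed side: 100 bootstrap resamples of
alignment columns (whole-family columns, not per quartet). The null
side: 100 simulated alignments scanned with the same quartets and the
same dominant topologies. After an independent seeded shuffle of each
side, the i-th values are paired and `P = #(sim > boot)/100`; the
strict inequality means ties favour significance, a deliberate,
documented direction (the procedure is conservative overall because the
parameter-rich null inflates the simulated R count). The same machinery
applied to B sites provides the conservativeness control: conversion
cannot create B sites, so a B-site excess would flag a mis-specified
null rather than exchange. Families with no informative sites, or no R
sites at all, skip the test and are reported as such.

Two reticulate fractions are reported, because published summaries are
ambiguous between them: the column-level fraction (R-union over
informative-union) and the mean per-quartet fraction.

## Track calling

**Conversion tracks** (quartet route): maximal runs of consecutive R
sites sharing one alternative topology. Runs are split when the
supported topology changes — a mixed run would conflate two donors.
Track boundaries are midpoints between the outermost R sites and their
flanking C sites; runs touching the informative range's edge use the
alignment boundary as flank. Eligibility for track estimation requires
a quartet with simulation-expected B < 5 (strict) and observed R > 5 on
the CpG-stripped alignment: with almost no parallel mutation expected,
observed R runs can be read as exchange tracks. Quartet-cluster
midpoints live in alignment coordinates and are mapped per member
through the column maps.

**Crossover breakpoints**: a terminal run of ≥5 consecutive
same-topology R sites reaching the first or last informative site. The
breakpoint window is the interval between the flanking C site and the
nearest R site of the run. The criterion is deliberately fragile: any
interior site of a different class interrupts the run, so only clean
suffix switches are called — consistent with such events being rare in
practice. No merging of clusters across single interior C sites is
performed (no published rule exists; not merging is the conservative
choice).

**Topology blocks**: the alignment is tiled by midpoints between
adjacent informative sites of differing supported topology; C sites
carry the dominant topology, B sites are transparent. Segment lengths
sum to the alignment length exactly, and the discordant fraction is
measured in bp. Intervals with ≥3 switches inside a 2 kb window are
flagged as complex (multi-template repair signature); the window has no
published value and is configurable, and edge-proximal flags are
annotated because alignment quality decays at the ends.

## Identity-track scanner

For each pair, maximal runs of identity across the family's polymorphic
columns; the score is the number of polymorphic sites spanned. Only
perfect-identity (zero-mismatch) inner fragments are scored — the
mismatch-tolerant variant and outer fragments are out of scope. The
null permutes the polymorphic-column order; one random rank assignment
per replicate is shared by all pairs, preserving their joint behaviour
(pairs share sequences), and per-pair maxima are read off the sorted
mismatch ranks in O(k log k) per pair. Global P = fraction of
permutations where any pair reaches the score; pairwise P = per-pair
fraction × number of pairs (Bonferroni), capped at 1. Ties count as
at-least-as-extreme; granularity is 1/n_perm (default 10,000; the
reference battery uses 1000 and compares within Monte-Carlo tolerance).
The production caller prunes by the score thresholds implied by the
null distributions before materialising fragments; a test verifies it
returns exactly the score-everything-then-filter result.

Monomorphic columns never move the statistic (the conditioning
property). Fragment genomic spans use the outermost spanned polymorphic
columns; extension to flanking monomorphic midpoints is available but
off by default, as dialects differ. Significant calls from nested,
redundant families are merged by a per-chromosome sort-and-sweep into
disjoint unique tracks (≥1 bp overlap merges); calls lacking genome
coordinates are kept in a separate alignment-only stratum.

On a 500-family null battery at the reference profile, the global route
rejects ~5–6% of families and the Bonferroni pairwise route ~4%, each
individually calibrated; their union flags ~9% of families because the
two routes catch nearly disjoint sets (the global max is dominated by
high-identity pairs, while the pairwise route is relatively more
sensitive for divergent pairs). This union behaviour matters when
comparing against external track counts that used the same OR rule.

## Genomic context

Length-matched re-placement: for each unique track of length l, sample
a family with probability ∝ alignment length (among families longer
than l), a random member pair, and a start uniform on (1, L−l); 1000
such datasets form the null for every context statistic. Overlap is ≥1
shared bp under 0-based half-open coordinates. Enrichment P-values are
quantile positions with the add-one correction, so an observed value
beyond all m simulated values reports 1/(m+1); both tails are always
computed, and a constant null is flagged degenerate. Observed and
simulated statistics flow through the same code path. PRDM9 motifs
(`CCnCCnTnnCCnC`) are counted on both strands with overlaps allowed.
Pericentromeric/subtelomeric zones are explicit BED inputs rather than
derived annotations. The machinery is validated on synthetic genome
layouts only; real-genome enrichment requires the real catalog.

## Rates

`c = 2μ(n−1)/d` assumes: each paralog equally likely to be converted by
any of its n−1 partners; conversion the only exchange mechanism; and
divergence at mutation–conversion equilibrium. On this scale c is the
per-site rate at which either member of a pair is overwritten from
within the family, so the balance gives d_eq = 2μ(n−1)/c. The default
μ = 1.2×10⁻⁸ /site/generation is the conventional human value.
Divergence d is computed on the CpG-*inclusive* alignment — the rate
describes the whole sequence, not the CpG-minus view. Every estimate
carries a formula tag so alternative closed forms can be swapped in.
The forward simulator (`evolve_with_igc`) implements exactly this
parameterisation (per-paralog initiation rate c/2, uniform donors) and
the estimator recovers truth within a factor of 2 across a 10× rate
grid when the equilibrium divergence stays inside the ≤12% regime the
identity floor admits; mean per-family and pooled variants of the rate
summary are both reported, as the published average is ambiguous
between them.

## Synthetic data

The generator emulates the analysed dataset profile: 4–16 paralogs,
10–40 kb, target mean identity 0.88–0.999, GTR+Γ4+I with human-like
defaults (transition-biased exchangeabilities, 41% GC, α = 1,
p_inv = 0.3). Random duplication histories are pure-birth trees whose
height is calibrated by root-finding so the model-expected mean pairwise
identity hits the target (realised identity lands within about a
percentage point). Conversion and crossover injection operate on
aligned coordinates post-simulation, giving exact truth intervals;
CpG hypermutability is an optional per-branch post-pass (extra C→T/G→A
at parental CpG sites with probability 1−exp(−boost·t)) sufficient to
induce a B-site excess that stripping demonstrably removes. The toy
genome fixture places members non-overlapping on a few chromosomes with
zone/repeat/gene BEDs and planted PRDM9 motifs.

What synthetic tests do **not** show: behaviour under alignment error,
indels, assembly collapse of near-identical copies, reference allelic
contamination, or realistic SD duplication histories — the generator's
trees are clock-like and its columns independent given the rate class.

## Reference battery sizes

The bundled checks use desk-scale problem sizes chosen to keep the full
suite in minutes: 200-family batteries for type-I control of each
detector (5 paralogs × 4 kb for the quartet test; the full 7–8 paralog
× 18.8 kb profile for the identity scanner at 1000 permutations),
25-family grids for sensitivity floors, and a 1246-family battery in
`scripts/acceptance.py` matching the reference catalog's family count.

## Known limitations

- The quartet method cannot see exchanges between sister paralogs, and
  cannot assign donor vs acceptor.
- The identity scanner is biased toward recent events (older tracks
  accumulate post-conversion mismatches and fragment).
- Support pruning may preferentially discard exactly the families with
  the most exchange, biasing family-level prevalence downward.
- The equilibrium rate estimate inherits all three of its assumptions;
  away from equilibrium it is an order-of-magnitude figure only.
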