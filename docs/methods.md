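# Methods

This note documents the models, parameters, numerical choices, and known
limitations behind `repinscan`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The question and the objects

An over-abundance of short oligonucleotides is a feature of nearly every
bacterial genome. Before reading function into a repeated motif one must
reject the null hypothesis that its frequency is what chance produces in a
genome of the same composition; and having rejected it, one must ask what
the *replicating unit* actually is. For REP sequences the candidate units
are the single 16-mer arm and the REPIN: two arms in inverted orientation,
separated by a spacer (start-to-start 71 bp for GI, 110 bp for GII in
SBW25), jointly able to fold into a long hairpin in single-stranded DNA,
and mobilised in trans by a RAYT transposase encoded once per genome.

All coordinates in the package are 0-based half-open; circular genomes are
treated as linear (the cost is at most k−1 windows per k); windows
containing non-ACGT characters are excluded from counting.

## Null models

**Markov null genomes.** The dinucleotide profile is measured separately
for the two replichore halves: top strand over `[0, L/2)`, bottom strand
(reverse complement) over `[L/2, L)`, capturing replication-strand skew.
Null genomes regenerate each half from its own order-1 chain (the second
half generated in bottom-strand orientation and reverse-complemented into
place). The first base of each half is drawn from that half's marginal
base frequencies — the conditional rule alone cannot seed the chain. The
split point defaults to `floor(L/2)` and is configurable; locating the
actual origin of replication is out of scope.

**Randomized extragenic space.** For false-positive estimation each
extragenic interval is independently replaced by an order-1 chain fitted
to that interval's own dinucleotide content, at exactly its length;
intervals shorter than 2 bp are copied verbatim.

**Random placement nulls.** Segments (16 bp for singlet nulls, 71/110 bp
for doublet nulls) are placed uniformly at random wholly within extragenic
intervals, non-overlapping, by rejection sampling with a bounded retry
loop (default 10⁴ rounds; colliding segments are redrawn). Cluster
spectra are computed per replicate; reported are the mean, SD, and the
empirical tail proportions `p_le`/`p_ge`, both including equality (so
`p_le + p_ge ≥ 1`). For doublet nulls each placed segment contributes two
REP positions (its start and `seg_len − 16` downstream) and spectra are
reported in REP units (2, 4, 6, ...).

## Census and grouping

Counting is a step-1 sliding window over the forward strand; under the
default *combined* policy `count(w) = fwd(w) + fwd(rc(w))`, which makes
counts orientation-symmetric (`count(w) == count(rc(w))`) and the census
total exactly twice the number of valid windows. A consequence worth
remembering: the "most abundant 16-mer" is only defined up to reverse
complement, and the deterministic tie-break (lexicographically smallest)
may report the reverse complement of the orientation a human would pick.
Everything downstream is orientation-aware, so this is cosmetic.

Grouping is the greedy flank-context algorithm: pop the most abundant
remaining 16-mer as seed; extract every genomic occurrence of the seed or
its reverse complement with 20 bp flanks (clipped at contig ends); join
with `|` (a symbol outside the DNA alphabet, so no window crosses a
boundary); assign every remaining 16-mer found in that string — in either
orientation — to the seed's group; repeat. The order (count descending,
then lexicographic) makes the partition deterministic.

## Family expansion and the shared-sequence rule

A family's degenerate pool is the union of Hamming balls of radius d ≤ 4
around the group seeds, enumerated explicitly (the full d = 4 pool is
~490k strings — exactness is cheap). Optional masks pin group-diagnostic
positions (GII: 2T, 6C; GIII: 6A, 13T, 1-based).

The SBW25 seeds lie 6–9 substitutions apart, so balls overlap from d = 3
on. `family_pool(..., shared="drop")` (default) removes every 16-mer
reachable from more than one seed — no unique family assignment exists for
such a sequence — giving pool sizes 3 / 147 / 3,387 / 48,707 / 488,367 for
d = 0..4. `shared="nearest"` instead keeps them, assigned to the nearest
seed (ties: masked groups first, then label order). Genome matching
reports one occurrence per footprint: a window whose forward and reverse
forms both match yields a single `+` occurrence, avoiding double-counting
of near-palindromes. A window is *extragenic* only if its full 16 bp span
lies inside one extragenic interval.

## REPIN validation

**Orientation.** Because the seed orientation is arbitrary under combined
counting, `(+,−)` and `(−,+)` doublets are the same physical geometry —
arms that are reverse complements of each other, hairpin-capable — and
both count as *inverted*; only co-oriented arms (a direct repeat) do not.
Both sub-orientations are reported separately.

**Spacing windows** default to each group's modal doublet spacing ± 5 bp.
The spacing peaks in real data are sharp but no tolerance is published;
±5 bp is exposed as a parameter.

**Folding** replaces thermodynamic prediction with a maximum-base-pairing
dynamic programme: Watson–Crick pairs only by default (G·T wobble
switchable), minimum hairpin loop 3 nt, no pseudoknots. The claim being
checked is qualitative — the conserved arm bases *can* pair into a long
stem — and an exact, dependency-free DP answers it deterministically. The
traceback prefers pairing the rightmost base with its outermost partner at
equal score, which favours contiguous stems; only the optimal pair count
is contract-guaranteed (verified against exhaustive structure enumeration
for sequences ≤ 12 nt). The DP is cubic; practical above a few hundred nt
it is not, and REPINs are ≤ ~130 nt.

**Excision footprint.** The deletion implied by observed excision events
is asymmetric: from the start of the left 16-mer to `tail_keep` (default
6, exposed because the observed value is "~6") bases short of the right
16-mer's end. Excised piece plus retained tail reconstitute the locus
byte-exactly; a spacing-71 REPIN yields an 81 bp footprint.

**Tandem arrays** are runs within a cluster whose (group, spacing) pattern
repeats with period 1 or 2, spacings agreeing within ±2 bp (tolerance
exposed), at least two full units and three occurrences.

## Singlet decay

Occurrence 16-mers (seed orientation) are pooled by family × context
(singlet / doublet / cluster ≥ 3, from the chaining pass), with the
group-diagnostic masks applied. Each resampling replicate draws a uniform
random perfect matching of a pool and records the mean pairwise identity
over its pairs; for odd pools the leftover sequence is discarded that
replicate (the minimal deviation from "draw until empty", which an odd
pool cannot satisfy). The non-overlap criterion reports whether the
maximum replicate mean of one pool reaches the minimum of the other, with
the conventional bound (1e-10 at ≥ 10⁵ non-overlapping replicates, 1e-8
when overlap appears only beyond the first 10³); because that convention
is non-standard, a two-sample permutation test on the all-pairs mean
identity difference is computed alongside and both are labelled.

## Excision screens

For each REPIN the 12 bp immediately 5′ and 3′ of the excision footprint
form a flank pair. Reads (both orientations; mates treated as independent
reads; < 36 bp discarded) are scanned for the left flank followed by the
right flank within a gap of ≤ 10 bp (the retained ~6 bp tail means the
junction need not be flank-adjacent; 10 covers 6 with margin and is
configurable). Flank matching is exact: with 24 matching bases required,
chance false positives on a 10⁵–10⁷ bp genome are negligible, which the
negative-control tests confirm. The singlet screen expands an 18-mer
palindrome seed to ≤ 5 mismatches (vectorized Hamming scan over both
strands), extends each matched interval by 0–3 bp independently on each
side to allow inexact excisions, and screens the same way.

## The synthetic world

The generator's defaults are the conditions the analysis is tested under:
5 Mb genome; GC 0.60 and i.i.d. background (Pseudomonas-like GC; an
explicit order-1 profile can be supplied); gene density 0.85 with gene
lengths ~N(1000, 400²) clipped to [150, 5000] and exponential intergenic
gaps — bacterial coding density with mostly short, operon-internal gaps;
200 GI REPINs at spacing 71 and 100 GII at 110; 50 lone singlets;
per-base substitution rates μ_doublet = 0.005 and μ_singlet = 0.05 (the
decay contrast the diversity test must recover). Planted elements are
placed in deliberately widened intergenic gaps with ≥ 250 bp margins, so
every element is extragenic, REPINs form their own clusters, and singlets
stay singlets. Spacers are biased toward self-complementarity (second
half the reverse complement of the first with a 20% scrambled fraction),
so fold-based validation is meaningful. Reads are 36–76 bp, uniform
starts, either orientation, optional uniform substitution errors; a
stated fraction of molecules carries the listed REPIN excisions.

The synthetic sister genome used for thresholding mirrors the real
sister-strain comparison: same background process, its own smaller REP
complement (20 REPINs of a third family by default in the tests). This
matters: a background-only sister sets the threshold at the background
noise maximum (~3 on 5 Mb), which admits decayed-arm variants occurring
~4 times; such variants sit at isolated loci, cannot join the seed groups
through flank context, and surface as micro-groups. A sister whose own
repeat complement sets the threshold — the situation the method was
actually designed for — cleanly separates family seeds from variant
noise.

What a green test does *not* establish: the background has no gene
duplications, insertion sequences, or compositional heterogeneity beyond
the replichore split, so thresholds transfer to real genomes only through
the sister/Markov-null machinery, not as absolute counts; planted REPIN
flanks are random, so context-grouping of *decayed* relatives (which in
real genomes share conserved flanking DNA) is weaker in simulation than
in reality; and read simulation has no indels or quality-score structure.

## Known limitations

- The d ≤ 4 pool size computed under the drop-shared rule is 488,367,
  six sequences (0.0012%) below the published 488,373; no reconstructible
  deduplication rule reproduces both published values at d = 3 and d = 4
  simultaneously (the drop-shared rule reproduces d ≤ 3 exactly).
- `fraction_inverted` counts both strand-discordant sub-orientations as
  inverted; the published convention for the non-inverted remainder is
  not stated, so both sub-counts are reported.
- Placement nulls use per-segment rejection resampling, which is not
  exactly uniform over non-overlapping configurations at high packing
  densities; at realistic densities (≤ a few percent of extragenic space)
  the bias is far below the reported SDs.
- RAYT discovery is out of scope: RAYT loci are user-supplied annotations
  and `scan_rayt_flanks` only proposes the REP seed next to them.
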