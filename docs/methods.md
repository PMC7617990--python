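# Methods

## Model of the library

A sequenced molecule is modelled as the concatenation

```
bottom splint [ NexteraR2 | barcode | AGTGGTATC | UMI | post-UMI constant | poly(T) ]
+ transcript body + TSO adaptor
```

observed on either strand with equal probability. The post-UMI constant
(58 nt) is the reverse complement of the top splint strand — the annealing
interface of the partially double-stranded adapter; the top strand's
3′ inverted dT is represented as a boolean flag on the design, not a
sequence character. The printed bottom-splint UMI region parses as 17
N-R-Y triplets (51 nt) while the accompanying text specifies 50 nt;
`umi_length` is therefore a free parameter defaulting to 50, N-first
phase (`pattern="NRY"`), matching the `...TATCNRYN...` context.

UMI positions admit {A,G} at R, {C,T} at Y, {A,C,G,T} at N. Because R→Y
transitions can never produce equal adjacent bases, only N-adjacent pairs
can match and homopolymer runs inside the UMI body are bounded at 2 — a
property the test suite checks on 10⁴ sampled UMIs across lengths. The
UMI-space size is K = 2^(#R)·2^(#Y)·4^(#N) and the collision estimate is
the birthday bound 1 − exp(−n(n−1)/2K). This is an approximation: for
very small K it deviates from the exact hypergeometric-style product, so
the Monte-Carlo agreement test runs at K = 256 where the bound is tight.

## Synthetic libraries and what they do (not) emulate

The simulator's defaults are the protocol's stated study conditions:
5 PCR duplicates per molecule, 50-nt R/Y/N UMIs, strand flips at 0.5, and
nanopore-like per-base error rates of 5% substitution, 1% insertion, 1%
deletion (the source does not publish the exact rates used in its own
simulations; these sit at the conservative end of current chemistry and
are configurable). Each molecule draws its UMI once; duplicates share it
verbatim before errors. Truncation (default probability 0.05, uniform cut
up to half the template) removes sequence from the TSO side, mirroring
the concern that RNA degradation shortens cDNA from the 5′ end. Poly(T)
tract length defaults to 25 nt, the dT-oligo length.

Concatemers: with probability `concatemer_fraction` a read gets a copy of
another read of the same library appended, so an adaptor occurrence lands
away from the ends. This keeps one ledger row per emitted read and exact
per-cell molecule counts, at the price that a concatemer's second half
duplicates an existing read — irrelevant for the QC-detection questions
the fixture serves.

Not emulated: signal-level (squiggle) artefacts, context-dependent error
hotspots, quality values that track true error probability (qualities are
constant per read, derived from the configured rates; no stage trusts
them for consensus), chimeric PCR artefacts other than concatemers, and
real transcriptome complexity (the toy pool has 7 genes + 3 TEs with
random sequence). Passing tests therefore demonstrate the algorithmic
machinery — grouping, consensus, bookkeeping — under a clean error model,
not performance on real flow-cell data.

## Adaptor QC and demultiplexing

Local alignment uses match +1, mismatch −1, gap opening 4, gap extension
1 (the published pipeline call states only the two gap parameters; the
match/mismatch pair is this package's default). One convention note: the
"opening" penalty here applies to the first gap base, so a length-L gap
costs 4 + (L−1); Bioconductor's equivalent charges 4 + L. Only the 250-bp
end windows are scanned unless internal detection is requested.

Score thresholds are empirical: every read is also scored against a
per-read random permutation of the adaptor, and the default threshold is
the 99th percentile of that scrambled null. An adaptor hit is *internal*
when its midpoint lies within 20–80% of the read length; the midpoint was
chosen because the source does not state which hit coordinate is compared
to the window. Reads are split at internal junctions with adaptor bases
assigned to the downstream fragment, so fragment concatenation exactly
reconstructs the parent read. The 20-kb length filter is strict (>).

Demultiplexing aligns the scaffold `R2 + N·barcode + constant` (barcode
slot as wildcards) once per read, projects the slot through the alignment
path, and scores the extracted slot against every candidate barcode —
cheaper than whole-read re-alignment per barcode and reliable because of
the flanking constant regions. A read passes only when best score ≥
threshold and best-minus-second gap ≥ gap threshold (default 1, so exact
ties always fail). The bundled 96-barcode panel is **synthetic** (seeded
random 24-mers with pairwise edit distance ≥ 8): real commercial barcode
sequences are proprietary and must be supplied by the user.

## UMI grouping

Reads are pre-grouped by their aligned feature (primary SAM/BAM records
or a plain mapping — spliced alignment itself is out of scope), then the
observed UMIs of one bin are clustered as connected components of the
graph joining pairs at Levenshtein distance ≤ threshold (default 14 for
50-nt UMIs; 6 is the documented 20-nt choice). Single linkage was chosen
because the source specifies only "clustering similar sequences"; the
clustering function is self-contained and swappable. Distances are
computed with edlib banded at the threshold, which is exact for the
≤ threshold decisions consumed — the suite verifies equality with a
textbook dynamic-programming oracle on 10³ random pairs and equality of
whole clusterings with an exhaustive all-pairs union-find oracle on
200-read instances. Groups larger than 50 reads get a seeded uniform
subsample for the MSA; remaining members inherit the consensus.
Evaluation counts a read correct when its group's majority ledger
molecule is its own; singletons are correct-but-uncorrectable and
reported separately as the under-grouped fraction.

## Consensus

Error correction orients all group members to a common strand, picks a
backbone read of median length (strand-invariant tie-break), aligns every
member to it globally, and takes a per-column majority over
{A,C,G,T,gap}; gap-majority columns are deleted, ties resolve to a base
over a gap and then lexicographically. The backbone aligner penalises a
gap opening (2.5) more than two mismatches, so equal-cost
substitution-vs-indel-pair ambiguities between two noisy sequences
resolve to substitutions; genuine indels still align as gaps. Without
this, optimal-but-arbitrary unit-cost paths shift columns and inflate the
consensus error several-fold above the per-site majority-vote expectation
that the acceptance suite checks. The star-MSA backend is pluggable: any
MSA yielding columns can feed the same vote. Groups are canonicalised to
the lexicographically smaller of backbone/reverse-complement, making the
consensus exactly strand-covariant. Two-read groups have no strict
majority at disagreeing columns; the documented tie rules above apply.
Deduplication is a seeded uniform draw of one representative.

## Quantification

Counts are collapsed molecules per (feature, cell); zero columns are kept
for configured cells. Classification: overlap with a repeat only → TE,
with a known isoform only → gene, with both → TE_isoform, neither →
unassigned; strand-aware by default, `min_overlap` 1 bp (or a fraction).
Intervals are normalised to 0-based half-open (GTF converted on read).
Exports are a long-format table plus MatrixMarket with feature/cell
sidecars; round trips are exact.

## Protocol arithmetic

Final concentrations are stock × volume / total well volume with the well
total always explicit — several published tables imply inconsistent
totals (the splint-hybridisation, ligation and proteinase-K tables), so
those cells are excluded from validation. One validated cell (dT oligo,
100 μM × 1 μl / 4.2 μl) prints 23.80 μM where the arithmetic gives
23.81; checks therefore accept one unit in the last printed decimal.
Master mixes scale by reactions × 1.1. Both published cycle rules are
exposed: onset − log₂(dilution) (subtract 4 at 1/16 input) and a fixed
"3 cycles before onset"; they are deliberately not reconciled. Molar
dilution uses 617.96 g/mol per bp + 36.04 g/mol ends.

## Problem sizes and determinism

The simulation suites run at desk scale: 1,000 molecules × 5 duplicates
for the grouping-recovery check (seconds), 200 molecules for the
UMI-length/threshold ordering, 50 groups × 1-kb templates for the
consensus-vs-oracle comparison, and a 4-cell × 10-molecule library for
the end-to-end inversion. All randomness flows through explicit integer
seeds; identical seeds reproduce byte-identical FASTQ output and manifest
checksums, and chunked versus serial group processing is exactly
invariant.

## Known limitations

* The error model is i.i.d. per base; real nanopore errors cluster in
  homopolymers and low-complexity contexts outside the UMI.
* Star MSA is a heuristic; a partial-order aligner would resolve dense
  indel neighbourhoods better for group sizes near 50.
* Feature classification has no precedence notion for known-vs-novel
  isoforms beyond the dual-overlap rule; the class rules are documented
  and the thresholds configurable rather than canonical.
* The demultiplexer assumes one barcode per read; dual-tagged chimeras
  are handled only insofar as internal-adaptor splitting separates them
  first.
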