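# Methods

This note documents the models and procedures implemented in `tssmap`, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Coordinates and strand conventions

All internal coordinates are 1-based and inclusive with an explicit strand;
BED input/output is converted at the boundary (half-open, 0-based). On the
minus strand the 5′ end of a read or contig is the *larger* coordinate, and
"upstream"/"downstream" always refer to the direction of transcription.
Circular replicons are accepted but treated as linearized: MTU spans and
scan windows are truncated at the origin rather than wrapped. This matters
only for features within ~54 nt of a replicon's origin and is flagged by
the MTU `truncated` field.

## TSS calling

Reads pass three filters (defaults): length ≥ 18 nt, unique mapping, and no
mismatches within the first three 5′ bases — the 5′-most bases of a
spurious or mis-trimmed read are the least trustworthy part of a putative
TSS signal. Pile-ups of ≥ 30 filtered reads sharing a 5′ position become
TSS contigs; the contig 3′ end is the furthest 3′ extent of any member
read. Sub-threshold positions are retained in a separate report channel, so
known TSS that narrowly miss the cutoff remain visible.

TSS positions closer than 3 nt (strict inequality) are merged, and the
relation is closed transitively: a chain at 100/102/104 becomes one TSS.
The surviving coordinate is the member with the highest read count, ties
resolved to the 5′-most member — the merged pile-up's most prominent 5′
end. The merge representative is a genuine choice (the merging rule itself
does not dictate a coordinate); read-weighting is the least arbitrary
option and is what the tests and oracles assume.

Relaxed contigs from prior lower-depth RNA-seq are maximal runs of coverage
≥ 5 with length 50–350 nt, retained only when their 5′ end coincides
exactly with a called TSS.

## The MTU model and TSS classes

A gene's minimal transcription unit is its CDS plus fixed margins: 14 nt of
5′-UTR (minimal ribosome binding site) and 20 nt of 3′-UTR (minimal
terminator hairpin). The 40-nt promoter region sits immediately upstream;
together with the 5′-UTR margin it forms the 54-nt m-window upstream of the
start codon.

The six classes are evaluated in the fixed precedence
lmTSS > mTSS > seTSS > asTSS > pmTSS > sTSS. The order is forced at two
points: mTSS must precede seTSS, otherwise any TSS inside the 14-nt 5′-UTR
margin would be absorbed by the "inside an MTU" rule; and asTSS must
precede pmTSS because the pmTSS definition requires the absence of any MTU
overlap, antisense included. Placing asTSS after seTSS means sense context
wins over antisense context when a contig touches both; the converse order
is defensible, and the classifier records the rule that fired (`evidence`)
so the decision is auditable. The seTSS rule tests only the TSS *position*
against the MTU span (the contig may poke beyond); the mTSS and asTSS rules
test the whole contig, as their definitions are about overlap.

pmTSS distance is measured from the TSS point to the start codon, and the
300-nt bound is inclusive: a TSS exactly 300 nt upstream is pmTSS, 301 nt
is sTSS. When several m-windows qualify, the target is the gene with the
nearest downstream start codon, which minimizes the claimed 5′-UTR length.

sRNA features are formed by merging overlapping same-strand sTSS contigs;
asRNAs by merging overlapping asTSS contigs that share a target gene. An
asRNA's `overlap_region` reports the most 5′ region of its target it
touches (5′-UTR before CDS before 3′-UTR, using the 14/20-nt margins).

## ORF discovery and the RBS energy model

Per TSS, same-strand ORFs (start ∈ {ATG, GTG, TTG}, in-frame stop, ≥ 60 nt)
overlapping the first 3 kb of the transcript are enumerated. Leaderless
ORFs require ATG exactly at the TSS; SD ORFs a leader ≥ 14 nt. An ORF
reachable from several TSS is reported once, preferring the leaderless call
and then the shortest leader.

The RBS score is the minimum hybridization free energy of the leader (as
RNA) with the 16S rRNA 3′ tail, under a deliberately simple duplex model:
antiparallel, ungapped, contiguous helices of ≥ 3 Watson–Crick or G:U
pairs, scored as ΔG°₃₇ = 4.09 (initiation) + Σ nearest-neighbor stacks
+ 0.45 per helix end closed by an A:U/G:U pair. Watson–Crick stack values
follow the standard Xia/Turner 37 °C set; G:U stacks use the weaker
Turner-style wobble parameters embedded in `orf_discovery.STACK_ENERGY`.
Bulges, loops and dangling ends are not modeled. The acceptance cutoff is
−3.4535 kcal/mol, inclusive. By default the search is restricted to the
3′-terminal 30 nt of the leader (`search_window`), the region where a bound
30S subunit can act; energy-function tests disable the window.

The anti-SD tail is a required parameter — there is no universal default
across species. The synthetic generator uses the canonical
5′-GAUCACCUCCUUA-3′ tail so its tests are closed.

A caveat measured during development and worth stating: at this cutoff the
energy filter alone is weakly discriminative in GC-rich sequence. Random or
shuffled leaders of 14–30 nt reach −3.4535 kcal/mol in roughly 15–50 % of
cases under this model, and a full-thermodynamics duplex model (which also
admits bulges and loops) is even more permissive. Any ≥ 4-bp GC-rich helix
against the CC-rich anti-SD core beats the cutoff, and such helices are
common. Real analyses should therefore treat the RBS filter as a necessary
condition and rely on the external protein-homology keep-filter (supported
as a precomputed hit table) to control false-positive new ORFs.

## Promoter discovery

Element PSSMs use raw counts + pseudocount 1, log-odds against a zero-order
background. The background defaults to the genome's strand-symmetrized
nucleotide frequencies (A with T, C with G): one matrix scans both strands,
so the background must be invariant to which strand was sequenced; this
also makes the whole pipeline exactly equivariant under
reverse-complementation. For a GC-rich genome a uniform background would
systematically distort P-values.

Element P-values are exact, not binned: the score distribution of a random
background word is built by dynamic programming over the attainable partial
sums (a dictionary of float sums, extended position by position in the same
order the scanner accumulates scores, so scanned scores match distribution
support bit for bit). P(score ≥ t) is then a suffix sum. For the element
widths used here (≤ 8) the support stays far below the 4^w worst case.

Scanning is exhaustive on both strands; windows containing N are skipped.
Chaining pairs every −35 element with every −10 element on the same strand
whose spacer (nucleotides strictly between the elements) lies within the
σ-specific range. A candidate is retained when the −10 element ends 5–12 nt
upstream of a TSS or relaxed-contig 5′ end; the gap is likewise counted as
nucleotides strictly between. The reported TSS link is the nearest-gap
anchor, but all associated TSS classes are kept for filtering.

The two-phase procedure: seeds are first extended by exact string matches
of each seed's element pair (label `extended_model`); Phase 1 builds PSSMs
from the extended set, scans, chains, associates, and keeps candidates with
both element P-values ≤ 0.005 whose associations are not exclusively seTSS
(label `new_initial`); Phase 2 rebuilds the PSSMs from the enlarged set and
repeats with P ≤ 0.02 and all classes admitted (label `second_search`). The
scan itself always runs at the relaxed 0.02 cutoff with phase-specific
filtering applied afterward, so Phase 2 never needs a looser rescan, and
the final hit set is by construction a superset of Phase 1. "Exclusively
seTSS" (rather than "any seTSS association") is the implemented reading of
the Phase-1 filter; a candidate also supported by another class keeps its
stronger association. Promoters are deduplicated on
(σ, replicon, strand, pos35, pos10); a TSS may carry several promoters.

Shipped σ parameter defaults (element widths 6/7 and spacer 14–20 for
σ⁷⁰/σ³²-type factors, narrower boxes for the ECF factors, −24/−12 boxes for
σ⁵⁴) are illustrative placeholders: per-σ widths and spacer ranges are
expected from the user's configuration, as published values vary by study.

String mode parses `BOX1-Nk-BOX2`, allows ≤ 1 total mismatch across both
boxes (N in the genome counts as mismatch), any spacer within the σ range,
and applies the same 5–12-nt gap test.

## TFBS analysis

The gapped motif scan builds a PSSM over the informative box columns only
(spacer columns unscored) with pseudo-frequency smoothing
f = (c + pf·N) / (N(1+4pf)), pf = 0.01 by default. Each gene's upstream
window (300 nt, truncated at the nearest annotated gene — the window length
is our choice, configurable) is scanned on the gene's own strand; hits need
a positive log-odds score, P ≤ 10⁻⁴ from the shared exact P-value engine,
and no overlap with any annotated ORF. Positional correlation categorizes a
site by the distance from its 3′ end to the nearest downstream same-strand
TSS: 22–25 nt is a −35-overlap (direct-regulation candidate), larger
offsets are farther-upstream, everything else downstream/none.

Upstream extraction emits the 40-nt window ending 1 nt upstream of each
mTSS/lmTSS with ≥ 300 reads and no σ assignment; windows truncated by a
replicon edge are skipped with a warning. The output FASTA is intended for
an external motif-discovery tool (for MEME the original parameters were
`-dna -mod anr -minw 18 -maxw 40 -minsites 10`); motif discovery itself is
out of scope.

## Synthetic data

The generator builds each replicon from blocks: every gene gets an
upstream pad sized for its planted features, a CDS (330–600 nt, ATG + stop,
internal stops excluded), and a downstream pad; placement arithmetic is
pure-integer, all randomness flows through one seeded `default_rng`, and
two calls with one seed are byte-identical. Default conditions: two
replicons, 200 genes, GC 0.6 (a GC-rich soil α-proteobacterium), operon
fraction 0.3, planted classes 50 mTSS / 10 lmTSS / 20 pmTSS / 40 seTSS /
40 asTSS / 20 sTSS, read depth mean 100 per TSS, read lengths 87–108 nt,
jitter rate 0.05 (±1–2 nt), background noise 0.5 spurious 5′ positions per
kb with small non-unique/5′-mismatch/short fractions to exercise the read
filters. Every planted TSS keeps ≥ 10 nt of margin to each class boundary,
so its class is unambiguous; a `boundary_cases` flag additionally plants
deliberate edge geometry (a TSS exactly 300 nt upstream of a start codon,
and a contig overlapping an m-window by exactly 1 nt). The bundled
benchmark fixture (`half_megabase_config`) scales this to ~0.5 Mb across
two replicons with 660 genes and 540 planted TSS.

Read depth is negative-binomial with variance (1 + φ)·mean, φ = 0.5 — a
quasi-Poisson overdispersion, so at mean 100 essentially every planted TSS
clears the 30-read threshold while dropouts remain possible at lower
means. Each planted pile-up realizes at least one read of maximal length,
making the planted contig extent (hence the class geometry) deterministic.
Promoters are written into the sequence (consensus or PSSM-sampled with
rejection below 80 % of the maximal log-odds score), as are SD leaders
(AGGAGG ending 8 nt upstream of the start codon), TFBS instances, and
small unannotated ORFs on a fraction of sRNA transcripts.

What the generator does not emulate: sequencing errors and quality scores,
enrichment chemistry for primary 5′ ends (all surviving read starts are
treated equally), transcript 3′ ends, expression-level heterogeneity
between genes, and compositional heterogeneity (GC skew, codon usage).
Passing the planted-recovery tests therefore shows the pipeline implements
its stated rules exactly and is robust to pile-up noise — not that the
thresholds are optimal for any particular real dataset.

## Numerical and determinism notes

- All thresholds are config fields; nothing is hard-coded.
- Exact float comparisons are used only where bit-identity holds by
  construction (scanner scores vs distribution support); everywhere else
  tolerances are explicit in the tests.
- The spacer and the TSS gap both count nucleotides strictly between
  elements; the gap window [5, 12] is inclusive on both ends.
- Outputs are written in deterministic (replicon, position, strand) order;
  rerunning the pipeline at one seed is byte-identical, and resuming from
  serialized intermediates equals a fresh run.
- Problem sizes in tests (toy replicons ≤ 20 kb, 0.5 Mb end-to-end fixture,
  1000-TSS oracle comparisons, 500-case RBS suites) were chosen to give the
  oracles full coverage of rule boundaries while keeping the whole suite
  and the acceptance script in the tens of seconds.

## Known limitations

- No wrap-around of windows on circular replicons (see above).
- The RBS energy cutoff is weakly discriminative in GC-rich sequence (see
  above); homology evidence is the decisive filter for new ORFs.
- The promoter search models exactly two boxes; extended −10 elements or
  one-box promoters are not represented.
- The asTSS-before-pmTSS precedence is forced, but seTSS-vs-asTSS ordering
  for contigs touching both sense and antisense context is a convention.
- σ element widths and spacer ranges must come from the user for real
  genomes; shipped defaults are illustrative.
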