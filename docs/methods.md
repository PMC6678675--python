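# Methods

This note records the models, parameter choices and numerical conventions
behind the pipeline, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates and record conventions

All intervals are 0-based half-open (BED/BEDPE native). A tag's 5′ position
is its `start` on the plus strand and its `end` (the exclusive bound) on the
minus strand; spans, footprints and extensions all use this convention, so
off-by-one choices are consistent across stages. After mapping, the two tags
of a PET are canonically ordered by (chromosome, start); strand information
travels with its tag through reordering, which makes deduplication and
categorization independent of mate order. BEDPE files carry the PET
multiplicity in the score column; per-tag MAPQ is not representable in
10-column BEDPE and defaults to 255 on re-read.

## Linker filtering

Linkers are located by Smith–Waterman local alignment with match +1,
mismatch −1, gap −2 (gapless placements dominate at linker lengths of
16–19 bp). Ties are broken deterministically: the maximal-scoring cell with
the smallest read end wins and the traceback prefers diagonal moves, which
yields the smallest read start among equivalent placements; between equal
scoring linkers, A precedes B. The implementation is in-package because the
classification contract needs the exact read↔linker column pairing (for the
barcode check) and reproducible tie-breaks; tests verify the scores against
Bio.Align.PairwiseAligner as an independent oracle.

A short-mode read earns label A or B only if (1) the best linker score is at
least `min_score` (default 14 for 16-bp half-linkers — roughly one mismatch
of slack; change it with linker length), (2) the best-vs-second-best margin
is at least `min_diff` (default 2), evaluated across the two candidate
linkers, (3) the trimmed tag length is inside `[18, 25]` bp (the MmeI
protocol's tag range; only the lower bound applies in long mode), and
(4) the 4-bp barcode is matched exactly at its aligned position. The barcode
locus is computed from the linker file as the maximal run of positions where
half-linkers A and B differ. Failure of any criterion on either read makes
the PET ambiguous. Only same-linker PETs continue; different-linker PETs
(inter-molecular ligation) are written to a side file.

In long-read mode the labels are A (bridge plus strand), B (minus strand)
and X (no linker above threshold). Combinations AB, BA, AX, XA, BX, XB are
usable and mapped to class "same"; AA/BB indicate improper ligation
("chimeric-excluded"); XX is ambiguous. Trimming removes everything from the
linker start onward; the reverse-complement orientation within a read is not
searched.

Linker filtering is implemented serially; the `workers` parameter is
accepted so the interface contract (output identical for any worker count)
is trivially honoured.

## Mapping

The external aligner is an interface, not a dependency: `plan_alignment`
emits the exact BWA command lines (short mode: `aln` + `samse` per mate;
long mode: `aln` below a 55-bp median tag length, `mem` at or above it,
chosen per library so a single engine produces the whole SAM), and the
pipeline can enter mid-stream from SAM or BEDPE. "Uniquely mapped" is
operationalized as a primary alignment with MAPQ ≥ 30 on both mates;
multi-mappers and unmapped mates are both "not uniquely mapped". The
built-in toy mapper does exact-occurrence search (unique hit of the tag or
its reverse complement → MAPQ 60) over a sorted 2-bit-packed 16-mer index
with string verification, and exists so synthetic libraries can be mapped
with perfectly known truth.

## Purification

Exact merge collapses PETs with identical (chrom, start, end, strand) on
both tags. Similar merge then groups PETs whose both 5′ tag positions agree
within ±2 bp, requiring equal chromosomes and strands. The 5′ end is used
because MmeI's variable cutting length moves the 3′ end. Groups are formed
transitively (single linkage) — chains A~B~C merge even when A and C are
4 bp apart; the representative is the highest-multiplicity member (ties:
smallest coordinates) and carries the summed multiplicity, so total
multiplicity is conserved and both merges are idempotent.

## Categorization and the span cutoff

Self-ligation PETs have the signature: same chromosome, leftmost tag on the
minus strand, rightmost on plus, short 5′-to-5′ span. Spans are histogrammed
in log-spaced bins (25 per decade, 100 bp – 100 Mb) per strand composition,
read as (leftmost strand, rightmost strand). Genuine inter-ligation PETs
populate all four compositions nearly identically, so the per-bin excess

    excess(b) = n−/+(b) − mean(n++, n+−, n−−)(b)

isolates self-ligation. Bins where the excess clears `noise_fraction`
(default 0.05) of the mean-other level form signal runs; the cutoff is the
upper edge of the last bin of the run carrying the most excess mass. A run
whose total excess is below 5 PETs is indistinguishable from Poisson noise
and falls through to the 8 kb default, as do empty distributions. The
categories partition the purified set: inter-chromosomal; intra-chromosomal
with span above the cutoff (inter-ligation, any composition); −/+ at or
below the cutoff (self-ligation); anything else at or below the cutoff
("other" — reported but used by no downstream stage).

## Peak calling

Each self-ligation PET's footprint is the interval between its two 5′
positions (inclusive of both), i.e. the measured fragment. Strictly
overlapping footprints merge into candidate regions. A region of length L
with k footprints is tested against a Poisson rate

    λ = max( N·(L+f)/G ,  c₁₀ₖ·(L+f)/10000 )

with N the number of self-ligation PETs, f their mean footprint length, G
the genome size and c₁₀ₖ the footprints overlapping a 10-kb window centred
on the region; p = P(Poisson(λ) ≥ k). This is the MACS construction in its
no-control form; a 5-kb window is deliberately not used because candidate
regions here are fragment-sized (1–3 kb) and would dominate their own 5-kb
background estimate. The window set is an argument for callers who want
otherwise. Reporting thresholds default to k ≥ 3 and p ≤ 1e-5; both are
exposed flags, as the upstream tools' values for them are not published.

## Interaction calling

Tags of inter-ligation PETs are extended 3′-ward from the 5′ position to the
expected fragment length — 500 bp by default, or the median self-ligation
span in auto mode (the tag is the visible end of its fragment, which
continues 3′-ward). Overlapping extensions merge into anchors. Each PET then
joins an ordered anchor pair; PETs whose two tags land in one anchor are
counted as "self-pairs" and excluded from pair testing (a diagnostic, not a
call). The significance model is an urn over the N inter-ligation PETs that
entered pairing: anchor A holds nA tags, anchor B nB, and the k PETs joining
them are tested with the hypergeometric upper tail (computed via
`scipy.stats.hypergeom.sf`, verified against exhaustive enumeration). This
parameterization is the single largest modelling inference in the package;
only the distribution family is fixed by the protocol's lineage. Clusters
with k ≥ 2 form the Benjamini–Hochberg family (intra- and inter-chromosomal
tested together); singletons are reported untested. Significant output
requires adjusted p < 0.05 and k ≥ 3. With user-supplied anchors (merged if
overlapping), tags outside every region are dropped and N becomes the
assigned-PET count.

One visible consequence of strandwise extension: an anchor can split when
all plus tags happen to lie 3′ of all minus tags at a site, in which case a
loop is reported as two adjacent clusters. The recovery experiments score a
loop as found when any significant cluster joins the two site
neighbourhoods.

## Report

The stage ledger (total, same-linker, uniquely mapped, after exact merge,
after similar merge, self-ligation, inter-ligation, other, peaks,
interactions) is validated before rendering: the three categories must sum
to the purified count and every stage must be monotone. Percentages are
computed at declared numerator/denominator pairings and rounded half-up to
two decimals with trailing zeros stripped (90.74, 14.2, 69.02 …), making
recomputed cells match printed ones character for character. Cluster tables
bin by PET count (2…9, ≥10) and by anchor-midpoint distance with
left-closed, right-open bins (<100 kb, [100 kb, 1 Mb), [1 Mb, 10 Mb),
≥10 Mb, inter-chromosomal). HTML is rendered from plain string templates
with inlined PNGs; every table is also written as TSV.

## Synthetic libraries: what they emulate, and what not

The generator plants, per library: a uniform-random genome (2 chromosomes,
500 kb each by default; 1 Mb in the loop-recovery experiments); 20 evenly
spaced binding sites; 10 loops of 8 PETs each between same-chromosome site
pairs ≥ 50 kb apart; and a molecule population of 32.3% self-ligation,
21.7% intra-chromosomal inter-ligation, 18.6% inter-chromosomal and 27.4%
short-span "other" — the purified-PET profile of a deep RNAPII library.
Linker classes (43.7% A_A, 47.0% B_B, 1.1% different, 8.2% ambiguous —
ambiguity realized as one corrupted barcode base), a 31% PCR duplication
rate and a 0.26% ±2 bp near-duplicate rate are properties of the molecule,
inherited by its copies. Self-ligation and "other" spans share one
log-normal distribution (median 500 bp, σ = 0.5, truncated at 7.5 kb): both
are single-fragment-scale products, and giving "other" molecules a separate,
longer span range would plant PETs between the estimated cutoff and the
inter-ligation floor (12 kb) that belong to no real population. 80% of
self-ligation fragments centre on a binding site (±150 bp) — an enriched
ChIP is the premise of the assay. Sequencing errors default to zero;
two-copy repeats and deliberately multi-mapping PETs are available as
options.

For the loop-recovery experiment the genome is 2×1 Mb, putting the
background inter-ligation density near 0.4 PETs/kb: at that density the
expected number of coincidental background triples joining one anchor pair
is well below one per library, so "zero non-planted significant pairs" is a
meaningful success measure rather than a coin flip. Scaled problem sizes
(thousands of molecules, megabase genomes) keep every experiment fast; the
statistics are scale-free percentages and recovery counts.

What passing these tests does **not** show about real data: no base-quality
or error model, no GC or mappability bias, no polymer-physics distance decay
(background inter-ligation distances are log-uniform), no restriction-site
structure, and real anchors are not cleanly separated point sites. The
synthetic results validate the machinery — classification, conservation,
calibration of the statistical kernels and recovery under the stated
conditions — not biological performance.

## Numerical details

- Percentage rounding: decimal half-up at two decimals, trailing zeros
  stripped; "N/A" on zero denominators.
- Histogram clipping: spans outside [100 bp, 100 Mb] land in the edge bins.
- Poisson and hypergeometric tails come from scipy (`poisson.sf`,
  `hypergeom.sf`); tests pin them to independent series-sum and
  integer-enumeration oracles at 1e-12 relative error.
- Benjamini–Hochberg adjustment uses statsmodels; a hand-written step-up
  reference agrees to ≤1e-13 relative error (bitwise equality across
  algebraically equivalent formula orderings is not defined in floating
  point).
- Interval merging is strict-overlap (touching intervals stay separate) for
  both peak footprints and anchors.
- Determinism: every stochastic component takes a NumPy `default_rng` seed;
  outputs are sorted before writing, so reruns are byte-identical.

## Known limitations

- The hypergeometric N (PETs, not tags) and the k ≥ 2 testing family are
  reconstructions; alternatives (N as tags, testing singletons) would shift
  absolute p-values but not the ranking.
- The toy mapper requires exact matches; it is a truth-recovery instrument
  for synthetic data, not a read aligner.
- Long-read mode is supported through classification and trimming; the
  synthetic long-read constructs place the genomic tag 5′ of the bridge only.
- The span-cutoff estimator assumes all four strand compositions are well
  populated; tiny libraries fall back to 8 kb.
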