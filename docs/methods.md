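# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. Coordinates are 0-based half-open everywhere
internally; rendered schemes print 1-based start positions; BED is native,
GFF3 is produced by exact conversion.

## Repeat-length spectrum (K-string interval histogram)

For every K-length window over {A,C,G,T} (windows containing N are
excluded, so assembly gaps cannot create phantom periods), the start-to-
start distances between consecutive occurrences of that exact K-string
are accumulated into a histogram, capped at `max_length`. A tandem repeat
of unit L makes every K-string inside the unit recur with period L; an
n-mer higher-order repeat (HOR) adds harmonics at 2L … nL. The histogram
is computed by 2-bit packing all windows and a single stable argsort, so
memory is linear in sequence length and the 10-Mb-segment use case runs
on a laptop; K > 32 falls back to string keys (memory bounded by the
number of distinct K-strings).

Parameters: `K = 12` by default (configurable 4–64). K is a free
parameter of the method: 12 is long enough that random recurrence is
negligible at the megabase scale (4^12 ≈ 1.7e7) and short enough that a
K-string survives the few-percent copy-to-copy divergence of real HOR
arrays with high probability. The histogram reports raw interval counts,
not normalized frequencies.

Peak detection merges bins greedily in descending count order with a
*relative* radius (±3% of the peak length) because unit-length jitter
from indels scales with length; peaks below `min_count = 5` are dropped.
The HOR signature rule accepts a candidate monomer length L only when
peaks are present within 5% at L, 2L, … nL.

Tandem-region location evaluates, per K-string, runs of consecutive
occurrences (split where the gap exceeds `max_length` or 5× the median
period): a run with ≥ 3 occurrences, coefficient of variation ≤ 0.1 and
modal period inside the requested unit range becomes a candidate region;
overlapping or near-adjacent (≤ 2 units) candidates with compatible units
are merged, keeping the leftmost candidate's key so the merged region
starts at a genuine key occurrence. With strongly diverged monomer
families, individual K-strings recur at the *HOR* period rather than the
monomer period — the prominent ~4.8 kb peak — and the monomer length is
recovered afterwards from the local spectrum via the signature rule.

## Divergence, clustering, consensus

Divergence between two sequences is the unit-cost edit (Levenshtein)
distance divided by the longer length: symmetric, zero iff equal, and
penalizing truncations. The normalizer is a convention choice (the
literature rarely states one); it is used consistently and reported.
All distances run through a blocked Myers/Hyyrö bit-parallel kernel
(O(n·⌈m/64⌉), numba-compiled), cross-checked in the test suite against a
quadratic reference DP.

Families are the connected components of the graph with an edge where
divergence is *strictly less than* the 5% threshold (single linkage).
Single linkage was chosen over clique clustering because the defining
phrase "differ from each other by less than 5%" is ambiguous; the looser
rule is used and `max_intra_divergence` is reported per family so chain
violations of the strict reading are visible. A pair at exactly the
threshold is not connected.

The consensus is a column-majority vote over a star alignment to the
family medoid (the member minimizing summed edit distance to the rest).
Members are globally aligned to the medoid with unit edit costs
(Bio.Align.PairwiseAligner); each medoid column takes the majority
aligned base, a gap majority drops the column, and an insertion is
emitted only when a strict majority of members insert identically at the
same position. Ties break alphabetically (A < C < G < T), making the
result deterministic given member order. With ≥ 5 members at ≤ 2%
per-copy noise the consensus error is far below 1%.

Family labels are assigned in genomic order of first occurrence and then
phase-canonicalized: all bijective relabellings are scored by how many
consecutive hit triples in a draft scan read m1→m2→m3, and the best is
applied; a tie keeps positional labels with a warning.

## Semi-global scanning

Each consensus monomer and its reverse complement is searched against
the assembly with the blocked Myers algorithm in infix mode (free start
and end in the text, whole pattern consumed): at every text position the
score of the best alignment ending there is available. Local minima
below `max_divergence` (default 0.15 of the consensus length — wide
enough for intra-family drift plus cross-assembly drift, far below the
~25% family separation) become candidates; the alignment start of each
candidate comes from the prefix-anchored reverse recurrence (ties prefer
the shortest span), so hit spans are indel-aware. Candidates from all
families and strands are accepted greedily by ascending divergence (ties:
start, then family order) under strict non-overlap; because optimal
alignments of abutting tandem copies may claim a few bases across the
junction, a new hit overlapping an accepted one by at most
`boundary_slack = 16` bases is trimmed to abut rather than rejected.
Hits with more than 10% N content are dropped; N matches nothing.
Assembly gaps are maximal N-runs *strictly* longer than `min_len`
(default 2000).

## HOR assembly

Hits are walked in genomic order — maximal reverse-complement blocks are
walked right-to-left so rows read m1→m2→m3 in gene orientation while
coordinates stay forward-strand. A new copy row starts when the family
label fails to strictly increase, the strand changes, or the gap exceeds
`intra_copy_gap_tol` (default 400 ≈ 0.25 monomer). Copies separated by
at most `array_gap_tol` (default 10 000 ≈ two canonical HOR lengths — a
quantification of the visual "blank space" between arrays) form tandem
arrays; an array is *prominent* when two neighboring canonical copies
occur in tandem; isolated monomers are single-copy arrays. Reports list
per-array copy and canonical counts with prominent arrays and scattered
groups distinguishable; gene-name labels are user-supplied annotations
applied positionally, never inferred. Schemes render one row per copy
(1-based start, family-colored boxes — m1 orange, m2 light blue, m3
blue — reverse-complement rows starred in text / bold in SVG), and
`align_panels` lays several reports side by side with anchor arrays'
first rows co-linear, purely presentationally.

## Discovery mode and frame calibration

Discovery chains: locate tandem regions over a wide unit range → keep
regions whose local spectrum passes the HOR signature → anchor the
monomer frame at the best-supported array's left edge (a homology walk
from the region's first key occurrence against its own periodic
extension; the slope constant 0.35 separates in-array from background
edit-growth rates) → read draft monomers off the genome at that edge,
cut at fractional multiples of the HOR period → draft-scan every kept
region, harvesting boundary-refined, strand-normalized monomer copies →
cluster, consensus, and merge any families whose consensus sequences are
within the clustering threshold of each other (satellite clusters from
duplicate harvests or drifted copies are the same family).

Repeat-unit boundaries inside an unbroken canonical run are a pure
convention: any consistent rotation of the monomer set annotates the
array identically. The true (planted, or biologically conventional)
boundaries are observable only where the canonical order breaks:

* a uniform rotation of the whole set is measured at array left edges
  (the homology walk back from the second hit, minus the lead family's
  interior-spacing median length; the walk's overshoot into background is
  one-sided, so the minimum over edges is used, with a ±2 dead-band);
* per-boundary offsets — caused by the indel noise of the single copy
  the drafts were read from — are estimated at variant-copy junctions: a
  grid search over the two free boundary offsets (the array-leading
  family's boundary is edge-pinned) minimizes the summed edit distance
  between junction neighbourhoods and their spliced-consensus model.

After any correction the consensus is rebuilt from a fresh harvest in
the corrected frame. Finally, if the majority of draft-scan hits are on
the reverse strand, the whole set is reverse-complemented so schemes
read in gene orientation, and families are phase-relabelled.

## Synthetic data: the stated world

The generator emulates the NBPF-like architecture: a uniform-random
background (GC 0.5), three 1600 bp monomer families descended from a
shared ancestor with measured pairwise divergence 25% ± 10% relative
(rejection-sampled), arrays of HOR-copy rows planted as insertions, each
monomer copy independently mutated (uniform substitutions at rate 2% in
the end-to-end scenario, single-base indels at 0.5%, insertion/deletion
balanced), whole arrays optionally reverse-complemented, and N-runs
emulating assembly gaps. The six-array scenario (19/15/14/13/5/9 total
copies = 75, with 11 variant rows spread so no two are adjacent — two
adjacent variant rows whose labels continue increasing would be
indistinguishable from a canonical copy by construction — hence 64
canonical) mirrors the copy-count structure of a complete human
chromosome 1 assembly at 2 Mb scale. Intra-array divergence defaults
follow the alpha-satellite analogy (copy divergence < 5%, an order of
magnitude below family divergence); the defaults are a declared choice,
not a measured NBPF value.

What a green end-to-end test establishes: exact copy/array count
recovery and < 1% consensus recovery under this regime, including
reverse-complement invariance and N-gap tolerance. What it does not:
performance on real assemblies with segmental duplications, hybrid
half-domains, nested repeats of other periods, or assembly errors;
GC-skewed backgrounds; monomer families at much lower mutual divergence
(where family assignment itself blurs).

## Numerical and degenerate-input choices

* Seeds: every stochastic step takes an explicit seed; family-ancestor
  and background draws use distinct seed-sequence streams so equal seeds
  cannot make the background collide with the planted monomers.
* `extract_repeat_copies` returns fragments between successive key
  occurrences only (the terminal fragment is dropped; fragments < 80% of
  the unit are discarded), so n copies yield n−1 fragments.
* Empty inputs: sequences shorter than K give an empty spectrum; a
  consensus longer than the target sequence warns and yields no hits; an
  empty truth writes an empty BED.
* The scan keeps, per locus, only the lowest-divergence family
  (greedy non-overlap), matching one-domain-one-family assignment.
* Reports and schemes are byte-deterministic given config + inputs; the
  run manifest records config and artifact checksums.

## Known limitations

* Discovery assumes the HOR order (default 3) when validating regions;
  other orders are configuration, not inference.
* Internal-boundary calibration needs variant junctions; a genome of
  pure unbroken canonical arrays leaves internal boundaries set by the
  draft copy's indel noise (a few bases, invisible to annotation).
* `align_panels` requires equal anchor counts and is presentational
  only; it performs no orthology inference.
* The scanner is exhaustive (no seeding heuristics); throughput is
  ~1 Mb·monomer/s per family-strand on one core, adequate for
  single-chromosome runs but not whole-genome surveys.
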