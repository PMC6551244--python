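# Methods

## Model and data

A phased haplotype panel is an `M × N` integer matrix: row `i` is a
haplotype, column `k` a variant site with alphabet size `t_k ≥ 1`
(codes `0..t_k-1`; 0 is the reference allele).  Per-site alphabets are
first-class: a panel may mix bi-allelic SNPs with tri- or ten-allelic
sites, and every sweep step sizes its bucket workspace to the current
`t_k`, so low-cardinality sites pay no overhead for the occasional
high-cardinality one.  A single global `t`, where needed, is the maximum
of the `t_k`.

All site intervals are 0-based half-open `[start, end)`.  This matches
the index arithmetic of the sweep (a match "ending at k" mismatches at
site `k` itself) and removes off-by-one ambiguity at the panel ends.

VCF input maps each diploid sample to two rows, left of the phase
separator first (the VCF specification itself fixes no such convention;
this is ours).  Unphased heterozygotes and half-calls are rejected —
the transform is defined on haplotypes.  Missing genotypes are rejected
by default; with `missing_policy="extra_allele"` a missing value becomes
code `t_k`, growing that site's alphabet by one, which keeps the panel
compressible but gives missing-aware match semantics that the user must
opt into knowingly.

## The sweep

State at position `k` is the prefix array `a_k` (haplotypes sorted by
reversed prefix, stable) and divergence array `d_k` (`d_k[i]` = start of
the match between sorted neighbours `i-1, i`; sentinel `d_k[0] = k`, so
position 0 always terminates a block scan).  One step is a stable
counting sort into `t_k` buckets in ascending allele order — ascending,
because that is the lexicographic order the sortedness invariant is
stated in.  Divergence maintenance uses one pending value per allele,
initialized to `k+1`, raised to every divergence value scanned since the
bucket last received a haplotype, appended and reset on placement.

The production implementation vectorises this: bucket membership via
per-allele index gathers, pending values via segmented maxima
(`np.maximum.reduceat` over `[prev_occurrence+1, current]` segments).
The segmented form is algebraically identical to the scalar loop — the
pending value at a placement is exactly the maximum divergence over the
positions since the previous placement of that allele, with `k+1` for a
bucket's first entry.  The scalar loop survives independently in the
bi-allelic reference (`mpbwt.oracle.BiallelicPBWT`), and both are tested
against an oracle that sorts explicit reversed-prefix strings and
computes divergence as `k` minus longest-common-suffix length.

## Matching

**Long matches (length ≥ L).**  "Greater than L" and "at least L" are
both used informally for this task; this package reports segments of
length **≥ L**, the convention of the last-site length check and of the
reference bi-allelic implementations.  At an interior site `k`, sorted
haplotypes not separated by `d > k-L` form a block; within a block,
every pair whose alleles differ at `k` terminates there and is reported,
with start equal to the running maximum of divergence values between the
two sorted positions (the unique value consistent with the divergence
invariant).  A block reports only if at least two distinct alleles occur
at `k` — the t-entry seen-allele table with its distinct-count trigger.

The last site is special: blocks are cut at `d > k-L+1` (segment of at
least L-1 sites before the last), and the allele at the last site
decides each pair: agreeing pairs end at `N` (always long enough by the
block bound), disagreeing pairs end at `N-1` and are kept only if
already ≥ L.  The final block is flushed with no terminating separator.
Without this routine, matches that never terminate by mismatch —
identical haplotype pairs above all — would be silently lost.

**Set-maximal matches.**  A match `[s, k)` from haplotype `q` is
set-maximal if it cannot be extended and no other haplotype matches `q`
on a longer interval ending at `k` — or on the same interval but
continuing through `k`.  At each `k` the candidates for sorted position
`i` are the neighbours on the side(s) attaining `min(d[i], d[i+1])`;
scanning outward while the divergence stays at or below that bound
enumerates every haplotype attaining it (the running maximum cannot
exceed the bound inside the scan).  If any of them carries `q`'s allele
at `k`, the match extends and nothing is reported for `i` at `k`;
otherwise all of them are reported — ties are all kept, since the
definition prefers no one of them.  Zero-length matches (first site) are
never reported.  The panel end is handled as a universal terminator: a
final pass at `k = N` reports each haplotype's longest matches with no
allele check.  Sorted-order sentinels are `k+1` on both ends.

The interior routine is validated purely against the exhaustive oracle
(per-haplotype enumeration of all maximal shared segments, discarding
those covered by a longer-or-equal segment that is strictly longer on
one side), the same way the last-site routine is.

Both reporters stream: records are produced grouped by end position,
with per-position de-duplication (a pair seen from both sides), so
match-dominated outputs need no memory beyond the per-site group.

## Compression

`transform` stores per site: the sorted column `y_k = x[a_k][k]`, allele
counts `c_k`, and the occurrence table `Occ_k[l][i]` (count of `l` among
`y_k[0..i-1]`) checkpointed every `occ_stride = 64` sorted positions —
dense `M × t` occurrence matrices would dwarf the panel; checkpoint +
short scan is standard FM-index practice and preserves exact semantics.
`c` is taken as per-allele counts and `CC` as their prefix sum; this is
the only reading under which the extension function

    w_k(i, l) = Occ_k[l][i] + CC_k(l-1),   CC_k(-1) = 0

satisfies `a_{k+1}[w_k(i, y_k[i])] = a_k[i]`, the inverse property the
whole scheme rests on (tested exhaustively on small panels).
Reconstruction sweeps forward from `a_0 = identity`, scattering `y_k`
through `a_k` and advancing with `w`.

The container is little-endian: magic `MPBWT`, version byte, `M`, `N`,
strides, per-site alphabet sizes, then per site the run-length-encoded
`y_k` (varint run count, varint (allele, length) pairs), `t_k - 1`
allele counts (the last is `M` minus the rest), and occurrence
checkpoints as per-block increments; finally prefix-array checkpoints
every `a_stride = 32` sites.  Encoding is byte-deterministic.  The
stored `a` checkpoints allow reconstruction to start mid-panel and are
verified during full reconstruction as a corruption check; divergence
arrays are deliberately *not* stored — they are needed only for query
search against a compressed panel, which this package does not do.

Checkpoint strides trade space for random-access latency: halving
`occ_stride` roughly doubles occurrence-checkpoint space and halves the
scan per rank query; `a_stride` likewise for mid-panel entry.  The
defaults (64, 32) keep checkpoint overhead well below the run-length
payload for panels with hundreds of haplotypes.

## Synthetic panels

The simulator is a minimal copying model, not a population-genetic one:
a few founder haplotypes are drawn from per-site allele frequencies
(uniform in `base_maf = (0.05, 0.5)`), and each subsequent haplotype
copies blocks of mean geometric length `block_length = 20` sites from
previously generated haplotypes, flipping alleles with
`mutation_rate = 0.01` per site.  Multi-allelic structure is added by
converting a fraction of sites (default experiment: 30%, matching the
standard benchmark construction for multi-allelic haplotype tools):
at each converted site the carriers of one of the two alleles are
re-assigned codes drawn uniformly from the target alphabet — how the
new alleles should be distributed is underdetermined, and uniform is
our choice.  Desk-scale defaults (`M = 200`, `N = 500`) keep brute-force
oracles usable; the scaling measurements go up to `M = 4000`,
`N = 5000`.

What the model does reproduce: haplotype sharing in blocks, hence long
exact matches and run-length-compressible sorted columns; what it does
not: recombination maps, demography, realistic allele-frequency spectra,
genotype error.  Passing tests therefore demonstrate algorithmic
correctness and the LD-driven compression mechanism, not calibrated
performance on cohort data.  LD is quantified as mean adjacent-site
squared correlation (r²): the signed correlation of a copying-model
panel inherits the founders' random per-site-pair sign and averages to
zero — as signed LD does in real panels — so r² is the meaningful
statistic; it is ~0.14 at `block_length = 25` versus ~0.006 at
`block_length = 1`.

`msprime` is installed in typical environments and can substitute
coalescent panels wherever a `HaplotypePanel` is constructed from a
matrix, but the package does not depend on it.

## Numerical and degenerate cases

* `N = 0`: building returns only the initial state; matching requires
  `1 ≤ L ≤ N` and so rejects empty panels.
* `M = 1`: all sweeps are trivial; set-maximal matching requires
  `M ≥ 2`.
* Alphabets may exceed observed codes (a fixed-`t` VCF convention);
  empty buckets cost one pointer per sweep step.
* All arrays are int32; panels beyond 2^31 haplotypes or sites are out
  of scope.
* Timing-based scaling checks use CPU time with repeats and wide
  tolerance bands (log-log slope < 1.6 over a 8-fold size range;
  set-maximal doubling ratio in [1.3, 3.0]) — they assert the complexity
  trend, not absolute speed.

## Known limitations

Query search against a compressed panel (which would require storing
divergence arrays), genotype-error-tolerant matching, and unphased or
genotype-likelihood input are out of scope.  Match reporting at interior
sites enumerates pairs within a block in O(block²), which exceeds the
output size when many same-allele pairs share a block at small L; for
the intended regime (L a few percent of N or more) blocks are small and
the output term dominates.
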