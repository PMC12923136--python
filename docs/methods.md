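# Methods

## Library design model

A coding sequence of L nucleotides (L divisible by 3) is tiled into
consecutive fragments of 25 codons; the last fragment keeps the remainder.
Codon coordinates are 1-based inclusive everywhere a user sees them;
internally nucleotide offsets are 0-based half-open. For a 1,068-codon gene
this yields 43 fragments: 42 of 75 nt and one of 54 nt. Fragment i covers
codons 25(i−1)+1 … min(25i, L/3); the last fragment of the 1,068-codon
layout therefore spans codons 1051–1068 (18 codons — the only reading
consistent with a 54-nt length and with 42 full tiles ending at codon
1050).

Each fragment's oPool contains one oligo per codon. The oligo concatenates:

1. the 40 nt immediately 5′ of the fragment in the parent construct (for
   fragment 1 this comes from a required user-supplied upstream context —
   homology arms belong to the destination vector, so there is no default);
2. the fragment with the target codon replaced by NNK (N = any base,
   K = G/T; 32 codons encoding all 20 amino acids plus the TAG stop);
3. the 4 nt immediately 3′ of the fragment;
4. the BsaI module `GGAGACCGAAGCTGGTCTCGACAG` — one recognition site per
   strand, separated by `CCGAAGCT` so the module cannot self-dimerize
   (stored uppercase; case carries no meaning);
5. the 30-nt barcode `NN + barcode1 + NN + barcode2 + NN`;
6. the constant primer-binding site PBS_i7
   `CTGTCTCTTATACACATCTCCGAGCCCACGAGAC`.

Full-fragment oligos are 207 nt (40+75+4+24+30+34) and the short last
fragment gives 186 nt, the minimum over the design. Every oligo carries
exactly nine degenerate positions (three NNK, six spacers). The WT
instantiation of the NNK codon is a synthesis reality and is retained in
the design; read processing classifies it as wild-type, not a variant.

## Barcode codebook

Barcodes are 12-mers filtered per-barcode (GC fraction within
[0.40, 0.60], i.e. 5–7 G/C bases, bounds inclusive; no BsaI recognition
sequence on either strand; first two and last two bases not identical) and
then selected greedily for a minimum pairwise Hamming distance of 3: all
4^12 candidates passing the per-barcode filters are visited in a seeded
random permutation and a candidate is accepted iff it is at distance ≥ 3
from every accepted barcode. "Distance 3" is read as a minimum pairwise
distance — the only reading that yields an error-tolerant code. Per-barcode
filters are applied before the pairwise constraint.

The greedy scan is exact but indexed: two 12-mers at distance ≤ 2 must
agree exactly on at least one of three contiguous 4-nt blocks (pigeonhole),
so each candidate is compared only against accepted barcodes sharing a
block. For other minimum distances the scan falls back to comparing
against all accepted members. Reaching 30,000 barcodes takes a few seconds;
the generator warns (rather than fails) if a target is unreachable and
returns the maximum found.

Codon positions receive disjoint barcode pairs whose combined G+C count
over 24 bases lies within 12 ± 1 (11–13, the tightest broadly satisfiable
window around "combined GC ≈ 50 %"). Pairing, like every randomized step,
is deterministic for a fixed seed. Forbidden-motif screening covers fixed
sequence only; BsaI sites that a particular random spacer fill could create
across a junction are not screened, but the report-only design validator
counts recognition sites per realized oligo and flags anything other than
the two sites inside the module, as well as duplicated barcode pairs.

## Read processing

The first-cloning-step (Gibson) merged read is modelled as
`fragment | anchor | BsaI module | 30-nt barcode`, with primer regions
assumed trimmed by the upstream merger (quality filtering, trimming and
pair merging are out of scope; the toolkit consumes merged reads).
Checks run in a fixed order and each rejected read gets exactly one
reason, the first failure:

1. exact expected length (indels shift it) → `length_mismatch`;
2. any uncalled base → `ambiguous_base`;
3. anchor/module flank not intact → `unknown_structure`;
4. more than one mutated codon in the fragment window → `multi_mutant`;
5. barcode fixed 12-mers not registered for this fragment →
   `barcode_mismatch`.

Accepted + rejected-by-reason always partitions the input; aggregation is
order-free. Barcode identity is exact by default: although the
distance-3 code could correct single mismatches, mismatched barcodes are
discarded (a `correct_mismatches` flag enables 1-mismatch rescue, refusing
ambiguous corrections). A barcode realization includes its six spacer
bases, so one codon position supports up to 4,096 realizations.

Reads whose observed mutation position contradicts their barcode's
registered position (template switches/chimeras) are flagged and excluded
from the association rather than reassigned; wild-type-sequence reads have
no mutated position and are exempt. Barcode–variant pairs with fewer than
two supporting reads are discarded; the threshold is applied at the pair
level (the stricter of the two possible readings), with an
aggregate-per-mutation option. A barcode is *informative* iff it is
associated with exactly one variant that is not the wild-type sequence.

## Quality metrics

Coverage metrics are computed over the **designed** mutation universe, not
the observed one: at amino-acid level, 21 states minus the wild-type amino
acid per position (20/position); at codon level, the NNK set minus the
wild-type codon. Mutation coverage is the percentage of designed mutations
with ≥ 1 informative barcode; diversity is the percentage with > 4 and > 9.

The Gini coefficient uses the mean-absolute-difference form
G = ΣᵢΣⱼ|xᵢ−xⱼ| / (2n²x̄), computed in O(n log n) and verified in the test
suite against the O(n²) double sum to 1e-12. By default it runs over the
designed universe including zero-count variants, so dropouts worsen G; an
observed-only option exists because either convention is defensible. The
uniformity score is log₁₀(P90) − log₁₀(P10) of per-variant read counts
with linear-interpolation percentiles, over observed variants only (P10=0
is undefined in log space).

Subsampling curves re-order transformation batches randomly 100 times,
recomputing all metrics on each cumulative union (support filtering is
re-applied to the union, so counts only accumulate and coverage paths are
monotone); the x axis is cumulative transformants per fragment bp and the
interval is the 2.5th–97.5th percentile across draws (the
confidence-interval definition was open; percentile bands make no
normality assumption).

## Selection coefficients

With counts per unit (barcode realization or variant codon) at two
timepoints, per replicate:

    f_t = (n_t + 1) / Σ(n_t + 1)          pseudocount 1 on every unit
    raw = log₂(f_TP2 / f_TP0)
    s   = raw / g − median{ s of silent variants }

g is the number of mitotic generations (g = n_cycles·log₂(OD_end/OD_start);
two cycles of 0.05 → 0.80 give 8.0). The silent set is codons differing
from wild type that encode the wild-type amino acid, excluding the
wild-type nucleotide sequence itself; after the shift the silent median is
exactly 0. Division by g precedes the silent subtraction (the procedure's
step order). The pseudocount keeps dropouts finite and is the one numerical
choice with a visible bias: units driven to very low TP2 counts are pulled
slightly toward 0. Units with TP0 < 5 reads are low-confidence and excluded
from aggregation. Replicates are scored separately and combined by median.
Amino-acid scores are the median over surviving synonymous units (a mean
option exists); classification uses strict inequalities at ±0.6, so exactly
±0.6 is intermediate.

Two estimators coexist deliberately: the full-data "barcode mode"
aggregates counts per variant before scoring, while the subsampling
analysis scores each barcode realization separately and averages exactly n
per-barcode scores per variant (resampling with replacement when a variant
has fewer than n barcodes, a random subset otherwise), correlating each of
100 draws against direct-sequencing scores with Pearson's r. When every
variant has exactly n barcodes the subsampled estimate equals the full
per-barcode mean.

## Simulator

The generator emulates the study conditions end to end: for every codon
position all 32 NNK realizations (the wild-type-matching one included when
the wild-type codon is NNK-compatible), a number of barcode realizations
per variant (default Poisson mean 10 truncated at ≥ 1, matching the
">9 barcodes for most mutations" regime; an integer gives a fixed count),
uniform-expectation multinomial sampling down to the transformant count
(the cloning bottleneck; default 25,000 per fragment), optional per-variant
synthesis dropout, i.i.d. per-base substitution errors and at-most-one
per-read indel, and competition counts drawn multinomially per timepoint
around the deterministic exponential expectation
E[TP2ᵢ] ∝ TP0ᵢ·2^{g(1+sᵢ)} with silent/WT s = 0 and non-silent s drawn
uniformly from [−0.6, 0.6]. Sequences seen once in a sample are zeroed
(singleton removal) before scoring. Synthetic coding sequences and vector
contexts are domesticated against the BsaI motif, mirroring the removal of
internal BsaI sites that Golden Gate assembly requires of the real
template. One master seed fixes the entire dataset byte for byte.

What the simulator does **not** model — and hence what passing tests do
not show about real data: PCR amplification bias (no UMI correction),
quality-score structure (errors are position-uniform; qualities are ignored
downstream), stochastic drift during growth (growth is deterministic in
expectation), chimera formation, and double-mutant synthesis errors beyond
what substitution errors produce.

## Problem sizes and verification

The test suite and examples run one 25-codon fragment (800 codon variants,
500 amino-acid mutations) at 25,000–30,000 transformants, 5–8 barcodes per
variant, and ~500 reads per variant per timepoint with two replicated
competitions — the per-fragment scale of the motivating experiment. Under
these conditions the pipeline recovers simulated landscapes with
r(true, estimated) ≥ 0.95 and mean absolute error ≤ 0.03 per generation
(typically r ≈ 0.99, MAE ≈ 0.02), barcode and direct readouts of the same
competition agree at r ≥ 0.99, and subsampling correlations rise
monotonically with barcodes per variant. Zero-error simulations are
reproduced exactly: 100 % of reads accepted and the ground-truth
association recovered verbatim.

## Known limitations

- Reads are assumed oriented and merged; reverse-complement auto-detection
  exists but is off by default.
- Double mutants are rejected, not scored; there is no epistasis mode.
- The discrepancy-adjudication step a full study would apply to variants
  where barcode and direct estimates disagree is not implemented.
- Indel variant libraries, primer Tm optimization and promoter/terminator
  mutagenesis are out of scope.
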