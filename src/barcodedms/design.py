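"""Barcoded NNK oligo-pool (oPool) design.

This module turns a coding sequence into a complete saturation-mutagenesis
oligo order: the CDS is tiled into 25-codon fragments, each codon of each
fragment gets one oligo in which that codon is replaced by the degenerate
NNK codon, and each oligo carries a 30-nt DNA barcode that encodes the codon
position (two fixed 12-nt barcodes drawn from a Hamming-distance-3 codebook)
while leaving six random spacer bases for clone-level diversity.

Every oligo is the concatenation

    40-nt upstream homology | fragment with one NNK codon | 4-nt anchor |
    BsaI module | NN + barcode1 + NN + barcode2 + NN | PBS_i7

for a total of nine degenerate positions (three in the NNK codon, six in the
barcode spacers).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "BSAI_MODULE",
    "PBS_I7",
    "BSAI_SITE",
    "BSAI_SITE_RC",
    "SPACER_OFFSETS",
    "CodingSequence",
    "FragmentPlan",
    "BarcodeCodebook",
    "BarcodePair",
    "BarcodeTemplate",
    "OligoDesign",
    "OPoolDesign",
    "ValidationReport",
    "CodebookWarning",
    "segment_cds",
    "fragment_residue_range",
    "generate_codebook",
    "pair_barcodes",
    "assemble_barcode_template",
    "build_opool",
    "build_full_design",
    "validate_design",
    "translate_codon",
    "enumerate_nnk",
    "count_bsai_sites",
]

#: BsaI module: two BsaI recognition sites (one per strand) separated by
#: CCGAAGCT to prevent self-dimerisation during Golden Gate assembly.
BSAI_MODULE = "GGAGACCGAAGCTGGTCTCGACAG"
#: Conserved i7 primer-binding site shared by every oligo.
PBS_I7 = "CTGTCTCTTATACACATCTCCGAGCCCACGAGAC"
#: BsaI recognition sequence (top strand) and its reverse complement.
BSAI_SITE = "GGTCTC"
BSAI_SITE_RC = "GAGACC"
#: 0-based offsets of the six degenerate spacer bases in the 30-nt barcode.
SPACER_OFFSETS = (0, 1, 14, 15, 28, 29)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_DEGENERATE = set("NK")  # the only IUPAC ambiguity codes emitted by designs


class CodebookWarning(UserWarning):
    """Raised (as a warning) when a codebook target size is unreachable."""


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard genetic code ('*' = stop)."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    return str(Seq(codon).translate())


def enumerate_nnk() -> tuple[str, ...]:
    """All 32 NNK codons (any base at positions 1-2, G or T at position 3)."""
    return tuple(
        a + b + c for a in _BASES for b in _BASES for c in "GT"
    )


@dataclass(frozen=True)
class CodingSequence:
    """A validated protein-coding nucleotide sequence.

    ``allow_internal_stops`` exists for partial-CDS use; by default an
    internal stop codon is treated as a design error.
    """

    id: str
    seq: str
    allow_internal_stops: bool = False

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError(
                f"CDS {self.id!r}: length {len(seq)} is not a positive multiple of 3"
            )
        bad = set(seq) - set(_BASES)
        if bad:
            raise ValueError(f"CDS {self.id!r}: ambiguous/invalid bases {sorted(bad)}")
        if not self.allow_internal_stops:
            aa = str(Seq(seq).translate())
            if "*" in aa[:-1]:
                raise ValueError(
                    f"CDS {self.id!r}: internal stop codon at codon "
                    f"{aa.index('*') + 1}"
                )

    @property
    def codon_count(self) -> int:
        return len(self.seq) // 3

    def codon(self, position: int) -> str:
        """Codon at 1-based position."""
        if not 1 <= position <= self.codon_count:
            raise IndexError(f"codon position {position} out of 1..{self.codon_count}")
        return self.seq[(position - 1) * 3 : position * 3]

    @property
    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    def translate(self) -> str:
        return str(Seq(self.seq).translate())


@dataclass(frozen=True)
class FragmentPlan:
    """One tile of the CDS with its assembly context.

    Codon coordinates are 1-based inclusive. ``upstream_homology`` is the
    40 nt immediately 5' of the fragment in the parent construct and
    ``downstream_anchor`` the 4 nt immediately 3'.
    """

    fragment_index: int
    codon_start: int
    codon_end: int
    nt_length: int
    upstream_homology: str
    downstream_anchor: str
    fragment_seq: str

    def __post_init__(self) -> None:
        if self.nt_length != 3 * (self.codon_end - self.codon_start + 1):
            raise ValueError("nt_length inconsistent with codon bounds")
        if len(self.upstream_homology) != 40:
            raise ValueError("upstream homology must be exactly 40 nt")
        if len(self.downstream_anchor) != 4:
            raise ValueError("downstream anchor must be exactly 4 nt")
        if len(self.fragment_seq) != self.nt_length:
            raise ValueError("fragment sequence length mismatch")

    @property
    def n_codons(self) -> int:
        return self.codon_end - self.codon_start + 1

    @property
    def positions(self) -> range:
        """1-based codon positions (in CDS coordinates) covered."""
        return range(self.codon_start, self.codon_end + 1)


def fragment_residue_range(
    fragment_index: int, tile_codons: int, codon_count: int
) -> tuple[int, int]:
    """1-based inclusive codon bounds of a fragment.

    Fragment 1 covers codons 1..tile, fragment 2 codons tile+1..2*tile, and
    so on; the last fragment may be short.
    """
    n_fragments = -(-codon_count // tile_codons)
    if not 1 <= fragment_index <= n_fragments:
        raise IndexError(
            f"fragment {fragment_index} out of 1..{n_fragments} "
            f"({codon_count} codons, tile {tile_codons})"
        )
    start = tile_codons * (fragment_index - 1) + 1
    end = min(tile_codons * fragment_index, codon_count)
    return start, end


def segment_cds(
    cds: CodingSequence,
    tile_codons: int = 25,
    *,
    upstream_context: str,
    downstream_context: str,
) -> list[FragmentPlan]:
    """Tile the CDS into consecutive fragments of ``tile_codons`` codons.

    ``upstream_context`` is the sequence immediately 5' of the CDS in the
    parent construct (promoter/vector; >=40 nt needed for fragment 1) and
    ``downstream_context`` the sequence immediately 3' (>=4 nt needed for
    the last fragment). There is no default context: homology arms are a
    property of the destination vector, not of the gene.
    """
    if tile_codons < 1:
        raise ValueError("tile_codons must be >= 1")
    upstream_context = upstream_context.upper()
    downstream_context = downstream_context.upper()
    if len(upstream_context) < 40:
        raise ValueError("upstream context must provide at least 40 nt")
    if len(downstream_context) < 4:
        raise ValueError("downstream context must provide at least 4 nt")
    parent = upstream_context + cds.seq + downstream_context
    offset = len(upstream_context)
    n_fragments = -(-cds.codon_count // tile_codons)
    plans = []
    for i in range(1, n_fragments + 1):
        start, end = fragment_residue_range(i, tile_codons, cds.codon_count)
        nt_start = offset + (start - 1) * 3
        nt_end = offset + end * 3
        plans.append(
            FragmentPlan(
                fragment_index=i,
                codon_start=start,
                codon_end=end,
                nt_length=nt_end - nt_start,
                upstream_homology=parent[nt_start - 40 : nt_start],
                downstream_anchor=parent[nt_end : nt_end + 4],
                fragment_seq=parent[nt_start:nt_end],
            )
        )
    return plans


# ---------------------------------------------------------------------------
# Barcode codebook
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BarcodeCodebook:
    """A set of k-nt barcodes with a guaranteed minimum pairwise Hamming
    distance, per-barcode GC bounds, forbidden-motif exclusion, and no
    identical adjacent bases at either terminus.

    ``members`` preserves acceptance order so that downstream pairing is
    deterministic for a fixed seed.
    """

    k: int = 12
    members: tuple[str, ...] = ()
    min_hamming: int = 3
    gc_min: float = 0.40
    gc_max: float = 0.60
    forbidden_motifs: tuple[str, ...] = (BSAI_SITE, BSAI_SITE_RC)
    rng_seed: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, barcode: str) -> bool:
        return barcode in set(self.members)

    def __iter__(self):
        return iter(self.members)


def _passes_barcode_filters(
    bc: str, gc_min: float, gc_max: float, forbidden: Sequence[str]
) -> bool:
    gc = sum(1 for b in bc if b in "GC") / len(bc)
    if not gc_min <= gc <= gc_max:
        return False
    if bc[0] == bc[1] or bc[-1] == bc[-2]:
        return False
    return not any(m in bc for m in forbidden)


def _filtered_candidates(
    k: int,
    gc_min: float,
    gc_max: float,
    forbidden: Sequence[str],
    rng: np.random.Generator,
) -> Iterator[np.ndarray]:
    """Chunks of k-mers passing the per-barcode filters, as integer codes in
    a seeded random order (2 bits per base, first base = most significant).

    Lazy per-chunk filtering lets small-target codebooks stop after one
    chunk instead of screening the whole 4^k space.
    """
    n = 4**k
    order = rng.permutation(n).astype(np.int64)
    shifts = np.arange(2 * (k - 1), -1, -2, dtype=np.int64)
    for lo in range(0, n, 1 << 20):
        chunk = order[lo : lo + (1 << 20)]
        bases = ((chunk[:, None] >> shifts) & 3).astype(np.uint8)
        gc_count = ((bases == 1) | (bases == 2)).sum(axis=1)
        mask = (gc_count >= np.ceil(gc_min * k) - 1e-9) & (
            gc_count <= np.floor(gc_max * k) + 1e-9
        )
        mask &= bases[:, 0] != bases[:, 1]
        mask &= bases[:, -1] != bases[:, -2]
        for motif in forbidden:
            if len(motif) > k:
                continue
            m = np.array([_BASE_INDEX[b] for b in motif.upper()], dtype=np.uint8)
            hit = np.zeros(len(chunk), dtype=bool)
            for off in range(k - len(motif) + 1):
                hit |= (bases[:, off : off + len(m)] == m).all(axis=1)
            mask &= ~hit
        yield chunk[mask]


def _int_to_barcode(code: int, k: int) -> str:
    return "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def _hamming_ge(a: int, b: int, k: int, d: int) -> bool:
    """True iff Hamming distance between 2-bit-packed k-mers >= d."""
    x = a ^ b
    mask = (1 << (2 * k)) // 3  # 0b0101...01
    y = (x | (x >> 1)) & mask
    return y.bit_count() >= d


def generate_codebook(
    k: int = 12,
    target_size: int = 30_000,
    *,
    min_hamming: int = 3,
    gc_min: float = 0.40,
    gc_max: float = 0.60,
    forbidden_motifs: Sequence[str] = (BSAI_SITE, BSAI_SITE_RC),
    seed: int = 0,
) -> BarcodeCodebook:
    """Greedy construction of a minimum-Hamming-distance barcode codebook.

    All 4^k candidates passing the per-barcode filters (GC window, no
    forbidden motif, distinct terminal dinucleotides) are visited in a
    seeded random order; a candidate is accepted iff its Hamming distance to
    every previously accepted barcode is >= ``min_hamming``. The scan stops
    when ``target_size`` barcodes are accepted or candidates are exhausted;
    in the latter case a :class:`CodebookWarning` is emitted and the maximum
    reached is returned.

    For ``min_hamming == 3`` the distance check is exact but indexed: two
    k-mers at distance <= 2 must agree exactly on one of three contiguous
    blocks of the barcode (pigeonhole), so only accepted barcodes sharing a
    block with the candidate need to be compared.
    """
    if k < 1 or k > 12:
        raise ValueError("k must be in 1..12 (candidate space is enumerated)")
    if min_hamming < 1:
        raise ValueError("min_hamming must be >= 1")
    rng = np.random.default_rng(seed)

    accepted: list[int] = []
    n_candidates = 0
    use_index = min_hamming == 3 and k >= 3
    if use_index:
        # three contiguous blocks; block i spans codons cut[i]..cut[i+1]
        cuts = [0, k // 3, 2 * k // 3, k]
        block_shifts = [2 * (k - cuts[i + 1]) for i in range(3)]
        block_masks = [(1 << (2 * (cuts[i + 1] - cuts[i]))) - 1 for i in range(3)]
        buckets: list[dict[int, list[int]]] = [{}, {}, {}]

    for chunk in _filtered_candidates(k, gc_min, gc_max, forbidden_motifs, rng):
        n_candidates += len(chunk)
        if use_index:
            for cand in chunk.tolist():
                keys = [
                    (cand >> block_shifts[i]) & block_masks[i] for i in range(3)
                ]
                ok = True
                for i in range(3):
                    for other in buckets[i].get(keys[i], ()):
                        if not _hamming_ge(cand, other, k, min_hamming):
                            ok = False
                            break
                    if not ok:
                        break
                if ok:
                    accepted.append(cand)
                    for i in range(3):
                        buckets[i].setdefault(keys[i], []).append(cand)
                    if len(accepted) >= target_size:
                        break
        else:
            for cand in chunk.tolist():
                if all(
                    _hamming_ge(cand, other, k, min_hamming) for other in accepted
                ):
                    accepted.append(cand)
                    if len(accepted) >= target_size:
                        break
        if len(accepted) >= target_size:
            break

    if len(accepted) < target_size:
        warnings.warn(
            f"codebook target {target_size} unreachable for k={k}: "
            f"accepted {len(accepted)} of {n_candidates} candidates",
            CodebookWarning,
            stacklevel=2,
        )
    members = tuple(_int_to_barcode(c, k) for c in accepted)
    return BarcodeCodebook(
        k=k,
        members=members,
        min_hamming=min_hamming,
        gc_min=gc_min,
        gc_max=gc_max,
        forbidden_motifs=tuple(m.upper() for m in forbidden_motifs),
        rng_seed=seed,
    )


@dataclass(frozen=True)
class BarcodePair:
    """The two fixed 12-nt barcodes assigned to one codon position."""

    codon_position: int
    barcode1: str
    barcode2: str

    @property
    def combined_gc_count(self) -> int:
        return sum(1 for b in self.barcode1 + self.barcode2 if b in "GC")


def pair_barcodes(
    codebook: BarcodeCodebook,
    n_pairs: int,
    *,
    combined_gc_tolerance: int = 1,
    seed: int = 0,
) -> list[BarcodePair]:
    """Pair codebook members into position-specific barcode pairs.

    The combined G+C count of each pair over 2k bases must lie within
    ``k +- combined_gc_tolerance`` (i.e., combined GC ~50%). Each member is
    used at most once; pairs are assigned to codon positions 1..n_pairs in
    a deterministic seeded order.
    """
    k = codebook.k
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(codebook.members))
    pool = [codebook.members[i] for i in order]
    gc = [sum(1 for b in m if b in "GC") for m in pool]
    used = [False] * len(pool)
    pairs: list[BarcodePair] = []
    lo, hi = k - combined_gc_tolerance, k + combined_gc_tolerance
    i = 0
    for position in range(1, n_pairs + 1):
        while i < len(pool) and used[i]:
            i += 1
        first = i
        partner = None
        if first < len(pool):
            for j in range(first + 1, len(pool)):
                if not used[j] and lo <= gc[first] + gc[j] <= hi:
                    partner = j
                    break
        if partner is None:
            raise ValueError(
                f"codebook exhausted: paired {len(pairs)} of {n_pairs} "
                f"positions (codebook size {len(pool)})"
            )
        used[first] = used[partner] = True
        pairs.append(
            BarcodePair(
                codon_position=position,
                barcode1=pool[first],
                barcode2=pool[partner],
            )
        )
    return pairs


@dataclass(frozen=True)
class BarcodeTemplate:
    """30-character degenerate barcode template: NN+barcode1+NN+barcode2+NN."""

    template: str
    degenerate_positions: tuple[int, ...] = SPACER_OFFSETS

    def __post_init__(self) -> None:
        if len(self.template) != 30:
            raise ValueError("barcode template must be exactly 30 characters")
        for off in self.degenerate_positions:
            if self.template[off] != "N":
                raise ValueError(f"expected N at template offset {off}")

    @property
    def barcode1(self) -> str:
        return self.template[2:14]

    @property
    def barcode2(self) -> str:
        return self.template[16:28]


def assemble_barcode_template(pair: BarcodePair) -> BarcodeTemplate:
    """Build the 30-nt degenerate barcode region for one codon position."""
    return BarcodeTemplate(
        template="NN" + pair.barcode1 + "NN" + pair.barcode2 + "NN"
    )


# ---------------------------------------------------------------------------
# Oligo assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OligoDesign:
    """One oPool member: a single-NNK variant oligo with its barcode."""

    fragment_index: int
    codon_position: int  # 1-based, CDS coordinates
    sequence: str  # IUPAC string with N/K degeneracies
    wt_codon: str
    barcode_template: BarcodeTemplate
    bsai_module: str = BSAI_MODULE
    pbs_i7: str = PBS_I7

    @property
    def name(self) -> str:
        return f"F{self.fragment_index}_c{self.codon_position}"

    @property
    def degenerate_count(self) -> int:
        return sum(1 for b in self.sequence if b in _DEGENERATE)


@dataclass(frozen=True)
class OPoolDesign:
    """All oligos for one fragment (one per codon)."""

    fragment: FragmentPlan
    oligos: tuple[OligoDesign, ...]

    @property
    def pool_id(self) -> str:
        return f"oPool_F{self.fragment.fragment_index}"


def build_opool(
    fragment: FragmentPlan,
    codon_position: int,
    template: BarcodeTemplate,
) -> OligoDesign:
    """Assemble the oligo targeting one codon of one fragment.

    Concatenation order: 40-nt homology, fragment with the target codon
    replaced by NNK, 4-nt anchor, BsaI module, 30-nt barcode, PBS_i7.
    """
    if codon_position not in fragment.positions:
        raise ValueError(
            f"codon {codon_position} outside fragment "
            f"{fragment.fragment_index} ({fragment.codon_start}-{fragment.codon_end})"
        )
    off = (codon_position - fragment.codon_start) * 3
    wt_codon = fragment.fragment_seq[off : off + 3]
    mutated = fragment.fragment_seq[:off] + "NNK" + fragment.fragment_seq[off + 3 :]
    sequence = (
        fragment.upstream_homology
        + mutated
        + fragment.downstream_anchor
        + BSAI_MODULE
        + template.template
        + PBS_I7
    )
    return OligoDesign(
        fragment_index=fragment.fragment_index,
        codon_position=codon_position,
        sequence=sequence,
        wt_codon=wt_codon,
        barcode_template=template,
    )


def build_full_design(
    cds: CodingSequence,
    codebook: BarcodeCodebook,
    *,
    upstream_context: str,
    downstream_context: str,
    tile_codons: int = 25,
    combined_gc_tolerance: int = 1,
    seed: int = 0,
) -> list[OPoolDesign]:
    """One oPool per fragment, one barcoded NNK oligo per codon of the CDS.

    Barcode pairs are unique across the whole design (each codebook member
    is consumed at most once).
    """
    fragments = segment_cds(
        cds,
        tile_codons,
        upstream_context=upstream_context,
        downstream_context=downstream_context,
    )
    pairs = pair_barcodes(
        codebook,
        cds.codon_count,
        combined_gc_tolerance=combined_gc_tolerance,
        seed=seed,
    )
    pools = []
    for frag in fragments:
        oligos = []
        for pos in frag.positions:
            template = assemble_barcode_template(pairs[pos - 1])
            oligos.append(build_opool(frag, pos, template))
        pools.append(OPoolDesign(fragment=frag, oligos=tuple(oligos)))
    return pools


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def count_bsai_sites(seq: str) -> int:
    """Count BsaI recognition occurrences on either strand of the fixed
    portion of ``seq``; windows containing degenerate symbols are skipped."""
    n = 0
    for motif in (BSAI_SITE, BSAI_SITE_RC):
        for off in range(len(seq) - len(motif) + 1):
            window = seq[off : off + len(motif)]
            if any(b in _DEGENERATE for b in window):
                continue
            if window == motif:
                n += 1
    return n


@dataclass(frozen=True)
class OligoCheck:
    oligo_name: str
    length: int
    bsai_site_count: int
    degenerate_count: int
    flags: tuple[str, ...]


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[OligoCheck, ...]
    duplicate_pairs: tuple[tuple[str, str], ...]

    @property
    def ok(self) -> bool:
        return not self.duplicate_pairs and all(not c.flags for c in self.checks)

    @property
    def flagged(self) -> list[OligoCheck]:
        return [c for c in self.checks if c.flags]


def validate_design(design: Iterable[OPoolDesign]) -> ValidationReport:
    """Report-only audit of a built design.

    Per oligo: BsaI site count on the fixed portion must be exactly 2 (both
    inside the BsaI module), the degenerate-symbol count must be 9, and
    barcode pairs must not collide across codon positions.
    """
    checks = []
    seen_pairs: dict[tuple[str, str], str] = {}
    duplicates = []
    for pool in design:
        for oligo in pool.oligos:
            flags = []
            sites = count_bsai_sites(oligo.sequence)
            if sites != 2:
                flags.append(f"bsai_site_count={sites}")
            deg = oligo.degenerate_count
            if deg != 9:
                flags.append(f"degenerate_count={deg}")
            pair = (oligo.barcode_template.barcode1, oligo.barcode_template.barcode2)
            if pair in seen_pairs:
                duplicates.append((seen_pairs[pair], oligo.name))
                flags.append("duplicate_barcode_pair")
            else:
                seen_pairs[pair] = oligo.name
            checks.append(
                OligoCheck(
                    oligo_name=oligo.name,
                    length=len(oligo.sequence),
                    bsai_site_count=sites,
                    degenerate_count=deg,
                    flags=tuple(flags),
                )
            )
    return ValidationReport(checks=tuple(checks), duplicate_pairs=tuple(duplicates))
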