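"""Amplicon read processing: variant calling and barcode-variant association.

Two sequencing designs are handled. After the first (Gibson) cloning step
the merged read covers the mutated fragment, the fixed anchor/BsaI module,
and the 30-nt barcode; these reads establish the barcode -> variant
reference. After the second (Golden Gate) step, and at competition
timepoints, only the barcode region is sequenced and counts are joined back
to that reference.

Barcode identity is exact: the two fixed 12-mers must match a registered
codon-position pair with zero mismatches (the distance-3 code would permit
single-mismatch correction, but mismatched barcodes are discarded instead;
``correct_mismatches`` turns 1-mismatch rescue on). A barcode *realization*
includes the six random spacer bases, so each codon position carries up to
4,096 distinct realizations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .design import OPoolDesign, translate_codon

__all__ = [
    "REJECTION_REASONS",
    "MergedRead",
    "VariantCall",
    "RejectionRecord",
    "FragmentReference",
    "parse_gibson_read",
    "cross_check_barcode_position",
    "build_association",
    "process_gibson_reads",
    "parse_barcode_only_read",
    "count_barcode_reads",
    "join_to_reference",
    "GibsonResult",
]

#: Fixed rejection order; every rejected read gets exactly one reason
#: (the first failing check).
REJECTION_REASONS = (
    "length_mismatch",
    "ambiguous_base",
    "unknown_structure",
    "multi_mutant",
    "barcode_mismatch",
)


@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str


@dataclass(frozen=True)
class VariantCall:
    fragment_index: int
    codon_position: int  # 1-based CDS coordinates
    variant_codon: str
    aa_state: str
    is_wt_sequence: bool
    is_silent: bool


@dataclass(frozen=True)
class RejectionRecord:
    read_id: str
    reason: str


class FragmentReference:
    """Expected read layout and barcode registry for one fragment.

    The Gibson-stage merged read is expected to be::

        fragment (nt_length) | 4-nt anchor | BsaI module | 30-nt barcode

    with the primer-binding regions already trimmed during merging.
    """

    def __init__(
        self,
        fragment_index: int,
        codon_start: int,
        wt_codons: list[str],
        downstream_anchor: str,
        bsai_module: str,
        pair_by_position: Mapping[int, tuple[str, str]],
    ):
        self.fragment_index = fragment_index
        self.codon_start = codon_start
        self.wt_codons = list(wt_codons)
        self.fixed_flank = downstream_anchor + bsai_module
        self.pair_by_position = dict(pair_by_position)
        self.position_by_pair = {
            pair: pos for pos, pair in self.pair_by_position.items()
        }
        if len(self.position_by_pair) != len(self.pair_by_position):
            raise ValueError("barcode pairs are not unique within the fragment")
        self.nt_length = 3 * len(wt_codons)
        self.barcode_offset = self.nt_length + len(self.fixed_flank)
        self.expected_length = self.barcode_offset + 30

    @classmethod
    def from_design(cls, design: Iterable[OPoolDesign], fragment_index: int
                    ) -> "FragmentReference":
        for pool in design:
            if pool.fragment.fragment_index == fragment_index:
                frag = pool.fragment
                pairs = {
                    o.codon_position: (
                        o.barcode_template.barcode1,
                        o.barcode_template.barcode2,
                    )
                    for o in pool.oligos
                }
                return cls(
                    fragment_index=fragment_index,
                    codon_start=frag.codon_start,
                    wt_codons=[
                        frag.fragment_seq[i : i + 3]
                        for i in range(0, frag.nt_length, 3)
                    ],
                    downstream_anchor=frag.downstream_anchor,
                    bsai_module=pool.oligos[0].bsai_module,
                    pair_by_position=pairs,
                )
        raise KeyError(f"fragment {fragment_index} not in design")

    def lookup_pair(
        self, barcode1: str, barcode2: str, correct_mismatches: bool = False
    ) -> int | None:
        """Codon position registered for a fixed 12-mer pair, else None."""
        pos = self.position_by_pair.get((barcode1, barcode2))
        if pos is not None or not correct_mismatches:
            return pos
        best = None
        for (b1, b2), p in self.position_by_pair.items():
            d = sum(x != y for x, y in zip(barcode1, b1))
            d += sum(x != y for x, y in zip(barcode2, b2))
            if d <= 1:
                if best is not None:
                    return None  # ambiguous correction
                best = p
        return best

    def wt_aa(self, codon_position: int) -> str:
        return translate_codon(self.wt_codons[codon_position - self.codon_start])


def _make_call(ref: FragmentReference, position: int, codon: str) -> VariantCall:
    wt_codon = ref.wt_codons[position - ref.codon_start]
    aa = translate_codon(codon)
    is_wt = codon == wt_codon
    return VariantCall(
        fragment_index=ref.fragment_index,
        codon_position=position,
        variant_codon=codon,
        aa_state=aa,
        is_wt_sequence=is_wt,
        is_silent=(not is_wt) and aa == translate_codon(wt_codon),
    )


def parse_gibson_read(
    read: MergedRead,
    ref: FragmentReference,
    *,
    correct_mismatches: bool = False,
) -> tuple[VariantCall, str] | RejectionRecord:
    """Call the variant and barcode carried by one Gibson-stage read.

    Checks, in fixed order: exact expected length (indels shift the length);
    no ambiguous base; fixed anchor/module flank intact; at most one mutated
    codon in the fragment window; fixed barcode 12-mers registered for some
    codon position of this fragment. A read whose mutated codon position
    disagrees with its barcode's registered position is *not* rejected here;
    see :func:`cross_check_barcode_position`.
    """
    seq = read.seq.upper()
    if len(seq) != ref.expected_length:
        return RejectionRecord(read.id, "length_mismatch")
    if "N" in seq:
        return RejectionRecord(read.id, "ambiguous_base")
    if seq[ref.nt_length : ref.barcode_offset] != ref.fixed_flank:
        return RejectionRecord(read.id, "unknown_structure")
    mutated: list[tuple[int, str]] = []
    for i, wt in enumerate(ref.wt_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon != wt:
            mutated.append((ref.codon_start + i, codon))
            if len(mutated) > 1:
                return RejectionRecord(read.id, "multi_mutant")
    barcode = seq[ref.barcode_offset : ref.barcode_offset + 30]
    pair_pos = ref.lookup_pair(
        barcode[2:14], barcode[16:28], correct_mismatches=correct_mismatches
    )
    if pair_pos is None:
        return RejectionRecord(read.id, "barcode_mismatch")
    if mutated:
        position, codon = mutated[0]
    else:
        # WT-sequence read: position taken from the barcode registration
        position = pair_pos
        codon = ref.wt_codons[position - ref.codon_start]
    return _make_call(ref, position, codon), barcode


def cross_check_barcode_position(
    call: VariantCall, barcode_position: int
) -> bool:
    """True iff the observed mutated codon position agrees with the codon
    position registered for the read's barcode pair. WT-sequence reads have
    no mutated position and are exempt (always consistent)."""
    if call.is_wt_sequence:
        return True
    return call.codon_position == barcode_position


def build_association(
    accepted: Iterable[tuple[VariantCall, str]] | Counter,
    ref: FragmentReference,
    *,
    min_support: int = 2,
    aggregate_level: bool = False,
) -> pd.DataFrame:
    """Aggregate accepted (variant, barcode) observations into the
    barcode -> variant association table.

    Pairs supported by fewer than ``min_support`` reads are discarded (with
    ``aggregate_level=True`` the support threshold is instead applied to the
    mutation aggregated across barcodes). A barcode is *informative* iff it
    is associated with exactly one variant that is not the WT sequence.

    Returns a DataFrame with columns barcode, fragment_index,
    codon_position, variant_codon, aa_state, is_wt, is_silent, count,
    informative.
    """
    if isinstance(accepted, Counter):
        counts = accepted
    else:
        counts = Counter()
        for call, barcode in accepted:
            counts[(barcode, call.codon_position, call.variant_codon)] += 1

    rows = []
    for (barcode, position, codon), n in counts.items():
        rows.append((barcode, position, codon, n))
    df = pd.DataFrame(rows, columns=["barcode", "codon_position", "variant_codon", "count"])
    if df.empty:
        return pd.DataFrame(
            columns=[
                "barcode", "fragment_index", "codon_position", "variant_codon",
                "aa_state", "is_wt", "is_silent", "count", "informative",
            ]
        )
    if aggregate_level:
        support = df.groupby(["codon_position", "variant_codon"])["count"].transform("sum")
        df = df[support >= min_support]
    else:
        df = df[df["count"] >= min_support]
    df = df.copy()
    df["fragment_index"] = ref.fragment_index
    wt = {
        pos: ref.wt_codons[pos - ref.codon_start]
        for pos in ref.pair_by_position
    }
    df["is_wt"] = [
        codon == wt[pos] for pos, codon in zip(df["codon_position"], df["variant_codon"])
    ]
    df["aa_state"] = [translate_codon(c) for c in df["variant_codon"]]
    df["is_silent"] = [
        (not w) and a == translate_codon(wt[p])
        for w, a, p in zip(df["is_wt"], df["aa_state"], df["codon_position"])
    ]
    n_variants = df.groupby("barcode")["variant_codon"].transform("nunique")
    any_wt = df.groupby("barcode")["is_wt"].transform("any")
    df["informative"] = (n_variants == 1) & ~any_wt
    df = df.sort_values(["codon_position", "variant_codon", "barcode"]).reset_index(drop=True)
    return df[
        [
            "barcode", "fragment_index", "codon_position", "variant_codon",
            "aa_state", "is_wt", "is_silent", "count", "informative",
        ]
    ]


@dataclass
class GibsonResult:
    """Outcome of a Gibson-stage association run."""

    association: pd.DataFrame
    rejections: Counter  # reason -> count
    total_reads: int
    accepted_reads: int
    flagged_position_mismatch: int

    @property
    def partition_ok(self) -> bool:
        """Accepted + rejected (by reason) must account for every read."""
        return self.accepted_reads + sum(self.rejections.values()) == self.total_reads


def process_gibson_reads(
    reads: Iterable[MergedRead],
    ref: FragmentReference,
    *,
    min_support: int = 2,
    correct_mismatches: bool = False,
    cross_check: bool = True,
) -> GibsonResult:
    """Full Gibson-stage pipeline: parse, cross-check, aggregate, filter.

    Reads whose barcode-registered position disagrees with the observed
    mutation position (template switches / chimeras) are counted as accepted
    reads but flagged and excluded from the association table.
    """
    counts: Counter = Counter()
    rejections: Counter = Counter()
    total = accepted = flagged = 0
    for read in reads:
        total += 1
        out = parse_gibson_read(read, ref, correct_mismatches=correct_mismatches)
        if isinstance(out, RejectionRecord):
            rejections[out.reason] += 1
            continue
        accepted += 1
        call, barcode = out
        if cross_check:
            pair_pos = ref.lookup_pair(
                barcode[2:14], barcode[16:28], correct_mismatches=correct_mismatches
            )
            if not cross_check_barcode_position(call, pair_pos):
                flagged += 1
                continue
        counts[(barcode, call.codon_position, call.variant_codon)] += 1
    table = build_association(counts, ref, min_support=min_support)
    return GibsonResult(
        association=table,
        rejections=rejections,
        total_reads=total,
        accepted_reads=accepted,
        flagged_position_mismatch=flagged,
    )


def parse_barcode_only_read(
    read: MergedRead,
    ref: FragmentReference,
    *,
    correct_mismatches: bool = False,
) -> str | RejectionRecord:
    """Extract the 30-nt barcode realization from a barcode-only read.

    The read must be exactly the 30-nt barcode region; the two fixed
    12-mers must match a registered pair, and spacer bases must be called
    (no N). The spacers are retained: they are part of the realization.
    """
    seq = read.seq.upper()
    if len(seq) != 30:
        return RejectionRecord(read.id, "length_mismatch")
    if "N" in seq:
        return RejectionRecord(read.id, "ambiguous_base")
    pos = ref.lookup_pair(seq[2:14], seq[16:28], correct_mismatches=correct_mismatches)
    if pos is None:
        return RejectionRecord(read.id, "barcode_mismatch")
    return seq


def count_barcode_reads(
    reads: Iterable[MergedRead],
    ref: FragmentReference,
    *,
    correct_mismatches: bool = False,
) -> tuple[Counter, Counter, int]:
    """Count barcode realizations in a barcode-only read stream.

    Returns (barcode counts, rejection counts by reason, total reads).
    """
    counts: Counter = Counter()
    rejections: Counter = Counter()
    total = 0
    for read in reads:
        total += 1
        out = parse_barcode_only_read(read, ref, correct_mismatches=correct_mismatches)
        if isinstance(out, RejectionRecord):
            rejections[out.reason] += 1
        else:
            counts[out] += 1
    return counts, rejections, total


def join_to_reference(
    barcode_counts: Mapping[str, int],
    reference: pd.DataFrame,
    *,
    drop_singletons: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Annotate observed barcode counts with the reference association.

    Singleton barcodes (count 1) are removed before joining by default.
    Returns the annotated count table and the unassigned fraction (barcodes
    absent from the reference, weighted per barcode).
    """
    items = [
        (bc, n)
        for bc, n in sorted(barcode_counts.items())
        if not (drop_singletons and n <= 1)
    ]
    counts = pd.DataFrame(items, columns=["barcode", "count"])
    ref_cols = reference[
        ["barcode", "fragment_index", "codon_position", "variant_codon",
         "aa_state", "is_wt", "is_silent", "informative"]
    ].drop_duplicates("barcode")
    joined = counts.merge(ref_cols, on="barcode", how="left")
    joined["assigned"] = joined["codon_position"].notna()
    unassigned = float((~joined["assigned"]).mean()) if len(joined) else 0.0
    return joined, unassigned
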