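"""Synthetic ground-truth data for the whole pipeline.

Emulates, with known truth, every wet-lab stage the toolkit consumes:
oPool synthesis (one NNK variant per codon, multiple barcode realizations
per variant), the transformation bottleneck (multinomial sampling of
clones), the two sequencing designs (fragment+barcode after the first
cloning step; barcode-only after the second), per-base substitution and
per-read indel sequencing errors, and pooled exponential competition over g
generations with per-variant selection coefficients.

The growth model is deterministic exponential expectation with multinomial
sequencing noise: expected TP2 abundance of clone i is proportional to its
TP0 abundance times 2^(g * (1 + s_i)), with silent and WT clones at s = 0.
All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .design import (
    BarcodeCodebook,
    CodingSequence,
    OPoolDesign,
    build_full_design,
    enumerate_nnk,
    generate_codebook,
    translate_codon,
)
from .readproc import MergedRead, FragmentReference

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "random_cds",
    "random_context",
    "simulate_library",
    "simulate_reads",
    "simulate_competition",
    "simulate_dataset",
]

_BASES = "ACGT"
_SENSE_CODONS = tuple(
    c for c in (a + b + d for a in _BASES for b in _BASES for d in _BASES)
    if translate_codon(c) != "*"
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    barcodes_per_variant: an int for a fixed count, or a float for the mean
    of a Poisson truncated at >= 1 (the observed regime of >9 barcodes for
    most mutations motivates the default mean of 10).
    """

    seed: int = 0
    cds_length_codons: int = 25
    tile_codons: int = 25
    barcodes_per_variant: int | float = 10.0
    transformant_count: int = 25_000
    read_depth: int = 100_000
    substitution_rate: float = 0.0  # per base
    indel_rate: float = 0.0  # per read
    dropout_probability: float = 0.0  # per designed variant, at synthesis
    generations: float = 8.0
    s_range: tuple[float, float] = (-0.6, 0.6)
    replicates: int = 1
    competition_depth: int = 400_000  # reads per timepoint per replicate

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "dropout_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """True clone population, barcode->variant map, and fitness landscape."""

    config: SimulationConfig
    cds: CodingSequence
    design: list[OPoolDesign]
    reference: FragmentReference
    clones: pd.DataFrame  # barcode, codon_position, variant_codon, aa_state,
    #                       is_wt, is_silent, abundance, s
    true_s: pd.DataFrame  # codon_position, variant_codon, s

    @property
    def association(self) -> pd.DataFrame:
        """The true barcode -> variant map (clones surviving the bottleneck)."""
        live = self.clones[self.clones["abundance"] > 0]
        return live[
            ["barcode", "codon_position", "variant_codon", "aa_state",
             "is_wt", "is_silent"]
        ].reset_index(drop=True)


def random_cds(
    n_codons: int,
    rng: np.random.Generator,
    id: str = "synthetic_cds",
    avoid_motifs: tuple[str, ...] = ("GGTCTC", "GAGACC"),
) -> CodingSequence:
    """A random stop-free CDS of ``n_codons`` codons.

    By default the sequence is domesticated against the BsaI recognition
    site on either strand, mirroring the removal of internal BsaI sites
    from the destination construct that Golden Gate assembly requires.
    """
    codons = [
        _SENSE_CODONS[i] for i in rng.choice(len(_SENSE_CODONS), size=n_codons)
    ]
    seq = "".join(codons)
    for _ in range(10_000):
        hit = min(
            (seq.find(m) for m in avoid_motifs if m in seq), default=-1,
            key=lambda x: x if x >= 0 else len(seq),
        )
        if hit < 0 or all(m not in seq for m in avoid_motifs):
            break
        codons[hit // 3] = _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
        seq = "".join(codons)
    return CodingSequence(id=id, seq=seq)


def random_context(
    rng: np.random.Generator,
    n: int,
    avoid_motifs: tuple[str, ...] = ("GGTCTC", "GAGACC"),
) -> str:
    """Random vector/promoter context sequence, free of forbidden motifs."""
    for _ in range(10_000):
        seq = "".join(_BASES[b] for b in rng.integers(0, 4, size=n))
        if all(m not in seq for m in avoid_motifs):
            return seq
    raise RuntimeError("could not draw a motif-free context")


def _spacer(rng: np.random.Generator) -> tuple[str, str, str]:
    return tuple(
        "".join(_BASES[b] for b in rng.integers(0, 4, size=2)) for _ in range(3)
    )


def simulate_library(
    config: SimulationConfig,
    *,
    cds: CodingSequence | None = None,
    design: list[OPoolDesign] | None = None,
    codebook: BarcodeCodebook | None = None,
) -> GroundTruth:
    """Build the true barcoded clone population for one fragment library.

    For every codon position of the (single-fragment by default) design and
    every NNK codon realization — including the WT realization when the WT
    codon is itself NNK-compatible — a number of distinct barcode
    realizations is drawn, clones are optionally dropped out (synthesis
    failure), and the transformation bottleneck samples clone abundances
    multinomially down to ``transformant_count``.
    """
    rng = np.random.default_rng(config.seed)
    if cds is None:
        cds = random_cds(config.cds_length_codons, rng)
    if design is None:
        if codebook is None:
            codebook = generate_codebook(
                k=12, target_size=4 * cds.codon_count, seed=config.seed
            )
        upstream = random_context(rng, 40)
        downstream = random_context(rng, 10)
        design = build_full_design(
            cds,
            codebook,
            upstream_context=upstream,
            downstream_context=downstream,
            tile_codons=config.tile_codons,
            seed=config.seed,
        )
    ref = FragmentReference.from_design(design, design[0].fragment.fragment_index)

    nnk = enumerate_nnk()
    rows = []
    s_rows = []
    for pos in sorted(ref.pair_by_position):
        wt_codon = ref.wt_codons[pos - ref.codon_start]
        wt_aa = translate_codon(wt_codon)
        b1, b2 = ref.pair_by_position[pos]
        # spacer triples are unique within a position so that every barcode
        # realization maps to exactly one variant
        spacers_seen: set = set()
        for codon in nnk:
            aa = translate_codon(codon)
            is_wt = codon == wt_codon
            is_silent = (not is_wt) and aa == wt_aa
            if is_wt or is_silent:
                s = 0.0
            else:
                s = float(rng.uniform(*config.s_range))
            s_rows.append((pos, codon, aa, is_wt, is_silent, s))
            if config.dropout_probability and rng.random() < config.dropout_probability:
                continue
            if isinstance(config.barcodes_per_variant, int):
                n_bc = config.barcodes_per_variant
            else:
                n_bc = 0
                while n_bc < 1:
                    n_bc = int(rng.poisson(config.barcodes_per_variant))
            for _ in range(n_bc):
                for _attempt in range(1000):
                    sp = _spacer(rng)
                    if sp not in spacers_seen:
                        spacers_seen.add(sp)
                        break
                barcode = sp[0] + b1 + sp[1] + b2 + sp[2]
                rows.append((barcode, pos, codon, aa, is_wt, is_silent, s))
    clones = pd.DataFrame(
        rows,
        columns=["barcode", "codon_position", "variant_codon", "aa_state",
                 "is_wt", "is_silent", "s"],
    )
    # transformation bottleneck: multinomial over clones, uniform expectation
    p = np.full(len(clones), 1.0 / len(clones))
    clones["abundance"] = rng.multinomial(config.transformant_count, p)
    true_s = pd.DataFrame(
        s_rows,
        columns=["codon_position", "variant_codon", "aa_state", "is_wt",
                 "is_silent", "s"],
    )
    return GroundTruth(
        config=config, cds=cds, design=design, reference=ref,
        clones=clones, true_s=true_s,
    )


def _apply_errors(
    seq: str, rng: np.random.Generator, substitution_rate: float, indel_rate: float
) -> str:
    if substitution_rate > 0:
        k = rng.binomial(len(seq), substitution_rate)
        if k:
            chars = list(seq)
            for pos in rng.choice(len(seq), size=k, replace=False):
                chars[pos] = _BASES[
                    (_BASES.index(chars[pos]) + rng.integers(1, 4)) % 4
                ]
            seq = "".join(chars)
    if indel_rate > 0 and rng.random() < indel_rate:
        pos = int(rng.integers(0, len(seq)))
        if rng.random() < 0.5:
            seq = seq[:pos] + seq[pos + 1 :]  # deletion
        else:
            seq = seq[:pos] + _BASES[rng.integers(0, 4)] + seq[pos:]
    return seq


def _clone_read_sequence(truth: GroundTruth, row, stage: str) -> str:
    ref = truth.reference
    if stage == "barcode_only":
        return row.barcode
    off = 3 * (row.codon_position - ref.codon_start)
    frag = truth.design[0].fragment.fragment_seq
    mutated = frag[:off] + row.variant_codon + frag[off + 3 :]
    return mutated + ref.fixed_flank + row.barcode


def simulate_reads(
    truth: GroundTruth,
    stage: Literal["gibson", "barcode_only"],
    *,
    depth: int | None = None,
    reads_per_clone: int | None = None,
    seed: int | None = None,
) -> list[MergedRead]:
    """Draw merged reads from the clone population.

    With ``depth``, reads are sampled multinomially from clone abundances
    (so counts sum exactly to depth). With ``reads_per_clone``, every
    surviving clone is emitted exactly that many times (saturating uniform
    coverage, useful for exact-reconstruction checks). Substitution errors
    are i.i.d. per base at the configured rate; at most one indel per read
    is introduced at the configured per-read rate.
    """
    config = truth.config
    if seed is None:
        seed = config.seed + (1 if stage == "gibson" else 3)
    rng = np.random.default_rng(seed)
    live = truth.clones[truth.clones["abundance"] > 0].reset_index(drop=True)
    if reads_per_clone is not None:
        counts = np.full(len(live), reads_per_clone)
    else:
        if depth is None:
            depth = config.read_depth
        p = live["abundance"].to_numpy(dtype=float)
        counts = rng.multinomial(depth, p / p.sum())
    reads = []
    i = 0
    for row, n in zip(live.itertuples(index=False), counts):
        if n == 0:
            continue
        base_seq = _clone_read_sequence(truth, row, stage)
        for _ in range(int(n)):
            seq = _apply_errors(
                base_seq, rng, config.substitution_rate, config.indel_rate
            )
            reads.append(MergedRead(id=f"read_{i}", seq=seq))
            i += 1
    return reads


def simulate_competition(
    truth: GroundTruth,
    *,
    depth: int | None = None,
    replicates: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pooled competition over g generations, sequenced at TP0 and TP2.

    Expected TP2 abundance of clone i is TP0 abundance * 2^(g * (1 + s_i));
    observed counts at each timepoint are multinomial draws at the
    configured depth, independently per replicate. Returns a barcode-level
    count table with columns unit (= barcode), codon_position,
    variant_codon, aa_state, is_wt, is_silent, replicate, tp0, tp2.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    if depth is None:
        depth = config.competition_depth
    if replicates is None:
        replicates = config.replicates
    live = truth.clones[truth.clones["abundance"] > 0].reset_index(drop=True)
    a0 = live["abundance"].to_numpy(dtype=float)
    w2 = a0 * np.power(2.0, config.generations * (1.0 + live["s"].to_numpy()))
    frames = []
    for rep in range(1, replicates + 1):
        tp0 = rng.multinomial(depth, a0 / a0.sum())
        tp2 = rng.multinomial(depth, w2 / w2.sum())
        frame = live[
            ["barcode", "codon_position", "variant_codon", "aa_state",
             "is_wt", "is_silent"]
        ].copy()
        frame = frame.rename(columns={"barcode": "unit"})
        frame["replicate"] = rep
        frame["tp0"] = tp0
        frame["tp2"] = tp2
        frames.append(frame)
    counts = pd.concat(frames, ignore_index=True)
    # singleton removal: a sequence seen once in a sample is treated as
    # sequencing noise and dropped from that sample (count -> 0)
    counts.loc[counts["tp0"] == 1, "tp0"] = 0
    counts.loc[counts["tp2"] == 1, "tp2"] = 0
    return counts


def aggregate_counts_to_variants(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum barcode-level timepoint counts to variant (codon) level, the
    "direct sequencing" view of the same competition."""
    agg = counts.groupby(
        ["codon_position", "variant_codon", "aa_state", "is_wt", "is_silent",
         "replicate"],
        as_index=False,
    ).agg(tp0=("tp0", "sum"), tp2=("tp2", "sum"))
    agg["unit"] = agg["variant_codon"] + "@" + agg["codon_position"].astype(str)
    return agg[COUNT_ORDER]


COUNT_ORDER = [
    "unit", "codon_position", "variant_codon", "aa_state",
    "is_wt", "is_silent", "replicate", "tp0", "tp2",
]


def simulate_dataset(config: SimulationConfig) -> dict:
    """One-call end-to-end dataset: truth, reads for both sequencing
    designs, and a competition count table."""
    truth = simulate_library(config)
    return {
        "truth": truth,
        "gibson_reads": simulate_reads(truth, "gibson"),
        "barcode_reads": simulate_reads(truth, "barcode_only"),
        "competition": simulate_competition(truth),
    }
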