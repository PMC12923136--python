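"""Library quality-control metrics.

Implements the four library performance parameters — informative-barcode
fraction, mutation coverage, barcode diversity (>4 / >9 informative
barcodes per mutation) — plus two uniformity indices (Gini coefficient and
the log10 P90/P10 uniformity score), transformant subsampling curves, and
numeric heatmap-matrix export. No plotting happens here; exports are
tabular.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import enumerate_nnk, translate_codon
from .readproc import FragmentReference, build_association

__all__ = [
    "CoverageReport",
    "UniformityReport",
    "gini",
    "uniformity_score",
    "coverage_metrics",
    "mutation_universe",
    "heatmap_matrix",
    "subsampling_curves",
    "variant_read_counts",
    "uniformity_report",
]

AA_STATES = tuple("ACDEFGHIKLMNPQRSTVWY") + ("*",)  # 20 amino acids + stop


@dataclass(frozen=True)
class CoverageReport:
    fragment_index: int
    level: str  # 'aa' or 'codon'
    pct_informative: float
    mutation_coverage: float
    pct_gt4: float
    pct_gt9: float
    universe_size: int

    def __post_init__(self) -> None:
        assert self.pct_gt9 <= self.pct_gt4 + 1e-9 <= self.mutation_coverage + 2e-9


def gini(counts: Sequence[float] | np.ndarray) -> float:
    """Gini coefficient of a count distribution.

    0 means perfect uniformity, values toward 1 mean maximal bias.
    Mean-absolute-difference definition, computed in O(n log n):
    G = sum_i sum_j |x_i - x_j| / (2 n^2 mean(x)).
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("counts must be a non-empty 1-D array")
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    xs = np.sort(x)
    n = xs.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))


def uniformity_score(counts: Sequence[float] | np.ndarray) -> float:
    """log10 difference between the 90th and 10th percentiles of per-variant
    read counts (linear-interpolation percentiles); small = uniform.

    Only variants with at least one read are meaningful input (P10 = 0 is
    undefined in log space).
    """
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size < 2:
        raise ValueError("need at least 2 positive counts")
    p10, p90 = np.percentile(x, [10, 90])
    return float(np.log10(p90) - np.log10(p10))


def mutation_universe(ref: FragmentReference, level: str = "aa"
                      ) -> list[tuple[int, str]]:
    """The designed mutation universe of one fragment.

    aa level: per codon position, the 21 amino-acid states minus the WT
    amino acid (20 mutations per position). codon level: per position, the
    NNK codon set minus the WT codon (31 or 32 per position, depending on
    whether the WT codon is itself NNK-compatible).
    """
    universe = []
    nnk = enumerate_nnk()
    for pos in sorted(ref.pair_by_position):
        wt_codon = ref.wt_codons[pos - ref.codon_start]
        if level == "aa":
            wt_aa = translate_codon(wt_codon)
            universe.extend((pos, aa) for aa in AA_STATES if aa != wt_aa)
        elif level == "codon":
            universe.extend((pos, c) for c in nnk if c != wt_codon)
        else:
            raise ValueError("level must be 'aa' or 'codon'")
    return universe


def _informative_barcodes_per_mutation(
    table: pd.DataFrame, level: str
) -> Counter:
    """Number of informative barcode realizations per designed mutation."""
    inf = table[table["informative"].astype(bool)]
    key = "aa_state" if level == "aa" else "variant_codon"
    counts: Counter = Counter()
    for pos, state, bc in zip(inf["codon_position"], inf[key], inf["barcode"]):
        counts[(pos, state)] += 1
    return counts


def coverage_metrics(
    table: pd.DataFrame,
    ref: FragmentReference,
    *,
    level: str = "aa",
    diversity_thresholds: tuple[int, int] = (4, 9),
) -> CoverageReport:
    """Coverage and barcode-diversity metrics over the *designed* universe.

    mutation_coverage is the percentage of designed mutations represented
    by at least one informative barcode; pct_gt4/pct_gt9 use the
    informative-barcode diversity thresholds (>4 and >9 by default).
    pct_informative is the percentage of observed barcode realizations that
    are informative.
    """
    universe = mutation_universe(ref, level)
    per_mut = _informative_barcodes_per_mutation(table, level)
    lo, hi = diversity_thresholds
    n = len(universe)
    covered = sum(1 for m in universe if per_mut.get(m, 0) >= 1)
    gt_lo = sum(1 for m in universe if per_mut.get(m, 0) > lo)
    gt_hi = sum(1 for m in universe if per_mut.get(m, 0) > hi)
    n_barcodes = table["barcode"].nunique()
    n_informative = table.loc[table["informative"].astype(bool), "barcode"].nunique()
    return CoverageReport(
        fragment_index=ref.fragment_index,
        level=level,
        pct_informative=100.0 * n_informative / n_barcodes if n_barcodes else 0.0,
        mutation_coverage=100.0 * covered / n if n else 0.0,
        pct_gt4=100.0 * gt_lo / n if n else 0.0,
        pct_gt9=100.0 * gt_hi / n if n else 0.0,
        universe_size=n,
    )


def heatmap_matrix(
    table: pd.DataFrame,
    ref: FragmentReference,
    *,
    level: str = "aa",
    clip: int | None = None,
) -> pd.DataFrame:
    """Informative-barcode-count matrix: rows = 21 amino-acid states (or 32
    NNK codons), columns = codon positions, WT cells masked with NaN."""
    positions = sorted(ref.pair_by_position)
    states = AA_STATES if level == "aa" else enumerate_nnk()
    mat = pd.DataFrame(0.0, index=list(states), columns=positions)
    per_mut = _informative_barcodes_per_mutation(table, level)
    for (pos, state), n in per_mut.items():
        if state in mat.index and pos in mat.columns:
            mat.loc[state, pos] = n
    if clip is not None:
        mat = mat.clip(upper=clip)
    for pos in positions:
        wt_codon = ref.wt_codons[pos - ref.codon_start]
        wt_state = translate_codon(wt_codon) if level == "aa" else wt_codon
        if wt_state in mat.index:
            mat.loc[wt_state, pos] = np.nan
    return mat


@dataclass(frozen=True)
class UniformityReport:
    gini: float
    uniformity_score: float


def variant_read_counts(
    table: pd.DataFrame,
    ref: FragmentReference,
    *,
    level: str = "aa",
    include_zero: bool = True,
    informative_only: bool = True,
) -> np.ndarray:
    """Per-variant read counts over the designed universe.

    With ``include_zero`` (default), designed mutations never observed are
    included as zeros — dropouts then worsen the Gini coefficient.
    """
    sub = table[table["informative"].astype(bool)] if informative_only else table
    key = "aa_state" if level == "aa" else "variant_codon"
    observed = sub.groupby(["codon_position", key])["count"].sum()
    if include_zero:
        universe = mutation_universe(ref, level)
        return np.array([float(observed.get(m, 0.0)) for m in universe])
    return observed.to_numpy(dtype=float)


def uniformity_report(
    table: pd.DataFrame,
    ref: FragmentReference,
    *,
    level: str = "aa",
    include_zero: bool = True,
) -> UniformityReport:
    """Gini (over the designed universe by default) and uniformity score
    (over observed variants only; zeros are undefined in log space)."""
    counts = variant_read_counts(table, ref, level=level, include_zero=include_zero)
    return UniformityReport(
        gini=gini(counts),
        uniformity_score=uniformity_score(counts),
    )


_CURVE_METRICS = ("pct_informative", "mutation_coverage", "pct_gt4", "pct_gt9")


def subsampling_curves(
    batches: Sequence[Counter],
    batch_sizes: Sequence[int],
    ref: FragmentReference,
    *,
    fragment_bp: int | None = None,
    level: str = "aa",
    min_support: int = 2,
    n_draws: int = 100,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
    return_paths: bool = False,
):
    """Transformant subsampling curves for the library metrics.

    ``batches`` holds the raw accepted (barcode, position, codon) -> read
    count tallies of independent transformation reactions, and
    ``batch_sizes`` the number of transformants each contributed. For each
    of ``n_draws`` random batch orderings, metrics are recomputed on the
    cumulative union after each batch (support filtering re-applied on the
    union, so the accumulation path is monotone for coverage metrics); the
    x axis is cumulative transformants per fragment bp.

    Returns a tidy frame (metric, x, mean, ci_lo, ci_hi); with
    ``return_paths`` additionally the per-draw metric paths, an array of
    shape (n_draws, n_batches, n_metrics) ordered as pct_informative,
    mutation_coverage, pct_gt4, pct_gt9.
    """
    if len(batches) != len(batch_sizes):
        raise ValueError("batches and batch_sizes length mismatch")
    if fragment_bp is None:
        fragment_bp = ref.nt_length
    rng = np.random.default_rng(seed)
    n_batches = len(batches)
    # values[d][step][metric]
    values = np.empty((n_draws, n_batches, len(_CURVE_METRICS)))
    xs = np.empty((n_draws, n_batches))
    for d in range(n_draws):
        order = rng.permutation(n_batches)
        cumulative: Counter = Counter()
        size = 0
        for step, b in enumerate(order):
            cumulative.update(batches[b])
            size += batch_sizes[b]
            table = build_association(cumulative, ref, min_support=min_support)
            report = coverage_metrics(table, ref, level=level)
            values[d, step] = [getattr(report, m) for m in _CURVE_METRICS]
            xs[d, step] = size / fragment_bp
    # all orderings share the same cumulative sizes set only if sizes equal;
    # report against the mean x per step (identical when sizes are uniform)
    rows = []
    for step in range(n_batches):
        for mi, metric in enumerate(_CURVE_METRICS):
            v = values[:, step, mi]
            rows.append(
                {
                    "metric": metric,
                    "x": float(xs[:, step].mean()),
                    "mean": float(v.mean()),
                    "ci_lo": float(np.percentile(v, ci[0])),
                    "ci_hi": float(np.percentile(v, ci[1])),
                }
            )
    df = pd.DataFrame(rows)
    if return_paths:
        return df, values
    return df
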