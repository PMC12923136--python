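"""Selection-coefficient estimation from pooled-competition count tables.

The per-generation selection coefficient of a sequencing unit (a barcode
realization or a variant codon) is

    s = log2(f_TP2 / f_TP0) / g  -  median_s(silent variants)

where f is the unit's relative read frequency at a timepoint (with a
pseudocount added to every count), g is the number of mitotic generations
between the timepoints, and the silent-variant median anchors WT-like
fitness at s = 0 (the WT nucleotide sequence itself is excluded from the
silent set). Units with TP0 support below a confidence threshold (5 reads)
are flagged low-confidence and excluded from amino-acid aggregation.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "generations_from_od",
    "selection_coefficients",
    "combine_replicates",
    "aggregate_to_aa",
    "classify",
    "barcode_vs_direct",
    "subsample_correlation",
]

#: Minimum TP0 read count for a high-confidence unit.
TP0_CONFIDENCE_THRESHOLD = 5

COUNT_COLUMNS = [
    "unit", "codon_position", "variant_codon", "aa_state",
    "is_wt", "is_silent", "replicate", "tp0", "tp2",
]


def generations_from_od(od_start: float, od_end: float, n_cycles: int = 1) -> float:
    """Mitotic generations implied by optical-density growth over dilution
    cycles: g = n_cycles * log2(od_end / od_start)."""
    if od_start <= 0 or od_end <= 0:
        raise ValueError("optical densities must be positive")
    if od_end < od_start:
        raise ValueError("od_end must be >= od_start")
    return float(n_cycles * np.log2(od_end / od_start))


def selection_coefficients(
    counts: pd.DataFrame,
    g: float,
    *,
    pseudocount: float = 1.0,
    min_tp0: int = TP0_CONFIDENCE_THRESHOLD,
) -> pd.DataFrame:
    """Per-unit selection coefficients, one row per (unit, replicate).

    ``counts`` must carry the columns unit, codon_position, variant_codon,
    aa_state, is_wt, is_silent, replicate, tp0, tp2. Frequencies are
    computed per replicate and timepoint after adding ``pseudocount`` to
    every unit's count (keeps dropouts finite). The silent-median shift is
    applied per replicate; if a replicate has no silent variants the shift
    is skipped with a warning column left at NaN.

    Adds columns raw_log2fc, s, silent_median, high_confidence.
    """
    required = set(COUNT_COLUMNS)
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if g <= 0:
        raise ValueError("generations must be positive")
    out = []
    for rep, grp in counts.groupby("replicate", sort=True):
        grp = grp.copy()
        f0 = (grp["tp0"] + pseudocount) / (grp["tp0"] + pseudocount).sum()
        f2 = (grp["tp2"] + pseudocount) / (grp["tp2"] + pseudocount).sum()
        grp["raw_log2fc"] = np.log2(f2 / f0)
        grp["s"] = grp["raw_log2fc"] / g
        silent = grp.loc[grp["is_silent"] & ~grp["is_wt"], "s"]
        if len(silent):
            shift = float(silent.median())
        else:
            import warnings

            warnings.warn(
                f"replicate {rep}: no silent variants; "
                "silent-median normalization skipped",
                stacklevel=2,
            )
            shift = 0.0
        grp["silent_median"] = shift if len(silent) else np.nan
        grp["s"] = grp["s"] - shift
        grp["high_confidence"] = grp["tp0"] >= min_tp0
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def combine_replicates(scores: pd.DataFrame) -> pd.DataFrame:
    """Median s across replicates per unit; high_confidence requires the
    TP0 threshold in every replicate."""
    agg = scores.groupby(
        ["unit", "codon_position", "variant_codon", "aa_state", "is_wt", "is_silent"],
        as_index=False,
    ).agg(
        s=("s", "median"),
        raw_log2fc=("raw_log2fc", "median"),
        tp0=("tp0", "min"),
        n_replicates=("replicate", "nunique"),
        high_confidence=("high_confidence", "all"),
    )
    return agg


def aggregate_to_aa(
    scores: pd.DataFrame,
    *,
    min_tp0: int = TP0_CONFIDENCE_THRESHOLD,
    stat: str = "median",
    hi: float = 0.6,
    lo: float = -0.6,
) -> pd.DataFrame:
    """Aggregate unit-level scores to amino-acid mutations.

    Low-confidence units (TP0 < ``min_tp0``) and the WT sequence are
    dropped; per (codon_position, aa_state) the median (or mean) s over the
    remaining synonymous units is reported, together with a resistance
    class. Missing combinations are simply absent rows.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    if "high_confidence" in scores.columns:
        keep = scores[scores["high_confidence"] & ~scores["is_wt"]]
    else:
        keep = scores[(scores["tp0"] >= min_tp0) & ~scores["is_wt"]]
    agg = keep.groupby(["codon_position", "aa_state"], as_index=False).agg(
        s=("s", stat), n_units=("s", "size")
    )
    agg["label"] = classify(agg["s"], hi=hi, lo=lo)
    return agg


def classify(
    s: Sequence[float] | float, *, hi: float = 0.6, lo: float = -0.6
) -> np.ndarray | str:
    """Resistance classification by deviation from WT-like fitness.

    s > hi -> resistant, s < lo -> sensitive, otherwise intermediate
    (boundaries are strict inequalities; exactly +-0.6 is intermediate).
    """
    arr = np.asarray(s, dtype=float)
    labels = np.where(arr > hi, "resistant", np.where(arr < lo, "sensitive", "intermediate"))
    if np.isscalar(s) or arr.ndim == 0:
        return str(labels)
    return labels


def barcode_vs_direct(
    barcode_scores: pd.DataFrame,
    direct_scores: pd.DataFrame,
    *,
    on: Sequence[str] = ("codon_position", "aa_state"),
) -> tuple[pd.DataFrame, float]:
    """Pair barcode-inferred and direct-sequencing scores and return the
    Pearson correlation; variants missing from either side are dropped
    (their count is visible as the shrinkage of the paired table)."""
    on = list(on)
    paired = barcode_scores[on + ["s"]].merge(
        direct_scores[on + ["s"]], on=on, suffixes=("_barcode", "_direct")
    )
    if len(paired) < 3:
        raise ValueError(f"only {len(paired)} shared variants; need >= 3")
    r = float(stats.pearsonr(paired["s_barcode"], paired["s_direct"])[0])
    return paired, r


def subsample_correlation(
    barcode_unit_scores: pd.DataFrame,
    direct_scores: pd.DataFrame,
    *,
    on: Sequence[str] = ("codon_position", "aa_state"),
    n_range: Iterable[int] = range(1, 11),
    draws: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Barcode-subsampling correlation analysis.

    For each target barcode count n and each of ``draws`` draws, every
    variant's score is the mean of exactly n of its barcode-level scores —
    resampled with replacement when the variant has fewer than n barcodes,
    a random subset without replacement when it has more — and the Pearson
    correlation with the direct-sequencing scores is recorded. Variants
    with zero barcodes are excluded (reported via the ``n_variants``
    column).

    ``barcode_unit_scores`` needs the key columns plus per-barcode ``s``;
    ``direct_scores`` the key columns plus variant-level ``s``.

    Returns a tidy frame (n, draw, r, n_variants).
    """
    on = list(on)
    rng = np.random.default_rng(seed)
    direct = direct_scores[on + ["s"]].drop_duplicates(on)
    direct_by_key = {
        tuple(row[:-1]): row[-1]
        for row in direct.itertuples(index=False)
    }
    groups: list[tuple[np.ndarray, float]] = []
    for key, grp in barcode_unit_scores.groupby(on, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if key in direct_by_key and len(grp):
            groups.append((grp["s"].to_numpy(dtype=float), float(direct_by_key[key])))
    if len(groups) < 3:
        raise ValueError("fewer than 3 variants shared between score sets")
    direct_vec = np.array([d for _, d in groups])
    rows = []
    for n in n_range:
        for draw in range(draws):
            means = np.empty(len(groups))
            for i, (vals, _) in enumerate(groups):
                if len(vals) >= n:
                    idx = rng.choice(len(vals), size=n, replace=False)
                else:
                    idx = rng.choice(len(vals), size=n, replace=True)
                means[i] = vals[idx].mean()
            r = float(stats.pearsonr(means, direct_vec)[0])
            rows.append({"n": n, "draw": draw, "r": r, "n_variants": len(groups)})
    return pd.DataFrame(rows)
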