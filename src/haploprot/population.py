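"""Group-level statistics over score tables.

Supports the variant-set case study pattern: annotate haplotypes by whether
they carry any variant from a curated identifier list (e.g. trait-associated
rsIDs), compare the two groups' score distributions with a bootstrap of the
median, and summarise inter-model agreement with Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

IN_SET = "in_set"
OUT_SET = "out_set"

DEFAULT_N_REPLICATES = 100


@dataclass(frozen=True)
class GroupedScores:
    group_label: str
    values: tuple[float, ...]


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate medians of same-size resamples with replacement."""

    n_replicates: int
    statistic: str
    replicate_values: tuple[float, ...]
    seed: int


@dataclass(frozen=True)
class GroupComparison:
    a: BootstrapResult
    b: BootstrapResult
    median_of_medians_a: float
    median_of_medians_b: float
    frac_a_lt_b: float


def annotate_by_variant_set(
    haplotype_variant_ids: Mapping[str, Iterable[str]],
    id_set: set[str],
) -> dict[str, str]:
    """Label each haplotype in_set iff it carries any id from ``id_set``.

    ``haplotype_variant_ids`` maps a haplotype key to the identifiers of the
    variants it carries (empty for the wild type, which is therefore always
    out_set).
    """
    return {
        key: IN_SET if any(v in id_set for v in ids) else OUT_SET
        for key, ids in haplotype_variant_ids.items()
    }


def bootstrap_median(
    values: Sequence[float],
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
) -> BootstrapResult:
    """Medians of ``n_replicates`` same-size resamples with replacement.

    Even-length medians are the mean of the two central order statistics.
    Fully determined by ``seed``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_replicates, arr.size))
    medians = np.median(arr[idx], axis=1)
    return BootstrapResult(
        n_replicates=n_replicates,
        statistic="median",
        replicate_values=tuple(float(m) for m in medians),
        seed=seed,
    )


def compare_groups(
    a: GroupedScores,
    b: GroupedScores,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    seed_offsets: tuple[int, int] = (0, 1),
) -> GroupComparison:
    """Independent median bootstraps for two groups plus a pairing summary.

    Each group resamples with its own stream (``seed + offset``); the
    summary reports each group's median of replicate medians and the
    fraction of replicate pairs where a's median is strictly below b's.
    """
    if not a.values or not b.values:
        raise ValueError("both groups must be non-empty")
    ra = bootstrap_median(a.values, n_replicates, seed + seed_offsets[0])
    rb = bootstrap_median(b.values, n_replicates, seed + seed_offsets[1])
    va = np.asarray(ra.replicate_values)
    vb = np.asarray(rb.replicate_values)
    return GroupComparison(
        a=ra,
        b=rb,
        median_of_medians_a=float(np.median(va)),
        median_of_medians_b=float(np.median(vb)),
        frac_a_lt_b=float(np.mean(va < vb)),
    )


def score_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and two-sided p-value over paired scores.

    Pairs with a missing (NaN) member are dropped listwise; zero variance in
    either vector yields (nan, nan) as an undefined-correlation marker.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must be paired (equal length)")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return float("nan"), float("nan")
    r = stats.pearsonr(xa, ya)
    return float(r.statistic), float(r.pvalue)


def correlation_matrix(
    scores_by_model: Mapping[str, Sequence[float]],
) -> dict[str, dict[str, float]]:
    """Pairwise Pearson r over all model pairs (diagonal 1)."""
    models = sorted(scores_by_model)
    out: dict[str, dict[str, float]] = {m: {} for m in models}
    for i, m1 in enumerate(models):
        for m2 in models[i:]:
            if m1 == m2:
                r = 1.0
            else:
                r, _ = score_correlation(
                    scores_by_model[m1], scores_by_model[m2]
                )
            out[m1][m2] = r
            out[m2][m1] = r
    return out
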