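"""Diversity statistics over genotype abundances.

Shannon entropy (natural log by default), the bias-corrected Chao1 richness
estimator, and analytic rarefaction curves computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln


def _positive_counts(counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        counts = list(counts.values())
    arr = np.asarray(counts, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("abundances must be non-negative")
    return arr[arr > 0]


def shannon(counts: Sequence[float], base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i over categories with count > 0.

    Natural log unless ``base`` is given.
    """
    pos = _positive_counts(counts)
    if pos.size == 0:
        raise ValueError("shannon requires at least one positive abundance")
    p = pos / pos.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts: Sequence[int], bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton and doubleton counts.

    Bias-corrected form (default): S_obs + F1(F1-1) / (2(F2+1)).
    Classic form: S_obs + F1^2 / (2 F2), falling back to the bias-corrected
    value when F2 == 0.
    """
    pos = _positive_counts(counts)
    s_obs = pos.size
    f1 = int(np.count_nonzero(pos == 1))
    f2 = int(np.count_nonzero(pos == 2))
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1 * f1 / (2.0 * f2)


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(k + 1) - gammaln(np.asarray(n) - k + 1)


def rarefaction_point(counts: Sequence[int], n: int) -> float:
    """Expected richness E[S_n] of a size-``n`` subsample without replacement.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)], evaluated in log space.
    """
    pos = _positive_counts(counts)
    total = pos.sum()
    if not 1 <= n <= total:
        raise ValueError(f"subsample size {n} outside [1, {int(total)}]")
    rest = total - pos
    terms = np.zeros_like(pos)
    feasible = rest >= n  # category can be entirely missed
    terms[feasible] = np.exp(_log_comb(rest[feasible], n) - _log_comb(total, n))
    return float((1.0 - terms).sum())


def rarefaction_curve(
    counts: Sequence[int], grid: Sequence[int]
) -> list[tuple[int, float]]:
    return [(int(n), rarefaction_point(counts, int(n))) for n in grid]


def default_grid(total: int, points: int = 20) -> list[int]:
    """An evenly spaced subsample grid from 1 to the total count."""
    if total < 1:
        return []
    return sorted(set(np.linspace(1, total, min(points, total)).astype(int).tolist()))


@dataclass
class DiversityStats:
    sample_id: str
    s_obs: int
    f1: int
    f2: int
    chao1: float
    shannon_h: float
    rarefaction: list[tuple[int, float]] = field(default_factory=list)


def sample_stats(
    sample_id: str,
    counts_by_label: Mapping[str, int],
    grid: Sequence[int] | None = None,
) -> DiversityStats:
    """All diversity statistics for one sample's per-CT abundances."""
    pos = _positive_counts(list(counts_by_label.values()))
    if pos.size == 0:
        raise ValueError(f"{sample_id}: no positive abundances")
    if grid is None:
        grid = default_grid(int(pos.sum()))
    return DiversityStats(
        sample_id=sample_id,
        s_obs=int(pos.size),
        f1=int(np.count_nonzero(pos == 1)),
        f2=int(np.count_nonzero(pos == 2)),
        chao1=chao1(pos),
        shannon_h=shannon(pos),
        rarefaction=rarefaction_curve(pos, grid),
    )
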