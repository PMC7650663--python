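"""Rank-based statistics shared by the imaging and electrophysiology modules.

The quantification pipeline leans on Mann-Whitney U (MWU) machinery in three
places: weighted intensity vectors are jointly ranked to form the
accumulating-tracer permeability index, voxel signals are compared to control
regions through rank quantiles, and all group comparisons use two-tailed
Mann-Whitney / Wilcoxon tests.  A sham-referenced "exceedance" classifier
(shift > mean + 3 SD of the sham null) turns a continuous permeability-index
shift into a binary dysfunction call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateNullWarning, InvalidInputError, InvalidPairingError

__all__ = [
    "RankedVector",
    "ShamNull",
    "mwu_rank",
    "mean_rank_ratio",
    "two_sample_test",
    "classify_exceedance",
]


@dataclass(frozen=True)
class RankedVector:
    """A sample together with its average (midrank) ranks in a joint pool.

    Parameters
    ----------
    values : ndarray
        Original sample values (arbitrary units).
    ranks : ndarray
        1-based average ranks of ``values`` within the joint pool of the two
        samples that were ranked together.
    pool_size : int
        Size of the joint pool the ranks were assigned in.
    """

    values: np.ndarray
    ranks: np.ndarray
    pool_size: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        ranks = np.asarray(self.ranks, dtype=float)
        if values.shape != ranks.shape:
            raise InvalidInputError("values and ranks must have equal length")
        if ranks.size and (ranks.min() < 1 or ranks.max() > self.pool_size):
            raise InvalidInputError("ranks must lie in [1, pool_size]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ranks", ranks)

    @property
    def mean_rank(self) -> float:
        return float(self.ranks.mean())


@dataclass(frozen=True)
class ShamNull:
    """Reference distribution of an endpoint under sham stimulation.

    ``mean`` and ``sd`` summarize per-trial shifts (%) observed under sham;
    the dysfunction call compares a measured shift against
    ``mean + 3 * sd``.
    """

    sham_shifts: np.ndarray = field(repr=False)
    mean: float
    sd: float

    @classmethod
    def from_shifts(cls, shifts) -> "ShamNull":
        shifts = np.asarray(shifts, dtype=float)
        if shifts.size < 2:
            raise InvalidInputError("need at least two sham shifts to form a null")
        if not np.all(np.isfinite(shifts)):
            raise InvalidInputError("sham shifts must be finite")
        return cls(
            sham_shifts=shifts,
            mean=float(shifts.mean()),
            sd=float(shifts.std(ddof=1)),
        )


def _check_sample(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise InvalidInputError(f"sample {name!r} is empty")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError(f"sample {name!r} contains non-finite values")
    return x


def mwu_rank(sample_a, sample_b) -> tuple[RankedVector, RankedVector]:
    """Jointly rank two samples with average ranks for ties.

    Both samples are pooled, the pool receives 1-based midranks (tied values
    share the mean of the rank positions they occupy), and each output carries
    the ranks of its own sample within that joint pool.
    """
    a = _check_sample(sample_a, "a")
    b = _check_sample(sample_b, "b")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled, method="average")
    n = pooled.size
    return (
        RankedVector(values=a, ranks=ranks[: a.size], pool_size=n),
        RankedVector(values=b, ranks=ranks[a.size :], pool_size=n),
    )


def mean_rank_ratio(a: RankedVector, b: RankedVector) -> float:
    """Ratio of mean ranks, (mean rank of ``a``) / (mean rank of ``b``).

    Both vectors must have been ranked in the same joint pool.
    """
    if a.pool_size != b.pool_size:
        raise InvalidPairingError(
            f"rank pools differ ({a.pool_size} vs {b.pool_size}); "
            "rank both samples jointly with mwu_rank first"
        )
    return a.mean_rank / b.mean_rank


def two_sample_test(a, b, paired: bool = False) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired).

    Returns ``(statistic, p)``.  For the unpaired test the exact null
    distribution is used when the joint pool has at most 25 observations and
    no ties; otherwise the normal approximation with tie correction is used.
    Paired zero differences are dropped (Wilcoxon convention); if every
    difference is zero the test is degenerate and ``(0.0, 1.0)`` is returned.
    """
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    if paired:
        if a.size != b.size:
            raise InvalidInputError("paired test requires equal-length samples")
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0
        res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                           method="auto")
        return float(res.statistic), float(res.pvalue)
    pool = np.concatenate([a, b])
    exact = pool.size <= 25 and np.unique(pool).size == pool.size
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def classify_exceedance(shift: float, null: ShamNull, n_sd: float = 3.0) -> bool:
    """Sham-referenced dysfunction call: ``shift > null.mean + n_sd * null.sd``.

    The inequality is strict; a shift exactly at the threshold is not flagged.
    A zero-spread null triggers :class:`DegenerateNullWarning` but the strict
    comparison against the mean is still returned.
    """
    if not np.isfinite(null.sd):
        raise InvalidInputError("null sd must be finite")
    if null.sd == 0:
        warnings.warn(
            "sham null has zero standard deviation; threshold degenerates "
            "to the null mean",
            DegenerateNullWarning,
            stacklevel=2,
        )
    return bool(shift > null.mean + n_sd * null.sd)
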