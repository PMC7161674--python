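"""Sample Entropy of RR-interval series.

SampEn(m, r, N) = -ln(A / B), where B is the number of ordered template
pairs of length m (Chebyshev distance, self-matches excluded, start indices
1..N-m) within tolerance r, and A the corresponding count for length m + 1.
Low values mean a regular tachogram; white-noise-like series score high.

Conventions follow Richman & Moorman: the tolerance is ``r_frac`` times the
sample standard deviation of the segment (so the measure is scale
invariant), both template lengths draw from the same N - m start indices,
and a zero count at either length yields a distinct UNDEFINED result rather
than an infinite value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthgen import RrSeries

__all__ = ["SampEnParams", "SampEnResult", "sample_entropy", "segment_sampen", "SEGMENTS"]

SEGMENTS = ("BASELINE", "SEQ_A", "SEQ_B")


@dataclass(frozen=True)
class SampEnParams:
    m: int = 2
    r_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.r_frac <= 0:
            raise ValueError(f"r_frac must be positive, got {self.r_frac}")


@dataclass(frozen=True)
class SampEnResult:
    value: float  # nan when undefined
    m: int
    tolerance_abs: float
    n_points: int
    matches_m: int
    matches_m1: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Counts for template lengths m and m+1 over the shared N - m starts."""
    n = len(x)
    nt = n - m  # number of start indices used for BOTH lengths
    # Running Chebyshev distance over the (nt, nt) pair matrix.
    dist_m = np.zeros((nt, nt))
    for k in range(m):
        seg = x[k : k + nt]
        np.maximum(dist_m, np.abs(seg[:, None] - seg[None, :]), out=dist_m)
    within_m = dist_m <= r
    seg = x[m : m + nt]
    dist_m1 = np.maximum(dist_m, np.abs(seg[:, None] - seg[None, :]))
    within_m1 = dist_m1 <= r
    b = int(within_m.sum()) - nt  # remove self-pairs (diagonal)
    a = int(within_m1.sum()) - nt
    return b, a


def sample_entropy(series, params: SampEnParams = SampEnParams()) -> SampEnResult:
    """Sample Entropy of a finite series with SD-relative tolerance.

    A constant series has tolerance 0 but identical templates still match
    (distance 0 <= 0), so it scores exactly 0 — perfectly regular.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = len(x)
    if n < params.m + 2:
        raise ValueError(f"series too short for m={params.m}: N={n} < {params.m + 2}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    r = params.r_frac * float(np.std(x, ddof=1))
    b, a = _match_counts(x, params.m, r)
    value = -math.log(a / b) if a > 0 and b > 0 else math.nan
    return SampEnResult(
        value=value,
        m=params.m,
        tolerance_abs=r,
        n_points=n,
        matches_m=b,
        matches_m1=a,
    )


def segment_sampen(rr: RrSeries, params: SampEnParams = SampEnParams()) -> dict[str, SampEnResult]:
    """SampEn per annotated segment (BASELINE, SEQ_A, SEQ_B), each using its
    own segment SD for the tolerance."""
    out: dict[str, SampEnResult] = {}
    for name in SEGMENTS:
        if name not in rr.segments:
            raise ValueError(f"missing segment annotation: {name}")
    for name, (start, end) in rr.segments.items():
        out[name] = sample_entropy(rr.intervals[start:end], params)
    return out
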