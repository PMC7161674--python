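"""Nonparametric paired/unpaired tests with effect sizes, and the
comparison grid over wave features and Sample Entropy.

Both tests report a signed standard-normal-scale z with mid-ranked ties,
tie-corrected variance and no continuity correction, matching the style of
the statistical packages that print signed z even at small n.  For the
signed-rank test the statistic is the sum of ranks of negative differences
(d = x - y), so x systematically larger than y yields a negative z.

The effect size is Rosenthal's r = |z| / sqrt(N).  N is a convention
choice: either the number of observations entering the test (paired count
x 2, or n1 + n2) or the number of subjects; both are exposed because
published reports mix them.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Method",
    "EffectCategory",
    "TestResult",
    "EffectSize",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "effect_size_r",
    "comparison_grid",
    "ALPHA",
]

#: Fixed significance threshold used throughout (multiple-comparison guard).
ALPHA = 0.005


class Method(str, enum.Enum):
    WILCOXON_SIGNED_RANK = "WILCOXON_SIGNED_RANK"
    MANN_WHITNEY = "MANN_WHITNEY"


class EffectCategory(str, enum.Enum):
    NOT_SIGNIFICANT = "NOT_SIGNIFICANT"  # r < 0.1
    LOW = "LOW"  # 0.1 <= r < 0.3
    MEDIUM = "MEDIUM"  # 0.3 <= r < 0.5
    HIGH = "HIGH"  # r >= 0.5


@dataclass(frozen=True)
class TestResult:
    z: float
    p_two_sided: float
    n_effective: int
    method: Method
    degenerate: bool = False  # all differences zero / identical samples


@dataclass(frozen=True)
class EffectSize:
    r: float  # rounded to 2 decimals for reporting
    category: EffectCategory
    n_used: int
    r_raw: float = float("nan")


def _categorize(r: float) -> EffectCategory:
    if r < 0.1:
        return EffectCategory.NOT_SIGNIFICANT
    if r < 0.3:
        return EffectCategory.LOW
    if r < 0.5:
        return EffectCategory.MEDIUM
    return EffectCategory.HIGH


def effect_size_r(z: float, n: int) -> EffectSize:
    """Rosenthal's r = |z| / sqrt(n), categorised on the conventional
    half-open boundaries."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    raw = abs(z) / math.sqrt(n)
    r = round(raw, 2)
    return EffectSize(r=r, category=_categorize(raw), n_used=n, r_raw=raw)


def _tie_term(ranked_values: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups of the ranked values."""
    _, counts = np.unique(ranked_values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def wilcoxon_signed_rank(x, y, exact: bool | None = None) -> TestResult:
    """Paired signed-rank test, normal approximation.

    Zero differences are dropped; tied absolute differences mid-ranked;
    z = (T - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - tie_term/48) with
    T = sum of ranks of negative differences, so x > y on balance gives
    z < 0.  ``exact=True`` (or n <= 12 when ``exact`` is requested via
    None never triggers automatically) replaces the p-value by the exact
    sign-flip enumeration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples differ in length: {x.shape} vs {y.shape}")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(
            z=0.0, p_two_sided=1.0, n_effective=0,
            method=Method.WILCOXON_SIGNED_RANK, degenerate=True,
        )
    if n < 3:
        raise ValueError(f"need >= 3 nonzero differences, got {n}")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    t_neg = float(ranks[d < 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(absd) / 48.0
    z = (t_neg - mean) / math.sqrt(var) if var > 0 else 0.0
    if exact:
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20")
        # Enumerate all sign assignments of the ranked magnitudes.
        t_obs = min(t_neg, float(ranks.sum()) - t_neg)
        count = 0
        total = 2**n
        for mask in range(total):
            t_m = sum(ranks[i] for i in range(n) if mask >> i & 1)
            t_m = min(t_m, float(ranks.sum()) - t_m)
            if t_m <= t_obs + 1e-9:
                count += 1
        p = count / total
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(
        z=z, p_two_sided=min(p, 1.0), n_effective=n,
        method=Method.WILCOXON_SIGNED_RANK,
    )


def mann_whitney(a, b, exact: bool | None = None) -> TestResult:
    """Two-sample rank-sum test, normal approximation with tie correction.

    U is the U-statistic of the first sample, so a stochastically smaller
    first sample gives z < 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    n = n1 + n2
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    z = (u1 - mean) / math.sqrt(var) if var > 0 else 0.0
    if exact:
        if math.comb(n, n1) > 500_000:
            raise ValueError("exact enumeration infeasible for these sizes")
        from itertools import combinations

        u_obs = min(u1, n1 * n2 - u1)
        count = 0
        total = 0
        idx = np.arange(n)
        for comb in combinations(range(n), n1):
            r = float(ranks[list(comb)].sum())
            u = r - n1 * (n1 + 1) / 2.0
            u = min(u, n1 * n2 - u)
            total += 1
            if u <= u_obs + 1e-9:
                count += 1
        p = count / total
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(
        z=z, p_two_sided=min(p, 1.0), n_effective=n,
        method=Method.MANN_WHITNEY,
        degenerate=(var == 0),
    )


# Comparison grid ------------------------------------------------------------

_GSR_FEATURES = ("peak_magnitude_uS", "time_to_peak_s", "decay_time_s")
_PAIRED_GSR = (("MUS4", "NOC3"), ("NOC3", "NOC_STAR"), ("MUS4", "NOC_STAR"))
_PAIRED_SAMPEN = (("BASELINE", "SEQ_A"), ("SEQ_A", "SEQ_B"))
_PROBE_EVENTS = ("MUS4", "NOC3", "NOC_STAR")
_SEGMENTS = ("BASELINE", "SEQ_A", "SEQ_B")


def _grid_row(contrast, feature, scope, res: TestResult, n_for_r: int) -> dict:
    es = effect_size_r(res.z, max(n_for_r, 1))
    return {
        "contrast": contrast,
        "feature": feature,
        "group_scope": scope,
        "z": res.z,
        "p": res.p_two_sided,
        "r": es.r,
        "category": es.category.value,
        "significant_at_0p005": bool(res.p_two_sided < ALPHA),
        "n": res.n_effective,
        "method": res.method.value,
    }


def comparison_grid(
    features: pd.DataFrame,
    sampen: pd.DataFrame,
    groups: dict | pd.Series,
    n_convention: str = "observations",
) -> pd.DataFrame:
    """The full within-/between-group contrast grid.

    ``features``: long table with columns subject_id, event_label and the
    three wave features.  ``sampen``: columns subject_id, segment, sampen.
    ``groups``: subject_id -> group label.  Within each group, the probe
    trials are compared pairwise per feature (signed-rank), and adjacent
    protocol segments per SampEn; between groups, every group pair is
    compared per feature/trial and per segment (rank-sum).

    ``n_convention`` sets the N in r = |z|/sqrt(N): "observations" (2 x
    pairs, or n1 + n2) or "subjects" (pairs, or per-group subject count is
    still n1 + n2 for unpaired contrasts).
    """
    if n_convention not in ("observations", "subjects"):
        raise ValueError(f"unknown n_convention: {n_convention}")
    groups = pd.Series(groups)
    unknown = set(features["subject_id"]) - set(groups.index)
    if unknown:
        raise ValueError(f"subjects with no group label: {sorted(unknown)[:5]}")
    feat = features.copy()
    feat["group"] = feat["subject_id"].map(groups)
    se = sampen.copy()
    se["group"] = se["subject_id"].map(groups)
    group_names = sorted(groups.unique())
    rows = []

    def n_r(res: TestResult, paired: bool) -> int:
        if paired and n_convention == "observations":
            return 2 * res.n_effective
        return res.n_effective

    for g in group_names:
        fg = feat[feat["group"] == g]
        wide = fg.pivot(index="subject_id", columns="event_label")
        for (e1, e2), fcol in product(_PAIRED_GSR, _GSR_FEATURES):
            x = wide[(fcol, e1)].to_numpy()
            y = wide[(fcol, e2)].to_numpy()
            res = wilcoxon_signed_rank(x, y)
            rows.append(_grid_row(f"{e1}_vs_{e2}", fcol, g, res, n_r(res, True)))
        sg = se[se["group"] == g].pivot(index="subject_id", columns="segment")["sampen"]
        for s1, s2 in _PAIRED_SAMPEN:
            res = wilcoxon_signed_rank(sg[s1].to_numpy(), sg[s2].to_numpy())
            rows.append(_grid_row(f"{s1}_vs_{s2}", "sampen", g, res, n_r(res, True)))

    for i, g1 in enumerate(group_names):
        for g2 in group_names[i + 1 :]:
            scope = f"{g1}_vs_{g2}"
            for ev, fcol in product(_PROBE_EVENTS, _GSR_FEATURES):
                a = feat[(feat["group"] == g1) & (feat["event_label"] == ev)][fcol]
                b = feat[(feat["group"] == g2) & (feat["event_label"] == ev)][fcol]
                res = mann_whitney(a.to_numpy(), b.to_numpy())
                rows.append(
                    _grid_row(scope, f"{fcol}@{ev}", "between", res, n_r(res, False))
                )
            for seg in _SEGMENTS:
                a = se[(se["group"] == g1) & (se["segment"] == seg)]["sampen"]
                b = se[(se["group"] == g2) & (se["segment"] == seg)]["sampen"]
                res = mann_whitney(a.to_numpy(), b.to_numpy())
                rows.append(
                    _grid_row(scope, f"sampen@{seg}", "between", res, n_r(res, False))
                )
    return pd.DataFrame(rows)
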