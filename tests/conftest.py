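"""Shared fixtures and independent oracles for the test suite."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tracecond.protocol import build_protocol


@pytest.fixture(scope="session")
def timeline():
    return build_protocol()


def naive_sampen_counts(x, m, r_frac):
    """Independent O(N^2) double-loop template-match counter.

    Returns (matches_m, matches_m1) over ordered pairs with self-matches
    excluded, Chebyshev distance, tolerance r_frac * sample SD, both
    template lengths drawn from the first N - m start indices.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_frac * float(np.std(x, ddof=1))
    b = 0
    a = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if not ok:
                continue
            b += 1
            if abs(x[i + m] - x[j + m]) <= r:
                a += 1
    return b, a


def naive_sampen_value(x, m, r_frac):
    b, a = naive_sampen_counts(x, m, r_frac)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def best_threshold_rule_error(df: pd.DataFrame, class_col: str, min_bucket: int) -> int:
    """Exhaustive search over single-attribute threshold rules.

    Considers the majority (single-bin) rule and, per attribute, every
    midpoint threshold with every class assignment whose bins each hold at
    least ``min_bucket`` instances of their own class.  Returns the
    minimal training-error count.
    """
    labels = df[class_col].to_numpy()
    classes = list(pd.unique(labels))
    best = min(int((labels != c).sum()) for c in classes)
    for attr in df.columns:
        if attr == class_col or not pd.api.types.is_numeric_dtype(df[attr]):
            continue
        v = df[attr].to_numpy(dtype=float)
        order = np.argsort(v, kind="stable")
        vs, ls = v[order], labels[order]
        distinct = np.unique(vs)
        for t in (distinct[:-1] + distinct[1:]) / 2.0:
            lower = vs <= t
            for cl, cu in itertools.permutations(classes, 2):
                if (ls[lower] == cl).sum() < min_bucket:
                    continue
                if (ls[~lower] == cu).sum() < min_bucket:
                    continue
                err = int((ls[lower] != cl).sum() + (ls[~lower] != cu).sum())
                best = min(best, err)
    return best


def separable_table(rng: np.random.Generator, n_per_class: int = 20,
                    margin: float = 2.0) -> pd.DataFrame:
    """Two-class table whose first attribute separates the classes with a
    clear margin; the second attribute is noise."""
    a = np.concatenate([
        rng.uniform(0.0, 1.0, n_per_class),
        rng.uniform(1.0 + margin, 2.0 + margin, n_per_class),
    ])
    return pd.DataFrame({
        "informative": a,
        "noise": rng.normal(size=2 * n_per_class),
        "cls": ["neg"] * n_per_class + ["pos"] * n_per_class,
    })
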