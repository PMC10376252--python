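"""Mann-Whitney U against exact enumeration, summaries, manifest totals."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiomap.stats import compare_groups, manifest_totals, mann_whitney, summarize
from cardiomap.synthetic import make_manifest_fixture


def exact_mw_oracle(a, b):
    """Enumerate all C(n_a+n_b, n_a) group assignments of the pooled values
    and return (U_a, two-sided p) with p = 2*min(P(U<=u), P(U>=u)) capped at 1.

    Valid for tie-free data; independent of any library routine.
    """
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a, n = len(a), len(a) + len(b)

    def u_of(group):
        r = sum(ranks[v] for v in group)
        return r - n_a * (n_a + 1) / 2

    u_obs = u_of(a)
    us = [u_of(c) for c in itertools.combinations(pooled, n_a)]
    le = sum(u <= u_obs for u in us) / len(us)
    ge = sum(u >= u_obs for u in us) / len(us)
    return u_obs, min(1.0, 2 * min(le, ge))


def test_separated_groups_exact_p():
    cmp = mann_whitney([1, 2, 3], [4, 5, 6])
    assert cmp.U == 0
    assert cmp.p_value == pytest.approx(0.1)
    assert cmp.method == "exact"


def test_tiny_groups_exact_p():
    cmp = mann_whitney([1, 2], [3, 4])
    assert cmp.U == 0
    assert cmp.p_value == pytest.approx(1 / 3)


def test_identical_samples_not_significant():
    cmp = mann_whitney([1, 2, 3], [1, 2, 3])
    assert cmp.p_value == pytest.approx(1.0)
    assert not cmp.significant


def test_symmetry_under_group_swap():
    rng = np.random.default_rng(5)
    a, b = rng.normal(size=6).tolist(), rng.normal(1.0, size=7).tolist()
    assert mann_whitney(a, b).p_value == pytest.approx(mann_whitney(b, a).p_value)


def test_invariant_under_monotone_transform():
    rng = np.random.default_rng(9)
    a, b = rng.uniform(1, 2, 5).tolist(), rng.uniform(1.5, 3, 6).tolist()
    p_raw = mann_whitney(a, b).p_value
    p_log = mann_whitney(np.log(a), np.log(b)).p_value
    assert p_raw == pytest.approx(p_log)


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    values=st.lists(
        st.floats(-100, 100, allow_nan=False), min_size=2, max_size=10, unique=True
    ),
    split=st.integers(1, 9),
)
def test_exact_enumeration_equality_small_samples(values, split):
    """For tie-free pooled samples of at most 10, the reported two-sided p
    equals the full-enumeration null distribution exactly."""
    split = min(split, len(values) - 1)
    a, b = values[:split], values[split:]
    u_oracle, p_oracle = exact_mw_oracle(a, b)
    cmp = mann_whitney(a, b)
    assert cmp.method == "exact"
    assert cmp.U == pytest.approx(u_oracle)
    assert cmp.p_value == pytest.approx(p_oracle, abs=1e-12)


def test_summarize_examples():
    s = summarize([2, 2, 2])
    assert (s.mean, s.sd) == (2.0, 0.0)
    s = summarize([1, 3])
    assert s.mean == 2.0 and s.sd == pytest.approx(math.sqrt(2), abs=1e-3)
    s = summarize([5.0])
    assert s.mean == 5.0 and s.sd is None
    with pytest.raises(ValueError):
        summarize([])


def test_manifest_totals_published_values():
    totals = manifest_totals(make_manifest_fixture())
    assert totals["total_videos"] == 78
    assert totals["videos_no_dox"] == 42
    assert totals["videos_dox"] == 36
    assert totals["total_batches"] == 30
    assert totals["mean_videos_per_batch"] == pytest.approx(2.6)


def test_manifest_totals_empty():
    empty = pd.DataFrame(columns=["line", "condition", "n_videos", "n_batches"])
    totals = manifest_totals(empty)
    assert totals["total_videos"] == 0
    assert math.isnan(totals["mean_videos_per_batch"])


def test_compare_groups_structure():
    rng = np.random.default_rng(3)
    rows = []
    for line in ("CTRL1", "CTX1"):
        for cond, shift in (("No DOX", 0.0), ("DOX", 5.0 if line == "CTX1" else 0.0)):
            for i in range(6):
                rows.append({
                    "line": line, "condition": cond,
                    "ps_density": rng.normal(1.0 + shift, 0.2),
                })
    out = compare_groups(pd.DataFrame(rows), "ps_density")
    assert set(out["line"]) == {"CTRL1", "CTX1"}
    assert (out["group_a"] == "No DOX").all()
    ctx = out.set_index("line").loc["CTX1"]
    ctrl = out.set_index("line").loc["CTRL1"]
    assert ctx["p_value"] < 0.05 < ctrl["p_value"]
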