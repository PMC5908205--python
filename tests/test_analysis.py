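import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gatenav.arena import Region, PlatformSpec
from gatenav.experiments import TrialRecord, ExperimentResult
from gatenav.analysis import (escape_latencies, occupancy_rate, occupancy_table,
                              selection_rates, kind_rate, classify_responders,
                              mann_whitney_u, wilcoxon_signed_rank, stars)


def record(xy, selected=None, tag="escape", latency=None, session=1, trial=1,
           index=0, rewarded=True):
    xy = np.asarray(xy, dtype=np.float32).reshape(-1, 2)
    sel = (np.zeros(len(xy), dtype=np.int16) if selected is None
           else np.asarray(selected, dtype=np.int16))
    return TrialRecord(session=session, trial=trial, index=index, tag=tag,
                       start=(0.0, 0.0), xy=xy, selected=sel,
                       latency=len(xy) if latency is None else latency,
                       rewarded=rewarded, guided=False)


def result(records_per_repeat, names=("D", "P", "E"),
           kinds=("direction", "planning", "exploration")):
    return ExperimentResult(experiment="I", condition="", group="DP",
                            master_seed=0, module_names=list(names),
                            module_kinds=list(kinds),
                            records=records_per_repeat)


class TestEscapeLatencies:
    def test_single_trial_value(self):
        res = result([[record([(1, 1)], latency=42)]])
        df = escape_latencies(res)
        assert df.loc[0, "latency"] == 42

    def test_capped_trial_reports_cap(self):
        res = result([[record(np.zeros((350, 2)), latency=350,
                              rewarded=False)]])
        assert escape_latencies(res).loc[0, "latency"] == 350

    def test_mean_over_repeats(self):
        res = result([[record([(0, 0)], latency=10)],
                      [record([(0, 0)], latency=20)]])
        df = escape_latencies(res, grouping="session")
        assert df["latency"].mean() == pytest.approx(15.0)

    def test_first_fourth_pivot(self):
        recs = [record([(0, 0)], latency=l, trial=t, index=t - 1)
                for t, l in zip((1, 2, 3, 4), (40, 30, 20, 10))]
        df = escape_latencies(result([recs]), grouping="first_fourth")
        assert df.loc[0, "first"] == 40 and df.loc[0, "fourth"] == 10


class TestOccupancy:
    def test_never_in_region_zero(self):
        reg = Region.disk((50.0, 50.0), 5.0)
        st = occupancy_rate(record(np.zeros((20, 2))), reg)
        assert st.fraction == 0.0

    def test_counting(self):
        reg = Region.disk((0.0, 0.0), 1.0)
        xy = np.array([(0.0, 0.0)] * 175 + [(50.0, 50.0)] * 175)
        assert occupancy_rate(record(xy), reg).fraction == pytest.approx(0.5)

    def test_whole_trial_inside(self):
        reg = Region.disk((0.0, 0.0), 10.0)
        assert occupancy_rate(record(np.zeros((30, 2))), reg).fraction == 1.0

    def test_before_after_partition(self):
        reg = Region.disk((10.0, 0.0), 1.0)
        xy = [(0, 0)] * 7 + [(10, 0)] * 3
        before = occupancy_rate(record(xy), reg, phase="before")
        after = occupancy_rate(record(xy), reg, phase="after")
        assert before.n_steps + after.n_steps == 10
        assert before.fraction == 0.0
        assert after.fraction == 1.0

    def test_unentered_reference_flags_empty_after(self):
        reg = Region.disk((99.0, 0.0), 1.0)
        st = occupancy_rate(record(np.zeros((5, 2))), reg, phase="after")
        assert st.empty and st.fraction == 0.0
        st = occupancy_rate(record(np.zeros((5, 2))), reg, phase="before")
        assert st.n_steps == 5


class TestSelectionRates:
    def test_single_module_rate_one(self):
        res = result([[record(np.zeros((10, 2)), selected=np.zeros(10))]],
                     names=("E",), kinds=("exploration",))
        df = selection_rates(res, grouping="total")
        assert df["rate"].tolist() == [1.0]

    def test_counting_and_normalization(self):
        sel = [0, 0, 1, 2]
        res = result([[record(np.zeros((4, 2)), selected=sel)]])
        df = selection_rates(res, grouping="total")
        rates = df.set_index("module")["rate"]
        assert rates["D"] == pytest.approx(0.5)
        assert rates["P"] == pytest.approx(0.25)
        assert rates["E"] == pytest.approx(0.25)
        assert df.groupby("cell")["rate"].sum().iloc[0] == pytest.approx(1.0)

    def test_kind_rate_sums_modules_of_kind(self):
        res = result([[record(np.zeros((4, 2)), selected=[0, 1, 1, 2])]],
                     names=("D1", "D2", "E"),
                     kinds=("direction", "direction", "exploration"))
        assert kind_rate(selection_rates(res, "total"),
                         "direction").iloc[0] == pytest.approx(0.75)


class TestClassifyResponders:
    def test_direct_path_is_cue_responder(self):
        old_zone = Region.disk((50.0, 50.0), 10.0)
        path = [(x, -x) for x in range(0, 60, 6)]
        res = result([[record(path, tag="competition")]])
        assert classify_responders(res, old_zone, None) == ["cue"]

    def test_old_zone_first_is_place_responder(self):
        old_zone = Region.disk((30.0, 0.0), 10.0)
        path = [(0, 0), (15, 0), (30, 0), (0, -40)]
        res = result([[record(path, tag="competition")]])
        assert classify_responders(res, old_zone, None) == ["place"]

    def test_missing_competition_trial_rejected(self):
        res = result([[record([(0, 0)], tag="escape")]])
        with pytest.raises(ValueError):
            classify_responders(res, Region.disk((0, 0), 1.0), None)


def mann_whitney_enumeration(a, b):
    """Exact two-sided p by full enumeration of group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)

    def u_stat(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    observed = u_stat(a, b)
    n_extreme = total = 0
    mid = len(a) * len(b) / 2
    for comb in itertools.combinations(range(len(pooled)), na):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mid) >= abs(observed - mid) - 1e-12:
            n_extreme += 1
    return n_extreme / total


def wilcoxon_enumeration(diffs):
    """Exact two-sided p by enumerating all sign assignments."""
    d = [x for x in diffs if x != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_plus = sum(r for r, x in zip(ranks, d) if x > 0)
    mid = ranks.sum() / 2
    n_extreme = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mid) >= abs(w_plus - mid) - 1e-12:
            n_extreme += 1
    return n_extreme / total


class TestNonparametricTests:
    def test_mann_whitney_textbook_case(self):
        U, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)

    def test_mann_whitney_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=6)
        assert mann_whitney_u(a, b)[1] == pytest.approx(
            mann_whitney_u(b, a)[1])

    def test_mann_whitney_identical_samples(self):
        _, p = mann_whitney_u([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_wilcoxon_all_positive_differences(self):
        a = [2.0, 3.0, 4.0, 5.0, 6.0]
        b = [1.0, 1.5, 2.0, 2.5, 3.0]
        W, p = wilcoxon_signed_rank(a, b)
        assert W == 0.0
        assert p == pytest.approx(2 / 2 ** 5)

    def test_wilcoxon_identical_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_wilcoxon_sign_flip_invariance(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        assert wilcoxon_signed_rank(a, b)[1] == pytest.approx(
            wilcoxon_signed_rank(b, a)[1])

    @pytest.mark.parametrize("seed", range(12))
    def test_mann_whitney_matches_enumeration_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        a = rng.normal(size=na)
        b = rng.normal(size=nb)
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(mann_whitney_enumeration(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_wilcoxon_matches_enumeration_small_samples(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(3, 6))
        a = rng.normal(size=n)
        b = a + rng.normal(size=n)
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(wilcoxon_enumeration(a - b), abs=1e-12)


class TestStars:
    def test_thresholds(self):
        assert stars(0.0005) == "***"
        assert stars(0.005) == "**"
        assert stars(0.03) == "*"
        assert stars(0.2) == ""
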