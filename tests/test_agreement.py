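import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiroref import (
    GoldStage,
    StageCrossTab,
    cohen_kappa,
    cross_tabulate,
    gold_stage,
    lins_ccc,
    load_stage_crosstab,
    percent_agreement,
)
from spiroref.errors import UndefinedStatisticWarning


# ---------------------------------------------------------------- oracles
def kappa_oracle(counts, weighting):
    """Brute-force weighted kappa straight from the definition, pure python."""
    k = len(counts)
    n = sum(sum(row) for row in counts)
    if weighting == "none":
        w = [[1.0 if i == j else 0.0 for j in range(k)] for i in range(k)]
    elif weighting == "linear":
        w = [[1.0 - abs(i - j) / (k - 1) for j in range(k)] for i in range(k)]
    else:
        w = [[1.0 - (i - j) ** 2 / (k - 1) ** 2 for j in range(k)] for i in range(k)]
    row_m = [sum(counts[i][j] for j in range(k)) for i in range(k)]
    col_m = [sum(counts[i][j] for i in range(k)) for j in range(k)]
    p_obs = sum(w[i][j] * counts[i][j] / n for i in range(k) for j in range(k))
    p_exp = sum(w[i][j] * row_m[i] * col_m[j] / n**2 for i in range(k) for j in range(k))
    if abs(1 - p_exp) < 1e-12:
        return float("nan")
    return (p_obs - p_exp) / (1 - p_exp)


def ccc_oracle(x, y):
    """Lin's concordance from first principles with explicit python loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((xi - mx) ** 2 for xi in x) / n
    vy = sum((yi - my) ** 2 for yi in y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return 2 * cov / (vx + vy + (mx - my) ** 2)


# ---------------------------------------------------------------- staging
class TestGoldStage:
    @pytest.mark.parametrize(
        "pct, stage",
        [
            (95.0, 1),
            (80.0, 1),  # closed lower bound of the mild band
            (79.999, 2),
            (50.0, 2),
            (49.999, 3),
            (30.0, 3),
            (29.999, 4),
            (5.0, 4),
        ],
    )
    def test_band_boundaries(self, pct, stage):
        assert gold_stage(pct, 100.0) == GoldStage(stage)

    def test_obstruction_gate(self):
        # ratio at/above 70% → no airflow limitation regardless of the pct
        assert (
            gold_stage(40.0, 100.0, measured_ratio=72.0, require_obstruction=True)
            is None
        )
        assert gold_stage(
            40.0, 100.0, measured_ratio=65.0, require_obstruction=True
        ) == GoldStage.SEVERE
        # gate off: ratio ignored
        assert gold_stage(40.0, 100.0, measured_ratio=72.0) == GoldStage.SEVERE

    def test_nonpositive_predicted(self):
        with pytest.raises(ValueError):
            gold_stage(2.0, 0.0)


class TestCrossTab:
    def test_identical_vectors_diagonal(self):
        stages = [GoldStage(s) for s in (1, 2, 2, 3, 4)]
        tab = cross_tabulate(stages, stages)
        assert tab.diagonal == tab.n == 5
        assert (tab.counts == np.diag([1, 2, 1, 1])).all()

    def test_swap_transposes(self):
        a = [GoldStage(s) for s in (1, 2, 3, 4, 2)]
        b = [GoldStage(s) for s in (2, 2, 3, 3, 1)]
        assert (cross_tabulate(a, b).counts == cross_tabulate(b, a).counts.T).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            cross_tabulate([GoldStage.MILD], [])

    def test_vectors_realizing_published_table(self):
        # expand the published local-vs-ECSC counts into aligned stage vectors
        ref = load_stage_crosstab("local_vs_ecsc")
        a, b = [], []
        for i in range(4):
            for j in range(4):
                a += [GoldStage(i + 1)] * ref.counts[i, j]
                b += [GoldStage(j + 1)] * ref.counts[i, j]
        assert (cross_tabulate(a, b).counts == ref.counts).all()


class TestAgreementStats:
    def test_published_percent_agreement(self):
        pct, diag = percent_agreement(load_stage_crosstab("local_vs_ecsc"))
        assert diag == 116
        assert pct == pytest.approx(100 * 116 / 124)
        pct_c, diag_c = percent_agreement(load_stage_crosstab("ecsc_vs_gli"))
        assert diag_c == 107
        assert round(pct_c, 1) == 86.3

    def test_all_diagonal_table(self):
        tab = StageCrossTab(np.diag([3, 4, 5, 6]))
        assert percent_agreement(tab)[0] == 100.0
        for w in ("none", "linear", "quadratic"):
            assert cohen_kappa(tab, w) == pytest.approx(1.0)

    def test_published_linear_weighted_kappas(self):
        expected = {"local_vs_ecsc": 0.936, "local_vs_gli": 0.895, "ecsc_vs_gli": 0.862}
        for name, value in expected.items():
            tab = load_stage_crosstab(name)
            assert round(cohen_kappa(tab, "linear"), 3) == value
            # unweighted does NOT reproduce the published coefficients,
            # which is what pins the linear-weights default
            assert round(cohen_kappa(tab, "none"), 3) != value

    def test_two_by_two_hand_example(self):
        # [[2,1],[1,2]]: p_obs=2/3, p_exp=1/2 → kappa = 1/3 (weights are the
        # identity at k=2)
        counts = [[2, 1], [1, 2]]
        assert kappa_oracle(counts, "linear") == pytest.approx(1 / 3)
        padded = np.zeros((4, 4), int)
        padded[:2, :2] = counts
        # embedding in 4 ordinal categories changes the weighting support, so
        # check the unweighted statistic which is embedding-invariant
        assert cohen_kappa(StageCrossTab(padded), "none") == pytest.approx(1 / 3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 50), min_size=16, max_size=16),
        st.sampled_from(["none", "linear", "quadratic"]),
    )
    def test_kappa_matches_bruteforce_oracle(self, flat, weighting):
        counts = np.array(flat).reshape(4, 4)
        if counts.sum() == 0:
            counts[0, 1] = 1
        tab = StageCrossTab(counts)
        ours = cohen_kappa(tab, weighting)
        oracle = kappa_oracle(counts.tolist(), weighting)
        if np.isnan(oracle) or abs(1 - oracle) < 1e-9:
            return
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_degenerate_marginals_signal(self):
        tab = StageCrossTab(np.diag([7, 0, 0, 0]))
        with pytest.warns(UndefinedStatisticWarning):
            assert np.isnan(cohen_kappa(tab, "linear"))

    def test_permutation_invariance_only_for_unweighted(self, rng):
        counts = rng.integers(0, 20, (4, 4))
        counts[0, 0] += 1
        perm = [2, 0, 3, 1]
        permuted = counts[np.ix_(perm, perm)]
        t1, t2 = StageCrossTab(counts), StageCrossTab(permuted)
        assert cohen_kappa(t1, "none") == pytest.approx(cohen_kappa(t2, "none"))
        # ordinal weights are order-sensitive: linear kappa changes
        assert cohen_kappa(t1, "linear") != pytest.approx(
            cohen_kappa(t2, "linear"), abs=1e-6
        )


class TestLinsCcc:
    def test_perfect_agreement(self, rng):
        x = rng.normal(size=50)
        rep = lins_ccc(x, x)
        assert rep.lins_ccc == pytest.approx(1.0)
        assert rep.average_difference == pytest.approx(0.0)

    def test_location_shift_penalised(self, rng):
        x = rng.normal(size=50)
        rep = lins_ccc(x, x + 2.0)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.lins_ccc < 1.0

    def test_hand_arithmetic_example(self):
        x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
        rep = lins_ccc(x, y)
        assert rep.lins_ccc == pytest.approx(ccc_oracle(x, y), abs=1e-12)
        # fully explicit: cov=1, var_x=2/3, var_y=14/9, dmean=-1/3 → 6/7
        assert rep.lins_ccc == pytest.approx(
            2 * 1 / (2 / 3 + 14 / 9 + 1 / 9), abs=1e-12
        )
        assert rep.lins_ccc == pytest.approx(6 / 7, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=3, max_size=40
        ),
        st.integers(0, 10_000),
    )
    def test_matches_oracle_and_bounded_by_pearson(self, x, seed):
        rng = np.random.default_rng(seed)
        x = np.asarray(x)
        y = x * rng.uniform(0.5, 2) + rng.normal(0, 1 + x.std(), x.size)
        if x.std() == 0 or y.std() == 0:
            return
        rep = lins_ccc(x, y)
        assert rep.lins_ccc == pytest.approx(ccc_oracle(list(x), list(y)), abs=1e-8)
        assert abs(rep.lins_ccc) <= abs(rep.pearson_r) + 1e-12

    def test_zero_variance_signal(self):
        with pytest.warns(UndefinedStatisticWarning):
            rep = lins_ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rep.lins_ccc)

    def test_sample_estimator_variant(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        pop = lins_ccc(x, y, estimator="population")
        samp = lins_ccc(x, y, estimator="sample")
        assert pop.lins_ccc != pytest.approx(samp.lins_ccc, abs=1e-12)
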