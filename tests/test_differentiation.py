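import numpy as np
import pytest

from haplopop import (AlleleMatrix, StrataMap, differentiation_report,
                      gst_and_nm, harmonic_mean_n, jost_d_haploid,
                      nei_chesser_haploid, theta_Qq)
from conftest import random_matrix
from oracles import brute_theta, direct_nei_chesser


def _with_pops(calls, labels):
    calls = np.asarray(calls)
    ids = [f"i{k}" for k in range(calls.shape[0])]
    m = AlleleMatrix(tuple(ids), tuple(f"L{j}" for j in range(calls.shape[1])),
                     calls)
    s = StrataMap.from_labels(ids, pop=[str(l) for l in labels])
    return m, s


def test_harmonic_mean():
    assert harmonic_mean_n([4, 4, 4]) == 4.0
    assert harmonic_mean_n([2, 6]) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        harmonic_mean_n([2, 0])


def test_nei_chesser_matches_direct_formula_evaluation():
    # two subpops of 4, frequencies {A:.75, B:.25} and {A:.25, B:.75}
    calls = np.array([[1], [1], [1], [2], [2], [2], [2], [1]])
    m, s = _with_pops(calls, [1, 1, 1, 1, 2, 2, 2, 2])
    got = nei_chesser_haploid(m, s, "pop").iloc[0]
    HS, HT = direct_nei_chesser(
        [{1: 0.75, 2: 0.25}, {1: 0.25, 2: 0.75}], [4, 4])
    assert got["H_S_est"] == pytest.approx(HS)
    assert got["H_T_est"] == pytest.approx(HT)
    assert got["n_tilde"] == 4.0 and got["s"] == 2


def test_nei_chesser_no_differentiation_limit():
    # identical frequencies in both subpops, large n: H_T ~ H_S
    rng = np.random.default_rng(0)
    block = rng.integers(1, 4, size=(300, 1))
    calls = np.vstack([block, block])
    m, s = _with_pops(calls, [1] * 300 + [2] * 300)
    row = nei_chesser_haploid(m, s, "pop").iloc[0]
    assert row["H_T_est"] == pytest.approx(row["H_S_est"], abs=5e-3)


def test_fixation_limit():
    n = 200
    calls = np.array([[1]] * n + [[2]] * n)
    m, s = _with_pops(calls, [1] * n + [2] * n)
    row = nei_chesser_haploid(m, s, "pop").iloc[0]
    assert row["H_S_est"] == pytest.approx(0.0)
    assert row["H_T_est"] == pytest.approx(0.5, abs=2e-3)
    gst, nm = gst_and_nm(row["H_S_est"], row["H_T_est"])
    assert gst == pytest.approx(1.0)
    assert nm == 0.0
    d = jost_d_haploid(row["H_S_est"], row["H_T_est"], 2)
    assert d["D"] == pytest.approx(1.0, abs=4e-3)


def test_gst_nm_formula_points():
    gst, nm = gst_and_nm(0.25, 0.5)
    assert gst == 0.5 and nm == 0.5
    gst, nm = gst_and_nm(0.5 * (1 - 0.01), 0.5 * (1 - 0.01) / 0.99)
    gst2, nm2 = gst_and_nm(0.99, 1.0)
    assert nm2 == pytest.approx(0.5 * 0.99 / 0.01)
    # no differentiation: infinite gene flow, flagged not crashed
    _, nm3 = gst_and_nm(0.5, 0.5)
    assert np.isinf(nm3)


def test_jost_d_values():
    d = jost_d_haploid(0.74, 0.745, 2)
    assert d["D"] == pytest.approx((0.005 / 0.26) * 2)
    assert d["Delta_ST"] == pytest.approx((1 / 0.255) / (1 / 0.26))
    assert d["Delta_S_over_T"] == pytest.approx(0.255 / 0.26)
    same = jost_d_haploid(0.6, 0.6, 5)
    assert same["D"] == 0.0 and same["Delta_ST"] == pytest.approx(1.0)


def test_theta_limits_and_oracle():
    # no structure: Q -> q and theta -> 0 as subpopulation size grows
    calls = np.array([[1]] * 50 + [[2]] * 50 + [[1]] * 50 + [[2]] * 50)
    m, s = _with_pops(calls, [1] * 100 + [2] * 100)
    theta, Q, q = theta_Qq(m, s, "pop")
    assert Q == pytest.approx(q, abs=0.01) and theta == pytest.approx(0.0, abs=0.02)
    # internally monomorphic, mutually distinct: theta = 1
    calls = np.array([[1], [1], [2], [2]])
    m, s = _with_pops(calls, [1, 1, 2, 2])
    theta, Q, q = theta_Qq(m, s, "pop")
    assert Q == 1.0 and theta == 1.0
    # toy 2 subpops x 3 haploids x 2 loci against pair enumeration
    rng = np.random.default_rng(7)
    for _ in range(10):
        calls = rng.integers(1, 4, size=(6, 2))
        labels = [1, 1, 1, 2, 2, 2]
        m, s = _with_pops(calls, labels)
        theta, _, q = theta_Qq(m, s, "pop")
        if q < 1:
            assert theta == pytest.approx(brute_theta(calls, labels))


def test_statistics_invariant_under_relabeling_and_merging(survey):
    matrix, strata = survey
    rep = differentiation_report(matrix, strata, "age_class")
    relabeled = AlleleMatrix(matrix.individuals, matrix.loci,
                             matrix.calls * 3 + 11)
    rep2 = differentiation_report(relabeled, strata, "age_class")
    for k in ("G_ST", "D", "D_est_hap", "theta"):
        assert rep2.summary[k] == pytest.approx(rep.summary[k])


def test_duplicating_the_subpopulation_panel_keeps_gst_and_d():
    # under the unweighted-mean convention, repeating every subpopulation as
    # an identical copy leaves the uncorrected diversities (hence G_ST and D
    # from them) exactly unchanged
    rng = np.random.default_rng(2)
    a = rng.integers(1, 5, size=(30, 3))
    b = rng.integers(1, 6, size=(30, 3))
    calls2 = np.vstack([a, b])
    calls4 = np.vstack([a, a, b, b])
    m2, s2 = _with_pops(calls2, [1] * 30 + [2] * 30)
    m4, s4 = _with_pops(calls4, [1] * 30 + [2] * 30 + [3] * 30 + [4] * 30)
    nc2 = nei_chesser_haploid(m2, s2, "pop")
    nc4 = nei_chesser_haploid(m4, s4, "pop")
    np.testing.assert_allclose(nc4["h_S"], nc2["h_S"], atol=1e-9)
    np.testing.assert_allclose(nc4["h_T"], nc2["h_T"], atol=1e-9)
    gst2 = (nc2["h_T"].mean() - nc2["h_S"].mean()) / nc2["h_T"].mean()
    gst4 = (nc4["h_T"].mean() - nc4["h_S"].mean()) / nc4["h_T"].mean()
    assert gst4 == pytest.approx(gst2, abs=1e-9)


def test_report_floors_negative_d_est_in_table_only(survey):
    matrix, strata = survey
    rep = differentiation_report(matrix, strata, "age_class")
    rendered = rep.table(floor_D_est=True)
    assert rendered["D_est_hap"] >= 0
    assert "D_est_hap_raw" in rep.summary.index
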