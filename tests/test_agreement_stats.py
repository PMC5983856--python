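"""Agreement battery: ANOVA variance components, ICC with F-based CI, Dice,
Fleiss kappa and Kruskal-Wallis, each checked against independent oracles
(hand arithmetic, closed forms, pingouin/statsmodels/scipy cross-checks)."""

import numpy as np
import pandas as pd
import pytest

from nodulesig import (VoxelMask, dsc, fleiss_kappa, icc, icc_panel,
                       kruskal_wallis, simulate_icc_table,
                       variance_components)
from nodulesig.agreement_stats import (OBSERVER_TABLE_COLUMNS, _viro_rows,
                                       signatures_to_observer_table)
from nodulesig.errors import (AlignmentError, BalanceError,
                              DegenerateDataError, UndefinedStatisticError)


def long_table(Y, voxel_class="X"):
    n, k = Y.shape
    return pd.DataFrame(
        [{"nodule": i, "observer": j, "voxel_class": voxel_class,
          "fraction_pct": Y[i, j]} for i in range(n) for j in range(k)],
        columns=list(OBSERVER_TABLE_COLUMNS))


# --- variance components ----------------------------------------------------

def hand_anova(Y):
    """Independent mean-squares oracle via explicit sums of squares."""
    n, k = Y.shape
    g = Y.mean()
    ss_nod = k * ((Y.mean(axis=1) - g) ** 2).sum()
    ss_obs = n * ((Y.mean(axis=0) - g) ** 2).sum()
    ss_tot = ((Y - g) ** 2).sum()
    ss_err = ss_tot - ss_nod - ss_obs
    return (ss_nod / (n - 1), ss_obs / (k - 1), ss_err / ((n - 1) * (k - 1)))


def test_components_match_hand_anova_on_small_table():
    Y = np.array([[10.0, 12.0, 11.0],
                  [20.0, 23.0, 22.0],
                  [5.0, 7.0, 9.0],
                  [14.0, 15.0, 16.0]])
    ms_nod, ms_obs, mse = hand_anova(Y)
    comp = variance_components(long_table(Y), "X")
    assert comp.sigma2_residual == pytest.approx(mse)
    assert comp.sigma2_observer == pytest.approx(max((ms_obs - mse) / 4, 0))
    assert comp.sigma2_nodule == pytest.approx(max((ms_nod - mse) / 3, 0))


def test_perfect_agreement_has_zero_observer_and_residual_variance():
    Y = np.tile(np.array([[10.0], [30.0], [50.0]]), (1, 3))
    comp = variance_components(long_table(Y), "X")
    assert comp.sigma2_observer == 0.0
    assert comp.sigma2_residual == 0.0
    assert comp.sigma2_nodule > 0


def test_constant_observer_shift_raises_only_observer_variance():
    rng = np.random.default_rng(0)
    Y = np.tile(rng.uniform(0, 100, (20, 1)), (1, 3))
    base = variance_components(long_table(Y), "X")
    Y2 = Y.copy()
    Y2[:, 2] += 5.0
    shifted = variance_components(long_table(Y2), "X")
    assert shifted.sigma2_observer > base.sigma2_observer
    assert shifted.sigma2_nodule == pytest.approx(base.sigma2_nodule)
    assert shifted.sigma2_residual == pytest.approx(base.sigma2_residual, abs=1e-9)


def test_incomplete_crossing_rejected():
    Y = np.arange(12, dtype=float).reshape(4, 3)
    t = long_table(Y).drop(index=5)
    with pytest.raises(BalanceError):
        variance_components(t, "X")
    with pytest.raises(BalanceError):
        variance_components(long_table(Y[:1]), "X")  # single nodule


# --- ICC --------------------------------------------------------------------

def test_icc_one_when_only_nodule_variance():
    Y = np.tile(np.array([[10.0], [30.0], [50.0], [70.0]]), (1, 3))
    r = icc(long_table(Y), "X")
    assert r.icc == 1.0
    assert (r.ci_low, r.ci_high) == (1.0, 1.0)


def test_icc_undefined_on_zero_total_variance():
    Y = np.full((4, 3), 25.0)
    with pytest.raises(UndefinedStatisticError):
        icc(long_table(Y), "X")


def test_icc_matches_pingouin_icc2():
    pg = pytest.importorskip("pingouin")
    t = simulate_icc_table(30, 3, 5.0, 1.0, 2.0, seed=3)
    mine = icc(t, "X")
    res = pg.intraclass_corr(
        data=t.rename(columns={"nodule": "targets", "observer": "raters",
                               "fraction_pct": "ratings"}),
        targets="targets", raters="raters", ratings="ratings")
    row = res[res["Type"] == "ICC(A,1)"] if (res["Type"] == "ICC(A,1)").any() \
        else res[res["Type"] == "ICC2"]
    assert mine.icc == pytest.approx(float(row["ICC"].iloc[0]), abs=1e-9)
    lo, hi = row["CI95"].iloc[0] if "CI95" in res.columns else row["CI95%"].iloc[0]
    assert mine.ci_low == pytest.approx(lo, abs=5e-3)
    assert mine.ci_high == pytest.approx(hi, abs=5e-3)


def test_icc_recovery_at_high_reliability():
    # true components (9, 0.5, 0.5): seed-averaged estimate within 0.03 of 0.9
    ests = [icc(simulate_icc_table(200, 3, 9.0, 0.5, 0.5, seed=s), "X").icc
            for s in range(10)]
    assert abs(np.mean(ests) - 0.9) <= 0.03


def test_icc_near_zero_under_null():
    # no nodule variance: ICC should sit near 0 with CI covering 0
    covered = 0
    ests = []
    for s in range(10):
        r = icc(simulate_icc_table(100, 3, 0.0, 0.5, 9.5, seed=s), "X")
        ests.append(r.icc)
        covered += r.ci_low <= 0.0 <= r.ci_high
    assert abs(np.mean(ests)) < 0.1
    assert covered >= 8


# --- ICC panel ---------------------------------------------------------------

def perfect_signature_frame(n_nodules=6, n_obs=3, seed=0):
    """Wide signature rows where all observers agree exactly."""
    rng = np.random.default_rng(seed)
    rows = []
    for nid in range(n_nodules):
        f = rng.dirichlet(np.ones(9))
        for oid in range(n_obs):
            row = {"nodule": nid, "observer": oid}
            row.update({c: f[i] for i, c in enumerate("VIBGYORCP")})
            rows.append(row)
    return pd.DataFrame(rows)


def test_panel_perfect_agreement_all_ones():
    table = signatures_to_observer_table(perfect_signature_frame())
    panel = icc_panel(table)
    assert np.allclose(panel["icc"].to_numpy(), 1.0)


def test_panel_average_is_mean_of_nine_class_iccs():
    rng = np.random.default_rng(1)
    sig = perfect_signature_frame(10, 3, seed=2)
    # perturb to create observer disagreement
    for c in "VIBGYORCP":
        sig[c] += rng.normal(0, 0.01, len(sig))
    table = signatures_to_observer_table(sig)
    panel = icc_panel(table).set_index("voxel_class")
    nine = [panel.loc[c, "icc"] for c in "VIBGYORCP"]
    assert panel.loc["Avg.", "icc"] == pytest.approx(np.mean(nine))


def test_panel_viro_uses_summed_fractions_not_averaged_iccs():
    sig = perfect_signature_frame(8, 3, seed=3)
    rng = np.random.default_rng(4)
    for c in "VIBGYORCP":
        sig[c] += rng.normal(0, 0.02, len(sig))
    table = signatures_to_observer_table(sig)
    viro_table = _viro_rows(table)
    expected = icc(viro_table, "VIRO").icc
    panel = icc_panel(table).set_index("voxel_class")
    assert panel.loc["VIRO", "icc"] == pytest.approx(expected)
    nine = [panel.loc[c, "icc"] for c in "VIRO"]
    assert panel.loc["VIRO", "icc"] != pytest.approx(np.mean(nine))


def test_panel_skips_small_stratum_with_warning():
    table = signatures_to_observer_table(perfect_signature_frame(5, 3))
    groups = {0: "thin", 1: "thick", 2: "thick", 3: "thick", 4: "thick"}
    with pytest.warns(UserWarning):
        panel = icc_panel(table, group_map=groups)
    assert set(panel["group"]) == {"thick"}


# --- Dice -------------------------------------------------------------------

def cube_mask(lo, hi, shape=(10, 10, 10)):
    v = np.zeros(shape, dtype=np.uint8)
    v[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1
    return VoxelMask(values=v, spacing=(1.0, 1.0, 1.0))


def test_dsc_identical_disjoint_and_hand_counted():
    a = cube_mask((0, 0, 0), (2, 3, 1))  # |A| = 6
    assert dsc(a, a) == 1.0
    b = cube_mask((5, 5, 5), (7, 7, 6))
    assert dsc(a, b) == 0.0
    # |A|=6, |B|=4, |A∩B|=3 -> 2*3/10
    c = cube_mask((0, 0, 0), (1, 4, 1))
    inter = int((a.values & c.values).sum())
    assert inter == 3 and c.count() == 4
    assert dsc(a, c) == pytest.approx(0.6)
    assert dsc(c, a) == pytest.approx(0.6)  # symmetry


def test_dsc_errors():
    a = cube_mask((0, 0, 0), (2, 2, 2))
    empty = cube_mask((0, 0, 0), (0, 0, 0))
    with pytest.raises(UndefinedStatisticError):
        dsc(empty, empty)
    other = VoxelMask(values=np.zeros((9, 10, 10), dtype=np.uint8),
                      spacing=(1.0, 1.0, 1.0))
    with pytest.raises(AlignmentError):
        dsc(a, other)


# --- Fleiss kappa -----------------------------------------------------------

def test_kappa_perfect_agreement():
    R = np.array([["Good"] * 3, ["Poor"] * 3, ["Intermediate"] * 3] * 2)
    r = fleiss_kappa(R)
    assert r.kappa == pytest.approx(1.0)
    assert r.interpretation == "almost perfect agreement"


def test_kappa_matches_direct_formula_on_toy_table():
    R = np.array([
        ["Good", "Good", "Poor"],
        ["Good", "Good", "Good"],
        ["Poor", "Poor", "Intermediate"],
        ["Intermediate", "Intermediate", "Intermediate"],
        ["Good", "Poor", "Poor"],
    ])
    # direct-formula oracle
    cats = ["Good", "Intermediate", "Poor"]
    counts = np.array([[sum(row == c) for c in cats] for row in R], dtype=float)
    N, n = 5, 3
    p = counts.sum(axis=0) / (N * n)
    P_i = (np.sum(counts**2, axis=1) - n) / (n * (n - 1))
    expected = (P_i.mean() - np.sum(p**2)) / (1 - np.sum(p**2))
    r = fleiss_kappa(R)
    assert r.kappa == pytest.approx(expected, abs=1e-9)
    assert r.ci_low < r.kappa < r.ci_high


def test_kappa_matches_statsmodels():
    sm_ir = pytest.importorskip("statsmodels.stats.inter_rater")
    rng = np.random.default_rng(8)
    R = rng.choice(["Good", "Intermediate", "Poor"], size=(30, 3))
    counts, _ = sm_ir.aggregate_raters(
        np.vectorize({"Good": 0, "Intermediate": 1, "Poor": 2}.get)(R))
    expected = sm_ir.fleiss_kappa(counts)
    assert fleiss_kappa(R).kappa == pytest.approx(expected, abs=1e-12)


def test_kappa_invariant_under_category_relabeling():
    rng = np.random.default_rng(9)
    R = rng.choice(["Good", "Intermediate", "Poor"], size=(20, 3))
    relabel = {"Good": "Poor", "Poor": "Good",
               "Intermediate": "Intermediate"}
    R2 = np.vectorize(relabel.get)(R)
    assert fleiss_kappa(R).kappa == pytest.approx(fleiss_kappa(R2).kappa,
                                                  abs=1e-12)


def test_kappa_two_raters_reduces_to_cohen():
    rng = np.random.default_rng(10)
    R = rng.choice(["Good", "Poor"], size=(40, 2))
    # independent Cohen's kappa oracle
    a, b = R[:, 0], R[:, 1]
    po = np.mean(a == b)
    pe = sum(np.mean(a == c) * np.mean(b == c) for c in ("Good", "Poor"))
    cohen = (po - pe) / (1 - pe)
    # Fleiss' chance model uses pooled category frequencies; with 2 raters it
    # matches Cohen up to the pooled-vs-per-rater marginal, equal here in
    # expectation — compare against the pooled-marginal form exactly
    p = np.array([np.mean(R == c) for c in ("Good", "Poor")])
    pooled = (po - np.sum(p**2)) / (1 - np.sum(p**2))
    assert fleiss_kappa(R, categories=("Good", "Poor")).kappa == \
        pytest.approx(pooled, abs=1e-9)
    assert fleiss_kappa(R, categories=("Good", "Poor")).kappa == \
        pytest.approx(cohen, abs=0.05)


def test_kappa_undefined_when_single_category():
    R = np.full((5, 3), "Good")
    with pytest.raises(UndefinedStatisticError):
        fleiss_kappa(R)


# --- Kruskal-Wallis ---------------------------------------------------------

def test_kw_identical_groups_yield_zero_h():
    r = kruskal_wallis([[1.0, 2.0], [1.0, 2.0]])
    assert r.statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)
    assert r.df == 1


def test_kw_matches_textbook_closed_form():
    groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
    # no ties: H = 12/(N(N+1)) * sum n_i (rbar_i - (N+1)/2)^2
    N = 6
    ranks = {v: i + 1 for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])}
    H = 12.0 / (N * (N + 1)) * sum(
        len(g) * (np.mean([ranks[v] for v in g]) - (N + 1) / 2) ** 2
        for g in groups)
    r = kruskal_wallis(groups)
    assert r.statistic == pytest.approx(H, abs=1e-9)
    assert r.df == 2


def test_kw_invariant_under_monotone_transform():
    groups = [[1.0, 5.0, 2.0], [7.0, 3.0], [10.0, 8.0, 4.0]]
    r1 = kruskal_wallis(groups)
    r2 = kruskal_wallis([[np.exp(v) for v in g] for g in groups])
    assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)


def test_kw_degenerate_and_invalid_inputs():
    with pytest.raises(DegenerateDataError):
        kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0]])
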