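"""geNorm: relative quantities, pairwise variation, M values, V curve."""

import itertools

import numpy as np
import pandas as pd
import pytest

from refstab.data import EfficiencyTable, RefstabError
from refstab.genorm import (
    GeNorm,
    m_values,
    normalization_factors,
    pairwise_v_curve,
    pairwise_variation_matrix,
    rank_genes_genorm,
    relative_quantities,
)
from refstab.simulate import reference_panel_config, simulate_cq_dataset

from conftest import make_annotations, wide_to_table


def as_wide(rows: dict[str, list[float]]) -> pd.DataFrame:
    frame = pd.DataFrame(rows).T
    frame.index.name = "gene"
    frame.columns = [f"s{i}" for i in range(1, frame.shape[1] + 1)]
    return frame


def test_relative_quantities_default_efficiency():
    q = relative_quantities(as_wide({"gA": [20.0, 21.0]}))
    assert q.loc["gA"].tolist() == pytest.approx([1.0, 0.5])


def test_relative_quantities_custom_efficiency():
    eff = EfficiencyTable(pd.Series({"gA": 1.9}))
    q = relative_quantities(as_wide({"gA": [20.0, 21.0]}), eff)
    assert q.loc["gA"].tolist() == pytest.approx([1.0, 1 / 1.9])


def test_relative_quantities_constant_row_is_all_ones():
    q = relative_quantities(as_wide({"gA": [25.0, 25.0, 25.0]}))
    assert (q.loc["gA"] == 1.0).all()


def test_pairwise_variation_of_shifted_profiles_is_zero():
    # a constant Cq offset between genes gives a constant log-ratio
    q = relative_quantities(as_wide({"gA": [20.0, 22.0, 21.0], "gB": [25.0, 27.0, 26.0]}))
    v = pairwise_variation_matrix(q)
    assert v.loc["gA", "gB"] == pytest.approx(0.0, abs=1e-12)


def test_pairwise_variation_hand_example():
    # log2 ratios of A against B are (0, -1); sample SD = 0.7071
    q = relative_quantities(as_wide({"gA": [20.0, 22.0], "gB": [25.0, 26.0]}))
    v = pairwise_variation_matrix(q)
    assert v.loc["gA", "gB"] == pytest.approx(np.sqrt(0.5), abs=1e-9)


def test_pairwise_variation_matches_brute_force(random_wide):
    q = relative_quantities(random_wide(n_genes=4, n_samples=8, seed=9))
    v = pairwise_variation_matrix(q)
    logq = np.log2(q)
    for a, b in itertools.combinations(q.index, 2):
        ratios = (logq.loc[a] - logq.loc[b]).to_numpy()
        expected = np.sqrt(((ratios - ratios.mean()) ** 2).sum() / (len(ratios) - 1))
        assert v.loc[a, b] == pytest.approx(expected, rel=1e-12)
        assert v.loc[b, a] == v.loc[a, b]
    assert (np.diag(v) == 0).all()


def test_m_of_two_genes_equals_their_pairwise_variation(random_wide):
    q = relative_quantities(random_wide(n_genes=2, n_samples=6, seed=4))
    v = pairwise_variation_matrix(q)
    m = m_values(v)
    assert m["g00"] == pytest.approx(v.loc["g00", "g01"])
    assert m["g01"] == pytest.approx(v.loc["g00", "g01"])


def test_proportional_panel_has_zero_m():
    base = np.array([20.0, 21.5, 19.0, 22.0])
    wide = as_wide({f"g{i}": list(base + i) for i in range(4)})
    q = relative_quantities(wide)
    m = m_values(pairwise_variation_matrix(q))
    assert np.allclose(m, 0.0, atol=1e-12)


def test_rank_genes_excludes_noise_gene_first():
    rng = np.random.default_rng(0)
    base = 20.0 + rng.uniform(0, 2, 8)
    wide = as_wide(
        {
            "gA": list(base),
            "gB": list(base + 3.0),           # proportional to gA
            "gC": list(base + rng.normal(0, 1.5, 8)),  # pure noise
        }
    )
    res = rank_genes_genorm(relative_quantities(wide))
    assert res.exclusion_order == ["gC"]
    assert res.final_pair == ("gA", "gB")
    assert res.ranks.tolist() == [1, 1, 3]


def test_identical_profiles_all_m_zero_nothing_flagged(random_wide):
    row = random_wide(n_genes=1, n_samples=6, seed=1).iloc[0]
    wide = as_wide({f"g{i}": list(row.values) for i in range(4)})
    res = rank_genes_genorm(relative_quantities(wide))
    assert np.allclose(res.m_at_exclusion, 0.0, atol=1e-12)
    assert res.unstable_genes == []


def test_normalization_factors_match_brute_force(random_wide):
    q = relative_quantities(random_wide(n_genes=5, n_samples=7, seed=12))
    order = list(q.index)
    nf1 = normalization_factors(q, order, 1)
    assert np.allclose(nf1, q.loc[order[0]])
    for n in (2, 3, 5):
        nf = normalization_factors(q, order, n)
        brute = np.prod(q.loc[order[:n]].to_numpy(), axis=0) ** (1.0 / n)
        assert np.allclose(nf, brute, rtol=1e-12)
    with pytest.raises(RefstabError):
        normalization_factors(q, order, 6)


def test_nf2_geometric_mean_example():
    q = pd.DataFrame(
        [[1.0, 0.25], [1.0, 1.0]],
        index=pd.Index(["gA", "gB"], name="gene"),
        columns=["s1", "s2"],
    )
    nf = normalization_factors(q, ["gA", "gB"], 2)
    assert nf.tolist() == pytest.approx([1.0, 0.5])


def test_v_curve_zero_when_third_gene_proportional():
    base = np.array([20.0, 21.0, 19.5, 22.5])
    wide = as_wide({"gA": list(base), "gB": list(base + 1), "gC": list(base + 2)})
    curve = pairwise_v_curve(relative_quantities(wide), ["gA", "gB", "gC"])
    assert curve.values[2] == pytest.approx(0.0, abs=1e-12)
    assert curve.n_optimal == 2


def test_v_curve_subset_equals_brute_force_on_submatrix(random_wide):
    wide = random_wide(n_genes=5, n_samples=10, seed=21)
    q = relative_quantities(wide)
    order = list(q.index)
    subset = list(wide.columns[:5])
    curve = pairwise_v_curve(q, order, samples=subset, label="6h")
    # brute force: recompute relative quantities from the Cq submatrix
    q_sub = relative_quantities(wide[subset])
    expected = pairwise_v_curve(q_sub, order)
    pd.testing.assert_series_equal(curve.values, expected.values)
    with pytest.raises(RefstabError):
        pairwise_v_curve(q, order, samples=subset[:1])


def test_loading_shift_leaves_genorm_invariant(random_wide):
    wide = random_wide(n_genes=5, n_samples=8, seed=33)
    shifted = wide.copy()
    shifted.iloc[:, 2] += 1.7  # one sample loaded differently
    res_a = rank_genes_genorm(relative_quantities(wide))
    res_b = rank_genes_genorm(relative_quantities(shifted))
    pd.testing.assert_frame_equal(res_a.pairwise_v, res_b.pairwise_v, atol=1e-9, rtol=0)
    pd.testing.assert_series_equal(
        res_a.m_at_exclusion, res_b.m_at_exclusion, atol=1e-9, rtol=0
    )
    pd.testing.assert_series_equal(
        res_a.v_curve.values, res_b.v_curve.values, atol=1e-9, rtol=0
    )


def test_per_gene_shift_invariant_at_e2(random_wide):
    wide = random_wide(n_genes=4, n_samples=6, seed=8)
    shifted = wide.add(pd.Series([0.0, 1.0, -2.0, 5.0], index=wide.index), axis=0)
    v_a = pairwise_variation_matrix(relative_quantities(wide))
    v_b = pairwise_variation_matrix(relative_quantities(shifted))
    pd.testing.assert_frame_equal(v_a, v_b, atol=1e-9, rtol=0)


def test_removal_tie_broken_by_later_gene_id():
    base = np.array([20.0, 21.0, 22.0, 19.0])
    noise = np.array([0.5, -0.5, 0.5, -0.5])
    wide = as_wide(
        {
            "gA": list(base),
            "gB": list(base + noise),   # symmetric deviations
            "gC": list(base - noise),   # same M as gB by symmetry
        }
    )
    res = rank_genes_genorm(relative_quantities(wide))
    assert res.exclusion_order == ["gC"]


def test_exclusion_order_recovers_planted_gradient():
    config = reference_panel_config()
    hits = 0
    n_seeds = 40
    for seed in range(n_seeds):
        table, truth = simulate_cq_dataset(config, seed=seed)
        res = GeNorm(table.collapse()).fit()
        # the two planted unstable genes must leave first
        if set(res.exclusion_order[:2]) == {"RG09", "RG10"}:
            hits += 1
    assert hits / n_seeds >= 0.9


def test_model_class_requires_three_genes(small_panel):
    two = small_panel.subset()  # copy
    meas = two.measurements[two.measurements["gene"].isin(["g1", "g2"])]
    from refstab.data import CqTable

    with pytest.raises(RefstabError):
        GeNorm(CqTable(meas, two.annotations, collapsed=True))
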