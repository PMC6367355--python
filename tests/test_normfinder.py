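"""NormFinder: variance decomposition, shrinkage, stability values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from refstab.data import CqTable, DesignError, RefstabError
from refstab.normfinder import (
    NormFinder,
    intergroup_variation,
    intragroup_variances,
    log_expression,
    stability_values,
)
from refstab.simulate import CqSimConfig, Design, simulate_cq_dataset

from conftest import wide_to_table


def two_group_table(wide: pd.DataFrame) -> CqTable:
    n = wide.shape[1]
    half = n // 2
    ann = pd.DataFrame(
        {
            "sample_id": wide.columns,
            "group": ["mock"] * half + ["Pf"] * (n - half),
            "timepoint": "6h",
            "bio_rep": list(range(1, half + 1)) + list(range(1, n - half + 1)),
        }
    )
    return wide_to_table(wide, ann)


def frames(arrs: dict[str, np.ndarray]) -> dict[str, pd.DataFrame]:
    return {
        g: pd.DataFrame(a, index=[f"g{i}" for i in range(a.shape[0])])
        for g, a in arrs.items()
    }


def test_log_expression_is_negated_cq_with_design_groups():
    table, _ = simulate_cq_dataset(
        CqSimConfig(genes=("gA", "gB", "gC"), noise_sd={"gA": 0, "gB": 0, "gC": 0}),
        Design(),
        seed=0,
    )
    collapsed = table.collapse()
    y = log_expression(collapsed)
    assert len(y) == 8  # 4 treatments x 2 timepoints
    assert all(frame.shape == (3, 3) for frame in y.values())
    wide = collapsed.to_wide()
    sample = y["mock:6h"].columns[0]
    assert y["mock:6h"][sample].tolist() == pytest.approx((-wide[sample]).tolist())


def test_zero_noise_group_gives_zero_variances():
    base = np.array([[25.0], [20.0], [30.0]]) @ np.ones((1, 4))
    loading = np.array([0.0, 0.5, -0.3, 1.0])
    v, s2 = intragroup_variances(frames({"g1": base + loading}))
    assert np.allclose(v, 0.0, atol=1e-20)
    assert np.allclose(s2, 0.0, atol=1e-20)


def test_single_noisy_gene_variance_recovered():
    rng = np.random.default_rng(6)
    k, n = 8, 400
    y = np.zeros((k, n))
    y[0] = rng.normal(0, 0.5, n)
    _, s2 = intragroup_variances(frames({"g": y}))
    est = s2["g"].to_numpy()
    assert est[0] == pytest.approx(0.25, rel=0.2)
    assert np.all(est[1:] < 0.05)


def test_variance_estimator_is_unbiased():
    """Monte-Carlo oracle for the k/(k-2) de-biasing correction."""
    rng = np.random.default_rng(0)
    k, n, reps = 10, 12, 2000
    sigma = np.linspace(0.2, 0.8, k)
    total = np.zeros(k)
    for _ in range(reps):
        y = rng.normal(0, sigma[:, None], (k, n))
        _, s2 = intragroup_variances(frames({"g": y}), truncate=False)
        total += s2["g"].to_numpy()
    bias = total / reps / sigma**2 - 1.0
    assert np.all(np.abs(bias) < 0.05)


def test_requires_three_genes_and_two_samples():
    with pytest.raises(RefstabError):
        intragroup_variances(frames({"g": np.zeros((2, 5))}))


def test_intergroup_deviations_center_and_flag_shifted_gene():
    k, n = 6, 4
    y1 = np.tile(np.arange(k, dtype=float)[:, None], (1, n))
    y2 = y1.copy()
    y2[2] += 1.0  # one gene shifted in the second group only
    y = frames({"a": y1, "b": y2})
    _, s2 = intragroup_variances(y)
    d, gamma2, d_shrunk = intergroup_variation(y, s2)
    assert d.abs().to_numpy().max() == pytest.approx(abs(d.loc["g2", "b"]))
    # centering identity: deviations sum to zero within each group
    assert np.allclose(d.sum(axis=0), 0.0, atol=1e-9)
    assert gamma2 > 0


def test_no_effects_no_noise_gives_all_zero():
    y = frames({"a": np.ones((4, 3)) * 5, "b": np.ones((4, 3)) * 5})
    _, s2 = intragroup_variances(y)
    d, gamma2, d_shrunk = intergroup_variation(y, s2)
    assert np.allclose(d, 0.0) and gamma2 == 0.0 and np.allclose(d_shrunk, 0.0)


def test_single_group_reduces_to_intragroup_sd(random_wide):
    wide = random_wide(n_genes=5, n_samples=8, seed=10)
    ann = pd.DataFrame(
        {
            "sample_id": wide.columns,
            "group": "mock",
            "timepoint": "6h",
            "bio_rep": range(1, 9),
        }
    )
    res = NormFinder(wide_to_table(wide, ann)).fit()
    assert res.single_group
    _, s2 = intragroup_variances(log_expression(wide_to_table(wide, ann)))
    expected = np.sqrt(s2.iloc[:, 0])
    assert np.allclose(res.rho, expected)
    assert res.ranks.loc[res.rho.idxmin()] == 1


def test_noiseless_effect_free_panel_has_zero_stability(random_wide):
    base = np.linspace(18, 28, 5)
    wide = pd.DataFrame(
        np.tile(base[:, None], (1, 8)),
        index=pd.Index([f"g{i}" for i in range(5)], name="gene"),
        columns=[f"s{j}" for j in range(8)],
    )
    res = NormFinder(two_group_table(wide)).fit()
    assert np.allclose(res.rho, 0.0, atol=1e-12)


def test_sign_invariance_of_rho(random_wide):
    wide = random_wide(n_genes=5, n_samples=8, seed=3)
    table = two_group_table(wide)
    res = NormFinder(table).fit()
    # recompute with y = +Cq by negating the stored Cq path: equivalent to
    # mirroring the matrix around a constant
    mirrored = two_group_table(50.0 - wide)
    res_m = NormFinder(mirrored).fit()
    assert np.allclose(res.rho, res_m.rho, atol=1e-9)
    pd.testing.assert_frame_equal(res.sigma2, res_m.sigma2, atol=1e-9, rtol=0)


def test_loading_and_gene_shift_invariance(random_wide):
    wide = random_wide(n_genes=5, n_samples=8, seed=14)
    res = NormFinder(two_group_table(wide)).fit()
    shifted = wide.copy()
    shifted.iloc[:, 3] += 2.0                       # per-sample loading
    shifted = shifted.add(
        pd.Series(np.arange(5, dtype=float), index=wide.index), axis=0
    )                                               # per-gene constant
    res_s = NormFinder(two_group_table(shifted)).fit()
    assert np.allclose(res.rho, res_s.rho, atol=1e-9)
    assert res.ranks.equals(res_s.ranks)


def test_group_of_one_sample_is_an_error(small_panel):
    with pytest.raises(DesignError):
        NormFinder(small_panel, group_by=("group", "bio_rep"))


def test_planted_unstable_genes_take_worst_ranks():
    config = CqSimConfig(
        genes=tuple(f"g{i}" for i in range(10)),
        noise_sd={**{f"g{i}": 0.1 for i in range(8)}, "g8": 0.8, "g9": 0.1},
        group_effects={"g9": {"Pf": 1.0}},
    )
    design = Design(treatments=("mock", "Pf"), timepoints=("6h",), n_bio=6)
    hits = 0
    n_seeds = 40
    for seed in range(n_seeds):
        table, _ = simulate_cq_dataset(config, design, seed=seed)
        res = stability_values(table.collapse())
        worst_two = set(res.rho.nlargest(2).index)
        hits += worst_two == {"g8", "g9"}
    assert hits / n_seeds >= 0.9


def test_rank_recovery_tracks_planted_instability_spectrum():
    """Estimated stability ranks follow the planted order when noise and
    group effects grow together (Spearman >= 0.9 on average).

    Group shifts of 2*sigma (alternating sign) keep the population
    stability values strictly ordered, so the planted index order is the
    unambiguous ground truth.
    """
    k = 10
    sigmas = np.linspace(0.1, 0.8, k)
    genes = tuple(f"g{i}" for i in range(k))
    config = CqSimConfig(
        genes=genes,
        noise_sd={g: float(s) for g, s in zip(genes, sigmas)},
        group_effects={
            g: {"Pf": 2.0 * float(s) * (-1) ** i}
            for i, (g, s) in enumerate(zip(genes, sigmas))
        },
        loading_sd=0.3,
    )
    design = Design(treatments=("mock", "Pf"), timepoints=("6h",), n_bio=12)
    truth_rank = np.arange(k)
    rhos = []
    for seed in range(60):
        table, _ = simulate_cq_dataset(config, design, seed=seed)
        res = stability_values(table.collapse())
        est = res.rho.loc[list(genes)].to_numpy()
        rhos.append(sps.spearmanr(truth_rank, est).statistic)
    assert np.mean(rhos) >= 0.9
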