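"""Unit and property tests for the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from braindeconv import (
    ExpressionMatrix,
    NoiseModel,
    ProportionMatrix,
    add_nb_noise,
    estimate_dispersion,
    generate_population,
    make_pseudobulk,
    simulate_genotypes,
    simulate_ihc,
    simulate_phenotype,
)
from braindeconv.downstream import celltype_eqtl


class TestGeneratePopulation:
    def test_planted_markers_are_disjoint_and_satisfy_fold_change(self):
        pop = generate_population(1000, [f"t{i}" for i in range(5)], 100, 8.0, seed=1,
                                  n_cells=200)
        all_markers = [g for genes in pop.marker_truth.values() for g in genes]
        assert len(all_markers) == 500
        assert len(set(all_markers)) == 500
        means = pop.type_means
        for ct, genes in pop.marker_truth.items():
            own = means.loc[genes, ct]
            others = means.loc[genes].drop(columns=ct).max(axis=1)
            assert (own >= 8.0 * others - 1e-9).all()

    def test_same_seed_is_bit_identical_and_seeds_differ(self):
        a = generate_population(200, ["A", "B"], 10, 4.0, seed=5, n_cells=100)
        b = generate_population(200, ["A", "B"], 10, 4.0, seed=5, n_cells=100)
        c = generate_population(200, ["A", "B"], 10, 4.0, seed=6, n_cells=100)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert not a.counts.equals(c.counts)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_genes=0),
            dict(fold_change=1.0),
            dict(cell_types=["A", "A"]),
            dict(markers_per_type=200),  # 2 types * 200 > 300 genes
            dict(cell_types=["A"]),
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        base = dict(n_genes=300, cell_types=["A", "B"], markers_per_type=10,
                    fold_change=4.0, seed=0, n_cells=50)
        base.update(kwargs)
        with pytest.raises(ValueError):
            generate_population(**base)


class TestMakePseudobulk:
    def test_truth_columns_sum_to_one_exactly(self, small_population):
        _, truth = make_pseudobulk(small_population, n_samples=20,
                                   cells_per_sample=50, seed=2)
        sums = truth.proportions.data.sum(axis=0)
        # realised cell fractions sum to 1 by construction; the float sum of
        # the fractions is exact to machine precision
        np.testing.assert_allclose(sums.to_numpy(), 1.0, rtol=0, atol=1e-12)

    def test_single_cell_type_gives_degenerate_truth(self):
        pop = generate_population(100, ["A", "B"], 5, 4.0, seed=0, n_cells=60,
                                  type_frequencies=[1e-9, 1.0])
        # effectively all cells are type B
        assert (pop.cell_labels == "B").all()
        _, truth = make_pseudobulk(pop, n_samples=4, cells_per_sample=10, seed=1)
        assert np.allclose(truth.proportions.data.loc["B"], 1.0)

    def test_cells_per_sample_one_reproduces_single_cells(self, small_population):
        expr, _ = make_pseudobulk(small_population, n_samples=10,
                                  cells_per_sample=1, seed=3)
        counts = small_population.counts.to_numpy()
        for j in range(10):
            col = expr.data.iloc[:, j].to_numpy()
            assert any(np.array_equal(col, counts[:, i])
                       for i in range(counts.shape[1]))

    def test_samples_are_means_of_drawn_cells(self, small_population):
        expr, truth = make_pseudobulk(small_population, n_samples=70,
                                      cells_per_sample=100, seed=4)
        assert expr.data.shape == (300, 70)
        # composition varies between samples (the Dirichlet layer)
        assert truth.proportions.data.std(axis=1).max() > 0.01


class TestNoiseModel:
    def test_nb_moments_match_target(self):
        mu = np.full((1, 100_000), 100.0)
        means = ExpressionMatrix(pd.DataFrame(mu), scale="linear")
        out = add_nb_noise(means, NoiseModel(dispersion=0.5), seed=9)
        draws = out.data.to_numpy().ravel()
        assert draws.mean() == pytest.approx(100.0, rel=0.05)
        assert draws.var() == pytest.approx(100 + 0.5 * 100**2, rel=0.05)

    def test_poisson_limit_and_zero_mean(self):
        mu = np.full((1, 100_000), 4.0)
        means = ExpressionMatrix(pd.DataFrame(mu), scale="linear")
        out = add_nb_noise(means, NoiseModel(dispersion=0.0), seed=9)
        assert out.data.to_numpy().var() == pytest.approx(4.0, rel=0.05)
        zeros = ExpressionMatrix(pd.DataFrame(np.zeros((5, 10)) + 1e-300 * 0),
                                 scale="linear")
        out0 = add_nb_noise(zeros, NoiseModel(dispersion=0.5), seed=1)
        assert (out0.data.to_numpy() == 0).all()

    def test_dispersion_recovered_from_simulated_counts(self):
        rng = np.random.default_rng(11)
        mu = rng.lognormal(2.0, 1.0, size=(5000, 1))
        means = ExpressionMatrix(
            pd.DataFrame(np.tile(mu, (1, 70))), scale="linear"
        )
        noisy = add_nb_noise(means, NoiseModel(dispersion=0.2), seed=12)
        est = estimate_dispersion(noisy)
        assert est.dispersion == pytest.approx(0.2, abs=0.05)

    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(13)
        counts = rng.poisson(20.0, size=(2000, 50))
        est = estimate_dispersion(
            ExpressionMatrix(pd.DataFrame(counts), scale="counts")
        )
        assert est.dispersion < 0.02

    def test_constant_matrix_clips_to_zero(self):
        est = estimate_dispersion(
            ExpressionMatrix(pd.DataFrame(np.full((10, 5), 7.0)), scale="counts")
        )
        assert est.dispersion == 0.0

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(dispersion=-0.1)


class TestSimulateIhc:
    def test_cv_zero_is_noiseless(self, simplex_frame):
        out = simulate_ihc(simplex_frame, cv=0.0, seed=1)
        np.testing.assert_allclose(out.data.to_numpy(),
                                   simplex_frame.data.to_numpy())

    def test_column_sums_scatter_around_one(self):
        rng = np.random.default_rng(21)
        values = rng.dirichlet(np.ones(5), size=70).T
        truth = ProportionMatrix(
            pd.DataFrame(values, index=list("abcde"),
                         columns=[f"s{i}" for i in range(70)]),
            kind="true",
        )
        out = simulate_ihc(truth, cv=0.2, seed=22)
        sums = out.data.sum(axis=0)
        assert sums.mean() == pytest.approx(1.0, abs=0.05)
        assert sums.std() > 0  # measured tables are not an exact simplex

    def test_zeros_stay_zero(self):
        truth = ProportionMatrix(
            pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["a", "b"],
                         columns=["s0", "s1"]),
            kind="true",
        )
        out = simulate_ihc(truth, cv=0.3, seed=2)
        assert (out.data.loc["b"] == 0).all()


class TestSimulatePhenotype:
    def test_noiseless_phenotype_tracks_mediated_proportion(self, scenario):
        pheno, params = simulate_phenotype(
            scenario.bulk, scenario.truth.proportions, [], "Neuron",
            effect=1.0, noise_sd=0.0, seed=1,
        )
        c = scenario.truth.proportions.data.loc["Neuron"]
        assert np.corrcoef(pheno, c)[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert params["mediated_celltype"] == "Neuron"

    def test_unknown_names_rejected(self, scenario):
        with pytest.raises(KeyError):
            simulate_phenotype(scenario.bulk, scenario.truth.proportions, [],
                               "Ghost", seed=1)
        with pytest.raises(KeyError):
            simulate_phenotype(scenario.bulk, scenario.truth.proportions,
                               ["nope"], "Neuron", seed=1)


class TestSimulateGenotypes:
    def test_null_injection_leaves_expression_unchanged(self, scenario):
        dos, expr = simulate_genotypes(
            70, 10, 0.3, [("snp00001", "g00000", "Neuron", 0.0)],
            scenario.truth.proportions, scenario.clean_bulk, seed=5,
        )
        pd.testing.assert_frame_equal(expr.data, scenario.clean_bulk.data)

    def test_mean_dosage_matches_binomial_moment(self, scenario):
        dos, _ = simulate_genotypes(70, 1000, 0.3, [],
                                    scenario.truth.proportions,
                                    scenario.clean_bulk, seed=6)
        assert dos.to_numpy().mean() == pytest.approx(0.6, abs=0.01)
        assert set(np.unique(dos.to_numpy())) <= {0, 1, 2}

    def test_planted_gamma_recovered_exactly_without_noise(self, scenario):
        dos, expr = simulate_genotypes(
            70, 5, 0.4, [("snp00000", "g00000", "Neuron", 2.0)],
            scenario.truth.proportions, scenario.clean_bulk, seed=7,
        )
        y = (expr.data.loc["g00000"] - scenario.clean_bulk.data.loc["g00000"]).to_numpy()
        g = dos.loc["snp00000"].to_numpy(dtype=float)
        c = scenario.truth.proportions.data.loc["Neuron"].to_numpy()
        fit = celltype_eqtl(y + 0.3 * g + 0.1 * c, g, c)
        assert fit.gamma == pytest.approx(2.0, abs=1e-9)

    def test_bad_maf_rejected(self, scenario):
        for maf in (0.0, 0.6, -0.1):
            with pytest.raises(ValueError):
                simulate_genotypes(70, 5, maf, [], scenario.truth.proportions,
                                   scenario.clean_bulk, seed=1)
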