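import numpy as np
import pytest
from scipy import stats

from suldex.bbm import BBMData, bbm_log_likelihood
from suldex.binding_core import BindingState, OligoSet
from suldex.gem import (
    EnergyModel,
    GEMState,
    additive_energy,
    encode_sequences,
    gem_log_likelihood,
    inclusion_probability,
    residuals,
)

LEU3_CONSENSUS = "CCGGTACCGG"


def leu3_table_model():
    """Posterior-mean terms of the published 10-position summary table."""
    terms = np.zeros((10, 4))
    rows = {
        # position (1-based): {nt: mean}
        1: {"G": 0.32, "T": 1.88},
        3: {"T": 0.05},
        4: {"A": 0.91, "C": 0.15, "T": 0.19},
        5: {"A": 0.42, "C": 0.58, "G": 0.80},
        6: {"C": 1.22, "G": 0.33, "T": 0.61},
        7: {"A": 0.57, "G": 0.71, "T": 0.29},
        8: {"A": 0.28},
        10: {"C": 0.92},
    }
    # position 7's optimal entry is C at 0.25 in the table; anchoring at zero
    # means only differences are meaningful, so shift the row accordingly
    nt_index = {nt: i for i, nt in enumerate("ACGT")}
    for pos, entries in rows.items():
        for nt, value in entries.items():
            terms[pos - 1, nt_index[nt]] = value
    return EnergyModel(optimal_sequence=LEU3_CONSENSUS, e0=0.0, terms=terms, sigma=0.3)


class TestAdditiveEnergy:
    def test_optimal_sequence_is_offset(self):
        model = leu3_table_model()
        assert additive_energy(LEU3_CONSENSUS, model) == pytest.approx(model.e0)

    def test_published_position1_T_term(self):
        # T at position 1 of the consensus adds 1.88 energy units
        model = leu3_table_model()
        mutant = "T" + LEU3_CONSENSUS[1:]
        assert additive_energy(mutant, model) == pytest.approx(model.e0 + 1.88)

    def test_double_mutant_additivity(self):
        model = leu3_table_model()
        # position 1 -> T (1.88) and position 6 -> C (1.22)
        seq = list(LEU3_CONSENSUS)
        seq[0], seq[5] = "T", "C"
        expected = model.e0 + 1.88 + 1.22
        assert additive_energy("".join(seq), model) == pytest.approx(expected)

    def test_invalid_character(self):
        with pytest.raises(ValueError, match="invalid nucleotide"):
            additive_energy("N" + LEU3_CONSENSUS[1:], leu3_table_model())

    def test_matrix_input_matches_scalar(self):
        model = leu3_table_model()
        seqs = [LEU3_CONSENSUS, "T" + LEU3_CONSENSUS[1:]]
        vec = additive_energy(encode_sequences(seqs), model)
        assert vec[0] == pytest.approx(additive_energy(seqs[0], model))
        assert vec[1] == pytest.approx(additive_energy(seqs[1], model))


class TestEnergyModelInvariants:
    def test_negative_terms_rejected(self):
        terms = np.zeros((4, 4))
        terms[0, 1] = -0.5
        with pytest.raises(ValueError, match="non-negative"):
            EnergyModel(optimal_sequence="AAAA", terms=terms)

    def test_optimal_anchor_enforced(self):
        terms = np.zeros((4, 4))
        terms[0, 0] = 0.3  # A is optimal at position 0
        with pytest.raises(ValueError, match="optimal-nucleotide"):
            EnergyModel(optimal_sequence="AAAA", terms=terms)

    def test_excluded_terms_must_be_zero(self):
        terms = np.zeros((2, 4))
        terms[0, 1] = 0.5
        delta = np.zeros((2, 4), dtype=int)
        with pytest.raises(ValueError, match="excluded"):
            EnergyModel(optimal_sequence="AA", terms=terms, indicators=delta)

    def test_interactive_terms_constrained_to_zero(self):
        with pytest.raises(ValueError, match="interactive"):
            EnergyModel(optimal_sequence="AA", interaction_terms={(0, 1): 0.2})

    def test_single_mutant_map_injective(self, rng):
        # the anchored parameterization determines single-mutant energies
        # uniquely: recovering terms from them reproduces the model
        for _ in range(10):
            length = int(rng.integers(3, 8))
            consensus = "".join(rng.choice(list("ACGT"), size=length))
            terms = np.zeros((length, 4))
            codes = encode_sequences([consensus])[0]
            for pos in range(length):
                for nt in range(4):
                    if nt != codes[pos]:
                        terms[pos, nt] = rng.uniform(0, 3)
            model = EnergyModel(optimal_sequence=consensus, terms=terms)
            recovered = np.zeros_like(terms)
            for pos in range(length):
                for nt, letter in enumerate("ACGT"):
                    if nt == codes[pos]:
                        continue
                    mutant = consensus[:pos] + letter + consensus[pos + 1 :]
                    recovered[pos, nt] = additive_energy(mutant, model) - model.e0
            np.testing.assert_allclose(recovered, terms, atol=1e-12)


class TestResiduals:
    def _binding_state(self, kds):
        k = len(kds)
        return BindingState(np.full(k, 1 / k), np.asarray(kds, dtype=float), 1.0)

    def test_exact_additive_model_zero_residuals(self):
        model = leu3_table_model()
        seqs = [LEU3_CONSENSUS, "T" + LEU3_CONSENSUS[1:], "G" + LEU3_CONSENSUS[1:]]
        kd_opt = 2.0
        kds = [kd_opt * np.exp(additive_energy(s, model) - model.e0) for s in seqs]
        eps = residuals(self._binding_state(kds), model, seqs, kd_opt)
        np.testing.assert_allclose(eps, 0.0, atol=1e-12)

    def test_e_fold_inflation_gives_unit_residual(self):
        model = leu3_table_model()
        seqs = [LEU3_CONSENSUS]
        kd_opt = 2.0
        eps = residuals(self._binding_state([kd_opt * np.e]), model, seqs, kd_opt)
        assert eps[0] == pytest.approx(1.0, rel=1e-12)

    def test_residual_std_recovered_from_simulation(self):
        # oracle: simulate 1000 sequences on the landscape with known noise
        rng = np.random.default_rng(5)
        model = leu3_table_model()
        codes = rng.integers(0, 4, size=(1000, 10))
        seqs = ["".join("ACGT"[c] for c in row) for row in codes]
        seqs = list(dict.fromkeys(seqs))
        kd_opt = 2.0
        e_rel = additive_energy(encode_sequences(seqs), model) - model.e0
        noise = rng.normal(0, 0.3, size=len(seqs))
        kds = kd_opt * np.exp(e_rel + noise)
        eps = residuals(self._binding_state(kds), model, seqs, kd_opt)
        assert np.std(eps) == pytest.approx(0.3, rel=0.1)


class TestGEMLikelihood:
    def _setup(self):
        oligos = OligoSet(
            ["AA", "CA", "AC"],
            np.array([30, 20, 10]),
            np.array([25, 20, 15]),
            {"AA": 1.0},
        )
        data = BBMData(oligo_set=oligos)
        binding = BindingState(
            np.array([0.5, 0.3, 0.2]), np.array([1.0, 3.0, 6.0]), 2.0
        )
        terms = np.zeros((2, 4))
        terms[0, 1] = 1.0
        terms[1, 1] = 1.5
        model = EnergyModel(optimal_sequence="AA", terms=terms, sigma=0.4)
        return data, GEMState(binding_state=binding, energy_model=model, kd_opt=1.0)

    def test_matches_independent_summation(self):
        # oracle: multinomial log-pmf differences plus scipy Gaussian
        # log-densities, assembled independently
        data, state = self._setup()
        seqs = data.oligo_set.sequences
        expected_eps = [
            np.log(kd / state.kd_opt)
            - (additive_energy(s, state.energy_model) - state.energy_model.e0)
            for s, kd in zip(seqs, state.binding_state.kds)
        ]
        expected = bbm_log_likelihood(state.binding_state, data) + sum(
            stats.norm.logpdf(e, 0, state.energy_model.sigma) for e in expected_eps
        )
        assert gem_log_likelihood(state, data) == pytest.approx(expected, rel=1e-12)

    def test_gaussian_at_mode(self):
        data, state = self._setup()
        # put all Kds exactly on the additive model
        model = state.energy_model
        kds = np.array(
            [
                state.kd_opt * np.exp(additive_energy(s, model) - model.e0)
                for s in data.oligo_set.sequences
            ]
        )
        binding = BindingState(state.binding_state.prebound_freqs, kds, 2.0)
        gem_state = GEMState(binding_state=binding, energy_model=model, kd_opt=state.kd_opt)
        k = len(kds)
        expected = bbm_log_likelihood(binding, data) + k * np.log(
            1.0 / (model.sigma * np.sqrt(2 * np.pi))
        )
        assert gem_log_likelihood(gem_state, data) == pytest.approx(expected, rel=1e-12)

    def test_large_sigma_ranking_approaches_bbm(self):
        data, state = self._setup()
        other = GEMState(
            binding_state=BindingState(
                np.array([0.4, 0.4, 0.2]), np.array([1.0, 5.0, 4.0]), 2.5
            ),
            energy_model=state.energy_model,
            kd_opt=1.0,
        )
        for gs in (state, other):
            gs.energy_model = EnergyModel(
                optimal_sequence="AA",
                terms=gs.energy_model.terms,
                sigma=1e6,
            )
        gem_diff = gem_log_likelihood(state, data) - gem_log_likelihood(other, data)
        bbm_diff = bbm_log_likelihood(state.binding_state, data) - bbm_log_likelihood(
            other.binding_state, data
        )
        assert gem_diff == pytest.approx(bbm_diff, abs=1e-6)

    def test_nonpositive_sigma_rejected_state(self):
        data, state = self._setup()
        state.energy_model.sigma = -1.0
        assert gem_log_likelihood(state, data) == -np.inf


class TestInclusionProbability:
    def test_always_included(self):
        draws = np.ones((50, 3, 4))
        np.testing.assert_allclose(inclusion_probability(draws), 1.0)

    def test_untested_flagged_not_zero(self):
        draws = np.zeros((10, 2, 4))
        mask = np.ones((2, 4), dtype=bool)
        mask[1, 3] = False
        prob = inclusion_probability(draws, mask)
        assert np.isnan(prob[1, 3])
        assert prob[0, 0] == 0.0

    def test_requires_samples(self):
        with pytest.raises(ValueError):
            inclusion_probability(np.zeros((0, 2, 4)))


class TestLargeCountFactorization:
    def test_gem_and_bbm_kd_means_agree_at_high_depth(self):
        # at high counts the joint model factors apart: count-determined Kds
        # dominate, so GEM posterior Kd means track BBM means within the
        # posterior spread even when the energy model is inaccurate
        from suldex import mcmc, simulator
        from suldex.bbm import BBMData

        config = simulator.leu3_like_preset(
            tf_free=10.0, mean_depth=10_000, seed=3, epsilon_std=0.8
        )
        experiment = simulator.simulate_experiment(config, replicate=0)
        data = BBMData(oligo_set=experiment.oligo_set)
        mc = mcmc.MCMCConfig(
            n_generations=8000, burn_in=3000, thin=5, seed=4, n_chains=1,
            prior_window=100.0,
        )
        bbm_result = mcmc.fit_bbm(data, mc, tf_total=15.0)
        gem_result = mcmc.fit_gem(
            data, mc, tf_total=15.0, optimal_sequence=LEU3_CONSENSUS
        )
        bbm_log = np.log10(bbm_result.samples["kd"])
        gem_log = np.log10(gem_result.samples["kd"])
        diff = np.abs(bbm_log.mean(axis=0) - gem_log.mean(axis=0))
        spread = np.maximum(bbm_log.std(axis=0), gem_log.std(axis=0))
        nonref = np.array(
            [s not in experiment.oligo_set.reference_kds
             for s in experiment.oligo_set.sequences]
        )
        assert np.mean(diff[nonref] < spread[nonref]) >= 0.9
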