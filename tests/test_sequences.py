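"""Markov charge-sequence generation: unbiasedness, run statistics, selection."""

import itertools

import numpy as np
import pytest

from pearlnecklace import (
    ChargeSequence,
    MarkovParams,
    average_block_length,
    generate_ensemble,
    generate_sequence,
    net_charge,
    select_subensemble,
)
from pearlnecklace.sequences import (
    load_sequences,
    n_charge_sites,
    save_sequences,
    sequences_to_csv,
)


class TestSiteConvention:
    @pytest.mark.parametrize("N,p,expected", [(202, 3, 68), (3, 3, 1), (10, 3, 4), (9, 3, 3)])
    def test_site_count(self, N, p, expected):
        assert n_charge_sites(N, p) == expected
        seq = generate_sequence(N, p, "pe", MarkovParams(0.5), seed=0)
        assert seq.n_sites == expected

    def test_sites_start_at_first_monomer(self):
        seq = generate_sequence(10, 3, "pe", seed=0)
        assert list(seq.site_monomer_indices) == [0, 3, 6, 9]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_sequence(2, 3, "pe", seed=0)
        with pytest.raises(ValueError):
            MarkovParams(stay_prob=1.0)
        with pytest.raises(ValueError):
            MarkovParams(stay_prob=0.0)
        with pytest.raises(ValueError):
            generate_sequence(10, 3, "dna", seed=0)


class TestGeneration:
    def test_symbols_per_model(self):
        pe = generate_sequence(202, 3, "pe", seed=1)
        pa = generate_sequence(202, 3, "pa", seed=1)
        assert set(pe.site_values) <= {0, 1}
        assert set(pa.site_values) <= {-1, 1}

    def test_seed_reproducibility(self):
        a = generate_sequence(202, 3, "pe", MarkovParams(0.75), seed=42)
        b = generate_sequence(202, 3, "pe", MarkovParams(0.75), seed=42)
        assert a.site_values == b.site_values

    def test_near_unit_stay_prob_gives_single_block(self):
        seq = generate_sequence(202, 3, "pe", MarkovParams(1.0 - 1e-12), seed=3)
        assert len(set(seq.site_values)) == 1

    def test_marginal_uniform_at_every_site(self, uncorrelated_pe_ensemble, blocky_pe_ensemble):
        # unbiasedness: per-site charge frequency within 4 standard errors of 1/2
        for ens in (uncorrelated_pe_ensemble, blocky_pe_ensemble):
            vals = np.array([s.site_values for s in ens])
            freq = vals.mean(axis=0)
            se = 0.5 / np.sqrt(len(ens))
            assert np.all(np.abs(freq - 0.5) < 4 * se)

    @pytest.mark.parametrize("stay", [0.5, 0.75])
    def test_lag1_autocorrelation(self, stay):
        # adjacent-site correlation of a symmetric two-state chain is 2s - 1
        ens = generate_ensemble(4000, 202, 3, "pe", MarkovParams(stay), seed=9)
        vals = np.array([s.site_values for s in ens], dtype=float) - 0.5
        corr = (vals[:, :-1] * vals[:, 1:]).mean() / 0.25
        assert corr == pytest.approx(2 * stay - 1, abs=0.02)


class TestBlockLength:
    def test_alternating_sequence(self):
        seq = ChargeSequence(model="pe", N=12, p=3, site_values=(0, 1, 0, 1))
        assert average_block_length(seq) == 1.0

    def test_constant_sequence(self):
        seq = ChargeSequence(model="pe", N=12, p=3, site_values=(1, 1, 1, 1))
        assert average_block_length(seq) == 4.0

    @pytest.mark.parametrize("stay,expected,tol", [(0.5, 2.0, 0.1), (0.75, 4.0, 0.2)])
    def test_ensemble_mean_matches_markov_expectation(self, stay, expected, tol):
        ens = generate_ensemble(3000, 202, 3, "pe", MarkovParams(stay), seed=5)
        assert average_block_length(ens) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("stay", [0.5, 0.75])
    def test_exact_enumeration_oracle(self, stay):
        # oracle: enumerate all 2^10 ten-site sequences weighted by their
        # Markov-chain probability.  The expected number of maximal runs is
        # 1 + 9(1-s), so the expected flip count is 9(1-s) and the renewal
        # estimator sum(sites-1)/sum(flips) recovers 1/(1-s) exactly in
        # expectation ratio, while the naive ratio tends to 10/(1 + 9(1-s)).
        n_sites = 10
        e_runs = 0.0
        for bits in itertools.product((0, 1), repeat=n_sites):
            prob = 0.5
            runs = 1
            for a, b in zip(bits[:-1], bits[1:]):
                prob *= stay if a == b else (1.0 - stay)
                runs += a != b
            e_runs += prob * runs
        assert e_runs == pytest.approx(1 + (n_sites - 1) * (1 - stay), abs=1e-12)
        assert (n_sites - 1) / (e_runs - 1) == pytest.approx(1 / (1 - stay), abs=1e-12)
        ens = generate_ensemble(20000, n_sites, 1, "pe", MarkovParams(stay), seed=8)
        naive = average_block_length(ens, estimator="naive")
        assert naive == pytest.approx(n_sites / e_runs, rel=0.03)
        assert average_block_length(ens) == pytest.approx(1 / (1 - stay), rel=0.03)

    def test_block_length_mapping(self):
        assert MarkovParams(0.5).block_length == 2.0
        assert MarkovParams(0.75).block_length == 4.0
        assert MarkovParams.from_block_length(4.0).stay_prob == pytest.approx(0.75)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            average_block_length([])


class TestNetCharge:
    def test_pa_majority_minus_minority(self):
        values = (1,) * 44 + (-1,) * 24
        seq = ChargeSequence(model="pa", N=202, p=3, site_values=values)
        assert net_charge(seq) == 20

    def test_all_neutral_pe(self):
        seq = ChargeSequence(model="pe", N=202, p=3, site_values=(0,) * 68)
        assert net_charge(seq) == 0

    def test_uncorrelated_pe_mean_near_half_sites(self, uncorrelated_pe_ensemble):
        qs = np.array([net_charge(s) for s in uncorrelated_pe_ensemble])
        assert qs.mean() == pytest.approx(34.0, abs=0.5)

    def test_pa_sign_symmetry(self):
        seq = ChargeSequence(model="pa", N=6, p=3, site_values=(-1, -1))
        assert net_charge(seq) == 2


class TestSubensemble:
    def test_exact_selection(self, uncorrelated_pe_ensemble):
        sub = select_subensemble(uncorrelated_pe_ensemble, 22)
        assert sub and all(net_charge(s) == 22 for s in sub)

    def test_infeasible_charge_gives_empty(self, uncorrelated_pe_ensemble):
        assert select_subensemble(uncorrelated_pe_ensemble, 69) == []

    def test_order_preserved(self, uncorrelated_pe_ensemble):
        sub = select_subensemble(uncorrelated_pe_ensemble, 34)
        idx = [uncorrelated_pe_ensemble.index(s) for s in sub]
        assert idx == sorted(idx)

    def test_mixed_models_rejected(self):
        pe = generate_sequence(9, 3, "pe", seed=0)
        pa = generate_sequence(9, 3, "pa", seed=0)
        with pytest.raises(ValueError):
            select_subensemble([pe, pa], 1)

    def test_blocky_subensemble_stays_blocky(self, blocky_pe_ensemble):
        sub = select_subensemble(blocky_pe_ensemble, 34)
        assert len(sub) > 20
        assert average_block_length(sub) > 2.5


class TestSerialization:
    def test_json_roundtrip(self, tmp_path, blocky_pe_ensemble):
        path = tmp_path / "seqs.json"
        save_sequences(blocky_pe_ensemble[:10], path)
        back = load_sequences(path)
        assert [s.site_values for s in back] == \
               [s.site_values for s in blocky_pe_ensemble[:10]]
        assert back[0].stay_prob == 0.75

    def test_csv_export(self, tmp_path):
        seq = generate_sequence(9, 3, "pe", seed=0)
        path = tmp_path / "seqs.csv"
        sequences_to_csv([seq], path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "sequence_index,site_index,monomer_index,value"
        assert len(lines) == 1 + 3
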