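"""Synthetic data generator: determinism, degradation statistics, round trips."""

import numpy as np
import pytest
from scipy import stats

from paleocollagen.consensus import assemble_consensus, concatenate_chains
from paleocollagen.digestion import peptide_mass, mz_from_mass, tryptic_digest
from paleocollagen.pmf import shared_peak_count, top_n_peaks
from paleocollagen.psm import filter_by_hfps, hfps
from paleocollagen.phylo import SubstitutionModel, Tree
from paleocollagen.simulate import (
    SimulationConfig,
    SyntheticDataset,
    degrade_to_specimen,
    mask_to_coverage,
    simulate_alignment,
    simulate_dataset,
    simulate_pmf,
    simulate_yule_tree,
    split_chains,
)


@pytest.fixture(scope="module")
def small_config():
    return SimulationConfig(n_taxa=4, chain_lengths=(120, 100), seed=0,
                            pmf_noise_peaks=5)


class TestYuleTree:
    def test_taxon_count_and_determinism(self):
        t1 = simulate_yule_tree(8, np.random.default_rng(5))
        t2 = simulate_yule_tree(8, np.random.default_rng(5))
        assert len(t1.leaves()) == 8
        assert t1.to_newick() == t2.to_newick()

    def test_mean_branch_length_scaled(self):
        tree = simulate_yule_tree(10, np.random.default_rng(1),
                                  mean_branch_length=0.07,
                                  min_internal_branch=0.0)
        lengths = [n.length for n in tree.postorder() if n.parent is not None]
        assert np.mean(lengths) == pytest.approx(0.07, rel=1e-9)

    def test_internal_branches_floored(self):
        tree = simulate_yule_tree(12, np.random.default_rng(2),
                                  min_internal_branch=0.02)
        for n in tree.postorder():
            if not n.is_leaf and n.parent is not None:
                assert n.length >= 0.02


class TestSimulateAlignment:
    def test_zero_length_branches_copy_parent(self, jtt_model):
        tree = Tree.from_newick("(A:0.0,B:0.0,C:0.0);")
        seqs = simulate_alignment(tree, jtt_model, 200, np.random.default_rng(0))
        assert seqs["A"] == seqs["B"] == seqs["C"]

    def test_same_seed_identical_alignment(self, jtt_model):
        tree = simulate_yule_tree(5, np.random.default_rng(3))
        a = simulate_alignment(tree, jtt_model, 100, np.random.default_rng(9))
        b = simulate_alignment(tree, jtt_model, 100, np.random.default_rng(9))
        assert a == b

    def test_long_branch_approaches_stationarity(self):
        # chi-square composition test of child states against the model's
        # stationary frequencies after a very long branch
        model = SubstitutionModel.jtt(alpha=1.0, p_inv=0.0, k=1)
        tree = Tree.from_newick("(A:0.0,B:20.0);")
        seqs = simulate_alignment(tree, model, 20000, np.random.default_rng(11))
        from paleocollagen.phylo.jtt import AA_ORDER

        counts = np.array([seqs["B"].count(a) for a in AA_ORDER])
        expected = model.frequencies * 20000
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # 19 degrees of freedom; 0.001 quantile ~ 43.8
        assert chi2 < stats.chi2.ppf(0.999, df=19)


class TestDegradeToSpecimen:
    def test_full_coverage_roundtrip_reconstructs_truth(self, small_config):
        rng = np.random.default_rng(0)
        tree = simulate_yule_tree(4, rng)
        seqs = simulate_alignment(tree, small_config.model(),
                                  small_config.concatenated_length, rng)
        l1 = small_config.chain_lengths[0]
        truth = seqs[tree.leaf_labels()[0]]
        truth = truth[:l1] + "R" + truth[l1 + 1:]  # fixed linker convention
        psms = degrade_to_specimen(truth, "sp1", small_config, rng,
                                   coverage_target=1.0)
        targets = [p for p in psms if not p.is_decoy]
        chains = {}
        for chain_id, length in zip(("COL1A1", "COL1A2"),
                                    small_config.chain_lengths):
            matches = [p for p in targets if p.chain_id == chain_id]
            chains[chain_id] = assemble_consensus(matches, length, taxon="t")
        rebuilt = concatenate_chains(chains["COL1A1"], chains["COL1A2"])
        assert rebuilt.residues == truth

    def test_decoys_weaker_and_removed_by_hfps(self, small_config):
        rng = np.random.default_rng(1)
        tree = simulate_yule_tree(4, rng)
        seqs = simulate_alignment(tree, small_config.model(),
                                  small_config.concatenated_length, rng)
        psms = degrade_to_specimen(seqs[tree.leaf_labels()[0]], "sp1",
                                   small_config, rng)
        threshold = hfps(psms)
        kept = filter_by_hfps(psms, threshold)
        assert kept, "filter should retain most genuine matches"
        assert all(not p.is_decoy for p in kept)
        assert all(p.score > threshold for p in kept)

    def test_coverage_near_target(self, small_config):
        rng = np.random.default_rng(2)
        tree = simulate_yule_tree(4, rng)
        seqs = simulate_alignment(tree, small_config.model(),
                                  small_config.concatenated_length, rng)
        truth = seqs[tree.leaf_labels()[0]]
        fractions = []
        for rep in range(5):
            psms = degrade_to_specimen(truth, f"s{rep}", small_config, rng,
                                       coverage_target=0.6)
            covered = set()
            for p in psms:
                if not p.is_decoy:
                    offset = 0 if p.chain_id == "COL1A1" else \
                        small_config.chain_lengths[0] + 1
                    covered.update(range(offset + p.ref_start,
                                         offset + p.ref_end))
            fractions.append(len(covered) / small_config.concatenated_length)
        # union coverage overshoots the per-chain target by at most one peptide
        assert all(0.55 <= f <= 0.72 for f in fractions)


class TestMaskToCoverage:
    def test_masked_fraction_near_target(self, rng):
        seq = "".join(rng.choice(list("GPAKRDENST"), 2000))
        masked = mask_to_coverage(seq, 0.6, rng)
        determined = sum(c != "X" for c in masked) / len(masked)
        assert 0.55 <= determined <= 0.70
        # unmasked positions agree with the original
        assert all(m in ("X", c) for m, c in zip(masked, seq))


class TestSimulatePmf:
    def test_identical_sequences_share_all_peaks(self, small_config):
        rng = np.random.default_rng(3)
        seq = "GPAGKR" * 40
        a = simulate_pmf(seq, small_config, np.random.default_rng(1))
        b = simulate_pmf(seq, small_config, np.random.default_rng(2))
        na = top_n_peaks(a, 100)
        nb = top_n_peaks(b, 100)
        # same theoretical peaks; only intensities and noise differ
        shared = shared_peak_count(na, nb, tol=0.01)
        assert shared >= min(len(na), len(nb)) - 2 * small_config.pmf_noise_peaks

    def test_zero_noise_all_peaks_theoretical(self):
        config = SimulationConfig(n_taxa=4, chain_lengths=(120, 100),
                                  pmf_noise_peaks=0)
        seq = "GPAGFFKNDERGEAGPAGPK" * 10
        pl = simulate_pmf(seq, config, np.random.default_rng(4))
        theoretical = {
            round(mz_from_mass(peptide_mass(p.sequence)), 6)
            for p in tryptic_digest(seq, 1)
        }
        assert set(np.round(pl.mz, 6)) <= theoretical

    def test_single_substitution_shifts_only_affected_peptides(self):
        config = SimulationConfig(n_taxa=4, chain_lengths=(120, 100),
                                  pmf_noise_peaks=0)
        base = "GPAGFFKNDERGEAGPKWWTR" * 8
        mutated = base[:3] + "S" + base[4:]  # inside the first tryptic peptide
        a = simulate_pmf(base, config, np.random.default_rng(5))
        b = simulate_pmf(mutated, config, np.random.default_rng(5))
        peps_a = {p.sequence for p in tryptic_digest(base, 1)}
        peps_b = {p.sequence for p in tryptic_digest(mutated, 1)}
        changed = peps_a ^ peps_b
        expected_changed_mz = {
            round(mz_from_mass(peptide_mass(p)), 4) for p in changed
        }
        diff = set(np.round(a.mz, 4)) ^ set(np.round(b.mz, 4))
        assert diff <= expected_changed_mz


class TestSimulateDataset:
    def test_byte_identical_given_same_config(self, small_config):
        d1 = simulate_dataset(small_config)
        d2 = simulate_dataset(small_config)
        assert d1.tree.to_newick() == d2.tree.to_newick()
        assert d1.true_sequences == d2.true_sequences
        for s in d1.psm_tables:
            assert [(p.peptide, p.score) for p in d1.psm_tables[s]] == \
                [(p.peptide, p.score) for p in d2.psm_tables[s]]
        for t in d1.peak_lists:
            np.testing.assert_array_equal(d1.peak_lists[t].mz,
                                          d2.peak_lists[t].mz)

    def test_fossil_taxa_have_replicate_specimens(self, small_config):
        data = simulate_dataset(small_config)
        assert len(data.fossil_taxa) == small_config.n_fossil_taxa
        for taxon in data.fossil_taxa:
            specimens = [s for s, t in data.specimen_taxon.items() if t == taxon]
            assert len(specimens) == small_config.specimens_per_fossil

    def test_split_chains_inverts_concatenation(self, small_config):
        data = simulate_dataset(small_config)
        seq = next(iter(data.true_sequences.values()))
        chains = split_chains(seq, small_config.chain_lengths)
        assert chains["COL1A1"] + seq[small_config.chain_lengths[0]] + \
            chains["COL1A2"] == seq

    def test_divergence_orders_pmf_and_variation_counts(self):
        # a three-taxon ladder: shared peaks fall and variation counts rise
        # with divergence
        from paleocollagen.consensus import count_variations
        from paleocollagen.pmf import pairwise_shared_matrix

        config = SimulationConfig(n_taxa=3, chain_lengths=(300, 250),
                                  pmf_noise_peaks=0, seed=5)
        rng = np.random.default_rng(5)
        tree = Tree.from_newick("(A:0.01,B:0.08,C:0.4);")
        seqs = simulate_alignment(tree, config.model(),
                                  config.concatenated_length, rng)
        close = count_variations(seqs["A"], seqs["B"])
        far = count_variations(seqs["A"], seqs["C"])
        assert close < far
        pls = {t: simulate_pmf(seqs[t], config, np.random.default_rng(i))
               for i, t in enumerate("ABC")}
        mat = pairwise_shared_matrix(pls, n=100)
        assert mat.loc["A", "B"] > mat.loc["A", "C"]
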