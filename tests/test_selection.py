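import itertools
import math

import numpy as np
import pytest

from immunopop import selection as sel
from immunopop.model import AlleleCatalog, SelectionRow, SiteSelectionTable
from immunopop.simulate import SimulationConfig, simulate_allele_pools


class TestNeiGojobori:
    def test_hand_counted_pair(self):
        p_n, p_s, s_sites, n_sites = sel.neigojobori_pair("TTTGGG", "TTCGGG")
        # TTT has 1/3 synonymous sites, GGG has 1; one synonymous difference
        assert s_sites == pytest.approx(4 / 3)
        assert n_sites == pytest.approx(6 - 4 / 3)
        assert p_s == pytest.approx(0.75)
        assert p_n == 0.0

    def test_identical_sequences(self):
        p_n, p_s, _, _ = sel.neigojobori_pair("ATGAAA", "ATGAAA")
        assert p_n == 0.0 and p_s == 0.0

    def test_symmetry(self):
        a, b = "ATGAAATTTCCC", "ATGAAGTATCCA"
        assert sel.neigojobori_pair(a, b) == pytest.approx(sel.neigojobori_pair(b, a))

    def test_site_counts_sum_to_three_per_codon(self):
        rng = np.random.default_rng(0)
        sense = [c for c in sel.CODONS if sel.AA[sel.CODON_INDEX[c]] != "*"]
        for _ in range(20):
            n = int(rng.integers(2, 8))
            a = "".join(rng.choice(sense, size=n))
            b = "".join(rng.choice(sense, size=n))
            _, _, s_sites, n_sites = sel.neigojobori_pair(a, b)
            assert s_sites + n_sites == pytest.approx(3 * n)

    def test_multistep_pathway_average(self):
        # TTT -> GGT: positions 1 and 2 differ; both pathway orders are
        # nonsynonymous at every step (TTT/F -> GTT/V -> GGT/G and
        # TTT/F -> TGT/C -> GGT/G)
        _, _, _, _ = sel.neigojobori_pair("TTT", "GGT")
        sd = sel.SD_TABLE[sel.CODON_INDEX["TTT"], sel.CODON_INDEX["GGT"]]
        nd = sel.ND_TABLE[sel.CODON_INDEX["TTT"], sel.CODON_INDEX["GGT"]]
        assert sd == pytest.approx(0.0)
        assert nd == pytest.approx(2.0)


class TestCodonZTest:
    def test_sequence_order_invariance_and_reproducibility(self):
        rng = np.random.default_rng(1)
        sense = [c for c in sel.CODONS if sel.AA[sel.CODON_INDEX[c]] != "*"]
        seqs = ["".join(rng.choice(sense, size=30)) for _ in range(5)]
        a = sel.codon_z_test(seqs, reps=200, seed=3)
        b = sel.codon_z_test(list(reversed(seqs)), reps=200, seed=3)
        assert a == pytest.approx(b)
        assert sel.codon_z_test(seqs, reps=200, seed=3) == a

    def test_observed_statistic_matches_brute_force(self):
        seqs = ["ATGAAATTT", "ATGAAATTT", "ATGCGGTAT"]
        dnds, z, _ = sel.codon_z_test(seqs, reps=300, seed=0)
        pn, ps = [], []
        for a, b in itertools.combinations(seqs, 2):
            p_n, p_s, _, _ = sel.neigojobori_pair(a, b)
            pn.append(p_n)
            ps.append(p_s)
        assert dnds == pytest.approx(np.mean(pn) - np.mean(ps))
        assert math.isfinite(z)

    def test_synonymous_only_divergence(self):
        # third-position synonymous changes only
        seqs = ["GGAGGAGGAGGA", "GGTGGAGGAGGG", "GGCGGTGGAGGA", "GGGGGCGGTGGA"]
        dnds, _, p = sel.codon_z_test(seqs, reps=300, seed=1)
        assert dnds < 0
        assert p > 0.5

    def test_power_under_strong_selection(self):
        """Strong positive selection at ~30% of codons is detected in >=90%
        of seeded simulated allele sets."""
        selected = frozenset(range(1, 74, 3))
        hits = 0
        n_runs = 50
        for s in range(n_runs):
            config = SimulationConfig(
                seed=2000 + s,
                selected_codons=selected,
                selected_omega=20.0,
                recombination_breakpoint=None,
            )
            catalog, _ = simulate_allele_pools(config)
            _, _, p = sel.codon_z_test(catalog, reps=300, seed=s)
            hits += p < 0.05
        assert hits >= int(0.9 * n_runs)


class TestSbpScan:
    def test_requires_enough_sequences_and_columns(self):
        with pytest.raises(ValueError):
            sel.sbp_scan(["ACGT" * 20] * 3)
        with pytest.raises(ValueError):
            sel.sbp_scan(["ACGT" * 5] * 6)

    def test_invariant_alignment_unsupported(self):
        result = sel.sbp_scan(["ACGT" * 30] * 6)
        assert not result.supported
        assert result.delta_aicc == 0.0

    def test_loglik_additive_over_segments(self):
        """Scoring both segments on the single tree with the breakpoint at an
        end reproduces the single-tree AICc exactly."""
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGT"), size=120)) for _ in range(6)]
        arr = sel._encode_nucleotides(seqs)
        ids = [f"s{i}" for i in range(6)]
        tree = sel._nj_tree(sel._jc_distance_matrix(arr, slice(0, 120)), ids)
        ll_all, br = sel._tree_loglik(tree, arr, ids, slice(0, 120))
        ll_left, _ = sel._tree_loglik(tree, arr, ids, slice(0, 70))
        ll_right, _ = sel._tree_loglik(tree, arr, ids, slice(70, 120))
        assert ll_left + ll_right == pytest.approx(ll_all)
        ll_empty, _ = sel._tree_loglik(tree, arr, ids, slice(0, 0))
        assert sel._aicc(ll_all + ll_empty, br + 1, 120) == pytest.approx(
            sel._aicc(ll_all, br + 1, 120)
        )

    def test_duplicate_sequence_does_not_move_breakpoint(self):
        from immunopop.simulate import simulate_two_tree_alignment

        rng = np.random.default_rng(7)
        seqs = simulate_two_tree_alignment(20, 150, 150, rng, rate=0.08)
        base = sel.sbp_scan(seqs)
        dup = sel.sbp_scan(seqs + [seqs[0]])
        assert base.supported and dup.supported
        assert abs(dup.best_position - base.best_position) <= 15


def _fitch_oracle_codon_changes(tree, leaf_states):
    """Independent minimal nucleotide-step count per codon column: Sankoff
    over sense codons with unit cost per differing nucleotide."""
    sense = [i for i in range(64) if sel.AA[i] != "*"]
    inf = float("inf")

    def rec(node):
        if node.is_tip():
            state = leaf_states[node.name]
            return {
                s: (0.0 if (state < 0 or s == state) else inf) for s in sense
            }
        child_costs = [rec(c) for c in node.children]
        out = {}
        for s in sense:
            total = 0.0
            for cc in child_costs:
                total += min(
                    cc[t] + sel.NT_DIFF_TABLE[s, t] for t in sense if cc[t] < inf
                )
            out[s] = total
        return out

    costs = rec(tree)
    return min(costs.values())


class TestSlac:
    def test_invariant_site_p_one(self):
        catalog = AlleleCatalog(
            "L",
            {f"a{i}": "ATGAAA" + ("TTT" if i < 2 else "TTC") for i in range(5)},
            codon_mode=True,
        )
        results = sel.slac_sites(catalog)
        by_site = {r.site: r for r in results}
        assert by_site[1].p_value == 1.0
        assert by_site[1].normalized_dn_ds == 0.0

    def test_total_changes_equal_parsimony_length(self):
        config = SimulationConfig(seed=9, recombination_breakpoint=None)
        catalog, _ = simulate_allele_pools(config)
        small = AlleleCatalog(
            catalog.locus_name,
            {a: catalog.sequence(a)[:30] for a in catalog.ids[:10]},
            codon_mode=True,
        )
        ids = small.ids
        seqs = [small.sequence(a) for a in ids]
        arr = sel._encode_nucleotides(seqs)
        enc = np.vstack([sel._encode_codons(s) for s in seqs])
        tree = sel._nj_tree(
            sel._jc_distance_matrix(arr, slice(0, arr.shape[1])), ids
        )
        results = sel.slac_sites(small)
        for r in results:
            leaf_states = {name: int(enc[i, r.site - 1]) for i, name in enumerate(ids)}
            oracle = _fitch_oracle_codon_changes(tree, leaf_states)
            assert r.syn_changes + r.nonsyn_changes == pytest.approx(oracle)

    def test_recovery_of_selected_sites(self):
        """Sites under strong positive selection are recovered (>=3 of 5 at
        p<0.05) in >=80% of seeded simulations."""
        targets = frozenset({10, 20, 30, 40, 50})
        n_runs = 50
        recovered = 0
        for s in range(n_runs):
            config = SimulationConfig(
                seed=300 + s,
                tree_scale=0.10,
                selected_codons=targets,
                selected_omega=10.0,
                recombination_breakpoint=None,
            )
            catalog, _ = simulate_allele_pools(config)
            sig = {r.site for r in sel.slac_sites(catalog) if r.p_value < 0.05}
            recovered += len(sig & targets) >= 3
        assert recovered >= int(0.8 * n_runs)

    def test_breakpoint_splits_codon_assignment(self):
        config = SimulationConfig(seed=5, recombination_breakpoint=None)
        catalog, _ = simulate_allele_pools(config)
        whole = sel.slac_sites(catalog)
        split = sel.slac_sites(catalog, breakpoint=111)
        assert len(whole) == len(split) == config.n_codons


class TestConsensus:
    def test_single_model_excluded(self):
        table = SiteSelectionTable(
            [SelectionRow(7, "MEME", "beta2", 3.1, "p_value", 0.031)]
        )
        assert sel.consensus_selected_sites(table) == set()

    def test_slac_plus_rel_included(self):
        table = SiteSelectionTable(
            [
                SelectionRow(52, "SLAC", "dnds", 7.18, "p_value", 0.002),
                SelectionRow(52, "REL", "e_dnds", 7.49, "bayes_factor", 1.57e6),
            ]
        )
        assert sel.consensus_selected_sites(table) == {52}

    def test_threshold_relaxation_is_monotone(self, published_selection_table):
        strict = sel.consensus_selected_sites(
            published_selection_table, slac_p=0.01, rel_bf=1000, meme_p=0.01
        )
        loose = sel.consensus_selected_sites(
            published_selection_table, slac_p=0.05, rel_bf=100, meme_p=0.05
        )
        loosest = sel.consensus_selected_sites(
            published_selection_table,
            slac_p=0.2,
            rel_bf=10,
            meme_p=0.2,
            min_models=1,
        )
        assert strict <= loose <= loosest

    def test_duplicate_model_rows_count_once(self):
        table = SiteSelectionTable(
            [
                SelectionRow(3, "MEME", "beta2", 1.0, "p_value", 0.01),
                SelectionRow(3, "MEME", "beta2", 2.0, "p_value", 0.02),
            ]
        )
        assert sel.consensus_selected_sites(table) == set()
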