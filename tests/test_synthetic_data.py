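"""Planted-truth generators: determinism, decoy placement, ER simulation,
toy structures."""

from io import StringIO

import numpy as np
import pytest

from dicer_atlas import synthetic_data as sd
from dicer_atlas.structure_metrics import parse_pdb, mean_plddt


class TestHitTableGenerator:
    def test_same_seed_gives_byte_identical_tables(self):
        config = sd.SimulationConfig(seed=5, n_proteins=40)
        hits1, truth1 = sd.generate_hit_table(config)
        hits2, truth2 = sd.generate_hit_table(config)
        assert hits1.equals(hits2) and truth1.equals(truth2)
        lengths = dict(zip(truth1.protein_id, truth1.protein_length))
        bufs = []
        for hits in (hits1, hits2):
            buf = StringIO()
            sd.write_domtblout(hits, lengths, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_canonical_protein_carries_all_eight_domains(self):
        config = sd.SimulationConfig(
            seed=3, n_proteins=1,
            category_mix={"canonical": 1.0})
        hits, truth = sd.generate_hit_table(config)
        planted = hits[hits.evalue <= 1e-3]
        assert truth.category.iloc[0] == "canonical"
        assert len(planted) == 8
        assert sorted(planted.domain_label) == sorted(
            ["DEAD", "ResIII", "HeliC", "DUF283", "PAZ",
             "RNaseIII", "RNaseIII", "dsRBD"])

    def test_decoys_are_above_threshold_and_never_overlap_planted(self):
        config = sd.SimulationConfig(seed=9, n_proteins=80, decoy_hit_mean=2.0)
        hits, _ = sd.generate_hit_table(config)
        decoys = hits[hits.evalue > 1e-3]
        planted = hits[hits.evalue <= 1e-3]
        assert len(decoys) > 0
        for d in decoys.itertuples(index=False):
            mine = planted[planted.protein_id == d.protein_id]
            overlap = (mine.start <= d.end) & (d.start <= mine.end)
            assert not overlap.any()

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError, match="n_proteins"):
            sd.SimulationConfig(n_proteins=0)
        with pytest.raises(ValueError, match="sums"):
            sd.SimulationConfig(category_mix={"canonical": 0.4, "D": 0.4})

    def test_architecture_spec_invariants(self):
        with pytest.raises(ValueError, match="overlapping"):
            sd.ArchitectureSpec("p", "D", 500,
                                [("DUF283", 10, 100), ("RNaseIII", 90, 200)])
        with pytest.raises(ValueError, match="outside"):
            sd.ArchitectureSpec("p", "D", 100, [("DUF283", 10, 200)])


class TestCharacterSimulation:
    def test_zero_rate_freezes_root_state(self):
        tree = sd.random_yule_tree(30, 4)
        states = sd.simulate_binary_character(tree, 0.0, 7)
        assert len(set(states.values())) == 1

    def test_negative_rate_rejected(self):
        tree = sd.random_yule_tree(5, 1)
        with pytest.raises(ValueError):
            sd.simulate_binary_character(tree, -1.0, 0)

    def test_high_rate_long_branches_reach_stationary_uniform(self):
        """At qt >> 1 the tip distribution is the ER stationary (1/2, 1/2)."""
        import dendropy
        newick = "(" + ",".join(f"t{i}:5.0" for i in range(10)) + ");"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        freqs = []
        for rep in range(1000):
            states = sd.simulate_binary_character(tree, 100.0, rep)
            freqs.extend(states.values())
        freq1 = np.mean(freqs)
        se = np.sqrt(0.25 / len(freqs))
        assert abs(freq1 - 0.5) < 4 * se

    @pytest.mark.parametrize("t", [0.25, 1.0, 3.0])
    def test_per_branch_flip_rate_matches_closed_form(self, t):
        """Over 10^4 simulated branches the flip frequency matches
        (1 - exp(-2 q t)) / 2 within 3 binomial standard errors."""
        import dendropy
        q = 0.5
        tree = dendropy.Tree.get(data=f"(a:{t},b:0.0);", schema="newick")
        n = 10_000
        flips = 0
        for rep in range(n):
            states = sd.simulate_binary_character(tree, q, rep)
            flips += states["a"] != states["b"]  # b:0.0 carries the root state
        expected = (1.0 - np.exp(-2.0 * q * t)) / 2.0
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(flips / n - expected) <= 3 * se

    def test_simulation_is_seed_deterministic(self):
        tree = sd.random_yule_tree(25, 8)
        assert (sd.simulate_binary_character(tree, 0.5, 42)
                == sd.simulate_binary_character(tree, 0.5, 42))


class TestSimilarityTableGenerator:
    def test_plan_determines_nodes_and_is_deterministic(self):
        plan = [(4, 70.0, 20.0), (3, 60.0, 20.0)]
        table1, planted1 = sd.generate_similarity_table(plan, 13)
        table2, planted2 = sd.generate_similarity_table(plan, 13)
        assert table1.equals(table2) and planted1 == planted2
        assert len(planted1) == 7
        within = table1[[a.split("_")[0] == b.split("_")[0]
                         for a, b in zip(table1.id_a, table1.id_b)]]
        assert (within.identity >= 59.0).all()


class TestToyStructures:
    def test_three_four_five_triangle(self):
        segments = [sd.SegmentPlan("PAZ", 1, 10, (0.0, 0.0, 0.0)),
                    sd.SegmentPlan("RNaseIIIa", 50, 60, (3.0, 4.0, 0.0))]
        text = sd.generate_toy_structure(segments)
        structure = parse_pdb(text)
        from dicer_atlas.structure_metrics import ResidueInterval, ruler_distance
        d = ruler_distance(structure,
                           ResidueInterval("PAZ", 1, 10),
                           ResidueInterval("RNaseIIIa", 50, 60))
        assert d == pytest.approx(5.0, abs=1e-6)

    def test_constant_plddt_average(self):
        segments = [sd.SegmentPlan("core", 1, 20, (0.0, 0.0, 0.0))]
        structure = parse_pdb(sd.generate_toy_structure(segments, plddt_plan=80.0))
        assert mean_plddt(structure) == pytest.approx(80.0)

    def test_round_trip_recovers_planted_anchors_and_plddt(self):
        segments = [sd.SegmentPlan("A", 1, 5, (1.25, -2.5, 3.75)),
                    sd.SegmentPlan("B", 10, 14, (10.0, 20.0, -30.0),
                                   direction=(0.0, 1.0, 0.0))]
        plddt = {"A": 91.5, "B": 64.25}
        structure = parse_pdb(sd.generate_toy_structure(segments, plddt))
        chain = next(iter(next(iter(structure))))
        for seg in segments:
            first = chain[seg.start]["CA"]
            np.testing.assert_allclose(first.coord, seg.anchor, atol=1e-3)
            assert first.bfactor == pytest.approx(plddt[seg.label], abs=0.005)
            # residues laid out at the planted spacing
            second = chain[seg.start + 1]["CA"]
            assert np.linalg.norm(second.coord - first.coord) == pytest.approx(
                seg.spacing, abs=1e-3)

    def test_malformed_plans_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            sd.generate_toy_structure([])
        with pytest.raises(ValueError, match="sorted"):
            sd.generate_toy_structure(
                [sd.SegmentPlan("A", 10, 20, (0, 0, 0)),
                 sd.SegmentPlan("B", 15, 30, (1, 1, 1))])
        with pytest.raises(ValueError, match="pLDDT"):
            sd.generate_toy_structure(
                [sd.SegmentPlan("A", 1, 5, (0, 0, 0))], plddt_plan={"X": 80})
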