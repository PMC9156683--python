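"""Simulator contracts: Yule ages, dispersal signal, perturbation, fossils."""

import numpy as np
import pytest

from biogeofit.phylo import PhyloTree
from biogeofit.synthetic import (
    SimulationConfig, default_stage_table, generate_paired_study,
    perturb_tree, simulate_biogeography, simulate_fossil_record,
    simulate_yule_tree,
)


def rf_distance(a: PhyloTree, b: PhyloTree) -> int:
    return len(a.bipartitions() ^ b.bipartitions())


class TestYule:
    def test_structure_and_ages(self):
        tree = simulate_yule_tree(6, 1.0, np.random.default_rng(0))
        assert tree.n_leaves == 6
        assert len(tree.internal_nodes()) == 5
        for node in tree.internal_nodes():
            for child in node.children:
                age = child.age if child.age is not None else 0.0
                assert node.age >= age
        assert all(leaf.age == 0.0 for leaf in tree.leaves())

    def test_determinism(self):
        a = simulate_yule_tree(8, 0.5, np.random.default_rng(42))
        b = simulate_yule_tree(8, 0.5, np.random.default_rng(42))
        assert a.to_newick() == b.to_newick()
        assert a.root.age == b.root.age

    def test_mean_root_age_matches_expectation(self):
        """E[root age] = Σ_{k=2..n} 1/(kλ) for the forward pure-birth process."""
        n, lam, reps = 6, 1.0, 500
        rng = np.random.default_rng(7)
        ages = [simulate_yule_tree(n, lam, rng).root.age for _ in range(reps)]
        expected = sum(1 / (k * lam) for k in range(2, n + 1))
        # var of a sum of independent Exp(k*lam)
        var = sum(1 / (k * lam) ** 2 for k in range(2, n + 1))
        assert abs(np.mean(ages) - expected) < 3 * np.sqrt(var / reps)


class TestBiogeography:
    def test_zero_rates_single_region(self):
        rng = np.random.default_rng(1)
        tree = simulate_yule_tree(6, 0.5, rng)
        config = SimulationConfig(n_taxa=6, dispersal_rate=0.0,
                                  extirpation_rate=0.0, seed=1)
        m = simulate_biogeography(tree, config, rng)
        assert m.n_regions == 1
        assert (m.entries == 1).all()

    def test_occupancy_grows_with_dispersal(self):
        occupancies = []
        for d in (0.05, 0.3, 1.0):
            rng = np.random.default_rng(9)
            total = 0.0
            for _ in range(10):
                tree = simulate_yule_tree(8, 0.3, rng)
                config = SimulationConfig(n_taxa=8, dispersal_rate=d,
                                          extirpation_rate=0.05, seed=1)
                m = simulate_biogeography(tree, config, rng)
                total += m.entries.sum(axis=1).mean()
            occupancies.append(total / 10)
        assert occupancies[0] < occupancies[1] < occupancies[2]

    def test_every_taxon_occupies_somewhere(self):
        rng = np.random.default_rng(3)
        tree = simulate_yule_tree(10, 0.2, rng)
        config = SimulationConfig(n_taxa=10, dispersal_rate=0.5,
                                  extirpation_rate=0.4, seed=1)
        m = simulate_biogeography(tree, config, rng)
        assert (m.entries.sum(axis=1) >= 1).all()


class TestPerturbTree:
    def test_identity_when_no_moves(self):
        rng = np.random.default_rng(0)
        tree = simulate_yule_tree(8, 0.5, rng)
        out = perturb_tree(tree, 0, 0.0, rng)
        assert out.bipartitions() == tree.bipartitions()

    def test_single_nni_changes_one_bipartition(self):
        rng = np.random.default_rng(5)
        tree = simulate_yule_tree(6, 0.5, rng)
        out = perturb_tree(tree, 1, 0.0, rng)
        assert sorted(out.leaf_labels) == sorted(tree.leaf_labels)
        assert rf_distance(tree, out) in (0, 2)  # one edge rearranged

    def test_rf_increases_with_nni_dose(self):
        rng = np.random.default_rng(11)
        mean_rf = []
        for n_nni in (0, 2, 8):
            total = 0
            for _ in range(60):
                tree = simulate_yule_tree(10, 0.5, rng)
                total += rf_distance(tree, perturb_tree(tree, n_nni, 0.0, rng))
            mean_rf.append(total / 60)
        assert mean_rf[0] == 0.0
        assert mean_rf[0] < mean_rf[1] < mean_rf[2]

    def test_collapse_creates_polytomies(self):
        rng = np.random.default_rng(2)
        tree = simulate_yule_tree(12, 0.5, rng)
        out = perturb_tree(tree, 0, 1.0, rng)
        assert len(out.internal_nodes()) == 1  # everything collapsed to a star
        assert sorted(out.leaf_labels) == sorted(tree.leaf_labels)


class TestFossils:
    def test_zero_rate_no_records(self):
        rng = np.random.default_rng(0)
        tree = simulate_yule_tree(6, 0.5, rng)
        fossils = simulate_fossil_record(tree, 0.0, None, rng)
        assert fossils.coverage == 0.0

    def test_high_rate_full_coverage_near_origin(self):
        rng = np.random.default_rng(1)
        tree = simulate_yule_tree(6, 0.5, rng)
        fossils = simulate_fossil_record(tree, 200.0, None, rng)
        assert fossils.coverage == 1.0
        origin = {leaf.label: leaf.parent.age for leaf in tree.leaves()}
        for taxon, fad in fossils.fad_age.items():
            assert fad <= tree.root.age + 1e-9
            # dense preservation: FAD falls close beneath the lineage origin
            assert fad >= origin[taxon] * 0.5

    def test_event_count_matches_poisson_expectation(self):
        """Mean records per tip ~ Bernoulli(1 - exp(-psi * path)) over replicates."""
        rng = np.random.default_rng(5)
        psi, reps = 0.05, 400
        covered, expected = 0, 0.0
        for _ in range(reps):
            tree = simulate_yule_tree(4, 0.2, rng)
            for leaf in tree.leaves():
                path = tree.root.age  # ultrametric: every tip path spans root age
                expected += 1 - np.exp(-psi * path)
            fossils = simulate_fossil_record(tree, psi, None, rng)
            covered += len(fossils.fad_age)
        sd = np.sqrt(expected)  # Poisson-binomial upper bound
        assert abs(covered - expected) < 4 * sd

    def test_stage_snapping(self):
        rng = np.random.default_rng(8)
        tree = simulate_yule_tree(6, 0.2, rng)
        stages = default_stage_table(oldest=max(60.0, tree.root.age * 2))
        fossils = simulate_fossil_record(tree, 0.5, stages, rng)
        for taxon, stage in fossils.fad_stage.items():
            assert fossils.fad_age[taxon] == stages.base_age(stage)


class TestPairedStudy:
    def test_bundle_satisfies_consumer_invariants(self):
        config = SimulationConfig(n_taxa=10, seed=33, n_clades=3)
        bundles = generate_paired_study(config)
        assert len(bundles) == 3
        for b in bundles:
            assert sorted(b.molecular_tree.leaf_labels) == sorted(
                b.morphological_tree.leaf_labels) == sorted(b.true_tree.leaf_labels)
            assert sorted(b.matrix.taxa) == sorted(b.true_tree.leaf_labels)
            assert (b.matrix.entries.sum(axis=1) >= 1).all()
            b.molecular_tree.validate()
            b.morphological_tree.validate()

    def test_seed_reproducibility(self):
        a = generate_paired_study(SimulationConfig(n_taxa=8, seed=5, n_clades=2))
        b = generate_paired_study(SimulationConfig(n_taxa=8, seed=5, n_clades=2))
        for x, y in zip(a, b):
            assert x.molecular_tree.to_newick() == y.molecular_tree.to_newick()
            assert x.morphological_tree.to_newick() == y.morphological_tree.to_newick()
            assert (x.matrix.entries == y.matrix.entries).all()
            assert x.fossils.fad_age == y.fossils.fad_age

    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            generate_paired_study(SimulationConfig(n_taxa=8, n_clades=1))

    def test_written_bundle_roundtrips(self, tmp_path):
        from biogeofit.phylo import parse_newick
        from biogeofit.regions import RegionMatrix

        config = SimulationConfig(n_taxa=8, seed=21, n_clades=1)
        (bundle,) = generate_paired_study(config, out_dir=tmp_path)
        mol = parse_newick((tmp_path / "clade001_molecular.nwk").read_text())
        assert mol.bipartitions() == bundle.molecular_tree.bipartitions()
        m = RegionMatrix.from_csv(tmp_path / "clade001_matrix.csv")
        assert (m.entries == bundle.matrix.entries).all()
        m2 = RegionMatrix.from_nexus(tmp_path / "clade001_matrix.nex")
        assert (m2.entries == bundle.matrix.entries).all()

    def test_config_file_roundtrip(self, tmp_path):
        text = "n_taxa = 12\nseed = 3\nnni_morphological = 4\ndispersal_rate = 0.2\n"
        path = tmp_path / "sim.cfg"
        path.write_text(text)
        config = SimulationConfig.from_file(path)
        assert (config.n_taxa, config.seed, config.nni_morphological,
                config.dispersal_rate) == (12, 3, 4, 0.2)
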