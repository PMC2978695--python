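"""Synthetic ontologies, planted networks, annotations, and locus sets."""

import numpy as np
import pytest

from phenonet.enrichment import genes_in_loci
from phenonet.evaluation import auprc, precision_recall_curve
from phenonet.ontology import GoldStandard
from phenonet.predict import summed_weight_score
from phenonet.synthetic import (
    SyntheticConfig,
    generate_annotations,
    generate_gene_positions,
    generate_loci,
    generate_ontology,
    generate_planted_network,
    ontology_leaves,
)


class TestGenerateOntology:
    def test_depth_one_branching_three(self):
        dag = generate_ontology(1, 3)
        assert len(dag.terms) == 4
        assert len(dag.roots) == 1

    def test_every_leaf_reaches_root(self):
        dag = generate_ontology(3, 2)
        (root,) = dag.roots
        for leaf in ontology_leaves(dag):
            assert root in dag.ancestors(leaf)

    def test_diamond_adds_one_multiparent_term(self):
        tree = generate_ontology(2, 2)
        dag = generate_ontology(2, 2, diamond=True)
        assert len(dag.terms) == len(tree.terms) + 1
        multi = [t for t, ps in dag.parents.items() if len(ps) > 1]
        assert len(multi) == 1


class TestPlantedNetwork:
    def test_within_module_weights_exceed_background(self):
        cfg = SyntheticConfig(seed=42)
        planted = generate_planted_network(cfg)
        net = planted.network
        within = []
        for members in planted.membership.values():
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    within.append(net.weight(a, b))
        module_set = {g for m in planted.membership.values() for g in m}
        bg_weights = [w for a, b, w in net.edges()
                      if a not in module_set and b not in module_set]
        assert np.mean(within) > np.mean(bg_weights)
        assert np.mean(within) > 0.7
        assert np.mean(bg_weights) < 0.2

    def test_no_hub_concentration_without_hubs(self):
        cfg = SyntheticConfig(seed=7, hub_count=0)
        planted = generate_planted_network(cfg)
        module_set = {g for m in planted.membership.values() for g in m}
        degree: dict[str, int] = {}
        for a, b, _ in planted.network.edges():
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        cap = cfg.n_genes * cfg.background_edge_density * 3
        for g, d in degree.items():
            if g not in module_set:
                assert d <= cap

    def test_hubs_connect_to_everything(self):
        cfg = SyntheticConfig(seed=3, hub_count=5)
        planted = generate_planted_network(cfg)
        assert len(planted.hubs) == 5
        others = [g for g in planted.network.genes if g not in planted.hubs][:50]
        for h in planted.hubs:
            weights = [planted.network.weight(h, g) for g in others]
            assert np.mean(weights) > 0.5
            assert min(weights) > 0.0

    def test_same_seed_identical_edge_list(self):
        cfg = SyntheticConfig(seed=11, n_genes=200, module_count=2, module_size=20)
        e1 = generate_planted_network(cfg).network.edges()
        e2 = generate_planted_network(cfg).network.edges()
        assert e1 == e2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_genes=100, module_count=5, module_size=30)


class TestGenerateAnnotations:
    @pytest.fixture
    def setup(self):
        cfg = SyntheticConfig(seed=5, n_genes=300, module_count=3, module_size=40)
        planted = generate_planted_network(cfg)
        dag = generate_ontology(2, 2)
        return planted, dag

    def test_zero_holdout_annotates_every_member(self, setup):
        planted, dag = setup
        annots, held_out = generate_annotations(planted.membership, dag, 0.0, seed=1)
        assert all(not h for h in held_out.values())
        annotated = {g for g, _, _ in annots.records}
        assert annotated == {g for m in planted.membership.values() for g in m}

    def test_heldout_and_annotated_partition_each_module(self, setup):
        planted, dag = setup
        annots, held_out = generate_annotations(planted.membership, dag, 0.4, seed=1)
        leaves = ontology_leaves(dag)
        for leaf, (_, members) in zip(leaves, sorted(planted.membership.items())):
            annotated = annots.genes_for_term(leaf)
            assert annotated | held_out[leaf] == set(members)
            assert not annotated & held_out[leaf]
            assert len(annotated) >= 1

    def test_holdout_binomially_plausible(self, setup):
        planted, dag = setup
        annots, _ = generate_annotations(planted.membership, dag, 0.4, seed=2)
        leaves = ontology_leaves(dag)
        counts = [len(annots.genes_for_term(l)) for l in leaves[:3]]
        # 40 members, keep prob 0.6 -> mean 24, sd ~3.1; allow 4 sd
        for c in counts:
            assert abs(c - 24) < 13

    def test_full_holdout_is_error(self, setup):
        planted, dag = setup
        with pytest.raises(ValueError):
            generate_annotations(planted.membership, dag, 1.0, seed=1)


class TestGenerateLoci:
    def test_coverage_within_tolerance(self):
        genes = [f"G{i:04d}" for i in range(500)]
        positions = generate_gene_positions(genes)
        loci = generate_loci(positions, coverage=0.83, seed=9)
        frac = len(genes_in_loci(positions, loci)) / len(genes)
        assert 0.81 <= frac <= 0.85

    def test_near_total_coverage_caps_to_whole_chromosomes(self):
        genes = [f"G{i:04d}" for i in range(100)]
        positions = generate_gene_positions(genes)
        loci = generate_loci(positions, coverage=0.999, seed=1)
        assert len(genes_in_loci(positions, loci)) == len(genes)

    def test_same_seed_identical_loci(self):
        genes = [f"G{i:04d}" for i in range(300)]
        positions = generate_gene_positions(genes)
        assert generate_loci(positions, 0.5, seed=4) == generate_loci(positions, 0.5, seed=4)


def test_planted_signal_is_learnable_by_summed_weight():
    """Sanity floor: held-out members rank above prevalence even for the
    naive baseline under default generator settings."""
    cfg = SyntheticConfig(seed=21)
    planted = generate_planted_network(cfg)
    net = planted.network
    dag = generate_ontology(2, 3)
    annots, held_out = generate_annotations(planted.membership, dag, 0.4, seed=22)
    leaf = sorted(held_out)[0]
    observed = annots.genes_for_term(leaf)
    sv = summed_weight_score(net, observed, net.genes)
    eval_genes = frozenset(net.genes) - observed
    from phenonet.predict import ScoreVector
    gold = GoldStandard(term=leaf, positives=held_out[leaf],
                        negatives=eval_genes - held_out[leaf])
    restricted = ScoreVector(scores={g: sv[g] for g in eval_genes},
                             provenance="summed_weight")
    assert auprc(precision_recall_curve(restricted, gold)) > gold.prevalence
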