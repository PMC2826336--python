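"""Generator contracts: determinism, planted fractions, noise-free limit."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from chillregnet.expression_calls import call_upregulated
from chillregnet.motif_discovery import iupac_to_set
from chillregnet.synthetic_data import (
    ConfigurationError,
    PlantedMotif,
    SimulationConfig,
    generate_gene_universe,
    generate_study,
    load_bundle,
    simulate_promoters,
    simulate_timecourse,
    write_bundle,
)


def contains_pattern(seq, pattern):
    """Literal IUPAC match on either strand."""
    from chillregnet.motif_discovery import reverse_complement

    sets = [iupac_to_set(s) for s in pattern]
    for target in (seq, reverse_complement(seq)):
        for off in range(len(target) - len(pattern) + 1):
            if all(target[off + j] in s for j, s in enumerate(sets)):
                return True
    return False


class TestUniverse:
    def test_determinism(self):
        cfg = SimulationConfig(seed=7, n_genes=500)
        u1 = generate_gene_universe(cfg)
        u2 = generate_gene_universe(cfg)
        assert u1.equals(u2)

    def test_tf_count_within_binomial_ci(self):
        cfg = SimulationConfig(seed=1, n_genes=2604, tf_fraction=0.06)
        n_tf = int(generate_gene_universe(cfg)["is_tf"].sum())
        lo, hi = stats.binom.interval(0.999, 2604, 0.06)
        assert lo <= n_tf <= hi  # ~148 expected

    def test_zero_tf_fraction(self):
        cfg = SimulationConfig(seed=1, n_genes=200, tf_fraction=0.0)
        u = generate_gene_universe(cfg)
        assert not u["is_tf"].any()
        assert (u.loc[~u["is_tf"], "tf_family"] == "").all()

    def test_tf_families_from_known_set(self):
        u = generate_gene_universe(SimulationConfig(seed=3, n_genes=800))
        fams = set(u.loc[u["is_tf"], "tf_family"])
        assert fams <= {"bZIP", "AP2/ERF", "MYB", "WRKY", "bHLH", "NAC"}

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=-5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(phase_mixture=(0.5, 0.5, 0.5))
        with pytest.raises(ConfigurationError):
            SimulationConfig(noise_sd=-0.1)
        with pytest.raises(ConfigurationError):
            SimulationConfig(chilling_timepoints=(2, 2, 4))


class TestTimecourse:
    def test_default_phase_mixture_realized(self, small_bundle):
        phases = list(small_bundle.truth.gene_phase.values())
        frac1 = phases.count(1) / len(phases)
        assert 0.6 < frac1 < 0.8  # mixture centred on 71%

    def test_noise_free_calls_recover_truth(self, small_config):
        cfg = dataclasses.replace(small_config, noise_sd=0.0)
        u = generate_gene_universe(cfg)
        chilling, _h2o2, truth = simulate_timecourse(u, cfg)
        called = {c.gene for c in call_upregulated(chilling)}
        assert called == truth.up_genes

    def test_pure_phase1_mixture(self):
        cfg = SimulationConfig(
            n_genes=300, phase_mixture=(1.0, 0.0, 0.0), n_clusters=4,
            cluster_phase_counts=(4, 0, 0),
            per_cluster_h2o2_fraction=(0.5, 0.5, 0.5, 0.5), seed=9,
        )
        u = generate_gene_universe(cfg)
        _c, _h, truth = simulate_timecourse(u, cfg)
        assert set(truth.gene_phase.values()) == {1}

    def test_pvalues_in_unit_interval(self, small_bundle):
        pv = small_bundle.chilling.pvalues.to_numpy()
        assert pv.min() >= 0 and pv.max() <= 1


class TestPromoters:
    def test_rate_one_places_pattern_everywhere(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            planted_motifs=tuple(
                PlantedMotif("TGACGTCA", i, 1.0, "as1/ocs/TGA-like",
                             "as1/ocs/TGA-like", "bZIP")
                for i in range(small_config.n_clusters)
            ),
        )
        u = generate_gene_universe(cfg)
        _c, _h, truth = simulate_timecourse(u, cfg)
        promoters = simulate_promoters(u, truth, cfg)
        for gene in truth.gene_cluster:
            assert contains_pattern(promoters.sequences[gene], "TGACGTCA")

    def test_realized_rate_within_binomial_ci(self, small_bundle):
        truth = small_bundle.truth
        cfg = small_bundle.config
        label = truth.cluster_labels[0]
        members = [g for g, c in truth.gene_cluster.items() if c == label]
        pattern = cfg.motifs()[0].pattern
        n_hit = sum(
            contains_pattern(small_bundle.promoters.sequences[g], pattern)
            for g in members
        )
        lo, hi = stats.binom.interval(0.99, len(members), cfg.motifs()[0].rate)
        # chance background occurrences can only push the count up
        assert lo <= n_hit <= len(members)

    def test_pattern_longer_than_promoter_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                promoter_length=6,
                planted_motifs=(PlantedMotif("TGACGTCA", 0, 0.5),),
            )

    def test_promoter_lengths(self, small_bundle):
        lengths = {len(s) for s in small_bundle.promoters.sequences.values()}
        assert lengths == {small_bundle.config.promoter_length}


class TestBundle:
    def test_bundle_roundtrip_and_determinism(self, small_config, tmp_path):
        b1 = generate_study(small_config)
        b2 = generate_study(small_config)
        d1 = write_bundle(b1, tmp_path / "a")
        d2 = write_bundle(b2, tmp_path / "b")
        import json

        m1 = json.loads((d1 / "manifest.json").read_text())
        m2 = json.loads((d2 / "manifest.json").read_text())
        assert m1 == m2  # byte-identical artifacts for a fixed seed

        loaded = load_bundle(d1)
        assert loaded.chilling.ratios.shape == b1.chilling.ratios.shape
        np.testing.assert_allclose(
            loaded.chilling.ratios.to_numpy(),
            b1.chilling.ratios.to_numpy(),
            rtol=1e-5,
        )
        assert loaded.truth.up_genes == b1.truth.up_genes
        assert loaded.truth.gene_cluster == b1.truth.gene_cluster
        assert loaded.promoters.sequences == b1.promoters.sequences
        assert loaded.qtl.equals(b1.qtl)

    def test_every_clustered_gene_has_one_cluster(self, small_bundle):
        truth = small_bundle.truth
        assert set(truth.gene_cluster.values()) <= set(truth.cluster_labels)
        assert set(truth.gene_cluster) <= truth.up_genes


class TestQTLPlanting:
    def test_factor_five_gives_power(self):
        from chillregnet.qtl_enrichment import colocalize_genes, fisher_enrichment
        from chillregnet.synthetic_data import simulate_qtl_map

        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            cfg = SimulationConfig(n_genes=2000, seed=seed, qtl_enrichment_factor=5.0)
            u = generate_gene_universe(cfg)
            _c, _h, truth = simulate_timecourse(u, cfg)
            qtl, u = simulate_qtl_map(u, cfg, truth)
            assoc = colocalize_genes(u, qtl)
            tf_up = set(u.loc[u["is_tf"], "gene_id"]) & truth.up_genes
            res = fisher_enrichment(tf_up, set(u["gene_id"]), assoc, alpha=0.25)
            hits += res.enriched
        assert hits >= 0.95 * n_seeds

    def test_no_qtl_no_associations(self):
        import pandas as pd

        from chillregnet.qtl_enrichment import colocalize_genes

        u = generate_gene_universe(SimulationConfig(seed=2, n_genes=50))
        empty = pd.DataFrame(columns=["trait", "chrom", "start", "end"])
        assert colocalize_genes(u, empty).empty
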