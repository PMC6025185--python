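"""Synthetic fixture generator: determinism, parseability and known rates."""

import numpy as np
import pytest

from gofuse import pipeline
from gofuse.config import RunConfig
from gofuse.homolog import filter_homologs, score_homolog
from gofuse.interpro import score_interpro
from gofuse.ontology import propagate
from gofuse.simulate import (
    FixtureConfig, FixtureConfigError, analytic_bin_lrs,
    binned_calibration_sample, generate,
)
from gofuse.structural import filter_neighbors, score_structural


class TestDeterminismAndValidity:
    def test_same_seed_gives_byte_identical_bundle(self):
        a = generate(FixtureConfig(seed=11))
        b = generate(FixtureConfig(seed=11))
        assert a.files.keys() == b.files.keys()
        for k in a.files:
            assert a.files[k] == b.files[k], k

    def test_different_seed_differs(self):
        a = generate(FixtureConfig(seed=11))
        b = generate(FixtureConfig(seed=12))
        assert a.files["gold.gaf"] != b.files["gold.gaf"]

    def test_all_files_round_trip_through_readers(self, bundle, bundle_dir):
        inputs = pipeline.load_inputs(bundle_dir)
        assert len(inputs.domains) == bundle.config.n_domains
        assert inputs.gold.total_annotations() > 0
        assert len(inputs.profiles) > 0

    def test_gold_is_true_path_closed(self, bundle):
        again = propagate(bundle.gold, bundle.ontology)
        assert again.entries == bundle.gold.entries

    def test_infeasible_config_rejected(self):
        with pytest.raises(FixtureConfigError):
            generate(FixtureConfig(n_terms=5))
        with pytest.raises(FixtureConfigError):
            generate(FixtureConfig(structural_signal=1.5))


class TestGeneratingRates:
    def test_noiseless_limit_counting_scorers_hit_one(self):
        cfg = FixtureConfig(seed=3, structural_signal=1.0, interpro_signal=1.0,
                            homolog_signal=1.0, noise_rate=0.0,
                            channel_coverage=1.0, n_domains=10)
        b = generate(cfg)
        import io

        from gofuse.io_formats import read_neighbor_table
        from gofuse.ontology import read_gaf

        protein_anno = propagate(
            read_gaf(io.StringIO(b.files["neighbor_proteins.gaf"])), b.ontology)
        mapping = filter_neighbors(
            read_neighbor_table(io.StringIO(b.files["neighbors.tsv"])),
            chain_level=True)
        p1 = {(r.domain_id, r.term): r.p1
              for r in score_structural(mapping, protein_anno)}
        checked = 0
        for d, terms in b.gold.entries.items():
            for g in terms:
                if (d, g) in p1:
                    assert p1[(d, g)] == 1.0
                    checked += 1
        assert checked > 0

    def test_structural_signal_is_binomial_mean(self):
        # 200 neighbors at signal 0.5: mean P1 over primitive gold ~ 0.5
        cfg = FixtureConfig(seed=5, n_domains=12, neighbors_per_domain=200,
                            structural_signal=0.5, noise_rate=0.0,
                            channel_coverage=1.0)
        b = generate(cfg)
        import io

        from gofuse.io_formats import read_neighbor_table
        from gofuse.ontology import read_gaf

        protein_anno = propagate(
            read_gaf(io.StringIO(b.files["neighbor_proteins.gaf"])), b.ontology)
        mapping = filter_neighbors(
            read_neighbor_table(io.StringIO(b.files["neighbors.tsv"])),
            chain_level=True)
        p1 = {(r.domain_id, r.term): r.p1
              for r in score_structural(mapping, protein_anno)}
        vals = [p1[(d, g)] for d, terms in b.primitive_gold.items()
                for g in terms if (d, g) in p1]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("channel", ["structural", "interpro", "homolog"])
    def test_signal_monotonicity(self, channel):
        """Raising a channel's signal raises that scorer's mean gold score."""
        means = []
        for signal in (0.3, 0.6, 0.9):
            cfg = FixtureConfig(seed=9, n_domains=25, channel_coverage=1.0,
                                **{f"{channel}_signal": signal})
            b = generate(cfg)
            import io

            from gofuse.io_formats import (
                read_blast_tab, read_interpro2go, read_interproscan_tsv,
                read_neighbor_table,
            )
            from gofuse.ontology import read_gaf

            if channel == "structural":
                anno = propagate(read_gaf(
                    io.StringIO(b.files["neighbor_proteins.gaf"])), b.ontology)
                mapping = filter_neighbors(read_neighbor_table(
                    io.StringIO(b.files["neighbors.tsv"])), chain_level=True)
                scores = {(r.domain_id, r.term): r.p1
                          for r in score_structural(mapping, anno)}
            elif channel == "interpro":
                hits = read_interproscan_tsv(io.StringIO(b.files["interproscan.tsv"]))
                m = read_interpro2go(io.StringIO(b.files["interpro2go.txt"]))
                scores = {(r.domain_id, r.term): r.p2
                          for r in score_interpro(hits, m, b.ontology)}
            else:
                hits = read_blast_tab(io.StringIO(b.files["blast_hits.tsv"]))
                anno = propagate(read_gaf(io.StringIO(b.files["homologs.gaf"])),
                                 b.ontology)
                scores = {(r.domain_id, r.term): r.p4
                          for r in score_homolog(filter_homologs(hits), anno)}
            vals = [scores.get((d, g), 0.0) for d, terms in b.primitive_gold.items()
                    for g in terms]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestBinnedCalibrationSample:
    def test_empirical_rates_match(self):
        rng = np.random.default_rng(0)
        rates = [0.1, 0.3, 0.5, 0.7, 0.9]
        scores, labels = binned_calibration_sample(rates, 50_000, rng)
        bins = np.minimum((scores * 5).astype(int), 4)
        for b in range(5):
            assert labels[bins == b].mean() == pytest.approx(rates[b], abs=0.02)

    def test_analytic_lr_of_flat_rates_is_one(self):
        np.testing.assert_allclose(analytic_bin_lrs([0.3, 0.3, 0.3]), 1.0)

    def test_degenerate_rates_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            binned_calibration_sample([0.0, 0.5], 10, rng)
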