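"""Synthetic-data generator: geometry, reproducibility, planted signals, presets."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hepalnc.cis_pairing import correlation, genomic_distance
from hepalnc.errors import ConfigurationError
from hepalnc.synthetic_data import (
    PlantedPair,
    SimulationConfig,
    _pair_components,
    generate_annotation,
    generate_expression,
    load_config,
    save_config,
    scenario_presets,
    write_dataset,
)


def small_config(**kw):
    defaults = dict(n_chromosomes=1, genes_per_chromosome=8, seed=11)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def loci_by_id(annotation):
    return {g.gene_id: g for g in annotation.loci}


class TestAnnotationGeometry:
    @pytest.mark.parametrize("gap", [0, 1, 181, 2206, 99_999, 100_001])
    def test_requested_gap_reproduced_exactly(self, gap):
        config = small_config(planted_pairs=[PlantedPair("L", "C", gap)])
        ann = generate_annotation(config)
        loci = loci_by_id(ann)
        assert genomic_distance(loci["L"], loci["C"]) == gap

    def test_random_configs_reproduce_all_gaps(self, rng):
        for k in range(30):
            pairs = [
                PlantedPair(f"L{k}_{j}", f"C{k}_{j}", int(rng.integers(0, 120_000)))
                for j in range(int(rng.integers(1, 4)))
            ]
            config = small_config(
                n_chromosomes=int(rng.integers(1, 4)),
                genes_per_chromosome=5,
                planted_pairs=pairs,
                seed=int(rng.integers(0, 2**31)),
            )
            ann = generate_annotation(config)
            loci = loci_by_id(ann)
            for p in pairs:
                assert genomic_distance(loci[p.lncrna_id], loci[p.coding_id]) == p.target_gap_bp

    def test_star_sharing_reproduces_gaps(self):
        pairs = [
            PlantedPair("L1", "CA", 5_000),
            PlantedPair("L1", "CB", 20_000),
            PlantedPair("LA", "C2", 7_000),
            PlantedPair("LB", "C2", 60_000),
        ]
        ann = generate_annotation(small_config(planted_pairs=pairs))
        loci = loci_by_id(ann)
        for p in pairs:
            assert genomic_distance(loci[p.lncrna_id], loci[p.coding_id]) == p.target_gap_bp

    def test_chain_sharing_rejected(self):
        pairs = [
            PlantedPair("L1", "C1", 1_000),
            PlantedPair("L1", "C2", 2_000),
            PlantedPair("L2", "C2", 3_000),
        ]
        with pytest.raises(ConfigurationError, match="star"):
            generate_annotation(small_config(planted_pairs=pairs))

    def test_transcript_models_cover_locus_span_and_lncrnas_multiexonic(self):
        config = small_config(planted_pairs=[PlantedPair("L", "C", 500, lncrna_known=False)])
        ann = generate_annotation(config)
        by_gene = {}
        for t in ann.transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        for locus in ann.loci:
            ts = by_gene[locus.gene_id]
            assert min(t.start for t in ts) == locus.start
            assert max(t.end for t in ts) == locus.end
            if locus.biotype in ("known_lncRNA", "novel_lncRNA"):
                for t in ts:
                    assert t.exon_count >= 2 and t.spliced_length >= 200
        # novel lncRNA transcripts carry negative coding-potential scores
        novel = [t for t in by_gene["L"]]
        assert all(ann.coding_scores[t.transcript_id] < 0 for t in novel)

    def test_pair_components_grouping(self):
        pairs = [PlantedPair("a", "x", 1), PlantedPair("a", "y", 1), PlantedPair("b", "z", 1)]
        comps = _pair_components(pairs)
        assert sorted(len(c) for c in comps) == [1, 2]


class TestReproducibility:
    def test_identical_seed_bit_identical_outputs(self):
        config = small_config(
            planted_pairs=[PlantedPair("L", "C", 1_000)],
            planted_degs=[("L", 2.0), ("C", 2.0), ("G01_001", -1.5)],
        )
        a1, a2 = generate_annotation(config), generate_annotation(config)
        assert a1.transcripts == a2.transcripts
        assert a1.loci == a2.loci
        m1, t1 = generate_expression(config, a1)
        m2, t2 = generate_expression(config, a2)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1.pairs, t2.pairs)

    def test_different_seed_changes_expression(self):
        c1 = small_config(seed=1)
        c2 = small_config(seed=2)
        m1, _ = generate_expression(c1, generate_annotation(c1))
        m2, _ = generate_expression(c2, generate_annotation(c2))
        assert not np.allclose(m1.values.to_numpy(), m2.values.to_numpy())


class TestExpressionModel:
    def test_noise_free_planted_pair_has_rho_one(self):
        config = small_config(noise_sd=0.0, planted_pairs=[PlantedPair("L", "C", 1_000, 1.0)])
        ann = generate_annotation(config)
        matrix, _ = generate_expression(config, ann)
        rho, p = correlation(matrix.values.loc["L"], matrix.values.loc["C"])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 720)

    def test_noise_free_fold_change_exact(self):
        config = small_config(noise_sd=0.0, planted_degs=[("G01_001", 2.0)])
        matrix, _ = generate_expression(config, generate_annotation(config))
        row = matrix.values.loc["G01_001"]
        ctrl = row[matrix.samples_in("control")].mean()
        case = row[matrix.samples_in("case")].mean()
        assert case / ctrl == pytest.approx(4.0)  # log2 shift 2 -> fold 4, no pseudocount

    def test_unknown_planted_gene_rejected(self):
        config = small_config(planted_degs=[("nope", 1.0)])
        with pytest.raises(ConfigurationError, match="nope"):
            generate_expression(config, generate_annotation(small_config()))

    def test_mean_pair_rho_matches_monte_carlo_oracle(self):
        # generative model: both members share w*z plus iid noise; the oracle
        # redraws the same model en masse and computes Spearman via the
        # tie-free sum-of-squared-rank-differences formula
        w, sd, n = 0.9, 0.25, 6
        g = np.random.default_rng(424242)
        z = g.standard_normal((200_000, n))
        x = w * z + g.normal(0, sd, z.shape)
        y = w * z + g.normal(0, sd, z.shape)

        def ranks(a):
            return a.argsort(axis=1).argsort(axis=1).astype(float)

        d2 = ((ranks(x) - ranks(y)) ** 2).sum(axis=1)
        oracle_mean = (1 - 6 * d2 / (n * (n**2 - 1))).mean()

        rhos = []
        for seed in range(200):
            config = small_config(
                noise_sd=sd,
                planted_pairs=[PlantedPair(f"L{j}", f"C{j}", 1_000, w) for j in range(3)],
                seed=seed,
            )
            matrix, _ = generate_expression(config, generate_annotation(config))
            for j in range(3):
                rho, _ = correlation(matrix.values.loc[f"L{j}"], matrix.values.loc[f"C{j}"])
                rhos.append(rho)
        assert np.mean(rhos) == pytest.approx(oracle_mean, abs=0.05)


class TestPresets:
    def test_null_has_no_planted_signal(self):
        config = scenario_presets("null")
        assert config.planted_degs == [] and config.planted_pairs == []

    def test_paper_like_pair_multiplicity(self):
        config = scenario_presets("paper_like")
        pairs = config.planted_pairs
        assert len(pairs) == 6
        lncs = [p.lncrna_id for p in pairs]
        cods = [p.coding_id for p in pairs]
        assert len(set(lncs)) == 5 and len(set(cods)) == 5
        # one lncRNA with two coding partners, one coding gene with two lncRNAs
        assert max(lncs.count(l) for l in lncs) == 2
        assert max(cods.count(c) for c in cods) == 2
        assert all(p.target_gap_bp <= 100_000 for p in pairs)
        lnc_degs = [g for g, _ in config.planted_degs if g in set(lncs)]
        assert len(lnc_degs) == 5

    def test_paper_like_planted_deg_counts(self):
        config = scenario_presets("paper_like")
        truthful = generate_expression(config, generate_annotation(config))[1]
        classes = truthful.biotype_classes()
        deg_ids = list(truthful.degs.gene_id)
        assert sum(classes[g] == "lncRNA" for g in deg_ids) == 30
        assert sum(classes[g] == "coding" for g in deg_ids) == 250

    def test_stress_straddles_distance_boundary(self):
        config = scenario_presets("stress")
        gaps = sorted(p.target_gap_bp for p in config.planted_pairs)
        assert gaps[0] < 100_000 < gaps[-1]

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ConfigurationError, match="null"):
            scenario_presets("bogus")


class TestSerialization:
    def test_config_yaml_round_trip(self, tmp_path):
        config = small_config(
            planted_pairs=[PlantedPair("L", "C", 42, 0.5, lncrna_known=False)],
            planted_degs=[("L", 2.0)],
        )
        save_config(config, tmp_path / "c.yaml")
        assert load_config(tmp_path / "c.yaml") == config

    def test_write_dataset_round_trips_matrix(self, tmp_path):
        from hepalnc.io_models import read_expression_matrix, read_gtf

        config = small_config(planted_pairs=[PlantedPair("L", "C", 1_000, lncrna_known=False)])
        paths = write_dataset(config, tmp_path / "ds")
        ann = generate_annotation(config)
        matrix, _ = generate_expression(config, ann)
        back = read_expression_matrix(paths["matrix"], matrix.groups)
        pd.testing.assert_frame_equal(back.values, matrix.values, check_exact=False, rtol=1e-12)
        assert read_gtf(paths["assembled_gtf"]) == ann.transcripts
        assert len(read_gtf(paths["ref_noncoding_gtf"])) > 0
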