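import dataclasses

import numpy as np
import pytest

from quadromics import (
    ComparisonSpec,
    PlantedEffect,
    PlantedPair,
    PlantedPathway,
    SimulationConfig,
    fold_change,
    generate_metabolome,
    generate_transcriptome,
    impute_zeros,
    pair_pcc,
)
from quadromics.data_io import load_abundance, load_design
from quadromics.simulate import largest_remainder, write_fixture_bundle


class TestLargestRemainder:
    def test_published_class_mix_on_100(self):
        counts = largest_remainder(
            {"amino": 0.15, "flavone": 0.15, "organic": 0.12, "lipid": 0.11, "nucleotide": 0.10},
            100,
        )
        assert counts["flavone"] == 15
        assert counts["other"] == 37
        assert sum(counts.values()) == 100

    @pytest.mark.parametrize("total", [7, 58, 581])
    def test_counts_always_sum_to_total(self, total):
        props = {"a": 0.31, "b": 0.27, "c": 0.21}
        assert sum(largest_remainder(props, total).values()) == total

    def test_matches_exhaustive_apportionment_oracle(self, rng):
        """Floor quotas, then distribute leftovers by descending remainder."""
        for _ in range(20):
            k = rng.integers(2, 6)
            raw = rng.uniform(0.5, 2, size=k)
            props = {f"c{i}": p for i, p in enumerate(raw / raw.sum())}
            total = int(rng.integers(10, 200))
            quotas = {c: total * p for c, p in props.items()}
            floors = {c: int(np.floor(q)) for c, q in quotas.items()}
            order = sorted(props, key=lambda c: quotas[c] - floors[c], reverse=True)
            for c in order[: total - sum(floors.values())]:
                floors[c] += 1
            got = largest_remainder(props, total)
            got.pop("other", None)
            assert got == floors


class TestGenerateMetabolome:
    def test_deterministic_under_fixed_seed(self, small_config):
        m1, t1 = generate_metabolome(small_config)
        m2, t2 = generate_metabolome(small_config)
        assert m1.values.equals(m2.values)
        assert all(t1.dam_status[c].equals(t2.dam_status[c]) for c in t1.dam_status)

    def test_class_apportionment(self, small_metabolome, small_config):
        matrix, _ = small_metabolome
        expected = largest_remainder(small_config.class_proportions, small_config.n_metabolites)
        observed = {}
        for ann in matrix.annotations.values():
            observed[ann.feature_class] = observed.get(ann.feature_class, 0) + 1
        assert observed == expected

    def test_within_stage_cv_tracks_config(self):
        """Empirical replicate CV of non-zero features ~ replicate_cv (20% band)."""
        cfg = SimulationConfig(n_metabolites=600, n_genes=10, seed=5, planted_pairs=())
        matrix, _ = generate_metabolome(cfg)
        stage = matrix.stage_values("NEC").to_numpy()
        nonzero = stage.min(axis=1) > 0
        cv = stage[nonzero].std(axis=1, ddof=1) / stage[nonzero].mean(axis=1)
        assert abs(cv.mean() - cfg.replicate_cv) / cfg.replicate_cv < 0.2

    def test_zero_reference_dam_huge_fc_noiseless(self):
        cfg = SimulationConfig(
            n_metabolites=20,
            replicate_cv=0.0,
            zero_fraction=0.0,
            planted_dams=(PlantedEffect("PEC:NEC", "up", 15.0, 1, zero_reference=True),),
            planted_degs=(),
            planted_pathways=(),
            planted_pairs=(),
            seed=7,
        )
        matrix, truth = generate_metabolome(cfg)
        status = truth.dam_status["PEC_vs_NEC"]
        fid = status.index[status == "up"][0]
        assert (matrix.stage_values("NEC").loc[fid] == 0).all()
        fc = fold_change(impute_zeros(matrix), ComparisonSpec("PEC", "NEC"))
        assert fc.loc[fid, "fc"] >= 2**14

    def test_truth_consistent_across_shared_stages(self, small_metabolome):
        """A feature planted up for GE:PEC is also up in GE:NEC by construction."""
        _, truth = small_metabolome
        ge_pec = truth.dam_status["GE_vs_PEC"]
        ge_nec_up = {
            f for f in ge_pec.index[ge_pec == "up"]
            if truth.dam_status["PEC_vs_NEC"][f] == "unchanged"
        }
        # those features have E[GE]=3, E[NEC]=0
        for f in ge_nec_up:
            assert truth.dam_status.get("GE_vs_NEC", ge_pec).get(f, "up") != "down"

    def test_infeasible_planting_rejected_before_sampling(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_metabolome(
                SimulationConfig(
                    n_metabolites=5,
                    planted_dams=(PlantedEffect("PEC:NEC", "up", 3.0, 10),),
                    planted_pathways=(),
                    planted_pairs=(),
                )
            )

    def test_infeasible_pathway_planting_rejected(self):
        with pytest.raises(ValueError, match="pathway"):
            generate_metabolome(
                SimulationConfig(
                    n_metabolites=30,
                    planted_dams=(PlantedEffect("PEC:NEC", "up", 3.0, 2),),
                    planted_pathways=(PlantedPathway("ko1", 20, 10),),
                    planted_pairs=(),
                    zero_fraction=0.0,
                )
            )


class TestPlantedEffectValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(comparison="PEC:NEC", direction="up", log2_effect=0.5, count=1),
            dict(comparison="PEC:NEC", direction="down", log2_effect=3.0, count=1),
            dict(comparison="PEC:NEC", direction="sideways", log2_effect=3.0, count=1),
            dict(comparison="PEC:NEC", direction="down", log2_effect=-3.0, count=1, zero_reference=True),
        ],
    )
    def test_invalid_effects_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PlantedEffect(**kwargs)


class TestGenerateTranscriptome:
    def test_planted_pair_signs_noiseless(self):
        cfg = SimulationConfig(
            n_metabolites=30,
            n_genes=20,
            replicate_cv=0.0,
            zero_fraction=0.0,
            planted_dams=(PlantedEffect("PEC:NEC", "up", 3.0, 5),),
            planted_degs=(),
            planted_pathways=(),
            planted_pairs=(PlantedPair(None, None, 1), PlantedPair(None, None, -1)),
            seed=3,
        )
        met, truth = generate_metabolome(cfg)
        tx, truth = generate_transcriptome(cfg, truth, met)
        for gene, metab, sign in truth.pair_signs:
            gp = np.log2(
                np.concatenate(
                    [tx.stage_values("NEC").loc[gene], tx.stage_values("PEC").loc[gene]]
                ) + 1
            )
            mp = np.log2(
                np.concatenate(
                    [met.stage_values("NEC").loc[metab], met.stage_values("PEC").loc[metab]]
                ) + 1
            )
            assert pair_pcc(gp, mp) == pytest.approx(sign, abs=1e-6)

    def test_unknown_pair_feature_rejected(self, small_config, small_metabolome):
        met, truth = small_metabolome
        cfg = dataclasses.replace(
            small_config, planted_pairs=(PlantedPair("nope", "pmb0001", 1),)
        )
        with pytest.raises(ValueError, match="unknown gene"):
            generate_transcriptome(cfg, truth, met)

    def test_reproducible(self, small_config, small_metabolome):
        met, truth = small_metabolome
        t1, _ = generate_transcriptome(small_config, truth, met)
        t2, _ = generate_transcriptome(small_config, truth, met)
        assert t1.values.equals(t2.values)


class TestFixtureBundle:
    def test_manifest_and_round_trip(self, tmp_path, small_config):
        manifest = write_fixture_bundle(small_config, tmp_path)
        for name in ("metabolome", "transcriptome", "annotations", "pathway_map", "design"):
            assert manifest[name].exists(), name
        design = load_design(manifest["design"])
        reloaded = load_abundance(manifest["metabolome"], design)
        in_memory, _ = generate_metabolome(small_config)
        np.testing.assert_allclose(
            reloaded.values.to_numpy(), in_memory.values.to_numpy(), rtol=1e-9
        )

    def test_truth_file_lists_planted_dams(self, tmp_path, small_config):
        import json

        manifest = write_fixture_bundle(small_config, tmp_path)
        truth = json.loads(manifest["truth"].read_text())
        _, expected = generate_metabolome(small_config)
        status = truth["dam_status"]["PEC_vs_NEC"]
        n_dams = sum(1 for v in status.values() if v != "unchanged")
        assert n_dams == (expected.dam_status["PEC_vs_NEC"] != "unchanged").sum()
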