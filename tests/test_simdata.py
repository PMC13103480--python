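import numpy as np
import pytest

from orchard import diversity
from orchard.genotypes import compute_grm
from orchard.simdata import (
    PhenoSimConfig,
    Protocol,
    SimGenoConfig,
    apply_protocol,
    inject_missing,
    simulate_genotypes,
    simulate_phenotypes,
)


def small_config(**overrides):
    base = dict(
        collection_sizes=(40, 40),
        n_chromosomes=3,
        markers_per_chromosome=120,
        chromosome_length_bp=20_000_000,
        clone_pairs=4,
        seed=1,
    )
    base.update(overrides)
    return SimGenoConfig(**base)


class TestSimulateGenotypes:
    def test_deterministic_under_seed(self):
        a = simulate_genotypes(small_config())
        b = simulate_genotypes(small_config())
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_no_missing_dosages_in_range(self):
        res = simulate_genotypes(small_config(missing_rate=0.0))
        X = res.genotypes.dosages
        assert not np.isnan(X).any()
        assert set(np.unique(X)) <= {0.0, 1.0, 2.0}

    def test_one_collection_per_individual_and_sizes(self):
        res = simulate_genotypes(small_config())
        labels, counts = np.unique(res.labels, return_counts=True)
        assert sorted(counts.tolist()) == [40, 40]

    def test_maf_spectrum_polymorphic(self):
        res = simulate_genotypes(small_config())
        p = res.genotypes.dosages.mean(axis=0) / 2
        maf = np.minimum(p, 1 - p)
        assert maf.min() > 0
        assert maf.max() <= 0.5

    def test_clone_pairs_identical_and_grm_entry(self):
        res = simulate_genotypes(small_config())
        ids = list(res.genotypes.individual_ids)
        grm = compute_grm(res.genotypes)
        for id_a, id_b in res.clone_map:
            i, j = ids.index(id_a), ids.index(id_b)
            np.testing.assert_array_equal(
                res.genotypes.dosages[i], res.genotypes.dosages[j]
            )
            assert grm.values[i, j] == pytest.approx(grm.values[i, i], abs=1e-10)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            small_config(collection_sizes=(0, 40))
        with pytest.raises(ValueError):
            small_config(missing_rate=1.0)
        with pytest.raises(ValueError):
            small_config(clone_pairs=100)
        with pytest.raises(ValueError):
            small_config(copying_switch_rate_per_bp=(-1e-7, 1e-7))

    def test_ld_decay_faster_for_higher_switch_rate(self):
        # the copying-rate knob must order the LD-decay crossing distances
        wins = 0
        for seed in range(5):
            cfg = SimGenoConfig(
                collection_sizes=(60, 60),
                n_chromosomes=3,
                markers_per_chromosome=250,
                chromosome_length_bp=50_000_000,
                haplotypes_per_pool=2,
                copying_switch_rate_per_bp=(5e-8, 5e-7),
                clone_pairs=0,
                seed=seed,
            )
            res = simulate_genotypes(cfg)
            crossing = {}
            for name in ("pop1", "pop2"):
                sub = res.genotypes.take_individuals(np.where(res.labels == name)[0])
                thr = diversity.background_threshold(
                    sub, snps_per_chromosome=150, seed=seed
                )
                decay = diversity.ld_decay(
                    sub,
                    snps_per_chromosome=250,
                    bin_width_bp=2_000_000,
                    max_distance_bp=50_000_000,
                    threshold=thr,
                    seed=seed,
                )
                crossing[name] = decay.crossing_distance_bp
            if crossing["pop2"] < crossing["pop1"]:
                wins += 1
        assert wins >= 4


class TestInjectMissing:
    def test_zero_rate_identity(self):
        res = simulate_genotypes(small_config())
        assert inject_missing(res.genotypes, 0.0) is res.genotypes

    def test_masked_fraction_matches_rate(self):
        res = simulate_genotypes(small_config(markers_per_chromosome=50))
        out = inject_missing(res.genotypes, 0.2, seed=3)
        frac = np.isnan(out.dosages).mean()
        assert out.dosages.size >= 10_000
        assert 0.18 < frac < 0.22  # binomial 99% interval at >= 1e4 calls

    def test_same_seed_same_mask(self):
        res = simulate_genotypes(small_config())
        a = inject_missing(res.genotypes, 0.3, seed=9)
        b = inject_missing(res.genotypes, 0.3, seed=9)
        np.testing.assert_array_equal(np.isnan(a.dosages), np.isnan(b.dosages))

    def test_rate_one_rejected(self):
        res = simulate_genotypes(small_config())
        with pytest.raises(ValueError):
            inject_missing(res.genotypes, 1.0)


class TestApplyProtocol:
    @pytest.mark.parametrize("kind", ["mean_of_k", "max_of_k"])
    def test_k1_identity(self, kind):
        assert apply_protocol([3.7], kind, k=1) == 3.7

    def test_mean_and_max(self):
        draws = [1.0, 5.0, 3.0]
        assert apply_protocol(draws, "mean_of_k", k=3) == pytest.approx(3.0)
        assert apply_protocol(draws, "max_of_k", k=3) == 5.0

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            apply_protocol([1.0, 2.0], "max_of_k", k=15)

    def test_expected_max_of_15_standard_normals(self):
        # Monte-Carlo oracle: E[max of 15 N(0,1)] ~ 1.736
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((120_000, 15))
        recorded = np.array(
            [apply_protocol(row, Protocol("max_of_k", 15)) for row in draws[:2_000]]
        )
        # the op agrees with a direct vectorized max
        np.testing.assert_allclose(recorded, draws[:2_000].max(axis=1))
        assert draws.max(axis=1).mean() == pytest.approx(1.736, abs=0.01)


class TestSimulatePhenotypes:
    def test_h2_one_no_gxe_phenotype_equals_breeding_value(self):
        res = simulate_genotypes(small_config())
        cfg = PhenoSimConfig(
            trait_names=("t",), h2_targets=(1.0,), n_causal=80,
            gxe_variance_fraction=0.0, seed=2,
        )
        table, truth = simulate_phenotypes(res.genotypes, res.labels, cfg)
        y = table.records["value"].to_numpy()
        r = np.corrcoef(y, truth.breeding_values[:, 0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_perfect_genetic_correlation_forces_equality(self):
        res = simulate_genotypes(small_config())
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        cfg = PhenoSimConfig(
            trait_names=("a", "b"), h2_targets=0.6,
            genetic_correlation_target=R, n_causal=80, seed=3,
        )
        _, truth = simulate_phenotypes(res.genotypes, res.labels, cfg)
        bv = truth.breeding_values
        za = (bv[:, 0] - bv[:, 0].mean()) / bv[:, 0].std()
        zb = (bv[:, 1] - bv[:, 1].mean()) / bv[:, 1].std()
        np.testing.assert_allclose(za, zb, atol=1e-4)

    def test_realized_h2_matches_target(self):
        cfg = SimGenoConfig(
            collection_sizes=(800,), n_chromosomes=3,
            markers_per_chromosome=500, chromosome_length_bp=20_000_000,
            clone_pairs=0, seed=10,
        )
        res = simulate_genotypes(cfg)
        realized = []
        for seed in range(6):
            pcfg = PhenoSimConfig(
                trait_names=("t",), h2_targets=(0.5,), n_causal=200, seed=seed,
                gxe_variance_fraction=0.0,
            )
            _, truth = simulate_phenotypes(res.genotypes, res.labels, pcfg)
            realized.append(truth.realized_h2[0])
        assert abs(np.mean(realized) - 0.5) < 0.05

    def test_gxe_fraction_sets_cross_collection_correlation(self):
        # many ancestral haplotypes keep LD (and hence the effective number
        # of independent causal draws) high enough for a tight check
        cfg = SimGenoConfig(
            collection_sizes=(500, 500), n_chromosomes=10,
            markers_per_chromosome=150, chromosome_length_bp=20_000_000,
            ancestral_pools=6, haplotypes_per_pool=10,
            clone_pairs=0, seed=20,
        )
        res = simulate_genotypes(cfg)
        for frac in (0.0, 0.4):
            rs = []
            for seed in (21, 22, 23):
                pcfg = PhenoSimConfig(
                    trait_names=("t",), h2_targets=(0.8,), n_causal=600,
                    gxe_variance_fraction=frac, seed=seed,
                )
                _, truth = simulate_phenotypes(res.genotypes, res.labels, pcfg)
                bv1 = truth.collection_breeding_values["pop1"][:, 0]
                bv2 = truth.collection_breeding_values["pop2"][:, 0]
                rs.append(np.corrcoef(bv1, bv2)[0, 1])
            assert np.mean(rs) == pytest.approx(1.0 - frac, abs=0.05)

    def test_non_psd_correlation_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            PhenoSimConfig(trait_names=("a", "b", "c"), h2_targets=0.5,
                           genetic_correlation_target=bad)

    def test_max_protocol_lowers_heritability(self):
        # paired traits with identical genetics: the max-of-15 recorder
        # realizes lower h2 than the mean-of-10 recorder
        from orchard.varcomp import greml_single

        wins = 0
        for seed in range(5):
            cfg = SimGenoConfig(
                collection_sizes=(200,), n_chromosomes=3,
                markers_per_chromosome=150, chromosome_length_bp=20_000_000,
                clone_pairs=0, seed=100 + seed,
            )
            res = simulate_genotypes(cfg)
            pcfg = PhenoSimConfig(
                trait_names=("mean10", "max15"), h2_targets=0.9,
                genetic_correlation_target=np.ones((2, 2)),
                n_causal=100, gxe_variance_fraction=0.0,
                environment_means=np.array([[400.0, 400.0]]), genetic_sd=40.0,
                protocols={
                    "mean10": Protocol("mean_of_k", 10),
                    "max15": Protocol("max_of_k", 15),
                },
                seed=200 + seed,
            )
            table, _ = simulate_phenotypes(res.genotypes, res.labels, pcfg)
            grm = compute_grm(res.genotypes)
            h2 = {
                t: greml_single(
                    table.records.query("trait == @t")["value"].to_numpy(),
                    grm=grm.values,
                ).h2
                for t in ("mean10", "max15")
            }
            wins += h2["max15"] < h2["mean10"]
        assert wins >= 4
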