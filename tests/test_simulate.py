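import numpy as np
import pytest

from crispramp.model import PipelineConfig
from crispramp.reads import merge_pair
from crispramp.simulate import (
    GenerationError,
    SimulationConfig,
    generate_catalog,
    simulate,
    simulate_composition,
    synthesize_reads,
)
from crispramp.variants import NEW_PLUS, ORIGIN, OTHERS, PROTO


def small_sim(**kwargs):
    defaults = dict(n_reference_cts=3, repertoire_length=6, n_samples=2,
                    n_read_pairs=100, rng_seed=17)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestGenerateCatalog:
    def test_counts_and_disjointness(self):
        sim = SimulationConfig(n_reference_cts=16, repertoire_length=10, rng_seed=1)
        catalog, aux = generate_catalog(sim)
        assert len(catalog.entries) == 16
        assert len(catalog.spacer_sequences) == 160
        catalog.validate()  # raises on shared spacers

    def test_pairwise_distance_guarantee(self):
        sim = small_sim(n_reference_cts=4, repertoire_length=5)
        catalog, aux = generate_catalog(sim)
        seqs = list(catalog.spacer_sequences.values()) + list(aux.novel_pool.values())
        for i, a in enumerate(seqs):
            for b in seqs[i + 1 :]:
                if len(a) == len(b):
                    dist = sum(1 for x, y in zip(a, b) if x != y)
                    assert dist >= sim.spacer_min_distance

    def test_deterministic_under_seed(self):
        sim = small_sim()
        c1, a1 = generate_catalog(sim)
        c2, a2 = generate_catalog(sim)
        assert c1.entries == c2.entries
        assert c1.spacer_sequences == c2.spacer_sequences
        assert a1.leader == a2.leader
        assert a1.novel_pool == a2.novel_pool

    def test_empty_catalog(self):
        sim = small_sim(n_reference_cts=0, novel_pool_size=0)
        catalog, _ = generate_catalog(sim)
        assert catalog.entries == {}

    def test_impossible_distance_raises(self):
        sim = small_sim(
            n_reference_cts=20, repertoire_length=10,
            spacer_length_range=(4, 4), spacer_min_distance=5,
        )
        with pytest.raises(GenerationError):
            generate_catalog(sim)

    def test_spacer_lengths_in_range(self):
        sim = small_sim()
        catalog, _ = generate_catalog(sim)
        lo, hi = sim.spacer_length_range
        assert all(lo <= len(s) <= hi for s in catalog.spacer_sequences.values())


class TestSimulateComposition:
    def test_proportions_sum_to_one(self):
        sim = small_sim()
        catalog, _ = generate_catalog(sim)
        comp = simulate_composition(catalog, sim)
        sums = comp.groupby("sample_id")["proportion"].sum()
        assert np.allclose(sums, 1.0)

    def test_dominant_ct_mean_over_seeds(self):
        target = 0.32
        realized = []
        for seed in range(60):
            sim = small_sim(
                rng_seed=seed, dominant_ct_index=0, dominant_fraction=target,
                n_reference_cts=6,
            )
            catalog, _ = generate_catalog(sim)
            comp = simulate_composition(catalog, sim)
            ct1 = comp[comp["ct"] == "CT1"].groupby("sample_id")["proportion"].sum()
            realized.append(ct1.mean())
        assert np.mean(realized) == pytest.approx(target, abs=0.02)

    def test_variant_fractions_respected(self):
        sim = small_sim(variant_fractions={ORIGIN: 0.7, PROTO: 0.3})
        catalog, _ = generate_catalog(sim)
        comp = simulate_composition(catalog, sim)
        per_ct = comp.groupby(["sample_id", "ct", "variant"])["proportion"].sum()
        for (sample, ct), group in comp.groupby(["sample_id", "ct"]):
            total = group["proportion"].sum()
            origin = per_ct.get((sample, ct, ORIGIN), 0.0)
            assert origin / total == pytest.approx(0.7)

    def test_lognormal_walk_model(self):
        sim = small_sim(abundance_model="lognormal_walk")
        catalog, _ = generate_catalog(sim)
        comp = simulate_composition(catalog, sim)
        sums = comp.groupby("sample_id")["proportion"].sum()
        assert np.allclose(sums, 1.0)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            small_sim(abundance_model="zipf")


class TestSynthesizeReads:
    def test_zero_error_pairs_remerge_to_template(self, cfg):
        sim = small_sim(
            error_rate_r1=0.0, error_rate_r2=0.0,
            mean_q_r1=38, mean_q_r2=38, decay_r1=0, decay_r2=0, q_noise_sd=0.0,
        )
        ds = simulate(sim)
        templates = dict(zip(ds.truth["read_pair_id"], ds.truth["template_sequence"]))
        sample = ds.samples[0]
        for r1, r2 in zip(sample.r1, sample.r2):
            amp = merge_pair(r1, r2, cfg)
            assert amp is not None
            assert amp.sequence == templates[r1.read_id]

    def test_fixed_spacer_count(self):
        sim = small_sim(spacers_per_amplicon=(0.0, 1.0, 0.0, 0.0, 0.0))
        ds = simulate(sim)
        lengths = ds.truth["true_spacer_ids"].str.split(",").str.len()
        assert (lengths == 2).all()

    def test_all_origin_mass(self):
        sim = small_sim(variant_fractions={ORIGIN: 1.0})
        ds = simulate(sim)
        assert (ds.truth["true_variant"] == ORIGIN).all()

    def test_multinomial_ct_counts(self):
        sim = small_sim(n_read_pairs=5000, n_samples=2, n_reference_cts=4)
        catalog, aux = generate_catalog(sim)
        comp = simulate_composition(catalog, sim)
        ds = synthesize_reads(catalog, comp, sim, aux)
        for sample, group in ds.truth.groupby("sample_id"):
            expected = comp[comp["sample_id"] == sample].groupby("ct")["proportion"].sum()
            observed = group["true_ct"].value_counts(normalize=True)
            n = len(group)
            for ct, p in expected.items():
                sd = max(np.sqrt(p * (1 - p) / n), 1e-9)
                assert abs(observed.get(ct, 0.0) - p) < 4 * sd

    def test_byte_identical_under_seed(self, tmp_path):
        sim = small_sim()
        out1 = simulate(sim).write(tmp_path / "a")
        out2 = simulate(sim).write(tmp_path / "b")
        files1 = sorted(p.relative_to(out1) for p in out1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(out2) for p in out2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (out1 / rel).read_bytes() == (out2 / rel).read_bytes()

    def test_variant_arrays_match_declared_class(self):
        sim = small_sim(
            variant_fractions={ORIGIN: 0.25, NEW_PLUS: 0.25, PROTO: 0.25, OTHERS: 0.25},
            n_read_pairs=300,
        )
        ds = simulate(sim)
        catalog = ds.catalog
        from crispramp.dictionary import SpacerArray
        from crispramp.variants import classify_variant

        for _, row in ds.truth.iterrows():
            ids = tuple(int(x) for x in row["true_spacer_ids"].split(","))
            origin = catalog.entries[row["true_ct"]]
            call = classify_variant(SpacerArray("x", ids), origin)
            assert call.variant == row["true_variant"]

    def test_r2_quality_below_r1(self):
        sim = small_sim()
        ds = simulate(sim)
        sample = ds.samples[0]
        mean_r1 = np.mean([r.qualities.mean() for r in sample.r1])
        mean_r2 = np.mean([r.qualities.mean() for r in sample.r2])
        assert mean_r2 < mean_r1

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            small_sim(error_rate_r2=0.5)
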