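import dataclasses

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from cnvcomplexity.complexity import complexity_score
from cnvcomplexity.simulator import (
    DEFAULT_COHORT_CONFIG,
    STATE_MULTIPLIER,
    SimulationConfig,
    emit_continuous,
    gene_positions_for,
    simulate_cohort,
    simulate_sample,
)

FAST = SimulationConfig(n_min=200, n_max=400, genome_size=500)


class TestConfig:
    def test_defaults_valid(self):
        SimulationConfig()
        DEFAULT_COHORT_CONFIG

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(p_dominant=1.0),
            dict(p_dominant=0.0),
            dict(n_min=0),
            dict(n_max=100, n_min=200),
            dict(c_min=1),
            dict(genome_size=100),  # smaller than max segment
            dict(noise_rate=1.5),
            dict(event_noise_rate=-0.1),
            dict(dominant_clade_min=0.0),
            dict(attachment_alpha=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_event_noise_scales_with_cells(self):
        cfg = SimulationConfig(event_noise_rate=0.3, noise_ref_cells=2000)
        assert cfg.effective_event_noise_rate(2000) == pytest.approx(0.3)
        assert cfg.effective_event_noise_rate(500) == pytest.approx(0.6)
        assert cfg.effective_event_noise_rate(100) == 0.9  # capped

    def test_flat_noise_without_ref(self):
        cfg = SimulationConfig(event_noise_rate=0.3)
        assert cfg.effective_event_noise_rate(100) == 0.3


class TestSimulateSample:
    def test_bounds_respected(self):
        s = simulate_sample("monoclonal", FAST, 0)
        assert 200 <= s.matrix.n_cells <= 400
        assert s.matrix.n_genes == 500
        assert s.truth.label == "monoclonal"

    def test_invalid_kind(self):
        with pytest.raises(ValueError):
            simulate_sample("oligoclonal", FAST, 0)

    def test_dominant_clone_share(self):
        for seed in range(5):
            s = simulate_sample("monoclonal", FAST, seed)
            sizes = sorted(s.truth.clone_sizes.values(), reverse=True)
            assert 0.80 <= sizes[0] / s.truth.n_cells <= 0.97

    def test_polyclonal_many_more_clones(self):
        mono = simulate_sample("monoclonal", FAST, 1)
        poly = simulate_sample("polyclonal", FAST, 1)
        n_mono = sum(1 for v in mono.truth.clone_sizes.values() if v > 0)
        n_poly = sum(1 for v in poly.truth.clone_sizes.values() if v > 0)
        assert n_poly >= 10 * n_mono

    def test_sizes_sum_to_n(self):
        for kind in ("monoclonal", "polyclonal"):
            s = simulate_sample(kind, FAST, 3)
            assert sum(s.truth.clone_sizes.values()) == s.truth.n_cells

    def test_every_cell_assigned_once(self):
        s = simulate_sample("polyclonal", FAST, 4)
        assert len(s.truth.cell_assignment) == s.truth.n_cells
        assert set(s.truth.cell_assignment) == set(s.matrix.cell_ids)

    def test_noise_free_cells_match_clone_profiles(self):
        cfg = dataclasses.replace(FAST, noise_rate=0.0, event_noise_rate=0.0)
        s = simulate_sample("polyclonal", cfg, 5)
        base = np.full(cfg.genome_size, 3, dtype=np.int16)
        for cell, clone in s.truth.cell_assignment.items():
            profile = base.copy()
            for start, end, state in s.truth.cumulative_events(clone):
                profile[start:end] = state
            col = s.matrix.states[:, s.matrix.cell_ids.index(cell)]
            np.testing.assert_array_equal(col, profile)

    def test_ancestor_events_inherited(self):
        s = simulate_sample("polyclonal", FAST, 6)
        t = s.truth
        leaf = next(c for c, n in t.clone_sizes.items() if n > 0 and c.startswith("sub"))
        lineage = t.lineage(leaf)
        assert lineage[0] == "root"
        cum = t.cumulative_events(leaf)
        for node in lineage:
            for ev in t.clone_events[node]:
                assert ev in cum

    def test_events_within_genome(self):
        s = simulate_sample("polyclonal", FAST, 7)
        for evs in s.truth.clone_events.values():
            for start, end, state in evs:
                assert 0 <= start < end <= FAST.genome_size
                assert state in (1, 2, 4, 5, 6)

    def test_noise_preserves_frequencies(self):
        """Gain/loss frequency per gene is a deterministic function of the
        clone structure: the noisy matrix must reproduce the noiseless
        frequencies up to the fixed background offset."""
        noisy_cfg = dataclasses.replace(
            FAST, noise_rate=0.1, event_noise_rate=0.4, noise_ref_cells=2000
        )
        clean_cfg = dataclasses.replace(FAST, noise_rate=0.0, event_noise_rate=0.0)
        s_noisy = simulate_sample("polyclonal", noisy_cfg, 8)
        s_clean = simulate_sample("polyclonal", clean_cfg, 8)
        n = s_clean.matrix.n_cells
        gain_clean = (s_clean.matrix.states > 3).sum(axis=1)
        gain_noisy = (s_noisy.matrix.states > 3).sum(axis=1)
        neutral_clean = (s_clean.matrix.states == 3).sum(axis=1)
        expected = gain_clean + np.round(0.1 * neutral_clean / 2)
        np.testing.assert_array_equal(gain_noisy, expected)

    def test_flat_polyclonal_variant(self):
        cfg = dataclasses.replace(FAST, flat_polyclonal=True)
        s = simulate_sample("polyclonal", cfg, 9)
        parents = {s.truth.clone_tree[c] for c in s.truth.clone_sizes if c.startswith("sub")}
        assert parents == {"root"}

    def test_infeasible_genome_raises(self):
        with pytest.raises(ValueError):
            SimulationConfig(genome_size=50)


class TestSimulateCohort:
    def test_counts_and_labels(self):
        cohort = simulate_cohort(3, 2, FAST, seed=0)
        assert len(cohort) == 5
        labels = [s.truth.label for s in cohort]
        assert labels.count("monoclonal") == 3
        assert labels.count("polyclonal") == 2

    def test_empty_cohort(self):
        assert simulate_cohort(0, 0, FAST, seed=0) == []

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            simulate_cohort(-1, 0, FAST, seed=0)

    def test_reproducible(self):
        a = simulate_cohort(2, 2, FAST, seed=42)
        b = simulate_cohort(2, 2, FAST, seed=42)
        for sa, sb in zip(a, b):
            assert sa.sample_id == sb.sample_id
            np.testing.assert_array_equal(sa.matrix.states, sb.matrix.states)
            assert sa.truth.clone_sizes == sb.truth.clone_sizes

    def test_different_seeds_differ(self):
        a = simulate_cohort(1, 0, FAST, seed=1)[0]
        b = simulate_cohort(1, 0, FAST, seed=2)[0]
        assert not np.array_equal(a.matrix.states, b.matrix.states)

    def test_label_separation(self):
        cohort = simulate_cohort(30, 30, dataclasses.replace(
            DEFAULT_COHORT_CONFIG, genome_size=1000, n_max=600), seed=11)
        mono = [complexity_score(s.matrix).entropy for s in cohort[:30]]
        poly = [complexity_score(s.matrix).entropy for s in cohort[30:]]
        assert np.mean(poly) > np.mean(mono)
        assert mannwhitneyu(poly, mono, alternative="greater").pvalue < 0.01


class TestEmitContinuous:
    def test_neutral_maps_to_one(self):
        cfg = dataclasses.replace(FAST, truncal_events_min=1, truncal_events_max=1)
        s = simulate_sample("monoclonal", cfg, 1)
        cont = emit_continuous(s, sigma=0.0)
        neutral = s.matrix.states == 3
        assert np.all(cont.values[neutral] == 1.0)

    def test_mapping_table(self):
        s = simulate_sample("monoclonal", FAST, 2)
        cont = emit_continuous(s, sigma=0.0)
        for state, mult in ((1, 0.0), (2, 0.5), (3, 1.0), (4, 1.5), (5, 2.0), (6, 3.0)):
            mask = s.matrix.states == state
            if mask.any():
                assert np.all(cont.values[mask] == mult)

    def test_noise_within_gaussian_bound(self):
        s = simulate_sample("monoclonal", FAST, 3)
        cont = emit_continuous(s, sigma=0.1, rng=0)
        mapped = STATE_MULTIPLIER[s.matrix.states]
        assert np.abs(cont.values - mapped).max() < 5 * 0.1

    def test_negative_sigma_raises(self):
        s = simulate_sample("monoclonal", FAST, 4)
        with pytest.raises(ValueError):
            emit_continuous(s, sigma=-1.0)


class TestGenePositions:
    def test_matches_genome(self):
        rows = gene_positions_for(FAST)
        assert len(rows) == FAST.genome_size
        chroms = {r.chrom for r in rows}
        assert len(chroms) <= FAST.n_chromosomes
        assert all(r.end >= r.start >= 1 for r in rows)
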