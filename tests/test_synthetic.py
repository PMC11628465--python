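"""Synthetic cohort generator: mixtures, planted effects, determinism."""
import numpy as np
import pytest
from scipy import stats

from microsig.flow import PANEL_CHANNELS
from microsig.synthetic import (ConfigurationError, FlowEffect,
                                PhenotypePopulation, SyntheticDesign,
                                TaxaEffect, default_design, make_metadata,
                                metadata_frame, simulate_event_sample,
                                simulate_flow_cohort, simulate_taxa_counts)

CH = PANEL_CHANNELS["immunoglobulin"]


def two_pop_design(**kwargs):
    pops = [
        PhenotypePopulation("p0", np.full(7, 1.0), np.full(7, 0.1), list(CH)),
        PhenotypePopulation("p1", np.full(7, 3.0), np.full(7, 0.1), list(CH)),
    ]
    base = dict(
        populations={"immunoglobulin": pops,
                     "lectin": [PhenotypePopulation(
                         f"l{i}", np.full(7, 1.0 + 2 * i), np.full(7, 0.1),
                         list(PANEL_CHANNELS["lectin"])) for i in range(2)]},
        base_weights={"immunoglobulin": np.array([0.7, 0.3]),
                      "lectin": np.array([0.5, 0.5])},
        taxa_base_composition=np.full(10, 0.1),
        events_per_sample=200,
        n_case={1: 3, 2: 3, 3: 3}, n_control={1: 3, 2: 3, 3: 3},
    )
    base.update(kwargs)
    return SyntheticDesign(**base)


class TestEventSample:
    def test_degenerate_mixture_sd_zero(self):
        pop = PhenotypePopulation("p", np.full(7, 2.0), np.zeros(7), list(CH))
        d = two_pop_design()
        ev = simulate_event_sample(d, np.array([1.0]), "immunoglobulin", 50,
                                   seed=0, populations=[pop])
        np.testing.assert_allclose(ev.intensities, 100.0, rtol=1e-12)

    def test_zero_weight_population_absent(self):
        d = two_pop_design()
        ev = simulate_event_sample(d, np.array([1.0, 0.0]), "immunoglobulin",
                                   500, seed=1)
        # population 1 sits at 10^3; all events must be near 10^1
        assert ev.intensities.max() < 100

    def test_mixture_fraction_binomial(self):
        d = two_pop_design()
        n = 10_000
        ev = simulate_event_sample(d, np.array([0.7, 0.3]), "immunoglobulin",
                                   n, seed=2)
        frac = (ev.intensities[:, 0] < 100).mean()
        sd = np.sqrt(0.7 * 0.3 / n)
        assert abs(frac - 0.7) <= 3 * sd

    def test_intensities_strictly_positive(self, design):
        ev = simulate_event_sample(design, design.base_weights["lectin"],
                                   "lectin", 1000, seed=3)
        assert (ev.intensities > 0).all()

    def test_channel_count_mismatch_rejected(self):
        bad = PhenotypePopulation("bad", np.ones(3), np.ones(3),
                                  ["FSC", "SSC", "DNA"])
        d = two_pop_design()
        with pytest.raises(ConfigurationError):
            simulate_event_sample(d, np.array([0.5, 0.5]), "immunoglobulin",
                                  10, seed=0,
                                  populations=[bad, d.populations[
                                      "immunoglobulin"][0]])


class TestFlowCohort:
    def test_determinism(self):
        d1, d2 = two_pop_design(seed=5), two_pop_design(seed=5)
        ev1, m1, _ = simulate_flow_cohort(d1)
        ev2, m2, _ = simulate_flow_cohort(d2)
        assert metadata_frame(m1).equals(metadata_frame(m2))
        s = m1[0].sample_id
        np.testing.assert_array_equal(
            ev1[s]["immunoglobulin"].intensities,
            ev2[s]["immunoglobulin"].intensities)

    def test_seed_changes_data(self):
        ev1, _, _ = simulate_flow_cohort(two_pop_design(seed=1))
        ev2, _, _ = simulate_flow_cohort(two_pop_design(seed=2))
        s = list(ev1)[0]
        assert not np.array_equal(ev1[s]["lectin"].intensities,
                                  ev2[s]["lectin"].intensities)

    def test_no_case_samples_when_count_zero(self):
        d = two_pop_design(n_case={1: 0, 2: 3, 3: 3})
        _, meta, _ = simulate_flow_cohort(d)
        df = metadata_frame(meta)
        assert ((df.cohort == "case") & (df.age_group == 1)).sum() == 0

    def test_weight_effect_restricted_to_planted_stratum(self):
        d = two_pop_design(
            n_case={1: 8, 2: 8, 3: 8}, n_control={1: 8, 2: 8, 3: 8},
            events_per_sample=2000,
            effect_map=[FlowEffect(age_group=2, population="p1",
                                   weight_multiplier=3.0)])
        events, meta, truth = simulate_flow_cohort(d)
        assert truth["perturbed_age_groups"] == [2]
        frac = {}
        for m in meta:
            ev = events[m.sample_id]["immunoglobulin"]
            frac.setdefault((m.age_group, m.cohort), []).append(
                (ev.intensities[:, 0] > 100).mean())
        # planted group: cases enriched for p1 (0.3*3/(0.7+0.9)=0.56 vs 0.3)
        assert np.mean(frac[(2, "case")]) > np.mean(frac[(2, "control")]) + 0.1
        for g in (1, 3):
            assert abs(np.mean(frac[(g, "case")])
                       - np.mean(frac[(g, "control")])) < 0.05

    def test_unknown_population_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown population"):
            two_pop_design(effect_map=[FlowEffect(2, "nope", 2.0)])

    def test_unknown_age_group_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown age group"):
            two_pop_design(effect_map=[FlowEffect(9, "p1", 2.0)])

    def test_effect_weights_renormalized(self):
        from microsig.synthetic import _effective_panel

        d = two_pop_design(effect_map=[FlowEffect(2, "p1", 3.0)])
        w, _ = _effective_panel(d, "immunoglobulin", "case", 2)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w[1] == pytest.approx(0.9 / 1.6)


class TestTaxaCounts:
    def test_fixed_depth(self):
        d = two_pop_design(depth_range=(5000, 5000))
        counts, _, _ = simulate_taxa_counts(d)
        assert (counts.sum(axis=1) == 5000).all()

    def test_depth_within_range(self):
        d = two_pop_design(depth_range=(1000, 2000))
        counts, _, _ = simulate_taxa_counts(d)
        s = counts.sum(axis=1)
        assert (s >= 1000).all() and (s <= 2000).all()

    def test_null_pvalues_uniform(self):
        d = default_design(seed=3)
        d.n_case = {1: 0, 2: 15, 3: 0}
        d.n_control = {1: 0, 2: 15, 3: 0}
        counts, meta, _ = simulate_taxa_counts(d)
        df = metadata_frame(meta)
        case = df.cohort == "case"
        rel = counts.to_numpy(float)
        rel = rel / rel.sum(axis=1, keepdims=True)
        pvals = []
        for j in range(rel.shape[1]):
            a, b = rel[case.to_numpy(), j], rel[~case.to_numpy(), j]
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            pvals.append(stats.mannwhitneyu(a, b,
                                            alternative="two-sided").pvalue)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_log_fold_effect_detected(self):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            d = default_design(seed=100 + rep)
            d.n_case = {1: 15, 2: 0, 3: 0}
            d.n_control = {1: 15, 2: 0, 3: 0}
            d.planted_taxa_effects = [TaxaEffect(1, 10, 2.0)]
            counts, meta, truth = simulate_taxa_counts(d)
            assert truth["planted_taxa"] == ["taxon_010"]
            df = metadata_frame(meta)
            rel = counts.to_numpy(float)
            rel = rel / rel.sum(axis=1, keepdims=True)
            case = (df.cohort == "case").to_numpy()
            if rel[case, 10].mean() > rel[~case, 10].mean():
                hits += 1
        assert hits >= int(0.95 * n_rep)

    def test_overdispersion_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            two_pop_design(overdispersion=0.0)

    def test_taxa_effect_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            two_pop_design(planted_taxa_effects=[TaxaEffect(1, 99, 1.0)])


class TestNullCalibration:
    def test_null_cohort_population_fractions_exchangeable(self):
        """With an empty effect map, case/control differences in a
        population fraction are non-significant at alpha=0.01 in >=95% of
        seeded replicates."""
        nonsig = 0
        n_rep = 40
        for rep in range(n_rep):
            d = two_pop_design(seed=500 + rep, events_per_sample=500,
                               n_case={2: 8}, n_control={2: 8})
            events, meta, _ = simulate_flow_cohort(d)
            fr_case, fr_ctrl = [], []
            for m in meta:
                ev = events[m.sample_id]["immunoglobulin"]
                f = (ev.intensities[:, 0] > 100).mean()
                (fr_case if m.cohort == "case" else fr_ctrl).append(f)
            p = stats.mannwhitneyu(fr_case, fr_ctrl,
                                   alternative="two-sided").pvalue
            if p > 0.01:
                nonsig += 1
        assert nonsig >= int(0.95 * n_rep)


class TestMetadata:
    def test_sample_ids_unique_and_complete(self):
        meta = make_metadata(two_pop_design())
        ids = [m.sample_id for m in meta]
        assert len(set(ids)) == len(ids) == 18
        assert all(m.cohort in ("case", "control") for m in meta)
        assert all(m.age_group in (1, 2, 3) for m in meta)

    def test_ages_fall_in_group_ranges(self):
        from microsig.synthetic import AGE_RANGES

        meta = make_metadata(default_design(seed=1))
        for m in meta:
            lo, hi = AGE_RANGES[m.age_group]
            assert lo <= m.age <= hi
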