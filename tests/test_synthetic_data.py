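import math

import numpy as np
import pandas as pd
import pytest

from clmscreen.decode import call_hits, candidates, flag_anomalies
from clmscreen.synthetic_data import (
    ProfilePriors,
    StrainProfile,
    SubstrateKinetics,
    generate_strain_profiles,
    make_study_fixture,
    simulate_assay,
    simulate_study,
)


def strain(sid="s", oxygen_dep=True, **rates):
    return StrainProfile(sid, {"ketone": SubstrateKinetics(**rates)},
                         oxygen_dependent_oxidation=oxygen_dep)


class TestGenerateProfiles:
    def test_empty_library(self):
        assert generate_strain_profiles(0) == []

    def test_deterministic_under_seed(self):
        a = generate_strain_profiles(24, seed=42, substrates=("k1", "k2"))
        b = generate_strain_profiles(24, seed=42, substrates=("k1", "k2"))
        assert a == b

    def test_zero_rate_priors_give_inactive_library(self):
        priors = ProfilePriors(k_red_range=(0.0, 0.0), p_oxidizer=0.0)
        profiles = generate_strain_profiles(10, priors, seed=1)
        assert all(p.is_inactive() for p in profiles)
        df = simulate_assay(profiles, "ketone", [4, 24])
        assert (df["conversion"] == 0).all()

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            ProfilePriors(k_red_range=(0.5, 0.1))


class TestSimulateAssay:
    def test_empty_pool_transforms_nothing(self):
        df = simulate_assay([], "ketone", [4, 24])
        assert (df["conversion"] == 0).all()
        assert df["alcohol_ee"].isna().all()

    def test_single_first_order_reducer_closed_form(self):
        """k = 0.1/h on the (R)-channel: conversion 1 - exp(-2.4) at 24 h, ee +1."""
        df = simulate_assay([strain(k_red_R=0.1)], "ketone", [24.0])
        assert df["conversion"][0] == pytest.approx(1 - math.exp(-2.4), abs=1e-9)
        assert df["alcohol_ee"][0] == pytest.approx(1.0)

    def test_mass_conserved_with_decaying_reduction(self):
        members = [
            strain("a", k_red_R=0.2, k_red_S=0.6, reduction_decay=0.4),
            strain("b", k_ox_S=0.5),
        ]
        from clmscreen.synthetic_data import _integrate_pool, _pooled_terms

        terms, koS, koR = _pooled_terms(members, "ketone", "aerobic", 1.0)
        y = _integrate_pool(terms, koS, koR, np.array([1.0, 0.0, 0.0]),
                            np.linspace(0, 24, 25))
        assert np.allclose(y.sum(axis=1), 1.0, atol=1e-6)

    def test_pooled_equals_control_for_single_active_member(self):
        """A pool whose only active member is s behaves exactly like s alone."""
        active = strain("act", k_red_R=0.12, k_red_S=0.05, k_ox_S=0.2)
        inert = [StrainProfile(f"i{j}", {}) for j in range(4)]
        pooled = simulate_assay([active] + inert, "ketone", [4, 24])
        control = simulate_assay([active], "ketone", [4, 24], mode="control")
        assert np.allclose(pooled["conversion"], control["conversion"], atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_adding_oxidation_free_member_never_lowers_conversion(self, seed):
        rng = np.random.default_rng(seed)
        base = [strain(f"b{j}", k_red_R=rng.uniform(0, 0.3),
                       k_red_S=rng.uniform(0, 0.3)) for j in range(3)]
        extra = strain("x", k_red_R=rng.uniform(0, 0.3), k_red_S=rng.uniform(0, 0.3))
        t = np.linspace(0.5, 24, 8)
        without = simulate_assay(base, "ketone", t)["conversion"]
        with_extra = simulate_assay(base + [extra], "ketone", t)["conversion"]
        assert (with_extra >= without - 1e-12).all()

    def test_anaerobic_gates_oxygen_dependent_oxidase_only(self):
        oxidase = strain("ox", k_ox_S=0.5, oxygen_dep=True)
        dehydrogenase = strain("adh", k_ox_S=0.5, oxygen_dep=False)
        y0 = (0.0, 0.5, 0.5)
        silent = simulate_assay([oxidase], "ketone", [24], aeration="anaerobic", y0=y0)
        active = simulate_assay([dehydrogenase], "ketone", [24], aeration="anaerobic", y0=y0)
        assert silent["conversion"][0] == pytest.approx(0.0, abs=1e-12)
        # only the (S)-half of the racemate can react: conversion tends to 0.5
        assert active["conversion"][0] == pytest.approx(0.5, abs=1e-4)

    def test_seeded_noise_is_reproducible(self):
        m = [strain(k_red_R=0.1)]
        a = simulate_assay(m, "ketone", [4, 24], noise_sd=0.05, seed=9)
        b = simulate_assay(m, "ketone", [4, 24], noise_sd=0.05, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_clipped_to_unit_interval(self):
        m = [strain(k_red_R=2.0)]
        df = simulate_assay(m, "ketone", [24] * 1, noise_sd=0.5, seed=0)
        assert 0.0 <= df["conversion"][0] <= 1.0


class TestStudyFixture:
    def test_designs_satisfy_stated_constraints(self, study_fixture):
        for d in (study_fixture.clm1, study_fixture.clm2):
            assert d.n_strains == 12 and d.pool_size == 5
            assert (d.incidence.sum(axis=0) == 5).all()
            rows = sorted(d.incidence.sum(axis=1).tolist())
            assert rows.count(2) == 8 and rows.count(1) == 4

    def test_truth_signatures(self, study_fixture):
        fx = study_fixture
        assert fx.clm1.signature("s01") == {"D"}
        assert fx.clm1.signature("s02") == fx.clm1.signature("s03") == {"A", "D"}
        assert fx.clm1.signature("s04") == {"B"}
        assert fx.clm2.signature("s13") == {"E"}
        assert fx.clm2.signature("s14") == fx.clm2.signature("s15") == {"E", "F"}

    @staticmethod
    def _clm1_rows(fx, readouts):
        return readouts[readouts["batch_or_strain"].isin(fx.clm1.batch_ids)]

    def test_aliphatic_channel_identifies_batch_D_strain(self, study_fixture,
                                                         noiseless_readouts):
        rows = self._clm1_rows(study_fixture, noiseless_readouts)
        hits = call_hits(rows, study_fixture.clm1, 0.5, 24.0)
        rep = candidates(study_fixture.clm1, hits["2-octanone"])
        assert rep.unique
        assert rep.candidate_sets == (("s01",),)

    def test_aromatic_channel_gives_two_candidates(self, study_fixture,
                                                   noiseless_readouts):
        rows = self._clm1_rows(study_fixture, noiseless_readouts)
        hits = call_hits(rows, study_fixture.clm1, 0.5, 24.0)
        for sub in ("acetonaphthone", "propiophenone"):
            rep = candidates(study_fixture.clm1, hits[sub])
            assert rep.hit_set == {"A", "D"}
            assert rep.candidate_sets == (("s02",), ("s03",))

    def test_acetophenone_channel_raises_anomaly_on_E_and_F(self, noiseless_readouts):
        rows = noiseless_readouts[noiseless_readouts["substrate"] == "acetophenone"]
        flagged = {
            a.batch for a in flag_anomalies(rows) if a.type == "non_monotone_product"
        }
        assert flagged == {"E", "F"}

    def test_fast_reducer_hits_E_at_4h(self, study_fixture, noiseless_readouts):
        rows = noiseless_readouts[
            noiseless_readouts["batch_or_strain"].isin(study_fixture.clm2.batch_ids)
        ]
        hits = call_hits(rows, study_fixture.clm2, 0.5, 4.0)
        assert "E" in hits["3-octanone"].active_batches

    def test_study_table_is_seed_deterministic(self, study_fixture):
        a = simulate_study(study_fixture, seed=5)
        b = simulate_study(study_fixture, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_inhibition_variant_has_inert_b_strain(self):
        fx = make_study_fixture(batch_b_mechanism="inhibition")
        assert fx.profiles["s04"].is_inactive()
        ox = make_study_fixture(batch_b_mechanism="oxidation")
        assert not ox.profiles["s04"].is_inactive()
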