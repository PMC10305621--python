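import itertools

import numpy as np
import pandas as pd
import pytest

from clmscreen.decode import (
    HitPattern,
    IncompleteDataError,
    call_hits,
    candidates,
    flag_anomalies,
    plan_confirmation,
    suspect_strains,
)
from clmscreen.design import PoolDesign, build_design
from clmscreen.synthetic_data import (
    StrainProfile,
    SubstrateKinetics,
    simulate_assay,
)


def hit(design, batches, substrate="sub", threshold=0.5, t=24.0):
    return HitPattern(
        substrate=substrate,
        active_batches=frozenset(batches),
        scores={b: (0.9 if b in batches else 0.1) for b in design.batch_ids},
        threshold=threshold,
        timepoint_used=t,
    )


def readout_table(rows):
    return pd.DataFrame(
        rows,
        columns=["batch_or_strain", "substrate", "time_h", "conversion",
                 "alcohol_ee", "aeration", "mode"],
    )


def brute_force_candidates(design, hit_set, max_actives):
    """Independent oracle: bitmask enumeration over all strain subsets."""
    sigs = [design.signature(s) for s in design.strain_ids]
    out = []
    n = design.n_strains
    for mask in range(1, 1 << n):
        idx = [i for i in range(n) if mask >> i & 1]
        if len(idx) > max_actives:
            continue
        union = frozenset().union(*(sigs[i] for i in idx))
        if union == frozenset(hit_set):
            out.append(tuple(design.strain_ids[i] for i in idx))
    out.sort(key=lambda cs: (len(cs), cs))
    return out


class TestCallHits:
    def test_all_zero_conversions_give_empty_hit_set(self):
        d = build_design(4, 2, 2, seed=0)
        rows = readout_table(
            [(b, "sub", 24.0, 0.0, np.nan, "aerobic", "pooled") for b in d.batch_ids]
        )
        hits = call_hits(rows, d, 0.5, 24.0)
        assert hits["sub"].active_batches == frozenset()

    def test_missing_batch_is_an_error(self):
        d = build_design(4, 2, 2, seed=0)
        rows = readout_table([("A", "sub", 24.0, 0.9, 0.5, "aerobic", "pooled")])
        with pytest.raises(IncompleteDataError):
            call_hits(rows, d, 0.5, 24.0)

    def test_raising_threshold_never_enlarges_hit_set(self):
        d = build_design(8, 4, 3, seed=2)
        rng = np.random.default_rng(0)
        rows = readout_table(
            [(b, "sub", 24.0, rng.uniform(), np.nan, "aerobic", "pooled")
             for b in d.batch_ids]
        )
        previous = None
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            hs = call_hits(rows, d, thr, 24.0)["sub"].active_batches
            if previous is not None:
                assert hs <= previous
            previous = hs


class TestCandidates:
    def test_empty_hit_set_means_no_strain(self, study_fixture):
        rep = candidates(study_fixture.clm1, hit(study_fixture.clm1, []))
        assert rep.unique and rep.candidate_sets == ((),)

    def test_exclusive_batch_gives_unique_candidate(self, study_fixture):
        rep = candidates(study_fixture.clm1, hit(study_fixture.clm1, ["D"]))
        assert rep.unique and rep.candidate_sets == (("s01",),)

    def test_shared_signature_gives_two_candidates(self, study_fixture):
        rep = candidates(study_fixture.clm1, hit(study_fixture.clm1, ["A", "D"]))
        assert rep.candidate_sets == (("s02",), ("s03",))
        assert not rep.unique
        assert rep.confirmation_plan == ("s02", "s03")

    def test_EF_pair_gives_two_candidates(self, study_fixture):
        rep = candidates(study_fixture.clm2, hit(study_fixture.clm2, ["E", "F"]))
        assert rep.candidate_sets == (("s14",), ("s15",))

    def test_inconsistent_hit_set_explained(self):
        M = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        d = PoolDesign(4, 2, M, 2, ("w", "x", "y", "z"), ("A", "B"))
        rep = candidates(d, hit(d, ["A", "B"]), max_actives=1)
        assert rep.candidate_sets == ()
        assert "tandem" in rep.explanation

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle_on_random_designs(self, seed):
        rng = np.random.default_rng(seed)
        n_strains = int(rng.integers(3, 11))
        n_batches = int(rng.integers(2, 7))
        pool_min = -(-n_strains // n_batches)
        pool = int(rng.integers(pool_min, n_strains + 1))
        d = build_design(n_strains, n_batches, pool, seed=seed)
        sigs = list(d.signatures().values())
        # probe realized unions plus a random batch subset
        probes = {frozenset(s) for s in sigs}
        probes |= {a | b for a, b in itertools.combinations(sigs, 2)}
        probes.add(frozenset(
            rng.choice(d.batch_ids, size=max(1, n_batches // 2), replace=False)
        ))
        for max_actives in (1, 2):
            for H in probes:
                got = candidates(d, hit(d, H), max_actives).candidate_sets
                assert list(got) == brute_force_candidates(d, H, max_actives)

    @pytest.mark.parametrize("seed", range(200))
    def test_noiseless_single_active_decoding_contains_truth(self, seed):
        """Simulated single-active pools always decode to a set holding the truth."""
        rng = np.random.default_rng(seed)
        d = build_design(int(rng.integers(4, 13)), 4, 3, seed=seed)
        active_id = str(rng.choice(d.strain_ids))
        profiles = {
            s: StrainProfile(
                s, {"sub": SubstrateKinetics(k_red_R=0.3)} if s == active_id else {}
            )
            for s in d.strain_ids
        }
        rows = pd.concat([
            simulate_assay(
                [profiles[s] for s in d.members(b)], "sub", [24.0],
                batch_or_strain=b,
            )
            for b in d.batch_ids
        ])
        hits = call_hits(rows, d, 0.5, 24.0)["sub"]
        assert hits.active_batches == d.signature(active_id)
        rep = candidates(d, hits, max_actives=1)
        assert (active_id,) in rep.candidate_sets


class TestFlagAnomalies:
    def test_product_drop_flagged(self):
        rows = readout_table([
            ("E", "sub", 4.0, 0.75, -0.2, "aerobic", "pooled"),
            ("E", "sub", 24.0, 0.25, 0.9, "aerobic", "pooled"),
        ])
        flags = flag_anomalies(rows)
        assert [a.type for a in flags] == ["non_monotone_product"]
        assert flags[0].evidence["product_early"] == 0.75

    def test_control_assay_divergence_flagged(self):
        rows = readout_table([
            ("B", "sub", 24.0, 0.51, np.nan, "aerobic", "pooled"),
            ("B", "sub", 24.0, 0.90, np.nan, "aerobic", "control"),
        ])
        flags = flag_anomalies(rows)
        assert [a.type for a in flags] == ["control_assay_divergence"]

    def test_identical_curves_raise_nothing(self):
        rows = readout_table([
            ("A", "sub", 4.0, 0.4, np.nan, "aerobic", m) for m in ("pooled", "control")
        ] + [
            ("A", "sub", 24.0, 0.8, np.nan, "aerobic", m) for m in ("pooled", "control")
        ])
        assert flag_anomalies(rows) == []

    def test_single_timepoint_skips_monotonicity_check(self, caplog):
        rows = readout_table([("A", "sub", 24.0, 0.9, np.nan, "aerobic", "pooled")])
        import logging

        with caplog.at_level(logging.INFO, logger="clmscreen.decode"):
            assert flag_anomalies(rows) == []
        assert any("skipped" in r.message for r in caplog.records)


class TestSuspicionAndPlanning:
    def test_suspects_strains_with_matching_signature(self, study_fixture):
        from clmscreen.decode import Anomaly

        anoms = [
            Anomaly("E", "acetophenone", "non_monotone_product", {}),
            Anomaly("F", "acetophenone", "non_monotone_product", {}),
        ]
        suspects = suspect_strains(study_fixture.clm2, anoms)
        assert suspects["acetophenone"] == ("s14", "s15")

    def test_two_candidates_need_two_confirmations(self, study_fixture):
        rep = candidates(study_fixture.clm1, hit(study_fixture.clm1, ["A", "D"]))
        plan = plan_confirmation(rep, study_fixture.clm1, n_substrates=1)
        assert plan.pooled_assays == 4
        assert plan.confirmatory_assays == 2
        assert plan.total == 6
        assert plan.conventional == 12

    def test_unique_candidate_needs_no_confirmation(self, study_fixture):
        rep = candidates(study_fixture.clm1, hit(study_fixture.clm1, ["D"]))
        plan = plan_confirmation(rep, study_fixture.clm1)
        assert plan.confirmatory_assays == 0

    def test_failed_decoding_falls_back_to_batch_members(self, study_fixture):
        d = study_fixture.clm1
        rep = candidates(d, hit(d, ["A", "B", "C", "D"]), max_actives=1)
        assert rep.candidate_sets == ()
        plan = plan_confirmation(rep, d)
        assert plan.confirmatory_assays == d.n_strains  # all batches implicated
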