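import numpy as np
import pandas as pd
import pytest

from oracles import attach_oracle
from silacq.amt_db import FilterParams, attach_ids, build_amt, filter_amt, merge_technical
from silacq.synthetic_data import SimConfig, build_manifest


def make_pair(run="r1", charge=2, light=1000.0, heavy=1008.0142036, apex=40.0, lid=0, hid=1, ria=0.5):
    return {
        "run_id": run,
        "charge": charge,
        "light_id": lid,
        "heavy_id": hid,
        "mass_light": light,
        "mass_heavy": heavy,
        "shift_class": "K",
        "ppm_error": 0.0,
        "rt_apex": apex,
        "area_light": 100.0 * ria,
        "area_heavy": 100.0 * (1 - ria),
        "ria": ria,
    }


def make_id(run="r1", seq="PEPTIDEK", charge=2, mass=1000.0, rt=40.0, score=50.0, acc="P1"):
    return {
        "run_id": run,
        "sequence": seq,
        "charge": charge,
        "mono_mass_da": mass,
        "rt_min": rt,
        "score": score,
        "accession": acc,
    }


MANIFEST = build_manifest(SimConfig())


class TestAttachIds:
    def test_within_tolerances_attached(self):
        pairs = pd.DataFrame([make_pair(light=1000.000003, apex=40.2)])
        ids = pd.DataFrame([make_id(mass=1000.0, rt=40.0)])
        out = attach_ids(pairs, ids, ppm_tol=5.0, rt_tol=5.0)
        assert len(out) == 1
        assert out.iloc[0]["sequence"] == "PEPTIDEK"

    def test_rt_gap_blocks(self):
        pairs = pd.DataFrame([make_pair(light=1000.000003, apex=40.2)])
        ids = pd.DataFrame([make_id(mass=1000.0, rt=52.0)])
        assert len(attach_ids(pairs, ids)) == 0

    def test_heavy_mass_matches_too(self):
        pairs = pd.DataFrame([make_pair()])
        ids = pd.DataFrame([make_id(mass=1008.0142, rt=40.0)])
        assert len(attach_ids(pairs, ids)) == 1

    def test_nearest_ppm_wins(self):
        pairs = pd.DataFrame(
            [make_pair(lid=0, hid=1, light=1000.0000), make_pair(lid=2, hid=3, light=1000.0020)]
        )
        ids = pd.DataFrame([make_id(mass=1000.0001)])
        out = attach_ids(pairs, ids)
        assert len(out) == 1
        assert out.iloc[0]["light_id"] == 0

    def test_equal_ppm_tie_goes_to_nearer_rt(self):
        pairs = pd.DataFrame(
            [make_pair(lid=0, hid=1, apex=41.0), make_pair(lid=2, hid=3, apex=39.0)]
        )
        ids = pd.DataFrame([make_id(mass=1000.0, rt=39.5)])
        log = []
        out = attach_ids(pairs, ids, log=log)
        assert out.iloc[0]["light_id"] == 2
        assert len(log) == 1

    def test_one_id_per_pair_per_sequence(self):
        pairs = pd.DataFrame([make_pair()])
        ids = pd.DataFrame([make_id(score=30.0), make_id(score=90.0)])
        out = attach_ids(pairs, ids)
        assert len(out) == 1
        assert out.iloc[0]["id_score"] == 90.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_nearest_neighbor_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        pairs = pd.DataFrame(
            [
                make_pair(
                    run=f"r{rng.integers(2)}",
                    charge=int(rng.choice([2, 3])),
                    light=float(rng.uniform(800, 2000)),
                    apex=float(rng.uniform(20, 60)),
                    lid=2 * k,
                    hid=2 * k + 1,
                )
                for k in range(n)
            ]
        )
        pairs["mass_heavy"] = pairs["mass_light"] + 8.0142036
        ids = pd.DataFrame(
            [
                make_id(
                    run=f"r{rng.integers(2)}",
                    seq=f"SEQ{k}K",
                    charge=int(rng.choice([2, 3])),
                    mass=float(
                        rng.choice(pairs["mass_light"]) * (1 + rng.normal(0, 3e-6))
                    ),
                    rt=float(rng.uniform(20, 60)),
                )
                for k in range(n)
            ]
        )
        got = attach_ids(pairs, ids)
        expected = attach_oracle(pairs, ids, 5.0, 5.0)
        got_set = sorted(zip(got["run_id"], got["sequence"], got["light_id"].astype(int)))
        assert got_set == expected


def labeled_row(seq="AAAK", charge=2, run="mix_fwd_b1_t1", ria=0.5, mass=400.0, rt=40.0, score=50.0, acc="P1"):
    return {
        "run_id": run,
        "charge": charge,
        "light_id": 0,
        "heavy_id": 1,
        "mass_light": mass,
        "mass_heavy": mass + 8.0142036,
        "shift_class": "K",
        "rt_apex": rt,
        "area_light": 50.0,
        "area_heavy": 50.0,
        "ria": ria,
        "sequence": seq,
        "accession": acc,
        "id_score": score,
        "id_mass": mass,
        "id_rt": rt,
    }


class TestBuildAmt:
    def test_presence_is_run_fraction(self):
        runs = MANIFEST["run_id"].head(12)
        labeled = pd.DataFrame([labeled_row(run=r) for r in runs])
        entries, obs = build_amt(labeled, MANIFEST)
        assert len(entries) == 1
        assert entries.iloc[0]["presence"] == pytest.approx(0.5)
        assert len(obs) == 12

    def test_single_observation_zero_span(self):
        labeled = pd.DataFrame([labeled_row()])
        entries, _ = build_amt(labeled, MANIFEST)
        assert entries.iloc[0]["rt_span"] == 0.0

    def test_highest_scoring_accession_wins(self):
        labeled = pd.DataFrame(
            [
                labeled_row(run="mix_fwd_b1_t1", acc="P1", score=10.0),
                labeled_row(run="mix_fwd_b1_t2", acc="P2", score=99.0),
            ]
        )
        entries, _ = build_amt(labeled, MANIFEST)
        assert entries.iloc[0]["accession"] == "P2"

    def test_per_entry_key_is_sequence_charge(self):
        labeled = pd.DataFrame(
            [labeled_row(charge=2), labeled_row(charge=3), labeled_row(seq="GGGR")]
        )
        entries, _ = build_amt(labeled, MANIFEST)
        assert len(entries) == 3

    def test_observed_mass_near_theoretical(self, small_noisy_experiment):
        from silacq.pair_quant import build_features, match_pairs

        exp = small_noisy_experiment
        pairs = match_pairs(build_features(exp.detections))
        labeled = attach_ids(pairs, exp.identifications)
        entries, _ = build_amt(labeled, exp.manifest)
        ppm_sigma = exp.truth.config.ppm_sigma
        err_ppm = (entries["obs_mass"] - entries["theo_mass"]) / entries["theo_mass"] * 1e6
        # chance cross-channel matches can misattach an occasional id, so
        # the 3-sigma bound is asserted for the bulk, not the extremes
        assert np.quantile(np.abs(err_ppm), 0.99) <= 3 * ppm_sigma
        assert np.median(np.abs(err_ppm)) <= ppm_sigma


def entry_row(eid, presence=0.5, rt_span=2.0, mean_rt=45.0):
    return {
        "entry_id": eid,
        "sequence": f"S{eid}",
        "charge": 2,
        "accession": "P1",
        "theo_mass": 1000.0,
        "obs_mass": 1000.0,
        "mean_rt": mean_rt,
        "rt_span": rt_span,
        "presence": presence,
        "n_runs": 12,
    }


class TestFilterAmt:
    def setup_method(self):
        self.entries = pd.DataFrame(
            [
                entry_row(0),  # clean
                entry_row(1, presence=0.2),  # below 25% presence
                entry_row(2, rt_span=12.0),  # RT varies > 10 min
                entry_row(3, mean_rt=6.0),  # inside wash window
                entry_row(4, mean_rt=125.0),  # post-gradient
            ]
        )
        self.obs = pd.DataFrame(
            {"entry_id": range(5), "sequence": "x", "charge": 2, "run_id": "r", "ria": 0.5, "mass": 1000.0, "rt": 45.0}
        )

    def test_each_rule_drops_intended_entry(self):
        kept, obs, counts = filter_amt(self.entries, self.obs)
        assert list(kept["entry_id"]) == [0]
        assert counts == {
            "low_presence": 1,
            "rt_span": 1,
            "excluded_window": 2,
            "total_dropped": 4,
        }
        assert list(obs["entry_id"]) == [0]

    def test_idempotent(self):
        kept1, obs1, _ = filter_amt(self.entries, self.obs)
        kept2, obs2, counts2 = filter_amt(kept1, obs1)
        pd.testing.assert_frame_equal(kept1, kept2)
        assert counts2["total_dropped"] == 0

    def test_survivors_satisfy_all_predicates(self):
        params = FilterParams()
        kept, _, _ = filter_amt(self.entries, self.obs, params)
        for row in kept.itertuples():
            assert row.presence >= params.min_presence
            assert row.rt_span <= params.max_rt_span
            for lo, hi in params.excluded_rt_windows:
                assert not (lo <= row.mean_rt <= hi)

    def test_params_validated(self):
        with pytest.raises(ValueError):
            FilterParams(min_presence=0.0)
        with pytest.raises(ValueError):
            FilterParams(max_rt_span=-1.0)


class TestMergeTechnical:
    def obs(self, rows):
        return pd.DataFrame(
            rows, columns=["entry_id", "sequence", "charge", "run_id", "ria", "mass", "rt"]
        )

    def test_duplicates_averaged(self):
        obs = self.obs(
            [
                (0, "A", 2, "mix_fwd_b1_t1", 0.60, 1000.0, 40.0),
                (0, "A", 2, "mix_fwd_b1_t2", 0.64, 1000.000001, 40.5),
            ]
        )
        merged = merge_technical(obs, MANIFEST)
        assert len(merged) == 1
        assert merged.iloc[0]["ria"] == pytest.approx(0.62)
        assert merged.iloc[0]["n_obs"] == 2

    def test_mass_outside_tolerance_kept_separate(self):
        obs = self.obs(
            [
                (0, "A", 2, "mix_fwd_b1_t1", 0.60, 1000.0, 40.0),
                (0, "A", 2, "mix_fwd_b1_t2", 0.64, 1000.011, 40.0),  # 11 ppm apart
            ]
        )
        log = []
        merged = merge_technical(obs, MANIFEST, log=log)
        assert len(merged) == 2
        assert (merged["n_obs"] == 1).all()
        assert len(log) == 1

    def test_rt_outside_tolerance_kept_separate(self):
        obs = self.obs(
            [
                (0, "A", 2, "mix_fwd_b1_t1", 0.60, 1000.0, 40.0),
                (0, "A", 2, "mix_fwd_b1_t2", 0.64, 1000.0, 46.0),
            ]
        )
        assert len(merge_technical(obs, MANIFEST)) == 2

    def test_distinct_entry_count_preserved(self):
        obs = self.obs(
            [
                (0, "A", 2, "mix_fwd_b1_t1", 0.60, 1000.0, 40.0),
                (0, "A", 2, "mix_fwd_b1_t2", 0.64, 1000.0, 40.0),
                (1, "B", 2, "mix_rev_b2_t1", 0.50, 1200.0, 50.0),
                (0, "A", 2, "ctrl_hela_b1_t1", 0.52, 1000.0, 40.1),
            ]
        )
        merged = merge_technical(obs, MANIFEST)
        assert merged["entry_id"].nunique() == obs["entry_id"].nunique()

    def test_noise_free_bookkeeping(self, noise_free_experiment):
        from silacq.pair_quant import build_features, match_pairs

        exp = noise_free_experiment
        pairs = match_pairs(build_features(exp.detections))
        labeled = attach_ids(pairs, exp.identifications)
        entries, obs = build_amt(labeled, exp.manifest)
        merged = merge_technical(obs, exp.manifest)
        # every peptide detected in all runs: post-merge one row per
        # (entry, sample_type, bio_rep), i.e. 12 per entry
        per_entry = merged.groupby("entry_id").size()
        assert (per_entry == 12).all()
        assert (merged["n_obs"] == 2).all()
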