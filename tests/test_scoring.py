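import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_model
from ppiscorekit import scoring
from ppiscorekit.model_io import ModelResult, ScoreRecord
from ppiscorekit.scoring import (
    compute_hiq_score,
    compute_iq_score,
    pae_gate,
    score_and_filter,
    select_best_model,
)

unit = st.floats(0, 1, allow_nan=False)
pi_scores = st.floats(-2.63, 2.63, allow_nan=False)


def model(iptm, idx):
    return ModelResult(job_id="A_and_B", model_index=idx, iptm=iptm, iptm_ptm=iptm)


class TestSelectBestModel:
    def test_argmax(self):
        models = [model(0.3, 1), model(0.9, 2), model(0.5, 3)]
        assert select_best_model(models).model_index == 2

    def test_single(self):
        m = model(0.1, 1)
        assert select_best_model([m]) is m

    def test_tie_goes_to_lowest_index(self):
        assert select_best_model([model(0.7, 1), model(0.7, 2)]).model_index == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_model([])


class TestCompositeScores:
    def test_iq_at_constituent_thresholds(self):
        assert round(compute_iq_score(0.05, 0.5, 0.5), 2) == 50.38

    def test_iq_bounds(self):
        assert compute_iq_score(-2.63, 0, 0) == 0
        assert compute_iq_score(2.63, 1, 1) == pytest.approx(100)

    def test_iq_hand_evaluated(self):
        # ((1.0+2.63)/5.26)*40 + 0.8*30 + 0.7*30 = 72.6046...
        assert compute_iq_score(1.0, 0.8, 0.7) == pytest.approx(72.6046, abs=1e-4)

    def test_hiq_at_constituent_thresholds(self):
        assert round(compute_hiq_score([0.05], 0.5), 2) == 50.57

    def test_hiq_bounds(self):
        assert compute_hiq_score([-2.63, -2.63], 0) == 0
        assert compute_hiq_score([2.63], 1) == pytest.approx(100)

    def test_hiq_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_hiq_score([], 0.5)

    def test_out_of_range_iptm_rejected(self):
        with pytest.raises(ValueError):
            compute_iq_score(0.0, 1.2, 0.5)
        with pytest.raises(ValueError):
            compute_iq_score(0.0, 0.5, -0.1)

    def test_pi_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            high = compute_iq_score(10.0, 0.5, 0.5)
        assert high == pytest.approx(compute_iq_score(2.63, 0.5, 0.5))

    @given(pi=pi_scores, t=unit, d=unit, eps=st.floats(1e-6, 0.5))
    @settings(max_examples=60, deadline=None)
    def test_iq_strictly_increasing_each_argument(self, pi, t, d, eps):
        base = compute_iq_score(pi, t, d)
        if pi + eps <= 2.63:
            assert compute_iq_score(pi + eps, t, d) > base
        if t + eps <= 1:
            assert compute_iq_score(pi, t + eps, d) > base
        if d + eps <= 1:
            assert compute_iq_score(pi, t, d + eps) > base

    @given(pi=pi_scores, t=unit, eps=st.floats(1e-6, 0.5))
    @settings(max_examples=60, deadline=None)
    def test_hiq_strictly_increasing_each_argument(self, pi, t, eps):
        base = compute_hiq_score([pi], t)
        if pi + eps <= 2.63:
            assert compute_hiq_score([pi + eps], t) > base
        if t + eps <= 1:
            assert compute_hiq_score([pi], t + eps) > base

    @given(pi=pi_scores, t=unit, n=st.integers(1, 6))
    @settings(max_examples=60, deadline=None)
    def test_hiq_mean_invariance(self, pi, t, n):
        """n identical interface scores give the same hiQ as one."""
        assert compute_hiq_score([pi] * n, t) == pytest.approx(
            compute_hiq_score([pi], t)
        )

    @given(pi=pi_scores, t=unit, d=unit)
    @settings(max_examples=300, deadline=None)
    def test_scores_in_0_100(self, pi, t, d):
        assert 0 <= compute_iq_score(pi, t, d) <= 100 + 1e-9
        assert 0 <= compute_hiq_score([pi], t) <= 100 + 1e-9


class TestPaeGate:
    def test_all_zero_passes(self):
        passed, m = pae_gate(make_model(np.zeros((6, 6)), [3, 3]))
        assert passed and m == 0

    def test_uniform_30_inter_block_fails(self):
        pae = np.full((6, 6), 5.0)
        pae[:3, 3:] = 30.0
        pae[3:, :3] = 30.0
        passed, m = pae_gate(make_model(pae, [3, 3]))
        assert not passed and m == 30.0

    def test_single_low_cell_amid_20s_passes(self):
        pae = np.full((8, 8), 3.0)
        pae[:4, 4:] = 20.0
        pae[4:, :4] = 20.0
        pae[1, 6] = 7.5
        passed, m = pae_gate(make_model(pae, [4, 4]))
        assert passed and m == 7.5
        # brute-force scan of the inter-chain region agrees
        brute = min(pae[i, j] for i in range(8) for j in range(8)
                    if (i < 4) != (j < 4))
        assert m == brute

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            pae_gate(make_model(np.zeros((4, 4)), [4]))

    def test_alternative_statistics(self):
        pae = np.full((4, 4), 2.0)
        pae[:2, 2:] = 12.0
        pae[2:, :2] = 12.0
        pae[0, 2] = 4.0
        m = make_model(pae, [2, 2])
        assert pae_gate(m, stat="min") == (True, 4.0)
        passed_med, med = pae_gate(m, stat="median")
        assert not passed_med and med == 12.0

    def test_three_chain_pairs_all_scanned(self):
        pae = np.full((9, 9), 20.0)
        np.fill_diagonal(pae, 0.0)
        pae[7, 1] = 6.0  # chain C vs chain A orientation
        passed, m = pae_gate(make_model(pae, [3, 3, 3]))
        assert passed and m == 6.0


class TestScoreAndFilter:
    def hetero_inputs(self, pi, iptm_ptm, pdockq, min_pae, job="A_and_B"):
        pae = np.full((6, 6), 3.0)
        pae[:3, 3:] = min_pae + 7.0
        pae[3:, :3] = min_pae + 7.0
        pae[0, 3] = min_pae
        models = {job: make_model(pae, [3, 3], job_id=job)}
        recs = [ScoreRecord(job, 1, 0.8, iptm_ptm, (pi,), pdockq)]
        return models, recs

    def test_hand_evaluated_retention(self):
        models, recs = self.hetero_inputs(1.0, 0.8, 0.7, 4.0)
        (s,), _ = score_and_filter(models, recs)
        assert s.iq_score == pytest.approx(72.6046, abs=1e-4)
        assert s.retained and s.min_interchain_pae == 4.0

    def test_gate_failure_reason_and_no_score(self):
        models, recs = self.hetero_inputs(1.2, 0.85, 0.8, 15.0)
        (s,), _ = score_and_filter(models, recs)
        assert not s.retained
        assert s.iq_score is None
        assert "PAE gate" in s.reason

    def test_missing_pdockq_for_hetero_rejected(self):
        models, recs = self.hetero_inputs(1.0, 0.8, None, 4.0)
        with pytest.raises(ValueError, match="pdockq"):
            score_and_filter(models, recs)

    def test_shallow_flag_independent_of_retention(self):
        models, recs = self.hetero_inputs(1.0, 0.8, 0.7, 4.0)
        (s,), _ = score_and_filter(models, recs, shallow_ids=["A"])
        assert s.retained and s.unreliable_msa

    def test_cohort_retained_matches_manifest(self, pipeline_results):
        results, manifest, _ = pipeline_results
        got_het = sorted(s.job_id for s in results["hetero"] if s.retained)
        got_homo = sorted(h.job_id for h in results["homo"] if h.retained)
        assert got_het == manifest["expected_retained_hetero"]
        assert got_homo == manifest["expected_retained_homo"]
        for s in results["hetero"]:
            expected = manifest["jobs"][s.job_id]["expected_iq_score"]
            if expected is None:
                assert s.iq_score is None
            else:
                assert s.iq_score == pytest.approx(expected, abs=1e-6)
        for h in results["homo"]:
            expected = manifest["jobs"][h.job_id]["expected_hiq_score"]
            if expected is None:
                assert h.hiq_score is None
            else:
                assert h.hiq_score == pytest.approx(expected, abs=1e-6)

    def test_retention_monotone_in_cutoff(self):
        rng = np.random.default_rng(11)
        models, recs = {}, []
        for k in range(40):
            job = f"A{k}_and_B{k}"
            m, r = self.hetero_inputs(
                float(rng.uniform(-2.6, 2.6)), float(rng.uniform(0, 1)),
                float(rng.uniform(0, 1)), float(rng.uniform(0, 20)), job=job,
            )
            models.update(m)
            recs += r
        retained_sets = []
        for cutoff in (30, 50, 70):
            het, _ = score_and_filter(models, recs, iq_cutoff=cutoff)
            retained_sets.append({s.job_id for s in het if s.retained})
        assert retained_sets[2] <= retained_sets[1] <= retained_sets[0]

    def test_oracle_brute_force_cohort(self):
        """score_and_filter equals straight-line formula+gate+cutoff per record."""
        rng = np.random.default_rng(5)
        models, recs, expected = {}, [], {}
        for k in range(300):
            job = f"X{k}_and_Y{k}"
            pi = float(rng.uniform(-3, 3))
            t = float(rng.uniform(0, 1))
            d = float(rng.uniform(0, 1))
            min_pae = float(rng.uniform(0, 25))
            m, r = self.hetero_inputs(pi, t, d, min_pae, job=job)
            models.update(m)
            recs += r
            pi_c = min(2.63, max(-2.63, pi))
            iq = ((pi_c + 2.63) / 5.26) * 40 + t * 30 + d * 30
            expected[job] = (min_pae <= 10.0) and (iq > 50.0)
        het, _ = score_and_filter(models, recs)
        assert {s.job_id: s.retained for s in het} == expected

    def test_sorted_retained_first_descending(self):
        models, recs = {}, []
        for k, pi in enumerate([0.5, 2.0, -2.0]):
            m, r = self.hetero_inputs(pi, 0.8, 0.8, 4.0, job=f"A{k}_and_B{k}")
            models.update(m)
            recs += r
        het, _ = score_and_filter(models, recs)
        scores = [s.iq_score for s in het if s.retained]
        assert scores == sorted(scores, reverse=True)
        assert [s.retained for s in het] == sorted(
            [s.retained for s in het], reverse=True
        )
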