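"""Within/across-hand decoding schemes, aggregation, and calibration."""
import numpy as np
import pytest

import braillemvpa as bm
from braillemvpa.decoding import grand_average

from conftest import make_epochs


def planted_pseudo(n_letters=4, n_pseudo=5, d=16, mix=1.0, snr=3.0,
                   noise=1.0, seed=0, timed=False):
    """Pseudo-trial array with a planted code: mix=1 hand-specific,
    mix=0 hand-independent."""
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(n_letters, 2, d))
    Q = rng.normal(size=(n_letters, 1, d))
    code = snr * (mix * P + (1 - mix) * Q)
    shape = (n_letters, 2, n_pseudo, d) + ((3,) if timed else ())
    eps = noise * rng.normal(size=shape)
    sig = code[:, :, None, :, None] if timed else code[:, :, None, :]
    return sig + eps


class TestPairwiseCv:
    def test_separable_pair_is_perfect(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 6)) + 8.0
        b = rng.normal(size=(5, 6)) - 8.0
        assert bm.pairwise_cv_decode(a, b) == 100.0

    def test_null_pair_averages_to_chance(self):
        rng = np.random.default_rng(1)
        accs = [bm.pairwise_cv_decode(rng.normal(size=(5, 8)),
                                      rng.normal(size=(5, 8)))
                for _ in range(300)]
        assert abs(np.mean(accs) - 50.0) < 2.5

    def test_engines_agree(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 5, 12))
        acc1 = bm.pairwise_cv_decode(a, b, engine="batched")
        acc2 = bm.pairwise_cv_decode(a, b, engine="libsvm")
        assert acc1 == acc2

    def test_shape_validation(self):
        with pytest.raises(ValueError, match="matching"):
            bm.pairwise_cv_decode(np.zeros((5, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError, match="dimensionality"):
            bm.pairwise_cv_decode(np.zeros((5, 3)), np.zeros((5, 3)),
                                  np.zeros((5, 4)), np.zeros((5, 4)))


class TestSchemes:
    def test_pair_counts(self):
        pseudo = planted_pseudo(n_letters=8)
        res = bm.within_hand_decode(pseudo)
        off = ~np.isnan(res.accuracies)
        assert off.sum() == 2 * 28  # 28 unordered pairs, symmetric
        pseudo2 = planted_pseudo(n_letters=2)
        res2 = bm.within_hand_decode(pseudo2)
        assert (~np.isnan(res2.accuracies)).sum() == 2

    def test_hand_specific_code_dissociates_schemes(self):
        pseudo = planted_pseudo(mix=1.0, seed=3)
        within = bm.within_hand_decode(pseudo)
        across = bm.across_hand_decode(pseudo)
        assert within.grand_mean() > 85.0
        assert abs(across.grand_mean() - 50.0) < 12.0

    def test_shared_code_generalizes_across_hands(self):
        pseudo = planted_pseudo(mix=0.0, seed=4)
        within = bm.within_hand_decode(pseudo)
        across = bm.across_hand_decode(pseudo)
        assert across.grand_mean() > 85.0
        assert abs(within.grand_mean() - across.grand_mean()) < 10.0

    def test_identical_hands_make_across_equal_within(self):
        pseudo = planted_pseudo(seed=5)
        pseudo[:, 1] = pseudo[:, 0]
        within = bm.within_hand_decode(pseudo)
        across = bm.across_hand_decode(pseudo)
        np.testing.assert_allclose(within.accuracies, across.accuracies)

    def test_hand_swap_symmetry(self):
        pseudo = planted_pseudo(seed=6)
        swapped = pseudo[:, ::-1].copy()
        for decode in (bm.within_hand_decode, bm.across_hand_decode):
            a = decode(pseudo).accuracies
            b = decode(swapped).accuracies
            np.testing.assert_allclose(a, b, equal_nan=True)

    def test_timed_input_and_axis(self):
        pseudo = planted_pseudo(timed=True, seed=7)
        res = bm.within_hand_decode(pseudo, axis_values=[0.0, 10.0, 20.0])
        assert res.accuracies.shape == (3, 4, 4)
        assert res.timecourse().shape == (3,)


class TestSensoryScore:
    def test_difference_arithmetic(self):
        w = bm.DecodingResult(scheme="within",
                              accuracies=np.full((2, 2), 75.0),
                              letters=("B", "C"))
        a = bm.DecodingResult(scheme="across",
                              accuracies=np.full((2, 2), 50.0),
                              letters=("B", "C"))
        diff = bm.sensory_score(w, a)
        off = ~np.eye(2, dtype=bool)
        np.testing.assert_allclose(diff.accuracies[off], 25.0)

    def test_equal_schemes_give_zero(self):
        pseudo = planted_pseudo(seed=8)
        w = bm.within_hand_decode(pseudo)
        a = bm.across_hand_decode(pseudo)
        a2 = bm.DecodingResult(scheme="across", accuracies=w.accuracies,
                               letters=w.letters)
        off = ~np.isnan(w.accuracies)
        assert (bm.sensory_score(w, a2).accuracies[off] == 0).all()

    def test_shape_mismatch_rejected(self):
        w = bm.DecodingResult(scheme="within", accuracies=np.zeros((2, 2)),
                              letters=("B", "C"))
        a = bm.DecodingResult(scheme="across", accuracies=np.zeros((3, 3)),
                              letters=("B", "C", "D"))
        with pytest.raises(ValueError):
            bm.sensory_score(w, a)


class TestTimeResolved:
    def test_deterministic_under_seed(self, planted_epochs):
        r1 = bm.time_resolved_decode(planted_epochs, n_iterations=1, seed=9,
                                     schemes=("within",))
        r2 = bm.time_resolved_decode(planted_epochs, n_iterations=1, seed=9,
                                     schemes=("within",))
        np.testing.assert_array_equal(r1["within"].accuracies,
                                      r2["within"].accuracies)

    def test_prestimulus_is_chance(self, planted_epochs):
        res = bm.time_resolved_decode(planted_epochs, n_iterations=2,
                                      seed=10)
        for scheme in ("within", "across"):
            tc = res[scheme].timecourse()
            pre = tc[res[scheme].axis_values < 0]
            assert abs(pre.mean() - 50.0) < 5.0

    def test_curves_rise_after_planted_onsets(self, planted_epochs):
        res = bm.time_resolved_decode(planted_epochs, n_iterations=2,
                                      seed=11)
        times = res["within"].axis_values
        wtc = res["within"].timecourse()
        atc = res["across"].timecourse()
        # before the sensory onset: no information in either scheme
        assert wtc[times < 70].mean() < 55.0
        assert wtc[(times >= 120) & (times < 400)].mean() > 60.0
        # across-hand rises only after the perceptual onset at 180 ms
        assert atc[times < 170].mean() < 55.0
        assert atc[(times >= 220) & (times < 400)].mean() > 55.0

    def test_label_permutation_destroys_decoding(self):
        ep = make_epochs(n_letters=4, reps=10, seed=13, sensory_snr=2.0,
                         perceptual_snr=1.0)
        rng = np.random.default_rng(0)
        lab = ep.labels.copy()
        for hand in ("left", "right"):
            sel = (lab["kind"] == "regular") & (lab["hand"] == hand)
            idx = np.flatnonzero(sel)
            lab.loc[idx, "letter"] = (
                lab.loc[idx, "letter"].to_numpy()[rng.permutation(idx.size)])
        ep_perm = ep.copy()
        ep_perm.labels = lab
        res = bm.time_resolved_decode(ep_perm, n_iterations=2, seed=14,
                                      schemes=("within",))
        assert abs(res["within"].grand_mean() - 50.0) < 3.0

    def test_requires_iterations(self, planted_epochs):
        with pytest.raises(ValueError, match="iteration"):
            bm.time_resolved_decode(planted_epochs, n_iterations=0)


class TestRoiDecode:
    def test_mix_controls_scheme_dissociation(self):
        """mix=1 ROIs decode within- but not across-hand; mix=0 ROIs
        generalize.  Averaged over subjects: each subject's across-hand
        accuracy under mix=1 deviates from chance only through its random
        pattern draw."""
        acc = {k: [] for k in ("tw", "ta", "rw", "ra", "td")}
        for seed in range(6):
            sets = bm.synthesize_roi_patterns(
                20, bm.EffectSpec(seed=100 + seed), n_features=30,
                mix={"tactile": 1.0, "reading": 0.0}, amplitude=2.0)
            res = bm.roi_decode(sets, seed=16 + seed)
            acc["tw"].append(res["tactile"]["within"].grand_mean())
            acc["ta"].append(res["tactile"]["across"].grand_mean())
            acc["rw"].append(res["reading"]["within"].grand_mean())
            acc["ra"].append(res["reading"]["across"].grand_mean())
            acc["td"].append(res["tactile"]["difference"].grand_mean())
        mean = {k: np.mean(v) for k, v in acc.items()}
        assert mean["tw"] > 80.0
        assert abs(mean["ta"] - 50.0) < 8.0
        assert mean["ra"] > 80.0
        assert abs(mean["rw"] - mean["ra"]) < 8.0
        assert mean["td"] > 25.0

    def test_grand_average_helper(self):
        pseudo = planted_pseudo(seed=17)
        res = [bm.within_hand_decode(pseudo) for _ in range(2)]
        assert grand_average(res) == pytest.approx(res[0].grand_mean())
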