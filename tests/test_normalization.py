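import math

import numpy as np
import pytest

from eivnpr.array_data import Flag
from eivnpr.exceptions import DataError
from eivnpr.normalization import (normalize_by_normalizers, normalize_loess,
                                  normalize_loess_m, normalize_median,
                                  normalize_quantile)

from conftest import make_profile


def nets(profile):
    return np.array([r.net for r in profile.records])


class TestMedian:
    def test_worked_example(self):
        a = make_profile([1.0, 2.0, 3.0], backgrounds=[10.0] * 3, array_id="a")
        b = make_profile([2.0, 4.0, 8.0], backgrounds=[10.0] * 3, array_id="b")
        out = normalize_median([a, b])
        # per-array medians 2 and 4; global median 3
        assert np.allclose(nets(out[0]), [1.5, 3.0, 4.5])
        assert np.allclose(nets(out[1]), [1.5, 3.0, 6.0])

    def test_single_array_unchanged(self):
        a = make_profile([5.0, 7.0, 9.0])
        out = normalize_median([a])
        assert np.allclose(nets(out[0]), [5.0, 7.0, 9.0])

    def test_equal_medians_unchanged(self):
        a = make_profile([1.0, 3.0, 5.0], array_id="a")
        b = make_profile([2.0, 3.0, 4.0], array_id="b")
        out = normalize_median([a, b])
        assert np.allclose(nets(out[0]), [1.0, 3.0, 5.0])
        assert np.allclose(nets(out[1]), [2.0, 3.0, 4.0])

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 100, 20)
        a = make_profile(list(vals), array_id="a")
        b = make_profile(list(vals * 3), array_id="b")
        out = normalize_median([a, b])
        assert (np.argsort(nets(out[1])) == np.argsort(vals)).all()

    def test_zero_median_rejected(self):
        a = make_profile([-1.0, 0.0, 1.0])
        b = make_profile([1.0, 2.0, 3.0], array_id="b")
        with pytest.raises(DataError, match="zero median"):
            normalize_median([a, b])


class TestQuantile:
    def test_worked_example(self):
        a = make_profile([1.0, 2.0, 3.0], array_id="a")
        b = make_profile([2.0, 4.0, 6.0], array_id="b")
        out = normalize_quantile([a, b])
        assert np.allclose(nets(out[0]), [1.5, 3.0, 4.5])
        assert np.allclose(nets(out[1]), [1.5, 3.0, 4.5])

    def test_rank_order_respected(self):
        a = make_profile([3.0, 1.0, 2.0], array_id="a")
        b = make_profile([10.0, 30.0, 20.0], array_id="b")
        out = normalize_quantile([a, b])
        assert (np.argsort(nets(out[0])) == np.argsort([3.0, 1.0, 2.0])).all()
        assert (np.argsort(nets(out[1])) == np.argsort([10.0, 30.0, 20.0])).all()

    def test_sorted_vectors_identical_postcondition(self):
        rng = np.random.default_rng(1)
        profs = [make_profile(list(rng.uniform(1, 500, 50)), array_id=f"a{i}")
                 for i in range(4)]
        out = normalize_quantile(profs)
        ref = np.sort(nets(out[0]))
        for p in out[1:]:
            assert np.allclose(np.sort(nets(p)), ref)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        profs = [make_profile(list(rng.uniform(1, 500, 30)), array_id=f"a{i}")
                 for i in range(3)]
        once = normalize_quantile(profs)
        twice = normalize_quantile(once)
        for p1, p2 in zip(once, twice):
            assert np.allclose(nets(p1), nets(p2))

    def test_identical_arrays_unchanged(self):
        vals = [5.0, 1.0, 9.0]
        profs = [make_profile(vals, array_id=f"a{i}") for i in range(3)]
        out = normalize_quantile(profs)
        for p in out:
            assert np.allclose(nets(p), vals)

    def test_unequal_counts_rejected(self):
        a = make_profile([1.0, 2.0], array_id="a")
        b = make_profile([1.0, 2.0, 3.0], array_id="b")
        with pytest.raises(DataError, match="equal probe counts"):
            normalize_quantile([a, b])


def _paired_profiles(nets_a, nets_b):
    ids = [f"m{i}" for i in range(len(nets_a))]
    a = make_profile(nets_a, mirna_ids=ids, array_id="a")
    b = make_profile(nets_b, mirna_ids=ids, array_id="b")
    return a, b


class TestLoess:
    def test_identical_pair_unchanged(self):
        vals = list(np.linspace(10, 1000, 40))
        a, b = _paired_profiles(vals, vals)
        out_a, out_b = normalize_loess((a, b))
        assert np.allclose(nets(out_a), vals, rtol=1e-8)
        assert np.allclose(nets(out_b), vals, rtol=1e-8)

    def test_constant_offset_removed(self):
        vals = np.linspace(10, 1000, 40)
        a, b = _paired_profiles(list(vals * 2.0), list(vals))
        out_a, out_b = normalize_loess((a, b))
        m_after = np.log(nets(out_a)) - np.log(nets(out_b))
        assert np.max(np.abs(m_after)) < 1e-6

    def test_curvature_removed(self):
        rng = np.random.default_rng(3)
        la = rng.uniform(2, 8, 200)
        # intensity-dependent distortion of the first channel
        lb = la - 0.4 * (la - 5.0) ** 2 / 10.0
        a, b = _paired_profiles(list(np.exp(la)), list(np.exp(lb)))
        m_before = np.log(nets(a)) - np.log(nets(b))
        out_a, out_b = normalize_loess((a, b), span=0.4)
        m_after = np.log(nets(out_a)) - np.log(nets(out_b))
        assert np.mean(np.abs(m_before)) / np.mean(np.abs(m_after)) >= 5.0

    def test_too_few_shared_probes(self):
        a, b = _paired_profiles([10.0] * 5, [10.0] * 5)
        with pytest.raises(DataError, match="shared"):
            normalize_loess((a, b))


class TestLoessM:
    def test_constant_offset_preserved(self):
        vals = np.linspace(10, 1000, 40)
        a, b = _paired_profiles(list(vals * 2.0), list(vals))
        out_a, out_b = normalize_loess_m((a, b))
        m_after = np.log(nets(out_a)) - np.log(nets(out_b))
        assert np.allclose(m_after, math.log(2.0), atol=1e-6)

    def test_median_log_ratio_invariant(self):
        rng = np.random.default_rng(4)
        la = rng.uniform(2, 8, 100)
        lb = la + 0.3 - 0.05 * (la - 5.0) ** 2 + rng.normal(0, 0.05, 100)
        a, b = _paired_profiles(list(np.exp(la)), list(np.exp(lb)))
        m_before = np.log(nets(a)) - np.log(nets(b))
        out_a, out_b = normalize_loess_m((a, b))
        m_after = np.log(nets(out_a)) - np.log(nets(out_b))
        assert np.median(m_after) == pytest.approx(np.median(m_before),
                                                   abs=1e-10)


def _normalizer_profiles(offsets, resid=None, n_norm=6, seed=0):
    rng = np.random.default_rng(seed)
    betas = np.linspace(6.0, 8.0, n_norm)
    ids = [f"norm{j}" for j in range(n_norm)]
    profiles = []
    for a, delta in enumerate(offsets):
        nets_a, mirnas = [], []
        for j in range(n_norm):
            noise = rng.normal(0, resid[j]) if resid is not None else 0.0
            nets_a.append(math.exp(betas[j] + delta + noise))
            mirnas.append(ids[j])
        profiles.append(make_profile(nets_a, backgrounds=[50.0] * n_norm,
                                     mirna_ids=mirnas, array_id=f"A{a}"))
    return profiles, ids


class TestNormalizeByNormalizers:
    def test_exact_offset_recovery_noise_free(self):
        offsets = [-0.3, 0.0, 0.3]
        profiles, ids = _normalizer_profiles(offsets)
        model, normalized = normalize_by_normalizers(profiles, ids)
        est = [model.offsets[f"A{a}"] for a in range(3)]
        assert np.allclose(est, offsets, atol=1e-9)
        # normalized normalizer nets agree across arrays
        ref = nets(normalized[0])
        for p in normalized[1:]:
            assert np.allclose(nets(p), ref, rtol=1e-9)

    def test_tiny_sig_level_drops_nothing(self):
        profiles, ids = _normalizer_profiles([0.1, -0.1, 0.0, 0.0],
                                             resid=[0.05] * 6, seed=1)
        model, _ = normalize_by_normalizers(profiles, ids, sig_level=1e-12)
        assert model.dropped == {}
        assert sorted(model.kept) == sorted(ids)

    def test_overdispersed_normalizer_dropped(self):
        resid = [0.5] + [0.05] * 5
        profiles, ids = _normalizer_profiles([0.0] * 10, resid=resid, seed=2)
        model, _ = normalize_by_normalizers(profiles, ids)
        assert "norm0" in model.dropped

    def test_partially_flagged_array_uses_remaining_normalizers(self):
        offsets = [-0.2, 0.0, 0.2]
        profiles, ids = _normalizer_profiles(offsets)
        # flag most normalizers on the last array; its offset must still be
        # recovered exactly from the remaining unflagged ones
        recs = profiles[-1].records
        profiles[-1] = make_profile(
            [r.net for r in recs], mirna_ids=[r.mirna_id for r in recs],
            array_id=profiles[-1].array_id,
            flags=[Flag.POOR] * 4 + [Flag.OK] * 2)
        model, _ = normalize_by_normalizers(profiles, ids)
        est = [model.offsets[f"A{a}"] for a in range(3)]
        assert np.allclose(est, offsets, atol=1e-9)

    def test_fully_flagged_array_warns(self):
        profiles, ids = _normalizer_profiles([0.0, 0.0, 0.0])
        flagged = make_profile(
            [100.0] * 6, mirna_ids=ids, array_id="A2x",
            flags=[Flag.POOR] * 6)
        with pytest.warns(UserWarning, match="flagged"):
            model, _ = normalize_by_normalizers(profiles + [flagged], ids)
        assert np.isfinite(model.offsets["A2x"])

    def test_too_few_normalizers_mentions_spike_ins(self):
        profiles, ids = _normalizer_profiles([0.0, 0.0], n_norm=2)
        with pytest.raises(DataError, match="spike-in"):
            normalize_by_normalizers(profiles, ids)

    def test_offsets_sum_to_zero(self):
        profiles, ids = _normalizer_profiles([0.2, -0.1, 0.4, 0.1],
                                             resid=[0.05] * 6, seed=3)
        model, _ = normalize_by_normalizers(profiles, ids)
        assert sum(model.offsets.values()) == pytest.approx(0.0, abs=1e-9)
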