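"""EM mixture on logged inserts, signal classification, window clustering, Tx."""

import numpy as np
import pytest

from silicosv.readio import LibraryStats
from silicosv.svscore import (
    ModelPairAlignment,
    UnscorableRegionError,
    WindowClustering,
    classify_signal,
    fit_insert_mixture,
    score_region,
    window_cluster,
)

STATS = LibraryStats(mean_insert=400.0, sd_insert=50.0, mean_summed_phred=2000.0)


def hand_rolled_em(x, mu, var, w, iters=400):
    """Independent two-component Gaussian EM oracle (plain numpy)."""
    x = np.asarray(x, float)
    mu, var, w = np.array(mu, float), np.array(var, float), np.array(w, float)
    for _ in range(iters):
        dens = np.exp(-0.5 * (x[:, None] - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)
        resp = w * dens
        resp /= resp.sum(axis=1, keepdims=True)
        nk = resp.sum(axis=0)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk + 1e-6
        w = nk / len(x)
    return resp


class TestMixtureFit:
    def test_emr_values_sum_to_one(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(10, 200, size=2)
            ins = np.concatenate(
                [np.exp(rng.normal(5.0, 0.3, n1)), np.exp(rng.normal(8.0, 0.3, n2))]
            )
            fit = fit_insert_mixture(ins)
            assert fit.emr.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(fit.responsibilities.sum(axis=1), 1.0)
            assert 0.0 <= fit.emr2 <= 1.0

    def test_known_label_proportions_recovered(self, rng):
        ins = np.concatenate(
            [np.exp(rng.normal(5.3, 0.1, 300)), np.exp(rng.normal(8.0, 0.1, 700))]
        )
        fit = fit_insert_mixture(ins)
        assert fit.emr2 == pytest.approx(0.70, abs=0.03)
        assert fit.means[0] < fit.means[1]

    def test_weight_recovery_on_separated_components(self):
        """Mixture weight recovered within +/-0.05 over 20 seeds, n >= 500."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            w2 = r.uniform(0.3, 0.7)
            n2 = int(round(600 * w2))
            ins = np.concatenate(
                [np.exp(r.normal(5.0, 0.15, 600 - n2)), np.exp(r.normal(8.0, 0.15, n2))]
            )
            fit = fit_insert_mixture(ins, seed=seed)
            assert fit.emr2 == pytest.approx(n2 / 600, abs=0.05)

    def test_matches_hand_rolled_em_oracle(self, rng):
        ins = np.concatenate(
            [np.exp(rng.normal(5.0, 0.2, 150)), np.exp(rng.normal(7.5, 0.2, 250))]
        )
        fit = fit_insert_mixture(ins)
        x = np.log(ins)
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        resp = hand_rolled_em(
            x, [lo.mean(), hi.mean()], [lo.var() + 1e-6, hi.var() + 1e-6],
            [len(lo) / len(x), len(hi) / len(x)],
        )
        assert fit.emr2 == pytest.approx(resp.mean(axis=0)[1], abs=1e-3)

    def test_identical_inserts_degenerate_but_scored(self):
        fit = fit_insert_mixture([350.0] * 40)
        assert fit.degenerate
        assert fit.emr.sum() == pytest.approx(1.0)

    def test_too_few_observations_unscorable(self):
        with pytest.raises(UnscorableRegionError):
            fit_insert_mixture([300.0, 5000.0] * 2)

    def test_nonpositive_inserts_rejected(self):
        with pytest.raises(ValueError):
            fit_insert_mixture([0.0] * 20)


def _pairs(inserts, mapq=60, pos=None):
    out = []
    for i, ins in enumerate(inserts):
        p1 = pos[i] if pos is not None else 100 + 7 * i
        out.append(ModelPairAlignment(f"r{i}", p1, p1 + int(ins) - 100, int(ins), mapq))
    return out


class TestClassification:
    def test_far_component2_read_is_signal(self, rng):
        inserts = [150] * 20 + [int(STATS.mean_insert + 5 * STATS.sd_insert)] * 20
        pairs = _pairs(inserts)
        fit = fit_insert_mixture([p.insert_size for p in pairs])
        cls = classify_signal(fit, pairs, STATS)
        signal_ids = {p.read_id for p in cls.signal}
        assert signal_ids == {f"r{i}" for i in range(20, 40)}
        assert not cls.inconsistent

    def test_mean_insert_low_mapq_read_is_noise(self):
        inserts = [150] * 20 + [400] * 20
        pairs = _pairs(inserts, mapq=0)
        fit = fit_insert_mixture([p.insert_size for p in pairs])
        cls = classify_signal(fit, pairs, STATS)
        assert all(p.insert_size != 400 for p in cls.signal)
        noise_ids = {p.read_id for p in cls.confirmed_noise}
        assert {f"r{i}" for i in range(20, 40)} <= noise_ids

    def test_inconsistency_flag_when_both_modes_inside_two_sd(self, rng):
        # both components within 2 s.d. of the library mean: no usable signal
        inserts = np.concatenate([rng.normal(360, 5, 30), rng.normal(440, 5, 30)])
        pairs = _pairs([int(i) for i in inserts])
        fit = fit_insert_mixture([p.insert_size for p in pairs])
        cls = classify_signal(fit, pairs, STATS)
        assert cls.inconsistent
        assert cls.signal == []


def brute_force_windows(positions, ref_len, window, step):
    counts = []
    s = 1
    while s <= max(ref_len - window + 1, 1):
        counts.append(sum(s <= p < s + window for p in positions))
        s += step
    return counts


class TestWindowClustering:
    def test_all_pairs_in_one_window_ratio_one(self):
        pairs = [ModelPairAlignment(f"r{i}", 990 + i, 2000 + i, 1010, 60) for i in range(10)]
        wc = window_cluster(pairs, ref_length=3000, junction_offset=1500, window=200, step=100)
        assert wc.nb == 10 and wc.wmax == 10
        assert wc.ratio == 1.0

    def test_sixty_forty_split_across_far_windows(self):
        pairs = [ModelPairAlignment(f"a{i}", 100, 6000, 5900, 60) for i in range(60)]
        pairs += [ModelPairAlignment(f"b{i}", 4000, 6000, 2000, 60) for i in range(40)]
        wc = window_cluster(pairs, ref_length=8000, junction_offset=5000, window=400, step=200)
        assert wc.nb == 100 and wc.wmax == 60
        assert wc.ratio == pytest.approx(0.6)

    def test_pair_on_one_side_of_junction_excluded(self):
        pairs = [
            ModelPairAlignment("span", 900, 1100, 300, 60),
            ModelPairAlignment("left", 100, 300, 300, 60),
            # a mate exactly at the offset is still on the first segment
            ModelPairAlignment("ends_at_junction", 800, 1000, 300, 60),
            ModelPairAlignment("just_over", 900, 1001, 200, 60),
        ]
        wc = window_cluster(pairs, ref_length=2000, junction_offset=1000, window=100, step=50)
        assert wc.nb == 2
        assert {p.read_id for p in pairs if min(p.pos1, p.pos2) <= 1000 < max(p.pos1, p.pos2)} == {
            "span", "just_over",
        }

    @pytest.mark.parametrize("seed", range(6))
    def test_counts_match_brute_force_scan(self, seed):
        r = np.random.default_rng(seed)
        ref_len = int(r.integers(2000, 10_000))
        junction = ref_len // 2
        pairs = []
        for i in range(int(r.integers(5, 80))):
            p1 = int(r.integers(1, junction + 1))
            p2 = int(r.integers(junction + 1, ref_len))
            pairs.append(ModelPairAlignment(f"r{i}", p1, p2, p2 - p1 + 100, 60))
        window = int(r.integers(100, 800))
        step = int(r.integers(50, window + 1))
        wc = window_cluster(pairs, ref_len, junction, window, step)
        brute = brute_force_windows([p.leftmost for p in pairs], ref_len, window, step)
        assert list(wc.counts) == brute
        assert wc.wmax == max(brute)
        assert wc.nb == len(pairs)

    def test_no_qualifying_reads_ratio_zero(self):
        wc = window_cluster([], ref_length=1000, junction_offset=500, window=100, step=50)
        assert wc.nb == 0 and wc.ratio == 0.0

    def test_adding_read_to_densest_window_never_decreases_ratio(self, rng):
        for _ in range(10):
            pairs = [
                ModelPairAlignment(f"r{i}", int(rng.integers(1, 1000)), int(rng.integers(1001, 2000)), 500, 60)
                for i in range(int(rng.integers(4, 30)))
            ]
            wc = window_cluster(pairs, 2000, 1000, 200, 100)
            dens_start = 1 + int(np.argmax(wc.counts)) * 100
            extra = pairs + [ModelPairAlignment("x", dens_start, 1500, 500, 60)]
            wc2 = window_cluster(extra, 2000, 1000, 200, 100)
            assert wc2.ratio >= wc.ratio - 1e-12


class TestRegionScore:
    def _clustering(self, wmax, nb):
        return WindowClustering(window=100, step=50, counts=np.array([wmax]), wmax=wmax, nb=nb)

    def _fit(self, emr2, n=50):
        from silicosv.svscore import MixtureFit

        resp = np.tile([1 - emr2, emr2], (n, 1))
        return MixtureFit(
            means=np.array([5.0, 8.0]), variances=np.ones(2) * 0.01,
            weights=np.array([1 - emr2, emr2]), responsibilities=resp,
            emr=np.array([1 - emr2, emr2]), n=n,
        )

    def test_tx_is_sum_of_parts(self):
        score = score_region("r", self._fit(0.6), self._clustering(4, 10))
        assert score.tx == pytest.approx(0.6 + 0.4)
        assert score.passed

    def test_nb_zero_gives_tx_equal_emr2(self):
        score = score_region("r", self._fit(0.8), self._clustering(0, 0))
        assert score.tx == pytest.approx(0.8)

    def test_tx_bounded_by_emr2_plus_one(self, rng):
        for _ in range(20):
            nb = int(rng.integers(1, 50))
            wmax = int(rng.integers(0, nb + 1))
            emr2 = float(rng.uniform(0, 1))
            score = score_region("r", self._fit(emr2), self._clustering(wmax, nb))
            assert 0.0 <= score.tx <= emr2 + 1.0 + 1e-12

    def test_noise_cutoff_failure_reported(self):
        # default rule: discarded when the noise component doubly dominates
        score = score_region("r", self._fit(0.25), self._clustering(5, 5))
        assert not score.passed
        assert score.tx == pytest.approx(1.25)  # still reported
        stricter = score_region("r", self._fit(0.45), self._clustering(5, 5),
                                noise_cutoff=0.5)
        assert not stricter.passed
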