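import itertools

import numpy as np
import pytest
from scipy import stats

from modelqa import qa_metrics as Q
from modelqa.decoy_sim import SimConfig, generate_native, perturb_model
from modelqa.geometry import kabsch_superpose

from conftest import make_ca_model, random_rigid_transform


def exhaustive_gdt(ca_model, ca_native, thresholds=Q.GDT_THRESHOLDS):
    """Brute-force GDT: try every residue subset of size >= 3, superpose on it,
    and count it if all subset members land within the cutoff."""
    L = len(ca_model)
    best = {d: 0 for d in thresholds}
    indices = range(L)
    for size in range(3, L + 1):
        for subset in itertools.combinations(indices, size):
            idx = np.array(subset)
            sup = kabsch_superpose(ca_native[idx], ca_model[idx])
            dev = np.linalg.norm(sup.apply(ca_model[idx]) - ca_native[idx], axis=1)
            for d in thresholds:
                if (dev <= d).all() and size > best[d]:
                    best[d] = size
    return np.mean([best[d] / L for d in thresholds])


class TestGdtTs:
    def test_identity_is_one(self, mixed_native):
        assert Q.gdt_ts(mixed_native, mixed_native) == 1.0

    def test_half_displaced_toy(self):
        rng = np.random.default_rng(0)
        ca_native = rng.normal(size=(10, 3)) * 4
        ca_model = ca_native.copy()
        ca_model[5:] += 20.0  # half the chain far outside every cutoff
        model = make_ca_model(ca_model)
        native = make_ca_model(ca_native)
        assert Q.gdt_ts(model, native) == pytest.approx(0.5)

    def test_heuristic_close_to_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            L = int(rng.integers(6, 11))
            nat = generate_native(SimConfig(L=max(L, 5), template="mixed", seed=trial))
            sigma = float(rng.uniform(0.5, 6.0))
            decoy = perturb_model(nat, sigma, "d", rng)
            heur = Q.gdt_ts(decoy, nat)
            oracle = exhaustive_gdt(decoy.ca_coords(), nat.ca_coords())
            assert heur >= oracle - 0.05

    def test_monotone_under_increasing_noise(self):
        nat = generate_native(SimConfig(L=20, template="mixed", seed=2))
        means = []
        for sigma in (0.5, 2.0, 8.0):
            rng = np.random.default_rng(3)
            vals = [Q.gdt_ts(perturb_model(nat, sigma, "d", rng), nat) for _ in range(10)]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_rigid_invariance(self, mixed_native):
        rng = np.random.default_rng(4)
        decoy = perturb_model(mixed_native, 2.0, "d", rng)
        rot, trans = random_rigid_transform(rng)
        a = Q.gdt_ts(decoy, mixed_native)
        b = Q.gdt_ts(decoy.transformed(rot, trans), mixed_native)
        assert a == pytest.approx(b, abs=1e-9)

    def test_length_mismatch(self, mixed_native, helix_native):
        with pytest.raises(ValueError, match="length"):
            Q.gdt_ts(helix_native, mixed_native)


class TestTmScore:
    def test_identity_is_one(self, mixed_native):
        assert Q.tm_score(mixed_native, mixed_native) == pytest.approx(1.0)

    def test_rigid_invariance(self, mixed_native):
        rng = np.random.default_rng(5)
        decoy = perturb_model(mixed_native, 1.0, "d", rng)
        rot, trans = random_rigid_transform(rng)
        a = Q.tm_score(decoy, mixed_native)
        b = Q.tm_score(decoy.transformed(rot, trans), mixed_native)
        assert a == pytest.approx(b, abs=1e-9)

    def test_one_displaced_residue_matches_restricted_superposition(self):
        nat = generate_native(SimConfig(L=20, template="mixed", seed=6))
        ca = nat.ca_coords().copy()
        ca[10] += 12.0
        model = make_ca_model(ca, sequence=nat.sequence)
        # Oracle: superpose on the 19 unperturbed residues and evaluate directly.
        keep = np.array([i for i in range(20) if i != 10])
        sup = kabsch_superpose(nat.ca_coords()[keep], ca[keep])
        dev = np.linalg.norm(sup.apply(ca) - nat.ca_coords(), axis=1)
        d0 = Q.tm_d0(20)
        oracle = np.mean(1.0 / (1.0 + (dev / d0) ** 2))
        assert Q.tm_score(model, nat) == pytest.approx(oracle, abs=0.02)

    def test_d0_floor_for_short_chains(self):
        assert Q.tm_d0(10) == 0.5
        assert Q.tm_d0(21) == 0.5
        assert Q.tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8)


class TestRmsd:
    def test_identity_zero(self, mixed_native):
        assert Q.rmsd(mixed_native, mixed_native) < 1e-9

    def test_rigid_copy_zero(self, mixed_native):
        rng = np.random.default_rng(7)
        rot, trans = random_rigid_transform(rng)
        assert Q.rmsd(mixed_native.transformed(rot, trans), mixed_native) < 1e-8

    def test_toy_case_matches_kabsch_value(self):
        a = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 1.0]])
        b = a.copy()
        b[3, 2] = 0.0
        model = make_ca_model(b)
        native = make_ca_model(a)
        assert Q.rmsd(model, native) == pytest.approx(
            kabsch_superpose(a, b).rmsd, abs=1e-12
        )


def _records(pred, true):
    return [
        Q.QualityRecord(model_id=f"m{i}", predicted=float(p), gdt_ts=float(t))
        for i, (p, t) in enumerate(zip(pred, true))
    ]


class TestCorrelationAndLoss:
    def test_perfect_predictor_r_one(self):
        true = [0.1, 0.4, 0.9]
        assert Q.per_target_correlation(_records(true, true)) == pytest.approx(1.0)

    def test_anti_predictor_r_minus_one(self):
        true = np.array([0.1, 0.4, 0.9])
        assert Q.per_target_correlation(_records(1 - true, true)) == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        recs = _records([0.0, 0.5, 1.0], [0.0, 1.0, 0.5])
        assert Q.per_target_correlation(recs) == pytest.approx(0.5)

    def test_zero_variance_returns_none(self):
        assert Q.per_target_correlation(_records([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])) is None

    def test_loss_zero_for_correct_pick(self):
        assert Q.per_target_loss(_records([0.9, 0.1], [0.8, 0.2])) == 0.0

    def test_loss_from_definition(self):
        recs = _records([0.9, 0.2, 0.1], [0.5, 0.3, 0.7])
        assert Q.per_target_loss(recs) == pytest.approx(0.2)

    def test_loss_nonnegative_random(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            recs = _records(rng.uniform(0, 1, 6), rng.uniform(0, 1, 6))
            assert Q.per_target_loss(recs) >= 0.0

    def test_prediction_ties_broken_lexicographically(self):
        recs = [
            Q.QualityRecord(model_id="b", predicted=0.5, gdt_ts=0.9),
            Q.QualityRecord(model_id="a", predicted=0.5, gdt_ts=0.3),
        ]
        assert Q.per_target_loss(recs) == pytest.approx(0.6)


class TestTopKSelection:
    def _pool(self):
        rng = np.random.default_rng(9)
        return [
            Q.QualityRecord(
                model_id=f"m{i}", predicted=float(p),
                tm_score=float(t), rmsd=float(r), gdt_ts=float(t),
            )
            for i, (p, t, r) in enumerate(
                zip(rng.uniform(0, 1, 8), rng.uniform(0.2, 0.9, 8), rng.uniform(1, 20, 8))
            )
        ]

    def test_k1_reduces_to_top1(self):
        pool = self._pool()
        top = sorted(pool, key=lambda r: (-r.predicted, r.model_id))[0]
        assert Q.top_k_selection(pool, k=1) == (top.tm_score, top.rmsd)

    def test_perfect_predictor_top5_hits_pool_max(self):
        true = [0.1, 0.5, 0.9, 0.3]
        pool = [
            Q.QualityRecord(model_id=f"m{i}", predicted=t, tm_score=t, gdt_ts=t)
            for i, t in enumerate(true)
        ]
        with pytest.warns(UserWarning):
            best_tm, _ = Q.top_k_selection(pool, k=5)
        assert best_tm == 0.9

    def test_k_equal_pool_size_gives_pool_extremes(self):
        pool = self._pool()
        best_tm, best_rmsd = Q.top_k_selection(pool, k=len(pool))
        assert best_tm == max(r.tm_score for r in pool)
        assert best_rmsd == min(r.rmsd for r in pool)


class TestZscoreSum:
    def test_mean_selection_gives_zero(self):
        pools = [[0.2, 0.4, 0.6], [0.1, 0.5, 0.9]]
        selected = [np.mean(p) for p in pools]
        assert Q.zscore_sum(selected, pools) == pytest.approx(0.0)

    def test_population_std_arithmetic(self):
        z = Q.zscore_sum([0.6], [[0.2, 0.4, 0.6]])
        assert z == pytest.approx(0.2 / np.std([0.2, 0.4, 0.6]), abs=1e-9)
        assert z == pytest.approx(1.2247, abs=1e-4)

    def test_random_selector_centered_at_zero(self):
        rng = np.random.default_rng(10)
        pools = [rng.uniform(0, 1, 10) for _ in range(1000)]
        selected = [p[rng.integers(0, 10)] for p in pools]
        z = Q.zscore_sum(selected, pools)
        # mean 0, per-target variance ~1 -> sum is O(sqrt(1000))
        assert abs(z) < 3 * np.sqrt(1000)

    def test_degenerate_pool_contributes_zero(self):
        assert Q.zscore_sum([0.5], [[0.5, 0.5, 0.5]]) == 0.0


class TestWilcoxon:
    def test_exact_p_all_positive_n5(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - 1.0
        p, degenerate = Q.wilcoxon_signed_rank(a, b)
        assert not degenerate
        assert p == pytest.approx(0.0625)

    def test_identical_samples_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        p, degenerate = Q.wilcoxon_signed_rank(a, a)
        assert degenerate and p == 1.0

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        p, _ = Q.wilcoxon_signed_rank(a, b)
        expected = stats.wilcoxon(a, b, mode="exact", alternative="two-sided").pvalue
        assert p == pytest.approx(expected, abs=1e-12)

    def test_exact_close_to_normal_approximation_at_boundary(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        exact_p, _ = Q.wilcoxon_signed_rank(a, b)
        approx_p = stats.wilcoxon(a, b, correction=True, mode="approx").pvalue
        assert exact_p == pytest.approx(approx_p, abs=0.02)


class TestLocalToGlobal:
    @pytest.mark.parametrize(
        "locals_,expected",
        [([0.0, 0.0], 1.0), ([5.0, 5.0], 0.5), ([0.0, 5.0], 0.75)],
    )
    def test_formula_values(self, locals_, expected):
        assert Q.local_to_global(locals_) == pytest.approx(expected)

    def test_negative_local_rejected(self):
        with pytest.raises(ValueError):
            Q.local_to_global([-1.0])


class TestEvaluateTargets:
    def test_perfect_predictor_report(self):
        rng = np.random.default_rng(13)
        records_by_target = {}
        for t in range(3):
            true = rng.uniform(0.1, 0.9, 6)
            records_by_target[f"T{t}"] = [
                Q.QualityRecord(
                    model_id=f"m{i}", predicted=float(v), gdt_ts=float(v),
                    tm_score=float(v), rmsd=float(20 * (1 - v)),
                )
                for i, v in enumerate(true)
            ]
        report = Q.evaluate_targets(records_by_target)
        assert report.average_loss == 0.0
        assert report.average_r == pytest.approx(1.0)
        assert report.zscore_sum_tm > 0
        assert report.zscore_sum_rmsd < 0
        summary = report.summary()
        assert summary["n_targets"] == 3
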