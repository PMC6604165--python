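import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nuclize import stats


def poisson_tail_by_summation(k: int, lam: float) -> float:
    """Sum the PMF from k upward until terms vanish (independent oracle)."""
    if k == 0:
        return 1.0
    # P(X >= k) = 1 - sum_{i<k} pmf, accumulated in log space for stability
    total = 0.0
    log_term = -lam  # log pmf at i=0
    for i in range(k):
        total += math.exp(log_term)
        log_term += math.log(lam) - math.log(i + 1)
    return max(1.0 - total, 0.0)


def bh_step_up_oracle(p):
    """Hand-executed step-up: adjusted_i = min_{j: p_(j) >= p_(i)} p_(j)*m/rank."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, p[i] * m / rank)
        adjusted[i] = best
    return adjusted


class TestPoissonUpperTail:
    def test_k_zero_is_one(self):
        assert stats.poisson_upper_tail(0, 0.1) == 1.0
        assert stats.poisson_upper_tail(0, 50.0) == 1.0

    def test_closed_form_k1(self):
        assert stats.poisson_upper_tail(1, 1.0) == pytest.approx(
            1 - math.exp(-1), abs=1e-12
        )

    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0, 20.0])
    def test_matches_series_summation(self, lam):
        for k in range(0, 101, 7):
            assert stats.poisson_upper_tail(k, lam) == pytest.approx(
                poisson_tail_by_summation(k, lam), abs=1e-12
            )

    def test_non_increasing_in_k(self):
        p = [stats.poisson_upper_tail(k, 3.7) for k in range(40)]
        assert all(b <= a for a, b in zip(p, p[1:]))

    def test_invalid_lambda_raises(self):
        with pytest.raises(ValueError):
            stats.poisson_upper_tail(3, 0.0)
        with pytest.raises(ValueError):
            stats.poisson_upper_tail(-1, 1.0)


class TestBenjaminiHochberg:
    def test_ties_stay_at_common_value(self):
        assert np.allclose(stats.benjamini_hochberg([0.03] * 5), 0.03)

    def test_hand_executed_example(self):
        out = stats.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert stats.benjamini_hochberg([0.123]).tolist() == [0.123]

    def test_empty_vector(self):
        assert stats.benjamini_hochberg([]).size == 0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            stats.benjamini_hochberg([0.0, 0.5])
        with pytest.raises(ValueError):
            stats.benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
        assert np.allclose(stats.benjamini_hochberg(p), bh_step_up_oracle(list(p)))

    def test_agrees_with_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        for _ in range(10):
            p = rng.uniform(1e-8, 1.0, size=60)
            ours = stats.benjamini_hochberg(p)
            theirs = sm.multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs)

    def test_readjustment_never_lowers_values(self, rng):
        # re-adjusting an adjusted vector can only push values toward 1
        p = rng.uniform(1e-6, 1.0, size=30)
        once = stats.benjamini_hochberg(p)
        twice = stats.benjamini_hochberg(once)
        assert np.all(twice >= once - 1e-12)
        assert np.all(twice <= 1.0)

    def test_preserves_input_order(self):
        p = [0.04, 0.01, 0.03, 0.02]
        out = stats.benjamini_hochberg(p)
        resorted = stats.benjamini_hochberg(sorted(p))
        assert np.allclose(sorted(out), resorted)


def candidate_frame(chip, lam_local, lam_input, scaled=None):
    n = len(chip)
    return pd.DataFrame(
        {
            "nucleosome_id": np.arange(n),
            "chrom": "chr1",
            "start": 100 + 200 * np.arange(n),
            "end": 247 + 200 * np.arange(n),
            "dyad": 173 + 200 * np.arange(n),
            "chip_count": chip,
            "input_count_raw": 0,
            "input_count_scaled": scaled if scaled is not None else lam_input,
            "lambda_local": lam_local,
            "lambda_input": lam_input,
            "excess": np.asarray(chip, dtype=float),
        }
    )


class TestTestPeaks:
    def test_strong_single_candidate_accepted(self):
        out = stats.test_peaks(candidate_frame([40], [5.0], [5.0]))
        row = out.iloc[0]
        assert row["status"] == "accepted"
        # fold = (chip + c) / (lambda + c) with c = 0.5
        assert row["fold_local"] == pytest.approx(40.5 / 5.5)
        assert row["fold_input"] == pytest.approx(40.5 / 5.5)
        # one-candidate family: fdr equals p
        assert row["fdr_local"] == pytest.approx(row["p_local"])
        assert row["p_local"] == pytest.approx(
            poisson_tail_by_summation(40, 5.0), rel=1e-9
        )

    def test_fold_gate_reject_reason(self):
        # chip=12 vs lambda_local=4: fold (12.5/4.5) = 2.78 < 4
        out = stats.test_peaks(candidate_frame([12], [4.0], [0.5]))
        row = out.iloc[0]
        assert row["status"] == "rejected"
        assert row["reject_reason"] == "fold_local"

    def test_p_gate_precedes_fold_gate(self):
        # chip=6 vs lambda_local=4: p ~ 0.21 fails first
        out = stats.test_peaks(candidate_frame([6], [4.0], [0.5]))
        assert out.iloc[0]["reject_reason"] == "p_local"

    def test_order_invariance(self, rng):
        chip = rng.integers(0, 60, size=50)
        lam = rng.uniform(0.5, 8.0, size=50)
        frame = candidate_frame(chip, lam, lam * 1.1)
        out = stats.test_peaks(frame)
        perm = rng.permutation(50)
        out_perm = stats.test_peaks(
            frame.iloc[perm].reset_index(drop=True)
        )
        merged = out.set_index("nucleosome_id").loc[
            out_perm["nucleosome_id"]
        ]
        assert merged["status"].tolist() == out_perm["status"].tolist()

    def test_tightening_thresholds_never_accepts_more(self, rng):
        chip = rng.integers(0, 60, size=80)
        lam = rng.uniform(0.5, 8.0, size=80)
        frame = candidate_frame(chip, lam, lam)
        base = stats.test_peaks(frame, alpha_p=0.01, min_fold=4, alpha_fdr=0.01)
        accepted = set(base.loc[base["status"] == "accepted", "nucleosome_id"])
        for kwargs in (
            dict(alpha_p=0.001), dict(min_fold=8), dict(alpha_fdr=0.001),
        ):
            tighter = stats.test_peaks(frame, **{
                "alpha_p": 0.01, "min_fold": 4, "alpha_fdr": 0.01, **kwargs
            })
            tight_ids = set(
                tighter.loc[tighter["status"] == "accepted", "nucleosome_id"]
            )
            assert tight_ids <= accepted

    def test_type_one_error_control(self, rng):
        """Null nucleosomes: P(p_local <= 0.01) stays at or below nominal
        (Poisson discreteness makes the test conservative)."""
        lam = 3.0
        chip = rng.poisson(lam, size=10_000)
        p = stats.poisson_upper_tail(chip, lam)
        frac = float(np.mean(p <= 0.01))
        assert 0.0 <= frac <= 0.015

    def test_empty_candidate_frame(self):
        out = stats.test_peaks(candidate_frame([], [], []))
        assert len(out) == 0
        assert "status" in out.columns
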