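"""Double Poisson enrichment tests, fold gates and BH-FDR filtering.

A surviving candidate is accepted only if it clears *both* one-sided
Poisson upper-tail tests — ChIP count against the local ChIP background
rate, and ChIP count against the depth-scaled input — each at
p <= ``alpha_p`` with fold change >= ``min_fold``, and both
Benjamini-Hochberg adjusted values (computed separately for the two
p-value families across all candidates of one mark) at <= ``alpha_fdr``.
Fold changes carry a small pseudocount so zero backgrounds stay finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Smallest p-value reported; keeps p strictly positive after underflow.
P_FLOOR = 1e-300

#: Gate evaluation order; reject_reason is the first gate that fails.
GATES = ("p_local", "p_input", "fold_local", "fold_input", "fdr_local", "fdr_input")


def poisson_upper_tail(k, lam):
    """P(X >= k) for X ~ Poisson(lam), vectorized and numerically stable.

    Computed as the survival function at k-1, so P(X >= 0) = 1 exactly.
    """
    k = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("lambda must be > 0")
    if np.any(k < 0):
        raise ValueError("count must be >= 0")
    out = sps.poisson.sf(k - 1, lam_arr)
    if out.ndim == 0:
        return float(out)
    return out


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up adjusted values, order-preserving, capped at 1.

    adjusted_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j),
    realised as a cumulative minimum from the largest rank downward.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def test_peaks(
    candidates: pd.DataFrame,
    alpha_p: float = 0.01,
    min_fold: float = 4.0,
    alpha_fdr: float = 0.01,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Run both Poisson tests on shape-passed candidates of one mark.

    The two BH families span all rows given here (one mark, genome-wide);
    callers must therefore pass the complete post-shape-filter candidate
    set in one call.  Returns the input with p/fold/fdr/status columns
    added; ``reject_reason`` is the first failed gate in :data:`GATES`.
    """
    out = candidates.copy().reset_index(drop=True)
    n = len(out)
    if n == 0:
        for col in GATES:
            out[col] = pd.Series(dtype=float)
        out["status"] = pd.Series(dtype=str)
        out["reject_reason"] = pd.Series(dtype=str)
        return out
    chip = out["chip_count"].to_numpy()
    lam_local = out["lambda_local"].to_numpy(dtype=float)
    lam_input = out["lambda_input"].to_numpy(dtype=float)
    c = pseudocount
    p_local = np.clip(poisson_upper_tail(chip, lam_local), P_FLOOR, 1.0)
    p_input = np.clip(poisson_upper_tail(chip, lam_input), P_FLOOR, 1.0)
    out["p_local"] = np.atleast_1d(p_local)
    out["p_input"] = np.atleast_1d(p_input)
    out["fold_local"] = (chip + c) / (lam_local + c)
    out["fold_input"] = (chip + c) / (lam_input + c)
    out["fdr_local"] = benjamini_hochberg(out["p_local"].to_numpy())
    out["fdr_input"] = benjamini_hochberg(out["p_input"].to_numpy())

    fails = {
        "p_local": out["p_local"] > alpha_p,
        "p_input": out["p_input"] > alpha_p,
        "fold_local": out["fold_local"] < min_fold,
        "fold_input": out["fold_input"] < min_fold,
        "fdr_local": out["fdr_local"] > alpha_fdr,
        "fdr_input": out["fdr_input"] > alpha_fdr,
    }
    reason = np.full(n, "", dtype=object)
    for gate in reversed(GATES):
        reason[fails[gate].to_numpy()] = gate
    out["status"] = np.where(reason == "", "accepted", "rejected")
    out["reject_reason"] = reason
    return out
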