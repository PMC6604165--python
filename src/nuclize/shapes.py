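"""Crosslinking-artifact shape filters (oblique and U-shaped peaks).

Formaldehyde crosslinking smears ChIP signal across nucleosome borders and
produces within-nucleosome coverage shapes that genuine mononucleosomal
enrichment does not: mass displaced off the dyad toward one edge
("oblique") or dipped at the dyad with high edges ("U-shaped").  Both are
detected from the fragment-midpoint histogram across the nucleosome:

* ``asymmetry``: normalized center-of-mass offset from the central bin,
  in [-1, 1]; symmetric profiles score 0.
* ``dip_ratio``: mean of the central third of bins over the mean of the two
  flanking thirds; ~1 is flat, << 1 is U-shaped, >> 1 is dyad-peaked
  (flank mean 0 yields an +inf sentinel, never filtered as U-shaped).

Profiles with fewer than ``min_reads`` fragments are not evaluable and pass
through to the statistical tests (verdict ``low_coverage_pass``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import NucleosomeMap

VERDICT_OK = "ok"
VERDICT_OBLIQUE = "oblique"
VERDICT_U = "u_shaped"
VERDICT_LOW = "low_coverage_pass"


def effective_bins(width: int, n_bins: int) -> int:
    """Number of bins actually used: n_bins, reduced (odd) for narrow intervals."""
    if n_bins < 3 or n_bins % 2 == 0:
        raise ValueError("n_bins must be odd and >= 3")
    if width >= n_bins:
        return n_bins
    nb = width if width % 2 == 1 else width - 1
    return max(nb, 1)


def profile_counts(
    midpoints: np.ndarray, start: int, end: int, n_bins: int = 21
) -> np.ndarray:
    """Histogram of fragment midpoints across ``[start, end)``.

    Bins are equal-width; a midpoint on a bin boundary falls in the bin to
    its right and the last bin is closed (any midpoint < end lands inside).
    """
    width = end - start
    nb = effective_bins(width, n_bins)
    mids = np.asarray(midpoints, dtype=np.int64)
    if np.any((mids < start) | (mids >= end)):
        raise ValueError("midpoint outside the nucleosome interval")
    idx = ((mids - start) * nb) // width
    return np.bincount(idx, minlength=nb).astype(np.int64)


def asymmetry_score(bins: np.ndarray) -> float:
    """Normalized center-of-mass offset: (mean bin index - center) / half-width."""
    bins = np.asarray(bins, dtype=float)
    total = bins.sum()
    if total <= 0:
        raise ValueError("asymmetry undefined for an empty profile")
    nb = len(bins)
    if nb == 1:
        return 0.0
    com = float((np.arange(nb) * bins).sum() / total)
    center = (nb - 1) / 2.0
    return (com - center) / center


def dip_score(bins: np.ndarray) -> float:
    """Central-third over flanking-thirds mean ratio (+inf if flanks empty)."""
    bins = np.asarray(bins, dtype=float)
    if bins.sum() <= 0:
        raise ValueError("dip ratio undefined for an empty profile")
    nb = len(bins)
    f = nb // 3
    if f == 0:
        return float("inf")
    flanks = np.concatenate([bins[:f], bins[nb - f:]])
    center = bins[f: nb - f]
    fm = flanks.mean()
    if fm == 0:
        return float("inf")
    return float(center.mean() / fm)


def shape_verdict(
    bins: np.ndarray,
    a_max: float = 0.5,
    d_min: float = 0.5,
    min_reads: int = 10,
) -> tuple[float, float, str]:
    """Classify one profile; returns (asymmetry, dip_ratio, verdict)."""
    total = int(np.asarray(bins).sum())
    if total < min_reads:
        if total > 0:
            return asymmetry_score(bins), dip_score(bins), VERDICT_LOW
        return float("nan"), float("nan"), VERDICT_LOW
    asym = asymmetry_score(bins)
    dip = dip_score(bins)
    if abs(asym) > a_max:
        return asym, dip, VERDICT_OBLIQUE
    if dip < d_min:
        return asym, dip, VERDICT_U
    return asym, dip, VERDICT_OK


def evaluate_shapes(
    candidates: pd.DataFrame,
    chip: pd.DataFrame,
    nucmap: NucleosomeMap,
    n_bins: int = 21,
    a_max: float = 0.5,
    d_min: float = 0.5,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Shape verdicts for every candidate nucleosome.

    Shape is judged on ChIP midpoints only: per-nucleosome input coverage is
    far too sparse to carry shape information.
    """
    ids = nucmap.assign(chip["chrom"].to_numpy(), chip["midpoint"].to_numpy())
    mids = chip["midpoint"].to_numpy()
    by_id: dict[int, np.ndarray] = {
        int(k): mids[ids == k] for k in np.unique(ids[ids >= 0])
    }
    rows = []
    for row in candidates.itertuples(index=False):
        nid = int(row.nucleosome_id)
        m = by_id.get(nid, np.empty(0, dtype=np.int64))
        bins = profile_counts(m, int(row.start), int(row.end), n_bins)
        asym, dip, verdict = shape_verdict(bins, a_max, d_min, min_reads)
        rows.append((nid, int(bins.sum()), asym, dip, verdict))
    return pd.DataFrame(
        rows, columns=["nucleosome_id", "total", "asymmetry", "dip_ratio", "verdict"]
    )


def apply_shape_filters(
    candidates: pd.DataFrame, verdicts: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split candidates into (passed, removed) by their shape verdicts.

    ``ok`` and ``low_coverage_pass`` proceed to statistical testing;
    ``oblique`` and ``u_shaped`` are removed.  A candidate without a verdict
    row is an error (its nucleosome id is named).
    """
    vmap = dict(
        zip(verdicts["nucleosome_id"].astype(int), verdicts["verdict"])
    )
    missing = [
        int(n) for n in candidates["nucleosome_id"] if int(n) not in vmap
    ]
    if missing:
        raise KeyError(f"no shape profile for nucleosome id(s) {missing}")
    verdict_col = candidates["nucleosome_id"].map(lambda n: vmap[int(n)])
    removed_mask = verdict_col.isin([VERDICT_OBLIQUE, VERDICT_U])
    passed = candidates.loc[~removed_mask].reset_index(drop=True)
    removed = candidates.loc[removed_mask].copy()
    removed["reject_reason"] = verdict_col[removed_mask].to_numpy()
    return passed, removed.reset_index(drop=True)
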