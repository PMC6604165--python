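"""Multivalent (co-occurring) histone marks per nucleosome and occupancy.

Because every mark is called against the same fixed nucleosome map, the
multivalent join is an exact set union on nucleosome id.  Mark sets are
rendered as canonical "+"-joined labels in the conventional mark order,
with the field's shorthand aliases:

* ``T`` = H3K4me3/H3K9ac/H3K27ac (trivalent active promoter mark)
* ``D`` = H3K4me3/H3K9ac
* ``A`` = H3K4me3
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import DEFAULT_MARKS, NucleosomeMap

CATEGORY_ALIASES: dict[str, frozenset[str]] = {
    "T": frozenset({"H3K4me3", "H3K9ac", "H3K27ac"}),
    "D": frozenset({"H3K4me3", "H3K9ac"}),
    "A": frozenset({"H3K4me3"}),
}
_ALIAS_BY_SET = {v: k for k, v in CATEGORY_ALIASES.items()}


def _mark_sort_key(mark: str):
    try:
        return (DEFAULT_MARKS.index(mark), mark)
    except ValueError:
        return (len(DEFAULT_MARKS), mark)


def category_label(marks: Iterable[str]) -> str:
    """Canonical label for a mark set (alias if one exists)."""
    s = frozenset(marks)
    if not s:
        raise ValueError("mark set must be non-empty")
    alias = _ALIAS_BY_SET.get(s)
    if alias is not None:
        return alias
    return "+".join(sorted(s, key=_mark_sort_key))


def category_marks(label: str) -> frozenset[str]:
    """Invert :func:`category_label` (aliases and "+"-joined labels)."""
    if label in CATEGORY_ALIASES:
        return CATEGORY_ALIASES[label]
    return frozenset(label.split("+"))


def join_marks(
    per_mark_accepted: Mapping[str, Iterable[int]], nucmap: NucleosomeMap
) -> pd.DataFrame:
    """One row per nucleosome with >= 1 accepted mark.

    Columns: nucleosome_id, chrom, start, end, dyad, marks (comma-joined in
    canonical order), category.  Ids outside the map raise.
    """
    n = len(nucmap)
    marks_by_id: dict[int, set[str]] = {}
    for mark, ids in per_mark_accepted.items():
        for nid in ids:
            nid = int(nid)
            if nid < 0 or nid >= n:
                raise ValueError(f"nucleosome id {nid} outside map of size {n}")
            marks_by_id.setdefault(nid, set()).add(mark)
    if not marks_by_id:
        return pd.DataFrame(
            columns=[
                "nucleosome_id", "chrom", "start", "end", "dyad",
                "marks", "category",
            ]
        )
    ids = np.array(sorted(marks_by_id), dtype=np.int64)
    tab = nucmap.table.loc[ids]
    out = pd.DataFrame(
        {
            "nucleosome_id": ids,
            "chrom": tab["chrom"].to_numpy(),
            "start": tab["start"].to_numpy(),
            "end": tab["end"].to_numpy(),
            "dyad": tab["dyad"].to_numpy(),
        }
    )
    out["marks"] = [
        ",".join(sorted(marks_by_id[i], key=_mark_sort_key)) for i in ids
    ]
    out["category"] = [category_label(marks_by_id[i]) for i in ids]
    return out


def tss_proximal_mask(
    dyads_chrom: np.ndarray, dyads_pos: np.ndarray, genes: pd.DataFrame,
    window_bp: int = 2000,
) -> np.ndarray:
    """True where a dyad lies within [tss - w, tss + w] of any gene's TSS."""
    out = np.zeros(len(dyads_pos), dtype=bool)
    for chrom, sub in genes.groupby("chrom"):
        tss = np.sort(sub["tss"].to_numpy())
        sel = np.flatnonzero(dyads_chrom == chrom)
        if sel.size == 0 or tss.size == 0:
            continue
        pos = dyads_pos[sel]
        i = np.searchsorted(tss, pos)
        left = np.where(i > 0, pos - tss[np.clip(i - 1, 0, None)], np.iinfo(np.int64).max)
        right = np.where(
            i < tss.size, tss[np.clip(i, None, tss.size - 1)] - pos,
            np.iinfo(np.int64).max,
        )
        out[sel] = np.minimum(left, right) <= window_bp
    return out


def occupancy_summary(
    calls: pd.DataFrame,
    nucmap: NucleosomeMap,
    genes: pd.DataFrame | None = None,
    window_bp: int = 2000,
) -> pd.DataFrame:
    """Per-category nucleosome occupancy genome-wide and near TSSs.

    Genome-wide fractions are over all map nucleosomes; TSS-proximal
    fractions are over the nucleosomes whose dyads lie within +-window_bp of
    any TSS (a within-window relative occupancy).
    """
    n_total = len(nucmap)
    cats = sorted(calls["category"].unique()) if len(calls) else []
    genome_counts = calls["category"].value_counts() if len(calls) else pd.Series(dtype=int)
    rows = []
    if genes is not None and len(genes):
        map_prox = tss_proximal_mask(
            nucmap.table["chrom"].to_numpy(),
            nucmap.table["dyad"].to_numpy(),
            genes,
            window_bp,
        )
        n_prox = int(map_prox.sum())
        call_prox = (
            tss_proximal_mask(
                calls["chrom"].to_numpy(), calls["dyad"].to_numpy(), genes, window_bp
            )
            if len(calls)
            else np.zeros(0, dtype=bool)
        )
        prox_counts = calls.loc[call_prox, "category"].value_counts() if len(calls) else pd.Series(dtype=int)
    else:
        n_prox = 0
        prox_counts = pd.Series(dtype=int)
    for cat in cats:
        g = int(genome_counts.get(cat, 0))
        t = int(prox_counts.get(cat, 0))
        rows.append(
            {
                "category": cat,
                "genome_count": g,
                "genome_fraction": g / n_total,
                "tss_count": t,
                "tss_fraction": (t / n_prox) if n_prox else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["category", "genome_count", "genome_fraction", "tss_count", "tss_fraction"],
    )
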