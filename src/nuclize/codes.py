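"""TSS-anchored histone codes: extraction, clustering, expression links.

A histone code is the strand-oriented string of per-nucleosome multivalent
categories for the nucleosomes whose dyads fall within a window around a
gene's TSS, read 5'->3' in the direction of transcription (on the minus
strand the genomic order is reversed).  Nucleosomes in the window without
any accepted mark contribute the explicit ``unmarked`` symbol; a dyad
exactly at the TSS counts as downstream.  Codes are one-hot featurized
(fixed slots per side, outer slots padded ``absent``) and clustered with
k-means; counts of chosen categories per gene are compared with expression
(RPKM) by Spearman correlation of per-cluster medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .intervals import NucleosomeMap

log = logging.getLogger(__name__)

UNMARKED = "unmarked"
ABSENT = "absent"


@dataclass(frozen=True)
class HistoneCode:
    """One gene's oriented per-nucleosome category string around its TSS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    slots: tuple[str, ...]          # 5'->3' in transcription direction
    nucleosome_ids: tuple[int, ...]  # same orientation as slots
    n_upstream: int
    n_downstream: int
    counts: dict                    # category -> (up, down, total)
    missing_chrom: bool = False

    def count(self, category: str) -> tuple[int, int, int]:
        return self.counts.get(category, (0, 0, 0))

    def marked_counts(self) -> tuple[int, int, int]:
        """Up/down/total number of marked slots (the gene's "codes" count)."""
        up = down = 0
        for cat, (u, d, _) in self.counts.items():
            if cat != UNMARKED:
                up += u
                down += d
        return up, down, up + down


def extract_codes(
    calls: pd.DataFrame,
    nucmap: NucleosomeMap,
    genes: pd.DataFrame,
    window_bp: int = 2000,
) -> list[HistoneCode]:
    """Per-gene oriented category strings for dyads in [tss-w, tss+w]."""
    cat_by_id = (
        dict(zip(calls["nucleosome_id"].astype(int), calls["category"]))
        if len(calls)
        else {}
    )
    dyads_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in nucmap.table.groupby("chrom", sort=False):
        order = np.argsort(sub["dyad"].to_numpy(), kind="stable")
        dyads_by_chrom[chrom] = (
            sub["dyad"].to_numpy()[order],
            sub["nucleosome_id"].to_numpy()[order],
        )
    out: list[HistoneCode] = []
    for g in genes.itertuples(index=False):
        entry = dyads_by_chrom.get(g.chrom)
        if entry is None:
            out.append(
                HistoneCode(
                    gene_id=g.gene_id, chrom=g.chrom, strand=g.strand,
                    tss=int(g.tss), slots=(), nucleosome_ids=(),
                    n_upstream=0, n_downstream=0, counts={}, missing_chrom=True,
                )
            )
            continue
        dyads, ids = entry
        lo = np.searchsorted(dyads, g.tss - window_bp, side="left")
        hi = np.searchsorted(dyads, g.tss + window_bp, side="right")
        win_ids = ids[lo:hi]
        win_dyads = dyads[lo:hi]
        cats = [cat_by_id.get(int(i), UNMARKED) for i in win_ids]
        if g.strand == "-":
            cats = cats[::-1]
            win_ids = win_ids[::-1]
            win_dyads = win_dyads[::-1]
            downstream = win_dyads <= g.tss
        else:
            downstream = win_dyads >= g.tss
        n_down = int(downstream.sum())
        n_up = len(cats) - n_down
        counts: dict[str, list[int]] = {}
        for cat, is_down in zip(cats, downstream):
            c = counts.setdefault(cat, [0, 0, 0])
            c[1 if is_down else 0] += 1
            c[2] += 1
        out.append(
            HistoneCode(
                gene_id=g.gene_id, chrom=g.chrom, strand=g.strand,
                tss=int(g.tss), slots=tuple(cats),
                nucleosome_ids=tuple(int(i) for i in win_ids),
                n_upstream=n_up, n_downstream=n_down,
                counts={k: tuple(v) for k, v in counts.items()},
            )
        )
    return out


def build_code_matrix(
    codes: Sequence[HistoneCode],
    slots_per_side: int = 15,
    alphabet: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """One-hot gene x slot-category matrix with fixed width.

    The nearest ``slots_per_side`` nucleosomes on each side of the TSS are
    retained (slot positions -s..-1, +1..+s in transcription direction);
    outer positions without a nucleosome are the ``absent`` symbol.
    Columns are ordered by slot position, then alphabetically by category.
    Returns (matrix, gene_ids, column_names).
    """
    if alphabet is None:
        seen = {UNMARKED, ABSENT}
        for code in codes:
            seen.update(code.slots)
        alphabet = sorted(seen)
    alphabet = list(alphabet)
    a_index = {c: i for i, c in enumerate(alphabet)}
    positions = list(range(-slots_per_side, 0)) + list(range(1, slots_per_side + 1))
    n_cat = len(alphabet)
    X = np.zeros((len(codes), len(positions) * n_cat))
    for r, code in enumerate(codes):
        up = code.slots[: code.n_upstream]       # farthest -> nearest
        down = code.slots[code.n_upstream:]      # nearest -> farthest
        for j, pos in enumerate(positions):
            if pos < 0:
                k = len(up) + pos                # pos=-1 -> nearest upstream
                cat = up[k] if k >= 0 else ABSENT
            else:
                cat = down[pos - 1] if pos - 1 < len(down) else ABSENT
            X[r, j * n_cat + a_index[cat]] = 1.0
    columns = [
        f"slot{pos:+d}:{cat}" for pos in positions for cat in alphabet
    ]
    return X, [c.gene_id for c in codes], columns


def cluster_codes(
    matrix: np.ndarray, k: int = 13, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """K-means labels in 1..k, renumbered by descending cluster size.

    Fixed seed => bitwise-reproducible assignment.  Raises if k exceeds the
    number of distinct rows.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n_distinct = len(np.unique(matrix, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct code rows")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    raw = km.fit_predict(matrix)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(1, k + 1)
    return relabel[raw]


def count_marks_vs_expression(
    codes: Sequence[HistoneCode],
    expression: Mapping[str, float] | None,
    categories: Sequence[str] = ("T", "D", "A"),
    clusters: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame | None]:
    """Per-gene category counts, per-cluster medians, Spearman correlations.

    Returns (per_gene, per_cluster, correlations).  Genes absent from the
    expression table are excluded from the per-gene table (their number is
    logged and stored in ``per_gene.attrs['n_missing_expression']``).  The
    correlation table relates cluster-median RPKM to cluster-median counts
    of T (up/down/total) and of all codes (up/down/total); an undefined
    correlation (constant input) is reported as NaN.
    """
    rows = []
    n_missing = 0
    for code in codes:
        if expression is not None and code.gene_id not in expression:
            n_missing += 1
            continue
        row = {"gene_id": code.gene_id}
        if expression is not None:
            row["rpkm"] = float(expression[code.gene_id])
        for cat in categories:
            u, d, t = code.count(cat)
            row[f"{cat}_up"], row[f"{cat}_down"], row[f"{cat}_total"] = u, d, t
        cu, cd, ct = code.marked_counts()
        row["codes_up"], row["codes_down"], row["codes_total"] = cu, cd, ct
        if clusters is not None:
            row["cluster"] = clusters.get(code.gene_id, -1)
        rows.append(row)
    per_gene = pd.DataFrame(rows)
    per_gene.attrs["n_missing_expression"] = n_missing
    if n_missing:
        log.warning("%d genes lack expression values; excluded", n_missing)
    if clusters is None or "cluster" not in per_gene.columns or len(per_gene) == 0:
        return per_gene, None, None
    count_cols = [c for c in per_gene.columns if c not in ("gene_id", "cluster")]
    per_cluster = (
        per_gene.groupby("cluster")[count_cols].median().reset_index()
    )
    per_cluster["n_genes"] = per_gene.groupby("cluster").size().to_numpy()
    corr = None
    if expression is not None and len(per_cluster) >= 2:
        feats = ["T_up", "T_down", "T_total", "codes_up", "codes_down", "codes_total"]
        feats = [f for f in feats if f in per_cluster.columns]
        crows = []
        y = per_cluster["rpkm"].to_numpy()
        for f in feats:
            x = per_cluster[f].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                rho, pval = float("nan"), float("nan")
            else:
                rho, pval = sps.spearmanr(x, y)
            crows.append({"feature": f, "spearman_rho": rho, "p_value": pval})
        corr = pd.DataFrame(crows)
    return per_gene, per_cluster, corr


def plot_expression_vs_counts(per_gene: pd.DataFrame, path, category: str = "T"):
    """Basic scatter of RPKM against the total count of one category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(per_gene[f"{category}_total"], per_gene["rpkm"], s=10, alpha=0.6)
    ax.set_xlabel(f"{category} marks within TSS window")
    ax.set_ylabel("RPKM")
    ax.set_yscale("symlog")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
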