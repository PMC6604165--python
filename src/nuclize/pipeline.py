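"""End-to-end per-mark peak calling: count -> candidates -> shape -> tests.

This is the library face of the ``nuclize call`` command; the CLI is a thin
wrapper around :func:`call_peaks`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import counting, shapes, stats
from .intervals import NucleosomeMap


@dataclass
class PipelineParams:
    """All tunable thresholds of the calling pipeline.

    Statistical gates carry the published defaults (excess >= 4 reads,
    p <= 0.01, fold >= 4, FDR <= 0.01); the shape-filter and background
    settings are this implementation's documented defaults.
    """

    min_excess: float = 4.0
    local_window_bp: int = 10_000
    effective_genome_size: float = 2.7e9
    n_bins: int = 21
    a_max: float = 0.5
    d_min: float = 0.5
    shape_min_reads: int = 10
    alpha_p: float = 0.01
    min_fold: float = 4.0
    alpha_fdr: float = 0.01
    pseudocount: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineParams":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CallSummary:
    """Per-stage record counts; candidates = shape_rejected + shape_passed."""

    n_nucleosomes: int
    n_candidates: int
    n_shape_rejected: int
    n_test_rejected: int
    n_accepted: int

    def line(self, mark: str) -> str:
        return (
            f"{mark}: nucleosomes={self.n_nucleosomes} "
            f"candidates={self.n_candidates} "
            f"shape_rejected={self.n_shape_rejected} "
            f"test_rejected={self.n_test_rejected} "
            f"accepted={self.n_accepted}"
        )


def call_peaks(
    chip: pd.DataFrame,
    input_frags: pd.DataFrame,
    nucmap: NucleosomeMap,
    mark: str,
    params: PipelineParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, CallSummary]:
    """Call single-nucleosome peaks for one mark.

    Returns (peaks, verdicts, summary).  ``peaks`` carries one row per
    candidate nucleosome — shape-rejected candidates included, with NaN
    statistics — with final status and reject reason, ordered by
    (chrom, start).
    """
    p = params or PipelineParams()
    counts = counting.build_count_table(
        chip, input_frags, nucmap,
        window_bp=p.local_window_bp,
        effective_genome_size=p.effective_genome_size,
        signal_exclusion_min_excess=p.min_excess,
    )
    candidates = counting.call_candidates(counts, min_excess=p.min_excess)
    verdicts = shapes.evaluate_shapes(
        candidates, chip, nucmap,
        n_bins=p.n_bins, a_max=p.a_max, d_min=p.d_min, min_reads=p.shape_min_reads,
    )
    passed, removed = shapes.apply_shape_filters(candidates, verdicts)
    tested = stats.test_peaks(
        passed,
        alpha_p=p.alpha_p, min_fold=p.min_fold, alpha_fdr=p.alpha_fdr,
        pseudocount=p.pseudocount,
    )
    if len(removed):
        removed = removed.copy()
        for col in ("fold_local", "fold_input", "p_local", "p_input",
                    "fdr_local", "fdr_input"):
            removed[col] = np.nan
        removed["status"] = "rejected"
    peaks = pd.concat([tested, removed], ignore_index=True) if len(removed) else tested
    peaks = peaks.copy()
    peaks["mark"] = mark
    peaks = peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    summary = CallSummary(
        n_nucleosomes=len(nucmap),
        n_candidates=len(candidates),
        n_shape_rejected=len(removed),
        n_test_rejected=int((tested["status"] == "rejected").sum()),
        n_accepted=int((tested["status"] == "accepted").sum()),
    )
    return peaks, verdicts, summary


def accepted_ids(peaks: pd.DataFrame) -> set[int]:
    """Nucleosome ids of accepted peaks in a call table."""
    return set(
        peaks.loc[peaks["status"] == "accepted", "nucleosome_id"].astype(int)
    )
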