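"""Ground-truthed synthetic data: phased nucleosome arrays, ChIP/input/MNase
fragment libraries, planted marks, crosslinking artifacts, genes, expression.

The generator emulates the data-generating setting of a native-MNase
nucleosome map plus crosslinked ChIP-Seq libraries:

* nucleosomes tiled at fixed spacing (phased array), 147 bp wide;
* MNase fragments per nucleosome ~ Poisson(depth), midpoints drawn from a
  truncated normal around the dyad (positioning fuzziness);
* ChIP per mark = uniform background Poisson process plus, at truly marked
  nucleosomes, Poisson(enrichment_fold * background_rate * width) extra
  fragments centered on the dyad;
* crosslinking artifacts planted at unmarked nucleosomes with the same
  fragment yield but displaced ("oblique", mean dyad + 0.4*width) or
  bimodal ("u_shaped", mixture at dyad +- 0.4*width) midpoints;
* input = pure background process;
* genes with alternating strands; optionally two planted promoter
  archetypes ("active": T marks downstream of the TSS plus an upstream D;
  "polycomb": H3K27me3 flanking the TSS) that make code clusters and the
  expression correlation recoverable by construction;
* expression RPKM = base_rpkm * (# downstream planted T) + lognormal noise.

A fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import io as nio
from .intervals import DEFAULT_MARKS, NucleosomeMap, fragment_table
from .multivalent import category_label, category_marks

#: Category sampling weights for randomly marked nucleosomes (renormalized
#: over the categories expressible with the configured mark list).
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "T": 0.20,
    "D": 0.10,
    "A": 0.20,
    "H3K9ac": 0.10,
    "H3K27ac": 0.10,
    "H3K9me3": 0.12,
    "H3K27me3": 0.12,
    "H3K9me3+H3K27me3": 0.06,
}

#: Planted promoter archetypes: oriented slot offset -> category.
#: Negative offsets are upstream of the TSS, positive downstream.
ARCHETYPES: dict[str, dict[int, str]] = {
    "active": {-1: "D", 1: "T", 2: "T", 3: "T"},
    "polycomb": {-2: "H3K27me3", -1: "H3K27me3", 1: "H3K27me3", 2: "H3K27me3"},
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_chromosomes: int = 1
    chrom_length_bp: int = 200_000
    nucleosome_spacing_bp: int = 200
    nucleosome_width_bp: int = 147
    fuzziness_sd_bp: float = 20.0
    mnase_depth: float = 20.0           # mean MNase fragments per nucleosome
    background_rate: float = 0.01       # ChIP/input background fragments per bp
    enrichment_fold: float = 20.0       # signal yield over background at marks
    marks: tuple[str, ...] = DEFAULT_MARKS
    n_marked_random: int = 100
    category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    n_artifacts: int = 30               # split evenly oblique / u_shaped
    artifact_offset_frac: float = 0.4   # displacement as fraction of width
    artifact_sd_bp: float = 8.0
    n_genes: int = 20
    plant_tss_archetypes: bool = True
    base_rpkm: float = 10.0
    expression_noise_sigma: float = 0.25

    def validate(self) -> None:
        if self.nucleosome_spacing_bp <= self.nucleosome_width_bp:
            raise ValueError("spacing must exceed nucleosome width")
        if min(self.background_rate, self.mnase_depth, self.enrichment_fold) < 0:
            raise ValueError("rates must be >= 0")
        if self.n_chromosomes < 1 or self.chrom_length_bp <= 0:
            raise ValueError("need at least one chromosome of positive length")
        if self.fuzziness_sd_bp <= 0 or self.artifact_sd_bp <= 0:
            raise ValueError("jitter sds must be > 0")
        if not self.marks:
            raise ValueError("need at least one mark")


@dataclass
class GroundTruth:
    """Everything the generator planted, for oracle-style testing."""

    nucleosomes: pd.DataFrame                    # chrom, start, end, dyad
    marked: dict[str, list[int]]                 # mark -> sorted nucleosome ids
    category_by_id: dict[int, str]
    artifacts: list[tuple[int, str]]             # (nucleosome id, shape)
    genes: pd.DataFrame                          # gene_id, chrom, tss, strand, archetype
    expression: dict[str, float]
    planted_t_downstream: dict[str, int]         # gene_id -> planted downstream T
    fragment_totals: dict[str, int]              # library name -> N

    def artifact_ids(self) -> list[int]:
        return sorted(i for i, _ in self.artifacts)


@dataclass
class SimResult:
    config: SimConfig
    nucmap: NucleosomeMap
    mnase: pd.DataFrame
    chip: dict[str, pd.DataFrame]
    input_frags: pd.DataFrame
    truth: GroundTruth


def tile_nucleosomes(config: SimConfig) -> pd.DataFrame:
    """Phased nucleosome array: margin + i*spacing per chromosome."""
    w, sp = config.nucleosome_width_bp, config.nucleosome_spacing_bp
    margin = (sp - w) // 2
    rows = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        start = margin
        while start + w + margin <= config.chrom_length_bp:
            rows.append((chrom, start, start + w, start + w // 2))
            start += sp
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "dyad"])


def _truncnorm_ints(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Integer midpoints from a normal truncated to [lo, hi] inclusive."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draws = truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return np.clip(np.rint(draws).astype(np.int64), lo, hi)


def _frags_from_midpoints(chrom: str, mids: np.ndarray, width: int) -> pd.DataFrame:
    # clamp at the chromosome start; the clamped midpoint stays inside the
    # first nucleosome's interval, so assignments are unaffected
    starts = np.maximum(mids - width // 2, 0)
    return fragment_table([chrom] * len(mids), starts, starts + width)


def simulate_tables(config: SimConfig) -> SimResult:
    """Generate all libraries and the ground truth in memory."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    w = config.nucleosome_width_bp
    nuc = tile_nucleosomes(config)
    nucmap = NucleosomeMap.from_intervals(nuc)
    tab = nucmap.table
    n_nuc = len(tab)

    # -- genes and planted archetypes ---------------------------------
    category_by_id: dict[int, str] = {}
    gene_rows = []
    planted_t_down: dict[str, int] = {}
    reserved: set[int] = set()
    if config.n_genes > 0:
        per_chrom = tab.groupby("chrom", sort=False).groups
        chroms = list(per_chrom)
        for g in range(config.n_genes):
            chrom = chroms[g % len(chroms)]
            idx = np.asarray(per_chrom[chrom])
            k = int(round((g // len(chroms) + 1) * len(idx) /
                          (config.n_genes // len(chroms) + 2)))
            k = min(max(k, 3), len(idx) - 4)
            anchor = int(tab.loc[idx[k], "nucleosome_id"])
            strand = "+" if g % 2 == 0 else "-"
            archetype = (
                ["active", "polycomb"][(g // 2) % 2]
                if config.plant_tss_archetypes
                else "none"
            )
            if strand == "+":
                tss = int(tab.loc[anchor, "start"])
            else:
                tss = int(tab.loc[anchor, "end"]) - 1
            gid = f"gene_{g + 1:03d}"
            gene_rows.append((gid, chrom, tss, strand, archetype))
            t_down = 0
            if archetype != "none":
                for off, cat in ARCHETYPES[archetype].items():
                    # oriented offset -> nucleosome id on the genomic axis
                    if strand == "+":
                        nid = anchor + off - 1 if off > 0 else anchor + off
                    else:
                        nid = anchor - off + 1 if off > 0 else anchor - off
                    if nid < 0 or nid >= n_nuc:
                        continue
                    if tab.loc[nid, "chrom"] != chrom:
                        continue
                    marks = category_marks(cat) & set(config.marks)
                    if not marks:
                        continue
                    category_by_id[nid] = category_label(marks)
                    reserved.add(nid)
                    if cat == "T" and off > 0:
                        t_down += 1
            planted_t_down[gid] = t_down
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "tss", "strand", "archetype"]
    )

    # -- randomly marked nucleosomes ----------------------------------
    weights = {
        cat: wgt
        for cat, wgt in config.category_weights.items()
        if category_marks(cat) <= set(config.marks)
    }
    if not weights:
        raise ValueError("no category is expressible with the configured marks")
    pool = np.array(sorted(set(range(n_nuc)) - reserved), dtype=np.int64)
    n_rand = min(config.n_marked_random, len(pool))
    rand_ids = rng.choice(pool, size=n_rand, replace=False)
    cats = list(weights)
    p = np.array([weights[c] for c in cats], dtype=float)
    p /= p.sum()
    for nid, ci in zip(rand_ids, rng.choice(len(cats), size=n_rand, p=p)):
        category_by_id[int(nid)] = cats[ci]

    marked: dict[str, list[int]] = {m: [] for m in config.marks}
    for nid, cat in category_by_id.items():
        for m in category_marks(cat):
            if m in marked:
                marked[m].append(nid)
    for m in marked:
        marked[m].sort()

    # -- artifacts ----------------------------------------------------
    art_pool = np.array(
        sorted(set(range(n_nuc)) - set(category_by_id) - reserved), dtype=np.int64
    )
    n_art = min(config.n_artifacts, len(art_pool))
    art_ids = np.sort(rng.choice(art_pool, size=n_art, replace=False))
    artifacts = [
        (int(nid), "oblique" if i % 2 == 0 else "u_shaped")
        for i, nid in enumerate(art_ids)
    ]

    # -- fragment libraries -------------------------------------------
    sizes = {f"chr{c + 1}": config.chrom_length_bp for c in range(config.n_chromosomes)}
    starts = tab["start"].to_numpy()
    ends = tab["end"].to_numpy()
    dyads = tab["dyad"].to_numpy()
    chrom_of = tab["chrom"].to_numpy()

    def background(rate: float) -> list[pd.DataFrame]:
        parts = []
        for chrom, L in sizes.items():
            n = rng.poisson(rate * L)
            mids = np.sort(rng.integers(w // 2, L - w // 2, size=n))
            parts.append(_frags_from_midpoints(chrom, mids, w))
        return parts

    def nucleosome_signal(nid: int, lam: float, mode: str) -> pd.DataFrame:
        n = rng.poisson(lam)
        s, e, d = int(starts[nid]), int(ends[nid]), int(dyads[nid])
        off = int(round(config.artifact_offset_frac * w))
        if mode == "mark":
            mids = _truncnorm_ints(rng, d, config.fuzziness_sd_bp, s, e - 1, n)
        elif mode == "oblique":
            mids = _truncnorm_ints(rng, d + off, config.artifact_sd_bp, s, e - 1, n)
        elif mode == "u_shaped":
            side = rng.integers(0, 2, size=n)
            mids = np.empty(n, dtype=np.int64)
            for sgn, sel in ((1, side == 1), (-1, side == 0)):
                k = int(sel.sum())
                mids[sel] = _truncnorm_ints(
                    rng, d + sgn * off, config.artifact_sd_bp, s, e - 1, k
                )
        else:  # pragma: no cover
            raise ValueError(mode)
        return _frags_from_midpoints(str(chrom_of[nid]), mids, w)

    # MNase library: every nucleosome contributes
    mnase_parts = []
    for nid in range(n_nuc):
        n = rng.poisson(config.mnase_depth)
        mids = _truncnorm_ints(
            rng, int(dyads[nid]), config.fuzziness_sd_bp,
            int(starts[nid]), int(ends[nid]) - 1, n,
        )
        mnase_parts.append(_frags_from_midpoints(str(chrom_of[nid]), mids, w))
    mnase = pd.concat(mnase_parts, ignore_index=True)

    # input library: background only
    input_frags = pd.concat(background(config.background_rate), ignore_index=True)

    # ChIP libraries per mark: background + signal + artifacts
    lam_signal = config.enrichment_fold * config.background_rate * w
    chip: dict[str, pd.DataFrame] = {}
    for mark in config.marks:
        parts = background(config.background_rate)
        for nid in marked[mark]:
            parts.append(nucleosome_signal(nid, lam_signal, "mark"))
        for nid, shape in artifacts:
            parts.append(nucleosome_signal(nid, lam_signal, shape))
        chip[mark] = pd.concat(parts, ignore_index=True)

    # -- expression -----------------------------------------------------
    expression: dict[str, float] = {}
    for gid in genes["gene_id"]:
        noise = rng.lognormal(mean=-1.0, sigma=config.expression_noise_sigma)
        expression[gid] = config.base_rpkm * planted_t_down[gid] + noise

    totals = {"mnase": len(mnase), "input": len(input_frags)}
    totals.update({f"chip_{m}": len(df) for m, df in chip.items()})
    truth = GroundTruth(
        nucleosomes=nuc,
        marked=marked,
        category_by_id=category_by_id,
        artifacts=artifacts,
        genes=genes,
        expression=expression,
        planted_t_downstream=planted_t_down,
        fragment_totals=totals,
    )
    return SimResult(
        config=config, nucmap=nucmap, mnase=mnase, chip=chip,
        input_frags=input_frags, truth=truth,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate(config: SimConfig, outdir) -> dict:
    """Run :func:`simulate_tables` and write every file; returns a manifest."""
    res = simulate_tables(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["nucleosome_map"] = outdir / "nucleosomes.danpos.tsv"
    nio.write_nucleosome_map_danpos(res.nucmap, files["nucleosome_map"])
    files["mnase"] = outdir / "mnase.fragments.bed"
    nio.write_fragments_bed(res.mnase, files["mnase"])
    files["input"] = outdir / "input.fragments.bed"
    nio.write_fragments_bed(res.input_frags, files["input"])
    for mark, df in res.chip.items():
        key = f"chip_{mark}"
        files[key] = outdir / f"{key}.fragments.bed"
        nio.write_fragments_bed(df, files[key])
    files["genes"] = outdir / "genes.bed"
    nio.write_genes_bed(res.truth.genes, files["genes"])
    files["expression"] = outdir / "expression.tsv"
    nio.write_expression(res.truth.expression, files["expression"])

    truth_path = outdir / "ground_truth.json"
    truth_json = {
        "marked": {m: list(map(int, v)) for m, v in res.truth.marked.items()},
        "category_by_id": {
            str(k): v for k, v in sorted(res.truth.category_by_id.items())
        },
        "artifacts": [[int(i), s] for i, s in res.truth.artifacts],
        "genes": res.truth.genes.to_dict(orient="records"),
        "expression": {k: round(v, 6) for k, v in res.truth.expression.items()},
        "planted_t_downstream": res.truth.planted_t_downstream,
        "fragment_totals": res.truth.fragment_totals,
    }
    truth_path.write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    files["ground_truth"] = truth_path

    manifest = {
        "config": asdict(config),
        "n_nucleosomes": len(res.nucmap),
        "files": {
            k: {"path": p.name, "sha256": _sha256(p)} for k, p in files.items()
        },
    }
    manifest["config"]["marks"] = list(config.marks)
    manifest["config"]["category_weights"] = dict(config.category_weights)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


PRESETS: dict[str, dict] = {
    "tiny": dict(
        chrom_length_bp=50_000, n_marked_random=20, n_artifacts=6, n_genes=6
    ),
    "default": dict(),
    "stress": dict(
        n_chromosomes=2, chrom_length_bp=500_000, n_marked_random=400,
        n_artifacts=60, n_genes=60,
    ),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SimConfig(seed=seed, **kwargs)
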