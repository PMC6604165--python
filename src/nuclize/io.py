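"""Readers and writers for the on-disk formats the pipeline touches.

Supported dialects: fragment files as BED3+ or 10-column BEDPE (a BEDPE
record's two ends are merged to one fragment spanning min(start)..max(end));
nucleosome maps as DANPOS-style tab-delimited tables (header row with named
columns, 1-based starts) or plain BED; gene annotations as BED6/BED12 or
GTF; expression as two-column TSV.  All readers normalize to 0-based
half-open coordinates.  Parsers fail fast with the offending line number.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import NucleosomeMap, fragment_table

log = logging.getLogger(__name__)

#: Accepted spellings for DANPOS-dialect columns (lower-cased).
DANPOS_COLUMNS = {
    "chrom": ("chr", "chrom", "chromosome"),
    "start": ("start",),
    "end": ("end",),
    "dyad": ("smt_pos", "smt_pos1", "summit", "dyad"),
}

PEAK_COLUMNS = [
    "chrom", "start", "end", "mark", "nucleosome_id",
    "chip_count", "input_count_scaled",
    "fold_local", "fold_input", "p_local", "p_input",
    "fdr_local", "fdr_input", "status", "reject_reason",
]


class ParseError(ValueError):
    """Malformed record in an input file; message carries the line number."""


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def read_fragments(path, fmt: str = "auto") -> pd.DataFrame:
    """Read a fragment file into the canonical fragment table.

    Parameters
    ----------
    path : str or Path
    fmt : {"auto", "bed", "bedpe"}
        With "auto" the dialect is sniffed from the first data line:
        >= 6 whitespace-separated fields whose fields 5 and 6 are integers
        and field 4 is not is taken as BEDPE.

    Returns
    -------
    DataFrame with columns chrom, start, end, midpoint; ``len(df)`` is the
    library size N.  Raises :class:`ParseError` on a malformed line (with
    its line number) and ``ValueError`` if the file holds zero fragments.
    """
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    n_mismatch = 0
    detected = None if fmt == "auto" else fmt
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if detected is None:
                detected = (
                    "bedpe"
                    if len(f) >= 6
                    and _is_int(f[4]) and _is_int(f[5]) and not _is_int(f[3])
                    else "bed"
                )
            try:
                if detected == "bedpe":
                    if len(f) < 6:
                        raise ValueError("fewer than 6 BEDPE fields")
                    if f[0] != f[3]:
                        n_mismatch += 1  # inter-chromosomal pair: skip
                        continue
                    start = min(int(f[1]), int(f[4]))
                    end = max(int(f[2]), int(f[5]))
                else:
                    if len(f) < 3:
                        raise ValueError("fewer than 3 BED fields")
                    start, end = int(f[1]), int(f[2])
                if end <= start or start < 0:
                    raise ValueError(f"bad interval [{start}, {end})")
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path.name}: malformed line {lineno}: {exc}") from exc
            chroms.append(f[0])
            starts.append(start)
            ends.append(end)
    if n_mismatch:
        log.warning("%s: skipped %d inter-chromosomal pairs", path.name, n_mismatch)
    if not chroms:
        raise ValueError(f"{path}: no fragments found")
    return fragment_table(chroms, starts, ends)


def write_fragments_bed(frags: pd.DataFrame, path) -> None:
    """Write a fragment table as BED3, sorted by (chrom, start, end)."""
    out = frags.sort_values(["chrom", "start", "end"], kind="stable")
    with open(path, "w") as fh:
        for row in out.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


# ---------------------------------------------------------------------------
# nucleosome map
# ---------------------------------------------------------------------------

def read_nucleosome_map(
    path, fmt: str = "auto", columns: Mapping[str, str] | None = None
) -> NucleosomeMap:
    """Read nucleosome calls (DANPOS table or BED) into a trimmed map.

    DANPOS tables carry a header with named columns and 1-based starts and
    summits; both are converted to 0-based.  ``columns`` may remap the
    DANPOS column names, e.g. ``{"dyad": "smt_pos2"}``.  BED input is
    header-less and already 0-based; the dyad defaults to the interval
    midpoint.  Unknown dialects raise with the detected columns listed.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    toks = first.strip().split("\t") if "\t" in first else first.split()
    has_header = len(toks) >= 3 and not (_is_int(toks[1]) and _is_int(toks[2]))
    if fmt == "auto":
        fmt = "danpos" if has_header else "bed"

    if fmt == "danpos":
        df = pd.read_csv(path, sep="\t")
        df.columns = [str(c).strip().lower() for c in df.columns]
        wanted = {k: tuple(v) for k, v in DANPOS_COLUMNS.items()}
        if columns:
            for key, name in columns.items():
                wanted[key] = (name.lower(),)
        resolved: dict[str, str] = {}
        for key, names in wanted.items():
            hit = next((n for n in names if n in df.columns), None)
            if hit is None and key != "dyad":
                raise ValueError(
                    f"{path.name}: cannot resolve DANPOS column {key!r}; "
                    f"file has columns {list(df.columns)}"
                )
            if hit is not None:
                resolved[key] = hit
        table = pd.DataFrame(
            {
                "chrom": df[resolved["chrom"]].astype(str),
                "start": df[resolved["start"]].astype(np.int64) - 1,
                "end": df[resolved["end"]].astype(np.int64),
            }
        )
        if "dyad" in resolved:
            table["dyad"] = df[resolved["dyad"]].astype(np.int64) - 1
    elif fmt == "bed":
        rows = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                try:
                    rows.append((f[0], int(f[1]), int(f[2])))
                except (ValueError, IndexError) as exc:
                    raise ParseError(
                        f"{path.name}: malformed line {lineno}: {exc}"
                    ) from exc
        table = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    else:
        raise ValueError(f"unknown nucleosome-map format {fmt!r}")
    if len(table) == 0:
        raise ValueError(f"{path}: no nucleosome calls found")
    return NucleosomeMap.from_intervals(table)


def write_nucleosome_map_danpos(nucmap: NucleosomeMap, path) -> None:
    """Write a map in the DANPOS dialect (1-based start and summit)."""
    with open(path, "w") as fh:
        fh.write("chr\tstart\tend\tsmt_pos\n")
        for row in nucmap.table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start + 1}\t{row.end}\t{row.dyad + 1}\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_genes(path, fmt: str = "auto") -> pd.DataFrame:
    """Read a gene annotation into (gene_id, chrom, tss, strand).

    BED6/BED12: one record per gene, TSS = start on "+" / end-1 on "-".
    GTF: transcript (fallback: gene) features are collected per ``gene_id``
    and the 5'-most transcript start on the gene strand defines the TSS.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "gtf" if path.suffix.lower() in {".gtf", ".gff"} else "bed"
    if fmt == "bed":
        rows = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                try:
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    name = f[3] if len(f) > 3 else f"gene_{lineno}"
                    strand = f[5] if len(f) > 5 else "+"
                    if strand not in ("+", "-"):
                        raise ValueError(f"bad strand {strand!r}")
                except (ValueError, IndexError) as exc:
                    raise ParseError(
                        f"{path.name}: malformed line {lineno}: {exc}"
                    ) from exc
                tss = start if strand == "+" else end - 1
                rows.append((name, chrom, tss, strand))
        genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    elif fmt == "gtf":
        feats: dict[str, list[tuple[str, int, int, str]]] = {}
        kinds: dict[str, set[str]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise ParseError(f"{path.name}: malformed line {lineno}")
                feature = f[2]
                if feature not in ("transcript", "mRNA", "gene"):
                    continue
                attrs = f[8]
                gid = None
                for field in attrs.split(";"):
                    field = field.strip()
                    if field.startswith("gene_id"):
                        gid = field.split(None, 1)[1].strip().strip('"')
                        break
                if gid is None:
                    raise ParseError(
                        f"{path.name}: line {lineno} lacks gene_id attribute"
                    )
                feats.setdefault(gid, []).append(
                    (f[0], int(f[3]) - 1, int(f[4]), f[6], feature)
                )
                kinds.setdefault(gid, set()).add(feature)
        rows = []
        for gid, recs in feats.items():
            # 5'-most transcript wins; gene records only matter when no
            # transcript features exist for this gene_id
            if {"transcript", "mRNA"} & kinds[gid]:
                recs = [r for r in recs if r[4] != "gene"]
            chrom, strand = recs[0][0], recs[0][3]
            if strand == "+":
                tss = min(r[1] for r in recs)
            else:
                tss = max(r[2] - 1 for r in recs)
            rows.append((gid, chrom, tss, strand))
        genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    else:
        raise ValueError(f"unknown gene annotation format {fmt!r}")
    if len(genes) == 0:
        raise ValueError(f"{path}: no gene records found")
    return genes.drop_duplicates("gene_id").reset_index(drop=True)


def write_genes_bed(genes: pd.DataFrame, path, body_bp: int = 2000) -> None:
    """Write genes as BED6 with a nominal ``body_bp`` gene body from the TSS."""
    out = genes.sort_values(["chrom", "tss"], kind="stable")
    with open(path, "w") as fh:
        for row in out.itertuples(index=False):
            if row.strand == "+":
                start, end = row.tss, row.tss + body_bp
            else:
                start, end = max(0, row.tss - body_bp + 1), row.tss + 1
            fh.write(f"{row.chrom}\t{start}\t{end}\t{row.gene_id}\t0\t{row.strand}\n")


def read_expression(path) -> dict[str, float]:
    """Read a two-column (gene_id, RPKM) TSV; a header row is tolerated."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 2:
                raise ParseError(f"malformed expression line {lineno}")
            try:
                out[f[0]] = float(f[1])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ParseError(f"malformed expression line {lineno}")
    return out


def write_expression(expression: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\trpkm\n")
        for gid in sorted(expression):
            fh.write(f"{gid}\t{expression[gid]:.4f}\n")


# ---------------------------------------------------------------------------
# peak calls
# ---------------------------------------------------------------------------

def peak_score(p_local: float, p_input: float) -> float:
    """BED score: -10*log10(max(p_local, p_input)), capped at 1000."""
    worst = max(p_local, p_input)
    if not math.isfinite(worst) or worst <= 0:
        return 1000.0
    return min(1000.0, -10.0 * math.log10(worst))


def write_peaks(peaks: pd.DataFrame, path) -> None:
    """Write per-nucleosome peak calls as BED6 + statistics columns.

    One row per nucleosome-mark call, ordered by (chrom, start, mark).
    Floats are written with ``repr`` so a read-back round-trips exactly;
    missing statistics (shape-rejected candidates) are written as NA.
    """
    cols = PEAK_COLUMNS
    out = peaks.sort_values(["chrom", "start", "mark"], kind="stable")
    header = (
        "#chrom\tstart\tend\tname\tscore\tstrand\t"
        + "\t".join(cols[5:])
    )

    def fmt(x) -> str:
        if isinstance(x, (float, np.floating)):
            x = float(x)  # numpy reprs don't round-trip through read_csv
            return "NA" if math.isnan(x) else repr(x)
        return str(x)

    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in out.itertuples(index=False):
            d = row._asdict()
            p_l = d["p_local"] if math.isfinite(d["p_local"]) else 1.0
            p_i = d["p_input"] if math.isfinite(d["p_input"]) else 1.0
            score = peak_score(p_l, p_i)
            fields = [
                d["chrom"], str(d["start"]), str(d["end"]),
                f"{d['mark']}:{d['nucleosome_id']}",
                repr(round(score, 4)), ".",
            ] + [fmt(d[c]) for c in cols[5:]]
            fh.write("\t".join(fields) + "\n")


def read_peaks(path) -> pd.DataFrame:
    """Read a peak file written by :func:`write_peaks`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if len(df.columns) and df.columns[0].startswith("#"):
        df = df.rename(columns={df.columns[0]: "chrom"})
    if len(df) == 0:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    if "name" in df.columns:
        split = df["name"].str.rsplit(":", n=1, expand=True)
        df["mark"] = split[0]
        df["nucleosome_id"] = split[1].astype(np.int64)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: peak file missing columns {missing}")
    df["reject_reason"] = df["reject_reason"].fillna("").astype(str)
    return df[PEAK_COLUMNS].reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as TSV (used for verdicts, occupancy, codes)."""
    df.to_csv(path, sep="\t", index=False)
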