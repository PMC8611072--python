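"""Readers and writers for every on-disk format the pipeline touches.

Coordinate convention is BED throughout: half-open, 0-based.  A motif hit
whose midpoint equals an interval's ``end`` does *not* overlap it.

Tables are written as TSV with '.' decimal separator.  Floats are printed
with 12 significant digits, positional notation down to 1e-4 and scientific
below that, so a write/read round trip is lossless at the printed precision
and diffs between runs are stable.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "TimeCourseMatrix",
    "MotifHitTable",
    "format_value",
    "read_hotspots_bed",
    "read_tss_bed",
    "read_matrix_with_samples",
    "read_fimo_hits",
    "write_table",
    "write_network",
    "write_outputs",
    "sha256_file",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in BED convention (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for interval {self.id!r}")
        if self.start >= self.end:
            raise ValueError(
                f"start >= end for interval {self.id!r} "
                f"({self.chrom}:{self.start}-{self.end})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class TimeCourseMatrix:
    """Features x samples matrix of signal with sample -> (donor, day) metadata.

    Columns are reordered on construction to (day, donor, sample_id) so every
    downstream computation sees a canonical sample order.

    Parameters
    ----------
    values
        features x samples DataFrame; index = feature ids, columns = sample ids.
    samples
        DataFrame indexed by sample_id with columns ``donor`` and ``day``.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        samples = samples.copy()
        if samples.index.has_duplicates:
            dups = samples.index[samples.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in sheet: {dups}")
        missing = [c for c in values.columns if c not in samples.index]
        if missing:
            raise ValueError(f"matrix columns missing from sample sheet: {missing}")
        samples = samples.loc[list(values.columns)]
        if (samples["day"] < 0).any():
            raise ValueError("negative day in sample sheet")
        if samples["day"].nunique() < 2:
            raise ValueError("sample sheet must span at least 2 distinct days")
        order = samples.sort_values(
            ["day", "donor"], kind="stable"
        ).index.tolist()
        self.values = values[order].astype(float)
        self.samples = samples.loc[order]
        if self.values.isna().any().any():
            raise ValueError("missing values in matrix")

    # -- convenience -------------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def days(self) -> np.ndarray:
        """Day of each sample column, in column order."""
        return self.samples["day"].to_numpy()

    @property
    def unique_days(self) -> np.ndarray:
        return np.unique(self.days)

    def day_means(self) -> pd.DataFrame:
        """Per-day replicate means (features x sorted unique days)."""
        return self.values.T.groupby(self.days).mean().T

    def subset(self, feature_ids: Sequence[str]) -> "TimeCourseMatrix":
        return TimeCourseMatrix(self.values.loc[list(feature_ids)], self.samples)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TimeCourseMatrix({self.values.shape[0]} features x "
            f"{self.values.shape[1]} samples, days {self.unique_days.min()}"
            f"..{self.unique_days.max()})"
        )


@dataclass
class MotifHitTable:
    """Aggregated motif hit counts per (dhs_id, tf_name).

    ``table`` has columns [dhs_id, tf_name, hit_count] with one row per pair;
    ``n_unmapped`` counts scanned hits whose midpoint fell in no interval.
    """

    table: pd.DataFrame
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        t = self.table
        expected = ["dhs_id", "tf_name", "hit_count"]
        if list(t.columns) != expected:
            raise ValueError(f"motif table columns must be {expected}")
        if (t["hit_count"] < 0).any():
            raise ValueError("negative hit_count")
        if t.duplicated(["dhs_id", "tf_name"]).any():
            raise ValueError("duplicate (dhs_id, tf_name) after aggregation")

    def tf_names(self) -> list[str]:
        return sorted(self.table["tf_name"].unique())

    def to_wide(
        self, dhs_ids: Sequence[str], tf_names: Sequence[str] | None = None
    ) -> pd.DataFrame:
        """Dense DHS x TF count matrix over the requested ids (absent = 0)."""
        if tf_names is None:
            tf_names = self.tf_names()
        wide = self.table.pivot(
            index="dhs_id", columns="tf_name", values="hit_count"
        )
        wide = wide.reindex(index=list(dhs_ids), columns=list(tf_names))
        return wide.fillna(0.0).astype(float)


# ---------------------------------------------------------------------------
# number formatting
# ---------------------------------------------------------------------------

def format_value(x) -> str:
    """Render a value for TSV output: 12 significant digits, '.' decimal,
    positional notation for magnitudes >= 1e-4, scientific below."""
    if isinstance(x, (bool, np.bool_)):
        return "True" if x else "False"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return "NA"
        if x == 0:
            return "0"
        if 1e-4 <= abs(x) < 1e16:
            return np.format_float_positional(
                float(x), precision=12, unique=False, fractional=False, trim="-"
            )
        return np.format_float_scientific(
            float(x), precision=11, unique=False, trim="-"
        )
    return str(x)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write a DataFrame as deterministic TSV using :func:`format_value`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.reset_index() if index else df
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, out.columns)) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(format_value(v) for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_hotspots_bed(path: str | Path) -> list[GenomicInterval]:
    """Read DHS hotspot intervals from a BED3+ file.

    The optional 4th column is used as the interval id, otherwise
    ``chrom:start-end``.  Rows with identical coordinates are collapsed; the
    number collapsed is reported with a warning.
    """
    intervals: dict[tuple[str, int, int], GenomicInterval] = {}
    ids_seen: set[str] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({line!r})")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            key = (chrom, start, end)
            if key in intervals:
                n_dup += 1
                continue
            iv_id = parts[3] if len(parts) >= 4 and parts[3] else f"{chrom}:{start}-{end}"
            if iv_id in ids_seen:
                raise ValueError(f"{path}:{lineno}: duplicate interval id {iv_id!r}")
            ids_seen.add(iv_id)
            intervals[key] = GenomicInterval(chrom, start, end, iv_id)
    if n_dup:
        warnings.warn(f"{path}: collapsed {n_dup} duplicate interval(s)")
    return sorted(intervals.values(), key=lambda iv: (iv.chrom, iv.start, iv.end))


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read a gene TSS annotation from BED (chrom, tss, tss+1, gene_id, [score], strand).

    Multi-TSS genes are canonicalized to the strand-aware most-upstream TSS
    (smallest coordinate on '+', largest on '-').
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: TSS BED needs >=4 columns")
            chrom, start = parts[0], int(parts[1])
            gene_id = parts[3]
            strand = parts[5] if len(parts) >= 6 else "+"
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: strand must be + or -")
            rows.append((gene_id, chrom, start, strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    picked = []
    for gid, grp in df.groupby("gene_id", sort=True):
        strand = grp["strand"].iloc[0]
        tss = grp["tss"].min() if strand == "+" else grp["tss"].max()
        picked.append((gid, grp["chrom"].iloc[0], int(tss), strand))
    return pd.DataFrame(picked, columns=["gene_id", "chrom", "tss", "strand"])


def read_matrix_with_samples(
    matrix_path: str | Path, sheet_path: str | Path
) -> TimeCourseMatrix:
    """Read a features x samples TSV plus its sample sheet.

    The sheet is TSV with header ``sample_id  donor  day``.  Any matrix
    column without a sheet row, or any non-numeric/missing cell, is an error
    naming the offender.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    sheet = pd.read_csv(sheet_path, sep="\t", dtype={"sample_id": str, "donor": str})
    for col in ("sample_id", "donor", "day"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    sheet = sheet.set_index("sample_id")
    orphans = [c for c in mat.columns if c not in sheet.index]
    if orphans:
        raise ValueError(f"samples without sheet row: {orphans}")
    values = pd.DataFrame(index=mat.index, columns=mat.columns, dtype=float)
    for col in mat.columns:
        converted = pd.to_numeric(mat[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            feat = mat.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric cell at (feature={feat!r}, sample={col!r}): "
                f"{mat.loc[feat, col]!r}"
            )
        values[col] = converted
    return TimeCourseMatrix(values, sheet)


_FIMO_REQUIRED = {"sequence_name", "start", "stop"}


def read_fimo_hits(
    path: str | Path, intervals: Iterable[GenomicInterval]
) -> MotifHitTable:
    """Read a motif-hit table and aggregate counts per (dhs_id, tf_name).

    Two dialects are accepted:

    * pre-intersected TSV with columns ``dhs_id``, ``tf_name`` and optional
      ``hit_count`` (missing count = 1 per row);
    * FIMO TSV with genomic coordinates (``motif_id``, ``sequence_name``,
      ``start``, ``stop``, 1-based inclusive), assigned to intervals by the
      motif-midpoint-in-interval rule; hits mapping to no interval are
      dropped and counted in ``n_unmapped``.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return MotifHitTable(
            pd.DataFrame(columns=["dhs_id", "tf_name", "hit_count"]), 0
        )
    if df.empty and df.columns.size == 0:
        return MotifHitTable(
            pd.DataFrame(columns=["dhs_id", "tf_name", "hit_count"]), 0
        )
    cols = set(df.columns)
    if {"dhs_id", "tf_name"} <= cols:
        if "hit_count" not in cols:
            df = df.assign(hit_count=1)
        agg = (
            df.groupby(["dhs_id", "tf_name"], as_index=False)["hit_count"]
            .sum()
            .sort_values(["dhs_id", "tf_name"], kind="stable")
            .reset_index(drop=True)
        )
        return MotifHitTable(agg.astype({"hit_count": int}), 0)
    if _FIMO_REQUIRED <= cols and ("motif_id" in cols or "motif_alt_id" in cols):
        trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.id)
        tf_col = "motif_id" if "motif_id" in cols else "motif_alt_id"
        records: list[tuple[str, str]] = []
        n_unmapped = 0
        for tf, chrom, start, stop in zip(
            df[tf_col], df["sequence_name"], df["start"], df["stop"]
        ):
            # FIMO prints 1-based inclusive coordinates
            mid = (int(start) - 1 + int(stop)) // 2
            tree = trees.get(str(chrom))
            hits = tree[mid] if tree is not None else set()
            if not hits:
                n_unmapped += 1
                continue
            for h in hits:
                records.append((h.data, str(tf)))
        if not records:
            return MotifHitTable(
                pd.DataFrame(columns=["dhs_id", "tf_name", "hit_count"]), n_unmapped
            )
        long = pd.DataFrame(records, columns=["dhs_id", "tf_name"])
        agg = (
            long.groupby(["dhs_id", "tf_name"], as_index=False)
            .size()
            .rename(columns={"size": "hit_count"})
            .sort_values(["dhs_id", "tf_name"], kind="stable")
            .reset_index(drop=True)
        )
        return MotifHitTable(agg, n_unmapped)
    raise ValueError(
        "unknown motif table dialect: expected columns (dhs_id, tf_name[, "
        "hit_count]) or FIMO columns (motif_id, sequence_name, start, stop); "
        f"got {sorted(cols)}"
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_network(graph, out_prefix: str | Path) -> list[Path]:
    """Write a TF->gene network as edge-list TSV and GraphML."""
    import networkx as nx

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for u, v, data in sorted(graph.edges(data=True)):
        rows.append(
            {
                "tf": u,
                "gene": v,
                "raw_weight": data.get("raw_weight", np.nan),
                "std_weight": data.get("std_weight", np.nan),
                "via_dhs": ",".join(sorted(data.get("via_dhs", ()))),
            }
        )
    edge_df = pd.DataFrame(
        rows, columns=["tf", "gene", "raw_weight", "std_weight", "via_dhs"]
    )
    tsv = write_table(edge_df, out_prefix.with_suffix(".edges.tsv"))
    g2 = nx.DiGraph()
    for n, data in graph.nodes(data=True):
        g2.add_node(n, **{k: str(v) for k, v in data.items()})
    for u, v, data in graph.edges(data=True):
        g2.add_edge(
            u,
            v,
            raw_weight=float(data.get("raw_weight", 0.0)),
            std_weight=float(data.get("std_weight", 0.0)),
            via_dhs=",".join(sorted(data.get("via_dhs", ()))),
        )
    gml = out_prefix.with_suffix(".graphml")
    nx.write_graphml(g2, gml)
    return [tsv, gml]


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    results: dict,
    out_dir: str | Path,
    parameters: dict | None = None,
    seed: int | None = None,
    input_checksums: dict | None = None,
) -> dict:
    """Write a dict of stage results and a JSON manifest.

    Recognized keys map to writers: any pandas DataFrame is written as
    ``<key>.tsv``; a networkx graph as ``<key>.edges.tsv`` + ``<key>.graphml``;
    a plain dict as ``<key>.json``.  The manifest records the package
    version, seed, parameters, input checksums and a checksum per output
    file; it contains no timestamps so reruns are byte-identical.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for key in sorted(results):
        obj = results[key]
        if obj is None:
            continue
        if isinstance(obj, pd.DataFrame):
            p = write_table(obj, out_dir / f"{key}.tsv")
            files[p.name] = sha256_file(p)
        elif isinstance(obj, dict):
            p = out_dir / f"{key}.json"
            with open(p, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
            files[p.name] = sha256_file(p)
        else:  # assume graph
            for p in write_network(obj, out_dir / key):
                files[p.name] = sha256_file(p)
    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": parameters or {},
        "inputs": input_checksums or {},
        "files": files,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    return manifest


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
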