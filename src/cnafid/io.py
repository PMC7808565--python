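"""Readers and writers for the standard input formats.

Supported formats: SEG-like segment tables (tab-delimited, header,
1-based inclusive by default), sample-metadata TSV, gene models as BED6 or
a minimal GTF subset, GMT gene sets, and dense expression TSV. All readers
normalize to the internal conventions (0-based half-open coordinates,
"chr"-less chromosome names, Y/MT dropped).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleRecord,
    SegmentProfile,
    normalize_chrom,
    validate_gene_table,
)

PathLike = Union[str, Path]

# Accepted header aliases for SEG-like tables (case-insensitive).
_SEG_ALIASES = {
    "sample": {"sample", "id", "sample_id", "sampleid"},
    "chrom": {"chrom", "chromosome", "chr"},
    "start": {"start", "loc.start", "loc_start"},
    "end": {"end", "loc.end", "loc_end"},
    "n_probes": {"n_probes", "num.mark", "num_mark", "num_probes", "probes"},
    "log2_ratio": {"log2_ratio", "seg.mean", "seg_mean", "segmean", "log2ratio"},
}


def _map_seg_columns(columns: list[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for col in columns:
        key = col.strip().lower()
        for canonical, aliases in _SEG_ALIASES.items():
            if key in aliases and canonical not in out:
                out[canonical] = col
    required = ("sample", "chrom", "start", "end", "log2_ratio")
    missing = [c for c in required if c not in out]
    if missing:
        raise ValueError(f"SEG header missing columns for {missing}; got {columns}")
    return out


def read_segments(
    path: PathLike,
    dialect: str = "seg1",
    genome_build: str = "GRCh38",
) -> list[SegmentProfile]:
    """Read a SEG-like table into one profile per sample.

    Parameters
    ----------
    dialect : {"seg1", "bed0"}
        ``seg1`` — 1-based inclusive coordinates (the common SEG dialect,
        default); ``bed0`` — already 0-based half-open.

    Rows on chromosomes outside the supported set (autosomes + X) are
    skipped with a single warning carrying the count; a malformed row
    raises an error naming its line number.
    """
    if dialect not in ("seg1", "bed0"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    colmap = _map_seg_columns(list(df.columns))
    out = pd.DataFrame(
        {
            "sample": df[colmap["sample"]].astype(str),
            "chrom": df[colmap["chrom"]],
            "start": pd.to_numeric(df[colmap["start"]], errors="coerce"),
            "end": pd.to_numeric(df[colmap["end"]], errors="coerce"),
            "log2_ratio": pd.to_numeric(df[colmap["log2_ratio"]], errors="coerce"),
        }
    )
    if "n_probes" in colmap:
        out["n_probes"] = pd.to_numeric(df[colmap["n_probes"]], errors="coerce").astype("Int64")
    else:
        out["n_probes"] = pd.array([pd.NA] * len(out), dtype="Int64")

    bad = out[["start", "end", "log2_ratio"]].isna().any(axis=1)
    if bad.any():
        # +2: one for the header line, one for 1-based line numbering.
        line = int(np.argmax(bad.to_numpy())) + 2
        raise ValueError(f"{path}: malformed row at line {line}")

    out["chrom"] = out["chrom"].map(normalize_chrom)
    n_skipped = int(out["chrom"].isna().sum())
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} rows on unsupported chromosomes", stacklevel=2)
        out = out.dropna(subset=["chrom"])

    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if dialect == "seg1":
        out["start"] = out["start"] - 1

    profiles = []
    for sample, sub in out.groupby("sample", sort=False):
        profiles.append(
            SegmentProfile(str(sample), sub.drop(columns="sample"), genome_build=genome_build)
        )
    return profiles


def write_segments(profiles: list[SegmentProfile], path: PathLike, dialect: str = "seg1") -> None:
    """Write profiles as a canonical SEG-like TSV (byte-stable)."""
    if dialect not in ("seg1", "bed0"):
        raise ValueError(f"unknown dialect {dialect!r}")
    off = 1 if dialect == "seg1" else 0
    lines = ["sample\tchrom\tstart\tend\tnum_probes\tseg_mean"]
    for p in profiles:
        for row in p.segments.itertuples(index=False):
            probes = "" if pd.isna(row.n_probes) else str(int(row.n_probes))
            lines.append(
                f"{p.sample_id}\t{row.chrom}\t{row.start + off}\t{row.end}\t"
                f"{probes}\t{row.log2_ratio!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


_META_REQUIRED = ["sample_id", "model_id", "patient_id", "tumor_type", "center", "sample_class", "platform"]


def read_metadata(path: PathLike) -> list[SampleRecord]:
    """Read the sample-metadata TSV into validated records.

    PDX rows with an empty passage are retained but flagged
    ``excluded_from_pairing`` (they never enter pair enumeration).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        passage = getattr(row, "passage", None)
        passage = None if passage is None or pd.isna(passage) or passage == "" else int(float(passage))
        lineage = getattr(row, "lineage_id", None)
        lineage = None if lineage is None or pd.isna(lineage) or lineage == "" else str(lineage)
        calibration = getattr(row, "calibration", "NA")
        calibration = "NA" if calibration is None or pd.isna(calibration) or calibration == "" else calibration
        try:
            rec = SampleRecord(
                sample_id=row.sample_id,
                model_id=row.model_id,
                patient_id=row.patient_id,
                tumor_type=row.tumor_type,
                center=row.center,
                sample_class=row.sample_class,
                passage=passage,
                lineage_id=lineage,
                platform=row.platform,
                calibration=calibration,
            )
        except ValueError as exc:
            raise ValueError(f"{path}: invalid record {row.sample_id!r}: {exc}") from exc
        records.append(rec)
    return records


def write_metadata(records: list[SampleRecord], path: PathLike) -> None:
    cols = list(dict.fromkeys(_META_REQUIRED + ["passage", "lineage_id", "calibration"]))
    lines = ["\t".join(cols)]
    for r in records:
        vals = {
            "sample_id": r.sample_id,
            "model_id": r.model_id,
            "patient_id": r.patient_id,
            "tumor_type": r.tumor_type,
            "center": r.center,
            "sample_class": r.sample_class.value,
            "platform": r.platform.value,
            "passage": "" if r.passage is None else str(r.passage),
            "lineage_id": "" if r.lineage_id is None else r.lineage_id,
            "calibration": r.calibration.value,
        }
        lines.append("\t".join(vals[c] for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models(path: PathLike, fmt: Optional[str] = None) -> pd.DataFrame:
    """Read gene models from BED6 or a minimal GTF subset.

    Only gene-level GTF records are used. Returns the canonical gene table
    (``gene_id, symbol, chrom, start, end, biotype``), 0-based half-open.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"
    if fmt == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            usecols=range(6), dtype=str,
        )
        genes = pd.DataFrame(
            {
                "gene_id": df["gene_id"],
                "symbol": df["gene_id"],
                "chrom": df["chrom"],
                "start": df["start"].astype(np.int64),
                "end": df["end"].astype(np.int64),
                "biotype": "protein_coding",
            }
        )
    elif fmt == "gtf":
        rows = []
        for ln in Path(path).read_text().splitlines():
            if not ln or ln.startswith("#"):
                continue
            f = ln.split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = {}
            for part in f[8].strip().strip(";").split(";"):
                part = part.strip()
                if not part:
                    continue
                k, _, v = part.partition(" ")
                attrs[k] = v.strip().strip('"')
            rows.append(
                {
                    "gene_id": attrs.get("gene_id", ""),
                    "symbol": attrs.get("gene_name", attrs.get("gene_id", "")),
                    "chrom": f[0],
                    "start": int(f[3]) - 1,  # GTF is 1-based inclusive
                    "end": int(f[4]),
                    "biotype": attrs.get("gene_biotype", "protein_coding"),
                }
            )
        genes = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown gene-model format {fmt!r}")
    return validate_gene_table(genes)


def read_gene_sets(
    path: PathLike, categories: Optional[dict[str, str]] = None
) -> GeneSetCollection:
    """Read a standard GMT file (name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT line {i}: set {fields[0]!r} is empty")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}: duplicate set name {name!r}")
        members = frozenset(m for m in fields[2:] if m)
        if not members:
            raise ValueError(f"{path}: GMT line {i}: set {name!r} is empty")
        sets[name] = members
    cats = {name: (categories or {}).get(name, "uncategorized") for name in sets}
    return GeneSetCollection(sets=sets, categories=cats)


def write_gene_sets(collection: GeneSetCollection, path: PathLike) -> None:
    lines = []
    for name, members in collection.sets.items():
        cat = collection.categories.get(name, "uncategorized")
        lines.append("\t".join([name, cat] + sorted(members)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(
    values_path: PathLike,
    feature_info_path: PathLike,
    sample_class_path: PathLike,
    unit: str = "TPM",
) -> ExpressionMatrix:
    """Read a dense expression TSV plus feature-position and class tables.

    ``values`` — features x samples, first column the feature id;
    ``feature_info`` — feature_id, gene_id, chrom, start, end;
    ``sample_class`` — sample_id, class (tumor/normal).
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    info = pd.read_csv(feature_info_path, sep="\t", index_col=0, dtype={"chrom": str})
    cls = pd.read_csv(sample_class_path, sep="\t", index_col=0)["class"]
    return ExpressionMatrix(values=values, feature_info=info, sample_class=cls, unit=unit)
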