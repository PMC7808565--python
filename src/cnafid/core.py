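"""Core domain types shared across the pipeline.

The universal currency is the :class:`SegmentProfile`: one sample's
genome-wide copy-number segments carrying log2[copy-number ratio] values
(log2 of total copy number over the sample baseline; 0 = neutral).
Coordinates are 0-based half-open throughout the package; chromosome names
are "chr"-less tokens ("1".."22", "X").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import numpy as np
import pandas as pd

#: Canonical chromosome order. The mitochondrial contig and Y are dropped on
#: input; X is retained for DNA profiles (it enters pairwise correlations by
#: default) but excluded from expression-based inference.
CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)

_CHROM_RANK: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}


def normalize_chrom(token: str) -> Optional[str]:
    """Map a chromosome token to the internal convention.

    Returns ``None`` for contigs the pipeline drops (Y, MT, unplaced).
    """
    t = str(token).strip()
    if t.lower().startswith("chr"):
        t = t[3:]
    if t == "23":
        t = "X"
    return t if t in _CHROM_RANK else None


def chrom_sort_key(chrom: str) -> int:
    return _CHROM_RANK[chrom]


class SampleClass(str, Enum):
    PT = "PT"
    PDX = "PDX"
    NORMAL = "NORMAL"


class Platform(str, Enum):
    SNP = "SNP"
    WES = "WES"
    WGS = "WGS"
    RNASEQ = "RNASEQ"
    EXPARR = "EXPARR"


class Calibration(str, Enum):
    NORM = "NORM"
    TUM = "TUM"
    NA = "NA"


SEGMENT_COLUMNS = ["chrom", "start", "end", "log2_ratio", "n_probes"]


@dataclass
class SegmentProfile:
    """One sample's copy-number segments.

    Parameters
    ----------
    sample_id : str
    segments : pandas.DataFrame
        Columns ``chrom, start, end, log2_ratio, n_probes`` (``n_probes``
        nullable). Sorted by (chromosome, start); non-overlapping within a
        chromosome; 0-based half-open.
    genome_build : str
    """

    sample_id: str
    segments: pd.DataFrame
    genome_build: str = "GRCh38"

    def __post_init__(self) -> None:
        df = self.segments
        if df.empty:
            df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
                SEGMENT_COLUMNS, [str, np.int64, np.int64, float, "Int64"])})
        missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"segment table missing columns {missing}")
        df = df[SEGMENT_COLUMNS].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["log2_ratio"] = df["log2_ratio"].astype(float)
        df["n_probes"] = df["n_probes"].astype("Int64")
        order = df["chrom"].map(_CHROM_RANK)
        if order.isna().any():
            bad = df.loc[order.isna(), "chrom"].unique()
            raise ValueError(f"unknown chromosomes in profile {self.sample_id}: {list(bad)}")
        df = df.sort_values(["chrom", "start"], key=lambda s: s.map(_CHROM_RANK) if s.name == "chrom" else s)
        df = df.reset_index(drop=True)
        self.segments = df
        self.validate()

    def validate(self) -> None:
        df = self.segments
        if (df["start"] >= df["end"]).any():
            i = int(np.argmax((df["start"] >= df["end"]).to_numpy()))
            raise ValueError(
                f"profile {self.sample_id}: segment {i} has start >= end "
                f"({df['start'].iat[i]} >= {df['end'].iat[i]})"
            )
        if not np.isfinite(df["log2_ratio"]).all():
            raise ValueError(f"profile {self.sample_id}: non-finite log2_ratio")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(
                    f"profile {self.sample_id}: overlapping segments on chromosome {chrom}"
                )

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def chroms(self) -> list[str]:
        return sorted(self.segments["chrom"].unique(), key=chrom_sort_key)

    def shifted(self, delta: float) -> "SegmentProfile":
        """Return a copy with ``delta`` added to every log2 ratio."""
        df = self.segments.copy()
        df["log2_ratio"] = df["log2_ratio"] + delta
        return SegmentProfile(self.sample_id, df, self.genome_build)

    def copy(self) -> "SegmentProfile":
        return SegmentProfile(self.sample_id, self.segments.copy(), self.genome_build)


@dataclass
class SampleRecord:
    """Provenance of a sample, driving pair enumeration and classification."""

    sample_id: str
    model_id: str
    patient_id: str
    tumor_type: str
    center: str
    sample_class: SampleClass
    passage: Optional[int] = None
    lineage_id: Optional[str] = None
    platform: Platform = Platform.SNP
    calibration: Calibration = Calibration.NA
    excluded_from_pairing: bool = False

    def __post_init__(self) -> None:
        self.sample_class = SampleClass(self.sample_class)
        self.platform = Platform(self.platform)
        self.calibration = Calibration(self.calibration)
        if self.passage is not None and self.passage < 0:
            raise ValueError(f"{self.sample_id}: negative passage")
        if self.sample_class is SampleClass.PDX and self.passage is None:
            # PDX samples without passage information are omitted downstream.
            self.excluded_from_pairing = True
        if self.sample_class is not SampleClass.PDX and self.passage is not None:
            warnings.warn(
                f"{self.sample_id}: passage given for non-PDX sample; ignored",
                stacklevel=2,
            )
            self.passage = None


GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "biotype"]


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a gene-model table (Ensembl-style)."""
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns {missing}")
    df = genes[GENE_COLUMNS].copy()
    df["chrom"] = df["chrom"].map(lambda c: normalize_chrom(c))
    df = df.dropna(subset=["chrom"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene table: start >= end")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"gene table: duplicate gene_id {dup!r}")
    df = df.sort_values(["chrom", "start"], key=lambda s: s.map(_CHROM_RANK) if s.name == "chrom" else s)
    return df.reset_index(drop=True)


@dataclass
class GeneSetCollection:
    """Named gene sets with a per-set category tag."""

    sets: dict[str, frozenset[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def resolve(self, genes: pd.DataFrame) -> pd.DataFrame:
        """Report members unresolvable against a gene table.

        Unresolved identifiers are reported, never silently dropped: each
        row carries the set name, its size and the unresolved members.
        """
        known = set(genes["gene_id"]) | set(genes["symbol"])
        rows = []
        for name, members in self.sets.items():
            unresolved = sorted(m for m in members if m not in known)
            rows.append(
                {
                    "set_name": name,
                    "size": len(members),
                    "n_unresolved": len(unresolved),
                    "unresolved": ",".join(unresolved),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ExpressionMatrix:
    """Feature x sample expression table with positions and sample classes.

    ``values`` rows are transcripts or probesets (index = feature id);
    ``feature_info`` maps feature id -> (gene_id, chrom, start, end);
    ``sample_class`` maps sample -> "tumor" | "normal". ``unit`` is
    ``"TPM"`` (linear) or ``"log2"`` (array intensities).
    """

    values: pd.DataFrame
    feature_info: pd.DataFrame
    sample_class: pd.Series
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "log2"):
            raise ValueError(f"unknown expression unit {self.unit!r}")
        if self.unit == "TPM" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative TPM values")
        if not self.values.index.equals(self.feature_info.index):
            missing = self.values.index.difference(self.feature_info.index)
            if len(missing):
                raise ValueError(f"features lacking positions: {list(missing[:5])}")
            self.feature_info = self.feature_info.loc[self.values.index]
        unknown = set(self.sample_class.unique()) - {"tumor", "normal"}
        if unknown:
            raise ValueError(f"unknown sample classes {unknown}")

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.sample_class[self.sample_class == "tumor"].index)

    @property
    def normal_samples(self) -> list[str]:
        return list(self.sample_class[self.sample_class == "normal"].index)


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "model_id": r.model_id,
                "patient_id": r.patient_id,
                "tumor_type": r.tumor_type,
                "center": r.center,
                "sample_class": r.sample_class.value,
                "passage": r.passage,
                "lineage_id": r.lineage_id,
                "platform": r.platform.value,
                "calibration": r.calibration.value,
                "excluded_from_pairing": r.excluded_from_pairing,
            }
        )
    return pd.DataFrame(rows)
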