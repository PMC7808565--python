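"""Expression-based copy-number inference (e-karyotyping).

Chromosomal copy number leaves a dosage footprint in gene expression along
genomic coordinates. The pipeline here: (1) clean an expression matrix
(floor low values, collapse transcripts/probesets, drop the most variable
genes, drop sex chromosomes); (2) express each tumor sample relative to a
calibration median (matched normals, or the tumor cohort itself for
tumor-only datasets); (3) segment the position-ordered relative values per
chromosome with an exact penalized piecewise-constant fit (PCF) and call
gains/losses; (4) bridge the calls back into genomic segments consumable
by the DNA-side comparison machinery.

The PCF objective is classical least squares with a per-breakpoint
penalty, solved exactly by dynamic programming. The external tool the
protocol descends from does not publish its internal variant; the
parameter mapping used here (penalty on MAD-standardized values, minimum
aberration size as a *call* requirement, threshold as a per-segment
significance level) is an approximation and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import CHROMOSOMES, ExpressionMatrix, SegmentProfile, chrom_sort_key

SEX_CHROMOSOMES = {"X", "Y"}


@dataclass
class EKaryoConfig:
    """Expression preprocessing parameters.

    ``floor`` is 1 (TPM, linear) for RNA-seq or a log2 intensity of 6 for
    arrays; genes below the floor in more than ``max_below_floor_fraction``
    of samples are removed, remaining sub-floor values are raised to the
    floor. The ``top_variable_fraction`` most variable genes (sum of squared
    deviations from the gene's cross-sample median) are removed because
    expression variability unrelated to dosage masquerades as CNA.
    """

    floor: float = 1.0
    max_below_floor_fraction: float = 0.20
    top_variable_fraction: float = 0.10
    calibration: str = "NORM"  # NORM: subtract normal medians; TUM: tumor medians
    drop_sex_chromosomes: bool = True

    def __post_init__(self) -> None:
        for f in (self.max_below_floor_fraction, self.top_variable_fraction):
            if not 0 < f < 1:
                raise ValueError("fractions must be in (0, 1)")
        if self.calibration not in ("NORM", "TUM"):
            raise ValueError(f"unknown calibration {self.calibration!r}")

    @classmethod
    def rnaseq(cls, calibration: str = "NORM") -> "EKaryoConfig":
        return cls(floor=1.0, calibration=calibration)

    @classmethod
    def array(cls, calibration: str = "NORM") -> "EKaryoConfig":
        return cls(floor=6.0, calibration=calibration)


@dataclass
class PCFParams:
    penalty: float = 12.0
    winsorize_q: float = 0.001
    min_aberration_size: int = 30  # genes
    min_deviation: float = 0.25  # log2 units
    call_threshold: float = 0.01  # two-sided t-test level on the segment mean

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if not 0 < self.winsorize_q < 0.5:
            raise ValueError("winsorize_q must be in (0, 0.5)")


@dataclass
class RelativeExpressionProfile:
    """Position-ordered relative log2 expression for one tumor sample.

    ``data`` columns: gene_id, chrom, start, end, value — sorted by
    chromosome then start; sex chromosomes absent.
    """

    sample_id: str
    data: pd.DataFrame


@dataclass
class PCFSegment:
    chrom: str
    start_index: int  # gene-index range within the chromosome, half-open
    end_index: int
    mean: float
    call: str  # gain / loss / neutral
    n_genes: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_genes = self.end_index - self.start_index


@dataclass
class PCFResult:
    sample_id: str
    segments: list[PCFSegment]

    def breakpoints(self, chrom: str) -> list[int]:
        segs = [s for s in self.segments if s.chrom == chrom]
        return [s.start_index for s in segs[1:]]


def preprocess_expression(
    matrix: ExpressionMatrix, cfg: EKaryoConfig
) -> dict[str, RelativeExpressionProfile]:
    """Run the e-karyotyping preprocessing, returning one relative profile
    per tumor sample.

    Order of operations: sex-chromosome drop; below-floor gene removal
    (> 20% of samples) then flooring; per-gene transcript/probeset collapse
    to the highest-median feature; top-10% variable-gene removal; per-gene
    subtraction of the calibration median (normals for NORM, the tumor
    cohort itself for TUM).
    """
    tumors = matrix.tumor_samples
    normals = matrix.normal_samples
    if not tumors:
        raise ValueError("no tumor samples in expression matrix")
    if cfg.calibration == "NORM" and not normals:
        raise ValueError("NORM calibration requires at least one normal sample")

    values = matrix.values.astype(float)
    info = matrix.feature_info

    if cfg.drop_sex_chromosomes:
        keep = ~info["chrom"].astype(str).isin(SEX_CHROMOSOMES)
        values, info = values.loc[keep.to_numpy()], info.loc[keep.to_numpy()]

    below = values < cfg.floor
    keep = below.mean(axis=1) <= cfg.max_below_floor_fraction
    values, info = values[keep], info[keep]
    values = values.clip(lower=cfg.floor)

    if matrix.unit == "TPM":
        values = np.log2(values)

    # collapse features to one per gene: highest median across the dataset
    med = values.median(axis=1)
    order = med.sort_values(ascending=False).index
    first = ~info.loc[order, "gene_id"].duplicated()
    chosen = order[first.to_numpy()]
    values, info = values.loc[chosen], info.loc[chosen]

    # drop the most variable genes (sum of squares around the gene median)
    ss = ((values.sub(values.median(axis=1), axis=0)) ** 2).sum(axis=1)
    n_drop = int(np.floor(cfg.top_variable_fraction * len(values)))
    if n_drop > 0:
        values = values.drop(index=ss.nlargest(n_drop).index)
        info = info.loc[values.index]

    calib_cols = normals if cfg.calibration == "NORM" else tumors
    calib_median = values[calib_cols].median(axis=1)

    base = pd.DataFrame(
        {
            "gene_id": info["gene_id"].to_numpy(),
            "chrom": info["chrom"].astype(str).to_numpy(),
            "start": info["start"].to_numpy(),
            "end": info["end"].to_numpy(),
        },
        index=values.index,
    )
    out = {}
    for s in tumors:
        df = base.copy()
        df["value"] = (values[s] - calib_median).to_numpy()
        df = df.sort_values(
            ["chrom", "start"],
            key=lambda col: col.map(chrom_sort_key) if col.name == "chrom" else col,
        ).reset_index(drop=True)
        out[s] = RelativeExpressionProfile(sample_id=s, data=df)
    return out


# ---------------------------------------------------------------------------
# penalized piecewise-constant fit


def winsorize(values: np.ndarray, q: float) -> np.ndarray:
    """Clamp values to the empirical (q, 1-q) quantiles."""
    lo, hi = np.quantile(values, [q, 1 - q])
    return np.clip(values, lo, hi)


def _segment_costs(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix sums enabling O(1) SSE of any contiguous stretch."""
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])
    return s1, s2


def _sse(s1: np.ndarray, s2: np.ndarray, i: int, j: int) -> float:
    n = j - i
    su = s1[j] - s1[i]
    return (s2[j] - s2[i]) - su * su / n


def pcf_fit(y: np.ndarray, penalty: float) -> list[tuple[int, int]]:
    """Exact minimizer of sum of within-segment SSE + penalty per breakpoint.

    Optimal-partitioning dynamic program, O(n^2); returns half-open
    (start, end) index ranges. The first segment carries no penalty.
    """
    n = len(y)
    if n == 0:
        return []
    s1, s2 = _segment_costs(y)
    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = -penalty  # first segment free
    # vectorized over candidate segment starts i for each end j
    su = s1
    for j in range(1, n + 1):
        i = np.arange(j)
        seg_n = j - i
        seg_sum = su[j] - su[i]
        sse = (s2[j] - s2[i]) - seg_sum * seg_sum / seg_n
        cand = best[:j] + sse + penalty
        k = int(np.argmin(cand))
        best[j] = cand[k]
        prev[j] = k
    cuts = [n]
    while cuts[-1] > 0:
        cuts.append(int(prev[cuts[-1]]))
    cuts = cuts[::-1]
    return list(zip(cuts[:-1], cuts[1:]))


def pcf_fit_bruteforce(y: np.ndarray, penalty: float) -> list[tuple[int, int]]:
    """Exhaustive search over all segmentations (oracle; n <= ~15)."""
    import itertools

    n = len(y)
    s1, s2 = _segment_costs(y)
    best_cost, best_segs = np.inf, [(0, n)]
    positions = list(range(1, n))
    for k in range(0, n):
        for cuts in itertools.combinations(positions, k):
            bounds = [0, *cuts, n]
            segs = list(zip(bounds[:-1], bounds[1:]))
            cost = sum(_sse(s1, s2, i, j) for i, j in segs) + penalty * k
            if cost < best_cost - 1e-12:
                best_cost, best_segs = cost, segs
    return best_segs


def pcf_segment(profile: RelativeExpressionProfile, params: Optional[PCFParams] = None) -> PCFResult:
    """Segment a relative expression profile chromosome by chromosome.

    Values are winsorized, standardized by a robust scale (1.4826 x MAD of
    the whole profile) for breakpoint placement so the penalty is
    comparable across samples, then segment means are reported on the
    original scale. A segment is called gain/loss when it has at least
    ``min_aberration_size`` genes, |mean| >= ``min_deviation`` and its mean
    differs from zero at the ``call_threshold`` level (two-sided t-test).
    """
    params = params or PCFParams()
    df = profile.data
    all_vals = winsorize(df["value"].to_numpy(dtype=float), params.winsorize_q)
    mad = np.median(np.abs(all_vals - np.median(all_vals)))
    scale = 1.4826 * mad
    if scale < 1e-9:
        sd = float(np.std(all_vals))
        scale = sd if sd > 1e-9 else 1.0

    segments: list[PCFSegment] = []
    offset = 0
    for chrom in sorted(df["chrom"].unique(), key=chrom_sort_key):
        sub = all_vals[df["chrom"].to_numpy() == chrom]
        n = len(sub)
        if n < 2:
            pieces = [(0, n)] if n else []
        else:
            pieces = pcf_fit(sub / scale, params.penalty)
        for i, j in pieces:
            seg_vals = sub[i:j]
            mean = float(np.mean(seg_vals))
            call = "neutral"
            if (j - i) >= params.min_aberration_size and abs(mean) >= params.min_deviation:
                if np.ptp(seg_vals) == 0:
                    p = 0.0 if mean != 0 else 1.0
                else:
                    p = float(stats.ttest_1samp(seg_vals, 0.0).pvalue)
                if p < params.call_threshold:
                    call = "gain" if mean > 0 else "loss"
            segments.append(PCFSegment(chrom=chrom, start_index=i, end_index=j, mean=mean, call=call))
        offset += n
    return PCFResult(sample_id=profile.sample_id, segments=segments)


def expression_cna_to_segments(
    pcf: PCFResult, profile: RelativeExpressionProfile
) -> SegmentProfile:
    """Bridge PCF calls into a genomic :class:`SegmentProfile`.

    Each PCF segment spans from its first gene's start to its last gene's
    end, carrying the segment mean as the log2 ratio; adjacent segments
    are clipped so they never overlap.
    """
    df = profile.data
    rows = []
    prev_end: dict[str, int] = {}
    for seg in pcf.segments:
        sub = df[df["chrom"] == seg.chrom].iloc[seg.start_index : seg.end_index]
        if sub.empty:
            continue
        start = int(sub["start"].iloc[0])
        end = int(sub["end"].max())
        start = max(start, prev_end.get(seg.chrom, -1))
        if start >= end:
            continue
        prev_end[seg.chrom] = end
        rows.append(
            {"chrom": seg.chrom, "start": start, "end": end,
             "log2_ratio": seg.mean, "n_probes": seg.n_genes}
        )
    cols = ["chrom", "start", "end", "log2_ratio", "n_probes"]
    return SegmentProfile(pcf.sample_id, pd.DataFrame(rows, columns=cols))
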