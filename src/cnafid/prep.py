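"""Segment-profile preparation.

Turns raw copy-number segments into the analysis-ready representations:
platform-aware filtering, 10-kb-window median re-centering, fixed-width
window binning, conservative gene-level copy numbers, aberration summaries
(variance and 5-95% inter-percentile range), gain/loss labels and
segment-size statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Platform, SegmentProfile

#: Minimum segment length retained on any platform (bp).
MIN_SEGMENT_BP = 1_000
#: SNP-array segments additionally require more than this many probes ...
SNP_MIN_PROBES = 10
#: ... at an average density of at least one probe per this many bp.
SNP_MAX_BP_PER_PROBE = 5_000

#: Window width used to compute the re-centering median (bp).
CENTERING_WIDTH = 10_000
#: Default analysis window width (bp).
WINDOW_WIDTH = 100_000

#: Gain/loss call threshold on centered log2 ratios (strict inequality).
GAIN_LOSS_THR = 0.1
#: Profiles with a 5-95% inter-percentile range below this are non-aberrant.
NON_ABERRANT_IPR = 0.3


@dataclass
class BinnedProfile:
    """Fixed-width window view of a segment profile.

    ``windows`` has columns ``chrom, start, value, segment_index`` where
    ``segment_index`` points back into the source profile's segment table
    (the segment with the largest overlap in that window; ties go to the
    leftmost segment). Windows with no segment overlap are absent.
    """

    sample_id: str
    width: int
    windows: pd.DataFrame

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def values(self) -> np.ndarray:
        return self.windows["value"].to_numpy()

    def keyed(self) -> pd.Series:
        """Values indexed by (chrom, window start) for cross-sample joins."""
        return self.windows.set_index(["chrom", "start"])["value"]


@dataclass
class GeneCopyProfile:
    """Per-gene log2 copy-number ratios for one sample.

    ``values`` maps gene_id -> log2 ratio (the minimum over overlapping
    segments — the most conservative estimate for the intact gene).
    """

    sample_id: str
    values: pd.Series
    floored_at_minus3: bool = False


@dataclass
class AberrationSummary:
    variance: float
    ipr_5_95: float
    n_windows: int

    @property
    def non_aberrant(self) -> bool:
        return self.ipr_5_95 < NON_ABERRANT_IPR


def filter_segments(profile: SegmentProfile, platform: Platform | str) -> SegmentProfile:
    """Remove sub-resolution segments.

    Segments shorter than 1 kb are dropped on every platform. SNP-array
    segments must additionally be covered by more than ten probes at an
    average density of at least one probe per 5 kb.
    """
    platform = Platform(platform)
    df = profile.segments
    length = (df["end"] - df["start"]).to_numpy()
    keep = length >= MIN_SEGMENT_BP
    if platform is Platform.SNP:
        if df["n_probes"].isna().any():
            raise ValueError(f"{profile.sample_id}: SNP profile lacks probe counts")
        probes = df["n_probes"].to_numpy(dtype=float)
        keep &= (probes > SNP_MIN_PROBES) & (length / probes <= SNP_MAX_BP_PER_PROBE)
    return SegmentProfile(profile.sample_id, df[keep], profile.genome_build)


def bin_profile(profile: SegmentProfile, width: int = WINDOW_WIDTH) -> BinnedProfile:
    """Bin segments into fixed-width windows.

    Each window covered by at least one segment takes the value of the
    segment with the largest overlap (ties broken toward the leftmost
    segment); uncovered windows are absent.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    chroms, starts, values, src = [], [], [], []
    df = profile.segments
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        v = sub["log2_ratio"].to_numpy()
        idx = sub.index.to_numpy()
        w_lo = int(s.min() // width)
        w_hi = int((e.max() - 1) // width)
        n = w_hi - w_lo + 1
        best_overlap = np.zeros(n, dtype=np.int64)
        win_val = np.full(n, np.nan)
        win_src = np.full(n, -1, dtype=np.int64)
        for si in range(len(s)):
            w0 = int(s[si] // width)
            w1 = int((e[si] - 1) // width)
            # Interior windows are fully covered; disjoint segments cannot
            # contest them, so assign directly.
            if w1 - w0 >= 2:
                sl = slice(w0 + 1 - w_lo, w1 - w_lo)
                best_overlap[sl] = width
                win_val[sl] = v[si]
                win_src[sl] = idx[si]
            for w in (w0, w1) if w1 > w0 else (w0,):
                ov = min(e[si], (w + 1) * width) - max(s[si], w * width)
                j = w - w_lo
                if ov > best_overlap[j]:  # strict: ties keep the leftmost
                    best_overlap[j] = ov
                    win_val[j] = v[si]
                    win_src[j] = idx[si]
        covered = best_overlap > 0
        k = int(covered.sum())
        chroms.extend([chrom] * k)
        starts.append((np.nonzero(covered)[0] + w_lo) * width)
        values.append(win_val[covered])
        src.append(win_src[covered])
    windows = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.concatenate(starts) if starts else np.array([], dtype=np.int64),
            "value": np.concatenate(values) if values else np.array([]),
            "segment_index": np.concatenate(src) if src else np.array([], dtype=np.int64),
        }
    )
    return BinnedProfile(profile.sample_id, width, windows)


def median_center(profile: SegmentProfile) -> SegmentProfile:
    """Re-center a profile by its 10-kb-window median log2 ratio.

    The median is taken over covered windows only; after centering, the
    profile's own 10-kb window median is 0. Centering approximates
    normalization by sample ploidy but cannot detect genome-wide ploidy
    multiplication.
    """
    if profile.n_segments == 0:
        raise ValueError(f"{profile.sample_id}: cannot center an empty profile")
    binned = bin_profile(profile, CENTERING_WIDTH)
    m = float(np.median(binned.values()))
    return profile.shifted(-m)


def gene_copy_number(profile: SegmentProfile, genes: pd.DataFrame) -> GeneCopyProfile:
    """Assign each gene the minimum log2 ratio over overlapping segments.

    The minimum is the most conservative estimate of the copy number of the
    intact gene when it spans several segments. Genes overlapping no
    segment are absent from the result.
    """
    if len(genes) == 0:
        raise ValueError("empty gene table")
    out_ids: list[str] = []
    out_vals: list[float] = []
    seg = profile.segments
    for chrom, gsub in genes.groupby("chrom", sort=False):
        ssub = seg[seg["chrom"] == chrom]
        if ssub.empty:
            continue
        starts = ssub["start"].to_numpy()
        ends = ssub["end"].to_numpy()
        vals = ssub["log2_ratio"].to_numpy()
        # Segments are sorted and disjoint: the overlap range for a gene is
        # [first segment ending after gene start, first segment starting at
        # or after gene end).
        lo = np.searchsorted(ends, gsub["start"].to_numpy(), side="right")
        hi = np.searchsorted(starts, gsub["end"].to_numpy(), side="left")
        gid = gsub["gene_id"].to_numpy()
        for g, a, b in zip(gid, lo, hi):
            if b > a:
                out_ids.append(g)
                out_vals.append(float(vals[a:b].min()))
    return GeneCopyProfile(
        profile.sample_id, pd.Series(out_vals, index=pd.Index(out_ids, name="gene_id"), dtype=float)
    )


def aberration_summary(binned: BinnedProfile, min_windows: int = 20) -> AberrationSummary:
    """Variance and 5-95% inter-percentile range of window values.

    The IPR is preferred over variance as the aberration metric: a narrow
    range means at least 90% of the covered genome shows only very low-level
    gains and losses, while variance can be inflated by a few extreme focal
    events.
    """
    v = binned.values()
    if len(v) < min_windows:
        raise ValueError(f"{binned.sample_id}: only {len(v)} windows (< {min_windows})")
    p5, p95 = np.percentile(v, [5, 95])
    return AberrationSummary(variance=float(np.var(v)), ipr_5_95=float(p95 - p5), n_windows=len(v))


def classify_gain_loss(profile: SegmentProfile, thr: float = GAIN_LOSS_THR) -> pd.DataFrame:
    """Label each centered segment gain / loss / neutral (strict threshold)."""
    df = profile.segments.copy()
    v = df["log2_ratio"].to_numpy()
    labels = np.where(v > thr, "gain", np.where(v < -thr, "loss", "neutral"))
    df["call"] = labels
    return df


def segment_size_stats(
    profiles: list[SegmentProfile], thr: float = GAIN_LOSS_THR
) -> dict[str, float]:
    """Size and dynamic-range statistics of aberrant segments.

    A segment counts as a CNA when |log2 ratio| >= thr (inclusive — the
    convention used for descriptive segment statistics, unlike the strict
    gain/loss call threshold). Returns the median and mean aberrant-segment
    length and the min/max log2 ratio over aberrant segments.
    """
    if not profiles:
        raise ValueError("no profiles given")
    lengths, values = [], []
    for p in profiles:
        df = p.segments
        mask = df["log2_ratio"].abs() >= thr
        lengths.append((df.loc[mask, "end"] - df.loc[mask, "start"]).to_numpy())
        values.append(df.loc[mask, "log2_ratio"].to_numpy())
    lengths = np.concatenate(lengths)
    values = np.concatenate(values)
    if len(lengths) == 0:
        raise ValueError("no aberrant segments at |log2| >= threshold")
    return {
        "median_size": float(np.median(lengths)),
        "mean_size": float(np.mean(lengths)),
        "value_min": float(values.min()),
        "value_max": float(values.max()),
        "n_segments": int(len(lengths)),
    }
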