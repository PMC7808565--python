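"""Pairwise CNA concordance between samples of a PDX model.

The central object is :class:`PairConcordanceModel`: an ordinary
least-squares regression of one sample's gene-level log2 copy-number
ratios on another's. The regression — rather than thresholded gain/loss
calls — absorbs systematic baseline and dynamic-range differences between
the samples (median-normalization offsets, stromal dilution, platform
sensitivity). Genes whose residuals from the outlier-cleaned ("improved")
fit exceed a threshold are called altered between the two samples.

Conventions fixed here (the residuals depend on them):

* the *reference* sample is the predictor — PT in PT-PDX pairs, the
  lower-passage sample in PDX-PDX pairs, the first-listed otherwise;
* "studentized residual" means externally studentized (leave-one-out
  residual variance), with outliers at |t| > 3;
* altered genes are called on raw residuals in log2 units from the
  improved fit, not on studentized residuals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import Platform, SampleClass, SampleRecord
from .prep import AberrationSummary, BinnedProfile, GeneCopyProfile

#: Flooring applied to deep deletions before correlation/regression.
DELETION_FLOOR = -3.0
#: Outlier cut on externally studentized residuals.
OUTLIER_Z = 3.0
#: Default altered-gene thresholds (log2 units, raw residuals).
THR_SUBCLONAL = 0.5
THR_FUNCTIONAL = 1.0

PAIR_TYPES = ("PT_PDX", "PDX_PDX", "PT_PT_INTRAPATIENT", "CROSS_MODEL")


# ---------------------------------------------------------------------------
# pair enumeration


def _usable(r: SampleRecord) -> bool:
    if r.excluded_from_pairing:
        return False
    return r.sample_class in (SampleClass.PT, SampleClass.PDX)


def _order_pair(a: SampleRecord, b: SampleRecord) -> tuple[SampleRecord, SampleRecord]:
    """Reference sample first: PT before PDX, lower passage before higher."""
    if a.sample_class is not b.sample_class:
        return (a, b) if a.sample_class is SampleClass.PT else (b, a)
    if a.sample_class is SampleClass.PDX:
        pa = a.passage if a.passage is not None else 10**9
        pb = b.passage if b.passage is not None else 10**9
        if pb < pa:
            return b, a
    return a, b


def _classify(a: SampleRecord, b: SampleRecord) -> tuple[str, str]:
    kinds = {a.sample_class, b.sample_class}
    if kinds == {SampleClass.PT, SampleClass.PDX}:
        return "PT_PDX", "NA"
    if kinds == {SampleClass.PDX}:
        if a.lineage_id is not None and b.lineage_id is not None:
            rel = "SAME_LINEAGE" if a.lineage_id == b.lineage_id else "DIFFERENT_LINEAGE"
        else:
            rel = "NA"
        return "PDX_PDX", rel
    return "PT_PT_INTRAPATIENT", "NA"


def enumerate_pairs(
    records: list[SampleRecord],
    cross_model_background: bool = False,
) -> pd.DataFrame:
    """Enumerate and classify comparable sample pairs.

    Intra-model pairs (all pairs of usable samples sharing a model and a
    platform) are always produced; PT-PT pairs across models of the same
    patient are classified ``PT_PT_INTRAPATIENT``. With
    ``cross_model_background``, pairs of samples from *different* models
    sharing tumor type, center and platform are added as the background.
    """
    usable = [r for r in records if _usable(r)]
    by_model: dict[str, list[SampleRecord]] = {}
    for r in usable:
        by_model.setdefault(r.model_id, []).append(r)

    rows = []

    def _append(a: SampleRecord, b: SampleRecord, pair_type: str, rel: str) -> None:
        rows.append(
            {
                "sample_a": a.sample_id,
                "sample_b": b.sample_id,
                "pair_type": pair_type,
                "lineage_relation": rel,
                "model_id": a.model_id if a.model_id == b.model_id else f"{a.model_id}|{b.model_id}",
                "platform": a.platform.value,
                "passage_a": a.passage,
                "passage_b": b.passage,
            }
        )

    for model_id, members in by_model.items():
        if len(members) < 2:
            continue
        for a, b in itertools.combinations(members, 2):
            if a.platform is not b.platform:
                continue
            a, b = _order_pair(a, b)
            pair_type, rel = _classify(a, b)
            _append(a, b, pair_type, rel)

    # intra-patient PT pairs across models (e.g. primary vs relapse)
    pts_by_patient: dict[str, list[SampleRecord]] = {}
    for r in usable:
        if r.sample_class is SampleClass.PT:
            pts_by_patient.setdefault(r.patient_id, []).append(r)
    for patient, pts in pts_by_patient.items():
        for a, b in itertools.combinations(pts, 2):
            if a.model_id == b.model_id or a.platform is not b.platform:
                continue
            _append(a, b, "PT_PT_INTRAPATIENT", "NA")

    if cross_model_background:
        for a, b in itertools.combinations(usable, 2):
            if a.model_id == b.model_id or a.patient_id == b.patient_id:
                continue
            if a.platform is not b.platform:
                continue
            if a.tumor_type != b.tumor_type or a.center != b.center:
                continue
            _append(a, b, "CROSS_MODEL", "NA")

    return pd.DataFrame(
        rows,
        columns=[
            "sample_a", "sample_b", "pair_type", "lineage_relation",
            "model_id", "platform", "passage_a", "passage_b",
        ],
    )


# ---------------------------------------------------------------------------
# correlation


def _as_series(profile) -> pd.Series:
    if isinstance(profile, GeneCopyProfile):
        return profile.values
    if isinstance(profile, BinnedProfile):
        return profile.keyed()
    if isinstance(profile, pd.Series):
        return profile
    raise TypeError(f"cannot correlate object of type {type(profile)!r}")


def correlate_profiles(a, b, min_shared: int = 30) -> float:
    """Pearson correlation over shared features (genes or windows).

    Features missing in either sample are excluded. Returns NaN when
    either vector has zero variance (the pair should be flagged invalid).
    """
    sa, sb = _as_series(a), _as_series(b)
    shared = sa.index.intersection(sb.index)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared features (< {min_shared})")
    x = sa.loc[shared].to_numpy(dtype=float)
    y = sb.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# the pair regression model


def externally_studentized(x: np.ndarray, y: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Externally studentized residuals of a simple linear regression.

    Closed form equivalent to refitting with each point left out: the
    internally studentized residual r_i = e_i / (s sqrt(1 - h_i)) is
    rescaled by sqrt((n - p - 1) / (n - p - r_i^2)) with p = 2 parameters.
    """
    n = len(x)
    xbar = x.mean()
    sxx = np.sum((x - xbar) ** 2)
    h = 1.0 / n + (x - xbar) ** 2 / sxx
    s2 = np.sum(resid**2) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = resid / np.sqrt(s2 * (1.0 - h))
        t = r * np.sqrt((n - 3) / (n - 2 - r**2))
    return t


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    residuals: pd.Series
    studentized: pd.Series
    outlier_features: frozenset[str]
    improved: bool


class PairConcordanceResults:
    """Results of :meth:`PairConcordanceModel.fit`.

    Carries the Pearson correlation, the initial and improved (outlier
    cleaned) regression fits, per-gene residuals and the altered-gene
    caller. ``valid`` is False when either profile is degenerate (zero
    variance) so no regression exists.
    """

    def __init__(
        self,
        model: "PairConcordanceModel",
        pearson_r: float,
        initial: Optional[RegressionFit],
        improved: Optional[RegressionFit],
    ) -> None:
        self.model = model
        self.pearson_r = pearson_r
        self.initial_fit = initial
        self.improved_fit = improved
        self.n_features = len(model.x)
        self.valid = improved is not None

    @property
    def residuals(self) -> pd.Series:
        """Raw residuals (log2 units) of every shared gene from the improved fit."""
        if not self.valid:
            raise ValueError("pair is degenerate; no regression fit")
        return self.improved_fit.residuals

    @property
    def outliers(self) -> frozenset[str]:
        return self.initial_fit.outlier_features if self.valid else frozenset()

    def altered_genes(self, thr: float = THR_SUBCLONAL, omit_both_deleted: bool = False) -> frozenset[str]:
        """Genes with |residual| > thr from the improved regression.

        With ``omit_both_deleted`` (the convention for the stringent
        thr=1.0 recurrence path), genes at or below the deletion floor in
        both samples are omitted — a residual among doubly-deleted genes
        carries no dosage information.
        """
        if not self.valid:
            raise ValueError("pair is degenerate; no regression fit")
        resid = self.improved_fit.residuals
        altered = resid.index[resid.abs() > thr]
        if omit_both_deleted:
            floor = self.model.floor
            both = (self.model.x <= floor) & (self.model.y <= floor)
            altered = altered.difference(self.model.x.index[both])
        return frozenset(altered)

    def proportion_altered(self, thr: float = THR_SUBCLONAL, universe: Optional[set[str]] = None) -> float:
        genes = universe if universe is not None else set(self.model.x.index)
        if not genes:
            return float("nan")
        return len(self.altered_genes(thr) & set(genes)) / len(genes)

    def summary(self) -> pd.DataFrame:
        """One-row summary table of the pair comparison."""
        row = {
            "reference": self.model.reference_id,
            "target": self.model.target_id,
            "n_features": self.n_features,
            "pearson_r": self.pearson_r,
            "valid": self.valid,
        }
        if self.valid:
            row.update(
                slope=self.improved_fit.slope,
                intercept=self.improved_fit.intercept,
                n_outliers=len(self.outliers),
                n_altered_05=len(self.altered_genes(THR_SUBCLONAL)),
                n_altered_10=len(self.altered_genes(THR_FUNCTIONAL, omit_both_deleted=True)),
            )
        return pd.DataFrame([row])


class PairConcordanceModel:
    """Regression-residual comparison of two gene-level CNA profiles.

    Parameters
    ----------
    reference, target : GeneCopyProfile or Series
        Gene-level log2 ratios; the reference is the predictor. Values
        below the deletion floor are rescaled to the floor before fitting
        (extreme negative log values would otherwise dominate the fit).
    floor : float
        Deletion floor, default −3.
    min_shared : int
        Minimum number of shared genes, default 200.
    """

    def __init__(self, reference, target, floor: float = DELETION_FLOOR, min_shared: int = 200):
        ra, rb = _as_series(reference), _as_series(target)
        self.reference_id = getattr(reference, "sample_id", "reference")
        self.target_id = getattr(target, "sample_id", "target")
        shared = ra.index.intersection(rb.index)
        if len(shared) < min_shared:
            raise ValueError(f"only {len(shared)} shared genes (< {min_shared})")
        self.floor = floor
        self.x = ra.loc[shared].clip(lower=floor).astype(float)
        self.y = rb.loc[shared].clip(lower=floor).astype(float)

    def _ols(self, x: pd.Series, y: pd.Series) -> sm.regression.linear_model.RegressionResultsWrapper:
        return sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()

    def fit(self, outlier_z: float = OUTLIER_Z) -> PairConcordanceResults:
        """Fit, remove |studentized residual| > 3 outliers, refit.

        The refit ("improved" model) is not biased by a few extreme genes;
        residuals of *all* shared genes are then taken from it.
        """
        x, y = self.x, self.y
        if np.ptp(x.to_numpy()) == 0 or np.ptp(y.to_numpy()) == 0:
            return PairConcordanceResults(self, float("nan"), None, None)
        r = float(np.corrcoef(x.to_numpy(), y.to_numpy())[0, 1])

        res0 = self._ols(x, y)
        student = pd.Series(
            externally_studentized(x.to_numpy(), y.to_numpy(), res0.resid), index=x.index
        )
        resid0 = pd.Series(res0.resid, index=x.index)
        outliers = frozenset(x.index[student.abs() > outlier_z])
        initial = RegressionFit(
            slope=float(res0.params[1]), intercept=float(res0.params[0]),
            residuals=resid0, studentized=student, outlier_features=outliers, improved=False,
        )

        keep = x.index.difference(outliers)
        res1 = self._ols(x.loc[keep], y.loc[keep])
        b0, b1 = float(res1.params[0]), float(res1.params[1])
        resid1 = y - (b0 + b1 * x)
        keep_student = pd.Series(
            externally_studentized(
                x.loc[keep].to_numpy(), y.loc[keep].to_numpy(), res1.resid
            ),
            index=keep,
        )
        improved = RegressionFit(
            slope=b1, intercept=b0, residuals=resid1,
            studentized=keep_student.reindex(x.index),
            outlier_features=outliers, improved=True,
        )
        return PairConcordanceResults(self, r, initial, improved)


def altered_genes(
    reference, target, thr: float = THR_SUBCLONAL, omit_both_deleted: bool = False
) -> frozenset[str]:
    """Convenience wrapper: altered genes between two gene-level profiles."""
    return (
        PairConcordanceModel(reference, target)
        .fit()
        .altered_genes(thr=thr, omit_both_deleted=omit_both_deleted)
    )


# ---------------------------------------------------------------------------
# cross-platform window comparison


@dataclass
class CrossPlatformResult:
    fit: RegressionFit
    outlier_windows: pd.DataFrame
    discordant_genome_fraction: float
    outlier_segment_sizes_a: np.ndarray
    outlier_segment_sizes_b: np.ndarray
    pearson_r: float
    n_windows: int


def cross_platform_compare(
    a: BinnedProfile,
    b: BinnedProfile,
    profile_a=None,
    profile_b=None,
    outlier_z: float = OUTLIER_Z,
    min_windows: int = 100,
) -> CrossPlatformResult:
    """Compare two binned profiles of one tumor across platforms.

    Fits ``b ~ a`` over shared 100-kb windows; windows with |externally
    studentized residual| > 3 are the discrepant copy-number calls. The
    discordant genome fraction is the summed length of outlier windows
    over the summed length of shared windows, and outlier windows are
    mapped back to their source segments to size the discordant events.
    """
    if a.width != b.width:
        raise ValueError("profiles binned at different widths")
    ka, kb = a.keyed(), b.keyed()
    shared = ka.index.intersection(kb.index)
    if len(shared) < min_windows:
        raise ValueError(f"only {len(shared)} shared windows (< {min_windows})")
    x = ka.loc[shared]
    y = kb.loc[shared]
    xv, yv = x.to_numpy(), y.to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero-variance window profile; cannot regress")
    res = sm.OLS(yv, sm.add_constant(xv)).fit()
    student = externally_studentized(xv, yv, res.resid)
    out_mask = np.abs(student) > outlier_z
    fit = RegressionFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        residuals=pd.Series(res.resid, index=shared),
        studentized=pd.Series(student, index=shared),
        outlier_features=frozenset(shared[out_mask]), improved=False,
    )
    out_windows = pd.DataFrame(
        [{"chrom": c, "start": s} for (c, s) in shared[out_mask]]
    )
    frac = float(out_mask.sum() / len(shared))

    def _segment_sizes(binned: BinnedProfile, profile) -> np.ndarray:
        if profile is None:
            return np.array([])
        wins = binned.windows.set_index(["chrom", "start"])
        seg_idx = wins.loc[shared[out_mask], "segment_index"].unique()
        seg = profile.segments.loc[seg_idx]
        return (seg["end"] - seg["start"]).to_numpy()

    return CrossPlatformResult(
        fit=fit,
        outlier_windows=out_windows,
        discordant_genome_fraction=frac,
        outlier_segment_sizes_a=_segment_sizes(a, profile_a),
        outlier_segment_sizes_b=_segment_sizes(b, profile_b),
        pearson_r=float(np.corrcoef(xv, yv)[0, 1]),
        n_windows=len(shared),
    )


# ---------------------------------------------------------------------------
# pair-level flags and statistics

#: Pairs where a sample is non-aberrant and correlation is low are invalid.
VALID_IPR_MIN = 0.3
VALID_R_MIN = 0.6
#: Discordance requires both samples clearly aberrant yet poorly correlated.
DISCORDANT_IPR_MIN = 0.5
DISCORDANT_R_MAX = 0.6


def pair_is_valid(r: float, ipr_a: float, ipr_b: float) -> bool:
    """A pair is omitted when low correlation is explained by a genomically
    stable (non-aberrant) sample: either IPR < 0.3 *and* r < 0.6."""
    if np.isnan(r):
        return False
    return not ((min(ipr_a, ipr_b) < VALID_IPR_MIN) and (r < VALID_R_MIN))


def flag_discordant(r: float, ipr_a: float, ipr_b: float) -> bool:
    """Highly discordant: both samples aberrant (IPR > 0.5) yet r < 0.6."""
    if np.isnan(r):
        return False
    return bool(ipr_a > DISCORDANT_IPR_MIN and ipr_b > DISCORDANT_IPR_MIN and r < DISCORDANT_R_MAX)


def range_ratio(summary_a: AberrationSummary, summary_b: AberrationSummary) -> float:
    """Ratio of CNA ranges (5-95% IPR), first sample over second.

    In PT-PDX pairs the PT is the first sample, so stromal dilution of the
    PT signal shows up as a ratio below 1.
    """
    if summary_b.ipr_5_95 == 0:
        warnings.warn("zero IPR in denominator sample; range ratio undefined", stacklevel=2)
        return float("nan")
    return summary_a.ipr_5_95 / summary_b.ipr_5_95


def filter_valid_pairs(pair_table: pd.DataFrame, summaries: dict[str, AberrationSummary]) -> pd.DataFrame:
    """Annotate a pair table (with a ``pearson_r`` column) with validity,
    discordance and range-ratio columns."""
    out = pair_table.copy()
    ipr_a = out["sample_a"].map(lambda s: summaries[s].ipr_5_95)
    ipr_b = out["sample_b"].map(lambda s: summaries[s].ipr_5_95)
    out["ipr_a"] = ipr_a
    out["ipr_b"] = ipr_b
    out["valid"] = [
        pair_is_valid(r, a, b) for r, a, b in zip(out["pearson_r"], ipr_a, ipr_b)
    ]
    out["discordant"] = [
        flag_discordant(r, a, b) for r, a, b in zip(out["pearson_r"], ipr_a, ipr_b)
    ]
    out["range_ratio"] = np.where(ipr_b > 0, ipr_a / ipr_b, np.nan)
    return out


def detect_mislabeled(
    pair_table: pd.DataFrame,
    gene_profiles: dict[str, GeneCopyProfile],
    records: list[SampleRecord],
    low_r: float = VALID_R_MIN,
    high_r: float = 0.9,
) -> pd.DataFrame:
    """Flag candidate sample swaps for manual review (never auto-dropped).

    A sample in an intra-model pair with r < 0.6 that correlates > 0.9
    with a sample from a *different* model is a mislabeling candidate.
    """
    by_sample = {r.sample_id: r for r in records}
    low = pair_table[pair_table["pearson_r"] < low_r]
    suspects = sorted(set(low["sample_a"]) | set(low["sample_b"]))
    rows = []
    for s in suspects:
        if s not in gene_profiles or s not in by_sample:
            continue
        for other, prof in gene_profiles.items():
            if other == s or other not in by_sample:
                continue
            if by_sample[other].model_id == by_sample[s].model_id:
                continue
            try:
                r = correlate_profiles(gene_profiles[s], prof)
            except ValueError:
                continue
            if r > high_r:
                rows.append({"sample": s, "matches_sample": other,
                             "matches_model": by_sample[other].model_id, "r": r})
    return pd.DataFrame(rows, columns=["sample", "matches_sample", "matches_model", "r"])


def compare_groups(
    group_a: np.ndarray,
    group_b: np.ndarray,
    test: str = "ranksum",
    alternative: str = "two-sided",
    min_n: int = 3,
) -> float:
    """Wilcoxon rank-sum or Kolmogorov-Smirnov p-value for two groups.

    ``alternative`` follows scipy: for ``ranksum``, "less"/"greater" test
    whether ``group_a`` is stochastically smaller/greater than ``group_b``.
    Degenerate all-tied input returns p = 1 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"each group needs >= {min_n} values")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied; p set to 1", stacklevel=2)
        return 1.0
    if test == "ranksum":
        return float(stats.mannwhitneyu(a, b, alternative=alternative).pvalue)
    if test == "ks":
        return float(stats.ks_2samp(a, b, alternative=alternative).pvalue)
    raise ValueError(f"unknown test {test!r}")
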