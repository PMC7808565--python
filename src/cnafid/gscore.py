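"""Cohort-level recurrent-CNA analysis.

A *G score* summarizes the recurrence of copy-number events across a
cohort: per 100-kb window it is the mean, over samples, of the event
amplitude in excess of a threshold — frequency times average amplitude in
one expression. Amplifications and deletions are scored separately (by
convention deletion scores are rendered negative for display only).

Because stromal DNA dilutes CNA amplitudes in patient tumors, the G-score
range is systematically lower in PT cohorts than in the matched PDX
cohorts; PDX scores are therefore mapped onto the PT scale by a global
linear regression before any cross-cohort comparison (ΔG, ΔNES).

Significance is empirical: cyclic within-genome permutation of each
sample's window values preserves the per-sample amplitude spectrum and
segment-length structure while destroying positional recurrence;
Benjamini-Hochberg q-values at q < 0.25 mark significant genes.

The preranked GSEA here runs on gene-level G scores with the classical
weighted Kolmogorov-Smirnov enrichment score and gene-label permutation,
plus one extra filter: contiguous genes inside a single recurrent amplicon
can produce spurious enrichment for positionally clustered gene sets, so
a set is only accepted when the leading-edge genes that are individually
significant make up at least 20% of the set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core import GeneSetCollection, SegmentProfile, chrom_sort_key
from .prep import WINDOW_WIDTH, bin_profile

#: Amplitude in excess of this threshold counts toward the G score.
EVENT_THRESHOLD = 0.1
#: Genes at BH q below this are "significant" for the GSEA leading-edge rule.
SIG_Q = 0.25


@dataclass
class GScoreScaling:
    slope_amp: float
    intercept_amp: float
    slope_del: float
    intercept_del: float


@dataclass
class CohortGScoreResults:
    """Per-bin and per-gene amplification/deletion recurrence scores."""

    bins: pd.DataFrame  # chrom, start, g_amp, g_del
    genes: pd.DataFrame  # gene_id (index), g_amp, g_del, q_amp, q_del
    n_samples: int
    width: int
    event_threshold: float

    def significant_genes(self, track: str, q: float = SIG_Q) -> frozenset[str]:
        g = self.genes
        col = {"amp": ("g_amp", "q_amp"), "del": ("g_del", "q_del")}[track]
        mask = (g[col[0]] > 0) & (g[col[1]] < q)
        return frozenset(g.index[mask])

    def gene_scores(self, track: str) -> pd.Series:
        return self.genes["g_amp" if track == "amp" else "g_del"]

    def summary(self) -> pd.DataFrame:
        rows = []
        for track in ("amp", "del"):
            s = self.gene_scores(track)
            rows.append(
                {
                    "track": track,
                    "n_genes": len(s),
                    "max_g": float(s.max()) if len(s) else np.nan,
                    "mean_g": float(s.mean()) if len(s) else np.nan,
                    "n_significant": len(self.significant_genes(track)),
                }
            )
        return pd.DataFrame(rows)


class CohortGScoreModel:
    """Recurrence-score model for a cohort of centered segment profiles.

    Parameters
    ----------
    profiles : list of SegmentProfile
        Median-centered profiles; at least 5 samples.
    genes : DataFrame
        Canonical gene table for gene-level scores.
    width : int
        Window width (bp), default 100 kb.
    event_threshold : float
        Only |log2| in excess of this contributes, default 0.1.
    """

    def __init__(
        self,
        profiles: list[SegmentProfile],
        genes: pd.DataFrame,
        width: int = WINDOW_WIDTH,
        event_threshold: float = EVENT_THRESHOLD,
        min_samples: int = 5,
    ) -> None:
        if len(profiles) < min_samples:
            raise ValueError(f"cohort has {len(profiles)} samples (< {min_samples})")
        self.profiles = profiles
        self.genes = genes
        self.width = width
        self.event_threshold = event_threshold

    def _window_matrix(self) -> tuple[pd.MultiIndex, np.ndarray]:
        keyed = [bin_profile(p, self.width).keyed() for p in self.profiles]
        union = keyed[0].index
        for k in keyed[1:]:
            union = union.union(k.index)
        union = pd.MultiIndex.from_tuples(
            sorted(union, key=lambda t: (chrom_sort_key(t[0]), t[1])),
            names=["chrom", "start"],
        )
        # windows a sample does not cover are neutral for that sample
        mat = np.vstack([k.reindex(union).fillna(0.0).to_numpy() for k in keyed])
        return union, mat

    @staticmethod
    def _scores(mat: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        g_amp = np.maximum(mat - t, 0.0).mean(axis=0)
        g_del = np.maximum(-mat - t, 0.0).mean(axis=0)
        return g_amp, g_del

    def fit(self, n_perm: int = 100, seed: int = 0) -> CohortGScoreResults:
        """Compute window and gene G scores with permutation q-values."""
        union, mat = self._window_matrix()
        t = self.event_threshold
        g_amp, g_del = self._scores(mat, t)

        rng = np.random.default_rng(seed)
        n_s, n_w = mat.shape
        null_amp = np.empty((n_perm, n_w))
        null_del = np.empty((n_perm, n_w))
        for p in range(n_perm):
            rolled = np.vstack(
                [np.roll(mat[i], rng.integers(1, n_w)) for i in range(n_s)]
            )
            null_amp[p], null_del[p] = self._scores(rolled, t)

        def _pvals(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
            pool = np.sort(null.ravel())
            n = len(pool)
            ge = n - np.searchsorted(pool, obs, side="left")
            return (1.0 + ge) / (1.0 + n)

        p_amp = _pvals(g_amp, null_amp)
        p_del = _pvals(g_del, null_del)

        bins = pd.DataFrame(
            {
                "chrom": [c for c, _ in union],
                "start": [s for _, s in union],
                "g_amp": g_amp,
                "g_del": g_del,
                "p_amp": p_amp,
                "p_del": p_del,
            }
        )
        gene_df = self._gene_level(bins)
        for track in ("amp", "del"):
            gene_df[f"q_{track}"] = multipletests(gene_df[f"p_{track}"], method="fdr_bh")[1]
        return CohortGScoreResults(
            bins=bins,
            genes=gene_df,
            n_samples=n_s,
            width=self.width,
            event_threshold=t,
        )

    def _gene_level(self, bins: pd.DataFrame) -> pd.DataFrame:
        """Gene value = value of the covering bin with the largest overlap
        (ties toward the lower-coordinate bin)."""
        width = self.width
        lookup = {
            (c, s): i
            for i, (c, s) in enumerate(zip(bins["chrom"], bins["start"]))
        }
        cols = {k: bins[k].to_numpy() for k in ("g_amp", "g_del", "p_amp", "p_del")}
        rows = []
        for row in self.genes.itertuples(index=False):
            w0 = row.start // width
            w1 = (row.end - 1) // width
            best, best_ov = None, -1
            for w in range(w0, w1 + 1):
                key = (row.chrom, w * width)
                if key not in lookup:
                    continue
                ov = min(row.end, (w + 1) * width) - max(row.start, w * width)
                if ov > best_ov:
                    best, best_ov = lookup[key], ov
            if best is None:
                continue
            rows.append(
                {
                    "gene_id": row.gene_id,
                    "g_amp": cols["g_amp"][best],
                    "g_del": cols["g_del"][best],
                    "p_amp": cols["p_amp"][best],
                    "p_del": cols["p_del"][best],
                }
            )
        return pd.DataFrame(rows).set_index("gene_id")


def compute_gscores(
    profiles: list[SegmentProfile],
    genes: pd.DataFrame,
    width: int = WINDOW_WIDTH,
    event_threshold: float = EVENT_THRESHOLD,
    n_perm: int = 100,
    seed: int = 0,
) -> CohortGScoreResults:
    """Functional front-end to :class:`CohortGScoreModel`."""
    return CohortGScoreModel(profiles, genes, width, event_threshold).fit(n_perm=n_perm, seed=seed)


def scale_gscores(
    pdx: CohortGScoreResults, pt: CohortGScoreResults
) -> tuple[CohortGScoreResults, GScoreScaling]:
    """Map PDX gene-level G scores onto the PT scale.

    Fits PDX G on PT G by global linear regression over shared genes,
    separately for the amplification and deletion tracks, then inverts the
    fit: scaled G = (G − intercept)/slope. Correlations are unchanged;
    only the range is matched to the PT cohort.
    """
    shared = pdx.genes.index.intersection(pt.genes.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between cohorts")
    out = pdx.genes.copy()
    params = {}
    for track in ("amp", "del"):
        col = f"g_{track}"
        x = pt.genes.loc[shared, col].to_numpy()
        y = pdx.genes.loc[shared, col].to_numpy()
        res = sm.OLS(y, sm.add_constant(x)).fit()
        b0, b1 = float(res.params[0]), float(res.params[1])
        if abs(b1) < 1e-8:
            raise ValueError(f"near-zero scaling slope on {track} track; cohorts incomparable")
        out[col] = (pdx.genes[col] - b0) / b1
        params[track] = (b1, b0)
    scaling = GScoreScaling(
        slope_amp=params["amp"][0], intercept_amp=params["amp"][1],
        slope_del=params["del"][0], intercept_del=params["del"][1],
    )
    scaled = CohortGScoreResults(
        bins=pdx.bins, genes=out, n_samples=pdx.n_samples,
        width=pdx.width, event_threshold=pdx.event_threshold,
    )
    return scaled, scaling


def delta_g(g1: CohortGScoreResults, g2: CohortGScoreResults) -> pd.DataFrame:
    """Per-gene G-score change (second minus first) on shared genes."""
    shared = g1.genes.index.intersection(g2.genes.index)
    return pd.DataFrame(
        {
            "dg_amp": g2.genes.loc[shared, "g_amp"] - g1.genes.loc[shared, "g_amp"],
            "dg_del": g2.genes.loc[shared, "g_del"] - g1.genes.loc[shared, "g_del"],
        },
        index=shared,
    )


def delta_g_correlation(d1: pd.DataFrame, d2: pd.DataFrame) -> dict[str, float]:
    """Pearson correlation between two ΔG vectors, per track."""
    shared = d1.index.intersection(d2.index)
    out = {}
    for track in ("amp", "del"):
        a = d1.loc[shared, f"dg_{track}"].to_numpy()
        b = d2.loc[shared, f"dg_{track}"].to_numpy()
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            out[f"r_{track}"] = float("nan")
        else:
            out[f"r_{track}"] = float(np.corrcoef(a, b)[0, 1])
    return out


# ---------------------------------------------------------------------------
# preranked GSEA


def enrichment_score(
    positions: np.ndarray, abs_scores_at_positions: np.ndarray, n_total: int, weight: float = 1.0
) -> tuple[float, int]:
    """Weighted KS enrichment score from sorted hit positions.

    The running sum only changes at hit positions, so the extremes occur
    immediately after a hit (running sum just increased) or immediately
    before one (just decayed); both candidate sets are O(|set|).

    Returns (ES, peak_hit_index) where the leading edge for a positive ES
    is the first ``peak_hit_index + 1`` hits.
    """
    k = len(positions)
    n_miss = n_total - k
    w = np.abs(abs_scores_at_positions) ** weight
    nr = w.sum()
    if nr == 0:
        w = np.ones(k)
        nr = float(k)
    cum = np.cumsum(w) / nr
    i = np.arange(k)
    after = cum - (positions + 1 - (i + 1)) / n_miss
    before = np.concatenate([[0.0], cum[:-1]]) - (positions - i) / n_miss
    cand = np.concatenate([after, before])
    j = int(np.argmax(np.abs(cand)))
    es = float(cand[j])
    peak = j if j < k else j - k
    return es, peak


def enrichment_score_naive(scores_sorted: np.ndarray, member_mask: np.ndarray, weight: float = 1.0) -> float:
    """O(N) running-sum recomputation (independent oracle for tests)."""
    w = np.abs(scores_sorted) ** weight
    nr = w[member_mask].sum()
    n_miss = (~member_mask).sum()
    run = 0.0
    best = 0.0
    for i in range(len(scores_sorted)):
        if member_mask[i]:
            run += w[i] / nr
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return float(best)


@dataclass
class GSEAResult:
    table: pd.DataFrame  # per set: es, nes, p, q, le_size, le_sig_fraction, significant
    leading_edges: dict[str, frozenset[str]]


def gsea_preranked(
    gene_scores: pd.Series,
    gene_sets: GeneSetCollection,
    significant_genes: frozenset[str] = frozenset(),
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_set_size: int = 5,
    min_genes: int = 500,
    nes_threshold: float = 1.5,
    q_threshold: float = 0.05,
    leading_edge_fraction: float = 0.20,
) -> GSEAResult:
    """Preranked GSEA on gene-level G scores.

    ``significant_genes`` are the genes passing the cohort's G-score
    significance mask (q < 0.25); a set is significant only when NES >
    ``nes_threshold``, FDR q < ``q_threshold`` *and* the significant
    leading-edge genes make up at least ``leading_edge_fraction`` of the
    set (guard against positional-amplicon artifacts).
    """
    scores = gene_scores.dropna().sort_values(ascending=False)
    n = len(scores)
    if n < min_genes:
        raise ValueError(f"ranked list has {n} genes (< {min_genes})")
    values = scores.to_numpy(dtype=float)
    rank_of = {g: i for i, g in enumerate(scores.index)}

    sets_used: dict[str, np.ndarray] = {}
    for name in gene_sets.names():
        pos = np.array(sorted(rank_of[g] for g in gene_sets[name] if g in rank_of), dtype=int)
        if len(pos) >= min_set_size:
            sets_used[name] = pos

    rng = np.random.default_rng(seed)
    rows = []
    leading: dict[str, frozenset[str]] = {}
    null_nes_pos: list[np.ndarray] = []
    null_nes_neg: list[np.ndarray] = []
    obs_nes = {}

    for name, pos in sets_used.items():
        es, peak = enrichment_score(pos, values[pos], n, weight)
        k = len(pos)
        null = np.empty(n_perm)
        for p in range(n_perm):
            rpos = np.sort(rng.choice(n, size=k, replace=False))
            null[p], _ = enrichment_score(rpos, values[rpos], n, weight)
        pos_null = null[null > 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if len(pos_null) else np.nan
        mean_neg = -neg_null.mean() if len(neg_null) else np.nan
        if es >= 0:
            nes = es / mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else np.nan
            p_nom = (1 + (pos_null >= es).sum()) / (1 + len(pos_null)) if len(pos_null) else 1.0
            null_nes_pos.append(pos_null / mean_pos if np.isfinite(mean_pos) else np.array([]))
            le_genes = frozenset(scores.index[pos[: peak + 1]])
        else:
            nes = es / mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else np.nan
            p_nom = (1 + (neg_null <= es).sum()) / (1 + len(neg_null)) if len(neg_null) else 1.0
            null_nes_neg.append(neg_null / mean_neg if np.isfinite(mean_neg) else np.array([]))
            le_genes = frozenset(scores.index[pos[peak:]])
        obs_nes[name] = nes
        leading[name] = le_genes
        set_size = k
        le_sig = len(le_genes & significant_genes)
        rows.append(
            {
                "set_name": name,
                "size": set_size,
                "es": es,
                "nes": nes,
                "p_nominal": float(p_nom),
                "leading_edge_size": len(le_genes),
                "leading_edge_sig_fraction": le_sig / set_size if set_size else np.nan,
            }
        )

    df = pd.DataFrame(rows)
    if df.empty:
        return GSEAResult(table=df, leading_edges=leading)

    # FDR: fraction of pooled normalized null >= NES over fraction of
    # observed NES >= NES (the standard permutation-GSEA estimate).
    pool_pos = np.concatenate(null_nes_pos) if null_nes_pos else np.array([])
    pool_neg = np.concatenate(null_nes_neg) if null_nes_neg else np.array([])
    obs = df["nes"].to_numpy()
    qs = np.ones(len(df))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            num = (pool_pos >= nes).mean() if len(pool_pos) else 1.0
            den = (obs[np.isfinite(obs) & (obs >= 0)] >= nes).mean()
        else:
            num = (pool_neg <= nes).mean() if len(pool_neg) else 1.0
            den = (obs[np.isfinite(obs) & (obs < 0)] <= nes).mean()
        qs[i] = min(1.0, num / den) if den > 0 else 1.0
    df["q"] = qs
    df["significant"] = (
        (df["nes"] > nes_threshold)
        & (df["q"] < q_threshold)
        & (df["leading_edge_sig_fraction"] >= leading_edge_fraction)
    )
    return GSEAResult(table=df.set_index("set_name"), leading_edges=leading)


def delta_nes(res1: GSEAResult, res2: GSEAResult) -> pd.DataFrame:
    """ΔNES (second minus first) restricted to sets significant in at
    least one of the two cohorts."""
    t1, t2 = res1.table, res2.table
    shared = t1.index.intersection(t2.index)
    if len(shared) == 0:
        warnings.warn("no shared gene sets; ΔNES empty", stacklevel=2)
        return pd.DataFrame(columns=["nes_1", "nes_2", "delta_nes"])
    sig = shared[(t1.loc[shared, "significant"]) | (t2.loc[shared, "significant"])]
    if len(sig) == 0:
        warnings.warn("no shared significant gene sets; ΔNES empty", stacklevel=2)
        return pd.DataFrame(columns=["nes_1", "nes_2", "delta_nes"])
    out = pd.DataFrame(
        {
            "nes_1": t1.loc[sig, "nes"],
            "nes_2": t2.loc[sig, "nes"],
        }
    )
    out["delta_nes"] = out["nes_2"] - out["nes_1"]
    return out


def delta_nes_correlation(d1: pd.DataFrame, d2: pd.DataFrame) -> float:
    """Pearson correlation between two ΔNES vectors on shared sets."""
    shared = d1.index.intersection(d2.index)
    if len(shared) < 3:
        return float("nan")
    a = d1.loc[shared, "delta_nes"].to_numpy()
    b = d2.loc[shared, "delta_nes"].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
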