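"""Cross-model recurrence of altered genes, gene-set burden and the
copy-number / drug-response association screen.

Recurrence counting is on a *model basis*: a gene altered between several
pairs of the same model contributes once, so models with many similar
samples do not dominate the frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import compare_groups
from .core import GeneSetCollection


@dataclass
class PairAlteredSet:
    """Altered genes called for one sample pair (at a fixed threshold)."""

    model_id: str
    pair_type: str  # PT_PDX or PDX_PDX
    sample_a: str
    sample_b: str
    genes: frozenset[str]
    universe: frozenset[str]  # evaluated genes shared by the pair


def recurrence_frequency(
    altered_sets: Iterable[PairAlteredSet],
    comparison_type: str,
) -> pd.DataFrame:
    """Per-gene recurrence frequencies across models.

    A gene counts once per model when altered in at least one pair of that
    model and comparison type; the denominator is the number of models
    contributing at least one valid pair of that type.
    """
    sets = [s for s in altered_sets if s.pair_type == comparison_type]
    if not sets:
        raise ValueError(f"no altered sets of type {comparison_type!r}")
    models = sorted({s.model_id for s in sets})
    per_model: dict[str, set[str]] = {m: set() for m in models}
    for s in sets:
        per_model[s.model_id] |= s.genes
    counts: dict[str, int] = {}
    for genes in per_model.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    n_total = len(models)
    df = pd.DataFrame(
        {
            "gene_id": list(counts),
            "n_models_altered": list(counts.values()),
        }
    ).sort_values(["n_models_altered", "gene_id"], ascending=[False, True])
    df["n_models_total"] = n_total
    df["frequency"] = df["n_models_altered"] / n_total
    df["comparison_type"] = comparison_type
    return df.reset_index(drop=True)


@dataclass
class GeneSetProportionResult:
    per_pair: pd.DataFrame  # pair x set proportions (+ background column)
    per_set: pd.DataFrame  # set-level one-sided rank-sum p vs background


def geneset_proportions(
    altered_sets: Iterable[PairAlteredSet],
    gene_sets: GeneSetCollection,
    background_genes: Optional[set[str]] = None,
) -> GeneSetProportionResult:
    """Per-pair proportion of altered genes within each gene set.

    For every pair, proportion = |altered ∩ set| / |set ∩ universe| where
    the universe is the pair's evaluated gene universe (optionally
    intersected with a protein-coding background). Each set's proportions
    are compared with the background proportions across pairs by a
    one-sided rank-sum test (set greater).
    """
    sets = list(altered_sets)
    if not sets:
        raise ValueError("no altered sets given")
    rows = []
    for s in sets:
        universe = set(s.universe)
        if background_genes is not None:
            universe &= set(background_genes)
        altered = s.genes & universe
        row = {
            "sample_a": s.sample_a,
            "sample_b": s.sample_b,
            "pair_type": s.pair_type,
            "background": len(altered) / len(universe) if universe else np.nan,
        }
        for name in gene_sets.names():
            members = gene_sets[name] & universe
            if not members:
                row[name] = np.nan
            else:
                row[name] = len(s.genes & members) / len(members)
        rows.append(row)
    per_pair = pd.DataFrame(rows)

    set_rows = []
    bg = per_pair["background"].dropna().to_numpy()
    for name in gene_sets.names():
        vals = per_pair[name].dropna().to_numpy()
        if len(vals) == 0:
            warnings.warn(f"gene set {name!r} has no members in any pair universe; skipped",
                          stacklevel=2)
            continue
        if len(vals) >= 3 and len(bg) >= 3:
            p = compare_groups(vals, bg, test="ranksum", alternative="greater")
        else:
            p = np.nan
        set_rows.append(
            {
                "set_name": name,
                "category": gene_sets.categories.get(name, "uncategorized"),
                "median_proportion": float(np.median(vals)),
                "median_background": float(np.median(bg)) if len(bg) else np.nan,
                "p_greater": p,
            }
        )
    return GeneSetProportionResult(per_pair=per_pair, per_set=pd.DataFrame(set_rows))


# ---------------------------------------------------------------------------
# CN–drug association screen


def drug_association(
    gene_cn: pd.DataFrame,
    drug_auc: pd.DataFrame,
    expression: pd.DataFrame,
    q_threshold: float = 0.1,
    expr_p_threshold: float = 0.05,
    min_lines: int = 20,
) -> pd.DataFrame:
    """Screen gene copy number against drug sensitivity across cell lines.

    ``gene_cn`` and ``expression`` are genes x cell lines; ``drug_auc`` is
    drugs x cell lines (area-under-curve sensitivity). For every gene-drug
    pair, the Pearson p-value of CN vs AUC is Bonferroni-corrected over
    the whole tested family (q = p x n_tests, capped at 1). Associations
    with q < 0.1 are kept, and called significant only when the gene's
    *expression* also correlates with AUC (p < 0.05) in the same
    direction — copy-number dosage without an expression echo is not
    considered actionable.
    """
    shared = gene_cn.columns.intersection(drug_auc.columns).intersection(expression.columns)
    rows = []
    tested = 0
    for gene in gene_cn.index:
        if gene not in expression.index:
            continue
        cn = gene_cn.loc[gene, shared].astype(float)
        ex = expression.loc[gene, shared].astype(float)
        for drug in drug_auc.index:
            auc = drug_auc.loc[drug, shared].astype(float)
            mask = cn.notna() & auc.notna()
            if int(mask.sum()) < min_lines:
                continue
            c, a = cn[mask].to_numpy(), auc[mask].to_numpy()
            if np.ptp(c) == 0 or np.ptp(a) == 0:
                continue
            tested += 1
            r_cn, p_cn = stats.pearsonr(c, a)
            emask = ex.notna() & auc.notna()
            if int(emask.sum()) >= min_lines and np.ptp(ex[emask].to_numpy()) > 0:
                r_ex, p_ex = stats.pearsonr(ex[emask].to_numpy(), auc[emask].to_numpy())
            else:
                r_ex, p_ex = np.nan, np.nan
            rows.append(
                {
                    "gene": gene,
                    "drug": drug,
                    "n_lines": int(mask.sum()),
                    "r_cn": float(r_cn),
                    "p_cn": float(p_cn),
                    "r_expr": float(r_ex) if np.isfinite(r_ex) else np.nan,
                    "p_expr": float(p_ex) if np.isfinite(p_ex) else np.nan,
                }
            )
    df = pd.DataFrame(
        rows, columns=["gene", "drug", "n_lines", "r_cn", "p_cn", "r_expr", "p_expr"]
    )
    if df.empty:
        return df.assign(q_cn=[], same_direction=[], significant=[])
    df["q_cn"] = np.minimum(df["p_cn"] * tested, 1.0)
    df["same_direction"] = np.sign(df["r_cn"]) == np.sign(df["r_expr"])
    df["significant"] = (
        (df["q_cn"] < q_threshold)
        & (df["p_expr"] < expr_p_threshold)
        & df["same_direction"]
    )
    return df.sort_values(["significant", "q_cn"], ascending=[False, True]).reset_index(drop=True)
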