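"""Shared fixtures: small hand-built profiles and a session-wide
simulated cohort (built once; several test modules read from it)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cnafid import concordance, prep, synthetic
from cnafid.core import SegmentProfile

#: Seed for the session cohort and the seeded studies.
STUDY_SEED = 2026


def make_profile(sample_id, rows, **kwargs):
    """rows: iterable of (chrom, start, end, log2_ratio[, n_probes])."""
    recs = []
    for r in rows:
        chrom, start, end, v = r[:4]
        probes = r[4] if len(r) > 4 else pd.NA
        recs.append(
            {"chrom": str(chrom), "start": start, "end": end,
             "log2_ratio": v, "n_probes": probes}
        )
    return SegmentProfile(sample_id, pd.DataFrame(recs), **kwargs)


@pytest.fixture
def toy_genes():
    """Ten 10-kb genes on chromosome 1."""
    rows = [
        {"gene_id": f"g{i}", "symbol": f"g{i}", "chrom": "1",
         "start": 100_000 * i + 10_000, "end": 100_000 * i + 20_000,
         "biotype": "protein_coding"}
        for i in range(10)
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def cohort20():
    """The tier-1 study cohort: 20 models on the scaled genome."""
    cfg = synthetic.SimulationConfig.scaled(n_models=20)
    return synthetic.simulate_cohort(cfg, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def cohort20_prepped(cohort20):
    """Centered gene-level profiles and aberration summaries per sample."""
    by_id = {r.sample_id: r for r in cohort20.records}
    gene_profiles, summaries = {}, {}
    for sid, p in cohort20.profiles.items():
        c = prep.median_center(prep.filter_segments(p, by_id[sid].platform))
        gene_profiles[sid] = prep.gene_copy_number(c, cohort20.genes)
        summaries[sid] = prep.aberration_summary(prep.bin_profile(c))
    return gene_profiles, summaries


@pytest.fixture(scope="session")
def cohort20_pairs(cohort20, cohort20_prepped):
    """Annotated pair table (correlations, validity, range ratios)."""
    gene_profiles, summaries = cohort20_prepped
    table = concordance.enumerate_pairs(cohort20.records)
    rows = []
    for row in table.itertuples(index=False):
        r = concordance.correlate_profiles(
            gene_profiles[row.sample_a], gene_profiles[row.sample_b]
        )
        rows.append({**row._asdict(), "pearson_r": r})
    return concordance.filter_valid_pairs(pd.DataFrame(rows), summaries)
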