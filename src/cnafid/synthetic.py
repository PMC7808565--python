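"""Ground-truthed synthetic PDX cohorts.

Generates the statistical structure the analysis assumes, so every
pipeline stage is testable without external data:

* clonal + subclonal segmental copy-number profiles per tumor;
* a PDX lineage tree — serial passaging with per-passage drift events and
  lineage splits (a tumor divided into multiple mice), so different-lineage
  pairs accumulate more true differences than same-lineage pairs at equal
  passage distance;
* stromal dilution — observed linear-scale copy number is
  ``(1−f)·CN_tumor + f·2`` before the log transform, with patient tumors
  carrying far more stroma than xenografts (mouse stroma does not
  hybridize/align to the human references);
* platform rendering — segmental resolution floors (SNP fine, WGS binned,
  WES coarse), additive noise on segment means and dynamic-range clipping;
* CN-coupled expression — tumor log2 expression = baseline + true gene
  log2 ratio + noise, with a configurable fraction of genes decoupled from
  dosage to emulate the limited fidelity of expression-based inference.

All randomness flows from an explicit seed; the truth is platform
independent and rendered observations depend only on truth + platform +
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import GeneSetCollection, SampleRecord, SegmentProfile
from .prep import GeneCopyProfile

# Approximate GRCh38 chromosome lengths (bp), autosomes + X.
HUMAN_CHROM_LENGTHS: dict[str, int] = {
    "1": 248_956_422, "2": 242_193_529, "3": 198_295_559, "4": 190_214_555,
    "5": 181_538_259, "6": 170_805_979, "7": 159_345_973, "8": 145_138_636,
    "9": 138_394_717, "10": 133_797_422, "11": 135_086_622, "12": 133_275_309,
    "13": 114_364_328, "14": 107_043_718, "15": 101_991_189, "16": 90_338_345,
    "17": 83_257_441, "18": 80_373_285, "19": 58_617_616, "20": 64_444_167,
    "21": 46_709_983, "22": 50_818_468, "X": 156_040_895,
}


def scaled_genome(total_bp: int = 300_000_000, n_chroms: int = 8) -> dict[str, int]:
    """A small genome (default ~300 Mb over 8 chromosomes) for fast runs,
    with chromosome lengths proportional to the human ones."""
    names = list(HUMAN_CHROM_LENGTHS)[:n_chroms]
    total = sum(HUMAN_CHROM_LENGTHS[c] for c in names)
    return {c: int(round(HUMAN_CHROM_LENGTHS[c] / total * total_bp)) for c in names}


@dataclass
class PlatformModel:
    """Rendering characteristics of one measurement platform."""

    resolution_bp: int  # segments shorter than this merge into a neighbor
    sigma: float  # additive Gaussian noise on segment log2 means
    log2_min: float  # dynamic-range clipping
    log2_max: float
    probe_spacing_bp: Optional[int] = None  # SNP arrays report probe counts


DEFAULT_PLATFORMS: dict[str, PlatformModel] = {
    "SNP": PlatformModel(50_000, 0.05, -8.0, 3.0, probe_spacing_bp=2_000),
    "WGS": PlatformModel(200_000, 0.08, -5.0, 2.5),
    "WES": PlatformModel(1_000_000, 0.15, -3.0, 2.0),
}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic PDX cohort.

    Defaults describe a realistic consortium-style cohort: ~30 clonal
    events per genome with lengths log-uniform over 100 kb–50 Mb and
    amplitudes from the canonical single-step set {±0.3, ±0.58, ±1, −3}
    (log2 units); a minor subclone; two drift events per passage with
    random cellular fraction; stroma Beta(2, 3) in patient tumors (mean
    0.4) versus a constant 5% residue in xenografts.
    """

    genome: dict[str, int] = field(default_factory=lambda: dict(HUMAN_CHROM_LENGTHS))
    n_models: int = 20
    clone_proportions: tuple[float, ...] = (0.7, 0.3)
    events_per_genome: float = 30.0
    subclonal_events: float = 8.0  # private to the minor clone
    event_length_range: tuple[float, float] = (100_000.0, 50_000_000.0)
    event_amplitudes: tuple[float, ...] = (0.3, -0.3, 0.58, -0.58, 1.0, -1.0, -3.0)
    event_weights: tuple[float, ...] = (0.18, 0.18, 0.18, 0.18, 0.12, 0.12, 0.04)
    drift_rate: float = 2.0  # expected new subclonal events per passage
    drift_fraction_range: tuple[float, float] = (0.2, 1.0)
    recurrent_events: float = 6.0  # cohort-shared events (expected count)
    recurrent_event_prob: float = 0.8  # per-model carriage probability
    n_passages: int = 2
    split_passage: int = 1
    pt_stroma_beta: tuple[float, float] = (2.0, 3.0)
    pdx_stroma: float = 0.05
    platforms: tuple[str, ...] = ("SNP", "WES", "WGS")
    platform_models: dict[str, PlatformModel] = field(
        default_factory=lambda: dict(DEFAULT_PLATFORMS)
    )
    n_genes: int = 2_000
    expression_baseline: tuple[float, float] = (5.0, 1.5)  # log2 TPM mean, sd
    expression_sigma: float = 0.5
    decoupled_fraction: float = 0.3
    n_normals: int = 10

    def __post_init__(self) -> None:
        if abs(sum(self.clone_proportions) - 1.0) > 1e-9:
            raise ValueError("clone proportions must sum to 1")
        if not 0 <= self.pdx_stroma < 1:
            raise ValueError("stromal fractions must be in [0, 1)")
        if len(self.event_amplitudes) != len(self.event_weights):
            raise ValueError("amplitudes and weights differ in length")

    @classmethod
    def scaled(cls, **overrides) -> "SimulationConfig":
        """Scaled-down (~300 Mb) configuration for fast runs.

        A statistical miniature of the full-genome conditions: event
        *lengths* shrink by the genome-size ratio and event *counts* grow
        to preserve the aberrant fraction of the genome, so per-profile
        summary statistics (IPR, centering medians) behave like the
        full-size configuration.
        """
        genome = scaled_genome()
        defaults = dict(
            genome=genome,
            event_length_range=(10_000.0, 5_000_000.0),
            events_per_genome=120.0,
            subclonal_events=30.0,
            n_genes=2_000,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class Event:
    chrom: str
    start: int
    end: int
    log2_amp: float
    fraction: float  # cellular fraction carrying the event


@dataclass
class SampleTruth:
    sample_id: str
    model_id: str
    sample_class: str  # PT / PDX
    passage: Optional[int]
    lineage_id: Optional[str]
    events: list[Event]
    stromal_fraction: float
    gene_log2: pd.Series  # true per-gene log2 ratio (tumor cells, no stroma)


@dataclass
class TruthSet:
    """Simulator ground truth: platform-independent per-sample profiles."""

    genome: dict[str, int]
    genes: pd.DataFrame
    samples: dict[str, SampleTruth]
    lineage_edges: list[tuple[str, str]]

    def true_altered(self, sample_a: str, sample_b: str, thr: float) -> frozenset[str]:
        """Genes whose true log2 ratios differ by more than ``thr``."""
        d = (self.samples[sample_b].gene_log2 - self.samples[sample_a].gene_log2).abs()
        return frozenset(d.index[d > thr])


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    records: list[SampleRecord]
    profiles: dict[str, SegmentProfile]  # platform-rendered DNA profiles
    truth: TruthSet
    genes: pd.DataFrame


# ---------------------------------------------------------------------------
# event machinery


def _draw_events(cfg: SimulationConfig, rng: np.random.Generator, n_expected: float,
                 fraction: float | tuple[float, float]) -> list[Event]:
    n = rng.poisson(n_expected)
    chroms = list(cfg.genome)
    lengths = np.array([cfg.genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    lo, hi = np.log(cfg.event_length_range[0]), np.log(cfg.event_length_range[1])
    amps = np.asarray(cfg.event_amplitudes)
    weights = np.asarray(cfg.event_weights) / np.sum(cfg.event_weights)
    events = []
    for _ in range(n):
        c = chroms[rng.choice(len(chroms), p=probs)]
        size = int(np.exp(rng.uniform(lo, hi)))
        size = min(size, cfg.genome[c] - 1)
        start = int(rng.integers(0, cfg.genome[c] - size))
        amp = float(amps[rng.choice(len(amps), p=weights)])
        if isinstance(fraction, tuple):
            frac = float(rng.uniform(*fraction))
        else:
            frac = float(fraction)
        events.append(Event(c, start, start + size, amp, frac))
    return events


def _bulk_segments(events: list[Event], genome: dict[str, int]) -> pd.DataFrame:
    """Piecewise-constant bulk tumor profile from an event list.

    Bulk linear CN at a locus is 2·(1 + Σ f_e·(2^a_e − 1)) over covering
    events: each event multiplies CN by 2^a in the cells carrying it.
    """
    rows = []
    for chrom, length in genome.items():
        evs = [e for e in events if e.chrom == chrom]
        bounds = sorted({0, length} | {e.start for e in evs} | {e.end for e in evs})
        for a, b in zip(bounds[:-1], bounds[1:]):
            delta = sum(e.fraction * (2.0 ** e.log2_amp - 1.0) for e in evs
                        if e.start <= a and e.end >= b)
            cn = max(2.0 * (1.0 + delta), 0.05)
            rows.append({"chrom": chrom, "start": a, "end": b,
                         "log2_ratio": float(np.log2(cn / 2.0)), "cn": cn})
    return pd.DataFrame(rows)


def _gene_truth(segs: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """True per-gene log2 ratio: value at the gene midpoint."""
    out = np.zeros(len(genes))
    for chrom, gsub in genes.groupby("chrom", sort=False):
        ssub = segs[segs["chrom"] == chrom]
        starts = ssub["start"].to_numpy()
        vals = ssub["log2_ratio"].to_numpy()
        mid = ((gsub["start"] + gsub["end"]) // 2).to_numpy()
        idx = np.searchsorted(starts, mid, side="right") - 1
        out[genes.index.get_indexer(gsub.index)] = vals[np.clip(idx, 0, len(vals) - 1)]
    return pd.Series(out, index=pd.Index(genes["gene_id"], name="gene_id"))


def synthetic_genes(genome: dict[str, int], n_genes: int, gene_length: int = 20_000,
                    seed: int = 0) -> pd.DataFrame:
    """Evenly spaced synthetic gene models across the genome."""
    total = sum(genome.values())
    rows = []
    i = 0
    for chrom, length in genome.items():
        k = max(1, int(round(n_genes * length / total)))
        starts = np.linspace(gene_length, length - 2 * gene_length, k).astype(int)
        for s in starts:
            rows.append({"gene_id": f"G{i:05d}", "symbol": f"G{i:05d}", "chrom": chrom,
                         "start": int(s), "end": int(s) + gene_length,
                         "biotype": "protein_coding"})
            i += 1
    return pd.DataFrame(rows)


def random_gene_sets(genes: pd.DataFrame, n_sets: int = 10, set_size: int = 40,
                     seed: int = 0, prefix: str = "SET") -> GeneSetCollection:
    """Random gene sets drawn uniformly from a gene table (null sets)."""
    rng = np.random.default_rng(seed)
    ids = genes["gene_id"].to_numpy()
    sets = {
        f"{prefix}_{i:03d}": frozenset(rng.choice(ids, size=set_size, replace=False))
        for i in range(n_sets)
    }
    return GeneSetCollection(sets=sets, categories={k: "synthetic" for k in sets})


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_model(
    cfg: SimulationConfig,
    genes: pd.DataFrame,
    model_id: str,
    platform: str,
    rng: np.random.Generator,
    shared_events: Optional[list[Event]] = None,
) -> tuple[list[SampleTruth], list[tuple[str, str]]]:
    """Simulate one PDX model: a patient tumor plus a split PDX lineage.

    The founder clone carries the clonal events — private ones plus any
    cohort-shared (recurrent) events the model happens to carry; a minor
    subclone adds private events at its mixing proportion. The xenograft
    line inherits the tumor's events; each passage adds Poisson(drift)
    subclonal events. At the split passage the line branches into lineage
    B, after which the two lineages drift independently — so
    different-lineage pairs accumulate roughly twice the drift of
    equal-distance same-lineage pairs.
    """
    founder = _draw_events(cfg, rng, cfg.events_per_genome, fraction=1.0)
    for ev in shared_events or []:
        if rng.random() < cfg.recurrent_event_prob:
            founder = founder + [ev]
    minor_frac = cfg.clone_proportions[1] if len(cfg.clone_proportions) > 1 else 0.0
    subclonal = (
        _draw_events(cfg, rng, cfg.subclonal_events, fraction=minor_frac)
        if minor_frac > 0
        else []
    )
    tumor_events = founder + subclonal

    def _truth(sample_id: str, sample_class: str, passage, lineage, events, stroma) -> SampleTruth:
        segs = _bulk_segments(events, cfg.genome)
        return SampleTruth(
            sample_id=sample_id, model_id=model_id, sample_class=sample_class,
            passage=passage, lineage_id=lineage, events=list(events),
            stromal_fraction=stroma, gene_log2=_gene_truth(segs, genes),
        )

    pt_stroma = float(rng.beta(*cfg.pt_stroma_beta))
    samples = [
        _truth(f"{model_id}-PT", "PT", None, None, tumor_events, pt_stroma)
    ]
    edges = []

    def _drift(rate: float) -> list[Event]:
        return _draw_events(cfg, rng, rate, fraction=cfg.drift_fraction_range)

    # lineage A: P0 .. Pn; lineage B branches from A at the split passage
    events_a = list(tumor_events) + _drift(cfg.drift_rate)  # engraftment = P0
    lineage_samples: dict[tuple[str, int], list[Event]] = {("A", 0): list(events_a)}
    prev = f"{model_id}-P0A"
    samples.append(_truth(prev, "PDX", 0, "A", events_a, cfg.pdx_stroma))
    edges.append((samples[0].sample_id, prev))

    events_b: Optional[list[Event]] = None
    prev_b: Optional[str] = None
    for p in range(1, cfg.n_passages + 1):
        events_a = list(events_a) + _drift(cfg.drift_rate)
        sid = f"{model_id}-P{p}A"
        samples.append(_truth(sid, "PDX", p, "A", events_a, cfg.pdx_stroma))
        edges.append((prev, sid))
        prev = sid
        if p == cfg.split_passage:
            # the tumor was divided: lineage B starts from A's previous state
            parent = lineage_samples[("A", p - 1)]
            events_b = list(parent) + _drift(cfg.drift_rate)
            sid_b = f"{model_id}-P{p}B"
            samples.append(_truth(sid_b, "PDX", p, "B", events_b, cfg.pdx_stroma))
            edges.append((f"{model_id}-P{p-1}A", sid_b))
            prev_b = sid_b
        elif events_b is not None and p > cfg.split_passage:
            events_b = list(events_b) + _drift(cfg.drift_rate)
            sid_b = f"{model_id}-P{p}B"
            samples.append(_truth(sid_b, "PDX", p, "B", events_b, cfg.pdx_stroma))
            edges.append((prev_b, sid_b))
            prev_b = sid_b
        lineage_samples[("A", p)] = list(events_a)
    return samples, edges


def render_platform(
    truth: SampleTruth,
    platform: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> SegmentProfile:
    """Render a truth sample as an observed segment profile.

    Stromal mixing happens on the linear copy scale before the log
    transform; segments below the platform resolution floor are merged
    into their longer neighbor; Gaussian noise is added per segment mean;
    log2 ratios are clipped to the platform dynamic range.
    """
    pm = cfg.platform_models[platform]
    f = truth.stromal_fraction
    segs = _bulk_segments(truth.events, cfg.genome)
    obs_cn = (1.0 - f) * segs["cn"].to_numpy() + 2.0 * f
    segs = segs.assign(log2_ratio=np.log2(obs_cn / 2.0)).drop(columns="cn")

    rows = []
    for chrom, sub in segs.groupby("chrom", sort=False):
        starts = list(sub["start"])
        ends = list(sub["end"])
        vals = list(sub["log2_ratio"])
        # merge sub-resolution segments into the longer neighbor
        changed = True
        while changed and len(starts) > 1:
            changed = False
            lengths = [e - s for s, e in zip(starts, ends)]
            i = int(np.argmin(lengths))
            if lengths[i] < pm.resolution_bp:
                left = lengths[i - 1] if i > 0 else -1
                right = lengths[i + 1] if i < len(starts) - 1 else -1
                j = i - 1 if left >= right else i + 1
                lo, hi = min(i, j), max(i, j)
                starts[lo:hi + 1] = [starts[lo]]
                keep_val = vals[j]
                ends[lo:hi + 1] = [ends[hi]]
                vals[lo:hi + 1] = [keep_val]
                changed = True
        # coalesce equal-valued neighbors left over from merging
        fused: list[list] = []
        for s, e, v in zip(starts, ends, vals):
            if fused and abs(fused[-1][2] - v) < 1e-12 and fused[-1][1] == s:
                fused[-1][1] = e
            else:
                fused.append([s, e, v])
        for s, e, v in fused:
            rows.append({"chrom": chrom, "start": s, "end": e, "log2_ratio": v})
    out = pd.DataFrame(rows)
    noise = rng.normal(0.0, pm.sigma, size=len(out))
    out["log2_ratio"] = np.clip(out["log2_ratio"] + noise, pm.log2_min, pm.log2_max)
    if pm.probe_spacing_bp:
        out["n_probes"] = ((out["end"] - out["start"]) // pm.probe_spacing_bp).astype(int)
    else:
        out["n_probes"] = pd.NA
    return SegmentProfile(truth.sample_id, out)


def render_gene_profile(
    truth: SampleTruth, sigma: float, rng: np.random.Generator,
    stroma: Optional[float] = None,
) -> GeneCopyProfile:
    """Directly render noisy gene-level log2 ratios (platform-free)."""
    f = truth.stromal_fraction if stroma is None else stroma
    cn = 2.0 * 2.0 ** truth.gene_log2.to_numpy()
    obs = (1.0 - f) * cn + 2.0 * f
    vals = np.log2(obs / 2.0) + rng.normal(0.0, sigma, size=len(obs))
    return GeneCopyProfile(truth.sample_id, pd.Series(vals, index=truth.gene_log2.index))


def render_expression(
    truth: TruthSet,
    cfg: SimulationConfig,
    seed: int = 0,
    sample_ids: Optional[list[str]] = None,
):
    """CN-coupled expression for tumor samples plus matched normals.

    Tumor log2 expression = per-gene baseline + true gene log2 ratio +
    noise; normals carry baseline + noise only. A ``decoupled_fraction``
    of genes ignores copy number entirely. Returns an
    :class:`~cnafid.core.ExpressionMatrix` in TPM units.
    """
    from .core import ExpressionMatrix

    rng = np.random.default_rng(seed)
    genes = truth.genes
    n = len(genes)
    mu, sd = cfg.expression_baseline
    baseline = rng.normal(mu, sd, size=n)
    coupled = rng.random(n) >= cfg.decoupled_fraction

    ids = sample_ids if sample_ids is not None else list(truth.samples)
    cols = {}
    classes = {}
    for sid in ids:
        t = truth.samples[sid]
        log2 = baseline + np.where(coupled, t.gene_log2.to_numpy(), 0.0)
        log2 = log2 + rng.normal(0.0, cfg.expression_sigma, size=n)
        cols[sid] = 2.0 ** log2
        classes[sid] = "tumor"
    for i in range(cfg.n_normals):
        nid = f"NORMAL-{i:02d}"
        cols[nid] = 2.0 ** (baseline + rng.normal(0.0, cfg.expression_sigma, size=n))
        classes[nid] = "normal"

    index = pd.Index(genes["gene_id"], name="feature_id")
    values = pd.DataFrame(cols, index=index)
    info = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "chrom": genes["chrom"].to_numpy(),
            "start": genes["start"].to_numpy(),
            "end": genes["end"].to_numpy(),
        },
        index=index,
    )
    return ExpressionMatrix(values=values, feature_info=info,
                            sample_class=pd.Series(classes), unit="TPM")


def simulate_cohort(cfg: SimulationConfig, seed: int = 0) -> SimulatedCohort:
    """Simulate a multi-model cohort with platform-rendered DNA profiles."""
    rng = np.random.default_rng(seed)
    genes = synthetic_genes(cfg.genome, cfg.n_genes)
    shared = _draw_events(cfg, rng, cfg.recurrent_events, fraction=1.0)
    records: list[SampleRecord] = []
    profiles: dict[str, SegmentProfile] = {}
    samples: dict[str, SampleTruth] = {}
    edges: list[tuple[str, str]] = []
    for m in range(cfg.n_models):
        model_id = f"M{m:03d}"
        platform = cfg.platforms[m % len(cfg.platforms)]
        truths, model_edges = simulate_model(cfg, genes, model_id, platform, rng,
                                             shared_events=shared)
        edges.extend(model_edges)
        for t in truths:
            samples[t.sample_id] = t
            profiles[t.sample_id] = render_platform(t, platform, cfg, rng)
            records.append(
                SampleRecord(
                    sample_id=t.sample_id, model_id=model_id,
                    patient_id=f"PA{m:03d}", tumor_type="CRC", center="SIM",
                    sample_class=t.sample_class, passage=t.passage,
                    lineage_id=t.lineage_id, platform=platform,
                )
            )
    truth = TruthSet(genome=dict(cfg.genome), genes=genes, samples=samples,
                     lineage_edges=edges)
    return SimulatedCohort(config=cfg, records=records, profiles=profiles,
                           truth=truth, genes=genes)
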