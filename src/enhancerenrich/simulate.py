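"""Synthetic genomes, enhancer sets and two-cohort GWAS summary statistics.

The generator emulates the statistical structure of a two-cohort dairy
cattle study: a genome of uniformly placed SNPs, named enhancer interval
sets covering a configurable genome fraction, a sparse set of causal
variants whose density inside a designated set is inflated by a known
fold, and per-cohort summary statistics in which both cohorts share the
causal signal but carry independent noise of cohort-specific magnitude
(cows' phenotypes being noisier than bulls' daughter-based ones).

Summary statistics are simulated directly — no genotypes and no linkage
disequilibrium. Per SNP and cohort the observed z-statistic is

    z = (true effect / noise_scale) + standard normal noise,

reported as ``beta = z * noise_scale`` with a two-sided normal P value, so
the implied standard error is exactly ``noise_scale`` and the planted
ground truth makes every downstream stage testable in closed form: with a
single enriched set of SNP fraction ``f`` and fold ``lam``, the expected
share of causal SNPs inside the set is ``lam*f / (lam*f + (1-f))``.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Gene, GeneModel
from .intervals import GenomicInterval, IntervalSet, merge_intervals, snps_in_intervals

__all__ = [
    "EnhancerSetSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedStudy",
    "simulate_truth",
    "simulate_cohort_stats",
    "simulate_study",
]


@dataclass(frozen=True)
class EnhancerSetSpec:
    """One enhancer set to plant: genome fraction covered and the relative
    risk of a SNP inside it being causal (1.0 = no enrichment)."""

    name: str
    genome_fraction: float = 0.05
    enrichment_fold: float = 1.0
    mean_length: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.genome_fraction < 1.0):
            raise ValueError(f"set {self.name}: genome_fraction must be in (0, 1)")
        if self.enrichment_fold < 0:
            raise ValueError(f"set {self.name}: enrichment_fold must be >= 0")
        if self.mean_length < 1:
            raise ValueError(f"set {self.name}: mean_length must be >= 1")


def _default_sets() -> tuple[EnhancerSetSpec, ...]:
    return (
        EnhancerSetSpec("enriched", genome_fraction=0.05, enrichment_fold=3.0),
        EnhancerSetSpec("decoy", genome_fraction=0.05, enrichment_fold=1.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the reference scenario used throughout the test
    suite: a 10-Mb genome of 100,000 SNPs, one 3-fold-enriched enhancer set
    and one matched decoy each covering 5% of the genome, 1% causal
    variants with effect scale 1.4, and bull/cow noise scales 0.08/0.12 —
    chosen so that roughly 200 variants clear the 1e-8 genome-wide
    threshold after meta-analysis.
    """

    n_chrom: int = 10
    chrom_length: int = 1_000_000
    n_snps: int = 100_000
    sets: tuple[EnhancerSetSpec, ...] = field(default_factory=_default_sets)
    causal_fraction: float = 0.01
    effect_scale: float = 1.4
    cohort_noise: tuple[tuple[str, float], ...] = (("bulls", 0.08), ("cows", 0.12))
    genes_per_chrom: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.causal_fraction < 1.0):
            raise ValueError("causal_fraction must be in (0, 1)")
        if self.effect_scale <= 0:
            raise ValueError("effect_scale must be > 0")
        if self.n_snps > self.n_chrom * self.chrom_length:
            raise ValueError("more SNPs requested than genome positions")
        for _, noise in self.cohort_noise:
            if noise <= 0:
                raise ValueError("noise_scale must be > 0")
        total_f = sum(s.genome_fraction for s in self.sets)
        if total_f > 0.9:
            raise ValueError(
                f"enhancer sets request {total_f:.2f} of the genome; infeasible"
            )
        for s in self.sets:
            if s.mean_length >= self.chrom_length:
                raise ValueError(f"set {s.name}: mean_length exceeds chromosome length")

    @property
    def genome_bp(self) -> int:
        return self.n_chrom * self.chrom_length


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation, sufficient to recompute every
    planted expectation."""

    seed: int
    causal_snp_ids: list[str]
    causal_effects: dict[str, float]
    set_folds: dict[str, float]
    realised_fraction: dict[str, float]  # fraction of SNPs inside each set
    expected_causal_share: dict[str, float]  # E[share of causal SNPs inside]
    causal_fraction: float
    effect_scale: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulatedStudy:
    """A simulated dataset: SNP map, enhancer sets, gene model, truth and
    (optionally) per-cohort summary-statistic tables."""

    config: SimulationConfig
    snps: pd.DataFrame  # snp_id, chrom, pos (1-based), causal, effect
    interval_sets: dict[str, IntervalSet]
    gene_model: GeneModel
    truth: SyntheticTruth
    cohorts: dict[str, pd.DataFrame] = field(default_factory=dict)


def _place_snps(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    lengths = np.full(config.n_chrom, config.chrom_length)
    counts = rng.multinomial(config.n_snps, lengths / lengths.sum())
    rows = []
    for ci, n_i in enumerate(counts):
        chrom = str(ci + 1)
        pos0 = rng.choice(config.chrom_length, size=n_i, replace=False)
        pos0.sort()
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos0 + 1}))
    snps = pd.concat(rows, ignore_index=True)
    snps.insert(0, "snp_id", [f"snp{i:07d}" for i in range(len(snps))])
    return snps


def _place_set(
    spec: EnhancerSetSpec, config: SimulationConfig, rng: np.random.Generator
) -> IntervalSet:
    target_bp = spec.genome_fraction * config.genome_bp
    n_iv = max(1, int(round(target_bp / spec.mean_length)))
    lengths = np.clip(
        rng.normal(spec.mean_length, 0.3 * spec.mean_length, size=n_iv), 100, None
    ).astype(int)
    chroms = rng.integers(1, config.n_chrom + 1, size=n_iv)
    ivs = []
    for chrom, length in zip(chroms, lengths):
        length = min(int(length), config.chrom_length - 1)
        start = int(rng.integers(0, config.chrom_length - length))
        ivs.append(GenomicInterval(str(chrom), start, start + length, spec.name))
    return merge_intervals(ivs, spec.name)


def _split_transcript(
    exons: list[tuple[int, int]], strand: str, u5: int, u3: int
) -> tuple[list, list, list]:
    """Split exonic sequence into 5'-UTR / CDS / 3'-UTR genomic intervals,
    taking the first ``u5`` and last ``u3`` transcript bp as UTRs."""
    total = sum(e - s for s, e in exons)
    if total <= u5 + u3 + 3:
        return [], [], []
    lo, hi = (u5, total - u3) if strand == "+" else (u3, total - u5)
    utr_left, cds, utr_right = [], [], []
    offset = 0
    for s, e in exons:
        length = e - s
        a, b = offset, offset + length  # transcript coords of this exon
        for t0, t1, bucket in ((0, lo, utr_left), (lo, hi, cds), (hi, total, utr_right)):
            ov0, ov1 = max(a, t0), min(b, t1)
            if ov0 < ov1:
                bucket.append((s + ov0 - a, s + ov1 - a))
        offset = b
    if strand == "+":
        return utr_left, cds, utr_right
    return utr_right, cds, utr_left


def _make_gene_model(config: SimulationConfig, rng: np.random.Generator) -> GeneModel:
    genes = []
    span, n_exons, exon_len = 12_000, 4, 300
    for ci in range(config.n_chrom):
        chrom = str(ci + 1)
        starts = rng.choice(
            max(1, config.chrom_length - span), size=config.genes_per_chrom, replace=False
        )
        starts.sort()
        prev_end = -1
        for gi, gs in enumerate(starts):
            gs = int(gs)
            if gs <= prev_end:  # keep genes disjoint for a clean model
                continue
            ge = gs + span
            gaps = np.linspace(gs, ge - exon_len, n_exons).astype(int)
            exons = [(int(s), int(s) + exon_len) for s in gaps]
            strand = "+" if rng.random() < 0.5 else "-"
            coding = rng.random() < 0.8
            utr5, cds, utr3 = ([], [], [])
            if coding:
                utr5, cds, utr3 = _split_transcript(exons, strand, 100, 150)
            genes.append(
                Gene(
                    gene_id=f"gene_{chrom}_{gi}",
                    chrom=chrom,
                    strand=strand,
                    start=gs,
                    end=ge,
                    exons=exons,
                    cds=cds,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
            prev_end = ge
    return GeneModel(genes)


def simulate_truth(config: SimulationConfig) -> SimulatedStudy:
    """Generate the SNP map, enhancer sets, gene model and causal ground
    truth (no cohort statistics yet).

    A SNP's probability of being causal is proportional to its relative
    risk — the largest enrichment fold among the sets containing it, 1
    outside all sets — normalised so that the overall expected causal
    fraction equals ``causal_fraction``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_map, rng_sets, rng_genes, rng_causal = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    snps = _place_snps(config, rng_map)
    interval_sets = {spec.name: _place_set(spec, config, rng_sets) for spec in config.sets}
    gene_model = _make_gene_model(config, rng_genes)

    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy()
    member = {
        name: snps_in_intervals(chrom_arr, pos_arr, iset)
        for name, iset in interval_sets.items()
    }
    risk = np.ones(len(snps))
    for spec in config.sets:
        m = member[spec.name]
        risk[m] = np.maximum(risk[m], spec.enrichment_fold)
    p_causal = np.minimum(config.causal_fraction * risk / risk.mean(), 1.0)
    causal = rng_causal.random(len(snps)) < p_causal
    effect = np.zeros(len(snps))
    effect[causal] = rng_causal.normal(0.0, config.effect_scale, size=int(causal.sum()))
    snps = snps.assign(causal=causal, effect=effect)

    total_p = p_causal.sum()
    truth = SyntheticTruth(
        seed=config.seed,
        causal_snp_ids=list(snps.loc[causal, "snp_id"]),
        causal_effects={
            sid: float(eff) for sid, eff in zip(snps.loc[causal, "snp_id"], effect[causal])
        },
        set_folds={s.name: s.enrichment_fold for s in config.sets},
        realised_fraction={
            name: float(m.mean()) for name, m in member.items()
        },
        expected_causal_share={
            name: float(p_causal[m].sum() / total_p) for name, m in member.items()
        },
        causal_fraction=config.causal_fraction,
        effect_scale=config.effect_scale,
    )
    return SimulatedStudy(config, snps, interval_sets, gene_model, truth)


def simulate_cohort_stats(
    study: SimulatedStudy,
    cohort: str,
    noise_scale: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Per-cohort GWAS summary table (snp_id, chrom, pos, beta, p).

    The implied standard error equals ``noise_scale`` for every SNP, and
    non-causal SNPs have uniform two-sided P values.
    """
    if noise_scale <= 0:
        raise ValueError("noise_scale must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = study.snps["effect"].to_numpy() / noise_scale + rng.standard_normal(len(study.snps))
    beta = z * noise_scale
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "snp_id": study.snps["snp_id"],
            "chrom": study.snps["chrom"],
            "pos": study.snps["pos"],
            "beta": beta,
            "p": p,
        }
    )


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full simulation: truth plus one summary-statistic table per cohort,
    sharing causal effects but with independent cohort noise."""
    study = simulate_truth(config)
    ss = np.random.SeedSequence(config.seed)
    # child streams 4+ are reserved for cohorts (0-3 used inside simulate_truth)
    children = ss.spawn(4 + len(config.cohort_noise))[4:]
    for (label, noise), child in zip(config.cohort_noise, children):
        study.cohorts[label] = simulate_cohort_stats(
            study, label, noise, np.random.default_rng(child)
        )
    return study


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write cohort TSVs, enhancer BEDs, the gene model and the truth JSON."""
    from .annotation import write_gff3
    from .intervals import write_bed

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for label, df in study.cohorts.items():
        paths[f"cohort:{label}"] = p = out / f"cohort_{label}.tsv"
        # %.17g round-trips float64 exactly; the default 16 digits do not
        df.to_csv(p, sep="\t", index=False, float_format="%.17g")
    for name, iset in study.interval_sets.items():
        paths[f"bed:{name}"] = p = out / f"{name}.bed"
        write_bed(iset, p)
    paths["genes"] = out / "genes.gff3"
    write_gff3(study.gene_model, paths["genes"])
    paths["truth"] = out / "truth.json"
    study.truth.to_json(paths["truth"])
    return paths
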