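"""Orchestration of the full enrichment analysis.

One run covers the cross of traits x enhancer sets (the shape of a
multi-phenotype, multi-database study): per trait a two-cohort
meta-analysis, then for every enhancer set one permutation test and one
running-sum (GSEA) test, plus derived set rows (the two-mark overlap and
each mark-specific remainder) when a pair of sets is nominated, an
overlap-percentage matrix across all sets, core-SNP lists for significant
GSEA results only, and a manifest that makes the run reproducible.

Per-analysis random streams are derived from the master seed and the
(trait, set, test) labels, so adding an analysis never perturbs the
results of the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .gsea import GseaResult, gsea_for_set
from .intervals import (
    IntervalSet,
    cluster_merge,
    intersect_sets,
    overlap_percentage_matrix,
    read_bed,
    subtract_sets,
)
from .meta import meta_analyse, read_cohort_table, write_meta_table
from .permutation import PermutationResult, permutation_test_for_set

__all__ = ["RunConfig", "SuiteResult", "enrichment_suite", "run_enrichment_suite", "seed_for"]

logger = logging.getLogger(__name__)


def seed_for(master_seed: int, *labels: str) -> int:
    """A 31-bit child seed derived from the master seed and string labels.

    Stable across runs and machines; independent analyses get independent
    streams keyed by their own labels.
    """
    digest = hashlib.sha256(
        ("/".join([str(master_seed), *labels])).encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Configuration of one enrichment-suite run."""

    cohort_paths: dict[str, dict[str, str]]  # trait -> cohort label -> TSV path
    set_paths: dict[str, str]  # set name -> BED path
    derive_pair: tuple[str, str] | None = None  # build specific/overlap subsets
    expand: dict[str, int] = field(default_factory=dict)  # set name -> cluster gap
    threshold: float = 1e-8
    n_perm: int = 10_000
    se_mode: str = "two-sided"
    weight_exponent: int = 1
    min_overlap: int = 0
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.cohort_paths:
            raise ValueError("at least one trait is required")
        if not self.set_paths:
            raise ValueError("at least one enhancer set is required")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class SuiteResult:
    """In-memory results of one suite run."""

    permutation: dict[tuple[str, str], PermutationResult]
    gsea: dict[tuple[str, str], GseaResult]
    meta_by_trait: dict[str, pd.DataFrame]
    filter_counts: dict[str, dict[str, int]]
    overlap: pd.DataFrame

    def permutation_table(self) -> pd.DataFrame:
        rows = [
            {"trait": trait, **res.to_row()}
            for (trait, _), res in self.permutation.items()
        ]
        return pd.DataFrame(rows)

    def gsea_table(self) -> pd.DataFrame:
        rows = [{"trait": trait, **res.to_row()} for (trait, _), res in self.gsea.items()]
        return pd.DataFrame(rows)


def derive_subsets(sets: dict[str, IntervalSet], pair: tuple[str, str]) -> dict[str, IntervalSet]:
    """Specific-only and overlap subsets for a nominated pair of sets."""
    a, b = pair
    if a not in sets or b not in sets:
        raise ValueError(f"derive pair {pair} not among loaded sets {sorted(sets)}")
    return {
        f"{a}-specific": subtract_sets(sets[a], sets[b], name=f"{a}-specific"),
        f"{b}-specific": subtract_sets(sets[b], sets[a], name=f"{b}-specific"),
        f"{a}&{b}": intersect_sets(sets[a], sets[b], name=f"{a}&{b}"),
    }


def enrichment_suite(
    meta_by_trait: Mapping[str, pd.DataFrame],
    sets: Mapping[str, IntervalSet],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Permutation + GSEA for every trait x set combination.

    Degenerate analyses (e.g. a set containing no SNPs) are recorded as
    ``None`` for that row instead of aborting the suite.
    """
    perm_results: dict[tuple[str, str], PermutationResult | None] = {}
    gsea_results: dict[tuple[str, str], GseaResult | None] = {}
    for trait, meta in meta_by_trait.items():
        for name, iset in sets.items():
            try:
                perm_results[(trait, name)] = permutation_test_for_set(
                    meta, iset, n_perm=n_perm, seed=seed_for(seed, trait, name, "perm")
                )
            except ValueError as exc:
                logger.warning("permutation %s x %s skipped: %s", trait, name, exc)
                perm_results[(trait, name)] = None
            try:
                gsea_results[(trait, name)] = gsea_for_set(
                    meta, iset, n_perm=n_perm, seed=seed_for(seed, trait, name, "gsea")
                )
            except ValueError as exc:
                logger.warning("gsea %s x %s skipped: %s", trait, name, exc)
                gsea_results[(trait, name)] = None
    return perm_results, gsea_results


def run_enrichment_suite(config: RunConfig) -> SuiteResult:
    """Run the full analysis from files and write all report files.

    Outputs under ``config.out_dir``: per-trait meta-analysis TSVs,
    ``permutation.tsv``, ``gsea.tsv``, ``overlap_matrix.tsv``, core-SNP
    lists for significant GSEA rows only, and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sets: dict[str, IntervalSet] = {}
    for name, path in config.set_paths.items():
        sets[name] = read_bed(path, name=name)
    for name, gap in config.expand.items():
        if name not in sets:
            raise ValueError(f"expand refers to unknown set {name!r}")
        sets[f"{name}-expanded"] = cluster_merge(sets[name], gap, name=f"{name}-expanded")
    base_names = list(sets)
    if config.derive_pair is not None:
        sets.update(derive_subsets(sets, tuple(config.derive_pair)))

    overlap = overlap_percentage_matrix([sets[n] for n in base_names]).to_dataframe()
    overlap.to_csv(out / "overlap_matrix.tsv", sep="\t")

    meta_by_trait: dict[str, pd.DataFrame] = {}
    filter_counts: dict[str, dict[str, int]] = {}
    for trait, cohort_paths in config.cohort_paths.items():
        cohorts = {label: read_cohort_table(p) for label, p in cohort_paths.items()}
        meta, counts = meta_analyse(
            cohorts,
            se_mode=config.se_mode,
            weight_exponent=config.weight_exponent,
            threshold=config.threshold,
        )
        meta_by_trait[trait] = meta
        filter_counts[trait] = counts
        write_meta_table(meta, out / f"meta_{trait}.tsv")

    perm_results, gsea_results = enrichment_suite(
        meta_by_trait, sets, n_perm=config.n_perm, seed=config.seed
    )

    perm_rows, gsea_rows = [], []
    for (trait, name), res in perm_results.items():
        row = {"trait": trait, "set": name}
        if res is None:
            row["p"] = "NA"
        else:
            row.update(res.to_row())
        perm_rows.append(row)
    for (trait, name), res in gsea_results.items():
        row = {"trait": trait, "set": name}
        if res is None:
            row["significant"] = "NA"
        else:
            row.update(res.to_row())
            if res.significant:
                core_path = out / f"core_snps_{trait}_{name}.txt"
                core_path.write_text("\n".join(map(str, res.core_snp_ids)) + "\n")
        gsea_rows.append(row)
    pd.DataFrame(perm_rows).to_csv(out / "permutation.tsv", sep="\t", index=False)
    pd.DataFrame(gsea_rows).to_csv(out / "gsea.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "threshold": config.threshold,
        "se_mode": config.se_mode,
        "weight_exponent": config.weight_exponent,
        "traits": {t: dict(p) for t, p in config.cohort_paths.items()},
        "sets": dict(config.set_paths),
        "derive_pair": list(config.derive_pair) if config.derive_pair else None,
        "expand": dict(config.expand),
        "filter_counts": filter_counts,
        "child_seeds": {
            f"{trait}/{name}/{test}": seed_for(config.seed, trait, name, test)
            for trait in meta_by_trait
            for name in sets
            for test in ("perm", "gsea")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return SuiteResult(
        permutation=perm_results,
        gsea=gsea_results,
        meta_by_trait=meta_by_trait,
        filter_counts=filter_counts,
        overlap=overlap,
    )
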