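"""Inverse-variance meta-analysis of two-cohort GWAS summary statistics.

The pipeline consumes per-SNP effect sizes (beta) and P values from each
gender cohort (e.g. bulls scored on daughter trait deviations and cows on
trait deviations), reconstructs a standard error per cohort from (beta, p),
combines the cohorts with inverse-variance weights, and recomputes a
combined P value:

    se_ij   = |beta_ij| / z(p_ij)          (z from the normal quantile)
    w_ij    = 1 / se_ij**weight_exponent   (weight_exponent = 1 as published)
    bhat_ij = beta_ij * w_ij
    bt_i    = sum_j bhat_ij / sum_j w_ij
    vt_i    = sqrt(n / sum_j w_ij)         (n = number of cohorts)
    pt_i    = 2 * (1 - Phi(|bt_i / vt_i|))

Two readings of the quantile in se_ij are supported (``se_mode``):

* ``"two-sided"`` (default): z = Phi^-1(1 - p/2), treating the GWAS P value
  as two-sided. Under this mode with ``weight_exponent=2`` a single-cohort
  meta-analysis reproduces the input P value exactly.
* ``"as-written"``: z = Phi^-1(p), the literal published formula (inside an
  absolute value). p = 0.5 then has no usable quantile and the variant is
  flagged for removal.

Variants with no effect (beta = 0) or P = 1 carry no reconstructible
standard error and are removed before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSnpStat",
    "MetaSnpResult",
    "standard_error",
    "combine_cohorts",
    "meta_p_value",
    "filter_and_flag",
    "meta_analyse",
    "read_cohort_table",
    "write_meta_table",
    "COHORT_COLUMNS",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["snp_id", "chrom", "pos", "beta", "p"]

SE_MODES = ("two-sided", "as-written")


@dataclass(frozen=True)
class CohortSnpStat:
    """One SNP's association summary in one cohort."""

    snp_id: str
    chrom: str
    pos: int
    cohort: str
    beta: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.snp_id}/{self.cohort}: P value {self.p} outside (0, 1]")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}/{self.cohort}: non-finite beta")


@dataclass
class MetaSnpResult:
    """Meta-analysed effect, dispersion and P value for one SNP."""

    snp_id: str
    chrom: str
    pos: int
    tilde_beta: float
    tilde_v: float
    tilde_p: float | None = None
    n_cohorts: int = 0
    se_by_cohort: dict[str, float] = field(default_factory=dict)
    w_by_cohort: dict[str, float] = field(default_factory=dict)
    hat_beta_by_cohort: dict[str, float] = field(default_factory=dict)
    significant: bool | None = None


def standard_error(beta, p, mode: str = "two-sided"):
    """Standard error reconstructed from (beta, p); NaN marks a variant that
    cannot yield one (beta = 0, p = 1, or p = 0.5 in as-written mode) and is
    removed downstream.

    Accepts scalars or arrays; returns the same shape.
    """
    if mode not in SE_MODES:
        raise ValueError(f"se mode must be one of {SE_MODES}, got {mode!r}")
    beta_arr = np.asarray(beta, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "two-sided":
            z = stats.norm.isf(p_arr / 2.0)
        else:
            z = stats.norm.ppf(p_arr)
        se = np.abs(beta_arr / z)
    bad = (p_arr >= 1.0) | (p_arr <= 0.0) | (beta_arr == 0.0) | (z == 0.0) | ~np.isfinite(se)
    se = np.where(bad, np.nan, se)
    if np.ndim(beta) == 0 and np.ndim(p) == 0:
        return float(se)
    return se


def combine_cohorts(
    records: Sequence[CohortSnpStat],
    se_mode: str = "two-sided",
    weight_exponent: int = 1,
) -> MetaSnpResult | None:
    """Combine one SNP's per-cohort statistics into a meta-analysed effect.

    Returns ``None`` (with a log entry) when no cohort yields a valid
    standard error. Cohort order does not affect the result. ``tilde_p`` is
    left unset; apply :func:`meta_p_value` next.
    """
    if not records:
        raise ValueError("combine_cohorts needs at least one cohort record")
    snp_id = records[0].snp_id
    for rec in records[1:]:
        if rec.snp_id != snp_id:
            raise ValueError(f"mixed snp_ids in one combine call: {snp_id} vs {rec.snp_id}")
        if (rec.chrom, rec.pos) != (records[0].chrom, records[0].pos):
            raise ValueError(
                f"snp {snp_id}: cohorts disagree on position "
                f"({records[0].chrom}:{records[0].pos} vs {rec.chrom}:{rec.pos})"
            )
    se_by, w_by, bhat_by = {}, {}, {}
    for rec in records:
        se = standard_error(rec.beta, rec.p, se_mode)
        if np.isnan(se):
            continue
        se_by[rec.cohort] = se
        w_by[rec.cohort] = 1.0 / se**weight_exponent
        bhat_by[rec.cohort] = rec.beta * w_by[rec.cohort]
    if not se_by:
        logger.info("snp %s dropped: no cohort with a valid standard error", snp_id)
        return None
    n = len(se_by)
    sum_w = sum(w_by.values())
    tilde_beta = sum(bhat_by.values()) / sum_w
    tilde_v = float(np.sqrt(n / sum_w))
    return MetaSnpResult(
        snp_id=snp_id,
        chrom=records[0].chrom,
        pos=records[0].pos,
        tilde_beta=tilde_beta,
        tilde_v=tilde_v,
        n_cohorts=n,
        se_by_cohort=se_by,
        w_by_cohort=w_by,
        hat_beta_by_cohort=bhat_by,
    )


def meta_p_value(tilde_beta, tilde_v):
    """Two-sided normal P value for the combined effect, 2*(1 - Phi(|bt/vt|))."""
    tb = np.asarray(tilde_beta, dtype=float)
    tv = np.asarray(tilde_v, dtype=float)
    if np.any(tv <= 0):
        raise ValueError("tilde_v must be > 0")
    p = 2.0 * stats.norm.sf(np.abs(tb / tv))
    p = np.minimum(p, 1.0)
    if np.ndim(tilde_beta) == 0 and np.ndim(tilde_v) == 0:
        return float(p)
    return p


def filter_and_flag(
    results: pd.DataFrame,
    threshold: float = 1e-8,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove untestable variants and flag genome-wide significance.

    Removes rows with ``tilde_beta == 0``, ``tilde_p == 1`` or missing
    values; flags the rest significant iff ``tilde_p <= threshold``. Returns
    the filtered frame plus removal bookkeeping counts.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    n_in = len(results)
    bad = (
        results["tilde_beta"].isna()
        | results["tilde_p"].isna()
        | (results["tilde_beta"] == 0.0)
        | (results["tilde_p"] >= 1.0)
    )
    out = results.loc[~bad].copy()
    out["significant"] = out["tilde_p"] <= threshold
    counts = {
        "input_variants": n_in,
        "removed_variants": int(bad.sum()),
        "variants_tested": len(out),
        "significant_variants": int(out["significant"].sum()),
    }
    logger.info(
        "meta filter: %(input_variants)d in, %(removed_variants)d removed, "
        "%(variants_tested)d tested, %(significant_variants)d significant",
        counts,
    )
    return out, counts


def meta_analyse(
    cohorts: Mapping[str, pd.DataFrame],
    se_mode: str = "two-sided",
    weight_exponent: int = 1,
    threshold: float = 1e-8,
    single_cohort: str = "keep",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Vectorised meta-analysis of whole cohort tables.

    ``cohorts`` maps a cohort label to a table with columns
    ``snp_id, chrom, pos, beta, p``. SNPs present in only one cohort are
    combined with n = 1 when ``single_cohort="keep"`` (the formulas degrade
    gracefully) or dropped with ``"drop"``. A SNP whose cohorts disagree on
    (chrom, pos) is an error. Any cohort record without a valid standard
    error removes the variant, matching the published filtering rule.

    Returns the filtered, flagged result table (columns ``snp_id, chrom,
    pos, tilde_beta, tilde_v, tilde_p, n_cohorts, significant``) and the
    filter bookkeeping counts.
    """
    if single_cohort not in ("keep", "drop"):
        raise ValueError("single_cohort must be 'keep' or 'drop'")
    frames = []
    for label, df in cohorts.items():
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort {label!r}: missing columns {missing}")
        sub = df[COHORT_COLUMNS].copy()
        sub["cohort"] = label
        frames.append(sub)
    stacked = pd.concat(frames, ignore_index=True)
    if stacked.duplicated(["snp_id", "cohort"]).any():
        dup = stacked[stacked.duplicated(["snp_id", "cohort"], keep=False)]["snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id within one cohort: {dup!r}")
    pos_check = stacked.groupby("snp_id")[["chrom", "pos"]].nunique()
    clash = pos_check[(pos_check["chrom"] > 1) | (pos_check["pos"] > 1)]
    if len(clash):
        raise ValueError(
            f"cohorts disagree on (chrom, pos) for snp_id(s) {list(clash.index[:5])}"
        )

    stacked["se"] = standard_error(stacked["beta"].to_numpy(), stacked["p"].to_numpy(), se_mode)
    # any invalid cohort record poisons the variant (published removal rule)
    invalid_ids = stacked.loc[stacked["se"].isna(), "snp_id"].unique()
    stacked["w"] = 1.0 / stacked["se"] ** weight_exponent
    stacked["bhat"] = stacked["beta"] * stacked["w"]

    grp = stacked.groupby("snp_id", sort=True)
    agg = grp.agg(
        chrom=("chrom", "first"),
        pos=("pos", "first"),
        sum_w=("w", "sum"),
        sum_bhat=("bhat", "sum"),
        n_cohorts=("cohort", "size"),
    ).reset_index()
    agg.loc[agg["snp_id"].isin(invalid_ids), ["sum_w", "sum_bhat"]] = np.nan
    if single_cohort == "drop":
        agg = agg[agg["n_cohorts"] > 1].reset_index(drop=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["tilde_beta"] = agg["sum_bhat"] / agg["sum_w"]
        agg["tilde_v"] = np.sqrt(agg["n_cohorts"] / agg["sum_w"])
        z = np.abs(agg["tilde_beta"] / agg["tilde_v"])
    agg["tilde_p"] = np.where(np.isfinite(z), 2.0 * stats.norm.sf(z), np.nan)
    agg["tilde_p"] = np.minimum(agg["tilde_p"], 1.0)
    result = agg[["snp_id", "chrom", "pos", "tilde_beta", "tilde_v", "tilde_p", "n_cohorts"]]
    return filter_and_flag(result, threshold)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cohort GWAS summary table (TSV with a header row)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"snp_id": str, "chrom": str}, float_precision="round_trip"
    )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        bad = df.loc[(df["p"] <= 0) | (df["p"] > 1)].index[0]
        raise ValueError(f"{path}: row {bad}: P value outside (0, 1]")
    return df


def write_meta_table(results: pd.DataFrame, path: str | Path) -> None:
    cols = ["snp_id", "chrom", "pos", "tilde_beta", "tilde_v", "tilde_p", "significant"]
    results[cols].to_csv(path, sep="\t", index=False)
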