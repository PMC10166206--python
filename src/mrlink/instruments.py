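"""Instrument selection and instrument-strength statistics.

Instrumental variables are chosen by association p-value against the exposure
(genome-wide 5e-8 or the looser locus-wide 1e-5 threshold), thinned by greedy
LD clumping (distance window plus an r-squared ceiling), and scored for
strength with the F statistic

    F = R^2 (N - 2) / (1 - R^2),

where R^2 is the fraction of exposure variance explained by the instruments.
For small instrument sets (J <= 10) R^2 is the sum of per-SNP contributions
2*EAF*(1-EAF)*beta^2; for larger sets each SNP's contribution is shrunk by
its sampling variance, 2pq*beta^2 / (2pq*beta^2 + 2pq*N*SE^2).  F > 10 is the
conventional weak-instrument bar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import SummaryTable

logger = logging.getLogger(__name__)

GENOME_WIDE = 5e-8
LOCUS_WIDE = 1e-5


@dataclass(frozen=True)
class ClumpParams:
    """Greedy-clumping parameters: distance window (kb) and r^2 ceiling."""

    window_kb: float = 500.0
    r2_max: float = 0.3

    def __post_init__(self) -> None:
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not 0.0 <= self.r2_max <= 1.0:
            raise ValueError("r2_max must be in [0, 1]")


@dataclass
class InstrumentSet:
    """Retained instruments for one exposure plus strength summaries."""

    exposure_id: str
    threshold: float
    snps: SummaryTable
    r2_explained: float
    f_aggregate: float
    f_per_snp: np.ndarray

    @property
    def f_min(self) -> float:
        return float(np.min(self.f_per_snp)) if len(self.f_per_snp) else float("nan")

    @property
    def weak(self) -> bool:
        """True when any per-SNP F is at or below the conventional bar of 10."""
        return bool(len(self.f_per_snp)) and bool(self.f_min <= 10.0)


def select_by_pvalue(table: SummaryTable, threshold: float) -> SummaryTable:
    """Keep records with ``pval < threshold``, preserving input order."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return table.replace(table.df.loc[table.df["P"] < threshold])


def clump(
    table: SummaryTable,
    ld: pd.DataFrame | None = None,
    params: ClumpParams = ClumpParams(),
    return_log: bool = False,
):
    """Greedy LD clumping.

    SNPs are visited in order of ascending p-value (ties broken by chromosome,
    then position).  Each visited SNP becomes an index SNP; every remaining SNP
    on the same chromosome within ``window_kb`` whose r^2 with the index
    exceeds ``r2_max`` is removed.  With no LD matrix, distance alone removes.
    A SNP missing from a provided LD matrix is treated as r^2 = 0 with a
    warning.

    Returns the clumped table, plus a removal log ``[(removed, index), ...]``
    when ``return_log`` is true.
    """
    df = table.df
    if len(df) <= 1:
        return (table.replace(df), []) if return_log else table.replace(df)

    if ld is not None:
        missing = sorted(set(df["SNP"]) - set(ld.index))
        if missing:
            logger.warning(
                "clump: %d SNP(s) absent from LD matrix treated as r2=0 (e.g. %s)",
                len(missing), missing[:3],
            )

    order = df.sort_values(
        by=["P", "CHR", "POS"], kind="mergesort"
    ).index.to_numpy()
    window_bp = params.window_kb * 1000.0
    alive = set(order.tolist())
    kept: list[int] = []
    log: list[tuple[str, str]] = []

    chrom = df["CHR"].to_numpy()
    pos = df["POS"].to_numpy()
    snp = df["SNP"].to_numpy()

    for i in order:
        if i not in alive:
            continue
        alive.discard(i)
        kept.append(i)
        for j in list(alive):
            if chrom[j] != chrom[i] or abs(pos[j] - pos[i]) > window_bp:
                continue
            if ld is None:
                r2 = 1.0  # distance alone removes
            elif snp[i] in ld.index and snp[j] in ld.columns:
                r2 = float(ld.at[snp[i], snp[j]])
            else:
                r2 = 0.0
            if r2 > params.r2_max:
                alive.discard(j)
                log.append((snp[j], snp[i]))

    kept_mask = df.index.isin(kept)
    result = table.replace(df.loc[kept_mask])  # original row order preserved
    return (result, log) if return_log else result


def apply_exclusion_list(table: SummaryTable, exclude: set[str] | None) -> SummaryTable:
    """Drop user-supplied SNPs (confounder / outcome-associated screen hook)."""
    if not exclude:
        return table
    keep = ~table.df["SNP"].isin(set(exclude))
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("exclusion list removed %d SNP(s)", n_removed)
    return table.replace(table.df.loc[keep])


def _valid_eaf_mask(eaf: np.ndarray) -> np.ndarray:
    ok = np.isfinite(eaf) & (eaf > 0) & (eaf < 1)
    if (~ok).any():
        logger.warning("r_squared: excluded %d record(s) with EAF outside (0,1)", int((~ok).sum()))
    return ok


def r_squared(
    records: pd.DataFrame | SummaryTable,
    n: float | None = None,
    mode: str = "auto",
) -> float:
    """Variance in the exposure explained by a set of instruments.

    ``mode="per_snp_small"`` sums 2*EAF*(1-EAF)*beta^2 over SNPs;
    ``mode="joint_large"`` sums the per-SNP ratio of genetic to
    genetic-plus-sampling variance; ``mode="auto"`` applies the small formula
    for J <= 10 instruments and the large one otherwise.  The result is
    clipped to [0, 1).
    """
    df = records.df if isinstance(records, SummaryTable) else records
    eaf = df["EAF"].to_numpy(dtype=float)
    beta = df["BETA"].to_numpy(dtype=float)
    se = df["SE"].to_numpy(dtype=float)
    nn = df["N"].to_numpy(dtype=float) if n is None else np.full(len(df), float(n))

    ok = _valid_eaf_mask(eaf)
    eaf, beta, se, nn = eaf[ok], beta[ok], se[ok], nn[ok]
    if len(eaf) == 0:
        return 0.0
    if mode == "auto":
        mode = "per_snp_small" if len(eaf) <= 10 else "joint_large"

    two_pq = 2.0 * eaf * (1.0 - eaf)
    if mode == "per_snp_small":
        r2 = float(np.sum(two_pq * beta**2))
    elif mode == "joint_large":
        num = two_pq * beta**2
        r2 = float(np.sum(num / (num + two_pq * nn * se**2)))
    else:
        raise ValueError(f"unknown r_squared mode {mode!r}")
    return float(np.clip(r2, 0.0, np.nextafter(1.0, 0.0)))


def f_statistic(r2: float, n: float) -> float:
    """Instrument-strength F = R^2 (N - 2) / (1 - R^2)."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must lie in [0, 1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    return float(r2 * (n - 2.0) / (1.0 - r2))


def f_per_snp(records: pd.DataFrame | SummaryTable) -> np.ndarray:
    """Per-instrument F from each SNP's own R^2 contribution and sample size."""
    df = records.df if isinstance(records, SummaryTable) else records
    eaf = df["EAF"].to_numpy(dtype=float)
    beta = df["BETA"].to_numpy(dtype=float)
    nn = df["N"].to_numpy(dtype=float)
    ok = _valid_eaf_mask(eaf)
    r2 = np.clip(2.0 * eaf[ok] * (1.0 - eaf[ok]) * beta[ok] ** 2, 0.0, np.nextafter(1.0, 0.0))
    return r2 * (nn[ok] - 2.0) / (1.0 - r2)


def build_instrument_set(table: SummaryTable, threshold: float) -> InstrumentSet:
    """Bundle a selected+clumped table with its strength statistics."""
    df = table.df
    n_agg = float(np.median(df["N"])) if len(df) else float("nan")
    r2 = r_squared(df, mode="auto") if len(df) else 0.0
    f_agg = f_statistic(r2, n_agg) if len(df) else float("nan")
    return InstrumentSet(
        exposure_id=table.trait_id,
        threshold=threshold,
        snps=table,
        r2_explained=r2,
        f_aggregate=f_agg,
        f_per_snp=f_per_snp(df) if len(df) else np.array([]),
    )
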