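"""End-to-end bidirectional MR workflow over many exposures.

Forward mode runs, per exposure: p-value selection -> LD clumping ->
optional exclusion list -> harmonization against the outcome -> estimation
(Wald ratio for a single instrument, IVW as primary for two or more, with
MR-Egger and weighted median as reference models from three) -> sensitivity
diagnostics -> odds-scale transforms.  Primary p-values across all exposures
form one Benjamini-Hochberg FDR family.  Reverse mode swaps the roles for
the hit taxa, forcing the genome-wide instrument threshold.

The pipeline is a pure function of (input files, configuration, seed): two
runs with identical inputs produce byte-identical report files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import estimators as est
from .diagnostics import DiagnosticsReport, compute_diagnostics
from .gwas_io import SummaryTable, harmonize, read_ld_matrix, read_summary_table, retained_pairs
from .instruments import (
    GENOME_WIDE,
    ClumpParams,
    apply_exclusion_list,
    build_instrument_set,
    clump,
    select_by_pvalue,
)

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "Classification", "Exposure", "No.SNP", "Method", "Beta", "SE", "OR",
    "CI_low", "CI_high", "P", "F", "Pleiotropy_P", "Heterogeneity_P",
    "FDR_q", "Tier",
]


@dataclass
class AnalysisConfig:
    """Configuration for one pipeline run (seed mandatory)."""

    exposure_paths: list[str | Path]
    outcome_path: str | Path
    seed: int
    mode: str = "forward"              # forward | reverse
    pthresh: float = 1e-5
    clump_params: ClumpParams = field(default_factory=ClumpParams)
    ld_path: str | Path | None = None
    palindrome_eaf_window: float = 0.42
    n_boot: int = 1000
    fdr_alpha: float = 0.05
    min_snps_egger: int = 3
    exclude_snps: set[str] = field(default_factory=set)
    exposure_trait_type: str = "quantitative"
    outcome_trait_type: str = "binary"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.mode not in ("forward", "reverse"):
            raise ValueError("mode must be 'forward' or 'reverse'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "clump_params" in raw:
            raw["clump_params"] = ClumpParams(**raw["clump_params"])
        if "exclude_snps" in raw:
            raw["exclude_snps"] = set(raw["exclude_snps"])
        return cls(**raw)


@dataclass
class TaxonResult:
    """All estimates and diagnostics for one exposure/outcome pair."""

    exposure_id: str
    classification: str
    status: str                        # ok | no_instruments
    n_snp: int = 0
    estimates: dict[str, est.MREstimate] = field(default_factory=dict)
    primary_method: str | None = None
    diagnostics: DiagnosticsReport | None = None
    f_aggregate: float = np.nan
    raw_p: float = np.nan
    fdr_q: float = np.nan
    significance_tier: str = "null"    # fdr_significant | nominal | null
    robustness_flag: bool = False

    @property
    def primary(self) -> est.MREstimate | None:
        return self.estimates.get(self.primary_method) if self.primary_method else None


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_taxon(trait_id: str) -> str:
    """Taxonomic rank from ids shaped like 'genus.Roseburia'."""
    rank = trait_id.split(".", 1)[0].lower()
    if rank in ("phylum", "class", "order", "family", "genus"):
        return rank.capitalize()
    return "NA"


def _analyse_one(
    exposure: SummaryTable,
    outcome: SummaryTable,
    config: AnalysisConfig,
    rng: np.random.Generator,
    ld: pd.DataFrame | None,
    pthresh: float,
) -> TaxonResult:
    result = TaxonResult(
        exposure_id=exposure.trait_id,
        classification=classify_taxon(exposure.trait_id),
        status="no_instruments",
    )
    selected = select_by_pvalue(exposure, pthresh)
    if len(selected) == 0:
        return result
    clumped = clump(selected, ld, config.clump_params)
    clumped = apply_exclusion_list(clumped, config.exclude_snps)
    if len(clumped) == 0:
        return result
    try:
        pairs = retained_pairs(
            harmonize(clumped, outcome, config.palindrome_eaf_window)
        )
    except ValueError:
        return result
    if len(pairs) == 0:
        return result

    # instrument strength from the harmonized exposure side
    inst_df = clumped.df[clumped.df["SNP"].isin(pairs["SNP"])]
    inst = build_instrument_set(clumped.replace(inst_df), pthresh)
    if inst.weak:
        logger.warning("%s: minimum per-SNP F <= 10 (weak instruments)",
                       exposure.trait_id)

    result.status = "ok"
    result.n_snp = len(pairs)
    result.f_aggregate = inst.f_aggregate

    if len(pairs) == 1:
        result.estimates["wald_ratio"] = est.wald_ratio(pairs)
        result.primary_method = "wald_ratio"
    else:
        ivw_fit = est.ivw(pairs)
        result.estimates["ivw"] = ivw_fit
        result.primary_method = "ivw"
        egger_fit = None
        if len(pairs) >= config.min_snps_egger:
            egger_fit = est.egger(pairs)
            result.estimates["egger"] = egger_fit
            result.estimates["weighted_median"] = est.weighted_median(
                pairs, n_boot=config.n_boot, seed=rng
            )
        result.diagnostics = compute_diagnostics(
            pairs, ivw_fit=ivw_fit, egger_fit=egger_fit,
            f_aggregate=inst.f_aggregate, f_min_per_snp=inst.f_min,
            outcome_binary=(outcome.trait_type == "binary"),
        )
    result.raw_p = result.primary.pval
    return result


def _finalize(results: list[TaxonResult], config: AnalysisConfig) -> list[TaxonResult]:
    """Joint FDR over primary p-values; significance tiers; robustness flags."""
    scored = [r for r in results if r.status == "ok"]
    if scored:
        qvals = bh_fdr([r.raw_p for r in scored])
        for r, q in zip(scored, qvals):
            r.fdr_q = float(q)
            if q < config.fdr_alpha:
                r.significance_tier = "fdr_significant"
            elif r.raw_p < 0.05:
                r.significance_tier = "nominal"
            else:
                r.significance_tier = "null"
            primary = r.primary
            for name in ("egger", "weighted_median"):
                ref = r.estimates.get(name)
                if ref is not None and ref.pval < 0.05 and \
                        np.sign(ref.beta) == np.sign(primary.beta):
                    r.robustness_flag = True
    return results


def run_forward(config: AnalysisConfig) -> list[TaxonResult]:
    """Run the forward MR screen of every exposure against the outcome."""
    if not config.exposure_paths:
        raise ValueError("no exposure tables supplied")
    outcome = read_summary_table(config.outcome_path, trait_type=config.outcome_trait_type)
    ld = read_ld_matrix(config.ld_path) if config.ld_path else None

    results = []
    for i, path in enumerate(sorted(map(str, config.exposure_paths))):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        try:
            exposure = read_summary_table(path, trait_type=config.exposure_trait_type)
            results.append(
                _analyse_one(exposure, outcome, config, rng, ld, config.pthresh)
            )
        except ValueError as exc:  # per-exposure failures logged, not fatal
            logger.error("exposure %s failed: %s", path, exc)
    if not results:
        raise ValueError("no exposures could be processed")
    return _finalize(results, config)


def run_reverse(config: AnalysisConfig, hits: list[str]) -> list[TaxonResult]:
    """Reverse MR: the outcome trait instruments the hit taxa.

    The disease GWAS becomes the exposure at the genome-wide threshold
    (5e-8); each hit taxon's summary table becomes an outcome.  Clumping and
    harmonization parameters are unchanged.
    """
    if not hits:
        raise ValueError("reverse MR requires a nonempty hit list")
    disease = read_summary_table(config.outcome_path, trait_type=config.outcome_trait_type)
    ld = read_ld_matrix(config.ld_path) if config.ld_path else None

    by_id: dict[str, str] = {}
    for path in map(str, config.exposure_paths):
        t = read_summary_table(path, trait_type=config.exposure_trait_type)
        by_id[t.trait_id] = path

    results = []
    for i, taxon in enumerate(sorted(hits)):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10_000 + i]))
        path = by_id.get(taxon)
        if path is None:
            logger.error("reverse MR: hit %s has no exposure table", taxon)
            continue
        taxon_table = read_summary_table(path, trait_type=config.exposure_trait_type)
        res = _analyse_one(disease, taxon_table, config, rng, ld, GENOME_WIDE)
        # label the row by the taxon under test, not the disease exposure
        res.exposure_id = taxon
        res.classification = classify_taxon(taxon)
        results.append(res)
    if not results:
        raise ValueError("no reverse analyses could be run")
    return _finalize(results, config)


def _fmt(x: float | int | str, nd: int = 3) -> str:
    if isinstance(x, str):
        return x
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.{nd}f}"


def _rows_for(result: TaxonResult) -> list[dict]:
    base = {
        "Classification": result.classification,
        "Exposure": result.exposure_id,
        "No.SNP": result.n_snp,
        "F": _fmt(result.f_aggregate),
        "FDR_q": _fmt(result.fdr_q),
        "Tier": result.significance_tier if result.status == "ok" else "NA",
    }
    if result.status != "ok":
        return [{**base, "Method": "NA", "Beta": "NA", "SE": "NA", "OR": "NA",
                 "CI_low": "NA", "CI_high": "NA", "P": "NA", "F": "NA",
                 "FDR_q": "NA", "Pleiotropy_P": "NA", "Heterogeneity_P": "NA"}]
    d = result.diagnostics
    method_order = ["wald_ratio", "ivw", "egger", "weighted_median"]
    labels = {"wald_ratio": "Wald ratio", "ivw": "IVW", "egger": "MR Egger",
              "weighted_median": "Weighted median"}
    rows = []
    for name in method_order:
        e = result.estimates.get(name)
        if e is None:
            continue
        primary = name == result.primary_method
        rows.append({
            **base,
            "Method": labels[name],
            "Beta": _fmt(e.beta), "SE": _fmt(e.se), "OR": _fmt(e.or_),
            "CI_low": _fmt(e.ci_low), "CI_high": _fmt(e.ci_high),
            "P": _fmt(e.pval),
            # single-SNP Wald rows have no applicable sensitivity tests
            "Pleiotropy_P": _fmt(d.egger_intercept_pval) if primary and d else "NA",
            "Heterogeneity_P": _fmt(d.q_pval) if primary and d else "NA",
            "F": base["F"] if primary else "NA",
            "FDR_q": base["FDR_q"] if primary else "NA",
        })
    return rows


def render_report(
    results: list[TaxonResult],
    out_dir: str | Path,
    alpha: float = 0.05,
) -> dict[str, Path]:
    """Write the all-results audit table and the significant-results table.

    Both are tab-separated with numeric cells at 3 decimals, rows ordered by
    (classification, exposure id).  The audit table contains every input
    exposure exactly once (no-instrument exposures included); the significant
    table keeps exposures whose primary p-value is below ``alpha`` together
    with reference-model rows.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(results, key=lambda r: (r.classification, r.exposure_id))

    all_rows, sig_rows = [], []
    for r in ordered:
        rows = _rows_for(r)
        all_rows.extend(rows)
        if r.status == "ok" and r.raw_p < alpha:
            sig_rows.extend(rows)

    paths = {
        "all": out_dir / "all_results.tsv",
        "significant": out_dir / "significant_results.tsv",
    }
    for key, rows in (("all", all_rows), ("significant", sig_rows)):
        df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        df.to_csv(paths[key], sep="\t", index=False)
    return paths


def forest_plot(results: list[TaxonResult], path: str | Path,
                alpha: float = 0.05) -> Path | None:
    """Plain forest plot of primary odds ratios with 95% intervals."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [(r.exposure_id, r.primary) for r in results
            if r.status == "ok" and r.primary is not None]
    if not rows:
        return None
    rows.sort(key=lambda t: t[0])
    labels = [t[0] for t in rows]
    ors = [t[1].or_ for t in rows]
    lo = [t[1].or_ - t[1].ci_low for t in rows]
    hi = [t[1].ci_high - t[1].or_ for t in rows]
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(rows) + 1.5))
    y = np.arange(len(rows))
    ax.errorbar(ors, y, xerr=[lo, hi], fmt="o", color="black", capsize=2, ms=3)
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xscale("log")
    ax.set_xlabel("Odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
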