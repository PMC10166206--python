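"""Synthetic paired GWAS summary statistics with known causal ground truth.

The generator emulates the structure of a microbiome-abundance GWAS panel
(many taxa, each with a handful of instrument SNPs) paired with one binary
disease GWAS, so that every pipeline stage — selection, clumping,
harmonization, estimation, diagnostics, FDR — can be exercised without any
external download and scored against a machine-readable truth manifest.

The model per instrument SNP j of one taxon:

    beta_exp_j = gamma_j + e_j,          e_j ~ N(0, se_exp_j^2)
    beta_out_j = b * gamma_j + a_j + u_j, u_j ~ N(0, se_out_j^2)

where b is the taxon's true causal effect (log odds per SD of abundance),
gamma_j the true instrument effect, and a_j a direct (pleiotropic) effect on
the outcome drawn on the invalid subset.  Standard errors follow the usual
GWAS approximations se = 1/sqrt(2*MAF*(1-MAF)*N) for the quantitative
exposure, with the binary outcome's effective sample size shrunk by
v = case_fraction * (1 - case_fraction) on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gwas_io import SummaryTable, write_ld_matrix, write_summary_table

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class TruthConfig:
    """Ground-truth configuration for a synthetic exposure/outcome panel.

    Defaults mirror the cohorts the package is designed around: an exposure
    GWAS of 18,473 individuals for taxon abundances and a binary outcome GWAS
    of 20,183 cases / 35,191 controls (case fraction ~0.3645), instruments in
    the locus-wide significance band, and mostly-null taxa.
    """

    seed: int
    n_taxa: int = 20
    n_snps_per_taxon: int = 12        # true instruments (gamma != 0)
    n_null_snps_per_taxon: int = 30   # background SNPs (gamma = 0)
    causal_taxa: dict[str, float] = field(default_factory=dict)
    n_exp: int = 18473
    n_out: int = 55374
    outcome_case_fraction: float | None = 20183 / 55374
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_range: tuple[float, float] = (0.06, 0.12)  # |gamma| per-SNP effect
    gamma_sign: str = "positive"      # effect alleles oriented abundance-increasing
    pleiotropy: str = "none"          # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    prop_invalid: float = 0.0
    inside_violation: bool = False    # scale pleiotropy with instrument strength
    ld_block_size: int = 1
    ld_block_r2: float = 0.0
    noise_scale: float = 1.0          # 0 gives exact, noiseless summary stats
    outcome_allele_swap_frac: float = 0.3  # exercise harmonization flips

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise ValueError("prop_invalid must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        total = self.n_snps_per_taxon + self.n_null_snps_per_taxon
        if self.ld_block_size > total:
            raise ValueError("ld_block_size exceeds the number of SNPs per taxon")
        if self.gamma_sign not in ("positive", "random"):
            raise ValueError("gamma_sign must be 'positive' or 'random'")

    def taxon_names(self) -> list[str]:
        return [f"genus.Taxon{i + 1:03d}" for i in range(self.n_taxa)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("maf_range", "gamma_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        raw = asdict(self)
        raw["maf_range"] = list(self.maf_range)
        raw["gamma_range"] = list(self.gamma_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
        return path


def default_truth(seed: int, **overrides) -> TruthConfig:
    """A 20-taxon panel with two causal taxa (+0.3 and -0.3 log odds per SD)."""
    cfg = dict(
        seed=seed,
        causal_taxa={"genus.Taxon001": 0.3, "genus.Taxon002": -0.3},
    )
    cfg.update(overrides)
    return TruthConfig(**cfg)


def _se_out(two_pq: np.ndarray, truth: TruthConfig) -> np.ndarray:
    v = 1.0
    if truth.outcome_case_fraction is not None:
        cf = truth.outcome_case_fraction
        v = cf * (1.0 - cf)
    return 1.0 / np.sqrt(two_pq * truth.n_out * v)


def _pleiotropy(truth: TruthConfig, gamma: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Direct SNP-on-outcome effects alpha_j on the invalid instrument subset."""
    j = len(gamma)
    alpha = np.zeros(j)
    if truth.pleiotropy == "none" or truth.prop_invalid == 0.0:
        return alpha
    n_invalid = int(round(truth.prop_invalid * j))
    idx = rng.choice(j, size=n_invalid, replace=False)
    if truth.pleiotropy == "balanced":
        vals = rng.normal(0.0, truth.pleiotropy_sd, n_invalid)
    else:  # directional
        vals = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, n_invalid)
    if truth.inside_violation and np.mean(np.abs(gamma[idx])) > 0:
        vals = vals * np.abs(gamma[idx]) / np.mean(np.abs(gamma[idx]))
    alpha[idx] = vals
    return alpha


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def simulate_pair(
    truth: TruthConfig,
    taxon: str = "genus.Taxon001",
    taxon_index: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[SummaryTable, SummaryTable, pd.DataFrame, dict]:
    """Simulate one taxon's exposure table, the matching outcome rows and LD.

    Returns ``(exposure, outcome, ld, info)`` where ``info`` records the true
    causal effect and the number of pleiotropic (invalid) instruments.  The
    per-taxon random stream is derived from ``(truth.seed, taxon_index)`` so
    panels are reproducible taxon by taxon.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([truth.seed, taxon_index]))
    beta_causal = float(truth.causal_taxa.get(taxon, 0.0))
    n_inst = truth.n_snps_per_taxon
    n_total = n_inst + truth.n_null_snps_per_taxon

    maf = rng.uniform(*truth.maf_range, n_total)
    eaf = np.where(rng.random(n_total) < 0.5, maf, 1.0 - maf)
    two_pq = 2.0 * maf * (1.0 - maf)

    gamma = np.zeros(n_total)
    mag = rng.uniform(*truth.gamma_range, n_inst)
    sign = np.ones(n_inst) if truth.gamma_sign == "positive" else rng.choice([-1.0, 1.0], n_inst)
    gamma[:n_inst] = mag * sign

    alpha = np.zeros(n_total)
    alpha[:n_inst] = _pleiotropy(truth, gamma[:n_inst], rng)
    n_invalid = int(np.sum(alpha[:n_inst] != 0.0))

    se_exp = 1.0 / np.sqrt(two_pq * truth.n_exp)
    se_out = _se_out(two_pq, truth)
    beta_exp = gamma + truth.noise_scale * rng.normal(0.0, se_exp)
    beta_out = beta_causal * gamma + alpha + truth.noise_scale * rng.normal(0.0, se_out)

    # positions: blocks of ld_block_size SNPs 50 kb apart (inside the 500 kb
    # clumping window); successive blocks 10 Mb apart, cycling chromosomes
    block = np.arange(n_total) // truth.ld_block_size
    within = np.arange(n_total) % truth.ld_block_size
    chrom = (block % 22 + 1).astype(int)
    pos = 1_000_000 + (block // 22) * 10_000_000 + within * 50_000

    slug = "".join(ch if ch.isalnum() else "_" for ch in taxon)
    snp = np.array([f"rs_{slug}_{i:04d}" for i in range(n_total)])
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n_total)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    exp_df = pd.DataFrame({
        "SNP": snp, "CHR": chrom.astype(str), "POS": pos, "EA": ea, "OA": oa,
        "EAF": eaf, "BETA": beta_exp, "SE": se_exp,
        "P": _two_sided_p(beta_exp, se_exp), "N": truth.n_exp,
    })

    # outcome file reports a random subset with swapped allele labels so the
    # harmonization stage has real work to do
    swap = rng.random(n_total) < truth.outcome_allele_swap_frac
    out_df = pd.DataFrame({
        "SNP": snp, "CHR": chrom.astype(str), "POS": pos,
        "EA": np.where(swap, oa, ea), "OA": np.where(swap, ea, oa),
        "EAF": np.where(swap, 1.0 - eaf, eaf),
        "BETA": np.where(swap, -beta_out, beta_out), "SE": se_out,
        "P": _two_sided_p(beta_out, se_out), "N": truth.n_out,
    })

    ld_vals = np.eye(n_total)
    if truth.ld_block_size > 1:
        same_block = block[:, None] == block[None, :]
        ld_vals = np.where(same_block, truth.ld_block_r2, 0.0)
        np.fill_diagonal(ld_vals, 1.0)
    ld = pd.DataFrame(ld_vals, index=snp, columns=snp)

    exposure = SummaryTable(taxon, "quantitative", exp_df)
    outcome = SummaryTable("outcome", "binary", out_df)
    info = {"taxon": taxon, "true_beta": beta_causal, "n_invalid": n_invalid}
    return exposure, outcome, ld, info


@dataclass
class Panel:
    """In-memory synthetic panel plus, when written, the file layout."""

    exposures: dict[str, SummaryTable]
    outcome: SummaryTable
    ld: pd.DataFrame
    manifest: pd.DataFrame
    exposure_paths: list[Path] = field(default_factory=list)
    outcome_path: Path | None = None
    ld_path: Path | None = None
    manifest_path: Path | None = None


def simulate_panel(truth: TruthConfig, out_dir: str | Path | None = None) -> Panel:
    """Simulate every taxon and (optionally) write the panel to ``out_dir``.

    The directory receives one canonical TSV per taxon, a shared outcome
    table covering the union of SNPs, the LD matrix, the truth manifest
    (taxon, true beta, invalid-instrument count) and the generating
    configuration as YAML.
    """
    unknown = set(truth.causal_taxa) - set(truth.taxon_names())
    if unknown:
        raise ValueError(f"causal_taxa not in panel: {sorted(unknown)}")

    exposures: dict[str, SummaryTable] = {}
    out_frames, ld_blocks, records = [], [], []
    for i, taxon in enumerate(truth.taxon_names()):
        exp, out, ld, info = simulate_pair(truth, taxon, taxon_index=i)
        exposures[taxon] = exp
        out_frames.append(out.df)
        ld_blocks.append(ld)
        records.append(info)

    outcome = SummaryTable("outcome", "binary",
                           pd.concat(out_frames, ignore_index=True))
    all_snps = np.concatenate([ld.index.to_numpy() for ld in ld_blocks])
    full = pd.DataFrame(0.0, index=all_snps, columns=all_snps)
    for ld in ld_blocks:
        full.loc[ld.index, ld.columns] = ld.to_numpy()
    manifest = pd.DataFrame(records)

    panel = Panel(exposures=exposures, outcome=outcome, ld=full, manifest=manifest)
    if out_dir is not None:
        out_dir = Path(out_dir)
        exp_dir = out_dir / "exposures"
        exp_dir.mkdir(parents=True, exist_ok=True)
        # file stem == trait_id so tables keep their identity on re-read
        for taxon, table in exposures.items():
            panel.exposure_paths.append(
                write_summary_table(table, exp_dir / f"{taxon}.tsv")
            )
        panel.outcome_path = write_summary_table(outcome, out_dir / "outcome.tsv")
        panel.ld_path = write_ld_matrix(full, out_dir / "ld_matrix.tsv")
        panel.manifest_path = out_dir / "truth_manifest.tsv"
        manifest.to_csv(panel.manifest_path, sep="\t", index=False)
        truth.to_yaml(out_dir / "truth_config.yaml")
    return panel
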