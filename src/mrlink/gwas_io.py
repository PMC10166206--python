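"""GWAS summary-statistics data model, file I/O and allele harmonization.

The canonical on-disk format is a tab-separated table with a header row and
columns ``SNP CHR POS EA OA EAF BETA SE P N``: variant identifier, chromosome
label, 1-based base-pair position, effect allele, other allele, effect-allele
frequency (``.`` when missing), per-allele additive effect (log odds ratio for
binary traits), its standard error, the two-sided association p-value and the
GWAS sample size.  Nonstandard headers are accommodated through a
``column_map`` at read time.

Harmonization aligns the exposure and outcome tables SNP-by-SNP so that both
effect sizes refer to the same effect allele, resolving reverse-coded and
strand-flipped records and removing ambiguous palindromic (A/T, G/C) variants
whose strand cannot be inferred from allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistics tables.
COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Harmonization outcomes for one shared SNP.
ACTIONS = ("unchanged", "flipped", "dropped_palindromic", "dropped_mismatch")


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float  # may be NaN when unknown
    beta: float
    se: float
    pval: float
    n: int

    def is_valid(self) -> bool:
        ok = (
            self.se > 0
            and 0 < self.pval <= 1
            and self.n >= 2
            and self.effect_allele != self.other_allele
            and np.isfinite(self.beta)
        )
        if np.isfinite(self.eaf):
            ok = ok and 0.0 <= self.eaf <= 1.0
        return bool(ok)


@dataclass
class SummaryTable:
    """An ordered set of :class:`SummaryRecord` rows for one trait.

    ``df`` holds the canonical columns; ``snp_id`` values are unique.
    """

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    df: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"summary table missing columns: {missing}")
        if self.df["SNP"].duplicated().any():
            dups = self.df.loc[self.df["SNP"].duplicated(), "SNP"].tolist()
            raise ValueError(f"duplicate snp_id in table: {dups[:5]}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[SummaryRecord]:
        return [
            SummaryRecord(
                snp_id=r.SNP, chrom=str(r.CHR), pos=int(r.POS),
                effect_allele=r.EA, other_allele=r.OA, eaf=float(r.EAF),
                beta=float(r.BETA), se=float(r.SE), pval=float(r.P), n=int(r.N),
            )
            for r in self.df.itertuples(index=False)
        ]

    def replace(self, df: pd.DataFrame) -> "SummaryTable":
        """New table with the same trait metadata but different rows."""
        return SummaryTable(self.trait_id, self.trait_type, df.reset_index(drop=True))


def _float_col(s: pd.Series) -> pd.Series:
    # numpy's strtod round-trips full double precision (pandas' fast parser
    # does not); invalid entries become NaN
    def parse(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan
    return s.map(parse).astype(float)


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["SNP"] = out["SNP"].astype(str)
    out["CHR"] = out["CHR"].astype(str)
    out["POS"] = _float_col(out["POS"])
    out["EA"] = out["EA"].astype(str).str.upper()
    out["OA"] = out["OA"].astype(str).str.upper()
    # "." denotes a missing effect-allele frequency
    out["EAF"] = _float_col(out["EAF"].mask(out["EAF"] == ".", np.nan))
    for col in ("BETA", "SE", "P", "N"):
        out[col] = _float_col(out[col])
    return out


def _enforce_invariants(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating SummaryRecord invariants; return (clean, n_dropped)."""
    ok = (
        df["SNP"].notna()
        & df["POS"].notna()
        & (df["SE"] > 0)
        & (df["P"] > 0)
        & (df["P"] <= 1)
        & (df["N"] >= 2)
        & (df["EA"] != df["OA"])
        & np.isfinite(df["BETA"])
    )
    # EAF may be missing; when present it must be a frequency
    ok &= df["EAF"].isna() | ((df["EAF"] >= 0) & (df["EAF"] <= 1))
    clean = df.loc[ok].copy()
    clean["POS"] = clean["POS"].astype(np.int64)
    clean["N"] = clean["N"].astype(np.int64)
    return clean.reset_index(drop=True), int((~ok).sum())


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
) -> SummaryTable:
    """Read a summary-statistics table from a tab- or comma-separated file.

    Parameters
    ----------
    path:
        File with a header row.
    column_map:
        Mapping from the file's column names to the canonical names in
        :data:`COLUMNS`, for files with nonstandard headers.
    trait_id:
        Trait label; defaults to the file stem.
    trait_type:
        ``"quantitative"`` or ``"binary"``.

    Rows violating record invariants (non-positive SE, p outside (0,1], equal
    alleles, N < 2, frequency outside [0,1]) are dropped and counted in
    ``SummaryTable.n_dropped``.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing summary-statistics file: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"supply a column_map if the file uses other names"
        )
    df = _coerce_types(df[COLUMNS])
    clean, n_dropped = _enforce_invariants(df)
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s)", path, n_dropped)
    table = SummaryTable(
        trait_id=trait_id or path.stem, trait_type=trait_type, df=clean
    )
    table.n_dropped = n_dropped
    return table


def write_summary_table(table: SummaryTable, path: str | Path) -> Path:
    """Write a table in the canonical TSV layout (full float precision).

    ``read_summary_table(write_summary_table(t))`` reproduces ``t`` exactly:
    floats are printed with the shortest representation that round-trips.
    """
    path = Path(path)
    table.df[COLUMNS].to_csv(path, sep="\t", index=False, na_rep=".")
    return path


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square r-squared matrix whose first row/column hold SNP ids."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.index = ld.index.astype(str)
    ld.columns = ld.columns.astype(str)
    if list(ld.index) != list(ld.columns):
        raise ValueError("LD matrix row and column SNP ids differ")
    vals = ld.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("LD matrix values must be r^2 in [0, 1]")
    return ld


def write_ld_matrix(ld: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    ld.to_csv(path, sep="\t")
    return path


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None  # non-ACGT (e.g. indel code): no strand complement


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T or G/C single-base variants: strand is unresolvable from alleles."""
    return len(ea) == 1 and len(oa) == 1 and _complement(ea) == oa


#: Columns of the harmonized exposure/outcome pair table.
HARMONIZED_COLUMNS = [
    "SNP", "CHR", "POS",
    "beta_exp", "se_exp", "eaf_exp", "n_exp",
    "beta_out", "se_out", "eaf_out", "n_out",
    "action",
]


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_eaf_window: float = 0.42,
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    For each SNP shared between the tables:

    * identical alleles -> ``unchanged``;
    * swapped alleles (exposure EA equals outcome OA and vice versa) ->
      outcome beta negated and EAF complemented (``flipped``);
    * a strand flip (complementing both outcome alleles) is attempted before
      declaring a mismatch;
    * palindromic variants are resolved from allele frequency when the minor
      allele frequency on both sides is at most ``palindrome_eaf_window``
      (default 0.42), and dropped as ambiguous otherwise (also when either
      EAF is missing);
    * any other configuration -> ``dropped_mismatch``.  Indels are matched by
      exact string equality only.

    Returns a DataFrame with :data:`HARMONIZED_COLUMNS`, one row per shared
    SNP including dropped ones (so the four action counts sum to the
    intersection size).  Raises ``ValueError`` when no SNPs are shared.
    """
    merged = exposure.df.merge(
        outcome.df, on="SNP", how="inner", suffixes=("_exp", "_out")
    )
    if merged.empty:
        raise ValueError(
            f"no overlapping SNPs between {exposure.trait_id} and {outcome.trait_id}"
        )

    rows = []
    for r in merged.itertuples(index=False):
        ea_e, oa_e = r.EA_exp, r.OA_exp
        ea_o, oa_o = r.EA_out, r.OA_out
        beta_o, eaf_o = r.BETA_out, r.EAF_out
        action = "dropped_mismatch"

        if is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                action = "dropped_mismatch"
            elif not np.isfinite(r.EAF_exp) or not np.isfinite(eaf_o):
                action = "dropped_palindromic"  # strand undecidable
            else:
                maf_e = min(r.EAF_exp, 1 - r.EAF_exp)
                maf_o = min(eaf_o, 1 - eaf_o)
                if maf_e > palindrome_eaf_window or maf_o > palindrome_eaf_window:
                    action = "dropped_palindromic"
                else:
                    # nominal alignment by allele label; a discordant
                    # frequency side then implies a strand flip on top —
                    # the two flips cancel when both apply
                    swap = ea_o != ea_e
                    f_nominal = 1 - eaf_o if swap else eaf_o
                    discordant = (r.EAF_exp - 0.5) * (f_nominal - 0.5) < 0
                    if swap != discordant:
                        action = "flipped"
                        beta_o, eaf_o = -beta_o, 1 - eaf_o
                    else:
                        action = "unchanged"
        else:
            ce, co = _complement(ea_o), _complement(oa_o)
            if (ea_o, oa_o) == (ea_e, oa_e):
                action = "unchanged"
            elif (ea_o, oa_o) == (oa_e, ea_e):
                action = "flipped"
                beta_o, eaf_o = -beta_o, 1 - eaf_o
            elif ce is not None and (ce, co) == (ea_e, oa_e):
                action = "unchanged"  # pure strand flip
            elif ce is not None and (ce, co) == (oa_e, ea_e):
                action = "flipped"
                beta_o, eaf_o = -beta_o, 1 - eaf_o
            else:
                action = "dropped_mismatch"

        rows.append(
            (
                r.SNP, str(r.CHR_exp), int(r.POS_exp),
                float(r.BETA_exp), float(r.SE_exp), float(r.EAF_exp), int(r.N_exp),
                float(beta_o), float(r.SE_out), float(eaf_o), int(r.N_out),
                action,
            )
        )
    out = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    n_drop = int(out["action"].str.startswith("dropped").sum())
    if n_drop:
        logger.info(
            "harmonize(%s, %s): dropped %d of %d shared SNPs",
            exposure.trait_id, outcome.trait_id, n_drop, len(out),
        )
    return out


def retained_pairs(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonized table that survived alignment."""
    keep = harmonized["action"].isin(["unchanged", "flipped"])
    return harmonized.loc[keep].reset_index(drop=True)
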