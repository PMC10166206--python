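"""Sensitivity analyses: heterogeneity, pleiotropy and directionality.

* Cochran's Q quantifies heterogeneity among per-SNP causal estimates around
  the IVW estimate; under homogeneity it is chi-square with J-1 df.
* The MR-Egger intercept test probes average directional (horizontal)
  pleiotropy; p > 0.05 is read as no evidence against the instruments.
* Steiger's directionality test compares the variance the instruments explain
  in exposure versus outcome via a Fisher-z contrast of the two multiple
  correlations, confirming that effects flow exposure -> outcome.  For a
  binary outcome the observed-scale R^2 makes this approximate (flagged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate

logger = logging.getLogger(__name__)

_P_FLOOR = np.nextafter(0.0, 1.0)

EXPOSURE_TO_OUTCOME = "exposure_to_outcome"
OUTCOME_TO_EXPOSURE = "outcome_to_exposure"


@dataclass
class DiagnosticsReport:
    """Per-exposure sensitivity summary attached to a pipeline result."""

    q_stat: float = np.nan
    q_df: int = 0
    q_pval: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_pval: float = np.nan
    steiger_direction: str | None = None
    steiger_pval: float = np.nan
    f_aggregate: float = np.nan
    f_min_per_snp: float = np.nan
    steiger_approximate: bool = False  # observed-scale R^2 on a binary trait


def cochran_q(pairs: pd.DataFrame, beta_ivw: float) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP ratios with IVW weights (beta_exp/se_out)^2.

    Returns (Q, df, p) with df = J - 1 and the p-value from the chi-square
    upper tail.
    """
    bx = pairs["beta_exp"].to_numpy(dtype=float)
    by = pairs["beta_out"].to_numpy(dtype=float)
    sy = pairs["se_out"].to_numpy(dtype=float)
    j = len(bx)
    if j < 2:
        raise ValueError("cochran_q needs >= 2 instruments")
    r = by / bx
    w = (bx / sy) ** 2
    q = float(np.sum(w * (r - beta_ivw) ** 2))
    df = j - 1
    pval = float(np.clip(stats.chi2.sf(q, df), _P_FLOOR, 1.0))
    return q, df, pval


def egger_intercept_test(egger_fit: MREstimate) -> float:
    """p-value of the MR-Egger intercept (two-sided t, J-2 df)."""
    if egger_fit.method != "egger" or "intercept_pval" not in egger_fit.extra:
        raise ValueError("egger_intercept_test expects an egger() estimate")
    return float(egger_fit.extra["intercept_pval"])


def _sum_r2(eaf: np.ndarray, beta: np.ndarray) -> float:
    r2 = np.sum(2.0 * eaf * (1.0 - eaf) * beta**2)
    return float(np.clip(r2, 0.0, np.nextafter(1.0, 0.0)))


def steiger_test(
    pairs: pd.DataFrame,
    n_exp: float | None = None,
    n_out: float | None = None,
) -> tuple[str, float]:
    """Directionality test on total variance explained per side.

    Per-SNP R^2 contributions 2*EAF*(1-EAF)*beta^2 are summed on each side
    (SNPs with a missing EAF on either side are excluded); direction is
    exposure -> outcome iff R^2_exposure > R^2_outcome.  The p-value contrasts
    the two correlation magnitudes: Fisher z of sqrt(R^2) on each side, the
    difference scaled by sqrt(1/(n_exp-3) + 1/(n_out-3)).
    """
    eaf_e = pairs["eaf_exp"].to_numpy(dtype=float)
    eaf_o = pairs["eaf_out"].to_numpy(dtype=float)
    ok = np.isfinite(eaf_e) & np.isfinite(eaf_o) & (eaf_e > 0) & (eaf_e < 1) \
        & (eaf_o > 0) & (eaf_o < 1)
    if not ok.any():
        raise ValueError("steiger_test: no SNP has usable EAF on both sides")
    if (~ok).any():
        logger.info("steiger_test: excluded %d SNP(s) with missing EAF", int((~ok).sum()))
    sub = pairs.loc[ok]
    ne = float(np.median(sub["n_exp"])) if n_exp is None else float(n_exp)
    no = float(np.median(sub["n_out"])) if n_out is None else float(n_out)

    r2_exp = _sum_r2(sub["eaf_exp"].to_numpy(float), sub["beta_exp"].to_numpy(float))
    r2_out = _sum_r2(sub["eaf_out"].to_numpy(float), sub["beta_out"].to_numpy(float))

    if r2_exp == r2_out:
        logger.warning("steiger_test: R2 tie; direction reported as exposure_to_outcome")
        return EXPOSURE_TO_OUTCOME, 1.0
    direction = EXPOSURE_TO_OUTCOME if r2_exp > r2_out else OUTCOME_TO_EXPOSURE
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / np.sqrt(
        1.0 / (ne - 3.0) + 1.0 / (no - 3.0)
    )
    pval = float(np.clip(2.0 * stats.norm.sf(abs(z)), _P_FLOOR, 1.0))
    return direction, pval


def compute_diagnostics(
    pairs: pd.DataFrame,
    ivw_fit: MREstimate | None = None,
    egger_fit: MREstimate | None = None,
    f_aggregate: float = np.nan,
    f_min_per_snp: float = np.nan,
    outcome_binary: bool = False,
) -> DiagnosticsReport:
    """Assemble the full sensitivity report for one instrument set."""
    rep = DiagnosticsReport(f_aggregate=f_aggregate, f_min_per_snp=f_min_per_snp,
                            steiger_approximate=outcome_binary)
    if ivw_fit is not None and len(pairs) >= 2:
        rep.q_stat, rep.q_df, rep.q_pval = cochran_q(pairs, ivw_fit.beta)
    if egger_fit is not None:
        rep.egger_intercept = egger_fit.extra["intercept"]
        rep.egger_intercept_se = egger_fit.extra["intercept_se"]
        rep.egger_intercept_pval = egger_fit.extra["intercept_pval"]
    try:
        rep.steiger_direction, rep.steiger_pval = steiger_test(pairs)
    except ValueError:
        rep.steiger_direction = None
    return rep
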