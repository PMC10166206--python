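import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrlink.gwas_io import COLUMNS, SummaryTable

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def make_table(rows, trait_id="genus.Demo", trait_type="quantitative"):
    """Build a SummaryTable from (snp, chr, pos, ea, oa, eaf, beta, se, p, n) tuples."""
    df = pd.DataFrame(rows, columns=COLUMNS)
    return SummaryTable(trait_id, trait_type, df)


def random_table(rng, n=20, trait_id="genus.Rand", chrom_span=3):
    snps = [f"rs{i}" for i in range(n)]
    rows = []
    for i, s in enumerate(snps):
        rows.append((
            s, str(rng.integers(1, chrom_span + 1)), int(rng.integers(1, 5_000_000)),
            "A", "G", float(rng.uniform(0.05, 0.95)), float(rng.normal(0, 0.1)),
            float(rng.uniform(0.005, 0.05)), float(rng.uniform(1e-12, 1.0)),
            int(rng.integers(5_000, 50_000)),
        ))
    return make_table(rows, trait_id=trait_id)


def make_pairs(beta_exp, beta_out, se_out, se_exp=None, eaf_exp=None, eaf_out=None,
               n_exp=18473, n_out=55374):
    """Harmonized-pair frame straight from effect arrays (all retained)."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    j = len(beta_exp)
    se_exp = np.full(j, 0.01) if se_exp is None else np.asarray(se_exp, dtype=float)
    eaf_exp = np.full(j, 0.3) if eaf_exp is None else np.asarray(eaf_exp, dtype=float)
    eaf_out = eaf_exp.copy() if eaf_out is None else np.asarray(eaf_out, dtype=float)
    return pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(j)],
        "CHR": "1", "POS": np.arange(j) * 10_000_000 + 1,
        "beta_exp": beta_exp, "se_exp": se_exp, "eaf_exp": eaf_exp, "n_exp": n_exp,
        "beta_out": beta_out, "se_out": se_out, "eaf_out": eaf_out, "n_out": n_out,
        "action": "unchanged",
    })


def random_pairs(rng, j):
    bx = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.005, 0.02, j)
    sy = rng.uniform(0.005, 0.03, j)
    by = 0.4 * bx + rng.normal(0, 0.02, j)
    return make_pairs(bx, by, sy, se_exp=sx)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately written unlike the library code paths)

def ivw_oracle(pairs):
    """Zero-intercept WLS via whitened least squares (lstsq, not closed form)."""
    bx = pairs["beta_exp"].to_numpy(float)
    by = pairs["beta_out"].to_numpy(float)
    sy = pairs["se_out"].to_numpy(float)
    X = (bx / sy)[:, None]
    y = by / sy
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[0])


def egger_oracle(pairs):
    """Two-parameter weighted normal equations solved explicitly (2x2 inverse)."""
    bx = pairs["beta_exp"].to_numpy(float).copy()
    by = pairs["beta_out"].to_numpy(float).copy()
    sy = pairs["se_out"].to_numpy(float)
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    w = 1.0 / sy**2
    s_w, s_wx = w.sum(), (w * bx).sum()
    s_wxx, s_wy, s_wxy = (w * bx * bx).sum(), (w * by).sum(), (w * bx * by).sum()
    det = s_w * s_wxx - s_wx**2
    intercept = (s_wxx * s_wy - s_wx * s_wxy) / det
    slope = (s_w * s_wxy - s_wx * s_wy) / det
    return float(slope), float(intercept)


def weighted_median_oracle(pairs):
    """Weighted-median interpolation by explicit bracket search (no np.interp)."""
    bx = pairs["beta_exp"].to_numpy(float)
    by = pairs["beta_out"].to_numpy(float)
    sy = pairs["se_out"].to_numpy(float)
    ratios = by / bx
    weights = (bx / sy) ** 2
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = []
    acc = 0.0
    for wj in w:
        s.append(acc + wj / 2.0)
        acc += wj
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    for k in range(len(s) - 1):
        if s[k] <= 0.5 <= s[k + 1]:
            frac = (0.5 - s[k]) / (s[k + 1] - s[k])
            return float(r[k] + frac * (r[k + 1] - r[k]))
    raise AssertionError("unreachable")


def clump_oracle(df, ld, window_kb, r2_max):
    """Greedy clumping re-enumerated step by step on plain records."""
    recs = df.to_dict("records")
    recs_sorted = sorted(recs, key=lambda r: (r["P"], r["CHR"], r["POS"]))
    kept, removed = [], set()
    for rec in recs_sorted:
        if rec["SNP"] in removed:
            continue
        kept.append(rec["SNP"])
        for other in recs_sorted:
            if other["SNP"] == rec["SNP"] or other["SNP"] in removed or other["SNP"] in kept:
                continue
            if other["CHR"] != rec["CHR"]:
                continue
            if abs(other["POS"] - rec["POS"]) > window_kb * 1000:
                continue
            if ld is None:
                r2 = 1.0
            else:
                try:
                    r2 = float(ld.at[rec["SNP"], other["SNP"]])
                except KeyError:
                    r2 = 0.0
            if r2 > r2_max:
                removed.add(other["SNP"])
    return [r["SNP"] for r in recs if r["SNP"] in kept]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
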