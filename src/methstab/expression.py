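"""RNA count preprocessing (CPM filter, TMM, log2) and the
methylation-expression correlation stage.

TMM follows the published trimmed-mean-of-M-values definition: pairwise
log-ratios (M) and average log-intensities (A) against a reference sample,
rank-trimmed at 30% (M) and 5% (A), combined by inverse asymptotic-variance
weighting, with factors rescaled to geometric mean 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million; every column sums to 1e6."""
    libs = counts.sum(axis=0)
    if (libs <= 0).any():
        bad = libs.index[libs <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    return counts / libs * 1e6


def cpm_filter(counts: pd.DataFrame, cpm_cut: float = 1.0, frac: float = 0.90) -> list[str]:
    """Genes with CPM > cpm_cut in at least ``frac`` of samples."""
    c = cpm(counts)
    ok = (c > cpm_cut).mean(axis=1) >= frac
    return counts.index[ok].tolist()


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
    do_weighting: bool,
) -> float:
    f_obs = obs / lib_obs
    f_ref = ref / lib_ref
    fin = (f_obs > 0) & (f_ref > 0)
    logR = np.log2(f_obs[fin] / f_ref[fin])
    absE = 0.5 * np.log2(f_obs[fin] * f_ref[fin])
    v = (lib_obs - obs[fin]) / (lib_obs * obs[fin]) + (lib_ref - ref[fin]) / (
        lib_ref * ref[fin]
    )
    if logR.size == 0:
        return 1.0
    if np.abs(logR).max() < 1e-6:
        return 1.0
    n = logR.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(logR)
    rank_a = stats.rankdata(absE)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    if do_weighting:
        f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(logR[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    ref: str | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    do_weighting: bool = True,
) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean 1.

    ``ref=None`` picks the sample whose 75th count-fraction percentile is
    closest to the mean across samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    libs = mat.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("samples with zero library size")
    if ref is None:
        f75 = np.quantile(mat / libs, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref)
    factors = np.array(
        [
            _tmm_pair(
                mat[:, j], mat[:, ref_idx], libs[j], libs[ref_idx],
                logratio_trim, sum_trim, do_weighting,
            )
            for j in range(mat.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log2_tmm_cpm(
    counts: pd.DataFrame, factors: pd.Series | None = None, prior: float = 1.0
) -> pd.DataFrame:
    """log2(CPM + prior) with TMM-effective library sizes; always finite."""
    if factors is None:
        factors = tmm_factors(counts)
    eff = counts.sum(axis=0) * factors
    return np.log2(counts / eff * 1e6 + prior)


def correlate_probe_expression(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    mapping: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each TSS probe with its mapped gene.

    ``meth`` is probes x samples on the chosen scale (M by default upstream),
    ``expr`` genes x samples; only shared samples are used, pairing the same
    sample's methylation and expression values.  Pairs where either vector
    is constant are reported with NaN r and flagged non-significant.
    """
    samples = meth.columns.intersection(expr.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 paired samples")
    rows = []
    for probe, gene in mapping.items():
        if probe not in meth.index or gene not in expr.index:
            continue
        x = meth.loc[probe, samples].to_numpy(dtype=float)
        y = expr.loc[gene, samples].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((probe, gene, np.nan, np.nan, False))
            continue
        res = stats.pearsonr(x, y)
        rows.append(
            (probe, gene, float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha))
        )
    return pd.DataFrame(
        rows, columns=["probe_id", "gene_symbol", "r", "p_value", "significant"]
    )


def expression_probe_sets(correlations: pd.DataFrame) -> dict[str, list[str]]:
    """Partition tested TSS probes into expression-correlated vs not."""
    tested = correlations.dropna(subset=["r"])
    return {
        "expression_correlated": tested.loc[tested["significant"], "probe_id"].tolist(),
        "expression_uncorrelated": tested.loc[~tested["significant"], "probe_id"].tolist(),
    }
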