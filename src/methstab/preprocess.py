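"""Beta/M conversions and detection-p based quality filters.

The filter order is fixed: samples first (mean detection p across probes),
then probes (fraction of failing samples among the retained samples, plus
sex-chromosome removal).  Both cut-offs are strict inequalities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: beta values of exactly 0 or 1 are clipped here before the logit2 transform
BETA_CLIP = 1e-6

SEX_CHROMOSOMES = ("chrX", "chrY")


def beta_to_m(beta):
    """logit2 transform: M = log2(beta / (1 - beta)).

    Accepts scalars or arrays; values of exactly 0/1 are clipped to
    ``[BETA_CLIP, 1 - BETA_CLIP]`` so the transform stays finite.
    """
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, BETA_CLIP, 1.0 - BETA_CLIP)
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse logit2: beta = 2**M / (2**M + 1), numerically stable."""
    m = np.asarray(m, dtype=float)
    # expit in base 2: avoids overflow for large |M|
    out = np.where(m >= 0, 1.0 / (1.0 + np.exp2(-m)), np.exp2(m) / (np.exp2(m) + 1.0))
    return out if out.ndim else float(out)


def filter_samples(detp: pd.DataFrame, threshold: float = 0.05) -> list[str]:
    """Samples whose mean detection p-value over probes is below ``threshold``.

    Returns the retained sample ids in matrix column order.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if detp.size == 0:
        raise ValueError("empty detection p-value matrix")
    mean_p = detp.mean(axis=0)
    return [s for s in detp.columns if mean_p[s] < threshold]


def filter_probes(
    detp: pd.DataFrame,
    annotation: pd.DataFrame,
    p_cut: float = 0.05,
    frac_cut: float = 0.10,
) -> list[str]:
    """Probes passing the detection-rate rule and not on sex chromosomes.

    A probe is dropped when its detection p exceeds ``p_cut`` in strictly
    more than ``frac_cut`` of samples, or when it maps to chrX/chrY.
    ``detp`` should already be restricted to the retained samples.
    """
    if not (0 < p_cut < 1 and 0 < frac_cut < 1):
        raise ValueError("p_cut and frac_cut must lie in (0, 1)")
    if detp.size == 0:
        raise ValueError("empty detection p-value matrix")
    ann = annotation.set_index("probe_id")
    missing = detp.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"annotation missing probes: {missing[:5].tolist()}")
    fail_frac = (detp > p_cut).mean(axis=1)
    chrom = ann.loc[detp.index, "chromosome"]
    keep = (fail_frac <= frac_cut) & ~chrom.isin(SEX_CHROMOSOMES)
    return detp.index[keep].tolist()


def apply_filters(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    annotation: pd.DataFrame,
    sample_threshold: float = 0.05,
    p_cut: float = 0.05,
    frac_cut: float = 0.10,
):
    """Run the sample filter then the probe filter; return filtered copies.

    Returns ``(beta, detp, kept_samples, kept_probes)``.
    """
    samples = filter_samples(detp, sample_threshold)
    detp_s = detp[samples]
    probes = filter_probes(detp_s, annotation, p_cut, frac_cut)
    return beta.loc[probes, samples], detp_s.loc[probes], samples, probes


def normalization_hook(beta: pd.DataFrame) -> pd.DataFrame:
    """Pass-through for already-normalized input (normalization is upstream)."""
    return beta
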