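"""Stress-session methylation changes at highly stable TSS probes.

Probes stable (ICC >= 0.90) across every NoStress scenario and the
cross-session baseline, and located in gene TSSs, are tested for mean
changes at T2/T3/T4 versus T1 within the Stress session.  The
repeated-measures model is a subject-random-intercept linear mixed model
with timepoint as a categorical factor (T1 reference) plus monocyte and
batch covariates; Wald t-tests on the timepoint coefficients give the
per-contrast p-values, and significance is Bonferroni-corrected over the
tested probe list.  Models are fitted on both scales: the M-scale fit
supplies the p-values, the beta-scale fit the parallel effect estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .icc import REMLFitter, VAR_UNDEFINED
from .scenarios import NOSTRESS_AND_CROSS

HIGH_STABILITY = 0.90

CONTRASTS = ("T2", "T3", "T4")


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def select_highly_stable(
    icc_tables: pd.DataFrame,
    annotation: pd.DataFrame,
    threshold: float = HIGH_STABILITY,
    scenarios: tuple[str, ...] = NOSTRESS_AND_CROSS,
    value: str = "icc21",
) -> list[str]:
    """Probes with ICC >= threshold in every listed scenario, restricted to TSS.

    ``icc_tables`` is the long-format table covering (at least) the NoStress
    scenarios and CrossSessionT1; a missing scenario is an error.
    """
    present = set(icc_tables["scenario"].unique())
    missing = [s for s in scenarios if s not in present]
    if missing:
        raise ValueError(f"missing scenario tables: {missing}")
    wide = icc_tables[icc_tables["scenario"].isin(scenarios)].pivot(
        index="probe_id", columns="scenario", values=value
    )
    stable = wide.index[(wide >= threshold).all(axis=1) & wide.notna().all(axis=1)]
    tss = set(
        annotation.loc[annotation["feature_class"] == "TSS", "probe_id"]
    )
    return [p for p in stable if p in tss]


def _stress_design(sheet: pd.DataFrame, covariates=("monocyte", "batch")):
    d = sheet[sheet["session"] == "Stress"].sort_values("sample_id").reset_index(drop=True)
    if d.empty:
        raise ValueError("no Stress-session samples in sheet")
    cols = [np.ones(len(d))]
    names = ["intercept"]
    tps = sorted(t for t in d["timepoint"].unique() if t != "T1")
    if "T1" not in set(d["timepoint"]) or not tps:
        raise ValueError("stress design needs T1 plus at least one later timepoint")
    for tp in tps:
        cols.append((d["timepoint"] == tp).astype(float).to_numpy())
        names.append(tp)
    if "monocyte" in covariates:
        cols.append(d["monocyte_proportion"].to_numpy(dtype=float))
        names.append("monocyte_proportion")
    if "batch" in covariates:
        batches = pd.Categorical(d["batch"])
        for lvl in batches.categories[1:]:
            cols.append((batches == lvl).astype(float))
            names.append(f"batch[{lvl}]")
    X = np.column_stack(cols)
    subj = pd.Categorical(d["subject_id"]).codes.astype(np.int64)
    return d, X, names, subj


def fit_stress_model(
    y: np.ndarray,
    design_sheet: pd.DataFrame,
    covariates=("monocyte", "batch"),
    _prebuilt=None,
) -> pd.DataFrame:
    """Per-contrast estimates for one probe on one scale.

    ``y`` must align with the Stress-session rows of ``design_sheet``
    ordered by sample_id.  Returns one row per contrast with columns
    (contrast, intercept, estimate, se, p_value).  A constant response
    yields zero estimates with p = 1.
    """
    if _prebuilt is None:
        d, X, names, subj = _stress_design(design_sheet, covariates)
        fitter = REMLFitter(X, [subj])
    else:
        d, X, names, subj, fitter = _prebuilt
    y = np.asarray(y, dtype=float)
    if len(y) != len(d):
        raise ValueError("y length does not match the stress design")
    contrasts = [nm for nm in names if nm in CONTRASTS]
    if np.var(y) < VAR_UNDEFINED:
        return pd.DataFrame(
            {
                "contrast": contrasts,
                "intercept": float(y[0]),
                "estimate": 0.0,
                "se": 0.0,
                "p_value": 1.0,
            }
        )
    s2, beta, cov_beta, converged, _ = fitter.fit(y)
    n_subj = len(np.unique(subj))
    dof = max(len(y) - X.shape[1] - (n_subj - 1), 1)
    rows = []
    for nm in contrasts:
        j = names.index(nm)
        est = float(beta[j])
        se = float(np.sqrt(max(cov_beta[j, j], 0.0)))
        if se == 0 or not converged:
            p = 1.0
        else:
            p = float(2.0 * stats.t.sf(abs(est) / se, dof))
        rows.append((nm, float(beta[0]), est, se, p))
    return pd.DataFrame(
        rows, columns=["contrast", "intercept", "estimate", "se", "p_value"]
    )


def stress_effect_table(
    beta: pd.DataFrame,
    m_values: pd.DataFrame,
    sheet: pd.DataFrame,
    probes: list[str],
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    covariates=("monocyte", "batch"),
) -> pd.DataFrame:
    """Stress-effect table over a highly-stable probe list.

    One row per probe x contrast, carrying beta-scale and M-scale intercepts
    and estimates; p-values come from the M-scale model.  The Bonferroni
    flag uses m = number of tested probes (the threshold is always computed
    from the list, never hard-coded).
    """
    if not probes:
        raise ValueError("empty probe list")
    d, X, names, subj = _stress_design(sheet, covariates)
    fitter = REMLFitter(X, [subj])
    prebuilt = (d, X, names, subj, fitter)
    gene_of = annotation.set_index("probe_id")["gene_symbol"]
    thr = bonferroni_threshold(alpha, len(probes))
    rows = []
    for pid in probes:
        ym = m_values.loc[pid, d["sample_id"]].to_numpy(dtype=float)
        yb = beta.loc[pid, d["sample_id"]].to_numpy(dtype=float)
        fit_m = fit_stress_model(ym, sheet, covariates, _prebuilt=prebuilt)
        fit_b = fit_stress_model(yb, sheet, covariates, _prebuilt=prebuilt)
        for (_, rm), (_, rb) in zip(fit_m.iterrows(), fit_b.iterrows()):
            rows.append(
                {
                    "probe_id": pid,
                    "gene_symbol": gene_of.get(pid, ""),
                    "contrast": rm["contrast"],
                    "beta_scale_intercept": rb["intercept"],
                    "beta_scale_estimate": rb["estimate"],
                    "m_scale_intercept": rm["intercept"],
                    "m_scale_estimate": rm["estimate"],
                    "p_value": rm["p_value"],
                    "bonferroni_significant": bool(rm["p_value"] < thr),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = thr
    out.attrs["n_tested_probes"] = len(probes)
    return out
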