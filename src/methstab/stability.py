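"""Summaries, comparisons, clustering, subsampling and group stratification
of per-probe ICC tables.

Throughout, the inclusion rule is the one used for all descriptive analyses:
probes with ICC < 0.01 are excluded (kept only as a count), and the bin
edges are half-open at the printed boundaries with exactly 0.01 included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .icc import REMLFitter, build_design, compute_scenario_icc, VAR_UNDEFINED
from .scenarios import Scenario

LOW_ICC = 0.01

BIN_LABELS = ("<0.01", "0.01-0.50", "0.50-0.75", "0.75-0.90", ">0.90")
_BIN_EDGES = (LOW_ICC, 0.50, 0.75, 0.90)


@dataclass
class StabilitySummary:
    scenario: str
    mean: float
    sd: float
    median: float
    skewness: float
    excess_kurtosis: float
    n_included: int
    n_excluded_low: int


def summarize(
    icc_values, scenario: str = "", exclude_below: float = LOW_ICC
) -> StabilitySummary:
    """Moments of an ICC distribution after the low-stability exclusion.

    Skewness is the bias-corrected Fisher-Pearson G1 and kurtosis the
    bias-corrected excess G2; a constant vector gets skew = kurtosis = 0 by
    convention.
    """
    v = np.asarray(icc_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty ICC slice")
    included = v[v >= exclude_below]
    n_low = int(v.size - included.size)
    if included.size == 0:
        raise ValueError("all probes excluded by the low-ICC rule")
    if included.size > 2 and np.std(included) > 0:
        skew = float(stats.skew(included, bias=False))
        kurt = float(stats.kurtosis(included, fisher=True, bias=False))
    else:
        skew = 0.0
        kurt = 0.0
    return StabilitySummary(
        scenario=scenario,
        mean=float(np.mean(included)),
        sd=float(np.std(included, ddof=1)) if included.size > 1 else 0.0,
        median=float(np.median(included)),
        skewness=skew,
        excess_kurtosis=kurt,
        n_included=int(included.size),
        n_excluded_low=n_low,
    )


def bin_probes(icc_values) -> pd.DataFrame:
    """Counts and percentages in the five stability bins.

    Bins: [0, 0.01), [0.01, 0.50), [0.50, 0.75), [0.75, 0.90), [0.90, 1].
    """
    v = np.asarray(icc_values, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("ICC values must lie in [0, 1]")
    edges = [-np.inf, *_BIN_EDGES, np.inf]
    counts = np.histogram(v, bins=edges)[0]
    pct = 100.0 * counts / v.size if v.size else np.zeros(len(BIN_LABELS))
    return pd.DataFrame({"bin": BIN_LABELS, "count": counts, "percent": pct})


def compare_paired(icc_a, icc_b) -> tuple[float, float]:
    """Paired t-test of matched per-probe stability vectors.

    Returns (beta, p) where beta = mean(A - B).  Degenerate zero-variance
    differences get p = 1 for beta = 0 and p = 0 otherwise.
    """
    a = np.asarray(icc_a, dtype=float)
    b = np.asarray(icc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 shared probes")
    diff = a - b
    beta = float(diff.mean())
    if np.std(diff) == 0:
        return beta, 1.0 if beta == 0 else 0.0
    t, p = stats.ttest_rel(a, b)
    return beta, float(p)


def low_icc_chisq(counts_a: tuple[int, int], counts_b: tuple[int, int]) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on the 2x2 table
    of (ICC < 0.01, ICC >= 0.01) counts for two scenarios/groups.
    """
    table = np.array([counts_a, counts_b], dtype=float)
    if (table < 0).any():
        raise ValueError("negative cell counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    if np.allclose(table[0], table[1]):
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def _icc_wide(tables: pd.DataFrame, value: str = "icc21") -> pd.DataFrame:
    """Pivot a long ICC table (one row per probe x scenario) to wide."""
    return tables.pivot(index="probe_id", columns="scenario", values=value)


def scenario_correlations(
    tables: pd.DataFrame, value: str = "icc21", exclude_below: float = LOW_ICC
) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-probe stability across scenarios.

    Each pair uses the probes included (ICC >= 0.01) in both members.
    """
    wide = _icc_wide(tables, value)
    names = list(wide.columns)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, si in enumerate(names):
        for j in range(i + 1, len(names)):
            sj = names[j]
            mask = (wide[si] >= exclude_below) & (wide[sj] >= exclude_below)
            if mask.sum() < 3:
                raise ValueError(f"too few shared probes for {si} vs {sj}")
            r = stats.pearsonr(wide.loc[mask, si], wide.loc[mask, sj]).statistic
            out.loc[si, sj] = out.loc[sj, si] = float(r)
    return out


def cluster_scenarios(
    tables: pd.DataFrame, value: str = "icc21", exclude_below: float = LOW_ICC
):
    """Complete-linkage Euclidean clustering of scenarios on probe ICC vectors.

    Probes included (ICC >= 0.01) in every scenario form the feature space.
    Returns (linkage_matrix, scenario_labels).
    """
    wide = _icc_wide(tables, value)
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 scenarios to cluster")
    keep = (wide >= exclude_below).all(axis=1)
    data = wide.loc[keep].to_numpy().T  # scenarios x probes
    if data.shape[1] == 0:
        raise ValueError("no probes included in all scenarios")
    Z = hierarchy.linkage(data, method="complete", metric="euclidean")
    return Z, list(wide.columns)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def subsample_icc(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    scenario: Scenario,
    n_sub: int = 14,
    per_probe_resample: bool = True,
    seed: int = 0,
    adjust: bool = True,
    include_batch: bool = True,
) -> pd.DataFrame:
    """ICC table from random subject subsamples of size ``n_sub``.

    With ``per_probe_resample`` every probe gets an independent subject
    draw (each probe's stability comes from a different random subsample);
    otherwise one draw is shared.  Fully reproducible from ``seed``.
    """
    design_all = scenario.select(sheet)
    subjects = np.array(sorted(design_all["subject_id"].unique()))
    if n_sub > len(subjects):
        raise ValueError(f"n_sub={n_sub} exceeds {len(subjects)} available subjects")
    rng = np.random.default_rng(seed)
    if n_sub == len(subjects):
        return compute_scenario_icc(beta, sheet, scenario, adjust, include_batch)
    if not per_probe_resample:
        chosen = rng.choice(subjects, size=n_sub, replace=False)
        return compute_scenario_icc(
            beta, sheet, scenario, adjust, include_batch, subjects=list(chosen)
        )
    nt = scenario.nt
    rows = []
    for pid in beta.index:
        chosen = rng.choice(subjects, size=n_sub, replace=False)
        design = design_all[design_all["subject_id"].isin(chosen)]
        y = beta.loc[pid, design["sample_id"]].to_numpy(dtype=float)
        if np.var(y) < VAR_UNDEFINED:
            rows.append((pid, scenario.name, 0.0, 0.0, adjust, False))
            continue
        X, _, subj, occ = build_design(design, adjust, include_batch)
        fitter = REMLFitter(X, [subj, occ])
        s2, _, _, converged, _ = fitter.fit(y)
        total = s2.sum()
        if not converged or total <= 0:
            rows.append((pid, scenario.name, 0.0, 0.0, adjust, False))
            continue
        rows.append(
            (
                pid,
                scenario.name,
                float(s2[0] / total),
                float(nt * s2[0] / (nt * s2[0] + s2[1] + s2[2])),
                adjust,
                True,
            )
        )
    return pd.DataFrame(
        rows, columns=["probe_id", "scenario", "icc21", "icc2k", "adjusted", "converged"]
    )


def stratify_by_group(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    scenario: Scenario,
    group_field: str = "group",
    adjust: bool = True,
    include_batch: bool = True,
    value: str = "icc21",
):
    """Per-group ICC tables plus the paired-t and low-ICC chi-square comparison.

    Returns ``(table_by_group, comparison)`` where ``comparison`` holds the
    paired mean difference (first group minus second), its p-value, and the
    chi-square p for the ICC < 0.01 count difference.
    """
    groups = sorted(sheet[group_field].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    tables = {}
    for g in groups:
        members = sheet.loc[sheet[group_field] == g, "subject_id"].unique()
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        tables[g] = compute_scenario_icc(
            beta, sheet, scenario, adjust, include_batch, subjects=list(members)
        )
    a = tables[groups[0]].set_index("probe_id")[value]
    b = tables[groups[1]].set_index("probe_id")[value]
    shared = a.index.intersection(b.index)
    beta_diff, p = compare_paired(a.loc[shared], b.loc[shared])
    chi_stat, chi_p = low_icc_chisq(
        (int((a < LOW_ICC).sum()), int((a >= LOW_ICC).sum())),
        (int((b < LOW_ICC).sum()), int((b >= LOW_ICC).sum())),
    )
    comparison = {
        "groups": groups,
        "beta": beta_diff,
        "p_value": p,
        "chisq_stat": chi_stat,
        "chisq_p": chi_p,
    }
    return tables, comparison
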