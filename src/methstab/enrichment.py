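"""Preranked permutation enrichment of probe sets against ICC rankings.

The statistic is the weighted Kolmogorov-Smirnov running sum used by
preranked GSEA: walking down the ICC-ranked probe list, the sum rises by
|stat|^p / sum(|stat in set|^p) on set members and falls by 1 / (N - |S|)
otherwise; the enrichment score (ES) is the maximal signed deviation.  The
null is random probe sets of the same size ("gene-set" permutation), and the
one-sided p-value for enrichment toward high stability is
(1 + #{ES_null >= ES_obs}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: probe sets larger than this are down-sampled before testing
SET_SIZE_CAP = 35_000
#: sets with fewer overlapping probes than this are rejected
MIN_OVERLAP = 5

#: published probe-set cardinalities used when fabricating synthetic sets
PUBLISHED_SET_SIZES = {
    "Horvath": 353,
    "Hannum": 89,
    "PhenoAge": 513,
    "PCClock": 78_464,
    "DunedinPACE": 173,
    "IDOL6": 450,
    "IDOLExtended": 1_200,
}


@dataclass(frozen=True)
class ProbeSet:
    name: str
    probe_ids: tuple[str, ...]
    source_tag: str = "custom"

    def __post_init__(self):
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError(f"duplicate probe ids in set {self.name!r}")


@dataclass
class EnrichmentResult:
    set_name: str
    scenario: str
    es: float
    nes: float
    p_value: float
    n_perm: int
    n_overlap: int


def rank_probes(icc_slice, exclude_below: float = 0.01) -> pd.Series:
    """Descending ICC ranking after the low-stability exclusion.

    Ties are broken by probe id (lexicographic), making the ranking
    deterministic.
    """
    s = pd.Series(icc_slice, dtype=float)
    s = s[s >= exclude_below]
    if s.empty:
        raise ValueError("no probes left after the low-ICC exclusion")
    order = sorted(s.index, key=lambda pid: (-s[pid], pid))
    return s.loc[order]


def _hit_positions(ranked_index, probe_ids) -> np.ndarray:
    lookup = {pid: i for i, pid in enumerate(ranked_index)}
    pos = sorted(lookup[p] for p in probe_ids if p in lookup)
    return np.asarray(pos, dtype=np.int64)


def _es_from_positions(pos: np.ndarray, stats_pow: np.ndarray, n: int) -> float:
    """ES for sorted 0-based hit positions; stats_pow = |stat|^p over the list."""
    m = len(pos)
    w = stats_pow[pos]
    total = w.sum()
    if total <= 0:
        # all-zero weights (possible with p=1 and zero stats): unweighted steps
        w = np.ones(m)
        total = float(m)
    cumw = np.cumsum(w) / total
    j = np.arange(1, m + 1)
    if n == m:
        # set covers the universe: running sum climbs straight to 1
        return 1.0
    miss = 1.0 / (n - m)
    top = cumw - (pos + 1 - j) * miss
    bottom = np.concatenate(([0.0], cumw[:-1])) - (pos - (j - 1)) * miss
    es_pos = top.max()
    es_neg = bottom.min()
    return float(es_pos if es_pos >= -es_neg else es_neg)


def enrichment_score(ranked: pd.Series, probe_set, weight: float = 1.0) -> float:
    """ES of a probe set against a ranked statistic (descending order)."""
    ids = probe_set.probe_ids if isinstance(probe_set, ProbeSet) else probe_set
    pos = _hit_positions(ranked.index, ids)
    if len(pos) == 0:
        raise ValueError("probe set does not intersect the ranked universe")
    stats_pow = np.abs(ranked.to_numpy(dtype=float)) ** weight
    return _es_from_positions(pos, stats_pow, len(ranked))


def _null_es(
    stats_pow: np.ndarray, n: int, m: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` uniformly random m-subsets, vectorized in chunks."""
    chunk = max(1, min(n_perm, int(2e7 // max(n, 1))))
    if n_perm > chunk:
        return np.concatenate(
            [
                _null_es(stats_pow, n, m, min(chunk, n_perm - i), rng)
                for i in range(0, n_perm, chunk)
            ]
        )
    keys = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(keys, m - 1, axis=1)[:, :m], axis=1)
    w = stats_pow[pos]
    totals = w.sum(axis=1, keepdims=True)
    bad = totals[:, 0] <= 0
    if bad.any():
        w[bad] = 1.0
        totals[bad] = m
    cumw = np.cumsum(w, axis=1) / totals
    j = np.arange(1, m + 1)
    if n == m:
        return np.ones(n_perm)
    miss = 1.0 / (n - m)
    top = cumw - (pos + 1 - j) * miss
    bottom = np.concatenate(
        (np.zeros((n_perm, 1)), cumw[:, :-1]), axis=1
    ) - (pos - (j - 1)) * miss
    es_pos = top.max(axis=1)
    es_neg = bottom.min(axis=1)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def permutation_pvalue(
    ranked: pd.Series,
    probe_set,
    n_perm: int = 10_000,
    seed: int = 0,
    weight: float = 1.0,
    scenario: str = "",
    size_cap: int = SET_SIZE_CAP,
    min_overlap: int = MIN_OVERLAP,
    alternative: str = "greater",
    _null: np.ndarray | None = None,
) -> EnrichmentResult:
    """Permutation enrichment of one probe set.

    ``alternative='greater'`` tests enrichment toward high ICC (the reported
    direction); ``'two-sided'`` doubles the smaller tail.  ``_null`` lets
    callers reuse a precomputed null ES sample of matching size.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if isinstance(probe_set, ProbeSet):
        name, ids = probe_set.name, list(probe_set.probe_ids)
    else:
        name, ids = "custom", list(probe_set)
    rng = np.random.default_rng(seed)
    if len(ids) > size_cap:
        ids = list(rng.choice(np.array(ids, dtype=object), size=size_cap, replace=False))
    pos = _hit_positions(ranked.index, ids)
    m = len(pos)
    if m < min_overlap:
        raise ValueError(
            f"set {name!r}: only {m} probes overlap the universe (floor {min_overlap})"
        )
    stats_pow = np.abs(ranked.to_numpy(dtype=float)) ** weight
    n = len(ranked)
    es_obs = _es_from_positions(pos, stats_pow, n)
    null = _null if _null is not None else _null_es(stats_pow, n, m, n_perm, rng)
    n_ge = int((null >= es_obs).sum())
    p_greater = (1 + n_ge) / (len(null) + 1)
    if alternative == "greater":
        p = p_greater
    elif alternative == "two-sided":
        n_le = int((null <= es_obs).sum())
        p = min(1.0, 2.0 * min(p_greater, (1 + n_le) / (len(null) + 1)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    same_sign = null[np.sign(null) == np.sign(es_obs)] if es_obs != 0 else null
    nes = float(es_obs / np.abs(same_sign).mean()) if len(same_sign) else float("nan")
    return EnrichmentResult(
        set_name=name,
        scenario=scenario,
        es=float(es_obs),
        nes=nes,
        p_value=float(p),
        n_perm=len(null),
        n_overlap=m,
    )


def enrich_sets(
    icc_slice,
    probe_sets: dict[str, list[str]],
    scenario: str = "",
    n_perm: int = 10_000,
    seed: int = 0,
    weight: float = 1.0,
    exclude_below: float = 0.01,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Run permutation enrichment for every probe set; one row per set.

    Sets failing the overlap floor are reported with NaN scores rather than
    aborting the batch.
    """
    ranked = rank_probes(icc_slice, exclude_below)
    rows = []
    for i, (name, ids) in enumerate(probe_sets.items()):
        try:
            res = permutation_pvalue(
                ranked,
                ProbeSet(name, tuple(ids)),
                n_perm=n_perm,
                seed=seed + i,
                weight=weight,
                scenario=scenario,
                alternative=alternative,
            )
            rows.append(
                (name, scenario, res.es, res.nes, res.p_value, res.n_perm, res.n_overlap)
            )
        except ValueError:
            rows.append((name, scenario, np.nan, np.nan, np.nan, n_perm, 0))
    return pd.DataFrame(
        rows,
        columns=["set_name", "scenario", "es", "nes", "p_value", "n_perm", "n_overlap"],
    )


def fabricate_probe_sets(
    annotation: pd.DataFrame,
    seed: int = 0,
    sizes: dict[str, int] | None = None,
) -> dict[str, list[str]]:
    """Synthetic probe-set collection mirroring the published set structure.

    Clock and cell-estimator memberships are random draws at the published
    cardinalities (capped by the universe size); feature-class, mQTL and
    circadian sets come from the annotation itself.
    """
    rng = np.random.default_rng(seed)
    sizes = dict(PUBLISHED_SET_SIZES if sizes is None else sizes)
    probes = annotation["probe_id"].to_numpy(dtype=object)
    out: dict[str, list[str]] = {}
    for name, size in sizes.items():
        k = min(size, len(probes) // 2)
        out[name] = sorted(rng.choice(probes, size=k, replace=False))
    for feat, grp in annotation.groupby("feature_class"):
        out[f"feature:{feat}"] = grp["probe_id"].tolist()
    out["mQTL"] = annotation.loc[annotation["mQTL"], "probe_id"].tolist()
    out["circadian_TSS"] = annotation.loc[
        annotation["circadian_TSS"], "probe_id"
    ].tolist()
    return out
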