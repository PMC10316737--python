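"""Synthetic EPIC-style cohort generator with known ground truth.

Each probe's M-values follow the crossed random-effects model the ICC engine
assumes (subject effect, occasion effect shared across subjects, residual),
plus monocyte and batch fixed effects, optional Stress-session mean shifts on
a planted set of responsive probes, and residual-variance inflation for the
ELA group under stress.  M-values are converted to beta values for output, so
the generated cohort looks like a normalized methylation-array export while
every probe retains an analytic true ICC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import SimConfig
from .preprocess import m_to_beta
from .scenarios import SCENARIOS

CIRCADIAN_GENES = (
    "CLOCK", "NPAS2", "BMAL1", "BMAL2", "PER1", "PER2", "PER3", "CRY1", "CRY2",
)


def true_icc(components, icc_type: str = "2,1", nt: int | None = None) -> float:
    """Analytic ICC from a variance-component triple.

    ICC(2,1) = s2_subject / (s2_subject + s2_time + s2_resid);
    ICC(2,k) replaces s2_subject with nt * s2_subject in both numerator and
    the subject term of the denominator.
    """
    s2w, s2v, s2e = (float(c) for c in components)
    if min(s2w, s2v, s2e) < 0:
        raise ValueError("variance components must be non-negative")
    if s2w + s2v + s2e == 0:
        raise ValueError("ICC undefined for all-zero variance components")
    if icc_type in ("2,1", "2_1", "21"):
        return s2w / (s2w + s2v + s2e)
    if icc_type in ("2,k", "2_k", "2k"):
        if nt is None or nt < 2:
            raise ValueError("ICC(2,k) requires nt >= 2")
        return nt * s2w / (nt * s2w + s2v + s2e)
    raise ValueError(f"unknown icc_type {icc_type!r}")


@dataclass
class SimTruth:
    """Ground truth of one generated cohort (the recovery-test oracle)."""

    probe_class: pd.Series                  # probe_id -> class name
    components: pd.DataFrame                # probe_id x (sigma2_subject, sigma2_time, sigma2_resid)
    true_icc21: pd.Series                   # probe_id -> ICC(2,1)
    true_icc2k: pd.DataFrame                # probe_id x scenario -> ICC(2,k) with scenario nt
    stress_responsive: dict[str, dict[str, float]]   # probe -> {timepoint: M shift}
    expression_map: dict[str, str]          # coupled probe -> gene symbol
    failed_samples: list[str]               # planted detection failures

    def to_json(self, path) -> None:
        payload = {
            "probe_class": self.probe_class.to_dict(),
            "components": {
                p: list(map(float, row))
                for p, row in zip(self.components.index, self.components.to_numpy())
            },
            "true_icc21": {p: float(v) for p, v in self.true_icc21.items()},
            "true_icc2k": {
                p: {s: float(v) for s, v in row.items()}
                for p, row in self.true_icc2k.iterrows()
            },
            "stress_responsive": self.stress_responsive,
            "expression_map": self.expression_map,
            "failed_samples": self.failed_samples,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class Cohort:
    beta: pd.DataFrame
    detection_p: pd.DataFrame
    sheet: pd.DataFrame
    annotation: pd.DataFrame
    counts: pd.DataFrame
    truth: SimTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_matrix(self.beta, outdir / "beta.tsv")
        mio.write_matrix(self.detection_p, outdir / "detection_p.tsv")
        mio.write_sample_sheet(self.sheet, outdir / "sample_sheet.csv")
        mio.write_annotation(self.annotation, outdir / "annotation.csv")
        mio.write_matrix(self.counts, outdir / "counts.tsv")
        self.truth.to_json(outdir / "truth.json")


def _class_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n probes to classes."""
    names = list(mix)
    exact = np.array([mix[c] * n for c in names])
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    order = np.argsort(-(exact - base))
    for i in order[:short]:
        base[i] += 1
    return dict(zip(names, base))


def _make_sheet(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    cov = config.covariate_spec
    subjects, groups = [], []
    for g_idx, group in enumerate(config.groups):
        for s in range(config.n_subjects_per_group):
            subjects.append(f"sub{g_idx * config.n_subjects_per_group + s + 1:03d}")
            groups.append(group)
    batch_of = {
        s: f"array{(i % cov.n_batches) + 1}" for i, s in enumerate(subjects)
    }
    base_mono = {
        s: rng.normal(cov.monocyte_mean, cov.monocyte_between_sd) for s in subjects
    }
    rows = []
    for subj, group in zip(subjects, groups):
        for session in config.sessions:
            for tp in config.timepoints:
                mono = (
                    base_mono[subj]
                    + cov.monocyte_diurnal.get(tp, 0.0)
                    + rng.normal(0.0, cov.monocyte_within_sd)
                )
                rows.append(
                    {
                        "sample_id": f"{subj}_{session}_{tp}",
                        "subject_id": subj,
                        "session": session,
                        "timepoint": tp,
                        "batch": batch_of[subj],
                        "group": group,
                        "monocyte_proportion": float(np.clip(mono, 0.01, 0.60)),
                    }
                )
    return pd.DataFrame(rows)


def _make_annotation(
    config: SimConfig, probe_ids: list[str], probe_class: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(probe_ids)
    feat_names = list(config.feature_class_mix)
    feats = rng.choice(
        feat_names, size=n, p=[config.feature_class_mix[f] for f in feat_names]
    ).astype(object)
    # circadian-class probes sit at the TSS of core clock genes
    circ = (probe_class == "circadian").to_numpy()
    feats[circ] = "TSS"
    chroms = np.array([f"chr{c}" for c in rng.integers(1, 23, size=n)], dtype=object)
    n_sex = int(round(config.sex_probe_fraction * n))
    if n_sex:
        sex_idx = rng.choice(n, size=n_sex, replace=False)
        chroms[sex_idx] = rng.choice(["chrX", "chrY"], size=n_sex)
    genes = np.array([f"GENE{i + 1:05d}" for i in range(n)], dtype=object)
    genes[circ] = [CIRCADIAN_GENES[i % len(CIRCADIAN_GENES)] for i in range(circ.sum())]
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chroms,
            "position": rng.integers(1, 2_000_000_00, size=n),
            "feature_class": feats,
            "gene_symbol": genes,
            "mQTL": rng.random(n) < config.mqtl_fraction,
            "circadian_TSS": circ,
        }
    )


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate one cohort; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    sheet = _make_sheet(config, rng)
    n_samples = len(sheet)
    n_probes = config.n_probes

    counts_by_class = _class_counts(dict(config.probe_class_mix), n_probes)
    classes = np.concatenate(
        [np.repeat(name, k) for name, k in counts_by_class.items()]
    )
    rng.shuffle(classes)
    probe_ids = [f"cg{i + 1:08d}" for i in range(n_probes)]
    probe_class = pd.Series(classes, index=probe_ids, name="probe_class")

    annotation = _make_annotation(config, probe_ids, probe_class, rng)

    comp = np.array(
        [config.variance_spec[c].as_tuple() for c in classes], dtype=float
    )
    sd_w, sd_v, sd_e = np.sqrt(comp).T  # per-probe sds

    bl = config.baseline_mu
    mix_idx = rng.choice(len(bl.weights), size=n_probes, p=bl.weights)
    mu = rng.normal(np.array(bl.means)[mix_idx], np.array(bl.sds)[mix_idx])

    subjects = sheet["subject_id"].unique()
    subj_idx = sheet["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    occ_labels = (sheet["session"] + ":" + sheet["timepoint"]).to_numpy()
    occ_levels = pd.unique(occ_labels)
    occ_idx = pd.Series(occ_labels).map({o: i for i, o in enumerate(occ_levels)}).to_numpy()

    omega = rng.normal(size=(n_probes, len(subjects))) * sd_w[:, None]
    nu = rng.normal(size=(n_probes, len(occ_levels))) * sd_v[:, None]
    eps = rng.normal(size=(n_probes, n_samples)) * sd_e[:, None]

    gs = config.group_spec
    if gs.ela_resid_multiplier != 1.0:
        ela_stress = (
            (sheet["group"] == config.groups[1]) & (sheet["session"] == "Stress")
        ).to_numpy()
        eps[:, ela_stress] *= np.sqrt(gs.ela_resid_multiplier)

    cov = config.covariate_spec
    mono = sheet["monocyte_proportion"].to_numpy()
    batch_codes = pd.Categorical(sheet["batch"]).codes
    fixed = cov.monocyte_beta * mono + cov.batch_beta * batch_codes

    m_values = mu[:, None] + fixed[None, :] + omega[:, subj_idx] + nu[:, occ_idx] + eps

    # planted stress shifts on high-stability TSS probes
    ss = config.stress_spec
    stress_responsive: dict[str, dict[str, float]] = {}
    if ss.n_responsive > 0 and ss.shift_by_timepoint:
        is_tss = (annotation["feature_class"] == "TSS").to_numpy()
        pool = np.flatnonzero((classes == "high") & is_tss)
        if len(pool) < ss.n_responsive:
            pool = np.flatnonzero(classes == "high")
        if len(pool) < ss.n_responsive:
            pool = np.arange(n_probes)
        chosen = np.sort(rng.choice(pool, size=min(ss.n_responsive, len(pool)), replace=False))
        for tp, shift in ss.shift_by_timepoint.items():
            mask = ((sheet["session"] == "Stress") & (sheet["timepoint"] == tp)).to_numpy()
            m_values[np.ix_(chosen, np.flatnonzero(mask))] += shift
        stress_responsive = {
            probe_ids[j]: {tp: float(sh) for tp, sh in ss.shift_by_timepoint.items()}
            for j in chosen
        }

    beta = pd.DataFrame(m_to_beta(m_values), index=probe_ids, columns=sheet["sample_id"])
    beta.index.name = "probe_id"

    ds = config.detection_spec
    detp_vals = rng.random((n_probes, n_samples)) * ds.pass_scale
    failed: list[str] = []
    n_fail = int(round(ds.failed_sample_fraction * n_samples))
    if n_fail:
        fail_cols = np.sort(rng.choice(n_samples, size=n_fail, replace=False))
        detp_vals[:, fail_cols] = rng.random((n_probes, n_fail)) * ds.fail_scale
        failed = sheet["sample_id"].iloc[fail_cols].tolist()
    detection_p = pd.DataFrame(detp_vals, index=probe_ids, columns=sheet["sample_id"])
    detection_p.index.name = "probe_id"

    counts, expression_map = _make_counts(config, annotation, m_values, sheet, rng)

    icc21 = pd.Series(
        comp[:, 0] / comp.sum(axis=1), index=probe_ids, name="true_icc21"
    )
    icc2k = pd.DataFrame(
        {
            name: sc.nt * comp[:, 0] / (sc.nt * comp[:, 0] + comp[:, 1] + comp[:, 2])
            for name, sc in SCENARIOS.items()
        },
        index=probe_ids,
    )
    truth = SimTruth(
        probe_class=probe_class,
        components=pd.DataFrame(
            comp,
            index=probe_ids,
            columns=["sigma2_subject", "sigma2_time", "sigma2_resid"],
        ),
        true_icc21=icc21,
        true_icc2k=icc2k,
        stress_responsive=stress_responsive,
        expression_map=expression_map,
        failed_samples=failed,
    )
    return Cohort(beta, detection_p, sheet, annotation, counts, truth)


def _make_counts(config, annotation, m_values, sheet, rng):
    """Gene x sample read counts with a subset of TSS probes driving expression."""
    es = config.expression_spec
    tss_mask = (annotation["feature_class"] == "TSS").to_numpy()
    tss_rows = np.flatnonzero(tss_mask)
    # one gene per TSS probe (first probe wins if a gene repeats)
    gene_of = annotation["gene_symbol"].to_numpy()
    seen: dict[str, int] = {}
    for j in tss_rows:
        seen.setdefault(gene_of[j], j)
    genes = list(seen)
    probe_rows = np.array([seen[g] for g in genes])

    n_coupled = int(round(es.coupled_fraction * len(genes)))
    coupled_pos = np.sort(rng.choice(len(genes), size=n_coupled, replace=False)) if n_coupled else np.array([], int)
    baseline = rng.normal(es.baseline_log2_mean, es.baseline_log2_sd, size=len(genes))

    log2_expr = np.tile(baseline[:, None], (1, len(sheet)))
    if len(coupled_pos):
        m_sub = m_values[probe_rows[coupled_pos], :]
        centered = m_sub - m_sub.mean(axis=1, keepdims=True)
        log2_expr[coupled_pos, :] += es.coupling * centered
    log2_expr += rng.normal(0.0, es.noise_sd, size=log2_expr.shape)

    weights = np.exp2(log2_expr)
    weights /= weights.sum(axis=0, keepdims=True)
    libs = rng.lognormal(es.log_library_mean, es.log_library_sd, size=len(sheet))
    counts = rng.poisson(weights * libs[None, :])
    cdf = pd.DataFrame(counts, index=genes, columns=sheet["sample_id"])
    cdf.index.name = "gene_id"
    expression_map = {
        annotation["probe_id"].iloc[probe_rows[p]]: genes[p] for p in coupled_pos
    }
    return cdf, expression_map
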