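"""Crossed random-effects REML and intraclass correlation for one probe.

The per-probe model is

    y_it = x_it' beta + omega_i + nu_t + eps_it

with a subject effect omega_i ~ N(0, s2_subject), an occasion effect
nu_t ~ N(0, s2_time) shared across subjects (crossed, one level per
timepoint — or per session for the cross-session scenario), and residual
eps ~ N(0, s2_resid).  Fixed effects are an intercept, optionally the
monocyte proportion, and array (batch) dummies.  Variance components are
estimated by REML with non-negativity enforced by optimizing standard
deviations, and converted to

    ICC(2,1) = s2_subject / (s2_subject + s2_time + s2_resid)
    ICC(2,k) = nt * s2_subject / (nt * s2_subject + s2_time + s2_resid)

For balanced designs the two random-effect Gram matrices commute, so the
covariance is jointly diagonalized once per scenario and each REML
evaluation is O(n) — this is what makes genome-scale per-probe fitting
feasible.  Unbalanced designs fall back to dense Cholesky factorizations.

A two-way ANOVA mean-squares estimator (Shrout–Fleiss) is shipped alongside
as an independent closed-form route; on balanced covariate-free data with an
interior optimum the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .scenarios import Scenario

#: variance floor inside the REML objective (keeps log terms finite)
_W_FLOOR = 1e-12
#: cap on variance ratios sigma2_factor / sigma2_resid (ICC plateau ~ 1)
_RATIO_CAP = 1e8
#: probes with less variance than this across samples are flagged undefined
VAR_UNDEFINED = 1e-12

_GOLDEN = 1.618033988749895


@dataclass
class VarianceComponents:
    """REML (or ANOVA) estimates for one probe in one scenario."""

    sigma2_subject: float
    sigma2_time: float
    sigma2_resid: float
    beta: np.ndarray            # fixed-effect estimates, intercept first
    cov_beta: np.ndarray        # GLS covariance of beta
    column_names: list[str]
    converged: bool
    n_subjects: int
    nt: int
    reml: float = np.nan        # -2 * restricted log-likelihood (up to constant)

    @property
    def beta0(self) -> float:
        return float(self.beta[0])


def icc_from_components(vc: VarianceComponents, icc_type: str = "2,1") -> float:
    """ICC from fitted components; (2,k) uses the scenario's nt."""
    s2w, s2v, s2e = vc.sigma2_subject, vc.sigma2_time, vc.sigma2_resid
    denom = s2w + s2v + s2e
    if denom <= 0:
        raise ValueError("all-zero variance components: ICC undefined")
    if icc_type in ("2,1", "2_1", "21"):
        return s2w / denom
    if icc_type in ("2,k", "2_k", "2k"):
        return vc.nt * s2w / (vc.nt * s2w + s2v + s2e)
    raise ValueError(f"unknown icc_type {icc_type!r}")


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(codes), n_levels))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


class REMLFitter:
    """REML for a linear model with independent random-effect factors.

    Built once per design (fixed-effect matrix ``X`` plus factor index
    vectors); ``fit`` is then called per probe.  When all factor Gram
    matrices commute, the objective is evaluated on a shared eigenbasis.
    """

    def __init__(self, X: np.ndarray, factors: list[np.ndarray]):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient fixed-effect design")
        self.X = X
        self.n = n
        self.k = len(factors)
        self.factors = [np.asarray(f) for f in factors]
        self.n_levels = [int(f.max()) + 1 for f in self.factors]
        self.A = [
            _indicator(f, nl) @ _indicator(f, nl).T
            for f, nl in zip(self.factors, self.n_levels)
        ]
        self._diagonalize()

    def _diagonalize(self) -> None:
        combo = np.eye(self.n) * 0.0
        for i, A in enumerate(self.A):
            combo = combo + (_GOLDEN ** (i + 1)) * A
        vals, Q = np.linalg.eigh(combo)
        eigs = []
        ok = True
        for A in self.A:
            M = Q.T @ A @ Q
            off = M - np.diag(np.diag(M))
            if np.abs(off).max() > 1e-8 * max(1.0, np.abs(M).max()):
                ok = False
                break
            eigs.append(np.clip(np.diag(M), 0.0, None))
        if ok:
            self.diagonal = True
            self.Q = Q
            self.eig = np.vstack(eigs) if eigs else np.zeros((0, self.n))
            self.Xt = Q.T @ self.X
        else:
            self.diagonal = False
            self.Q = None

    # ---- objective -----------------------------------------------------
    #
    # The residual variance is profiled out: with V = s2_e * W(lam),
    # W = I + sum_f lam_f A_f, the REML-optimal s2_e is r' W^-1 r / (n - p),
    # leaving a k-dimensional search over the variance ratios lam_f >= 0.

    def _profiled_diag(self, lam: np.ndarray, yt: np.ndarray):
        w = 1.0 + lam @ self.eig
        Xw = self.Xt / w[:, None]
        XtWX = self.Xt.T @ Xw
        try:
            beta = np.linalg.solve(XtWX, Xw.T @ yt)
            sign, logdet_xtx = np.linalg.slogdet(XtWX)
        except np.linalg.LinAlgError:
            return np.inf, None
        if sign <= 0:
            return np.inf, None
        r = yt - self.Xt @ beta
        quad = float(r @ (r / w))
        dof = self.n - self.X.shape[1]
        s2e = max(quad / dof, _W_FLOOR)
        val = float(dof * np.log(s2e) + np.log(w).sum() + logdet_xtx + dof)
        return val, (s2e, beta, XtWX)

    def _profiled_dense(self, lam: np.ndarray, y: np.ndarray):
        W = np.eye(self.n)
        for j, A in enumerate(self.A):
            W += lam[j] * A
        try:
            Wi_X = np.linalg.solve(W, self.X)
            Wi_y = np.linalg.solve(W, y)
            sign_w, logdet_w = np.linalg.slogdet(W)
        except np.linalg.LinAlgError:
            return np.inf, None
        XtWX = self.X.T @ Wi_X
        try:
            beta = np.linalg.solve(XtWX, self.X.T @ Wi_y)
            sign, logdet_xtx = np.linalg.slogdet(XtWX)
        except np.linalg.LinAlgError:
            return np.inf, None
        if sign <= 0 or sign_w <= 0:
            return np.inf, None
        r = y - self.X @ beta
        quad = float(r @ np.linalg.solve(W, r))
        dof = self.n - self.X.shape[1]
        s2e = max(quad / dof, _W_FLOOR)
        val = float(dof * np.log(s2e) + logdet_w + logdet_xtx + dof)
        return val, (s2e, beta, XtWX)

    # ---- fitting -------------------------------------------------------

    def _starts(self, y: np.ndarray) -> list[np.ndarray]:
        beta_ols, *_ = np.linalg.lstsq(self.X, y, rcond=None)
        r = y - self.X @ beta_ols
        s2_tot = max(float(np.var(r)), _W_FLOOR)
        ratios = []
        for f, nl in zip(self.factors, self.n_levels):
            cnt = np.bincount(f, minlength=nl)
            means = np.bincount(f, weights=r, minlength=nl) / np.maximum(cnt, 1)
            between = float(np.var(means[cnt > 0]))
            ratios.append(max(between / s2_tot, 0.05))
        mom = np.sqrt(np.array(ratios))
        flat = np.sqrt(np.full(self.k, 0.5))
        return [mom, flat]

    def fit(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, float]:
        """Return (sigma2 per factor + resid, beta, cov_beta, converged, -2llR)."""
        y = np.asarray(y, dtype=float)
        if self.diagonal:
            yt = self.Q.T @ y
            prof = lambda lam: self._profiled_diag(lam, yt)
        else:
            prof = lambda lam: self._profiled_dense(lam, y)
        # parametrize lam = clip(u^2, 0, RATIO_CAP): non-negative, and a hard
        # cap so perfect-fit probes (residual -> 0) terminate on a plateau
        to_lam = lambda u: np.minimum(u**2, _RATIO_CAP)
        obj = lambda u: prof(to_lam(u))[0]

        if self.k == 1:
            # single variance ratio: bounded Brent on log1p(lam)
            res = minimize_scalar(
                lambda t: prof(np.array([np.expm1(t)]))[0],
                bounds=(0.0, np.log1p(_RATIO_CAP)),
                method="bounded",
                options={"xatol": 1e-10},
            )
            lam = np.array([np.expm1(res.x)])
            val, extra = prof(lam)
            if extra is None:
                p = self.X.shape[1]
                return (
                    np.zeros(2), np.full(p, np.nan), np.full((p, p), np.nan),
                    False, np.inf,
                )
            s2e, beta, XtWX = extra
            cov_beta = s2e * np.linalg.inv(XtWX)
            return (
                np.append(lam * s2e, s2e), beta, cov_beta,
                bool(res.success and np.isfinite(val)), val,
            )

        best = None
        for x0 in self._starts(y):
            res = minimize(
                obj, x0, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-12, "maxfev": 2000},
            )
            # restart from the incumbent: rebuilds the simplex and polishes
            res2 = minimize(
                obj, res.x, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-13, "maxfev": 1000},
            )
            cand = res2 if res2.fun <= res.fun else res
            if best is None or cand.fun < best.fun:
                best = cand
        lam = to_lam(best.x)
        val, extra = prof(lam)
        converged = bool(np.isfinite(val)) and extra is not None and bool(best.success)
        if extra is None:
            p = self.X.shape[1]
            return np.zeros(self.k + 1), np.full(p, np.nan), np.full((p, p), np.nan), False, np.inf
        s2e, beta, XtWX = extra
        cov_beta = s2e * np.linalg.inv(XtWX)
        s2 = np.append(lam * s2e, s2e)
        return s2, beta, cov_beta, converged, val


def build_design(
    design: pd.DataFrame, adjust: bool, include_batch: bool = True
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Fixed-effect matrix and factor codes from a scenario sample-sheet slice.

    ``design`` must carry subject_id, occasion (or timepoint),
    monocyte_proportion and batch columns.  Returns
    (X, column_names, subject_codes, occasion_codes).
    """
    d = design
    occ = d["occasion"] if "occasion" in d.columns else d["timepoint"]
    subj = pd.Categorical(d["subject_id"]).codes.astype(np.int64)
    occ_codes = pd.Categorical(occ).codes.astype(np.int64)
    cols = [np.ones(len(d))]
    names = ["intercept"]
    if adjust:
        cols.append(d["monocyte_proportion"].to_numpy(dtype=float))
        names.append("monocyte_proportion")
    if include_batch:
        batches = pd.Categorical(d["batch"])
        for lvl in batches.categories[1:]:
            cols.append((batches == lvl).astype(float))
            names.append(f"batch[{lvl}]")
    X = np.column_stack(cols)
    return X, names, subj, occ_codes


def _check_design(subj: np.ndarray, occ: np.ndarray) -> None:
    n_subj = len(np.unique(subj))
    n_occ = len(np.unique(occ))
    if n_subj < 2 or n_occ < 2:
        raise ValueError(
            f"degenerate design: {n_subj} subject(s), {n_occ} occasion(s)"
        )
    # at least two subjects must contribute two or more occasions
    per = pd.DataFrame({"s": subj, "o": occ}).groupby("s")["o"].nunique()
    if (per >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects with >= 2 occasions each")


def fit_probe_model(
    y, design: pd.DataFrame, adjust: bool, include_batch: bool = True
) -> VarianceComponents:
    """Fit the crossed random-effects model for a single probe."""
    X, names, subj, occ = build_design(design, adjust, include_batch)
    _check_design(subj, occ)
    fitter = REMLFitter(X, [subj, occ])
    s2, beta, cov_beta, converged, reml = fitter.fit(np.asarray(y, dtype=float))
    return VarianceComponents(
        sigma2_subject=float(s2[0]),
        sigma2_time=float(s2[1]),
        sigma2_resid=float(s2[2]),
        beta=beta,
        cov_beta=cov_beta,
        column_names=names,
        converged=converged,
        n_subjects=len(np.unique(subj)),
        nt=len(np.unique(occ)),
        reml=reml,
    )


def anova_components(y: np.ndarray, subj: np.ndarray, occ: np.ndarray):
    """Two-way mean-squares (Shrout–Fleiss) variance components.

    Requires a complete balanced subject x occasion grid with one
    observation per cell.  Returns raw (possibly negative) method-of-moments
    estimates (s2_subject, s2_time, s2_resid).
    """
    y = np.asarray(y, dtype=float)
    subj_lv, subj_c = np.unique(subj, return_inverse=True)
    occ_lv, occ_c = np.unique(occ, return_inverse=True)
    n, k = len(subj_lv), len(occ_lv)
    grid = np.full((n, k), np.nan)
    grid[subj_c, occ_c] = y
    if np.isnan(grid).any():
        raise ValueError("ANOVA estimator requires a complete balanced grid")
    grand = grid.mean()
    row = grid.mean(axis=1)
    col = grid.mean(axis=0)
    msr = k * np.sum((row - grand) ** 2) / (n - 1)
    msc = n * np.sum((col - grand) ** 2) / (k - 1)
    resid = grid - row[:, None] - col[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return (msr - mse) / k, (msc - mse) / n, mse


def compute_scenario_icc(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    scenario: Scenario,
    adjust: bool = True,
    include_batch: bool = True,
    subjects: list[str] | None = None,
) -> pd.DataFrame:
    """Per-probe ICC table for one scenario (beta-scale input).

    Non-converged or variance-degenerate probes get ICC 0 with
    ``converged=False``.  ``subjects`` restricts the cohort (used by the
    subsampling analyses).
    """
    design = scenario.select(sheet)
    if subjects is not None:
        design = design[design["subject_id"].isin(subjects)]
    if design.empty:
        raise ValueError(f"no samples for scenario {scenario.name}")
    present = set(design["occasion"])
    expected = set(scenario.timepoint_list)
    if present != expected:
        raise ValueError(
            f"scenario {scenario.name}: missing occasions {sorted(expected - present)}"
        )
    design = design[design["sample_id"].isin(beta.columns)]
    X, names, subj, occ = build_design(design, adjust, include_batch)
    _check_design(subj, occ)
    fitter = REMLFitter(X, [subj, occ])
    values = beta[design["sample_id"]].to_numpy(dtype=float)
    nt = scenario.nt
    rows = []
    for pid, y in zip(beta.index, values):
        if np.var(y) < VAR_UNDEFINED:
            rows.append((pid, scenario.name, 0.0, 0.0, adjust, False))
            continue
        s2, _, _, converged, _ = fitter.fit(y)
        total = s2.sum()
        if not converged or total <= 0:
            rows.append((pid, scenario.name, 0.0, 0.0, adjust, False))
            continue
        icc21 = s2[0] / total
        icc2k = nt * s2[0] / (nt * s2[0] + s2[1] + s2[2])
        rows.append((pid, scenario.name, float(icc21), float(icc2k), adjust, True))
    return pd.DataFrame(
        rows, columns=["probe_id", "scenario", "icc21", "icc2k", "adjusted", "converged"]
    )


def compute_all_scenarios(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    scenarios: dict[str, Scenario],
    adjust: bool = True,
    include_batch: bool = True,
) -> pd.DataFrame:
    tables = [
        compute_scenario_icc(beta, sheet, sc, adjust, include_batch)
        for sc in scenarios.values()
    ]
    return pd.concat(tables, ignore_index=True)
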