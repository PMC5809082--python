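"""ROI aggregation and mixed-model group inference with FDR-corrected post hocs.

The inferential model is a linear mixed-effects model with group as the fixed
effect and animal as a random intercept,

    y_ij = μ + group_g(i) + a_i + e_ij,   a_i ~ N(0, τ²),  e_ij ~ N(0, σ²),

estimated by REML (profiled over the variance ratio θ = τ²/σ²).  The overall
group test is an F-test whose denominator degrees of freedom come from the
Satterthwaite approximation computed from the numerical REML information
matrix; if significant at α, pairwise group contrasts are tested with
Satterthwaite-df t-tests and Benjamini–Hochberg adjustment within the
(metric, ROI) family.

Group means are additionally summarized descriptively (per-group t-intervals
on animal-level means), which preserves visible between-group differences in
dispersion that a pooled-variance model-based interval would hide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .dmri_data import ParameterMap, ROIMask

log = logging.getLogger(__name__)

GROUPS = ("control", "anhedonic", "resilient")
_THETA_BOUNDARY = 1e-7

COHORT_COLUMNS = ("animal_id", "group", "roi", "replicate", "metric", "value")


@dataclass
class CohortTable:
    """Tidy long-format records (animal, group, roi, replicate, metric, value)."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns {missing}")
        keys = ["animal_id", "roi", "replicate", "metric"]
        if df.duplicated(subset=keys).any():
            dup = df[df.duplicated(subset=keys, keep=False)].iloc[0]
            raise ValueError(
                f"duplicate (animal, roi, replicate, metric) key: "
                f"{tuple(dup[k] for k in keys)}"
            )
        if not np.isfinite(df["value"]).all():
            raise ValueError("non-finite values in cohort table")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "CohortTable":
        return cls(pd.DataFrame.from_records(records, columns=COHORT_COLUMNS))

    @classmethod
    def read_csv(cls, path: str | Path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path):
        self.df.to_csv(path, index=False, float_format="%.10g")

    def subset(self, metric: str, roi: str) -> pd.DataFrame:
        out = self.df[(self.df.metric == metric) & (self.df.roi == roi)]
        return out.reset_index(drop=True)

    def metrics(self) -> list[str]:
        return sorted(self.df.metric.unique())

    def rois(self) -> list[str]:
        return sorted(self.df.roi.unique())

    def concat(self, other: "CohortTable") -> "CohortTable":
        return CohortTable(pd.concat([self.df, other.df], ignore_index=True))


def aggregate_roi(
    maps_by_animal: dict[str, list[ParameterMap]],
    mask: ROIMask,
    cohort_meta: pd.DataFrame,
) -> CohortTable:
    """Slice-wise ROI means of parameter maps, one record per slice in the window.

    ``cohort_meta`` needs columns ``animal_id`` and ``group``.  Voxels outside
    each map's fit mask are excluded; an empty ROI cross-section is skipped
    with a warning.
    """
    groups = dict(zip(cohort_meta.animal_id, cohort_meta.group))
    records = []
    for animal, maps in maps_by_animal.items():
        for pmap in maps:
            if pmap.values.shape != mask.labels.shape:
                raise ValueError(
                    f"map '{pmap.name}' of animal {animal} is not aligned with the ROI mask"
                )
            for roi in mask.label_names.values():
                roi_vox = mask.roi_voxels(roi)
                lo, hi = mask.slice_range
                for k in range(lo, hi):
                    sel = [slice(None)] * 3
                    sel[mask.axis] = k
                    plane_roi = roi_vox[tuple(sel)]
                    plane_val = pmap.values[tuple(sel)]
                    vals = plane_val[plane_roi]
                    vals = vals[np.isfinite(vals)]
                    if vals.size == 0:
                        warnings.warn(
                            f"empty ROI cross-section: {roi} slice {k} "
                            f"(animal {animal}, metric {pmap.name})",
                            stacklevel=2,
                        )
                        continue
                    records.append(
                        (animal, groups[animal], roi, k, pmap.name, float(vals.mean()))
                    )
    return CohortTable.from_records(records)


# ---------------------------------------------------------------------------
# Random-intercept REML


class RandomInterceptLMM:
    """REML fit of ``value ~ group + (1 | animal)`` with dense-free block algebra.

    Observations are grouped by animal; V₀ = I + θ·ZZᵀ is block diagonal with
    blocks (I + θ·J_m), inverted in closed form, so the profiled REML
    objective is a fast scalar function of θ.
    """

    def __init__(self, y: np.ndarray, group_labels: np.ndarray, animal_ids: np.ndarray):
        order = np.lexsort((np.asarray(animal_ids, dtype=object),))
        self.y = np.asarray(y, dtype=float)[order]
        glab = np.asarray(group_labels, dtype=object)[order]
        aid = np.asarray(animal_ids, dtype=object)[order]
        self.group_names = _group_order(glab)
        if len(self.group_names) < 2:
            raise ValueError("need >= 2 groups")
        counts = pd.Series(glab).groupby(
            pd.Series(aid).astype(str)
        ).first().value_counts()
        if (counts.reindex(self.group_names).fillna(0) < 2).any():
            raise ValueError("need >= 2 animals per group")
        self.animals, self.animal_index = np.unique(aid.astype(str), return_inverse=True)
        self.n = self.y.size
        self.q = len(self.animals)
        self.p = len(self.group_names)
        self.X = np.column_stack(
            [np.ones(self.n)]
            + [(glab == g).astype(float) for g in self.group_names[1:]]
        )
        self.block_sizes = np.bincount(self.animal_index, minlength=self.q)
        self._fitted = False

    # -- block algebra -----------------------------------------------------
    def _apply_v0inv(self, M: np.ndarray, theta: float) -> np.ndarray:
        """(I + θ ZZᵀ)⁻¹ M, block-wise: subtract θ/(1+mθ) times block sums."""
        M = np.atleast_2d(M.T).T
        sums = np.zeros((self.q, M.shape[1]))
        np.add.at(sums, self.animal_index, M)
        shrink = theta / (1 + self.block_sizes * theta)
        return M - (shrink[:, None] * sums)[self.animal_index]

    def _logdet_v0(self, theta: float) -> float:
        return float(np.sum(np.log1p(self.block_sizes * theta)))

    def _profile(self, theta: float):
        WX = self._apply_v0inv(self.X, theta)
        Wy = self._apply_v0inv(self.y[:, None], theta)[:, 0]
        XtWX = self.X.T @ WX
        beta = np.linalg.solve(XtWX, self.X.T @ Wy)
        r = self.y - self.X @ beta
        quad = float(r @ self._apply_v0inv(r[:, None], theta)[:, 0])
        sigma2 = quad / (self.n - self.p)
        return beta, XtWX, sigma2

    def _neg_reml(self, theta: float) -> float:
        beta, XtWX, sigma2 = self._profile(theta)
        sign, logdet_xtwx = np.linalg.slogdet(XtWX)
        return 0.5 * (
            (self.n - self.p) * np.log(sigma2)
            + self._logdet_v0(theta)
            + logdet_xtwx
        )

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "RandomInterceptLMM":
        res = optimize.minimize_scalar(
            lambda u: self._neg_reml(np.exp(u)),
            bounds=(np.log(1e-8), np.log(1e6)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        theta = float(np.exp(res.x))
        if self._neg_reml(0.0) <= res.fun:
            theta = 0.0
        self.theta = theta
        self.degenerate = theta < _THETA_BOUNDARY
        beta, XtWX, sigma2 = self._profile(theta)
        self.beta = beta
        self.sigma2 = sigma2
        self.tau2 = theta * sigma2
        self.cov_beta = sigma2 * np.linalg.inv(XtWX)
        self._fitted = True
        return self

    # -- REML surface in (σ², τ²) for Satterthwaite ------------------------
    def _reml_ll(self, s2: float, t2: float) -> float:
        theta = t2 / s2
        beta, XtWX, _ = self._profile(theta)
        r = self.y - self.X @ beta
        quad = float(r @ self._apply_v0inv(r[:, None], theta)[:, 0]) / s2
        logdet_v = self.n * np.log(s2) + self._logdet_v0(theta)
        sign, ld = np.linalg.slogdet(XtWX / s2)
        return -0.5 * (logdet_v + ld + quad)

    def varcomp_cov(self) -> np.ndarray:
        """Asymptotic covariance of (σ̂², τ̂²) from the numeric REML Hessian."""
        s2, t2 = self.sigma2, self.tau2
        h1 = max(s2, 1e-12) * 1e-4
        h2 = max(t2, 1e-3 * s2) * 1e-4
        f = self._reml_ll

        def d2(fa, fb, fc, h):
            return (fa - 2 * fb + fc) / h**2

        H = np.empty((2, 2))
        H[0, 0] = d2(f(s2 + h1, t2), f(s2, t2), f(s2 - h1, t2), h1)
        H[1, 1] = d2(f(s2, t2 + h2), f(s2, t2), f(s2, max(t2 - h2, 0.0)), h2)
        H[0, 1] = H[1, 0] = (
            f(s2 + h1, t2 + h2) - f(s2 + h1, max(t2 - h2, 0.0))
            - f(s2 - h1, t2 + h2) + f(s2 - h1, max(t2 - h2, 0.0))
        ) / (4 * h1 * h2)
        try:
            return np.linalg.inv(-H)
        except np.linalg.LinAlgError:  # pragma: no cover
            return np.full((2, 2), np.nan)

    def _contrast_var(self, c: np.ndarray, s2: float, t2: float) -> float:
        theta = t2 / s2
        WX = self._apply_v0inv(self.X, theta)
        XtWX = self.X.T @ WX
        return s2 * float(c @ np.linalg.solve(XtWX, c))

    def satterthwaite_df(self, c: np.ndarray) -> float:
        """Effective df of a fixed-effect contrast by the Satterthwaite method."""
        if self.degenerate:
            return float(self.n - self.p)
        s2, t2 = self.sigma2, self.tau2
        A = self.varcomp_cov()
        if not np.isfinite(A).all():
            return float(self.q - self.p)
        h1 = max(s2, 1e-12) * 1e-5
        h2 = max(t2, 1e-3 * s2) * 1e-5
        v0 = self._contrast_var(c, s2, t2)
        g = np.array(
            [
                (self._contrast_var(c, s2 + h1, t2) - self._contrast_var(c, s2 - h1, t2))
                / (2 * h1),
                (self._contrast_var(c, s2, t2 + h2)
                 - self._contrast_var(c, s2, max(t2 - h2, 0.0)))
                / (h2 + min(h2, t2)),
            ]
        )
        denom = float(g @ A @ g)
        if denom <= 0:
            return float(self.q - self.p)
        return 2 * v0**2 / denom


def _group_order(labels: np.ndarray) -> list[str]:
    names = sorted(set(labels.tolist()))
    ordered = [g for g in GROUPS if g in names] + [g for g in names if g not in GROUPS]
    return ordered


@dataclass
class PairwiseContrast:
    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    df: float
    p_raw: float
    p_fdr: float | None = None


@dataclass
class LMMResult:
    """Group inference for one (metric, ROI) cell."""

    metric: str
    roi: str
    f_stat: float
    df_num: float
    df_den: float
    p_value: float
    group_means: dict[str, dict]
    pairwise: list[PairwiseContrast] = field(default_factory=list)
    degraded: bool = False
    note: str = ""
    model: RandomInterceptLMM | None = field(default=None, repr=False)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _descriptive_group_means(df: pd.DataFrame, level: float = 0.95) -> dict[str, dict]:
    """Per-group mean of animal means with a group-specific t-interval.

    Computing the interval within each group (rather than from the pooled
    model variance) keeps group-to-group differences in spread visible — the
    stress groups of this paradigm are expected to be more heterogeneous.
    """
    out = {}
    for g, sub in df.groupby("group", sort=False):
        am = sub.groupby("animal_id")["value"].mean().to_numpy()
        n = am.size
        m = float(am.mean())
        if n > 1:
            half = float(sps.t.ppf(0.5 + level / 2, n - 1) * am.std(ddof=1) / np.sqrt(n))
        else:  # pragma: no cover
            half = float("nan")
        out[str(g)] = {
            "estimate": m,
            "ci_low": m - half,
            "ci_high": m + half,
            "n_animals": int(n),
        }
    return out


def lmm_group_test(table: CohortTable, metric: str, roi: str) -> LMMResult:
    """Overall group F-test for one metric × ROI with Satterthwaite df.

    Degrades gracefully to a fixed-effects ANOVA (flagged) when the
    between-animal variance estimate hits the boundary or each animal
    contributes a single observation.
    """
    df = table.subset(metric, roi)
    if df.empty:
        raise ValueError(f"no records for metric={metric} roi={roi}")
    model = RandomInterceptLMM(
        df["value"].to_numpy(), df["group"].to_numpy(), df["animal_id"].to_numpy()
    ).fit()
    qc = model.p - 1
    L = np.zeros((qc, model.p))
    L[:, 1:] = np.eye(qc)
    M = L @ model.cov_beta @ L.T
    lb = L @ model.beta
    f_stat = float(lb @ np.linalg.solve(M, lb)) / qc

    if model.degenerate:
        df_den = float(model.n - model.p)
        note = "between-animal variance at boundary; fixed-effects ANOVA df used"
    else:
        evals, evecs = np.linalg.eigh(M)
        dfs = []
        for i in range(qc):
            c = evecs[:, i] @ L
            dfs.append(model.satterthwaite_df(c))
        dfs = np.asarray(dfs)
        ok = dfs > 2
        if ok.sum() == 0:  # pragma: no cover
            df_den, note = float(model.q - model.p), "Satterthwaite fallback"
        else:
            E = float(np.sum(dfs[ok] / (dfs[ok] - 2)))
            df_den = 2 * E / (E - qc) if E > qc else float(model.q - model.p)
            note = ""
    p_value = float(sps.f.sf(f_stat, qc, df_den))
    # a lone observation per animal makes τ² and σ² inseparable
    one_obs = df.groupby("animal_id").size().max() == 1
    return LMMResult(
        metric=metric,
        roi=roi,
        f_stat=f_stat,
        df_num=float(qc),
        df_den=float(df_den),
        p_value=p_value,
        group_means=_descriptive_group_means(df),
        degraded=bool(model.degenerate or one_obs),
        note=note,
        model=model,
    )


def posthoc_pairwise(result: LMMResult, alpha: float = 0.05) -> LMMResult:
    """FDR-corrected pairwise contrasts, gated on the overall F-test.

    Following the gatekeeping convention, post hocs run only when the overall
    test is significant at ``alpha``; otherwise the result is returned
    unchanged with a note.
    """
    if result.p_value > alpha:
        result.note = (result.note + "; " if result.note else "") + (
            f"overall p={result.p_value:.3g} > alpha={alpha}; post hocs skipped"
        )
        return result
    model = result.model
    if model is None:
        raise ValueError("result carries no fitted model")
    names = model.group_names
    contrasts = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            c = np.zeros(model.p)
            if i > 0:
                c[i] = -1.0
            if j > 0:
                c[j] = 1.0
            contrasts.append((f"{names[j]} - {names[i]}", c))
    rows = []
    for label, c in contrasts:
        est = float(c @ model.beta)
        se = float(np.sqrt(c @ model.cov_beta @ c))
        dfc = (
            float(model.n - model.p) if model.degenerate else model.satterthwaite_df(c)
        )
        tval = est / se
        p_raw = float(2 * sps.t.sf(abs(tval), dfc))
        half = float(sps.t.ppf(0.975, dfc) * se)
        rows.append(PairwiseContrast(label, est, est - half, est + half, dfc, p_raw))
    p_adj = bh_adjust(np.array([r.p_raw for r in rows]))
    for r, pa in zip(rows, p_adj):
        r.p_fdr = float(pa)
    result.pairwise = rows
    return result


def results_table(results: list[LMMResult]) -> pd.DataFrame:
    """Flatten LMM results (overall tests + contrasts + means) for CSV export."""
    rows = []
    for r in results:
        rows.append(
            {
                "metric": r.metric, "roi": r.roi, "kind": "overall",
                "term": "group", "estimate": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "f_stat": r.f_stat, "df_num": r.df_num,
                "df_den": r.df_den, "p": r.p_value, "p_fdr": np.nan,
                "degraded": r.degraded,
            }
        )
        for g, gm in r.group_means.items():
            rows.append(
                {
                    "metric": r.metric, "roi": r.roi, "kind": "group_mean",
                    "term": g, "estimate": gm["estimate"], "ci_low": gm["ci_low"],
                    "ci_high": gm["ci_high"], "f_stat": np.nan, "df_num": np.nan,
                    "df_den": np.nan, "p": np.nan, "p_fdr": np.nan,
                    "degraded": r.degraded,
                }
            )
        for pc in r.pairwise:
            rows.append(
                {
                    "metric": r.metric, "roi": r.roi, "kind": "contrast",
                    "term": pc.contrast, "estimate": pc.estimate,
                    "ci_low": pc.ci_low, "ci_high": pc.ci_high, "f_stat": np.nan,
                    "df_num": np.nan, "df_den": pc.df, "p": pc.p_raw,
                    "p_fdr": pc.p_fdr, "degraded": r.degraded,
                }
            )
    return pd.DataFrame(rows)
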