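"""ROI aggregation, the random-intercept REML model, and FDR post hocs.

The mixed model is cross-checked against two independent oracles: the exact
balanced-design equivalence with a one-way ANOVA on animal means, and
statsmodels / R lmerTest fits of the same data.
"""

import json
import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as hst

from cmscortex.dmri_data import ParameterMap, ROIMask
from cmscortex.stats import (
    CohortTable,
    aggregate_roi,
    bh_adjust,
    lmm_group_test,
    posthoc_pairwise,
)


def make_table(rng, effects=(0.0, 0.0, 0.0), n_animals=(8, 8, 8), reps=4, sb=1.0, sw=1.0):
    rows = []
    for gi, (g, n) in enumerate(zip(("control", "anhedonic", "resilient"), n_animals)):
        for a in range(n):
            animal = f"{g}_{a}"
            eff = rng.normal(0.0, sb)
            for r in range(reps):
                rows.append(
                    (animal, g, "AC", r, "m", effects[gi] + eff + rng.normal(0.0, sw))
                )
    return CohortTable.from_records(rows)


# ---------------------------------------------------------------------------
# aggregation


def _roi_mask_3x3():
    labels = np.zeros((3, 3, 2), dtype=np.int16)
    labels[:2, :2, :] = 1
    return ROIMask(labels, {1: "AC"}, slice_range=(0, 2))


def _meta():
    return pd.DataFrame({"animal_id": ["a1"], "group": ["control"]})


def test_aggregate_constant_map():
    mask = _roi_mask_3x3()
    pm = ParameterMap("D_eff", np.full((3, 3, 2), 0.7), "um^2/ms", np.ones((3, 3, 2), bool))
    table = aggregate_roi({"a1": [pm]}, mask, _meta())
    assert (table.df.value == 0.7).all()
    assert len(table.df) == 2  # one record per slice


def test_aggregate_mean_of_four_voxels():
    mask = _roi_mask_3x3()
    vals = np.zeros((3, 3, 2))
    vals[:2, :2, 0] = np.array([[1.0, 2.0], [3.0, 4.0]])
    pm = ParameterMap("D_eff", vals, "um^2/ms", np.ones((3, 3, 2), bool))
    table = aggregate_roi({"a1": [pm]}, mask, _meta())
    assert table.df[table.df.replicate == 0].value.iloc[0] == pytest.approx(2.5)


def test_aggregate_ignores_unfit_voxels():
    """Mean over valid voxels only, verified against a hand-computed mean."""
    mask = _roi_mask_3x3()
    vals = np.full((3, 3, 2), np.nan)
    fit_mask = np.zeros((3, 3, 2), bool)
    vals[0, 0, 0], vals[0, 1, 0] = 1.0, 3.0
    fit_mask[0, 0, 0] = fit_mask[0, 1, 0] = True
    pm = ParameterMap("D_eff", vals, "um^2/ms", fit_mask)
    with pytest.warns(UserWarning, match="empty ROI cross-section"):
        table = aggregate_roi({"a1": [pm]}, mask, _meta())
    assert len(table.df) == 1  # slice 1 fully unfit → skipped
    assert table.df.value.iloc[0] == pytest.approx(2.0)  # (1 + 3) / 2


def test_aggregate_rejects_misaligned_grid():
    mask = _roi_mask_3x3()
    pm = ParameterMap("D_eff", np.ones((4, 4, 2)), "um^2/ms", np.ones((4, 4, 2), bool))
    with pytest.raises(ValueError, match="aligned"):
        aggregate_roi({"a1": [pm]}, mask, _meta())


def test_cohort_table_rejects_duplicates():
    rows = [("a1", "control", "AC", 0, "m", 1.0)] * 2
    with pytest.raises(ValueError, match="duplicate"):
        CohortTable.from_records(rows)


# ---------------------------------------------------------------------------
# mixed model


def test_balanced_f_matches_animal_mean_anova(rng):
    """Exact REML equivalence: balanced random-intercept F = one-way ANOVA F
    on per-animal means, with denominator df = N_animals − g."""
    table = make_table(rng)
    res = lmm_group_test(table, "m", "AC")
    df = table.subset("m", "AC")
    am = df.groupby(["animal_id", "group"])["value"].mean().reset_index()
    groups = [am[am.group == g].value.to_numpy() for g in ("control", "anhedonic", "resilient")]
    f_ref, p_ref = sps.f_oneway(*groups)
    assert res.f_stat == pytest.approx(f_ref, abs=1e-6)
    assert res.p_value == pytest.approx(p_ref, abs=1e-6)
    assert res.df_den == pytest.approx(21.0, abs=1e-3)


def test_group_mean_cis_match_t_intervals(rng):
    """Descriptive group CIs equal the closed-form t-interval on animal means."""
    table = make_table(rng, effects=(0.0, 0.5, 1.0))
    res = lmm_group_test(table, "m", "AC")
    df = table.subset("m", "AC")
    for g in ("control", "anhedonic", "resilient"):
        am = df[df.group == g].groupby("animal_id").value.mean().to_numpy()
        half = sps.t.ppf(0.975, am.size - 1) * am.std(ddof=1) / np.sqrt(am.size)
        gm = res.group_means[g]
        assert gm["estimate"] == pytest.approx(am.mean(), abs=1e-6)
        assert gm["ci_high"] - gm["estimate"] == pytest.approx(half, abs=1e-6)


def test_infinite_separation_gives_tiny_p(rng):
    table = make_table(rng, effects=(0.0, 0.0, 5.0), sb=1e-7, sw=1e-6)
    res = lmm_group_test(table, "m", "AC")
    assert res.p_value < 1e-10


def test_one_observation_per_animal_degrades_gracefully(rng):
    table = make_table(rng, reps=1)
    res = lmm_group_test(table, "m", "AC")
    assert res.degraded
    assert np.isfinite(res.p_value)


def test_preconditions(rng):
    table = make_table(rng)
    df = table.subset("m", "AC")
    only_ctrl = CohortTable(df[df.group == "control"].reset_index(drop=True))
    with pytest.raises(ValueError, match="2 groups"):
        lmm_group_test(only_ctrl, "m", "AC")
    with pytest.raises(ValueError, match="no records"):
        lmm_group_test(table, "missing", "AC")


def test_against_statsmodels_mixedlm(rng):
    """Independent oracle: statsmodels MixedLM (REML) on unbalanced data."""
    import statsmodels.formula.api as smf

    table = make_table(rng, effects=(0.0, 0.4, 0.1), n_animals=(6, 5, 7), reps=3, sb=0.5, sw=0.7)
    res = lmm_group_test(table, "m", "AC")
    df = table.subset("m", "AC")
    df["group"] = pd.Categorical(df.group, categories=["control", "anhedonic", "resilient"])
    sm_fit = smf.mixedlm("value ~ group", df, groups=df.animal_id).fit(reml=True)
    model = res.model
    np.testing.assert_allclose(model.beta, sm_fit.fe_params.to_numpy(), atol=1e-5)
    assert model.sigma2 == pytest.approx(sm_fit.scale, rel=1e-4)
    assert model.tau2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-8)


def test_against_r_lmertest(tmp_path, rng):
    """Independent oracle: lmerTest's Satterthwaite F-test on unbalanced data."""
    table = make_table(rng, effects=(0.0, 0.35, 0.1), n_animals=(6, 5, 7), reps=3, sb=0.5, sw=0.7)
    df = table.subset("m", "AC")
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        """
suppressMessages({library(lmerTest); library(jsonlite)})
args <- commandArgs(trailingOnly=TRUE)
d <- read.csv(args[1])
d$group <- factor(d$group, levels=c("control","anhedonic","resilient"))
m <- lmer(value ~ group + (1|animal_id), data=d, REML=TRUE)
a <- anova(m, type=3)
cat(toJSON(list(F=a$`F value`[1], df_den=a$DenDF[1], p=a$`Pr(>F)`[1]),
    digits=12, auto_unbox=TRUE))
"""
    )
    out = subprocess.run(
        ["Rscript", str(script), str(csv)], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    ref = json.loads(out.stdout)
    res = lmm_group_test(table, "m", "AC")
    assert res.f_stat == pytest.approx(ref["F"], rel=1e-5)
    assert res.df_den == pytest.approx(ref["df_den"], rel=1e-2)
    assert res.p_value == pytest.approx(ref["p"], abs=1e-4)


# ---------------------------------------------------------------------------
# post hocs and FDR


@pytest.mark.parametrize(
    "p_raw, expected",
    [
        ((0.01, 0.02, 0.03), (0.03, 0.03, 0.03)),
        ((0.001, 0.9, 0.95), (0.003, 0.95, 0.95)),
    ],
)
def test_bh_known_values(p_raw, expected):
    np.testing.assert_allclose(bh_adjust(np.array(p_raw)), expected, atol=1e-12)


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(10):
        p = rng.uniform(size=rng.integers(2, 12))
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


@settings(max_examples=60, derandomize=True)
@given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
def test_bh_properties(p):
    """BH is monotone in the input order sense, bounded by [p, 1]."""
    p = np.array(p)
    adj = bh_adjust(p)
    assert (adj >= p - 1e-12).all() and (adj <= 1.0 + 1e-12).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_posthoc_gatekeeping(rng):
    table = make_table(rng)  # null → overall test not significant
    res = lmm_group_test(table, "m", "AC")
    assume_ns = res.p_value > 0.05
    if not assume_ns:  # pragma: no cover - seed chosen to be null-typical
        pytest.skip("unlucky draw")
    res = posthoc_pairwise(res, alpha=0.05)
    assert res.pairwise == []
    assert "skipped" in res.note


def test_posthoc_recovers_planted_contrast(rng):
    table = make_table(rng, effects=(0.0, 0.0, 1.5), sb=0.3, sw=0.3)
    res = posthoc_pairwise(lmm_group_test(table, "m", "AC"), alpha=0.05)
    assert len(res.pairwise) == 3
    by_name = {c.contrast: c for c in res.pairwise}
    target = by_name["resilient - control"]
    assert target.p_fdr < 0.05
    assert target.ci_low < target.estimate < target.ci_high
    assert target.estimate == pytest.approx(1.5, abs=0.5)
    for c in res.pairwise:
        assert c.p_fdr >= c.p_raw - 1e-12
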