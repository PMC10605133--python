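"""Class aggregation and group comparison: oracles, invariants, null behaviour."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidkit.errors import TooFewSamplesError
from lipidkit.profile import (
    anova_groups,
    class_totals,
    compare_groups,
    profile_table,
    stars_for_p,
)
from lipidkit.quantify import SampleMeta


def _meta(n_wt=3, n_hom=3, extra_groups=()):
    meta = [SampleMeta(f"WT{i}", "WT") for i in range(n_wt)]
    meta += [SampleMeta(f"HOM{i}", "HOM") for i in range(n_hom)]
    for g, n in extra_groups:
        meta += [SampleMeta(f"{g}{i}", g) for i in range(n)]
    return meta


def test_single_species_class_total():
    df = pd.DataFrame({"s1": [2.0], "s2": [3.0]}, index=["LPC 18:1"])
    totals = class_totals(df)
    assert list(totals.values.index) == ["LPC"]
    assert np.allclose(totals.values.loc["LPC"], df.loc["LPC 18:1"])


def test_class_totals_match_groupby_oracle(rng):
    """Random 50-species matrix: totals equal an independent groupby-sum."""
    classes = ["PC", "PE", "PA", "CE", "SM"]
    names, cls_of = [], {}
    for i in range(50):
        cls = classes[i % len(classes)]
        c, d, d2 = 14 + 2 * (i % 6), i % 3, i % 2
        if cls == "CE":
            name = f"CE {c}:{d}"
        elif cls == "SM":
            name = f"SM 18:1;O2/{c}:{d}"
        else:
            name = f"{cls} {c}:{d}_18:{d2}"
        names.append(name)
        cls_of[name] = cls
    df = pd.DataFrame(
        rng.uniform(0.1, 5.0, (len(names), 4)),
        index=pd.Index(names),
        columns=["a", "b", "c", "d"],
    )
    df = df[~df.index.duplicated()]
    totals = class_totals(df)
    oracle = df.groupby(pd.Series(cls_of)).sum()
    pd.testing.assert_frame_equal(
        totals.values.sort_index(), oracle.sort_index(), check_names=False
    )
    assert np.allclose(totals.grand_total, df.sum(axis=0))


def test_grand_total_conservation(sn_matrix):
    """Grand total == sum of class totals == sum of species, per sample."""
    totals = class_totals(sn_matrix)
    per_sample_species = sn_matrix.values.sum(axis=0)
    assert np.allclose(totals.values.sum(axis=0), per_sample_species)
    assert np.allclose(totals.grand_total, per_sample_species)


def test_identical_groups_no_stars(rng):
    block = rng.uniform(1, 2, (4, 3))
    df = pd.DataFrame(
        np.hstack([block, block]),  # HOM columns copy the WT columns exactly
        index=["PC 16:0_18:1", "PE 18:0_20:4", "PA 18:1_18:1", "CE 18:2"],
        columns=[m.sample_id for m in _meta()],
    )
    out = compare_groups(df, _meta())
    assert np.allclose(out["p"], 1.0)
    assert (out["stars"] == "").all()


def test_stars_monotone_in_p():
    ps = [1e-5, 5e-4, 0.0009, 0.002, 0.04, 0.05, 0.5]
    stars = [stars_for_p(p) for p in ps]
    assert stars == ["***", "***", "***", "**", "*", "", ""]
    lengths = [len(s) for s in stars]
    assert lengths == sorted(lengths, reverse=True)


def test_welch_equals_student_with_equal_variance(rng):
    """Both tests agree when group sizes and variances match exactly."""
    x = rng.normal(0, 1, 6)
    y = np.concatenate([x[:3] + 5, x[3:] + 5.5])  # same spread, shifted
    df = pd.DataFrame([np.concatenate([x[:3], y[:3]])],
                      index=["PC 16:0_18:1"],
                      columns=[m.sample_id for m in _meta()])
    welch = compare_groups(df, _meta(), test="welch")
    student = compare_groups(df, _meta(), test="student")
    # equal n: Welch df shrinks only when variances differ; p close
    assert welch.loc["PC 16:0_18:1", "p"] == pytest.approx(
        student.loc["PC 16:0_18:1", "p"], rel=0.2
    )


def test_null_type_one_error_rate():
    """Two groups from one distribution: rejection rate at alpha=0.05 stays
    inside the binomial 95% interval over 2000 simulated species."""
    rng = np.random.default_rng(11)
    n_sim = 2000
    data = rng.lognormal(0.0, 0.3, (n_sim, 9))
    meta = _meta(5, 4)
    df = pd.DataFrame(
        data, index=[f"PC {14 + i % 12}:{i % 4}_18:1" for i in range(n_sim)],
        columns=[m.sample_id for m in meta],
    )
    df = df[~df.index.duplicated()]
    out = compare_groups(df, meta)
    rate = float((out["p"] < 0.05).mean())
    half = 1.96 * np.sqrt(0.05 * 0.95 / len(df))
    assert 0.05 - half <= rate <= 0.05 + half


def test_percent_composition_sums_to_100(sn_matrix):
    totals = class_totals(sn_matrix)
    out = compare_groups(totals.values, sn_matrix.meta)
    assert out["pct_WT"].sum() == pytest.approx(100.0)
    assert out["pct_HOM"].sum() == pytest.approx(100.0)


def test_profile_table_shape(sn_matrix):
    table = profile_table(sn_matrix)
    assert "Total" in table.index
    assert table.shape[0] == 19  # 18 classes + total row
    assert {"mean_WT", "mean_HOM", "p", "stars"} <= set(table.columns)


def test_anova_identical_groups(rng):
    vals = rng.uniform(1, 2, 3)
    meta = _meta(3, 3, extra_groups=[("HET", 3)])
    df = pd.DataFrame(
        [np.tile(vals, 3)], index=["PC 16:0_18:1"],
        columns=[m.sample_id for m in meta],
    )
    out = anova_groups(df, meta)
    assert out.loc["PC 16:0_18:1", "p"] == pytest.approx(1.0)


def test_anova_two_groups_matches_student_t(rng):
    """With two groups, one-way ANOVA F equals Student's t squared."""
    meta = _meta(4, 4)
    df = pd.DataFrame(
        rng.lognormal(0, 0.4, (6, 8)),
        index=[f"PC 1{k}:0_18:1" for k in range(6)],
        columns=[m.sample_id for m in meta],
    )
    f_out = anova_groups(df, meta)
    t_out = compare_groups(df, meta, test="student")
    assert np.allclose(f_out["F"], t_out["t"] ** 2)
    assert np.allclose(f_out["p"], t_out["p"])


def test_anova_power_increases_with_effect(rng):
    """Mean p over simulations decreases monotonically with the shift."""
    meta = _meta(5, 5, extra_groups=[("HET", 5)])
    mean_p = []
    for shift in (0.0, 0.5, 1.5):
        sims = []
        for _ in range(40):
            base = rng.normal(0, 1, (1, 15))
            base[0, 10:] += shift  # shift the third group
            df = pd.DataFrame(base, index=["PC 16:0_18:1"],
                              columns=[m.sample_id for m in meta])
            sims.append(float(anova_groups(df, meta)["p"].iloc[0]))
        mean_p.append(np.mean(sims))
    assert mean_p[0] > mean_p[1] > mean_p[2]


def test_too_few_samples_raises():
    df = pd.DataFrame([[1.0, 2.0]], index=["PC 16:0_18:1"], columns=["WT0", "HOM0"])
    meta = [SampleMeta("WT0", "WT"), SampleMeta("HOM0", "HOM")]
    with pytest.raises(TooFewSamplesError):
        compare_groups(df, meta)
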