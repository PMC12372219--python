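import numpy as np
import pandas as pd
import pytest

from driftchoice.group_stats import (format_report, mixed_anova, report_frame,
                                     simple_effects, stats_report)


def _table(values):
    """values: {(group, participant, context): value}"""
    rows = [{"participant_id": p, "group": g, "context": c, "value": v}
            for (g, p, c), v in values.items()]
    return pd.DataFrame(rows)


@pytest.fixture()
def hand_dataset():
    # 2 participants per group, both contexts; chosen with non-trivial
    # group, context and interaction structure
    return _table({
        ("g1", "p1", "gain"): 1.0, ("g1", "p1", "loss"): 2.0,
        ("g1", "p2", "gain"): 2.0, ("g1", "p2", "loss"): 4.0,
        ("g2", "p3", "gain"): 3.0, ("g2", "p3", "loss"): 3.5,
        ("g2", "p4", "gain"): 4.0, ("g2", "p4", "loss"): 6.0,
    })


def brute_force_mixed_anova(df):
    """Direct sums-of-squares arithmetic for the balanced 2x2 mixed design."""
    wide = df.pivot_table(index=["group", "participant_id"], columns="context",
                          values="value")
    grand = df["value"].mean()
    n_subj = len(wide)
    n_cond = wide.shape[1]
    subj_means = wide.mean(axis=1)
    group_means = df.groupby("group")["value"].mean()
    n_per_group = wide.groupby("group").size()
    ss_between_subj = n_cond * ((subj_means - grand) ** 2).sum()
    ss_group = sum(n_per_group[g] * n_cond * (group_means[g] - grand) ** 2
                   for g in group_means.index)
    ss_subj_err = ss_between_subj - ss_group
    ctx_means = df.groupby("context")["value"].mean()
    ss_ctx = sum(n_subj * (ctx_means[c] - grand) ** 2 for c in ctx_means.index)
    cell_means = df.groupby(["group", "context"])["value"].mean()
    ss_inter = sum(
        n_per_group[g] * (cell_means[g, c] - group_means[g] - ctx_means[c] + grand) ** 2
        for g in group_means.index for c in ctx_means.index)
    ss_total_within = ((wide.sub(subj_means, axis=0)) ** 2).sum().sum()
    ss_within_err = ss_total_within - ss_ctx - ss_inter
    df_err = n_subj - 2
    out = {}
    for name, ss, err in [("group", ss_group, ss_subj_err),
                          ("context", ss_ctx, ss_within_err),
                          ("interaction", ss_inter, ss_within_err)]:
        out[name] = {"F": (ss / 1) / (err / df_err),
                     "np2": ss / (ss + err)}
    return out


class TestMixedAnova:
    def test_matches_brute_force_sums_of_squares(self, hand_dataset):
        res = mixed_anova(hand_dataset)
        oracle = brute_force_mixed_anova(hand_dataset)
        for eff in ("group", "context", "interaction"):
            assert res[eff]["F"] == pytest.approx(oracle[eff]["F"], abs=1e-10)
            assert res[eff]["np2"] == pytest.approx(oracle[eff]["np2"], abs=1e-10)
            assert res[eff]["df1"] == 1
            assert res[eff]["df2"] == 2

    def test_degenerate_no_variance_flagged(self):
        t = _table({(g, p, c): 1.0
                    for g, p in [("g1", "p1"), ("g1", "p2"), ("g2", "p3"), ("g2", "p4")]
                    for c in ("gain", "loss")})
        res = mixed_anova(t)
        assert res["degenerate"]
        assert res["group"]["F"] == 0.0

    def test_translation_invariance(self, hand_dataset):
        res = mixed_anova(hand_dataset)
        shifted = hand_dataset.assign(value=hand_dataset["value"] + 100.0)
        res2 = mixed_anova(shifted)
        for eff in ("group", "context", "interaction"):
            assert res2[eff]["F"] == pytest.approx(res[eff]["F"], rel=1e-9)

    def test_group_label_swap_leaves_F_unchanged(self, hand_dataset):
        res = mixed_anova(hand_dataset)
        swapped = hand_dataset.assign(
            group=hand_dataset["group"].map({"g1": "g2", "g2": "g1"}))
        res2 = mixed_anova(swapped)
        assert res2["group"]["F"] == pytest.approx(res["group"]["F"], rel=1e-9)

    def test_incomplete_participant_dropped_and_counted(self, hand_dataset):
        extra = pd.concat([hand_dataset, _table({("g1", "p9", "gain"): 1.5})],
                          ignore_index=True)
        res = mixed_anova(extra)
        assert res["n_dropped"] == 1


class TestSimpleEffects:
    def test_identical_groups_null(self):
        t = _table({("g1", "p1", "gain"): 1.0, ("g1", "p2", "gain"): 2.0,
                    ("g2", "p3", "gain"): 1.0, ("g2", "p4", "gain"): 2.0})
        (c,) = simple_effects(t, "context")
        assert c["t"] == pytest.approx(0.0)
        assert c["cohen_d"] == pytest.approx(0.0)

    def test_hand_sample_pooled_formulas(self):
        t = _table({("g1", "p1", "gain"): 1.0, ("g1", "p2", "gain"): 2.0,
                    ("g1", "p3", "gain"): 3.0,
                    ("g2", "p4", "gain"): 2.0, ("g2", "p5", "gain"): 3.0,
                    ("g2", "p6", "gain"): 4.0})
        (c,) = simple_effects(t, "context")
        sp = 1.0  # both samples have variance 1
        t_manual = (2.0 - 3.0) / (sp * np.sqrt(2 / 3))
        assert c["t"] == pytest.approx(t_manual, abs=1e-10)
        assert c["cohen_d"] == pytest.approx(-1.0, abs=1e-10)
        assert c["df"] == 4
        assert c["p_bonferroni"] >= c["p"]

    def test_label_swap_flips_contrast_sign(self, hand_dataset):
        res = simple_effects(hand_dataset, "context")
        swapped = hand_dataset.assign(
            group=hand_dataset["group"].map({"g1": "g2", "g2": "g1"}))
        res2 = simple_effects(swapped, "context")
        for c1, c2 in zip(res, res2):
            assert c2["t"] == pytest.approx(-c1["t"], rel=1e-9)

    def test_single_group_slice_skipped_with_note(self):
        t = _table({("g1", "p1", "gain"): 1.0, ("g1", "p2", "gain"): 2.0})
        (c,) = simple_effects(t, "context")
        assert c["skipped"]

    def test_bad_slicer(self, hand_dataset):
        with pytest.raises(ValueError):
            simple_effects(hand_dataset, "participant")


def test_full_report_structure(hand_dataset):
    params = hand_dataset.rename(columns={"value": "a"})
    params["beta0"] = params["a"] * 0.1 - 0.2
    rep = stats_report(params, ("a", "beta0"))
    assert rep["family_size"] == 2
    frame = report_frame(rep)
    assert {"parameter", "effect", "stat", "p_bonferroni"} <= set(frame.columns)
    assert (frame["p_bonferroni"] >= frame["p"] - 1e-15).all()
    text = format_report(rep)
    assert "== a ==" in text and "partial eta2" in text
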