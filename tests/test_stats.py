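"""ANOVA partitions against brute-force and pingouin oracles."""

import numpy as np
import pandas as pd
import pytest

from pupilpath.errors import ValidationError
from pupilpath.stats import mixed_anova, pairwise_paired_t, rm_anova


def brute_force_rm(x):
    """Textbook two-way within-subjects SS partition computed from raw
    sums with explicit loops (independent of the implementation)."""
    n, a, b = x.shape
    g = sum(x[s, i, j] for s in range(n) for i in range(a)
            for j in range(b)) / (n * a * b)
    ss = {k: 0.0 for k in ("A", "B", "AB", "AS", "BS", "total")}
    m_s = [x[s].mean() for s in range(n)]
    m_a = [x[:, i, :].mean() for i in range(a)]
    m_b = [x[:, :, j].mean() for j in range(b)]
    for i in range(a):
        ss["A"] += n * b * (m_a[i] - g) ** 2
    for j in range(b):
        ss["B"] += n * a * (m_b[j] - g) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (x[:, i, j].mean() - m_a[i] - m_b[j] + g) ** 2
    for s in range(n):
        for i in range(a):
            ss["AS"] += b * (x[s, i, :].mean() - m_s[s] - m_a[i] + g) ** 2
        for j in range(b):
            ss["BS"] += a * (x[s, :, j].mean() - m_s[s] - m_b[j] + g) ** 2
    for s in range(n):
        for i in range(a):
            for j in range(b):
                ss["total"] += (x[s, i, j] - g) ** 2
    ss_subj = sum(a * b * (m - g) ** 2 for m in m_s)
    ss_abs = ss["total"] - ss_subj - ss["A"] - ss["B"] - ss["AB"] \
        - ss["AS"] - ss["BS"]
    F_A = (ss["A"] / (a - 1)) / (ss["AS"] / ((a - 1) * (n - 1)))
    F_B = (ss["B"] / (b - 1)) / (ss["BS"] / ((b - 1) * (n - 1)))
    F_AB = (ss["AB"] / ((a - 1) * (b - 1))) / \
        (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    return F_A, F_B, F_AB


class TestRmAnova:
    def test_study_sized_grid_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        res = rm_anova(rng.normal(size=(21, 4, 10)))
        d = res.effect("difficulty")
        t = res.effect("time")
        i = res.effect("difficulty x time")
        assert (d.df_num, d.df_den) == (3, 60)
        assert (t.df_num, t.df_den) == (9, 180)
        assert (i.df_num, i.df_den) == (27, 540)

    def test_constant_grid_flags_zero_variance(self):
        res = rm_anova(np.full((5, 3, 4), 13.3))
        assert res.zero_variance
        assert all(e.F == 0.0 for e in res.effects)
        assert res.ss_total == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(13, 1, size=(5, 3, 4))
        res = rm_anova(x, ("A", "B"))
        F_A, F_B, F_AB = brute_force_rm(x)
        assert res.effect("A").F == pytest.approx(F_A, abs=1e-9)
        assert res.effect("B").F == pytest.approx(F_B, abs=1e-9)
        assert res.effect("A x B").F == pytest.approx(F_AB, abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(size=(8, 3, 5))
        res = rm_anova(x, ("A", "B"))
        rows = [(s, i, j, x[s, i, j]) for s in range(8) for i in range(3)
                for j in range(5)]
        df = pd.DataFrame(rows, columns=["s", "A", "B", "y"])
        ref = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="s")
        for name, src in [("A", "A"), ("B", "B"), ("A x B", "A * B")]:
            F_ref = float(ref.loc[ref.Source == src, "F"].iloc[0])
            assert res.effect(name).F == pytest.approx(F_ref, rel=1e-9)

    def test_affine_invariance_of_f(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(6, 4, 3))
        base = rm_anova(x)
        shifted = rm_anova(3.7 * x + 11.0)
        for e_b, e_s in zip(base.effects, shifted.effects):
            assert e_s.F == pytest.approx(e_b.F, rel=1e-9)

    def test_ss_decomposition_sums_to_total(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(7, 4, 6))
        res = rm_anova(x)
        parts = res.ss_subjects + sum(e.ss for e in res.effects) + \
            sum(res.extra_ss.values())
        assert parts == pytest.approx(res.ss_total, rel=1e-9)

    def test_incomplete_grid_names_missing_cells(self):
        x = np.random.default_rng(1).normal(size=(4, 3, 3))
        x[2, 1, 0] = np.nan
        with pytest.raises(ValidationError, match="subject 2"):
            rm_anova(x)

    def test_gg_epsilon_bounds(self):
        rng = np.random.default_rng(12)
        res = rm_anova(rng.normal(size=(10, 4, 5)), gg=True)
        for e in res.effects:
            assert 1.0 / e.df_num - 1e-12 <= e.gg_epsilon <= 1.0 + 1e-12
            if e.F > 1.0:  # shrinking df is conservative only when F > 1
                assert e.p_gg >= e.p - 1e-12


class TestMixedAnova:
    def test_between_effect_df(self):
        rng = np.random.default_rng(2)
        groups = ["faculty"] * 6 + ["resident"] * 15
        res = mixed_anova(rng.normal(size=(21, 4)), groups)
        e = res.effect("expertise")
        assert (e.df_num, e.df_den) == (1, 19)
        w = res.effect("category")
        assert (w.df_num, w.df_den) == (3, 57)

    def test_duplicated_groups_give_null_between_effect(self):
        rng = np.random.default_rng(3)
        block = rng.normal(size=(5, 4))
        values = np.vstack([block, block])
        groups = ["g1"] * 5 + ["g2"] * 5
        res = mixed_anova(values, groups)
        assert res.effect("expertise").F == pytest.approx(0.0, abs=1e-12)

    def test_matches_pingouin_balanced(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        values = rng.normal(size=(10, 4))
        groups = ["g1"] * 5 + ["g2"] * 5
        res = mixed_anova(values, groups)
        rows = [(s, groups[s], w, values[s, w]) for s in range(10)
                for w in range(4)]
        df = pd.DataFrame(rows, columns=["s", "g", "w", "y"])
        ref = pg.mixed_anova(data=df, dv="y", within="w", subject="s",
                             between="g")
        pairs = [("expertise", "g"), ("category", "w"),
                 ("category x expertise", "Interaction")]
        for name, src in pairs:
            F_ref = float(ref.loc[ref.Source == src, "F"].iloc[0])
            assert res.effect(name).F == pytest.approx(F_ref, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            mixed_anova(np.zeros((3, 4)), ["a", "a", "b"])


class TestPairwisePairedT:
    def test_identical_columns_flagged(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 2))
        out = pairwise_paired_t(x, ["a", "b"])
        row = out.iloc[0]
        assert row.t == 0.0 and row.p == 1.0 and row.zero_variance

    def test_constant_offset_flagged_undefined(self):
        base = np.arange(5.0)
        x = np.column_stack([base, base + 1.0])
        row = pairwise_paired_t(x).iloc[0]
        assert row.zero_variance and np.isnan(row.p)

    def test_matches_hand_computed_t(self):
        a = np.array([13.1, 13.4, 13.0, 13.8, 13.2, 13.6])
        b = np.array([13.0, 13.1, 13.2, 13.5, 13.1, 13.3])
        diff = a - b
        t_hand = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        out = pairwise_paired_t(np.column_stack([a, b]), ["a", "b"])
        assert out.iloc[0].t == pytest.approx(t_hand, abs=1e-9)
        assert out.iloc[0].dof == 5

    def test_all_pairs_enumerated(self):
        x = np.random.default_rng(0).normal(size=(6, 4))
        out = pairwise_paired_t(x, list("wxyz"))
        assert len(out) == 6
        assert set(zip(out.a, out.b)) == {
            ("w", "x"), ("w", "y"), ("w", "z"),
            ("x", "y"), ("x", "z"), ("y", "z")}
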