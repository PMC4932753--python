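"""Within-subject and mixed ANOVA on cell-mean grids, plus paired t-tests.

The two-way repeated-measures ANOVA uses the univariate sums-of-squares
partition: each within-subject effect is tested against its own
effect x subject interaction (MS_effect / MS_effect-x-subject), with no
sphericity correction by default -- Greenhouse-Geisser-corrected p
values are available by flag.  For a grid of ``n`` subjects, ``a`` and
``b`` factor levels, the degrees of freedom are (a-1, (a-1)(n-1)),
(b-1, (b-1)(n-1)) and ((a-1)(b-1), (a-1)(b-1)(n-1)).

The mixed design tests the between-subjects factor against
subjects-within-groups, and the within factor and its interaction with
group against the within x subjects-within-groups error.

F statistics are invariant to adding a constant to all observations and
to positive rescaling; degenerate (zero-variance) inputs are flagged
rather than raising.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError


@dataclass
class EffectResult:
    name: str
    df_num: int
    df_den: int
    ss: float
    ss_error: float
    F: float
    p: float
    gg_epsilon: float | None = None
    p_gg: float | None = None

    @property
    def ms(self) -> float:
        return self.ss / self.df_num if self.df_num else math.nan

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_den if self.df_den else math.nan


@dataclass
class AnovaResult:
    effects: list[EffectResult]
    ss_subjects: float
    ss_total: float
    zero_variance: bool = False
    extra_ss: dict = field(default_factory=dict)

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.name, e.df_num, e.df_den, e.ss, e.ms, e.ss_error,
              e.ms_error, e.F, e.p, e.gg_epsilon, e.p_gg)
             for e in self.effects],
            columns=["effect", "df_num", "df_den", "SS", "MS", "SS_error",
                     "MS_error", "F", "p", "gg_epsilon", "p_gg"],
        )

    def to_json(self, path=None) -> str:
        payload = {
            "effects": [
                {"name": e.name, "df_num": e.df_num, "df_den": e.df_den,
                 "SS": e.ss, "MS": e.ms, "SS_error": e.ss_error,
                 "MS_error": e.ms_error, "F": e.F, "p": e.p,
                 "gg_epsilon": e.gg_epsilon, "p_gg": e.p_gg}
                for e in self.effects
            ],
            "SS_subjects": self.ss_subjects,
            "SS_total": self.ss_total,
            "zero_variance": self.zero_variance,
            "extra_SS": self.extra_ss,
        }
        text = json.dumps(payload, indent=1, default=float)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _f_test(ss, df, ss_err, df_err):
    ms_err = ss_err / df_err if df_err else 0.0
    if ms_err <= 0:
        return 0.0, 1.0
    F = (ss / df) / ms_err
    return float(F), float(sps.f.sf(F, df, df_err))


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subjects x levels score matrix:
    double-center the covariance matrix S and form
    (sum of eigenvalues)^2 / ((k-1) * sum of squared eigenvalues)."""
    k = scores.shape[1]
    if k < 2:
        return 1.0
    S = np.cov(scores, rowvar=False)
    S = np.atleast_2d(S)
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) \
        + S.mean()
    tr = np.trace(Sc)
    denom = (k - 1) * float((Sc * Sc).sum())
    if denom <= 0:
        return 1.0
    eps = float(tr * tr / denom)
    return min(1.0, max(eps, 1.0 / (k - 1)))


def rm_anova(
    values: np.ndarray,
    factor_names: tuple[str, str] = ("difficulty", "time"),
    gg: bool = False,
) -> AnovaResult:
    """Two-way fully within-subjects ANOVA on a subjects x A x B grid.

    Parameters
    ----------
    values
        Complete (no NaN) array of cell means, shape ``(n, a, b)``.
    factor_names
        Labels for the two within factors, used in the result table.
    gg
        Also report Greenhouse-Geisser epsilon and corrected p values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 3:
        raise ValidationError("expected a subjects x A x B grid")
    n, a, b = x.shape
    if n < 2 or a < 2 or b < 2:
        raise ValidationError("need >= 2 subjects and >= 2 levels per factor")
    bad = np.argwhere(~np.isfinite(x))
    if bad.size:
        cells = ", ".join(
            f"(subject {i}, {factor_names[0]} {j}, {factor_names[1]} {k})"
            for i, j, k in bad[:5]
        )
        raise ValidationError(f"incomplete grid; missing cells: {cells}")

    g = x.mean()
    m_s = x.mean(axis=(1, 2))
    m_a = x.mean(axis=(0, 2))
    m_b = x.mean(axis=(0, 1))
    m_sa = x.mean(axis=2)
    m_sb = x.mean(axis=1)
    m_ab = x.mean(axis=0)

    ss_total = float(((x - g) ** 2).sum())
    ss_s = float(a * b * ((m_s - g) ** 2).sum())
    ss_a = float(n * b * ((m_a - g) ** 2).sum())
    ss_b = float(n * a * ((m_b - g) ** 2).sum())
    ss_ab = float(n * ((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2).sum())
    ss_as = float(b * ((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2).sum())
    ss_bs = float(a * ((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2).sum())
    ss_abs = ss_total - ss_s - ss_a - ss_b - ss_ab - ss_as - ss_bs
    ss_abs = max(ss_abs, 0.0)

    zero_variance = bool(ss_total <= 1e-12 * max(1.0, abs(g)) ** 2)

    specs = [
        (factor_names[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1), m_sa),
        (factor_names[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1), m_sb),
        (f"{factor_names[0]} x {factor_names[1]}", ss_ab,
         (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1), None),
    ]
    effects = []
    for name, ss, df, ss_err, df_err, scores in specs:
        F, p = _f_test(ss, df, ss_err, df_err)
        if zero_variance:
            F, p = 0.0, 1.0
        eff = EffectResult(name, df, df_err, ss, ss_err, F, p)
        if gg:
            if scores is None:
                # interaction residuals per subject x cell
                resid = (x - m_sa[:, :, None] - m_sb[:, None, :]
                         + m_s[:, None, None]).reshape(n, a * b)
                eps = _gg_epsilon(resid)
            else:
                eps = _gg_epsilon(scores)
            eff.gg_epsilon = eps
            if not zero_variance and eff.F > 0:
                eff.p_gg = float(sps.f.sf(eff.F, df * eps, df_err * eps))
            else:
                eff.p_gg = 1.0
        effects.append(eff)

    return AnovaResult(
        effects=effects,
        ss_subjects=ss_s,
        ss_total=ss_total,
        zero_variance=zero_variance,
        extra_ss={"A x subjects": ss_as, "B x subjects": ss_bs,
                  "A x B x subjects": ss_abs},
    )


def mixed_anova(
    values: np.ndarray,
    groups: Sequence[str],
    within_name: str = "category",
    between_name: str = "expertise",
) -> AnovaResult:
    """Mixed-design ANOVA: one within factor, one between-groups factor.

    Parameters
    ----------
    values
        Complete subjects x within-levels grid of cell means.
    groups
        One between-group label per subject; every group needs >= 2
        subjects.

    Notes
    -----
    Sums of squares are count-weighted (raw-score formulas), which for
    unequal group sizes corresponds to the sequential decomposition.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValidationError("expected a subjects x within-levels grid")
    n, w = x.shape
    if len(groups) != n:
        raise ValidationError("one group label per subject required")
    if not np.all(np.isfinite(x)):
        raise ValidationError("incomplete grid")
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups")
    gidx = {lab: [i for i, gl in enumerate(groups) if gl == lab]
            for lab in labels}
    for lab, idx in gidx.items():
        if len(idx) < 2:
            raise ValidationError(f"group {lab!r} has < 2 subjects")

    g = x.mean()
    m_s = x.mean(axis=1)
    m_w = x.mean(axis=0)
    ss_total = float(((x - g) ** 2).sum())
    ss_between_subj = float(w * ((m_s - g) ** 2).sum())
    ss_group = float(sum(
        len(idx) * w * (m_s[idx].mean() - g) ** 2 for idx in gidx.values()
    ))
    ss_subj_within = ss_between_subj - ss_group
    ss_within_total = ss_total - ss_between_subj
    ss_w = float(n * ((m_w - g) ** 2).sum())
    ss_inter = 0.0
    for idx in gidx.values():
        cell = x[idx].mean(axis=0)            # group x within cell means
        mg = m_s[idx].mean()
        ss_inter += len(idx) * float(((cell - mg - m_w + g) ** 2).sum())
    ss_err_within = ss_within_total - ss_w - ss_inter
    ss_err_within = max(ss_err_within, 0.0)

    ngroups = len(labels)
    df_group, df_sw = ngroups - 1, n - ngroups
    df_w, df_wer = w - 1, (w - 1) * (n - ngroups)
    df_int = (ngroups - 1) * (w - 1)

    zero_variance = bool(ss_total <= 1e-12 * max(1.0, abs(g)) ** 2)

    effs = []
    for name, ss, df, ss_err, df_err in [
        (between_name, ss_group, df_group, ss_subj_within, df_sw),
        (within_name, ss_w, df_w, ss_err_within, df_wer),
        (f"{within_name} x {between_name}", ss_inter, df_int,
         ss_err_within, df_wer),
    ]:
        F, p = _f_test(ss, df, ss_err, df_err)
        if zero_variance:
            F, p = 0.0, 1.0
        effs.append(EffectResult(name, df, df_err, ss, ss_err, F, p))

    return AnovaResult(
        effects=effs,
        ss_subjects=ss_between_subj,
        ss_total=ss_total,
        zero_variance=zero_variance,
        extra_ss={"subjects within groups": ss_subj_within,
                  "within error": ss_err_within},
    )


def pairwise_paired_t(
    values: np.ndarray,
    condition_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-sided paired t-tests over all unordered condition pairs.

    P values are unadjusted.  Pairs whose difference has zero variance
    are flagged: t = 0, p = 1 when the columns are identical, NaN
    otherwise.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need >= 2 subjects and >= 2 conditions")
    k = x.shape[1]
    names = list(condition_names) if condition_names else \
        [f"c{i}" for i in range(k)]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = x[:, i] - x[:, j]
            if np.allclose(diff.std(ddof=1), 0.0):
                if np.allclose(diff, 0.0):
                    t, p = 0.0, 1.0
                else:
                    t, p = math.nan, math.nan
                flagged = True
            else:
                res = sps.ttest_rel(x[:, i], x[:, j])
                t, p, flagged = float(res.statistic), float(res.pvalue), False
            rows.append((names[i], names[j], t, x.shape[0] - 1, p, flagged))
    return pd.DataFrame(
        rows, columns=["a", "b", "t", "dof", "p", "zero_variance"]
    )
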