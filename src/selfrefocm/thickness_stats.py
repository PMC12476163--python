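"""Group-level thickness statistics: one-way and two-way ANOVA.

Per-eye thickness summaries (map mean/SD per animal) are compared across
genotype (WT vs FECD) and age (5 wk vs 16 wk) with explicit
sums-of-squares ANOVA. F ratios are formed from the mean squares and
p-values from the upper tail of the F distribution. The two-way analysis
uses Type II sums of squares, which are order-invariant and appropriate
for the study's mildly unbalanced design (n = 4 WT vs n = 5 FECD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic_cornea import GROUP_DEFAULTS, GroupLabel, GroupParams

__all__ = [
    "EyeSummary",
    "AnovaResult",
    "one_way_anova",
    "two_way_anova",
    "group_comparison",
    "simulate_eye_summaries",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EyeSummary:
    """Per-eye (per-animal) thickness summary in µm."""

    animal: str
    group: GroupLabel
    layer: str
    mean_um: float
    sd_um: float
    n_valid: int

    def __post_init__(self) -> None:
        if self.mean_um <= 0:
            raise ValueError("mean thickness must be > 0 for a valid eye")


@dataclass(frozen=True)
class AnovaResult:
    """One tested effect: F ratio, degrees of freedom, p-value."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p <= self.alpha


def _f_pvalue(F: float, df_num: int, df_den: int) -> float:
    """Upper tail of the F distribution (regularized incomplete beta)."""
    return float(sps.f.sf(F, df_num, df_den))


def one_way_anova(groups: list[np.ndarray], alpha: float = DEFAULT_ALPHA,
                  effect: str = "group") -> AnovaResult:
    """Fixed-effects one-way ANOVA from explicit sums of squares.

    ``F = MS_between / MS_within`` with ``df = (k - 1, N - k)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_num = len(groups) - 1
    df_den = len(allv) - len(groups)
    if ss_within <= 0:
        if ss_between <= 0:
            raise ValueError("degenerate input: all values identical, F undefined")
        return AnovaResult(effect, float("inf"), df_num, df_den, 0.0, alpha)
    F = (ss_between / df_num) / (ss_within / df_den)
    return AnovaResult(effect, float(F), df_num, df_den, _f_pvalue(F, df_num, df_den), alpha)


def _design_columns(a: np.ndarray, b: np.ndarray) -> dict[str, np.ndarray]:
    """Effect-coded (+1/−1) design columns for a 2×2 layout."""
    ca = np.where(a, 1.0, -1.0)
    cb = np.where(b, 1.0, -1.0)
    return {"A": ca[:, None], "B": cb[:, None], "AB": (ca * cb)[:, None]}


def _rss(y: np.ndarray, cols: list[np.ndarray]) -> float:
    """Residual sum of squares of an OLS fit with intercept."""
    X = np.hstack([np.ones((len(y), 1))] + cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(
    values: np.ndarray,
    genotype: np.ndarray,
    age: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    labels: tuple[str, str, str] = ("genotype", "age", "interaction"),
) -> dict[str, AnovaResult]:
    """Two-way fixed-effects ANOVA (genotype × age), Type II sums of squares.

    ``genotype`` and ``age`` are boolean (or two-level) arrays. Each main
    effect is tested by the increase in residual SS when it is dropped from
    the additive model; the interaction against the full model. For
    balanced data this reduces to the classical orthogonal decomposition.
    All four cells must be non-empty.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(genotype)
    b = np.asarray(age)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must have equal length")
    ua, ub = np.unique(a), np.unique(b)
    if len(ua) != 2 or len(ub) != 2:
        raise ValueError("both factors must have exactly two levels")
    for va in ua:
        for vb in ub:
            if not np.any((a == va) & (b == vb)):
                raise ValueError("empty cell in the 2x2 design")
    abin = a == ua[1]
    bbin = b == ub[1]
    cols = _design_columns(abin, bbin)

    rss_full = _rss(y, [cols["A"], cols["B"], cols["AB"]])
    rss_additive = _rss(y, [cols["A"], cols["B"]])
    rss_no_a = _rss(y, [cols["B"]])
    rss_no_b = _rss(y, [cols["A"]])

    ss = {
        labels[0]: rss_no_a - rss_additive,
        labels[1]: rss_no_b - rss_additive,
        labels[2]: rss_additive - rss_full,
    }
    df_den = len(y) - 4
    if df_den < 1:
        raise ValueError("need more than 4 observations")
    ms_err = rss_full / df_den
    out = {}
    for name, s in ss.items():
        s = max(s, 0.0)
        if ms_err <= 0:
            F = float("inf") if s > 0 else 0.0
            p = 0.0 if s > 0 else 1.0
        else:
            F = (s / 1) / ms_err
            p = _f_pvalue(F, 1, df_den)
        out[name] = AnovaResult(name, float(F), 1, df_den, p, alpha)
    return out


_AGE = {GroupLabel.WT_5wk: "5wk", GroupLabel.FECD_5wk: "5wk",
        GroupLabel.WT_16wk: "16wk", GroupLabel.FECD_16wk: "16wk"}
_GENO = {GroupLabel.WT_5wk: "WT", GroupLabel.WT_16wk: "WT",
         GroupLabel.FECD_5wk: "FECD", GroupLabel.FECD_16wk: "FECD"}

#: the four pairwise contrasts reported for the study design
PAIRWISE_COMPARISONS = (
    (GroupLabel.WT_5wk, GroupLabel.FECD_5wk),
    (GroupLabel.WT_16wk, GroupLabel.FECD_16wk),
    (GroupLabel.WT_5wk, GroupLabel.WT_16wk),
    (GroupLabel.FECD_5wk, GroupLabel.FECD_16wk),
)


def group_comparison(
    summaries: list[EyeSummary] | pd.DataFrame,
    design: str = "both",
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """Full group-comparison report for the 2×2 study design.

    Emits per-group mean ± SD, the four pairwise one-way ANOVAs
    (genotype at each age, age within each genotype) and, when all four
    cells are present, the two-way genotype × age analysis. Percent
    difference of FECD vs WT means is reported at each age.
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
        df["group"] = df["group"].map(lambda g: GroupLabel(g))
    else:
        df = pd.DataFrame(
            {
                "animal": [s.animal for s in summaries],
                "group": [s.group for s in summaries],
                "mean_um": [s.mean_um for s in summaries],
            }
        )
    by_group = {g: df.loc[df["group"] == g, "mean_um"].to_numpy() for g in GroupLabel}
    present = {g for g, v in by_group.items() if len(v) > 0}
    for g in present:
        if len(by_group[g]) < 2:
            raise ValueError(f"need at least 2 eyes per group, {g.value} has {len(by_group[g])}")

    report: dict = {"alpha": alpha, "groups": {}, "pairwise": {}, "percent_difference": {}}
    for g in present:
        v = by_group[g]
        report["groups"][g.value] = {
            "n": int(len(v)),
            "mean_um": float(np.mean(v)),
            "sd_um": float(np.std(v, ddof=1)),
        }
    for g1, g2 in PAIRWISE_COMPARISONS:
        if g1 in present and g2 in present:
            res = one_way_anova([by_group[g1], by_group[g2]], alpha,
                                effect=f"{g1.value}_vs_{g2.value}")
            report["pairwise"][res.effect] = res
    for age in ("5wk", "16wk"):
        wt = GroupLabel(f"WT_{age}")
        fecd = GroupLabel(f"FECD_{age}")
        if wt in present and fecd in present:
            m_wt = float(np.mean(by_group[wt]))
            m_f = float(np.mean(by_group[fecd]))
            report["percent_difference"][age] = 100.0 * (m_f - m_wt) / m_wt
    if design in ("both", "twoway") and present == set(GroupLabel):
        values = np.concatenate([by_group[g] for g in GroupLabel])
        geno = np.concatenate([[_GENO[g]] * len(by_group[g]) for g in GroupLabel])
        age = np.concatenate([[_AGE[g]] * len(by_group[g]) for g in GroupLabel])
        report["twoway"] = two_way_anova(values, geno, age, alpha)
    return report


def simulate_eye_summaries(
    group: GroupParams | GroupLabel,
    n_eyes: int,
    seed: int,
    layer: str = "dm",
) -> list[EyeSummary]:
    """Draw per-eye mean thicknesses from the group's between-eye
    distribution (printed group mean ± SD)."""
    if isinstance(group, GroupLabel):
        group = GROUP_DEFAULTS[group]
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    rng = np.random.default_rng(seed)
    mean, sd = (group.dm_mean, group.dm_sd) if layer == "dm" else (group.stroma_mean, group.stroma_sd)
    out = []
    for i in range(n_eyes):
        m = float(np.clip(rng.normal(mean, sd), 0.05 * mean, None))
        out.append(EyeSummary(f"{group.label.value}-{i}", group.label, layer, m, sd, 1))
    return out
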