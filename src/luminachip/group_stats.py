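"""Group-comparison statistics: t-test, one-way ANOVA + Tukey, two-way ANOVA.

This mirrors the comparison layer used for chip-derived measurements
(invasion distances, protrusion lengths, permeabilities): classical
equal-variance tests with significance declared at p < 0.05, Tukey's HSD
for pairwise comparisons after a one-way ANOVA, and a type-II two-way
ANOVA for designs with a second factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
#: ``one_way_anova`` is the omnibus F-test alone — the cheap variant for
#: simulation studies; ``one_way_anova_tukey`` adds Tukey HSD pairwise tests
DESIGNS = ("t_test", "one_way_anova", "one_way_anova_tukey", "two_way_anova")


@dataclass
class GroupSamples:
    """Named groups of measurements, optionally with a second factor.

    ``factors`` maps each group name to per-observation labels of the
    second factor (required for the two-way design).
    """

    groups: dict
    factors: dict | None = None

    def __post_init__(self):
        self.groups = {str(k): np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for name, values in self.groups.items():
            if values.size < 2:
                raise ValueError(f"group {name!r} needs at least two measurements")
        if self.factors is not None:
            for name, labels in self.factors.items():
                if name not in self.groups:
                    raise ValueError(f"factor labels given for unknown group {name!r}")
                if len(labels) != self.groups[name].size:
                    raise ValueError(f"factor labels for {name!r} do not match group size")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, values in self.groups.items():
            labels = self.factors.get(name) if self.factors else [None] * values.size
            for v, f2 in zip(values, labels):
                rows.append({"value": v, "group": name, "factor2": f2})
        return pd.DataFrame(rows)


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    pairwise: list = field(default_factory=list)  # (pair, adjusted p, significant)
    alpha: float = ALPHA
    terms: dict = field(default_factory=dict)  # two-way: term -> (F, p)
    warnings: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _degenerate(data: GroupSamples) -> bool:
    allv = np.concatenate(list(data.groups.values()))
    return bool(np.ptp(allv) == 0)


def compare_groups(data: GroupSamples, design: str = "one_way_anova_tukey", equal_var: bool = True) -> TestResult:
    """Run the requested comparison and flag significance at p < alpha.

    ``equal_var=False`` switches the two-sample design to Welch's t-test.
    Identical values in every group are reported as p = 1 with a warning
    rather than a numerical error.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    if _degenerate(data):
        warnings.warn("all measurements identical: no variance to test", stacklevel=2)
        return TestResult(test_name=design, statistic=0.0, p_value=1.0,
                          warnings=["degenerate variance"])

    if design == "t_test":
        if len(data.groups) != 2:
            raise ValueError("t_test requires exactly two groups")
        a, b = data.groups.values()
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        return TestResult(test_name="t_test" if equal_var else "welch_t_test",
                          statistic=float(t), p_value=float(p))

    if design in ("one_way_anova", "one_way_anova_tukey"):
        values = list(data.groups.values())
        F, p = stats.f_oneway(*values)
        result = TestResult(test_name=design, statistic=float(F), p_value=float(p))
        if design == "one_way_anova_tukey" and len(values) >= 2:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            flat = np.concatenate(values)
            labels = np.concatenate(
                [np.full(v.size, name) for name, v in data.groups.items()]
            )
            tk = pairwise_tukeyhsd(flat, labels, alpha=ALPHA)
            from itertools import combinations

            pairs = list(combinations(tk.groupsunique, 2))
            for (g1, g2), padj, rej in zip(pairs, tk.pvalues, tk.reject):
                result.pairwise.append(((str(g1), str(g2)), float(padj), bool(rej)))
        return result

    # two-way ANOVA, type-II sums of squares
    if data.factors is None:
        raise ValueError("two_way_anova requires second-factor labels")
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    frame = data.to_frame()
    if frame["factor2"].isna().any():
        raise ValueError("every observation needs a second-factor label")
    model = smf.ols("value ~ C(group) + C(factor2) + C(group):C(factor2)", data=frame).fit()
    table = anova_lm(model, typ=2)
    terms = {
        str(idx): (float(row["F"]), float(row["PR(>F)"]))
        for idx, row in table.iterrows()
        if np.isfinite(row["F"])
    }
    F, p = terms["C(group)"]
    return TestResult(test_name="two_way_anova", statistic=F, p_value=p, terms=terms)
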