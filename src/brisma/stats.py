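"""Group-comparison reporting layer.

Deliberately a thin wrapper over standard routines: a Shapiro-Wilk
normality gate (alpha = 0.05) selects the two-group test (unpaired
two-tailed t-test if all groups normal, Mann-Whitney otherwise); for more
than two groups, one-way ANOVA followed by Tukey's all-pairs comparison or
Dunnett's comparisons against the control.  The gate rule is encoded so the
test selection is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import SampleSizeError

__all__ = ["GroupComparison", "compare_groups"]


@dataclass
class GroupComparison:
    """Outcome of a gated group comparison."""

    group_labels: list[str]
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    test_name: str  # t-test | mann-whitney | anova+tukey | anova+dunnett
    normal: dict[str, bool]
    p_value: float
    pairwise: dict[str, float] = field(default_factory=dict)
    effect_direction: dict[str, str] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Group comparison", "================"]
        for g in self.group_labels:
            lines.append(
                f"{g:>12}: n={self.n[g]:<4d} mean={self.mean[g]:.4g} sd={self.sd[g]:.4g} "
                f"normal={self.normal[g]}"
            )
        lines.append(f"test: {self.test_name}   p = {self.p_value:.4g}")
        for pair, p in self.pairwise.items():
            lines.append(f"  {pair}: p = {p:.4g} ({self.effect_direction.get(pair, '')})")
        return "\n".join(lines)


def compare_groups(
    values: dict[str, "np.ndarray | list"],
    design: str = "all-pairs",
    control: str = "control",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare groups with the normality-gated test selection rule.

    Parameters
    ----------
    values:
        Mapping of group label -> observations (each n >= 3).
    design:
        ``"all-pairs"`` (Tukey) or ``"vs-control"`` (Dunnett) for >2 groups.
    control:
        Label of the control group for the Dunnett design.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    if len(groups) < 2:
        raise SampleSizeError("need at least two groups")
    for k, v in groups.items():
        if v.size < 3:
            raise SampleSizeError(f"group {k!r} has n={v.size} < 3")
    labels = list(groups)
    normal = {k: bool(sps.shapiro(v).pvalue > alpha) for k, v in groups.items()}
    all_normal = all(normal.values())
    n = {k: int(v.size) for k, v in groups.items()}
    mean = {k: float(v.mean()) for k, v in groups.items()}
    sd = {k: float(v.std(ddof=1)) for k, v in groups.items()}

    pairwise: dict[str, float] = {}
    direction: dict[str, str] = {}
    if len(groups) == 2:
        a, b = (groups[k] for k in labels)
        if all_normal:
            test_name = "t-test"
            p = float(sps.ttest_ind(a, b).pvalue)
        else:
            test_name = "mann-whitney"
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        direction[f"{labels[0]} vs {labels[1]}"] = (
            "higher" if mean[labels[0]] > mean[labels[1]] else "lower"
        )
    else:
        p = float(sps.f_oneway(*groups.values()).pvalue)
        if design == "vs-control":
            if control not in groups:
                raise SampleSizeError(f"control group {control!r} missing for Dunnett design")
            test_name = "anova+dunnett"
            others = [k for k in labels if k != control]
            res = sps.dunnett(*(groups[k] for k in others), control=groups[control])
            for k, pv in zip(others, res.pvalue):
                key = f"{k} vs {control}"
                pairwise[key] = float(pv)
                direction[key] = "higher" if mean[k] > mean[control] else "lower"
        else:
            test_name = "anova+tukey"
            res = sps.tukey_hsd(*groups.values())
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    key = f"{labels[i]} vs {labels[j]}"
                    pairwise[key] = float(res.pvalue[i, j])
                    direction[key] = (
                        "higher" if mean[labels[i]] > mean[labels[j]] else "lower"
                    )
    return GroupComparison(
        group_labels=labels,
        n=n,
        mean=mean,
        sd=sd,
        test_name=test_name,
        normal=normal,
        p_value=p,
        pairwise=pairwise,
        effect_direction=direction,
    )
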