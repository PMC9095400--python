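"""Clinical outcome arithmetic from printed group summary tables.

Works entirely from summary statistics of two nursing groups (a control
group under conventional care and an experimental group under
perioperative management, n = 50 each): per-complication patient
counts, three-category nursing-satisfaction tallies, and (mean, sd)
pairs for continuous outcomes.  Provides the complication-rate and
total-satisfaction percentages and two-sample t comparisons (pooled or
Welch) computed from the summaries alone.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml
from scipy import stats

__all__ = [
    "OutcomeGroup", "GroupComparison", "complication_rate",
    "total_satisfaction", "two_sample_t", "load_group_tables",
    "summary_report",
]


@dataclass
class OutcomeGroup:
    """Summary statistics of one study arm."""

    label: str
    n: int
    complication_counts: dict[str, int] = field(default_factory=dict)
    satisfaction: dict[str, float] = field(default_factory=dict)
    satisfaction_as_percent: bool = True
    continuous_outcomes: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("group size must be positive")
        for name, count in self.complication_counts.items():
            if count < 0 or count > self.n:
                raise ValueError(f"complication count {name!r} outside [0, n]")
        if self.satisfaction:
            keys = {"very_satisfied", "satisfied", "dissatisfied"}
            if set(self.satisfaction) != keys:
                raise ValueError(f"satisfaction needs exactly the keys {keys}")
            total = sum(self.satisfaction.values())
            if self.satisfaction_as_percent:
                if abs(total - 100.0) > 1.0:
                    raise ValueError("satisfaction percentages must sum to 100 +/- 1")
            elif total != self.n:
                raise ValueError("satisfaction counts must sum to n")


@dataclass
class GroupComparison:
    outcome: str
    group_values: dict[str, tuple[float, float]]
    t_statistic: float
    p_value: float
    variant: str
    df: float

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def complication_rate(group: OutcomeGroup) -> float:
    """Percentage of patients with a complication.

    Assumes one recorded complication per affected patient, so the rate
    is 100 * (sum of counts) / n; a sum exceeding n violates that
    assumption and raises.
    """
    total = sum(group.complication_counts.values())
    if total > group.n:
        raise ValueError("complication counts exceed group size; "
                         "one-complication-per-patient assumption violated")
    return 100.0 * total / group.n


def total_satisfaction(group: OutcomeGroup) -> float:
    """Total satisfaction percent: (very satisfied + satisfied) / n.

    Accepts either category counts or percentages (the canonical
    printed form), returning a percentage in both cases.
    """
    if not group.satisfaction:
        raise ValueError("group has no satisfaction data")
    vs = group.satisfaction["very_satisfied"]
    s = group.satisfaction["satisfied"]
    if group.satisfaction_as_percent:
        return float(vs + s)
    return 100.0 * (vs + s) / group.n


def two_sample_t(a: tuple[float, float, int], b: tuple[float, float, int],
                 variant: str = "pooled", outcome: str = "") -> GroupComparison:
    """Two-sided two-sample t-test from (mean, sd, n) summaries."""
    mean_a, sd_a, n_a = a
    mean_b, sd_b, n_b = b
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                     equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = n_a + n_b - 2
    else:
        va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
        df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    return GroupComparison(
        outcome=outcome,
        group_values={"a": (mean_a, sd_a), "b": (mean_b, sd_b)},
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        variant=variant,
        df=float(df),
    )


def _group_from_dict(d: dict) -> OutcomeGroup:
    return OutcomeGroup(
        label=d["label"],
        n=d["n"],
        complication_counts=dict(d.get("complication_counts", {})),
        satisfaction=dict(d.get("satisfaction", {})),
        satisfaction_as_percent=d.get("satisfaction_as_percent", True),
        continuous_outcomes={k: tuple(v) for k, v in
                             d.get("continuous_outcomes", {}).items()},
    )


def load_group_tables(path=None) -> dict[str, OutcomeGroup]:
    """Load the packaged (or a user-supplied) group-table YAML fixture."""
    if path is None:
        ref = importlib.resources.files("usdenoise.data") / "group_tables.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {key: _group_from_dict(d) for key, d in raw["groups"].items()}


def summary_report(groups: dict[str, OutcomeGroup] | None = None,
                   variant: str = "pooled") -> dict:
    """Full JSON-ready report: rates, satisfaction, and t-tests for every
    continuous outcome shared by both groups."""
    groups = groups or load_group_tables()
    control, experimental = groups["control"], groups["experimental"]
    report = {
        "complication_rate_percent": {
            g.label: complication_rate(g) for g in (control, experimental)
        },
        "total_satisfaction_percent": {
            g.label: total_satisfaction(g) for g in (control, experimental)
        },
        "comparisons": {},
    }
    shared = set(control.continuous_outcomes) & set(experimental.continuous_outcomes)
    for name in sorted(shared):
        mc, sc = control.continuous_outcomes[name]
        me, se = experimental.continuous_outcomes[name]
        cmp = two_sample_t((me, se, experimental.n), (mc, sc, control.n),
                           variant=variant, outcome=name)
        report["comparisons"][name] = {
            "experimental_mean_sd": [me, se],
            "control_mean_sd": [mc, sc],
            "t": cmp.t_statistic,
            "p": cmp.p_value,
            "df": cmp.df,
            "variant": variant,
        }
    return report
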