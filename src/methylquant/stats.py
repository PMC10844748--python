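"""Group statistics for methylation assays.

The comparisons used throughout methylation-stoichiometry experiments:
ordinary one-way ANOVA with Dunnett's many-to-one post hoc against a
control group, Sidak-adjusted planned pairwise comparisons, Welch's
unequal-variance t-test, ordinary least-squares lines restricted to an
x range (initial-rate fits), and four-parameter logistic (4PL)
dose-response fits with r².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GroupTable",
    "DoseResponse",
    "AnovaDunnettResult",
    "FitError",
    "anova_dunnett",
    "pairwise_sidak",
    "welch_t",
    "linear_fit",
    "fit_4pl",
    "four_pl",
    "significance_stars",
]


@dataclass
class GroupTable:
    """Labelled replicate values, optionally with a designated control group."""

    groups: dict
    control_label: Optional[str] = None

    def __post_init__(self):
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        for label, values in self.groups.items():
            if values.ndim != 1 or values.size == 0:
                raise ValueError(f"group {label!r} must be a non-empty 1-D array")
        if self.control_label is not None and self.control_label not in self.groups:
            raise KeyError(f"control label {self.control_label!r} not in groups")

    @classmethod
    def from_frame(cls, df, group_col="group", value_col="value", control_label=None):
        groups = {
            str(g): sub[value_col].to_numpy(float)
            for g, sub in df.groupby(group_col, sort=False)
        }
        return cls(groups, control_label)


def significance_stars(p: float) -> str:
    """GraphPad-style significance annotation."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaDunnettResult:
    f_statistic: float
    p_value: float
    control_label: str
    comparisons: dict  # group label -> adjusted p vs control

    def stars(self) -> dict:
        return {k: significance_stars(p) for k, p in self.comparisons.items()}


def anova_dunnett(table: GroupTable) -> AnovaDunnettResult:
    """One-way ANOVA F/p plus Dunnett-adjusted p per group vs the control.

    Dunnett p-values come from the multivariate-t distribution of the
    many-to-one contrasts, controlling family-wise error across the
    non-control groups.  Degenerate all-equal input returns F = 0 and
    adjusted p = 1 for every comparison.
    """
    if table.control_label is None:
        raise ValueError("anova_dunnett requires a control_label")
    labels = [l for l in table.groups if l != table.control_label]
    if not labels:
        raise ValueError("need at least one non-control group")
    control = table.groups[table.control_label]
    samples = [table.groups[l] for l in labels]
    for label, values in table.groups.items():
        if values.size < 2:
            raise ValueError(f"group {label!r} needs n >= 2 for variance estimates")

    all_values = np.concatenate([control] + samples)
    if np.ptp(all_values) == 0:
        return AnovaDunnettResult(0.0, 1.0, table.control_label,
                                  {l: 1.0 for l in labels})

    f_stat, p = stats.f_oneway(control, *samples)
    # the multivariate-t CDF behind Dunnett's p is evaluated by quasi-Monte
    # Carlo; a fixed internal rng keeps reports byte-reproducible
    dunnett = stats.dunnett(*samples, control=control,
                            rng=np.random.default_rng(1905))
    comparisons = {l: float(pv) for l, pv in zip(labels, dunnett.pvalue)}
    return AnovaDunnettResult(float(f_stat), float(p), table.control_label, comparisons)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-tailed t-test: (t, Welch-Satterthwaite df, p).

    Two zero-variance groups with equal means return (0, df, 1) by
    convention rather than NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires n >= 2 in each group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pairwise_sidak(pairs: Sequence[tuple[Sequence[float], Sequence[float]]]) -> list[float]:
    """Sidak-adjusted Welch p-values over m planned pairs: 1 - (1-p)^m."""
    if not pairs:
        raise ValueError("need at least one pair")
    m = len(pairs)
    raw = [welch_t(a, b)[2] for a, b in pairs]
    return [float(1.0 - (1.0 - p) ** m) for p in raw]


def linear_fit(
    x: Sequence[float],
    y: Sequence[float],
    x_range: Optional[tuple[float, float]] = None,
) -> tuple[float, float, float]:
    """OLS line restricted to an x range: (slope, intercept, r2).

    Constant y returns slope 0, intercept mean(y), r2 = 0 by convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x_range is not None:
        mask = (x >= x_range[0]) & (x <= x_range[1])
        x, y = x[mask], y[mask]
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct x values in range")
    if np.ptp(y) == 0:
        return 0.0, float(y.mean()), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def four_pl(dose, bottom, top, ec50, hill):
    """Four-parameter logistic on a linear dose axis (0-dose allowed)."""
    dose = np.asarray(dose, float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ec50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge; carries diagnostics."""


@dataclass
class DoseResponse:
    """Dose-response observations and, after fitting, the 4PL parameters."""

    doses: np.ndarray
    responses: np.ndarray
    fit: Optional[tuple[float, float, float, float]] = None  # bottom, top, ec50, hill
    r2: Optional[float] = None
    degenerate: bool = False

    def __post_init__(self):
        self.doses = np.asarray(self.doses, float)
        self.responses = np.asarray(self.responses, float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")

    @property
    def ec50(self) -> float:
        if self.fit is None:
            raise AttributeError("dose-response not yet fitted")
        return self.fit[2]


def fit_4pl(data: DoseResponse) -> DoseResponse:
    """Least-squares 4PL fit y = bottom + (top-bottom)/(1 + (d/ec50)^hill).

    Zero doses are kept on the linear-dose parameterisation.  Constant
    responses are flagged degenerate (r2 convention 0).  Non-convergence
    raises FitError with the optimiser message.
    """
    doses, y = data.doses, data.responses
    if np.unique(doses).size < 5:
        raise ValueError("fit_4pl requires >= 5 distinct dose levels")
    if np.ptp(y) == 0:
        return DoseResponse(doses, y, fit=(float(y[0]), float(y[0]), np.nan, np.nan),
                            r2=0.0, degenerate=True)

    positive = doses[doses > 0]
    ec50_0 = float(np.exp(np.mean(np.log(positive)))) if positive.size else 1.0
    # hill is constrained positive, so 'top' is the zero-dose asymptote and
    # the response direction is carried by the top/bottom ordering.
    t0 = float(y[np.argmin(doses)])
    b0 = float(y[np.argmax(doses)])
    guesses = [
        (b0, t0, ec50_0, 1.0),
        (b0, t0, ec50_0, 2.0),
        (float(y.min()), float(y.max()), ec50_0, 1.5),
        (float(y.max()), float(y.min()), ec50_0, 1.5),
    ]
    best = None
    last_err = ""
    for p0 in guesses:
        try:
            popt, _ = optimize.curve_fit(
                four_pl, doses, y, p0=p0, maxfev=20000,
                bounds=([-np.inf, -np.inf, 1e-12, 1e-6], [np.inf, np.inf, np.inf, 50]),
            )
        except (RuntimeError, ValueError) as exc:
            last_err = str(exc)
            continue
        ss_res = float(np.sum((y - four_pl(doses, *popt)) ** 2))
        if best is None or ss_res < best[1]:
            best = (popt, ss_res)
    if best is None:
        raise FitError(f"4PL fit failed to converge: {last_err}")
    popt, ss_res = best
    bottom, top, ec50, hill = (float(v) for v in popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return DoseResponse(doses, y, fit=(bottom, top, ec50, hill), r2=float(r2))
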