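"""24 h output estimation and the equivalence/ANOVA statistics.

The clinical summary quantity is the 24 h total cortisol output: the
trapezoidal integral of concentration over the admission window, with time
in minutes (so a constant 1 ug/dl profile integrates to 1440 ug*min/dl).

Equivalence between interpolated and observed outputs is tested with two
one-sided paired t-tests (TOST) on the log scale: with paired differences
d_i = log(y_i) - log(x_i), the mean difference is tested against -epsilon
and +epsilon (default epsilon = 0.25, i.e. roughly a +/-25% ratio region);
equivalence is declared when both one-sided p-values fall below alpha,
equivalently when the (1 - 2 alpha) CI lies inside (-epsilon, +epsilon).
Cohen's d is the magnitude of mean(d)/sd(d).

Mean output differences across specimen and condition are tested with a
two-way fixed-effects ANOVA (statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import rmse  # noqa: F401  (re-exported convenience)
from .profiles import WINDOW_MAX, WINDOW_MIN

INTEGRATION_RULES = ("trapezoid", "trapezoid_hours", "sum")


@dataclass(frozen=True)
class OutputEstimate:
    """A 24 h output (AUC) with its provenance."""

    subject_id: str
    condition: str
    specimen: str
    scheme: str
    auc: float  #: ug*min/dl over [0, 1440]
    source: str = "observed"  #: "observed" or "interpolated"
    degree: int | None = None


def total_output(profile, window=(WINDOW_MIN, WINDOW_MAX), rule: str = "trapezoid") -> float:
    """Integrated concentration over ``window`` (default the full 24 h).

    ``profile`` is anything with ``times`` (minutes) and ``values`` arrays
    whose grid contains both window endpoints.  The default rule is the
    trapezoid with time in minutes; ``trapezoid_hours`` divides by 60;
    ``sum`` is the plain sample sum (no time weighting).
    """
    times = np.asarray(profile.times, dtype=float)
    values = np.asarray(profile.values, dtype=float)
    lo, hi = float(window[0]), float(window[1])
    if lo not in times or hi not in times:
        raise ValueError(f"profile must contain both window endpoints {window}")
    mask = (times >= lo) & (times <= hi)
    t, v = times[mask], values[mask]
    if rule == "trapezoid":
        return float(np.trapezoid(v, t))
    if rule == "trapezoid_hours":
        return float(np.trapezoid(v, t / 60.0))
    if rule == "sum":
        return float(np.sum(v))
    raise ValueError(f"unknown integration rule {rule!r}; choose from {INTEGRATION_RULES}")


@dataclass(frozen=True)
class TOSTConfig:
    """Equivalence-test settings: region half-width, level, transform."""

    epsilon: float = 0.25
    alpha: float = 0.05
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class EquivalenceResult:
    """Paired TOST estimate, CI, one-sided p-values, decision, effect size."""

    estimate: float
    ci_lower: float
    ci_upper: float
    p_lower: float
    p_upper: float
    equivalent: bool
    cohens_d: float
    epsilon: float
    alpha: float
    n: int


def cohens_d_paired(d) -> float:
    """Magnitude of mean(d)/sd(d) for paired differences ``d``."""
    d = np.asarray(d, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 paired differences")
    sd = d.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(abs(d).max())):
        raise ValueError("zero standard deviation: Cohen's d undefined")
    return float(abs(d.mean() / sd))


def tost_paired(x, y, config: TOSTConfig = TOSTConfig()) -> EquivalenceResult:
    """Two one-sided paired t-tests of equivalence between ``x`` and ``y``.

    Pairs are by position (same subject).  With the log transform on (the
    default), the tested quantity is the mean of log(y) - log(x).  The CI
    is reported at the 1 - 2*alpha level, the standard TOST convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if config.log_transform:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log transform requires strictly positive outputs")
        d = np.log(y) - np.log(x)
    else:
        d = y - x
    m = float(d.mean())
    s = float(d.std(ddof=1))
    df = n - 1
    eps, alpha = config.epsilon, config.alpha
    if s <= 1e-12 * max(1.0, float(np.abs(d).max())):
        # degenerate: the mean difference is known exactly
        p_lower = 0.0 if m > -eps else 1.0
        p_upper = 0.0 if m < eps else 1.0
        ci_lower = ci_upper = m
        cohens = float("nan")
    else:
        se = s / np.sqrt(n)
        p_lower = float(stats.t.sf((m + eps) / se, df))
        p_upper = float(stats.t.cdf((m - eps) / se, df))
        tcrit = stats.t.ppf(1.0 - alpha, df)
        ci_lower = m - tcrit * se
        ci_upper = m + tcrit * se
        cohens = cohens_d_paired(d)
    equivalent = max(p_lower, p_upper) < alpha
    return EquivalenceResult(
        estimate=m,
        ci_lower=float(ci_lower),
        ci_upper=float(ci_upper),
        p_lower=p_lower,
        p_upper=p_upper,
        equivalent=bool(equivalent),
        cohens_d=cohens,
        epsilon=eps,
        alpha=alpha,
        n=n,
    )


def anova_outputs(outputs: list[OutputEstimate], interaction: bool = False) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of AUC on specimen and condition.

    Expects ground-truth-scheme observed outputs covering every
    specimen x condition cell with the same subjects (balanced design).
    Returns a tidy table with factor, df, sum_sq, F and p columns.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    frame = pd.DataFrame(
        {
            "subject_id": [o.subject_id for o in outputs],
            "specimen": [o.specimen for o in outputs],
            "condition": [o.condition for o in outputs],
            "auc": [o.auc for o in outputs],
        }
    )
    cells = frame.groupby(["specimen", "condition"])["subject_id"].apply(set)
    expected = [(s, c) for s in sorted(frame["specimen"].unique())
                for c in sorted(frame["condition"].unique())]
    for cell in expected:
        if cell not in cells.index:
            raise ValueError(f"missing specimen x condition cell: {cell}")
    subjects = cells.iloc[0]
    if not all(cell_subjects == subjects for cell_subjects in cells):
        raise ValueError("unbalanced design: cells cover different subjects")

    if np.ptp(frame["auc"].to_numpy()) == 0.0:
        # no variation at all: F = 0/0 formally; report the null outcome
        factors = ["C(specimen)", "C(condition)"]
        if interaction:
            factors.append("C(specimen):C(condition)")
        n = len(frame)
        dfs = [1.0] * len(factors) + [float(n - len(factors) - 1)]
        return pd.DataFrame(
            {
                "factor": factors + ["Residual"],
                "df": dfs,
                "sum_sq": [0.0] * (len(factors) + 1),
                "F": [0.0] * len(factors) + [np.nan],
                "p": [1.0] * len(factors) + [np.nan],
            }
        )

    formula = "auc ~ C(specimen) " + (
        "* C(condition)" if interaction else "+ C(condition)"
    )
    model = smf.ols(formula, data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2).reset_index(names="factor")
    table = table.rename(columns={"PR(>F)": "p", "F": "F"})
    return table[["factor", "df", "sum_sq", "F", "p"]]


def build_output_table(outputs: list[OutputEstimate], degrees=(2, 3)) -> pd.DataFrame:
    """Mean (SE) 24 h output per specimen x condition x scheme.

    Columns: observed mean/SE plus one mean/SE pair per interpolation
    degree in ``degrees``.  Ground-truth scheme rows have the degree
    columns empty (nothing is interpolated there).  SE = sd/sqrt(n) over
    subjects; for a single subject the SE is left empty.
    """
    frame = pd.DataFrame(
        {
            "specimen": [o.specimen for o in outputs],
            "condition": [o.condition for o in outputs],
            "scheme": [o.scheme for o in outputs],
            "source": [o.source for o in outputs],
            "degree": [o.degree for o in outputs],
            "auc": [o.auc for o in outputs],
        }
    )

    def mean_se(values: pd.Series) -> tuple[float, float]:
        n = len(values)
        mean = float(values.mean())
        se = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return mean, se

    rows = []
    scheme_order = {name: i for i, name in enumerate(
        ["Q60", "Q120", "Q180", "Q240", "Q360", "INT1", "INT2"])}
    keys = frame[["specimen", "condition", "scheme"]].drop_duplicates()
    keys = keys.sort_values(
        by=["specimen", "scheme", "condition"],
        key=lambda col: col.map(scheme_order) if col.name == "scheme" else col,
        ascending=[False, True, False],
    )
    for _, key in keys.iterrows():
        sel = frame[
            (frame["specimen"] == key["specimen"])
            & (frame["condition"] == key["condition"])
            & (frame["scheme"] == key["scheme"])
        ]
        obs = sel[sel["source"] == "observed"]["auc"]
        row = {
            "specimen": key["specimen"],
            "condition": key["condition"],
            "scheme": key["scheme"],
        }
        row["obs_mean"], row["obs_se"] = mean_se(obs) if len(obs) else (np.nan, np.nan)
        for deg in degrees:
            cell = sel[(sel["source"] == "interpolated") & (sel["degree"] == deg)]["auc"]
            if len(cell):
                row[f"deg{deg}_mean"], row[f"deg{deg}_se"] = mean_se(cell)
            else:
                row[f"deg{deg}_mean"] = row[f"deg{deg}_se"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
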