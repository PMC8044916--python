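"""Cohort selection, outcome dichotomization, and group-comparison tests.

The response label derives from the Miller-Payne pathological grade: grades
4 and 5 (more than 90% tumor cell loss, near-pCR/pCR) are responders,
grades 1-3 nonresponders.

Categorical group comparisons use the chi-square test — with Yates'
continuity correction on 2x2 tables — switching to Fisher's exact test when
any expected cell count is below five.  The 2xK exact test enumerates all
margin-consistent tables and sums the probabilities of those no more likely
than the observed one (the probability-mass two-sided rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .simulate import PatientRecord

__all__ = [
    "ExclusionReport",
    "filter_cohort",
    "dichotomize_mp",
    "chi2_yates_2x2",
    "pearson_chi2",
    "fisher_exact_2xk",
    "anova_oneway",
    "expected_counts",
    "test_chooser",
]

# exclusion reasons in the order they are applied; a record with several
# flags counts under the first applicable reason
EXCLUSION_ORDER = ("missing_imaging", "missing_mp", "missing_clinical")


@dataclass
class ExclusionReport:
    initial: int
    excluded: dict[str, int]
    retained: int

    def __post_init__(self):
        if self.retained != self.initial - sum(self.excluded.values()):
            raise ValueError("exclusion accounting does not balance")


def filter_cohort(
    records: Iterable[PatientRecord], order: Sequence[str] = EXCLUSION_ORDER
) -> tuple[list[PatientRecord], ExclusionReport]:
    """Apply the exclusion flags in the stated order; accounting balances."""
    records = list(records)
    counts = {reason: 0 for reason in order}
    retained = []
    for r in records:
        for reason in order:
            if getattr(r, reason):
                counts[reason] += 1
                break
        else:
            retained.append(r)
    report = ExclusionReport(initial=len(records), excluded=counts, retained=len(retained))
    return retained, report


def dichotomize_mp(records: Iterable[PatientRecord]) -> list[PatientRecord]:
    """Set ``responder`` from the Miller-Payne grade: responder <=> MP >= 4."""
    out = []
    for r in records:
        if r.mp_grade is None:
            raise ValueError(f"patient {r.patient_id} has no Miller-Payne grade")
        if not 1 <= r.mp_grade <= 5:
            raise ValueError(f"MP grade must be in 1..5, got {r.mp_grade}")
        r.responder = r.mp_grade >= 4
        out.append(r)
    return out


def _check_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2D")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.number):
        raise ValueError("table must hold nonnegative counts")
    if t.sum() <= 0:
        raise ValueError("empty table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    return t.astype(np.int64)


def expected_counts(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.float64)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def chi2_yates_2x2(table) -> tuple[float, float]:
    """Yates-corrected chi-square on a 2x2 table; returns (statistic, p)."""
    t = _check_table(table)
    if t.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables")
    stat, p, _, _ = stats.chi2_contingency(t, correction=True)
    return float(stat), float(p)


def pearson_chi2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square, df = (R-1)(C-1); returns (statistic, p)."""
    t = _check_table(table)
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def fisher_exact_2xk(table, max_tables: int = 5_000_000) -> float:
    """Two-sided Fisher exact p for a 2xK table by full enumeration.

    Enumerates every table with the observed margins; the p-value is the
    total hypergeometric probability of tables whose probability does not
    exceed the observed one (with a 1e-7 relative tolerance for ties).
    """
    t = _check_table(table)
    if t.shape[0] != 2:
        t = t.T
    if t.shape[0] != 2:
        raise ValueError("fisher_exact_2xk requires a 2xK table")
    col = t.sum(axis=0)
    r1 = int(t.sum(axis=1)[0])
    n = int(t.sum())
    k = len(col)

    # guard the enumeration size: prod of per-column ranges
    bound = np.prod([min(c, r1) + 1.0 for c in col])
    if bound > max_tables:
        raise ValueError(f"enumeration bound {bound:.3g} exceeds limit {max_tables}")

    from scipy.special import gammaln

    logfact = gammaln(np.arange(n + 2, dtype=np.float64) + 1.0)
    const = (
        logfact[r1]
        + logfact[n - r1]
        + logfact[col].sum()
        - logfact[n]
    )

    # enumerate first-row vectors summing to r1 within column bounds
    partial = np.zeros((1, 0), dtype=np.int64)
    sums = np.zeros(1, dtype=np.int64)
    for j in range(k):
        rest_max = int(col[j + 1 :].sum())
        new_parts = []
        for v in range(int(col[j]) + 1):
            ok = (sums + v <= r1) & (sums + v >= r1 - rest_max)
            if ok.any():
                block = np.column_stack(
                    [partial[ok], np.full(int(ok.sum()), v, dtype=np.int64)]
                )
                new_parts.append(block)
        partial = np.vstack(new_parts)
        sums = partial.sum(axis=1)
    tables = partial[sums == r1]

    logp = const - logfact[tables].sum(axis=1) - logfact[col[None, :] - tables].sum(axis=1)
    log_obs = (
        const - logfact[t[0]].sum() - logfact[col - t[0]].sum()
    )
    p = np.exp(logp)
    p_obs = np.exp(log_obs)
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-7)].sum()))


def anova_oneway(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F-test across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0.0:
        return 0.0, 1.0  # identical values everywhere: no effect by convention
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def test_chooser(table) -> str:
    """'fisher' when any expected count < 5, else 'chi2' (Yates on 2x2)."""
    t = _check_table(table)
    if (expected_counts(t) < 5.0).any():
        return "fisher"
    return "chi2_yates" if t.shape == (2, 2) else "chi2"


def _run_chosen_test(table) -> tuple[str, float]:
    choice = test_chooser(table)
    if choice == "fisher":
        return choice, fisher_exact_2xk(table)
    if choice == "chi2_yates":
        return choice, chi2_yates_2x2(table)[1]
    return choice, pearson_chi2(table)[1]


def arm_comparison(records_frame) -> "pd.DataFrame":
    """Development-vs-testing covariate comparison (patient-table style).

    Categorical rows use the chi-square/Fisher chooser; age uses one-way
    ANOVA.  Expects a DataFrame with columns arm, age, menopausal_status,
    family_history, mp_grade, molecular_subtype.
    """
    import pandas as pd

    df = records_frame
    rows = []
    dev = df[df["arm"] == "development"]
    test = df[df["arm"] == "testing"]

    f, p = anova_oneway(dev["age"].to_numpy(), test["age"].to_numpy())
    rows.append({"variable": "age", "test": "anova", "statistic": f, "p_value": p})

    for var, levels in (
        ("menopausal_status", ("pre", "post")),
        ("family_history", ("no", "yes")),
        ("mp_grade", (1, 2, 3, 4, 5)),
        ("molecular_subtype", None),
    ):
        if levels is None:
            levels = sorted(df[var].dropna().unique())
        table = np.array(
            [[int((arm_df[var] == lv).sum()) for lv in levels] for arm_df in (dev, test)]
        )
        table = table[:, table.sum(axis=0) > 0]
        name, p = _run_chosen_test(table)
        rows.append({"variable": var, "test": name, "statistic": np.nan, "p_value": p})
    return pd.DataFrame(rows)
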