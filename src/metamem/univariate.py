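"""Classical univariate statistics for the cohort design.

The central analysis is a split-plot (mixed) ANOVA on recognition scores
with Age (young, old) and Stimulus Type (words, names, nonwords) as
between-subjects factors and Test Type (item, associate) as a
within-subjects factor.  Between-subjects effects are tested against the
subjects-within-groups error stratum and within-subjects effects against
the test-type-by-subjects error stratum, each with its own partial eta
squared (SS_effect / (SS_effect + SS_error-of-stratum)).

Unequal cell sizes are handled by the classical unweighted-means solution
(effect sums of squares computed from unweighted cell means with the
harmonic mean of the cell sizes as the effective n); on balanced data
this coincides exactly with the textbook decomposition, and the SS of all
effects and errors then add up to the total SS.

Also provided: pooled-variance two-sample t tests (summary or raw form),
Cohen's d in the mean-of-SDs convention, the stimulus-type post-hoc
tests, and the Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

__all__ = [
    "TTestResult",
    "mixed_anova",
    "pooled_t_test",
    "pooled_t_test_raw",
    "cohens_d_avg_sd",
    "posthoc_stimulus_tests",
    "bonferroni",
]


def mixed_anova(
    scores,
    age,
    stimulus,
    within_labels: tuple[str, str] = ("item", "associate"),
) -> pd.DataFrame:
    """Split-plot ANOVA of an n x 2 within-subjects score matrix.

    ``scores`` has one row per subject and one column per test type;
    ``age`` and ``stimulus`` give each subject's between-group levels.
    Returns a table indexed by effect with columns SS, df, MS, F, p and
    partial_eta_squared; the two error strata appear as rows
    ``Error(between)`` and ``Error(within)``.
    """
    Y = np.asarray(scores, dtype=float)
    age = np.asarray(age)
    stimulus = np.asarray(stimulus)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("scores must be n x 2 (one column per test type)")
    n = Y.shape[0]
    if age.shape != (n,) or stimulus.shape != (n,):
        raise ValueError("age and stimulus must have one entry per subject")
    bad = np.flatnonzero(~np.isfinite(Y).all(axis=1))
    if bad.size:
        raise ValueError(f"subject(s) at row(s) {bad.tolist()} missing a within-subject score")

    a_levels = sorted(set(age.tolist()))
    s_levels = sorted(set(stimulus.tolist()))
    A, S, q = len(a_levels), len(s_levels), 2
    cells = [(a, s) for a in a_levels for s in s_levels]
    cell_rows = {(a, s): np.flatnonzero((age == a) & (stimulus == s)) for a, s in cells}
    empty = [c for c, rows in cell_rows.items() if rows.size == 0]
    if empty:
        raise ValueError(f"empty Age x Stimulus cell(s): {empty}")

    # unweighted cell x time means and the harmonic effective cell size
    C = np.array([[Y[cell_rows[c], t].mean() for t in range(q)] for c in cells])
    C = C.reshape(A, S, q)
    n_tilde = len(cells) / sum(1.0 / cell_rows[c].size for c in cells)

    cell_mean = C.mean(axis=2)                 # A x S
    a_mean = cell_mean.mean(axis=1)            # over stimulus
    s_mean = cell_mean.mean(axis=0)
    t_mean = C.mean(axis=(0, 1))               # per test type
    at_mean = C.mean(axis=1)                   # A x q
    st_mean = C.mean(axis=0)                   # S x q
    grand = cell_mean.mean()

    ss_age = q * n_tilde * S * float(((a_mean - grand) ** 2).sum())
    ss_stim = q * n_tilde * A * float(((s_mean - grand) ** 2).sum())
    ss_as = q * n_tilde * float(
        ((cell_mean - a_mean[:, None] - s_mean[None, :] + grand) ** 2).sum()
    )
    ss_t = n_tilde * A * S * float(((t_mean - grand) ** 2).sum())
    ss_ta = n_tilde * S * float(
        ((at_mean - a_mean[:, None] - t_mean[None, :] + grand) ** 2).sum()
    )
    ss_ts = n_tilde * A * float(
        ((st_mean - s_mean[:, None] - t_mean[None, :] + grand) ** 2).sum()
    )
    three_way = (
        C
        - cell_mean[:, :, None]
        - at_mean[:, None, :]
        - st_mean[None, :, :]
        + a_mean[:, None, None]
        + s_mean[None, :, None]
        + t_mean[None, None, :]
        - grand
    )
    ss_tas = n_tilde * float((three_way**2).sum())

    # error strata use the raw (weighted) data
    subj_mean = Y.mean(axis=1)
    ss_subj = 0.0
    ss_tsubj = 0.0
    for (a, s) in cells:
        rows = cell_rows[(a, s)]
        cm = subj_mean[rows].mean()
        ss_subj += q * float(((subj_mean[rows] - cm) ** 2).sum())
        cell_time = Y[rows].mean(axis=0)
        resid = Y[rows] - subj_mean[rows, None] - cell_time[None, :] + cm
        ss_tsubj += float((resid**2).sum())

    df_between_err = n - A * S
    df_within_err = (q - 1) * (n - A * S)

    # suppress pure floating-point residue (relative to the total SS) so a
    # constant dataset yields exact zeros rather than 0/0 artifacts
    total_ss = float(((Y - Y.mean()) ** 2).sum())
    eps = 1e-12 * max(1.0, total_ss)
    ss_age, ss_stim, ss_as, ss_t, ss_ta, ss_ts, ss_tas, ss_subj, ss_tsubj = (
        0.0 if ss < eps else ss
        for ss in (ss_age, ss_stim, ss_as, ss_t, ss_ta, ss_ts, ss_tas, ss_subj, ss_tsubj)
    )

    effects = [
        ("Age", ss_age, A - 1, ss_subj, df_between_err),
        ("Stimulus", ss_stim, S - 1, ss_subj, df_between_err),
        ("Age:Stimulus", ss_as, (A - 1) * (S - 1), ss_subj, df_between_err),
        ("TestType", ss_t, q - 1, ss_tsubj, df_within_err),
        ("TestType:Age", ss_ta, (q - 1) * (A - 1), ss_tsubj, df_within_err),
        ("TestType:Stimulus", ss_ts, (q - 1) * (S - 1), ss_tsubj, df_within_err),
        ("TestType:Age:Stimulus", ss_tas, (q - 1) * (A - 1) * (S - 1), ss_tsubj, df_within_err),
    ]

    rows = []
    for name, ss, df, ss_err, df_err in effects:
        ms = ss / df
        ms_err = ss_err / df_err
        F = ms / ms_err if ms_err > 0 else (np.inf if ss > 0 else 0.0)
        p = float(f_dist.sf(F, df, df_err)) if np.isfinite(F) else 0.0
        pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        rows.append((name, ss, df, ms, F, p, pes))
    rows.insert(
        3,
        (
            "Error(between)",
            ss_subj,
            df_between_err,
            ss_subj / df_between_err,
            np.nan,
            np.nan,
            np.nan,
        ),
    )
    rows.append(
        (
            "Error(within)",
            ss_tsubj,
            df_within_err,
            ss_tsubj / df_within_err,
            np.nan,
            np.nan,
            np.nan,
        )
    )
    table = pd.DataFrame(
        rows, columns=["effect", "SS", "df", "MS", "F", "p", "partial_eta_squared"]
    ).set_index("effect")
    table.attrs["within_labels"] = within_labels
    table.attrs["harmonic_cell_size"] = n_tilde
    return table


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sample t test with effect size."""

    t: float
    df: int
    p_two_tailed: float
    p_bonferroni: float
    cohens_d: float  # mean-of-SDs convention, signed with the mean difference
    mean_difference: float


def pooled_t_test(
    m1: float,
    sd1: float,
    n1: int,
    m2: float,
    sd2: float,
    n2: int,
    m_tests: int = 1,
) -> TTestResult:
    """Student's two-sample t from group summaries, pooled variance.

    ``m_tests`` applies a Bonferroni correction to the two-tailed p.
    Cohen's d uses the mean-of-SDs denominator (see
    :func:`cohens_d_avg_sd`) and keeps the sign of ``m1 - m2``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = float(2.0 * t_dist.sf(abs(t), df))
    d = (m1 - m2) / ((sd1 + sd2) / 2.0)
    return TTestResult(
        t=float(t),
        df=df,
        p_two_tailed=p,
        p_bonferroni=min(1.0, m_tests * p),
        cohens_d=float(d),
        mean_difference=float(m1 - m2),
    )


def pooled_t_test_raw(x1, x2, m_tests: int = 1) -> TTestResult:
    """Pooled t test from raw vectors; equals the summary form on their stats."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return pooled_t_test(
        float(x1.mean()),
        float(x1.std(ddof=1)),
        x1.size,
        float(x2.mean()),
        float(x2.std(ddof=1)),
        x2.size,
        m_tests=m_tests,
    )


def cohens_d_avg_sd(m1: float, sd1: float, m2: float, sd2: float) -> float:
    """Cohen's d with the mean of the two SDs as denominator.

    |m1 - m2| / ((sd1 + sd2) / 2).  This convention (rather than the
    pooled-SD form) matches the effect sizes the cohort's demographic
    comparisons report.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both SDs are zero; d is undefined")
    return abs(m1 - m2) / ((sd1 + sd2) / 2.0)


def posthoc_stimulus_tests(
    item_scores,
    assoc_scores,
    stimulus,
    conditions: tuple[str, ...] = ("words", "names", "nonwords"),
) -> dict[tuple[str, str], TTestResult]:
    """Pairwise pooled t tests between stimulus conditions.

    Each subject contributes two observations (the item and the associate
    recognition score), treated as independent in these contrasts: with
    condition group sizes (36, 36, 34) this yields the dfs 142/138/138 of
    the corresponding pooled observation counts.  Bonferroni correction
    uses m = 3.
    """
    item_scores = np.asarray(item_scores, dtype=float)
    assoc_scores = np.asarray(assoc_scores, dtype=float)
    stimulus = np.asarray(stimulus)
    pooled = {}
    for cond in conditions:
        rows = stimulus == cond
        if not rows.any():
            raise ValueError(f"no subjects in condition {cond!r}")
        pooled[cond] = np.concatenate([item_scores[rows], assoc_scores[rows]])
    return {
        (c1, c2): pooled_t_test_raw(pooled[c1], pooled[c2], m_tests=3)
        for c1, c2 in combinations(conditions, 2)
    }


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p values: min(1, m * p).

    ``m`` defaults to the number of p values and must be at least that.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, m * p)
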