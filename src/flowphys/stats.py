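"""Baseline correction, cohort outlier screening and paired condition tests.

Baseline correction expresses every per-minute variable as a percent change
from its resting-baseline value,

    x_BC = (x - x_BL) / x_BL * 100,

with both eyes-open and eyes-closed baselines for EEG and the eyes-closed
baseline only for the autonomic and motion variables (eyes-closed rest is
the most relaxed reference state).

Condition contrasts are one-sample t-tests on within-subject condition
differences (equivalently paired t-tests): one phase-level value per subject
per condition, differenced, screened for outliers with Bonferroni-corrected
externally studentized residuals (an automated stand-in for QQ-plot
inspection), and tested against zero at alpha = 0.05 with a 95% CI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats


class BaselineError(ValueError):
    """Baseline value is zero: the percent change is undefined."""


def baseline_correct(x, x_bl):
    """Percent change of ``x`` relative to baseline ``x_bl`` (Eq.-1 style)."""
    x_bl_arr = np.asarray(x_bl, dtype=float)
    if np.any(x_bl_arr == 0):
        raise BaselineError("baseline value is zero; percent change undefined")
    result = (np.asarray(x, dtype=float) - x_bl_arr) / x_bl_arr * 100.0
    return float(result) if np.isscalar(x) or np.ndim(x) == 0 else result


def remove_outliers(
    values: np.ndarray, alpha: float = 0.05, max_iter: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Flag outliers by Bonferroni-tested externally studentized values.

    Each value is studentized against the mean and SD of the remaining
    values (leave-one-out), compared with the two-sided t threshold at
    level ``alpha`` Bonferroni-corrected for the sample size, and removal is
    iterated at most ``max_iter`` times.  This automates QQ-plot screening
    of a location model.  Returns (kept values, flags over the original
    vector).  With fewer than 3 values nothing is removed.
    """
    values = np.asarray(values, dtype=float)
    flags = np.zeros(len(values), dtype=bool)
    if len(values) < 3:
        warnings.warn("fewer than 3 values: outlier screening skipped")
        return values.copy(), flags
    for _ in range(max_iter):
        keep_idx = np.flatnonzero(~flags)
        n = len(keep_idx)
        if n < 3:
            break
        x = values[keep_idx]
        t_stats = np.empty(n)
        for i in range(n):
            rest = np.delete(x, i)
            s = rest.std(ddof=1)
            if s == 0:
                t_stats[i] = np.inf if x[i] != rest.mean() else 0.0
            else:
                t_stats[i] = (x[i] - rest.mean()) / (s * math.sqrt(1 + 1.0 / (n - 1)))
        threshold = sstats.t.ppf(1 - alpha / (2 * n), df=n - 2)
        new = np.abs(t_stats) > threshold
        if not new.any():
            break
        flags[keep_idx[new]] = True
    return values[~flags], flags


@dataclass
class TestResult:
    """One condition-pair comparison row (t, df, 95% CI, estimate, p)."""

    label: str
    t: float
    df: int
    ci_low: float
    ci_high: float
    estimate: float
    p: float
    n: int
    n_outliers: int = 0
    degenerate: bool = False

    def as_row(self) -> dict:
        return {
            "comparison": self.label,
            "t": self.t,
            "df": self.df,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "estimate": self.estimate,
            "p": self.p,
            "n": self.n,
            "n_outliers": self.n_outliers,
        }


def one_sample_t(
    values: np.ndarray, label: str = "", alpha: float = 0.05, n_outliers: int = 0
) -> TestResult:
    """Two-sided one-sample t-test of the mean against zero with 95% CI."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError(f"{label or 'comparison'}: need at least 2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    df = n - 1
    if sd == 0:
        # zero-variance sentinel: infinite t unless the mean is exactly zero
        t_stat = 0.0 if mean == 0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0 else 0.0
        return TestResult(label, t_stat, df, mean, mean, mean, p, n,
                          n_outliers, degenerate=True)
    se = sd / math.sqrt(n)
    t_stat = mean / se
    p = 2 * float(sstats.t.sf(abs(t_stat), df))
    crit = float(sstats.t.ppf(1 - (1 - 0.95) / 2, df))
    return TestResult(
        label, t_stat, df, mean - crit * se, mean + crit * se, mean, p, n,
        n_outliers,
    )


def paired_difference_test(
    a_values: np.ndarray,
    b_values: np.ndarray,
    label: str = "",
    alpha: float = 0.05,
    screen_outliers: bool = True,
) -> tuple[TestResult, np.ndarray]:
    """Paired test: outlier-screen the within-subject differences, then t-test.

    Returns the result and the outlier flags over the input pair order.
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"{label}: paired vectors differ in length")
    if len(a) < 3:
        raise ValueError(f"{label}: need at least 3 complete pairs, got {len(a)}")
    diffs = a - b
    if screen_outliers:
        kept, flags = remove_outliers(diffs, alpha=alpha)
    else:
        kept, flags = diffs, np.zeros(len(diffs), dtype=bool)
    result = one_sample_t(kept, label=label, alpha=alpha,
                          n_outliers=int(flags.sum()))
    return result, flags


def paired_condition_test(
    test_values: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    variable: str,
    channel: str = "",
    band: str = "",
    baseline: str = "closed",
    alpha: float = 0.05,
    label: str | None = None,
) -> tuple[TestResult, pd.DataFrame]:
    """Condition contrast on a cohort test-value table.

    ``test_values`` is long-format with columns subject, condition,
    variable, channel, band, baseline, value.  Subjects must have both
    conditions present (pairwise-complete).  Returns the test result and a
    frame of flagged outlier subjects.
    """
    sel = test_values[
        (test_values["variable"] == variable)
        & (test_values["channel"] == channel)
        & (test_values["band"] == band)
        & (test_values["baseline"] == baseline)
    ]
    a = sel[sel["condition"] == cond_a].set_index("subject")["value"]
    b = sel[sel["condition"] == cond_b].set_index("subject")["value"]
    subjects = sorted(set(a.index) & set(b.index))
    if len(subjects) < 3:
        raise ValueError(
            f"{cond_a} vs {cond_b} ({variable}{' ' + channel if channel else ''}"
            f"{' ' + band if band else ''}): only {len(subjects)} complete pairs"
        )
    if label is None:
        label = f"{cond_a.capitalize()}-{cond_b}"
        extra = ", ".join(x for x in (channel, band) if x)
        if extra:
            label = f"{label}, {extra}"
    result, flags = paired_difference_test(
        a.loc[subjects].to_numpy(), b.loc[subjects].to_numpy(),
        label=label, alpha=alpha,
    )
    outliers = pd.DataFrame(
        {
            "comparison": label,
            "subject": [s for s, f in zip(subjects, flags) if f],
            "reason": "studentized difference beyond Bonferroni threshold",
        }
    )
    return result, outliers


def aggregate_curves(
    corrected: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-subject mean curves with per-cell outlier screening.

    ``corrected`` is long-format (subject, condition, variable, channel,
    band, baseline, minute, value) of baseline-corrected percent changes,
    with excluded-incomplete rows already absent.  Outlier subjects are
    screened per (condition, variable, channel, band, baseline) cell on
    their phase-mean value and removed from that cell's curve only.

    Returns (curves, outlier log); curves carry per-minute mean/SD/n and a
    whole-phase summary row (minute = 0) giving the mean and SD of the
    subject phase means.
    """
    keys = ["condition", "variable", "channel", "band", "baseline"]
    curve_rows = []
    outlier_rows = []
    for cell, grp in corrected.groupby(keys, sort=True):
        phase_means = grp.groupby("subject")["value"].mean()
        if len(phase_means) >= 3:
            _, flags = remove_outliers(phase_means.to_numpy(), alpha=alpha)
        else:
            flags = np.zeros(len(phase_means), dtype=bool)
        bad_subjects = set(phase_means.index[flags])
        for s in sorted(bad_subjects):
            outlier_rows.append(
                dict(zip(keys, cell), subject=s,
                     reason="phase-mean outlier (studentized, Bonferroni)")
            )
        kept = grp[~grp["subject"].isin(bad_subjects)]
        by_minute = kept.groupby("minute")["value"]
        for minute, vals in by_minute:
            curve_rows.append(
                dict(
                    zip(keys, cell),
                    minute=int(minute),
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    n=int(len(vals)),
                )
            )
        kept_means = phase_means[~flags]
        curve_rows.append(
            dict(
                zip(keys, cell),
                minute=0,  # whole-phase summary
                mean=float(kept_means.mean()),
                sd=float(kept_means.std(ddof=1)) if len(kept_means) > 1 else 0.0,
                n=int(len(kept_means)),
            )
        )
    return pd.DataFrame(curve_rows), pd.DataFrame(
        outlier_rows, columns=keys + ["subject", "reason"]
    )


def emit_results_table(
    results: list[TestResult], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full and significant (p < alpha) results tables.

    Columns: comparison, t, df, ci_low, ci_high, estimate, p (plus n and
    the outlier count for audit).
    """
    cols = ["comparison", "t", "df", "ci_low", "ci_high", "estimate", "p",
            "n", "n_outliers"]
    full = pd.DataFrame([r.as_row() for r in results], columns=cols)
    significant = full[full["p"] < alpha].reset_index(drop=True)
    return full, significant


# ---------------------------------------------------------------------------
# Type-I-error calibration on null-preset synthetic autonomic data
# ---------------------------------------------------------------------------

def simulate_null_rejection_rate(
    n_comparisons: int = 2000,
    n_subjects: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Empirical rejection rate of the paired test on null-preset cohorts.

    Generates HR series for the eyes-closed baseline and the three (here
    identically distributed) conditions per subject, runs the full
    per-minute / baseline-correction / paired-test chain for the HR mean and
    HR SD variables, and pools the three condition pairs.  Under the null
    the rate should sit near ``alpha``.
    """
    from .autonomic import minute_stats
    from .synth import PhaseEffect, generate_hr_spo2

    rng = np.random.default_rng(seed)
    eff = PhaseEffect()
    pairs = [("boredom", "flow"), ("flow", "frustration"), ("boredom", "frustration")]
    rejections = 0
    done = 0
    while done < n_comparisons:
        values: dict[str, dict[str, np.ndarray]] = {}
        for phase, dur in (
            ("baseline_closed", 60),
            ("boredom", 480),
            ("flow", 480),
            ("frustration", 480),
        ):
            means = np.empty(n_subjects)
            sds = np.empty(n_subjects)
            for s in range(n_subjects):
                hr, _ = generate_hr_spo2(
                    dur, eff.hr_mean, eff.hr_sd, rng=rng, rate=1.0
                )
                m, sd = minute_stats(hr, rate=1.0)
                means[s] = m.mean()
                sds[s] = sd.mean()
            values[phase] = {"hr_mean": means, "hr_sd": sds}
        bl = values["baseline_closed"]
        for a_cond, b_cond in pairs:
            for var in ("hr_mean", "hr_sd"):
                a = baseline_correct(values[a_cond][var], bl[var])
                b = baseline_correct(values[b_cond][var], bl[var])
                result, _ = paired_difference_test(a, b, label=f"{a_cond}-{b_cond}")
                if result.p < alpha:
                    rejections += 1
                done += 1
                if done >= n_comparisons:
                    break
            if done >= n_comparisons:
                break
    return rejections / n_comparisons
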