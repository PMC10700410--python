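"""Split-half and test-retest reliability of the fitted gains.

Within a session, each subject's valid trials are split into two disjoint
halves — by trial parity (odd/even) or by position in the session
(first/second half) — and the Pearson correlation across subjects between
the half means of log K_p (or log K_d) is the split-half reliability.
Fisher's z transformation compares the split-half correlations of the two
sessions.  Across sessions, test-retest reliability is ICC(3,1): the
intraclass correlation from a two-way mixed model, consistency form,
single fixed rater (the two sessions are the raters), with a p-value from
the between-subjects F test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitScheme",
    "split_half_means",
    "split_half_correlation",
    "fisher_z_compare",
    "icc3",
    "reliability_report",
]

PARAMETERS = ("log_k_p", "log_k_d")


class SplitScheme(str, Enum):
    """Rule assigning a subject's valid trials to two half-session bins.

    ``ODD_EVEN`` splits on the parity of the nominal trial index (odd
    trials form half 1).  ``FIRST_SECOND`` splits on rank within the
    session's valid trials; with an odd count the middle trial goes to the
    first half.
    """

    ODD_EVEN = "odd_even"
    FIRST_SECOND = "first_second"

    def assign(self, trial_indices: np.ndarray) -> np.ndarray:
        """Map trial indices to half labels (1 or 2), one per trial."""
        trial_indices = np.asarray(trial_indices)
        if len(np.unique(trial_indices)) != len(trial_indices):
            raise ValueError("trial indices must be unique within a session")
        if self is SplitScheme.ODD_EVEN:
            return np.where(trial_indices % 2 == 1, 1, 2)
        order = np.argsort(trial_indices, kind="stable")
        halves = np.empty(len(trial_indices), dtype=int)
        n_first = math.ceil(len(trial_indices) / 2)
        halves[order[:n_first]] = 1
        halves[order[n_first:]] = 2
        return halves


def split_half_means(fits: pd.DataFrame, scheme: SplitScheme) -> pd.DataFrame:
    """Per-subject-session half means of the log gains.

    ``fits`` is the parameter table (one row per trial fit); only valid
    trials enter.  Returns one row per subject x session with columns
    ``<param>_half1`` / ``<param>_half2``; subjects lacking trials in
    either half carry NaN there.
    """
    valid = fits[fits["valid"]].copy()
    if valid.empty:
        raise ValueError("no valid trials to split")

    rows = []
    for (subject, session), grp in valid.groupby(["subject_id", "session"], sort=True):
        halves = scheme.assign(grp["trial"].to_numpy())
        row: dict = {"subject_id": subject, "session": session}
        for param in PARAMETERS:
            values = grp[param].to_numpy()
            for half in (1, 2):
                sel = values[halves == half]
                row[f"{param}_half{half}"] = float(sel.mean()) if len(sel) else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def split_half_correlation(
    half1: np.ndarray, half2: np.ndarray
) -> tuple[float, int, float]:
    """Pearson correlation across subjects of the two half estimates.

    Pairs with a missing half are dropped.  Returns ``(r, n, p)`` with a
    two-sided p.  Requires at least 4 complete pairs and nonzero variance
    in both halves.
    """
    half1 = np.asarray(half1, dtype=float)
    half2 = np.asarray(half2, dtype=float)
    keep = np.isfinite(half1) & np.isfinite(half2)
    half1, half2 = half1[keep], half2[keep]
    n = len(half1)
    if n < 4:
        raise ValueError(f"split-half correlation needs >= 4 subjects, got {n}")
    if np.std(half1) == 0 or np.std(half2) == 0:
        raise ValueError("zero variance in one half across subjects")
    result = stats.pearsonr(half1, half2)
    return float(result.statistic), n, float(result.pvalue)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via Fisher's z transformation.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p.  Degenerate correlations (|r| >= 1, infinite
    transform) are reported as such.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher z comparison needs n > 3 in both samples")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| = 1 has an infinite Fisher transform; comparison undefined")
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (math.atanh(r1) - math.atanh(r2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, float(p)


def icc3(session1: np.ndarray, session2: np.ndarray) -> tuple[float, float]:
    """ICC(3,1): two-way mixed model, consistency, single fixed rater.

    With subjects as rows and the k = 2 sessions as fixed raters,

        ICC = (MS_subjects - MS_error) / (MS_subjects + (k-1) * MS_error)

    from the two-way ANOVA decomposition; the p-value is from the
    between-subjects F test ``MS_subjects / MS_error`` on
    ``(n-1, (n-1)(k-1))`` degrees of freedom.  Consistency form: a constant
    session offset does not reduce the ICC.
    """
    x = np.column_stack([np.asarray(session1, float), np.asarray(session2, float)])
    if not np.all(np.isfinite(x)):
        raise ValueError("icc3 requires complete pairs (no missing values)")
    n, k = x.shape
    if n < 5:
        raise ValueError(f"icc3 needs >= 5 paired subjects, got {n}")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise ValueError("zero between-subject variance; ICC undefined")

    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols

    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_err = max(ss_err / df_err, 0.0)

    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    if ms_err == 0.0:
        return icc, 0.0
    f = ms_rows / ms_err
    p = float(stats.f.sf(f, df_rows, df_err))
    return icc, p


def reliability_report(
    fits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    *,
    exclude_same_day: bool = False,
    exclude_non_mobile: bool = False,
    schemes: tuple[SplitScheme, ...] = (SplitScheme.ODD_EVEN, SplitScheme.FIRST_SECOND),
) -> pd.DataFrame:
    """Full reliability table from a per-trial parameter table.

    Emits one row per statistic:

    * ``split_half`` — per session x scheme x parameter: Pearson r, n, p;
    * ``fisher_z`` — per scheme x parameter: z and p comparing the two
      sessions' split-half correlations (only when both sessions present);
    * ``icc3`` — per parameter: ICC(3,1) across sessions on subject mean
      log gains, over subjects with both sessions non-missing.

    ``exclude_same_day`` / ``exclude_non_mobile`` drop subjects flagged in
    the covariate table (columns ``same_day_sessions`` / ``device_mobile``),
    mirroring the sensitivity analyses; ``n`` columns record the subject
    counts actually used.
    """
    fits = fits.copy()
    if exclude_same_day or exclude_non_mobile:
        if covariates is None:
            raise ValueError("exclusion flags require a covariate table")
        cov = covariates.set_index("subject_id")
        keep = pd.Series(True, index=cov.index)
        if exclude_same_day:
            keep &= cov["same_day_sessions"] == 0
        if exclude_non_mobile:
            keep &= cov["device_mobile"] == 1
        fits = fits[fits["subject_id"].isin(keep[keep].index)]

    rows: list[dict] = []
    sessions = sorted(fits.loc[fits["valid"], "session"].unique())

    split_r: dict[tuple[str, str, int], tuple[float, int]] = {}
    for scheme in schemes:
        halves = split_half_means(fits, scheme)
        for session in sessions:
            sess = halves[halves["session"] == session]
            for param in PARAMETERS:
                r, n, p = split_half_correlation(
                    sess[f"{param}_half1"], sess[f"{param}_half2"]
                )
                split_r[(scheme.value, param, session)] = (r, n)
                rows.append(
                    {
                        "statistic": "split_half",
                        "scheme": scheme.value,
                        "parameter": param,
                        "session": session,
                        "value": r,
                        "n": n,
                        "p": p,
                    }
                )

    if set(sessions) >= {1, 2}:
        for scheme in schemes:
            for param in PARAMETERS:
                r1, n1 = split_r[(scheme.value, param, 1)]
                r2, n2 = split_r[(scheme.value, param, 2)]
                z, p = fisher_z_compare(r1, n1, r2, n2)
                rows.append(
                    {
                        "statistic": "fisher_z",
                        "scheme": scheme.value,
                        "parameter": param,
                        "session": math.nan,
                        "value": z,
                        "n": min(n1, n2),
                        "p": p,
                    }
                )

        valid = fits[fits["valid"]]
        means = (
            valid.groupby(["subject_id", "session"])[list(PARAMETERS)]
            .mean()
            .unstack("session")
        )
        for param in PARAMETERS:
            wide = means[param].dropna()
            if len(wide) >= 5:
                icc, p = icc3(wide[1].to_numpy(), wide[2].to_numpy())
                rows.append(
                    {
                        "statistic": "icc3",
                        "scheme": "",
                        "parameter": param,
                        "session": math.nan,
                        "value": icc,
                        "n": len(wide),
                        "p": p,
                    }
                )

    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`reliability_report` output."""
    lines = ["Reliability report", "=" * 60]
    for _, row in report.iterrows():
        if row["statistic"] == "split_half":
            lines.append(
                f"split-half  {row['scheme']:<13} {row['parameter']:<8} "
                f"session {int(row['session'])}: r = {row['value']:+.3f} "
                f"(n = {int(row['n'])}, p = {row['p']:.2g})"
            )
        elif row["statistic"] == "fisher_z":
            lines.append(
                f"Fisher z    {row['scheme']:<13} {row['parameter']:<8} "
                f"s1 vs s2 : z = {row['value']:+.3f} (p = {row['p']:.2g})"
            )
        else:
            lines.append(
                f"ICC(3,1)    {'':<13} {row['parameter']:<8} "
                f"sessions : ICC = {row['value']:+.3f} "
                f"(n = {int(row['n'])}, p = {row['p']:.2g})"
            )
    return "\n".join(lines) + "\n"
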