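"""Test-retest reliability statistics for paired instrument administrations.

Implements the three coefficients used to assess temporal stability of a
screening instrument:

* Cronbach's alpha over the k items of one administration,
  ``alpha = k/(k-1) * (1 - sum_i var_i / var_total)`` with n-1 sample
  variances — internal consistency.
* Single-measures intraclass correlation from the two-way
  subjects x administrations ANOVA decomposition, in both the consistency
  form ICC(C,1) (column effects ignored) and the absolute-agreement form
  ICC(A,1) (column effects penalized) of the McGraw-Wong taxonomy.
* Lin's concordance correlation coefficient
  ``ccc = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with n-denominator
  moments, measuring agreement around the identity line, with a 95% CI from
  the Fisher z-transform using Lin's (1989) variance estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classification import classify_record
from .model import ParticipantRecord, Source
from .scoring import score_triplet

__all__ = [
    "UndefinedStatisticError",
    "cronbach_alpha",
    "icc_single",
    "lin_ccc",
    "ReliabilityReport",
    "reliability_report",
]


class UndefinedStatisticError(ValueError):
    """Raised when a coefficient's denominator degenerates (zero variance)."""


def _as_matrix(values, min_rows: int, min_cols: int) -> np.ndarray:
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"expected a 2-D ratings matrix, got shape {m.shape}")
    if not np.isfinite(m).all():
        raise ValueError("ratings matrix contains non-finite entries")
    n, k = m.shape
    if n < min_rows or k < min_cols:
        raise ValueError(f"need at least {min_rows}x{min_cols} ratings, got {n}x{k}")
    return m


def cronbach_alpha(matrix) -> float:
    """Internal-consistency alpha for an n_subjects x k_items matrix."""
    m = _as_matrix(matrix, min_rows=2, min_cols=2)
    k = m.shape[1]
    item_vars = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedStatisticError("total-score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def icc_single(matrix, form: str = "consistency") -> float:
    """Two-way single-measures ICC for an n x k matrix (k administrations).

    ``form="consistency"`` gives ICC(C,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E);
    ``form="agreement"`` gives ICC(A,1), whose denominator adds the
    between-administration term (k/n)(MS_C - MS_E).
    """
    if form not in ("consistency", "agreement"):
        raise ValueError(f"form must be 'consistency' or 'agreement', got {form!r}")
    m = _as_matrix(matrix, min_rows=3, min_cols=2)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r == 0 and ms_e == 0:
        raise UndefinedStatisticError("degenerate ANOVA decomposition; ICC undefined")
    if form == "consistency":
        denom = ms_r + (k - 1) * ms_e
    else:
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        raise UndefinedStatisticError("zero ICC denominator")
    return (ms_r - ms_e) / denom


def lin_ccc(x, y, ci_level: float = 0.95) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    Moments use the n denominator.  Returns ``(ccc, ci_low, ci_high)``.  For a
    perfect (anti-)concordance the z-variance degenerates and the interval
    collapses onto the point estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if not 0 < ci_level < 1:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    mx, my = x.mean(), y.mean()
    sx2 = x.var()  # n denominator
    sy2 = y.var()
    sxy = ((x - mx) * (y - my)).mean()
    if sx2 == 0 and sy2 == 0:
        raise UndefinedStatisticError("both vectors are constant; CCC undefined")
    ccc = 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)

    if abs(ccc) >= 1.0 or sx2 == 0 or sy2 == 0:
        return float(ccc), float(ccc), float(ccc)

    r = sxy / np.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25  # location shift in pooled-scale units
    v = np.sqrt(sx2 / sy2)
    c_b = 2 / (v + 1 / v + u**2)  # bias correction; ccc = r * c_b
    z = np.arctanh(ccc)
    # Lin (1989) variance of the z-transformed estimate, written via c_b so
    # the r -> 0 limit (var_z = c_b^2 / (n-2)) is handled without 0/0.
    var_z = (
        (1 - r**2) * c_b**2 / (1 - ccc**2)
        + 2 * r**2 * c_b**3 * (1 - ccc) * u**2 / (1 - ccc**2) ** 2
        - r**2 * c_b**4 * u**4 / (2 * (1 - ccc**2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    half = stats.norm.ppf(0.5 + ci_level / 2) * np.sqrt(var_z)
    return float(ccc), float(np.tanh(z - half)), float(np.tanh(z + half))


@dataclass(frozen=True)
class ReliabilityReport:
    """Coefficients for one paired test-retest study.

    ICC and CCC are reported over paired total spectrum scores and, because
    the published protocol does not pin down which score they apply to, also
    over the paired report-sum (R1+SR+R2) scores.
    """

    alpha_r1: float
    alpha_r2: float
    icc_consistency: float
    icc_agreement: float
    ccc: float
    ccc_ci_low: float
    ccc_ci_high: float
    icc_consistency_reports: float
    icc_agreement_reports: float
    ccc_reports: float
    n: int

    def to_dict(self) -> dict:
        return {
            "alpha_r1": self.alpha_r1,
            "alpha_r2": self.alpha_r2,
            "icc_consistency": self.icc_consistency,
            "icc_agreement": self.icc_agreement,
            "ccc": self.ccc,
            "ccc_ci_low": self.ccc_ci_low,
            "ccc_ci_high": self.ccc_ci_high,
            "icc_consistency_reports": self.icc_consistency_reports,
            "icc_agreement_reports": self.icc_agreement_reports,
            "ccc_reports": self.ccc_reports,
            "n": self.n,
        }


def _triplet_item_matrix(cohort: list[ParticipantRecord], source: Source) -> np.ndarray:
    """Subjects x 3-questions score matrix for one triplet; DK scores as 0."""
    rows = []
    for record in cohort:
        triplet = record.triplet(source)
        rows.append([r.score if r.score != "DK" else 0 for r in triplet.responses])
    return np.asarray(rows, dtype=float)


def reliability_report(
    test_cohort: list[ParticipantRecord],
    retest_cohort: list[ParticipantRecord],
    ci_level: float = 0.95,
) -> ReliabilityReport:
    """Full reliability block for matched test/retest cohorts.

    Alpha is computed per administration over the three questions (items =
    questions, subjects = participants): R1 from the test cohort, R2 from the
    retest cohort.  ICC and CCC are computed over paired spectrum totals (and
    report sums), pairing participants by id.
    """
    test_by_id = {r.participant_id: r for r in test_cohort}
    retest_by_id = {r.participant_id: r for r in retest_cohort}
    orphans = sorted(set(test_by_id) ^ set(retest_by_id))
    if orphans:
        raise ValueError(f"unmatched participant ids across stages: {', '.join(orphans)}")
    ids = sorted(test_by_id)
    if len(ids) < 3:
        raise ValueError(f"need at least 3 matched participants, got {len(ids)}")

    def totals(by_id, id_list):
        return np.array([classify_record(by_id[i]).total for i in id_list], dtype=float)

    def report_sums(by_id, id_list):
        out = []
        for i in id_list:
            rec = by_id[i]
            out.append(
                sum(score_triplet(rec.triplet(s)).raw_sum for s in Source)
            )
        return np.asarray(out, dtype=float)

    t_tot, r_tot = totals(test_by_id, ids), totals(retest_by_id, ids)
    t_rep, r_rep = report_sums(test_by_id, ids), report_sums(retest_by_id, ids)
    paired_tot = np.column_stack([t_tot, r_tot])
    paired_rep = np.column_stack([t_rep, r_rep])

    ccc, lo, hi = lin_ccc(t_tot, r_tot, ci_level=ci_level)
    ccc_rep, _, _ = lin_ccc(t_rep, r_rep, ci_level=ci_level)
    return ReliabilityReport(
        alpha_r1=cronbach_alpha(_triplet_item_matrix(test_cohort, Source.R1)),
        alpha_r2=cronbach_alpha(_triplet_item_matrix(retest_cohort, Source.R2)),
        icc_consistency=icc_single(paired_tot, "consistency"),
        icc_agreement=icc_single(paired_tot, "agreement"),
        ccc=ccc,
        ccc_ci_low=lo,
        ccc_ci_high=hi,
        icc_consistency_reports=icc_single(paired_rep, "consistency"),
        icc_agreement_reports=icc_single(paired_rep, "agreement"),
        ccc_reports=ccc_rep,
        n=len(ids),
    )
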