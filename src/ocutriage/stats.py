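"""Diagnostic-accuracy and agreement statistics for the triage evaluation.

The study design is paired: every patient receives an automated triage
disposition and an optometrist triage outcome, and two masked specialist
reviewers (plus a third casting vote on disagreement) supply the
gold-standard urgent/non-urgent label.  Dispositions are dichotomized at
the 24-hour boundary — urgent iff the urgency band is same-day emergency
or within-24-hours — and each triage arm's sensitivity and specificity is
computed against the adjudicated gold standard.  Paired arm differences
use the continuity-corrected McNemar test on the discordant counts;
inter-rater agreement uses Cohen's kappa with a large-sample confidence
interval and a fixed a-priori interpretation band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .acuity import AcuityLevel
from .errors import EvaluationError, UndefinedMetricError

__all__ = [
    "is_urgent_24h", "adjudicate", "GoldStandardRecord",
    "ConfusionCounts", "confusion", "sensitivity", "specificity",
    "McNemarResult", "mcnemar_cc", "KappaResult", "cohens_kappa",
    "kappa_band", "mann_whitney_u", "odds_ratio", "summarize_cohort",
    "evaluate_records", "render_metrics",
]


def is_urgent_24h(urgency: AcuityLevel | str) -> bool:
    """Dichotomize an urgency band at the 24-hour boundary.

    Urgent means hospital or community specialist assessment within 24
    hours, i.e. the two most acute ordinal bands.
    """
    if isinstance(urgency, str):
        urgency = AcuityLevel[urgency]
    return urgency.is_urgent_24h


@dataclass(frozen=True)
class GoldStandardRecord:
    """Two masked reviewer labels plus the adjudicated truth."""

    reviewer1: bool
    reviewer2: bool
    tiebreak: Optional[bool]
    adjudicated: bool


def adjudicate(
    reviewer1: bool, reviewer2: bool, tiebreak: Optional[bool] = None
) -> GoldStandardRecord:
    """Resolve two reviewer labels into the gold-standard label.

    Agreement stands as-is; disagreement is settled by a mandatory third
    clinician's casting vote.  A tiebreak supplied on agreement, or missing
    on disagreement, is an error.
    """
    if reviewer1 == reviewer2:
        if tiebreak is not None:
            raise EvaluationError(
                "spurious tiebreak: reviewers agree, no casting vote applies"
            )
        return GoldStandardRecord(reviewer1, reviewer2, None, reviewer1)
    if tiebreak is None:
        raise EvaluationError(
            "reviewers disagree and no tiebreak label was supplied"
        )
    return GoldStandardRecord(reviewer1, reviewer2, tiebreak, tiebreak)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    predicted: Sequence[bool], gold: Sequence[bool]
) -> ConfusionCounts:
    """2x2 counts of a predicted urgent/non-urgent vector against gold."""
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(gold, dtype=bool)
    if pred.shape != true.shape:
        raise EvaluationError(
            f"length mismatch: {pred.shape[0]} predictions vs "
            f"{true.shape[0]} gold labels"
        )
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
        tn=int(np.sum(~pred & ~true)),
    )


def sensitivity(counts: ConfusionCounts) -> float:
    """Percent of gold-urgent cases labeled urgent (unrounded)."""
    pos = counts.tp + counts.fn
    if pos == 0:
        raise UndefinedMetricError("sensitivity undefined: no gold-urgent cases")
    return 100.0 * counts.tp / pos


def specificity(counts: ConfusionCounts) -> float:
    """Percent of gold-non-urgent cases labeled non-urgent (unrounded)."""
    neg = counts.tn + counts.fp
    if neg == 0:
        raise UndefinedMetricError(
            "specificity undefined: no gold-non-urgent cases"
        )
    return 100.0 * counts.tn / neg


@dataclass(frozen=True)
class McNemarResult:
    b: int
    c: int
    statistic: float
    p_value: float


def mcnemar_cc(b: int, c: int) -> McNemarResult:
    """Continuity-corrected McNemar test on discordant pair counts.

    statistic = (|b - c| - 1)^2 / (b + c), referred to chi-square with one
    degree of freedom.  With no discordant pairs the test carries no
    information: statistic 0, p = 1 by convention.
    """
    if b < 0 or c < 0:
        raise EvaluationError("discordant counts must be non-negative")
    if b + c == 0:
        return McNemarResult(b=b, c=c, statistic=0.0, p_value=1.0)
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    p_value = float(sps.chi2.sf(statistic, df=1))
    return McNemarResult(b=b, c=c, statistic=statistic, p_value=p_value)


KAPPA_BANDS = (
    (0.00, "no agreement"),
    (0.20, "none to slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    """A-priori interpretation band for a kappa value.

    Cut-points: <=0 no agreement; 0.01-0.20 none to slight; 0.21-0.40
    fair; 0.41-0.60 moderate; 0.61-0.80 substantial; 0.81-1.00 almost
    perfect.
    """
    for upper, label in KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            return label
    return "almost perfect"


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    band: str
    p_observed: float
    p_expected: float
    n: int


def cohens_kappa(
    labels_a: Sequence[bool], labels_b: Sequence[bool]
) -> KappaResult:
    """Cohen's kappa for two raters with a large-sample 95% CI.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    raters' marginals.  The confidence interval uses the asymptotic
    variance of the kappa estimate (Fleiss-Cohen-Everitt form), truncated
    to [-1, 1].  Undefined (raises) when both raters are constant and
    identical, since p_e = 1.
    """
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape:
        raise EvaluationError("label vectors differ in length")
    n = a.shape[0]
    if n < 2:
        raise EvaluationError("need at least 2 paired labels")

    # 2x2 proportion table: index 0 = non-urgent, 1 = urgent
    p = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            p[i, j] = np.sum((a == bool(i)) & (b == bool(j))) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        raise EvaluationError(
            "kappa undefined: both raters constant and identical (p_e = 1)"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss-Cohen-Everitt large-sample variance
    term_a = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2
        for i in (0, 1)
    )
    term_b = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in (0, 1) for j in (0, 1) if i != j
    )
    term_c = (kappa - p_e * (1.0 - kappa)) ** 2
    var = max((term_a + term_b - term_c) / (n * (1.0 - p_e) ** 2), 0.0)
    half = 1.959963984540054 * np.sqrt(var)
    return KappaResult(
        kappa=float(kappa),
        ci_low=float(max(kappa - half, -1.0)),
        ci_high=float(min(kappa + half, 1.0)),
        band=kappa_band(float(kappa)),
        p_observed=p_o,
        p_expected=p_e,
        n=int(n),
    )


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for group_a, p-value).

    Ties count one half toward U.  The exact null distribution is used for
    small untied samples (both n <= 20); otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EvaluationError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def odds_ratio(
    a: float, b: float, c: float, d: float
) -> tuple[float, tuple[float, float]]:
    """Odds ratio (a*d)/(b*c) with a Woolf logit 95% CI.

    Zero cells are handled by the Haldane-Anscombe correction (0.5 added
    to every cell).
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise EvaluationError("cell counts must be non-negative")
    if any(x == 0 for x in cells):
        cells = [x + 0.5 for x in cells]
    a_, b_, c_, d_ = cells
    est = (a_ * d_) / (b_ * c_)
    log_se = float(np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_))
    half = 1.959963984540054 * log_se
    lo = float(np.exp(np.log(est) - half))
    hi = float(np.exp(np.log(est) + half))
    return float(est), (lo, hi)


AGE_BANDS = (
    ("<20", 0, 19), ("20-29", 20, 29), ("30-39", 30, 39),
    ("40-49", 40, 49), ("50-59", 50, 59), ("60-69", 60, 69),
    ("70-79", 70, 79), (">79", 80, 200),
)


def summarize_cohort(cohort: pd.DataFrame) -> dict:
    """Descriptive summary of a record-level cohort table.

    Expects (a subset of) columns ``age``, ``duration_s``, ``category``
    and ``likert`` (NaN = no voluntary feedback).  Returns mean/SD/range
    for age and duration, complaint-category and age-band frequency
    tables, and the Likert response rate, top-2 proportion and mean/SD.
    """
    if len(cohort) == 0:
        raise EvaluationError("empty cohort")
    out: dict = {"n": int(len(cohort))}
    if "age" in cohort:
        ages = cohort["age"].astype(float)
        out["age"] = {
            "mean": float(ages.mean()),
            "sd": float(ages.std(ddof=1)) if len(ages) > 1 else 0.0,
            "min": float(ages.min()), "max": float(ages.max()),
        }
        out["age_bands"] = {
            label: int(((ages >= lo) & (ages <= hi)).sum())
            for label, lo, hi in AGE_BANDS
        }
    if "duration_s" in cohort:
        dur = cohort["duration_s"].astype(float)
        out["duration_s"] = {
            "mean": float(dur.mean()),
            "sd": float(dur.std(ddof=1)) if len(dur) > 1 else 0.0,
            "min": float(dur.min()), "max": float(dur.max()),
        }
    if "category" in cohort:
        out["categories"] = {
            str(k): int(v)
            for k, v in cohort["category"].value_counts().items()
        }
    if "likert" in cohort:
        likert = pd.to_numeric(cohort["likert"], errors="coerce").dropna()
        n_resp = int(len(likert))
        top2 = int((likert >= 4).sum())
        out["feedback"] = {
            "respondents": n_resp,
            "response_rate": n_resp / len(cohort),
            "top2": top2,
            "top2_proportion": (top2 / n_resp) if n_resp else float("nan"),
            "mean": float(likert.mean()) if n_resp else float("nan"),
            "sd": float(likert.std(ddof=1)) if n_resp > 1 else float("nan"),
        }
    return out


def _paired_mcnemar(
    arm_a: np.ndarray, arm_b: np.ndarray, stratum: np.ndarray
) -> McNemarResult:
    """McNemar on correctness disagreement within a gold stratum."""
    b = int(np.sum(arm_a[stratum] & ~arm_b[stratum]))
    c = int(np.sum(~arm_a[stratum] & arm_b[stratum]))
    return mcnemar_cc(b, c)


def evaluate_records(records: pd.DataFrame) -> dict:
    """Run the full paired accuracy analysis on a record-level table.

    Required columns: ``tool_urgent``, ``opt_urgent``, ``reviewer1_urgent``,
    ``reviewer2_urgent`` and (where the reviewers disagree)
    ``tiebreak_urgent``.  The adjudicated gold standard is derived once and
    reused for both arms.  Returns confusion counts, sensitivity and
    specificity per arm with the paired McNemar comparisons, and the
    four inter-rater kappa pairings.
    """
    required = {"tool_urgent", "opt_urgent", "reviewer1_urgent",
                "reviewer2_urgent"}
    missing = required - set(records.columns)
    if missing:
        raise EvaluationError(f"records table missing column(s): {sorted(missing)}")

    tool = records["tool_urgent"].astype(bool).to_numpy()
    opt = records["opt_urgent"].astype(bool).to_numpy()
    r1 = records["reviewer1_urgent"].astype(bool).to_numpy()
    r2 = records["reviewer2_urgent"].astype(bool).to_numpy()
    ties = records.get("tiebreak_urgent")

    gold = np.empty(len(records), dtype=bool)
    for i in range(len(records)):
        tb = None
        if ties is not None and not pd.isna(ties.iloc[i]):
            tb = bool(ties.iloc[i])
        if r1[i] == r2[i]:
            tb = None  # spurious tiebreaks are ignored at table level
        gold[i] = adjudicate(bool(r1[i]), bool(r2[i]), tb).adjudicated

    result: dict = {"n": int(len(records)),
                    "gold_urgent": int(gold.sum())}
    arms = {}
    for name, pred in (("tool", tool), ("optometry", opt)):
        counts = confusion(pred, gold)
        arms[name] = {
            "counts": counts,
            "urgent_n": int(pred.sum()),
            "tp": counts.tp, "fp": counts.fp,
            "fn": counts.fn, "tn": counts.tn,
            "sensitivity": sensitivity(counts),
            "specificity": specificity(counts),
        }
    result["arms"] = arms

    tool_correct = tool == gold
    opt_correct = opt == gold
    result["mcnemar"] = {
        "sensitivity": _paired_mcnemar(tool_correct, opt_correct, gold),
        "specificity": _paired_mcnemar(tool_correct, opt_correct, ~gold),
    }
    result["kappa"] = {
        "optometrist_vs_tool": cohens_kappa(opt, tool),
        "reviewer1_vs_tool": cohens_kappa(r1, tool),
        "reviewer2_vs_tool": cohens_kappa(r2, tool),
        "reviewer1_vs_reviewer2": cohens_kappa(r1, r2),
    }
    return result


def render_metrics(result: dict) -> str:
    """Plain-text tables mirroring the accuracy and agreement layout."""
    lines = [
        f"Records analyzed: {result['n']} "
        f"(gold-standard urgent: {result['gold_urgent']})",
        "",
        "Accuracy at identifying urgent (within 24 h) cases",
        f"{'Arm':<12}{'Urgent n':>9}{'Sens %':>8}{'Spec %':>8}",
    ]
    for name, arm in result["arms"].items():
        lines.append(
            f"{name:<12}{arm['urgent_n']:>9}"
            f"{arm['sensitivity']:>8.1f}{arm['specificity']:>8.1f}"
        )
    mc = result["mcnemar"]
    lines += [
        "",
        f"Paired comparison (McNemar, continuity-corrected):",
        f"  sensitivity: chi2={mc['sensitivity'].statistic:.3f} "
        f"P={mc['sensitivity'].p_value:.3g}",
        f"  specificity: chi2={mc['specificity'].statistic:.3f} "
        f"P={mc['specificity'].p_value:.3g}",
        "",
        "Inter-rater reliability (Cohen kappa, 95% CI)",
    ]
    for pair, kr in result["kappa"].items():
        lines.append(
            f"  {pair.replace('_', ' '):<28}"
            f"{kr.kappa:.2f} ({kr.ci_low:.2f}-{kr.ci_high:.2f})  {kr.band}"
        )
    return "\n".join(lines) + "\n"
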