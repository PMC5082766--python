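"""Inclusion/exclusion rules, derived measures and the edit-agreement check.

Implements the study-style preprocessing of a raw cohort table: BMI
classification into weight groups, ordered exclusion rules (age, underweight,
image quality), hemisphere aggregation, Box-Cox normalization, and a
Bland-Altman agreement analysis for paired pre-/post-edit measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special, stats

from .cohort import Cohort
from .exceptions import DomainError, InputError, MissingDataError, PipelineError

#: Weight-group boundaries, kg/m^2, half-open intervals [lo, hi).
BMI_EDGES = {"underweight": (0.0, 18.5), "lean": (18.5, 25.0),
             "overweight": (25.0, 30.0), "obese": (30.0, np.inf)}

OVERWEIGHT_OBESE = ("overweight", "obese")


def classify_bmi(bmi):
    """Classify BMI into underweight / lean / overweight / obese.

    Boundaries are half-open: [18.5, 25) lean, [25, 30) overweight,
    [30, inf) obese, (0, 18.5) underweight. Accepts a scalar or an array
    and returns a matching string or object array.
    """
    arr = np.asarray(bmi, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("bmi must be finite and positive")
    cats = np.select(
        [arr < 18.5, arr < 25.0, arr < 30.0],
        ["underweight", "lean", "overweight"],
        default="obese",
    )
    if np.isscalar(bmi) or np.ndim(bmi) == 0:
        return str(cats if cats.ndim == 0 else cats.item())
    return cats.astype(object)


@dataclass
class ExclusionReport:
    """Counts and identities of excluded subjects, one reason per subject.

    Rules are applied in a fixed order (age, underweight, qc) and each subject
    is counted once, under the first rule it triggers.
    """

    n_input: int
    n_excluded_age: int
    n_excluded_underweight: int
    n_excluded_qc: int
    n_retained: int
    excluded_ids: list = field(default_factory=list)  # (subject_id, reason)

    def __post_init__(self):
        total = (self.n_excluded_age + self.n_excluded_underweight +
                 self.n_excluded_qc + self.n_retained)
        if total != self.n_input:
            raise InputError("exclusion counts do not reconcile with n_input")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"n_input": self.n_input,
             "n_excluded_age": self.n_excluded_age,
             "n_excluded_underweight": self.n_excluded_underweight,
             "n_excluded_qc": self.n_excluded_qc,
             "n_retained": self.n_retained,
             "excluded_ids": [list(x) for x in self.excluded_ids]},
            indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def apply_exclusions(cohort: Cohort, min_age: float = 20.0,
                     min_bmi: float = 18.5,
                     drop_qc: tuple = ("poor",)) -> tuple[Cohort, ExclusionReport]:
    """Apply the ordered exclusion rules and return the retained cohort.

    Order of precedence: age below ``min_age``, then BMI below ``min_bmi``
    (underweight), then QC rating in ``drop_qc``. The operation is idempotent.
    """
    df = cohort.df
    if len(df) == 0:
        raise InputError("cohort is empty")
    reason = np.full(len(df), "", dtype=object)
    age_mask = (df["age"].to_numpy() < min_age) & (reason == "")
    reason[age_mask] = "age"
    bmi_mask = (df["bmi"].to_numpy() < min_bmi) & (reason == "")
    reason[bmi_mask] = "underweight"
    qc_mask = df["qc"].isin(drop_qc).to_numpy() & (reason == "")
    reason[qc_mask] = "qc"

    keep = reason == ""
    if not keep.any():
        raise PipelineError("all subjects excluded; downstream fits impossible")
    excluded = [(sid, r) for sid, r in zip(df["subject_id"], reason) if r]
    report = ExclusionReport(
        n_input=len(df),
        n_excluded_age=int(age_mask.sum()),
        n_excluded_underweight=int(bmi_mask.sum()),
        n_excluded_qc=int(qc_mask.sum()),
        n_retained=int(keep.sum()),
        excluded_ids=excluded,
    )
    retained = cohort.replace(df.loc[keep], exclusions={
        "min_age": min_age, "min_bmi": min_bmi, "drop_qc": list(drop_qc)})
    return retained, report


def aggregate_hemispheres(left, right, kind: str, subject_id=None):
    """Combine left/right hemisphere measures into one per-subject value.

    Volumes and surface areas are summed; thickness is averaged.
    """
    for side, val in (("left", left), ("right", right)):
        if val is None or (np.isscalar(val) and not np.isfinite(val)):
            who = f" for subject {subject_id}" if subject_id is not None else ""
            raise MissingDataError(f"missing {side} hemisphere value{who}")
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(~np.isfinite(left)) or np.any(~np.isfinite(right)):
        who = f" for subject {subject_id}" if subject_id is not None else ""
        raise MissingDataError(f"missing hemisphere value{who}")
    if np.any(left <= 0) or np.any(right <= 0):
        raise DomainError("hemisphere measures must be positive")
    if kind in ("volume_sum", "area_sum"):
        out = left + right
    elif kind == "thickness_mean":
        out = (left + right) / 2.0
    else:
        raise InputError(f"unknown aggregation kind: {kind!r}")
    return float(out) if out.ndim == 0 else out


def boxcox(values, lam="mle"):
    """Box-Cox transform: (x^k - 1)/k for k != 0, log x for k = 0.

    With ``lam="mle"`` the exponent maximizes the profile log-likelihood
    under a normal model. Returns ``(transformed, lambda_used)``.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.where(~(arr > 0) | ~np.isfinite(arr))[0]
    if bad.size:
        raise DomainError(f"Box-Cox requires positive values; offending "
                          f"indices: {bad.tolist()[:10]}")
    if isinstance(lam, str):
        if lam != "mle":
            raise InputError(f"lambda must be a number or 'mle', got {lam!r}")
        transformed, lam_used = stats.boxcox(arr)
        return transformed, float(lam_used)
    lam = float(lam)
    return special.boxcox(arr, lam), lam


@dataclass
class AgreementResult:
    """Bland-Altman agreement between paired measurements.

    ``mean_difference`` is the bias (post minus pre); the limits of agreement
    are mean +/- 1.96 SD of the paired differences; the F statistic and
    p-value test a zero mean paired difference (F = t^2 of the paired t-test).
    """

    mean_difference: float
    limits_of_agreement: tuple
    f_statistic: float
    p_value: float

    def __post_init__(self):
        lo, hi = self.limits_of_agreement
        if not (lo <= self.mean_difference <= hi):
            raise InputError("limits of agreement must bracket the mean difference")


def bland_altman(pre_values, post_values) -> AgreementResult:
    """Bland-Altman analysis of paired pre-/post-edit measurements."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise InputError("pre and post must be 1-D vectors of equal length")
    if pre.size < 3:
        raise InputError("need at least 3 pairs")
    if np.any(~np.isfinite(pre)) or np.any(~np.isfinite(post)):
        raise InputError("non-finite values in paired vectors")
    d = post - pre
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    limits = (md - 1.96 * sd, md + 1.96 * sd)
    n = d.size
    if sd == 0.0:
        f_stat, p = (0.0, 1.0) if md == 0.0 else (np.inf, 0.0)
    else:
        t = md / (sd / np.sqrt(n))
        f_stat = float(t ** 2)
        p = float(stats.f.sf(f_stat, 1, n - 1))
    return AgreementResult(mean_difference=md, limits_of_agreement=limits,
                           f_statistic=f_stat, p_value=p)
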