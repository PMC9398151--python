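"""Patient-level aggregation and cohort statistics.

A patient counts as ctDNA positive when at least one sample is
positive.  Association of positivity with risk group uses a two-sided
Fisher exact test computed by full hypergeometric enumeration with the
minimum-likelihood convention (sum over tables whose point probability
does not exceed the observed table's) -- the convention of mainstream
statistical software, and the one under which the high-risk association
is significant; the doubling convention would not be.  Group
comparisons of Ki-67 and total cfDNA use equal-variance Student t tests
on log10 values, with out-of-range (non-detected) measurements replaced
by half the lowest detected value; tumor size is compared untransformed.
Imaging concordance assumes complete response should be ctDNA negative
and progressive, partial-response and stable disease ctDNA positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import SampleResult

RISK_GROUPS = ("very_low_low", "intermediate", "high")
IMAGING_CODES = ("CR", "PR", "SD", "PD")
EXPECTED_POSITIVE_IMAGING = frozenset({"PD", "PR", "SD"})
EXPECTED_NEGATIVE_IMAGING = frozenset({"CR"})


@dataclass
class PatientRecord:
    patient_id: str
    risk_group: str
    ki67_percent: float
    tumor_size_cm: float
    metastatic: bool = False
    samples: list[SampleResult] = field(default_factory=list)
    imaging_status: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.risk_group not in RISK_GROUPS:
            raise ValueError(f"unknown risk group {self.risk_group!r}")
        if not (0 <= self.ki67_percent <= 100):
            raise ValueError("Ki-67 must lie in [0, 100] percent")
        if self.tumor_size_cm <= 0:
            raise ValueError("tumor size must be positive")


def patient_positivity(record: PatientRecord) -> bool:
    """True iff the patient has at least one ctDNA-positive sample.

    ``negative_low_input`` is a negative subclass and never counts.
    """
    if not record.samples:
        raise ValueError("patient has no samples")
    return any(s.classification == "positive" for s in record.samples)


# ---------------------------------------------------------------------------
# Fisher exact test (full enumeration, minimum-likelihood two-sided)


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact P by hypergeometric enumeration.

    Enumerates every table with the observed margins and sums the point
    probabilities of those no more probable than the observed table
    (minimum-likelihood convention).  Returns 1.0 when a margin is
    empty, where no association is testable.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        return 1.0
    # integer table weights w(x) = C(row1, x) * C(row2, col1 - x); the point
    # probability is w(x) / C(n, col1), so ties compare exactly in integers
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    w_obs = math.comb(row1, a) * math.comb(row2, col1 - a)
    acc = sum(
        w
        for x in range(lo, hi + 1)
        if (w := math.comb(row1, x) * math.comb(row2, col1 - x)) <= w_obs
    )
    return acc / math.comb(n, col1)


def fisher_one_sided_2x2(table: ContingencyTable2x2) -> float:
    """One-sided (greater) hypergeometric tail for the top-left cell."""
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        return 1.0
    return float(stats.hypergeom(n, col1, row1).sf(a - 1))


# ---------------------------------------------------------------------------
# t tests


def _replace_oor(values: Sequence[float], replacement: float) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return np.where(np.isnan(arr), replacement, arr)


def log_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    oor_rule: bool = True,
) -> tuple[float, float]:
    """Equal-variance Student t test on log10 values.

    Non-detected measurements are encoded as NaN; with ``oor_rule`` they
    are replaced by half the lowest detected value across both groups
    before the log transform (the out-of-range convention).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if oor_rule:
        detected = np.concatenate([a[~np.isnan(a)], b[~np.isnan(b)]])
        if detected.size == 0:
            raise ValueError("all values non-detected: no minimum to halve")
        repl = float(detected.min()) / 2.0
        a = _replace_oor(a, repl)
        b = _replace_oor(b, repl)
    elif np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("non-detected values present but oor_rule disabled")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("log transform requires positive values")
    t, p = stats.ttest_ind(np.log10(a), np.log10(b), equal_var=True)
    return float(t), float(p)


def plain_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Equal-variance Student t test on raw values."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# imaging concordance


def imaging_concordance(
    pairs: Iterable[tuple[str, str]],
) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) in percent of ctDNA versus imaging.

    Expected-positive imaging states are PD, PR and SD; expected
    negative is CR.  An undefined denominator yields ``None`` rather
    than 0.
    """
    tp = fn = tn = fp = 0
    for imaging, classification in pairs:
        if imaging not in IMAGING_CODES:
            raise ValueError(f"unknown imaging code {imaging!r}")
        ct_positive = classification == "positive"
        if imaging in EXPECTED_POSITIVE_IMAGING:
            tp += ct_positive
            fn += not ct_positive
        else:
            tn += not ct_positive
            fp += ct_positive
    sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) else None
    specificity = 100.0 * tn / (tn + fp) if (tn + fp) else None
    return sensitivity, specificity


# ---------------------------------------------------------------------------
# cohort aggregation


def cohort_table(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tidy per-sample table over the cohort (one row per sample)."""
    rows = []
    for r in records:
        for s in r.samples:
            tumor = next((c for c in s.calls if c.variant.label == "tumor_specific"), None)
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "risk_group": r.risk_group,
                    "sample_id": s.sample_id,
                    "timepoint": s.timepoint,
                    "classification": s.classification,
                    "molecule_count": s.molecule_count,
                    "tumor_maf_percent": tumor.maf if tumor is not None else float("nan"),
                    "tumor_status": tumor.status if tumor is not None else "",
                    "qc_flags": ";".join(sorted(s.qc_flags)),
                }
            )
    return pd.DataFrame(rows)


def risk_association(records: Sequence[PatientRecord]) -> tuple[ContingencyTable2x2, float]:
    """High-risk versus other groups, patient positive at any time: 2x2 and two-sided P."""
    a = b = c = d = 0
    for r in records:
        pos = patient_positivity(r)
        if r.risk_group == "high":
            a += pos
            b += not pos
        else:
            c += pos
            d += not pos
    table = ContingencyTable2x2(a, b, c, d)
    return table, fisher_exact_2x2(table)


def cohort_summary(records: Sequence[PatientRecord]) -> dict:
    """The cohort-level statistics battery as one JSON-serializable dict."""
    table, p_risk = risk_association(records)
    pos = [r for r in records if patient_positivity(r)]
    neg = [r for r in records if not patient_positivity(r)]
    out: dict = {
        "n_patients": len(records),
        "n_patients_positive": len(pos),
        "risk_table": {"high_pos": table.a, "high_neg": table.b, "other_pos": table.c, "other_neg": table.d},
        "fisher_two_sided_p": p_risk,
        "fisher_one_sided_p": fisher_one_sided_2x2(table),
    }
    if len(pos) >= 2 and len(neg) >= 2:
        t, p = log_ttest([r.ki67_percent for r in pos], [r.ki67_percent for r in neg], oor_rule=False)
        out["ki67_log_ttest"] = {"t": t, "p": p}
        t, p = plain_ttest([r.tumor_size_cm for r in pos], [r.tumor_size_cm for r in neg])
        out["tumor_size_ttest"] = {"t": t, "p": p}
    pairs = []
    for r in records:
        for imaging, s in zip(r.imaging_status, r.samples):
            pairs.append((imaging, s.classification))
    if pairs:
        sens, spec = imaging_concordance(pairs)
        out["imaging_sensitivity_percent"] = sens
        out["imaging_specificity_percent"] = spec
    return out
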