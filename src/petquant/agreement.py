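"""Inter-reader agreement statistics for paired quantitative biomarkers.

Two readers (Reading A and Reading B) each produce MTV, TLG and Dmax per
patient.  Agreement between the paired readings is summarised by:

* descriptives per reading (median, IQR, mean, SD, range),
* Spearman's rank correlation with a 95% Fisher-z confidence interval,
* Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 x SD of the
  paired differences),
* a median-split dichotomization (below/above a shared cutoff, the median
  of the pooled 2n values), the resulting 2x2 contingency table, the raw
  percentage agreement and Cohen's chance-corrected kappa.

Conventions pinned for reproducibility: quantiles use linear interpolation
between order statistics (numpy's default, the "type 7" rule); all SDs use
the n-1 denominator; a value equal to the cutoff classifies as "above".
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

METRIC_FIELDS = {"MTV": "mtv_cm3", "TLG": "tlg", "Dmax": "dmax_cm"}


@dataclass
class PairedMetricVector:
    """Aligned per-patient values of one metric for Readings A and B."""

    metric_name: str
    values_a: np.ndarray
    values_b: np.ndarray
    patient_ids: list[str]

    def __post_init__(self):
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.ndim != 1 or self.values_a.shape != self.values_b.shape:
            raise ValueError("values_a and values_b must be 1D and equal length")
        if len(self.values_a) < 2:
            raise ValueError("need at least 2 paired observations")
        if len(self.patient_ids) != len(self.values_a):
            raise ValueError("patient_ids must align with the value vectors")

    @property
    def n(self) -> int:
        return len(self.values_a)

    def swapped(self) -> "PairedMetricVector":
        """The same pairing with Readings A and B exchanged."""
        return PairedMetricVector(self.metric_name, self.values_b.copy(),
                                  self.values_a.copy(), list(self.patient_ids))


@dataclass
class ContingencyTable2x2:
    """Below/above-median cross-classification of the two readings.

    Cell names read (Reading A class, Reading B class).
    """

    a_below_b_below: int
    a_below_b_above: int
    a_above_b_below: int
    a_above_b_above: int

    def __post_init__(self):
        cells = (self.a_below_b_below, self.a_below_b_above,
                 self.a_above_b_below, self.a_above_b_above)
        if any(c < 0 for c in cells):
            raise ValueError("cell counts must be nonnegative")
        if sum(cells) == 0:
            raise ValueError("contingency table must have positive total")

    @property
    def n(self) -> int:
        return (self.a_below_b_below + self.a_below_b_above
                + self.a_above_b_below + self.a_above_b_above)

    def transposed(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a_below_b_below, self.a_above_b_below,
                                   self.a_below_b_above, self.a_above_b_above)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a_below_b_below, self.a_below_b_above],
                         [self.a_above_b_below, self.a_above_b_above]])


class Descriptives(NamedTuple):
    median: float
    iqr: float
    mean: float
    sd: float
    min: float
    max: float


def descriptives(values) -> Descriptives:
    """Median, IQR (Q3 - Q1, linear-interpolation quantiles), mean, SD
    (n-1 denominator) and range of a sample."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("values must be a nonempty 1D sequence")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    return Descriptives(median=float(med), iqr=float(q3 - q1),
                        mean=float(x.mean()), sd=sd,
                        min=float(x.min()), max=float(x.max()))


def spearman_with_ci(pair: PairedMetricVector,
                     confidence: float = 0.95) -> tuple[float, float, float, float]:
    """Spearman's rho with a Fisher-z confidence interval and t-test p-value.

    rho is the Pearson correlation of the average-ranked values (ties get
    average ranks).  The CI transforms rho with z = artanh(rho), uses
    standard error 1/sqrt(n - 3), and back-transforms.  The two-sided
    p-value uses the t approximation with n - 2 degrees of freedom.

    Returns ``(rho, ci_low, ci_high, p_value)``.  Requires n >= 4 and
    non-constant vectors.
    """
    a, b = pair.values_a, pair.values_b
    n = pair.n
    if n < 4:
        raise ValueError(f"need n >= 4 for Spearman correlation with CI, got {n}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError(
            f"rank correlation undefined for constant input ({pair.metric_name})"
        )
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    rho = float(np.corrcoef(ra, rb)[0, 1])
    zcrit = float(stats.norm.ppf(0.5 + confidence / 2))
    se = 1.0 / np.sqrt(n - 3)
    with np.errstate(divide="ignore"):
        z = np.arctanh(rho)
    ci_low = float(np.tanh(z - zcrit * se))
    ci_high = float(np.tanh(z + zcrit * se))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, ci_low, ci_high, p


def bland_altman(pair: PairedMetricVector) -> tuple[float, float]:
    """Bias and limits-of-agreement half-width for paired readings.

    Differences are Reading A - Reading B; bias is their mean and the
    half-width is 1.96 x SD of the differences (n-1 denominator).  The
    limits of agreement are ``bias +/- halfwidth``.
    """
    d = pair.values_a - pair.values_b
    bias = float(d.mean())
    halfwidth = 1.96 * float(d.std(ddof=1))
    return bias, halfwidth


def dichotomize_by_median(pair: PairedMetricVector, pooled: bool = True):
    """Split both readings at the median and cross-classify the patients.

    With ``pooled=True`` (default) a single cutoff is used: the median of
    the pooled 2n values of both readings.  With ``pooled=False`` each
    reading is split at its own median and a (cutoff_a, cutoff_b) tuple is
    returned instead of a scalar.  A value is "below" iff value < cutoff;
    values equal to the cutoff classify as "above".

    Returns ``(cutoff, ContingencyTable2x2)``.
    """
    a, b = pair.values_a, pair.values_b
    if pooled:
        cutoff = float(np.median(np.concatenate([a, b])))
        below_a, below_b = a < cutoff, b < cutoff
        cut = cutoff
    else:
        ca, cb = float(np.median(a)), float(np.median(b))
        below_a, below_b = a < ca, b < cb
        cut = (ca, cb)
    table = ContingencyTable2x2(
        a_below_b_below=int(np.sum(below_a & below_b)),
        a_below_b_above=int(np.sum(below_a & ~below_b)),
        a_above_b_below=int(np.sum(~below_a & below_b)),
        a_above_b_above=int(np.sum(~below_a & ~below_b)),
    )
    return cut, table


def percent_agreement(table: ContingencyTable2x2) -> float:
    """Raw percentage of patients classified identically by both readings."""
    return 100.0 * (table.a_below_b_below + table.a_above_b_above) / table.n


def cohen_kappa(table: ContingencyTable2x2) -> float:
    """Cohen's chance-corrected agreement, kappa = (P0 - Pe) / (1 - Pe).

    P0 is the observed agreement fraction; Pe sums, over the two classes,
    the products of the row and column marginal fractions.  A degenerate
    table with Pe = 1 yields kappa = 1 when agreement is also perfect and
    raises otherwise.
    """
    n = table.n
    p0 = (table.a_below_b_below + table.a_above_b_above) / n
    row_below = table.a_below_b_below + table.a_below_b_above
    row_above = table.a_above_b_below + table.a_above_b_above
    col_below = table.a_below_b_below + table.a_above_b_below
    col_above = table.a_below_b_above + table.a_above_b_above
    pe = (row_below * col_below + row_above * col_above) / (n * n)
    if pe >= 1.0:
        if p0 == 1.0:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 but observed "
                         "agreement is not")
    return float((p0 - pe) / (1.0 - pe))


@dataclass
class AgreementReport:
    """All agreement statistics for one metric and filter variant."""

    metric: str
    filter_label: str
    n: int
    median_a: float
    iqr_a: float
    median_b: float
    iqr_b: float
    pooled_median_cutoff: float
    spearman_rho: float
    rho_ci_low: float
    rho_ci_high: float
    p_value: float
    bias: float
    loa_halfwidth: float
    contingency: ContingencyTable2x2
    percent_agreement: float
    kappa: float

    def to_dict(self) -> dict:
        """Full-precision JSON-ready mapping, plus display rounding
        (rho and kappa to 2 dp, percentages to 1 dp)."""
        return {
            "metric": self.metric,
            "filter_label": self.filter_label,
            "n": self.n,
            "median_a": self.median_a,
            "iqr_a": self.iqr_a,
            "median_b": self.median_b,
            "iqr_b": self.iqr_b,
            "pooled_median_cutoff": self.pooled_median_cutoff,
            "spearman_rho": self.spearman_rho,
            "rho_ci_low": self.rho_ci_low,
            "rho_ci_high": self.rho_ci_high,
            "p_value": self.p_value,
            "bias": self.bias,
            "loa_halfwidth": self.loa_halfwidth,
            "contingency": {
                "a_below_b_below": self.contingency.a_below_b_below,
                "a_below_b_above": self.contingency.a_below_b_above,
                "a_above_b_below": self.contingency.a_above_b_below,
                "a_above_b_above": self.contingency.a_above_b_above,
            },
            "percent_agreement": self.percent_agreement,
            "kappa": self.kappa,
            "display": {
                "spearman_rho": round(self.spearman_rho, 2),
                "rho_ci": [round(self.rho_ci_low, 2), round(self.rho_ci_high, 2)],
                "percent_agreement": round(self.percent_agreement, 1),
                "kappa": round(self.kappa, 2),
            },
        }


def analyze_pair(pair: PairedMetricVector, filter_label: str = "all",
                 pooled_cutoff: bool = True) -> AgreementReport:
    """Run the full agreement battery on one paired metric vector."""
    desc_a = descriptives(pair.values_a)
    desc_b = descriptives(pair.values_b)
    rho, lo, hi, p = spearman_with_ci(pair)
    bias, halfwidth = bland_altman(pair)
    cutoff, table = dichotomize_by_median(pair, pooled=pooled_cutoff)
    return AgreementReport(
        metric=pair.metric_name,
        filter_label=filter_label,
        n=pair.n,
        median_a=desc_a.median, iqr_a=desc_a.iqr,
        median_b=desc_b.median, iqr_b=desc_b.iqr,
        pooled_median_cutoff=cutoff if np.isscalar(cutoff) else float("nan"),
        spearman_rho=rho, rho_ci_low=lo, rho_ci_high=hi, p_value=p,
        bias=bias, loa_halfwidth=halfwidth,
        contingency=table,
        percent_agreement=percent_agreement(table),
        kappa=cohen_kappa(table),
    )


def paired_vectors(records, filter_label: str = "all",
                   reader_a: str | None = None,
                   reader_b: str | None = None) -> dict[str, PairedMetricVector]:
    """Assemble per-metric paired vectors from patient metric records.

    Every patient must have exactly one record per reader for the requested
    filter variant.  Reader identities default to the two distinct
    ``reader_id`` values in sorted order (A = first).
    """
    subset = [r for r in records if r.filter_label == filter_label]
    if not subset:
        raise ValueError(f"no records with filter_label={filter_label!r}")
    readers = sorted({r.reader_id for r in subset})
    if reader_a is None or reader_b is None:
        if len(readers) != 2:
            raise ValueError(f"expected exactly 2 readers, found {readers}")
        reader_a, reader_b = readers

    by_patient: dict[str, dict[str, object]] = defaultdict(dict)
    for r in subset:
        if r.reader_id in by_patient[r.patient_id]:
            raise ValueError(f"duplicate record for patient {r.patient_id!r}, "
                             f"reader {r.reader_id!r}")
        by_patient[r.patient_id][r.reader_id] = r
    unpaired = sorted(pid for pid, d in by_patient.items()
                      if reader_a not in d or reader_b not in d)
    if unpaired:
        raise ValueError(f"patients without both readings: {unpaired}")

    pids = sorted(by_patient)
    out = {}
    for metric, attr in METRIC_FIELDS.items():
        out[metric] = PairedMetricVector(
            metric_name=metric,
            values_a=[getattr(by_patient[p][reader_a], attr) for p in pids],
            values_b=[getattr(by_patient[p][reader_b], attr) for p in pids],
            patient_ids=pids,
        )
    return out


def run_agreement_study(records, filter_label: str = "all",
                        reader_a: str | None = None,
                        reader_b: str | None = None,
                        pooled_cutoff: bool = True) -> dict[str, AgreementReport]:
    """Full agreement analysis for MTV, TLG and Dmax on one filter variant.

    Returns a mapping ``{"MTV": report, "TLG": report, "Dmax": report}``.
    """
    pairs = paired_vectors(records, filter_label=filter_label,
                           reader_a=reader_a, reader_b=reader_b)
    return {metric: analyze_pair(pair, filter_label=filter_label,
                                 pooled_cutoff=pooled_cutoff)
            for metric, pair in pairs.items()}
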