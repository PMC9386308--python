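"""External-validation statistics for NIR calibration models.

The quantities every validation table in this field reports:

* ``RSQ`` — squared Pearson correlation between predicted and reference;
* ``slope`` — OLS slope of predicted on reference (ideal 1);
* ``bias`` — signed mean(laboratory - predicted): negative means the model
  overestimates on average;
* ``SEP`` — standard error of prediction, ``sqrt(sum((x1 - x2 - b)^2)/n)``
  with ``x1`` predicted, ``x2`` measured, and ``b`` the bias when
  bias-corrected (SEP(C)) or 0 otherwise; the denominator is ``n``;
* ``RPD`` — SD of the reference values divided by SEP, with the conventional
  qualitative bands (>= 2.5 "excellent", 2.0-2.5 "very good", ...);
* a paired-sample t-test on laboratory vs predicted values at a 95%
  confidence interval.

The uncorrected and bias-corrected SEP obey the exact identity
``SEP^2 = SEP(C)^2 + bias^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .core_io import ReferenceTable, SpectraSet
from .preprocessing import ScatterCorrection, apply_scatter, apply_treatment, parse_treatment
from .regression import CalibrationModel

__all__ = [
    "ValidationReport",
    "PairedTestResult",
    "rsq",
    "bias",
    "sep",
    "rpd",
    "rpd_class",
    "slope",
    "paired_t_test",
    "validation_report",
]

_EPS = 1e-12

RPD_BANDS = (
    (1.0, "very poor"),
    (1.4, "poor"),
    (1.8, "fair"),
    (2.0, "good"),
    (2.5, "very good"),
    (math.inf, "excellent"),
)


def _pair(predicted, reference) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {r.shape}")
    return p, r


def rsq(predicted, reference) -> float:
    """Squared Pearson correlation."""
    p, r = _pair(predicted, reference)
    if p.size < 3:
        raise ValueError("rsq needs n >= 3")
    if np.std(p) < _EPS or np.std(r) < _EPS:
        raise ValueError("zero variance: correlation undefined")
    c = float(np.corrcoef(p, r)[0, 1])
    return c * c


def bias(predicted, reference) -> float:
    """Signed mean(reference - predicted); positive = model underestimates."""
    p, r = _pair(predicted, reference)
    return float(np.mean(r - p))


def sep(predicted, reference, bias_corrected: bool = True) -> float:
    """Standard error of prediction.

    ``sqrt(sum((x1 - x2 - b)^2) / n)`` with x1 predicted, x2 measured.  When
    ``bias_corrected`` (the SEP(C) form), b centres the differences at their
    mean; otherwise b = 0.  The denominator is n, not n - 1.
    """
    p, r = _pair(predicted, reference)
    if p.size < 2:
        raise ValueError("sep needs n >= 2")
    d = p - r
    if bias_corrected:
        d = d - d.mean()
    return float(np.sqrt(np.mean(d * d)))


def rpd(sd_reference: float, sep_value: float) -> float:
    """Ratio of performance to deviation: SD(reference)/SEP."""
    if sep_value <= 0:
        raise ValueError(
            "SEP is zero: RPD is infinite (perfect prediction); not returned as a number"
        )
    return float(sd_reference) / float(sep_value)


def rpd_class(rpd_value: float) -> str:
    """Qualitative band for an RPD value."""
    if rpd_value < 0:
        raise ValueError("RPD must be >= 0")
    for upper, label in RPD_BANDS:
        if rpd_value < upper:
            return label
    return "excellent"  # pragma: no cover


def slope(predicted, reference) -> float:
    """OLS slope of predicted regressed on reference."""
    p, r = _pair(predicted, reference)
    vr = float(np.var(r))
    if vr < _EPS:
        raise ValueError("zero reference variance: slope undefined")
    return float(np.cov(p, r, ddof=0)[0, 1] / vr)


@dataclass
class PairedTestResult:
    """Paired-sample t-test on laboratory vs predicted values."""

    label: str
    n: int
    mean_difference: float
    sd_difference: float
    se_mean: float
    ci95: tuple
    t_value: float
    df: int
    p_value: float


def paired_t_test(lab, predicted, label: str = "") -> PairedTestResult:
    """Two-sided paired t-test on d = lab - predicted.

    Sample SD (n-1 denominator), SE = SD/sqrt(n), t = mean/SE, df = n-1,
    p from Student's t; 95% CI = mean -/+ t_crit(0.975, df) * SE.  Identical
    vectors give t = 0, p = 1; zero-variance differences with nonzero mean
    give t = +/-inf with p = 0.
    """
    l_, p_ = _pair(lab, predicted)
    n = l_.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = l_ - p_
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    se = sd / math.sqrt(n)
    tcrit = float(_sps.t.ppf(0.975, df))
    if se < _EPS:
        if abs(mean) < _EPS:
            t_val, p_val = 0.0, 1.0
        else:
            t_val = math.inf if mean > 0 else -math.inf
            p_val = 0.0
        ci = (mean, mean)
    else:
        t_val = mean / se
        p_val = float(2.0 * _sps.t.sf(abs(t_val), df))
        ci = (mean - tcrit * se, mean + tcrit * se)
    return PairedTestResult(
        label=label,
        n=n,
        mean_difference=mean,
        sd_difference=sd,
        se_mean=se,
        ci95=ci,
        t_value=t_val,
        df=df,
        p_value=p_val,
    )


@dataclass
class ValidationReport:
    """One external-validation table row for one trait."""

    trait: str
    n: int
    calibration_range: tuple
    validation_range: tuple
    treatment: str
    scatter: str
    method: str
    rsq: float
    slope: float
    bias: float
    sd: float
    sep: float  # uncorrected, Eq-form with b = 0
    sep_c: float  # bias-corrected SEP(C)
    rpd: float
    rpd_label: str
    in_sample: bool = False
    paired_t: PairedTestResult | None = None
    predicted: np.ndarray | None = None
    reference_values: np.ndarray | None = None

    def to_row(self) -> dict:
        return {
            "trait": self.trait,
            "n": self.n,
            "range_cal": f"{self.calibration_range[0]:.4g}-{self.calibration_range[1]:.4g}",
            "range_val": f"{self.validation_range[0]:.4g}-{self.validation_range[1]:.4g}",
            "treatment": self.treatment,
            "scatter": self.scatter,
            "method": self.method,
            "rsq": self.rsq,
            "slope": self.slope,
            "bias": self.bias,
            "sd": self.sd,
            "sep": self.sep,
            "sep_c": self.sep_c,
            "rpd": self.rpd,
            "rpd_class": self.rpd_label,
        }


def validation_report(
    model: CalibrationModel,
    spectra: SpectraSet,
    reference: ReferenceTable,
    trait: str | None = None,
    scatter_correction: ScatterCorrection | None = None,
    rpd_from: str = "sep_c",
    allow_in_sample: bool = False,
) -> ValidationReport:
    """Apply a fitted model to an external validation set and assemble all
    statistics.

    The spectra are passed through the model's stored preprocessing (scatter
    correction — MSC uses the stored calibration mean — then the math
    treatment).  No outlier removal is performed in external validation.
    Overlap between validation and training IDs is a hard error unless
    ``allow_in_sample`` is set, in which case the report is flagged.
    """
    trait = trait or model.trait
    if not trait:
        raise ValueError("trait name required (model.trait is empty)")
    overlap = set(spectra.sample_ids) & set(model.training_ids)
    in_sample = bool(overlap)
    if in_sample and not allow_in_sample:
        raise ValueError(
            f"{len(overlap)} validation samples were used in calibration "
            f"(e.g. {sorted(overlap)[:3]}); external validation requires disjoint sets"
        )

    if scatter_correction is None:
        scatter_correction = ScatterCorrection(model.scatter, reference=None) \
            if model.scatter != "msc" else None
    if scatter_correction is None:
        raise ValueError("MSC model requires the fitted ScatterCorrection")
    treated = apply_treatment(
        apply_scatter(spectra, scatter_correction), parse_treatment(model.treatment)
    )
    predicted = model.predict(treated)

    ref = reference.subset(spectra.sample_ids)
    y = ref.values_for(trait)
    sd_ref = float(np.std(y, ddof=1))
    sep_u = sep(predicted, y, bias_corrected=False)
    sep_c = sep(predicted, y, bias_corrected=True)
    sep_for_rpd = sep_c if rpd_from == "sep_c" else sep_u
    rpd_val = rpd(sd_ref, sep_for_rpd)
    cal_range = (
        model.stats.get("y_min", float("nan")),
        model.stats.get("y_max", float("nan")),
    )
    return ValidationReport(
        trait=trait,
        n=y.size,
        calibration_range=cal_range,
        validation_range=(float(y.min()), float(y.max())),
        treatment=model.treatment,
        scatter=model.scatter,
        method=model.method,
        rsq=rsq(predicted, y),
        slope=slope(predicted, y),
        bias=bias(predicted, y),
        sd=sd_ref,
        sep=sep_u,
        sep_c=sep_c,
        rpd=rpd_val,
        rpd_label=rpd_class(rpd_val),
        in_sample=in_sample,
        paired_t=paired_t_test(y, predicted, label=trait),
        predicted=predicted,
        reference_values=y,
    )
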