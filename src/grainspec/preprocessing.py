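"""Scatter corrections and WinISI-style math treatments.

Two families of operators act on a :class:`~grainspec.core_io.SpectraSet`
before calibration:

* scatter corrections — multiplicative scatter correction (MSC: per-spectrum
  least-squares fit against a reference mean spectrum, corrected spectrum
  ``(x - a)/b``) and SNV-detrend (per-spectrum z-scoring followed by removal
  of a fitted 2nd-degree polynomial in wavelength);
* math treatments — the four-integer code ``d,g,s1,s2``: first moving-average
  smoothing of width ``s1``, then ``d`` successive centred gap differences
  ``y[i] = x[i + g/2] - x[i - g/2]`` (gap ``g`` in grid points), then a second
  smoothing of width ``s2``.

Edge samples whose value would require points outside the grid are trimmed,
never padded; the output wavelength grid records the trim.  All operators are
row-local except MSC's reference mean, which is fitted on the calibration set
and stored for out-of-set application.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import MathTreatment, SpectraSet

__all__ = [
    "ScatterCorrection",
    "msc_fit_apply",
    "snv_detrend",
    "apply_scatter",
    "parse_treatment",
    "apply_treatment",
    "preprocess",
]

_B_EPS = 1e-12


@dataclass
class ScatterCorrection:
    """A fitted (or trivially row-local) scatter correction.

    For MSC, ``reference`` holds the calibration-set mean spectrum the
    correction was fitted against; it is stored, never recomputed, when the
    correction is applied to validation data.
    """

    method: str  # none | msc | snv_dt
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in ("none", "msc", "snv_dt"):
            raise ValueError(f"unknown scatter method {self.method!r}")
        if self.method == "msc" and self.reference is None:
            raise ValueError("msc correction requires a reference spectrum")


def msc_fit_apply(
    spectra: SpectraSet, reference: np.ndarray | None = None
) -> tuple[SpectraSet, ScatterCorrection]:
    """Fit-and-apply MSC.

    Each spectrum ``x`` is regressed on the reference ``m`` (default: column
    mean of the fitted set): ``x ~ a + b*m``; the corrected spectrum is
    ``(x - a)/b``.  Raises if any fitted ``b`` is numerically zero.
    """
    X = spectra.absorbance
    if reference is None:
        if spectra.n_samples < 2:
            raise ValueError("MSC needs >= 2 spectra to fit a mean reference")
        m = X.mean(axis=0)
    else:
        m = np.asarray(reference, dtype=float)
        if m.size != spectra.n_wavelengths:
            raise ValueError(
                f"reference length {m.size} != grid length {spectra.n_wavelengths}"
            )
    mc = m - m.mean()
    denom = float(mc @ mc)
    if denom < _B_EPS:
        raise ValueError("MSC reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ mc / denom
    small = np.abs(b) < _B_EPS
    if small.any():
        bad = spectra.sample_ids[int(np.argmax(small))]
        raise ValueError(f"MSC slope numerically zero for sample {bad!r}")
    a = X.mean(axis=1) - b * m.mean()
    corrected = (X - a[:, None]) / b[:, None]
    out = spectra.with_absorbance(corrected, history_entry="msc")
    return out, ScatterCorrection("msc", reference=m.copy())


def snv_detrend(spectra: SpectraSet) -> SpectraSet:
    """SNV followed by quadratic detrend, per spectrum.

    SNV: subtract the row mean, divide by the row SD.  Detrend: fit a
    2nd-degree polynomial of the SNV spectrum on wavelength and subtract it,
    so any affine or quadratic wavelength trend maps to zero.
    """
    X = spectra.absorbance
    sd = X.std(axis=1, ddof=0)
    flat = sd < _B_EPS
    if flat.any():
        bad = spectra.sample_ids[int(np.argmax(flat))]
        raise ValueError(f"constant spectrum for sample {bad!r}: SNV undefined")
    snv = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    # orthonormal quadratic basis in wavelength for a stable fit
    wl = spectra.wavelengths_nm
    span = float(np.ptp(wl))
    t = (wl - wl.mean()) / (span if span > 0 else 1.0)
    basis = np.vander(t, 3, increasing=True)  # [1, t, t^2]
    q, _ = np.linalg.qr(basis)
    detrended = snv - (snv @ q) @ q.T
    return spectra.with_absorbance(detrended, history_entry="snv_dt")


def apply_scatter(spectra: SpectraSet, correction: ScatterCorrection) -> SpectraSet:
    """Apply a scatter correction out of set (MSC uses the stored reference)."""
    if correction.method == "none":
        return spectra.with_absorbance(spectra.absorbance.copy(), history_entry="scatter:none")
    if correction.method == "snv_dt":
        return snv_detrend(spectra)
    out, _ = msc_fit_apply(spectra, reference=correction.reference)
    return out


def parse_treatment(code: str) -> MathTreatment:
    """Parse a ``"d,g,s1,s2"`` math-treatment code."""
    parts = [p.strip() for p in str(code).split(",")]
    if len(parts) != 4:
        raise ValueError(
            f"treatment code must have four comma-separated integers, got {code!r}"
        )
    try:
        d, g, s1, s2 = (int(p) for p in parts)
    except ValueError:
        raise ValueError(f"non-integer component in treatment code {code!r}") from None
    return MathTreatment(d, g, s1, s2)


def _boxcar(X: np.ndarray, wl: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Centred moving average of ``width`` points; even widths use the
    left-centre convention (window ``[i - w//2, i + w//2 - 1]``).  Edges are
    trimmed."""
    if width == 1:
        return X, wl
    p = X.shape[1]
    left = width // 2
    right = width - left - 1
    if p - width + 1 <= 0:
        raise ValueError(
            f"smoothing width {width} needs a grid of >= {width} points, have {p}"
        )
    csum = np.cumsum(X, axis=1, dtype=float)
    csum = np.concatenate([np.zeros((X.shape[0], 1)), csum], axis=1)
    smoothed = (csum[:, width:] - csum[:, :-width]) / width
    return smoothed, wl[left : p - right]


def _gap_difference(X: np.ndarray, wl: np.ndarray, gap: int) -> tuple[np.ndarray, np.ndarray]:
    """One centred gap difference y[i] = x[i + g/2] - x[i - g/2]."""
    h = gap // 2
    p = X.shape[1]
    if p - gap <= 0:
        raise ValueError(f"gap {gap} needs a grid of > {gap} points, have {p}")
    return X[:, gap:] - X[:, :-gap], wl[h : p - h]


def apply_treatment(spectra: SpectraSet, treatment: MathTreatment) -> SpectraSet:
    """Apply a math treatment: smooth(s1) -> d gap derivatives -> smooth(s2).

    ``d = 0`` skips the derivative stage; a smoothing width of 1 is the
    identity.  The output grid is trimmed to wavelengths where every stage is
    defined; an empty output grid is an error.
    """
    X = spectra.absorbance
    wl = spectra.wavelengths_nm
    needed = (treatment.smooth1 - 1) + treatment.derivative * treatment.gap + (
        treatment.smooth2 - 1
    )
    if spectra.n_wavelengths - needed < 1:
        raise ValueError(
            f"treatment {treatment.code()} needs a grid of >= {needed + 1} points, "
            f"have {spectra.n_wavelengths}"
        )
    X, wl = _boxcar(X, wl, treatment.smooth1)
    for _ in range(treatment.derivative):
        X, wl = _gap_difference(X, wl, treatment.gap)
    X, wl = _boxcar(X, wl, treatment.smooth2)
    return spectra.with_absorbance(
        X, wavelengths_nm=wl, history_entry=f"treatment:{treatment.code()}"
    )


def preprocess(
    spectra: SpectraSet,
    scatter: str | ScatterCorrection = "none",
    treatment: MathTreatment | str = "0,0,1,1",
) -> tuple[SpectraSet, ScatterCorrection]:
    """Scatter correction followed by math treatment.

    ``scatter`` may be a method name (``none``/``msc``/``snv_dt``; MSC is then
    fitted on this set) or an already fitted :class:`ScatterCorrection` for
    out-of-set application.  Returns the treated spectra and the fitted
    correction; both steps are appended to the processing history.
    """
    if isinstance(treatment, str):
        treatment = parse_treatment(treatment)
    if isinstance(scatter, ScatterCorrection):
        corrected = apply_scatter(spectra, scatter)
        fitted = scatter
    elif scatter == "none":
        corrected, fitted = spectra, ScatterCorrection("none")
    elif scatter == "snv_dt":
        corrected, fitted = snv_detrend(spectra), ScatterCorrection("snv_dt")
    elif scatter == "msc":
        corrected, fitted = msc_fit_apply(spectra)
    else:
        raise ValueError(f"unknown scatter spec {scatter!r}")
    return apply_treatment(corrected, treatment), fitted
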