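"""Multivariate calibration: NIPALS PLS1, modified PLS (MPLS) and PCR.

All three fitters regress one trait on treated spectra.  X and y are
mean-centred (not variance-scaled — the spectroscopy convention); MPLS
additionally standardises the X- and y-residuals by their current standard
deviations between factor extractions, which damps the domination of
high-variance spectral regions and is the classical "modified" PLS of NIR
calibration software.

Factor count is chosen by contiguous-block cross-validation (SECV argmin)
under a hard cap — 5 principal components by default, the ceiling commonly
imposed when calibrating on a hundred-odd samples.  Calibration outliers are
eliminated iteratively by a standardised-residual rule (|t| > 2.5) and a
Mahalanobis-type leverage rule in score space (GH > 3), at most two passes,
with the total number of removals capped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import SpectraSet

__all__ = [
    "CalibrationModel",
    "CVResult",
    "fit_pls",
    "fit_mpls",
    "fit_pcr",
    "fit_method",
    "cross_validate",
    "remove_outliers",
]

DEFAULT_MAX_PCS = 5
_EPS = 1e-12


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectraSet):
        return X.absorbance
    return np.asarray(X, dtype=float)


@dataclass
class CalibrationModel:
    """A fitted calibration equation for one trait.

    ``coefficients`` act on the *treated* spectral grid (after scatter
    correction and math treatment); ``intercept`` completes the affine map so
    that ``predict`` consumes raw treated absorbance rows.  Training
    statistics use the reference values of the samples actually kept after
    outlier elimination.
    """

    method: str  # pls | mpls | pcr
    n_pcs: int
    coefficients: np.ndarray
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    trait: str = ""
    scatter: str = "none"
    treatment: str = "0,0,1,1"
    wavelengths_nm: np.ndarray | None = None
    stats: dict = field(default_factory=dict)  # rsq, slope, sd, sec, secv
    outliers_removed: list = field(default_factory=list)  # (sample_id, reason)
    training_ids: list = field(default_factory=list)
    # training scores, kept for leverage diagnostics; not serialised
    scores_: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        M = _as_matrix(X)
        if M.shape[1] != self.coefficients.size:
            raise ValueError(
                f"treated grid length {M.shape[1]} != coefficient length "
                f"{self.coefficients.size}"
            )
        return M @ self.coefficients + self.intercept

    # -- lossless JSON serialisation -------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "method": self.method,
            "n_pcs": self.n_pcs,
            "coefficients": [float(v) for v in self.coefficients],
            "intercept": float(self.intercept),
            "x_mean": [float(v) for v in self.x_mean],
            "y_mean": float(self.y_mean),
            "trait": self.trait,
            "scatter": self.scatter,
            "treatment": self.treatment,
            "wavelengths_nm": None
            if self.wavelengths_nm is None
            else [float(v) for v in self.wavelengths_nm],
            "stats": self.stats,
            "outliers_removed": [list(t) for t in self.outliers_removed],
            "training_ids": list(self.training_ids),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            method=d["method"],
            n_pcs=int(d["n_pcs"]),
            coefficients=np.array(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            x_mean=np.array(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            trait=d.get("trait", ""),
            scatter=d.get("scatter", "none"),
            treatment=d.get("treatment", "0,0,1,1"),
            wavelengths_nm=None
            if d.get("wavelengths_nm") is None
            else np.array(d["wavelengths_nm"], dtype=float),
            stats=dict(d.get("stats", {})),
            outliers_removed=[tuple(t) for t in d.get("outliers_removed", [])],
            training_ids=list(d.get("training_ids", [])),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh)

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


# ---------------------------------------------------------------------------
# core factor extraction
# ---------------------------------------------------------------------------

def _check_xy(X: np.ndarray, y: np.ndarray, n_pcs: int) -> None:
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"{n} spectra but {y.size} reference values")
    if n <= n_pcs:
        raise ValueError(f"need n_samples > n_pcs, have n={n}, n_pcs={n_pcs}")
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if np.std(y) < _EPS:
        raise ValueError("reference values have zero variance")


def _pls_factors(Xc: np.ndarray, yc: np.ndarray, n_pcs: int, modified: bool):
    """NIPALS PLS1 factor extraction, optionally with MPLS residual
    standardisation.  Returns (B, scores) where ``B[:, a]`` is the
    coefficient vector using a+1 factors and ``scores`` the training scores.

    In the modified mode, the X- and y-residuals are standardised by their
    current standard deviations when forming the weight vector for the next
    factor; scores, loadings and deflation stay in the unstandardised space,
    so the standard identity  b = W (P^T W)^-1 q  applies in both modes.
    """
    n, p = Xc.shape
    E = Xc.copy()
    f = yc.copy()
    W = np.zeros((p, n_pcs))
    P = np.zeros((p, n_pcs))
    q = np.zeros(n_pcs)
    T = np.zeros((n, n_pcs))
    for a in range(n_pcs):
        if modified:
            col_sd = E.std(axis=0, ddof=0)
            scale = np.where(col_sd > _EPS, col_sd, 1.0)
            if np.any(col_sd <= _EPS):
                warnings.warn(
                    "zero-variance residual columns excluded from MPLS scaling",
                    stacklevel=3,
                )
            y_sd = f.std(ddof=0)
            y_scale = y_sd if y_sd > _EPS else 1.0
            w = (E / scale).T @ (f / y_scale)
        else:
            w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < _EPS:
            # residual y no longer correlates with X: truncate the path
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            n_pcs = a
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt < _EPS:
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            n_pcs = a
            break
        W[:, a] = w
        P[:, a] = E.T @ t / tt
        q[a] = float(f @ t) / tt
        T[:, a] = t
        E -= np.outer(t, P[:, a])
        f -= q[a] * t
    if n_pcs == 0:
        raise ValueError("no extractable PLS factor (X uncorrelated with y)")
    # coefficient path: b_k = W_k (P_k^T W_k)^{-1} q_k
    B = np.zeros((p, n_pcs))
    PtW = P.T @ W  # upper triangular, unit diagonal in exact arithmetic
    for k in range(1, n_pcs + 1):
        r = np.linalg.solve(PtW[:k, :k], q[:k])
        B[:, k - 1] = W[:, :k] @ r
    return B, T


def _pcr_factors(Xc: np.ndarray, yc: np.ndarray, n_pcs: int):
    """PCA scores of centred X, OLS of y on leading scores; returns the
    coefficient path and training scores."""
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = min(n_pcs, rank)
    if k == 0:
        raise ValueError("X has zero rank")
    T = U[:, :k] * s[:k]
    p = Xc.shape[1]
    B = np.zeros((p, k))
    # scores are orthogonal, so per-component regressions accumulate
    acc = np.zeros(p)
    for a in range(k):
        g = float(T[:, a] @ yc) / float(T[:, a] @ T[:, a])
        acc = acc + g * Vt[a]
        B[:, a] = acc
    return B, T


def _fit(X, y, n_pcs: int, method: str) -> CalibrationModel:
    M = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    _check_xy(M, yv, n_pcs)
    x_mean = M.mean(axis=0)
    y_mean = float(yv.mean())
    Xc = M - x_mean
    yc = yv - y_mean
    if method in ("pls", "mpls"):
        B, T = _pls_factors(Xc, yc, n_pcs, modified=(method == "mpls"))
    elif method == "pcr":
        B, T = _pcr_factors(Xc, yc, n_pcs)
    else:
        raise ValueError(f"unknown regression method {method!r}")
    k = B.shape[1]
    b = B[:, k - 1]
    intercept = y_mean - float(x_mean @ b)
    model = CalibrationModel(
        method=method,
        n_pcs=k,
        coefficients=b,
        intercept=intercept,
        x_mean=x_mean,
        y_mean=y_mean,
        scores_=T,
    )
    model.stats.update(_training_stats(model, M, yv, k))
    if isinstance(X, SpectraSet):
        model.wavelengths_nm = X.wavelengths_nm.copy()
        model.training_ids = list(X.sample_ids)
    return model


def _training_stats(model: CalibrationModel, M: np.ndarray, y: np.ndarray, k: int) -> dict:
    pred = model.predict(M)
    resid = y - pred
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    n = y.size
    dof = max(n - 1 - k, 1)
    vy = np.var(y)
    vp = np.var(pred)
    slope = float(np.cov(pred, y, ddof=0)[0, 1] / vy) if vy > _EPS else float("nan")
    return {
        "rsq": 1.0 - rss / tss if tss > _EPS else float("nan"),
        "slope": slope,
        "sd": float(np.std(y, ddof=1)),
        "sec": float(np.sqrt(rss / dof)),
        "n": int(n),
        "y_min": float(y.min()),
        "y_max": float(y.max()),
    }


def fit_pls(X, y, n_pcs: int) -> CalibrationModel:
    """NIPALS PLS1.  At full rank the coefficients coincide with OLS."""
    return _fit(X, y, n_pcs, "pls")


def fit_mpls(X, y, n_pcs: int) -> CalibrationModel:
    """Modified PLS: X/y residuals are standardised between factors."""
    return _fit(X, y, n_pcs, "mpls")


def fit_pcr(X, y, n_pcs: int) -> CalibrationModel:
    """Principal component regression on the leading PCA scores."""
    return _fit(X, y, n_pcs, "pcr")


def fit_method(X, y, n_pcs: int, method: str) -> CalibrationModel:
    return _fit(X, y, n_pcs, method)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    secv_by_pcs: dict  # {k: SECV}
    chosen_n_pcs: int

    @property
    def secv(self) -> float:
        return self.secv_by_pcs[self.chosen_n_pcs]


def _coefficient_path(Xc, yc, n_pcs, method):
    if method in ("pls", "mpls"):
        B, _ = _pls_factors(Xc, yc, n_pcs, modified=(method == "mpls"))
    else:
        B, _ = _pcr_factors(Xc, yc, n_pcs)
    return B


def cross_validate(
    X,
    y,
    method: str = "mpls",
    n_pcs_max: int = DEFAULT_MAX_PCS,
    n_groups: int = 4,
) -> CVResult:
    """Contiguous-block group cross-validation.

    The sample axis is split into ``n_groups`` contiguous blocks (deterministic,
    no shuffling); SECV(k) is the RMSE of the pooled held-out predictions with
    k factors, and the chosen factor count is the SECV argmin subject to the
    cap (smaller k wins ties).
    """
    M = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n = yv.size
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    bounds = np.linspace(0, n, n_groups + 1).astype(int)
    sizes = np.diff(bounds)
    if sizes.min() < 2:
        raise ValueError(
            f"cross-validation group with < 2 samples (n={n}, groups={n_groups})"
        )
    kmax = min(n_pcs_max, n - int(sizes.max()) - 1)
    if kmax < 1:
        raise ValueError("too few samples for cross-validation at any factor count")
    press = np.zeros(kmax)
    for g in range(n_groups):
        held = np.zeros(n, dtype=bool)
        held[bounds[g] : bounds[g + 1]] = True
        Mtr, ytr = M[~held], yv[~held]
        x_mean = Mtr.mean(axis=0)
        y_mean = ytr.mean()
        B = _coefficient_path(Mtr - x_mean, ytr - y_mean, kmax, method)
        pred = (M[held] - x_mean) @ B + y_mean  # (n_held, k_avail)
        err = pred - yv[held][:, None]
        k_avail = B.shape[1]
        sq = (err**2).sum(axis=0)
        press[:k_avail] += sq
        if k_avail < kmax:  # path truncated: last coefficients persist
            press[k_avail:] += sq[-1]
    secv = np.sqrt(press / n)
    chosen = int(np.argmin(secv)) + 1
    return CVResult(
        secv_by_pcs={k + 1: float(secv[k]) for k in range(kmax)},
        chosen_n_pcs=chosen,
    )


# ---------------------------------------------------------------------------
# outlier elimination
# ---------------------------------------------------------------------------

def _leverage_gh(T: np.ndarray) -> np.ndarray:
    """Mahalanobis-type leverage in score space, normalised so the average
    is ~1 (the conventional GH statistic)."""
    n, k = T.shape
    C = (T.T @ T) / max(n - 1, 1)
    Ci = np.linalg.pinv(C)
    d2 = np.einsum("ij,jk,ik->i", T, Ci, T)
    return d2 / max(k, 1)


def remove_outliers(
    X,
    y,
    method: str = "mpls",
    n_pcs: int = DEFAULT_MAX_PCS,
    sample_ids: list | None = None,
    t_limit: float = 2.5,
    gh_limit: float = 3.0,
    max_passes: int = 2,
    max_remove_fraction: float = 0.10,
):
    """Iterative calibration-outlier elimination.

    On each pass a model is fitted and samples with standardised y-residual
    ``|t| > t_limit`` or leverage ``GH > gh_limit`` are removed, then the
    model is refitted; at most ``max_passes`` passes and at most
    ``max_remove_fraction`` of the starting samples in total.  Hitting the
    cap warns and stops; it never raises.

    Returns ``(model, removed)`` with ``removed`` a list of
    ``(sample_id, reason)`` tuples.
    """
    if t_limit <= 0 or gh_limit <= 0:
        raise ValueError("outlier limits must be positive")
    M = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    if sample_ids is None:
        sample_ids = (
            list(X.sample_ids)
            if isinstance(X, SpectraSet)
            else [str(i) for i in range(yv.size)]
        )
    ids = list(sample_ids)
    n0 = yv.size
    cap = int(np.floor(max_remove_fraction * n0))
    keep = np.ones(n0, dtype=bool)
    removed: list[tuple[str, str]] = []

    model = fit_method(M, yv, n_pcs, method)
    for _ in range(max_passes):
        sub = np.flatnonzero(keep)
        pred = model.predict(M[sub])
        resid = yv[sub] - pred
        sec = model.stats.get("sec", float(np.std(resid, ddof=1)))
        if sec < _EPS:
            break
        tstat = np.abs(resid) / sec
        gh = _leverage_gh(model.scores_) if model.scores_ is not None else np.zeros(sub.size)
        flagged = []
        for j in range(sub.size):
            if tstat[j] > t_limit:
                flagged.append((sub[j], f"t={tstat[j]:.2f}"))
            elif gh[j] > gh_limit:
                flagged.append((sub[j], f"GH={gh[j]:.2f}"))
        if not flagged:
            break
        # worst first, respecting the removal cap
        flagged.sort(key=lambda it: -float(it[1].split("=")[1]))
        capped = False
        for idx, reason in flagged:
            if len(removed) >= cap:
                capped = True
                break
            keep[idx] = False
            removed.append((ids[idx], reason))
        model = fit_method(M[keep], yv[keep], n_pcs, method)
        if capped:
            warnings.warn(
                f"outlier removal cap ({cap} of {n0}) reached; stopping",
                stacklevel=2,
            )
            break
    model.outliers_removed = removed
    model.training_ids = [ids[i] for i in np.flatnonzero(keep)]
    return model, removed
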