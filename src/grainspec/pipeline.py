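"""End-to-end study orchestration.

``run_study`` reproduces the whole workflow on either simulated or supplied
data: simulate (or ingest) spectra and compositions → MSC-normalise and
Ward-cluster to select a diverse reference subset → per-trait 2:1
rank-ordered split → grid search over math treatments × scatter corrections
× regression methods with cross-validated factor choice and calibration
outlier removal → external validation statistics for every cell → best model
per trait.  Everything is deterministic under the configured seed, and a
:class:`RunManifest` captures the parameters actually used.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .core_io import ReferenceTable, SpectraSet, STANDARD_TRAITS
from .evaluation_stats import (
    ValidationReport,
    bias,
    paired_t_test,
    rpd,
    rpd_class,
    rsq,
    sep,
    slope,
)
from .preprocessing import apply_scatter, apply_treatment, parse_treatment, preprocess
from .regression import DEFAULT_MAX_PCS, cross_validate, remove_outliers
from .sampling_split import select_representatives, split_by_trait, ward_cluster
from .synthetic_data import SimulationConfig, default_band_model, simulate_compositions, simulate_spectra
from .preprocessing import msc_fit_apply

__all__ = ["GridSpec", "StudyConfig", "RunManifest", "run_grid", "run_study", "StudyResult"]

#: the 17 math-treatment codes of the historical screening grid
DEFAULT_TREATMENTS = (
    "2,4,4,1", "2,6,6,1", "2,8,8,1",
    "3,4,4,1", "3,6,6,1", "3,8,8,1", "3,10,8,1", "3,12,8,1", "3,14,8,1",
    "3,16,8,1", "3,16,8,2",
    "4,6,6,1", "4,8,6,1", "4,8,8,1", "4,12,8,1", "4,16,8,1", "4,16,8,2",
)

#: the trait-winning treatments of the historical screen (protein and oil
#: share 4,8,8,1, so five trait choices give four unique codes)
CHOSEN_TREATMENTS = ("4,8,8,1", "3,16,8,2", "4,6,6,1", "2,8,8,1")


@dataclass
class GridSpec:
    """The model-search grid: treatments × scatter corrections × methods."""

    treatments: tuple = DEFAULT_TREATMENTS
    scatter_methods: tuple = ("snv_dt", "msc", "none")
    regression_methods: tuple = ("pls", "mpls", "pcr")
    # ranking: maximise external RSQ, tie-break higher RPD then lower SEP
    ranking: tuple = ("rsq", "rpd", "sep")

    def __post_init__(self) -> None:
        if not (self.treatments and self.scatter_methods and self.regression_methods):
            raise ValueError("grid must be non-empty on every axis")
        for code in self.treatments:
            parse_treatment(code)  # raises on malformed codes

    @property
    def n_cells(self) -> int:
        return len(self.treatments) * len(self.scatter_methods) * len(self.regression_methods)


@dataclass
class StudyConfig:
    """Everything a full study run needs; the seed drives all randomness."""

    seed: int = 42
    n_samples: int = 500
    traits: tuple = STANDARD_TRAITS
    # selection
    k_main: int = 6
    k_sub: int = 5
    small_cluster_max: int = 4
    selection_target: int = 180
    # calibration
    grid: GridSpec = field(default_factory=GridSpec)
    max_pcs: int = DEFAULT_MAX_PCS
    cv_groups: int = 4
    outlier_t_limit: float = 2.5
    outlier_gh_limit: float = 3.0
    outlier_max_passes: int = 2
    outlier_max_fraction: float = 0.10
    rpd_from: str = "sep_c"
    simulation: SimulationConfig | None = None

    def boundary_per_subcluster(self) -> int:
        """Boundary-member count derived from the selection target: with
        k_main*k_sub sub-clusters each yielding 1 centre + b boundary members,
        b = round(target / (k_main*k_sub)) - 1."""
        cells = max(self.k_main * self.k_sub, 1)
        return max(int(round(self.selection_target / cells)) - 1, 0)

    def config_hash(self) -> str:
        payload = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("grid", "simulation")
        }
        payload["grid"] = {
            "treatments": list(self.grid.treatments),
            "scatter": list(self.grid.scatter_methods),
            "methods": list(self.grid.regression_methods),
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one study run."""

    config_hash: str
    seed: int
    version: str
    stage_seconds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stage_seconds": {k: round(v, 3) for k, v in self.stage_seconds.items()},
            "counts": self.counts,
            "output_digests": self.output_digests,
        }


def _digest_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(float_format="%.12g").encode()
    ).hexdigest()


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def _external_stats(predicted: np.ndarray, y: np.ndarray, rpd_from: str) -> dict:
    sd_ref = float(np.std(y, ddof=1))
    sep_u = sep(predicted, y, bias_corrected=False)
    sep_c = sep(predicted, y, bias_corrected=True)
    chosen_sep = sep_c if rpd_from == "sep_c" else sep_u
    rpd_val = rpd(sd_ref, chosen_sep) if chosen_sep > 0 else float("inf")
    return {
        "rsq": rsq(predicted, y),
        "slope": slope(predicted, y),
        "bias": bias(predicted, y),
        "sd": sd_ref,
        "sep": sep_u,
        "sep_c": sep_c,
        "rpd": rpd_val,
        "rpd_class": rpd_class(rpd_val) if np.isfinite(rpd_val) else "excellent",
    }


def run_grid(
    cal_spectra: SpectraSet,
    cal_y: np.ndarray,
    val_spectra: SpectraSet,
    val_y: np.ndarray,
    trait: str,
    grid: GridSpec | None = None,
    max_pcs: int = DEFAULT_MAX_PCS,
    cv_groups: int = 4,
    remove_calibration_outliers: bool = True,
    outlier_kwargs: dict | None = None,
    rpd_from: str = "sep_c",
):
    """Fit and externally validate every grid cell for one trait.

    Returns ``(table, best_model, best_report)``: a ranked DataFrame with one
    row per attempted cell (failed cells carry an ``error`` string, they are
    recorded, not fatal), the winning :class:`CalibrationModel` and its
    :class:`ValidationReport`.  Ranking maximises external RSQ, breaking ties
    by higher RPD then lower SEP; it does not depend on enumeration order.
    """
    grid = grid or GridSpec()
    outlier_kwargs = outlier_kwargs or {}
    overlap = set(cal_spectra.sample_ids) & set(val_spectra.sample_ids)
    if overlap:
        raise ValueError(f"calibration/validation overlap: {sorted(overlap)[:3]}")

    rows = []
    best = None  # (sort_key, model, report)
    cal_y = np.asarray(cal_y, dtype=float)
    val_y = np.asarray(val_y, dtype=float)

    for scatter in grid.scatter_methods:
        for code in grid.treatments:
            try:
                cal_treated, correction = preprocess(cal_spectra, scatter, code)
                val_treated = apply_treatment(
                    apply_scatter(val_spectra, correction), parse_treatment(code)
                )
            except ValueError as exc:
                for method in grid.regression_methods:
                    rows.append(
                        {"trait": trait, "scatter": scatter, "treatment": code,
                         "method": method, "error": str(exc)}
                    )
                continue
            for method in grid.regression_methods:
                try:
                    cv = cross_validate(
                        cal_treated.absorbance, cal_y, method=method,
                        n_pcs_max=max_pcs, n_groups=cv_groups,
                    )
                    if remove_calibration_outliers:
                        model, _ = remove_outliers(
                            cal_treated, cal_y, method=method,
                            n_pcs=cv.chosen_n_pcs, **outlier_kwargs,
                        )
                    else:
                        from .regression import fit_method

                        model = fit_method(cal_treated, cal_y, cv.chosen_n_pcs, method)
                    model.trait = trait
                    model.scatter = scatter
                    model.treatment = code
                    model.stats["secv"] = cv.secv
                    predicted = model.predict(val_treated)
                    ext = _external_stats(predicted, val_y, rpd_from)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    rows.append(
                        {"trait": trait, "scatter": scatter, "treatment": code,
                         "method": method, "error": str(exc)}
                    )
                    continue
                row = {
                    "trait": trait, "scatter": scatter, "treatment": code,
                    "method": method, "n_pcs": model.n_pcs,
                    "n_cal": len(model.training_ids),
                    "n_outliers": len(model.outliers_removed),
                    "sec": model.stats["sec"], "secv": cv.secv,
                    "rsq_cal": model.stats["rsq"],
                    "error": "",
                }
                row.update({f"val_{k}": v for k, v in ext.items() if k != "rpd_class"})
                row["val_rpd_class"] = ext["rpd_class"]
                rows.append(row)
                key = (-ext["rsq"], -ext["rpd"], ext["sep_c" if rpd_from == "sep_c" else "sep"],
                       scatter, code, method)
                if best is None or key < best[0]:
                    report = ValidationReport(
                        trait=trait, n=val_y.size,
                        calibration_range=(model.stats["y_min"], model.stats["y_max"]),
                        validation_range=(float(val_y.min()), float(val_y.max())),
                        treatment=code, scatter=scatter, method=method,
                        rsq=ext["rsq"], slope=ext["slope"], bias=ext["bias"],
                        sd=ext["sd"], sep=ext["sep"], sep_c=ext["sep_c"],
                        rpd=ext["rpd"], rpd_label=ext["rpd_class"],
                        paired_t=paired_t_test(val_y, predicted, label=trait),
                        predicted=predicted, reference_values=val_y,
                    )
                    best = (key, model, report, correction)

    table = pd.DataFrame(rows)
    ok = table[table["error"] == ""] if "error" in table else table
    if best is None:
        raise ValueError(f"every grid cell failed for trait {trait!r}")
    # stable, enumeration-order-independent ranking
    if not ok.empty:
        ok = ok.sort_values(
            by=["val_rsq", "val_rpd", "val_sep_c", "scatter", "treatment", "method"],
            ascending=[False, False, True, True, True, True],
        )
        failed = table[table["error"] != ""]
        table = pd.concat([ok, failed], ignore_index=True)
    return table, best[1], best[2]


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Everything a study run produces."""

    spectra: SpectraSet
    reference: ReferenceTable
    selected_ids: list
    splits: dict  # trait -> SplitPlan
    grid_tables: dict  # trait -> DataFrame
    best_models: dict  # trait -> CalibrationModel
    reports: dict  # trait -> ValidationReport
    manifest: RunManifest

    def validation_table(self) -> pd.DataFrame:
        """Table-style summary of the best model per trait."""
        return pd.DataFrame([r.to_row() for r in self.reports.values()])

    def calibration_table(self) -> pd.DataFrame:
        rows = []
        for trait, m in self.best_models.items():
            rows.append(
                {
                    "trait": trait, "n": m.stats["n"],
                    "range": f"{m.stats['y_min']:.4g}-{m.stats['y_max']:.4g}",
                    "treatment": m.treatment, "scatter": m.scatter,
                    "method": m.method, "n_pcs": m.n_pcs,
                    "rsq": m.stats["rsq"], "slope": m.stats["slope"],
                    "sd": m.stats["sd"], "sec": m.stats["sec"],
                    "secv": m.stats.get("secv", float("nan")),
                    "n_outliers": len(m.outliers_removed),
                }
            )
        return pd.DataFrame(rows)

    def paired_t_table(self) -> pd.DataFrame:
        rows = []
        for trait, r in self.reports.items():
            t = r.paired_t
            rows.append(
                {
                    "pair": f"{trait} - predicted", "n": t.n,
                    "mean": t.mean_difference, "sd": t.sd_difference,
                    "se_mean": t.se_mean, "ci95_low": t.ci95[0],
                    "ci95_high": t.ci95[1], "t": t.t_value,
                    "df": t.df, "p": t.p_value,
                }
            )
        return pd.DataFrame(rows)


def run_study(
    config: StudyConfig | None = None,
    spectra: SpectraSet | None = None,
    reference: ReferenceTable | None = None,
) -> StudyResult:
    """Execute the full workflow.

    Without explicit data, a synthetic study set of ``config.n_samples``
    accessions is generated from ``config.seed``.  Stage timings, counts and
    output digests land in the manifest; two runs with the same config are
    digest-identical.
    """
    config = config or StudyConfig()
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed, version=_version
    )
    t0 = time.perf_counter()
    if spectra is None or reference is None:
        sim = config.simulation or SimulationConfig(
            n_samples=config.n_samples, seed=config.seed
        )
        sim.n_samples = config.n_samples
        sim.seed = config.seed
        reference = simulate_compositions(sim)
        spectra = simulate_spectra(reference, default_band_model(), sim)
    manifest.stage_seconds["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    normalized, _ = msc_fit_apply(spectra)
    tree = ward_cluster(normalized)
    selected = select_representatives(
        tree,
        normalized,
        k_main=config.k_main,
        k_sub=config.k_sub,
        small_cluster_max=config.small_cluster_max,
        n_boundary=config.boundary_per_subcluster(),
    )
    manifest.stage_seconds["select"] = time.perf_counter() - t0
    manifest.counts["n_scanned"] = spectra.n_samples
    manifest.counts["n_selected"] = len(selected)

    sel_reference = reference.subset(selected)
    sel_spectra = spectra.subset(selected)

    splits, grid_tables, best_models, reports = {}, {}, {}, {}
    outlier_kwargs = {
        "t_limit": config.outlier_t_limit,
        "gh_limit": config.outlier_gh_limit,
        "max_passes": config.outlier_max_passes,
        "max_remove_fraction": config.outlier_max_fraction,
    }
    t0 = time.perf_counter()
    for trait in config.traits:
        plan = split_by_trait(sel_reference, trait)
        splits[trait] = plan
        cal_sp = sel_spectra.subset(plan.calibration_ids)
        val_sp = sel_spectra.subset(plan.validation_ids)
        cal_y = sel_reference.subset(plan.calibration_ids).values_for(trait)
        val_y = sel_reference.subset(plan.validation_ids).values_for(trait)
        table, model, report = run_grid(
            cal_sp, cal_y, val_sp, val_y, trait,
            grid=config.grid, max_pcs=config.max_pcs, cv_groups=config.cv_groups,
            outlier_kwargs=outlier_kwargs, rpd_from=config.rpd_from,
        )
        grid_tables[trait] = table
        best_models[trait] = model
        reports[trait] = report
    manifest.stage_seconds["calibrate_validate"] = time.perf_counter() - t0
    manifest.counts["n_traits"] = len(config.traits)
    manifest.counts["grid_cells_per_trait"] = config.grid.n_cells

    result = StudyResult(
        spectra=spectra, reference=reference, selected_ids=selected,
        splits=splits, grid_tables=grid_tables, best_models=best_models,
        reports=reports, manifest=manifest,
    )
    manifest.output_digests["validation_table"] = _digest_frame(result.validation_table())
    manifest.output_digests["calibration_table"] = _digest_frame(result.calibration_table())
    return result
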