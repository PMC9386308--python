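"""Synthetic brown-rice NIR spectra and composition generator.

Real germplasm scan sets are rarely redistributable, so the toolkit ships a
generator that emulates the statistical structure such a study assumes:

* ~500 accessions whose five compositional traits (protein, total dietary
  fibre, starch, amylose, oil; % dry basis) span wide germplasm ranges with
  deliberate mass at the extremes;
* absorbance spectra built by Beer–Lambert-style linear mixing of Gaussian
  constituent bands placed at the six absorption features seen in brown-rice
  flour (1,196 and 2,322 nm C–H/oil; 1,466 and 2,288 nm N–H/protein with an
  O–H starch shoulder; 1,634 nm water; 1,904 nm starch);
* per-sample multiplicative/additive scatter (what MSC and SNV-DT are
  designed to remove), a smooth instrument baseline, and i.i.d. noise.

With scatter and noise switched off the spectra are exact linear functions
of composition, which makes every downstream stage testable against known
ground truth.  The generator aims at statistical structure, not spectral
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import DEFAULT_GRID, ReferenceTable, SpectraSet, write_reference, write_spectra

__all__ = [
    "GaussianBand",
    "ComponentBandModel",
    "SimulationConfig",
    "default_band_model",
    "simulate_compositions",
    "simulate_spectra",
    "make_study_fixture",
]

#: six observed band centres (nm) in the mean brown-rice flour spectrum
OBSERVED_BAND_CENTERS = (1196.0, 1466.0, 1634.0, 1904.0, 2288.0, 2322.0)

#: maps band-model constituents to reference-table columns
CONSTITUENT_COLUMNS = {
    "protein": "protein_pct",
    "tdf": "tdf_pct",
    "starch": "starch_pct",
    "amylose": "amylose_pct",
    "oil": "oil_pct",
    "water": "moisture_pct",
}


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band: Gaussian in wavelength, linear in concentration."""

    center_nm: float
    sigma_nm: float
    amplitude_per_pct: float  # absorbance units per % constituent

    def profile(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        z = (wavelengths_nm - self.center_nm) / self.sigma_nm
        return self.amplitude_per_pct * np.exp(-0.5 * z * z)


@dataclass
class ComponentBandModel:
    """Per-constituent Gaussian band lists.

    Amylose is a starch sub-component and carries its own band weights (a
    narrow 1,904 nm component and a broad 2,288 nm shoulder) so that it is
    spectrally distinguishable from total starch.  Water loads only on the
    1,634 nm band and is a nuisance variable, not a predicted trait.
    """

    bands: dict[str, list[GaussianBand]]

    def __post_init__(self) -> None:
        for name, lst in self.bands.items():
            if not lst:
                raise ValueError(f"constituent {name!r} has no bands")
            for b in lst:
                if b.amplitude_per_pct < 0:
                    raise ValueError(f"negative amplitude for {name!r}")

    def constituents(self) -> list[str]:
        return list(self.bands)

    def signature(self, name: str, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Unit-concentration spectrum of one constituent."""
        out = np.zeros_like(wavelengths_nm, dtype=float)
        for band in self.bands[name]:
            out += band.profile(wavelengths_nm)
        return out

    def validate_grid(self, wavelengths_nm: np.ndarray) -> None:
        lo, hi = wavelengths_nm[0], wavelengths_nm[-1]
        for name, lst in self.bands.items():
            for b in lst:
                if not (lo <= b.center_nm <= hi):
                    raise ValueError(
                        f"band center {b.center_nm} nm of {name!r} outside grid "
                        f"[{lo}, {hi}]"
                    )


def default_band_model() -> ComponentBandModel:
    """Band placement at the six observed centres, widths and unit
    absorptivities chosen so constituent signatures are linearly independent
    and the mean spectrum keeps a local maximum at each centre."""
    return ComponentBandModel(
        {
            "protein": [GaussianBand(1466.0, 16.0, 0.010), GaussianBand(2288.0, 12.0, 0.012)],
            "tdf": [GaussianBand(1466.0, 10.0, 0.016), GaussianBand(2322.0, 30.0, 0.006)],
            "starch": [GaussianBand(1466.0, 40.0, 0.0030), GaussianBand(1904.0, 22.0, 0.008)],
            "amylose": [GaussianBand(1904.0, 12.0, 0.0040), GaussianBand(2288.0, 35.0, 0.0012)],
            "oil": [GaussianBand(1196.0, 18.0, 0.015), GaussianBand(2322.0, 12.0, 0.018)],
            "water": [GaussianBand(1634.0, 20.0, 0.012)],
        }
    )


# germplasm trait ranges (% dry basis) used as generator defaults
DEFAULT_TRAIT_RANGES = {
    "protein_pct": (6.45, 14.63),
    "tdf_pct": (4.43, 5.84),
    "starch_pct": (65.0, 85.45),
    "amylose_pct": (5.23, 30.7),
    "oil_pct": (3.05, 7.00),
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the output.

    Trait ranges default to the wide germplasm ranges above; protein is tied
    to a Kjeldahl-style nitrogen column through ``nitrogen_factor`` (protein
    = %N x 5.95).  The scatter model (per-sample multiplicative slope and
    additive offset) produces exactly the artefacts MSC/SNV-DT remove.
    """

    n_samples: int = 500
    trait_ranges: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_RANGES))
    nitrogen_factor: float = 5.95
    moisture_range: tuple = (9.5, 11.9)
    central_fraction: float = 0.7  # Beta(2,2) mass; remainder uniform
    amylose_fraction_range: tuple = (0.07, 0.41)  # amylose as fraction of starch
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    baseline_offset: float = 0.2
    baseline_slope_per_nm: float = 2e-4
    baseline_curvature_per_nm2: float = 2e-8
    noise_sd: float = 3e-4
    wavelengths_nm: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name, (lo, hi) in self.trait_ranges.items():
            if not lo < hi:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")
        if not 0.0 <= self.central_fraction <= 1.0:
            raise ValueError("central_fraction must be in [0, 1]")

    def baseline(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        dx = wavelengths_nm - wavelengths_nm[0]
        return (
            self.baseline_offset
            + self.baseline_slope_per_nm * dx
            + self.baseline_curvature_per_nm2 * dx * dx
        )


def _mixed_marginal(rng: np.random.Generator, n: int, lo: float, hi: float,
                    central_fraction: float) -> np.ndarray:
    """70/30 (by default) mixture of scaled Beta(2,2) and Uniform over [lo, hi]:
    a hump in the middle plus mass at the extremes, mimicking a germplasm set
    curated for near-uniform coverage of the trait range."""
    central = rng.random(n) < central_fraction
    values = np.empty(n)
    values[central] = lo + (hi - lo) * rng.beta(2.0, 2.0, central.sum())
    values[~central] = rng.uniform(lo, hi, (~central).sum())
    return values


def simulate_compositions(config: SimulationConfig) -> ReferenceTable:
    """Draw per-sample compositions.

    Protein, TDF, starch and oil are drawn independently from the mixed
    marginal; amylose is a uniform fraction of each sample's starch, clipped
    to its own range (it is physically a starch sub-fraction, so amylose <=
    starch row-wise by construction).  A nitrogen column is emitted such
    that protein == nitrogen * nitrogen_factor exactly, and moisture is a
    uniform nuisance column.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    ranges = config.trait_ranges

    cols: dict[str, np.ndarray] = {}
    for trait in ("protein_pct", "tdf_pct", "starch_pct", "oil_pct"):
        lo, hi = ranges[trait]
        cols[trait] = _mixed_marginal(rng, n, lo, hi, config.central_fraction)

    am_lo, am_hi = ranges["amylose_pct"]
    f_lo, f_hi = config.amylose_fraction_range
    starch = cols["starch_pct"]
    if am_lo > f_hi * starch.max() or am_lo >= am_hi:
        raise ValueError(
            "infeasible amylose constraint: configured amylose range "
            f"({am_lo}, {am_hi}) cannot be reached as a fraction "
            f"{config.amylose_fraction_range} of starch"
        )
    amylose = np.clip(rng.uniform(f_lo, f_hi, n) * starch, am_lo, am_hi)
    cols["amylose_pct"] = np.minimum(amylose, starch)

    # exact Kjeldahl tie: regenerate protein from the rounded-trip nitrogen
    nitrogen = cols["protein_pct"] / config.nitrogen_factor
    cols["protein_pct"] = np.clip(
        nitrogen * config.nitrogen_factor, *ranges["protein_pct"]
    )
    cols["nitrogen_pct"] = cols["protein_pct"] / config.nitrogen_factor

    cols["moisture_pct"] = rng.uniform(*config.moisture_range, n)

    ids = [f"ACC{i+1:04d}" for i in range(n)]
    df = pd.DataFrame(cols, index=ids)
    order = ["protein_pct", "tdf_pct", "starch_pct", "amylose_pct", "oil_pct",
             "nitrogen_pct", "moisture_pct"]
    return ReferenceTable(df[order])


def simulate_spectra(
    compositions: ReferenceTable,
    bands: ComponentBandModel | None = None,
    config: SimulationConfig | None = None,
) -> SpectraSet:
    """Linear-mixing spectra for the given compositions.

    absorbance_i(L) = b_i * (baseline(L) + sum_k c_ik * s_k(L)) + a_i + eps,
    with b_i ~ N(1, slope_sd^2), a_i ~ N(0, offset_sd^2) and eps i.i.d.
    N(0, noise_sd^2).  With scatter and noise set to zero the spectra are
    exact linear functions of composition.
    """
    if compositions.traits.shape[0] == 0:
        raise ValueError("compositions table is empty")
    bands = bands if bands is not None else default_band_model()
    config = config if config is not None else SimulationConfig()
    wl = np.asarray(config.wavelengths_nm, dtype=float)
    bands.validate_grid(wl)

    missing = [
        c for c in bands.constituents()
        if CONSTITUENT_COLUMNS[c] not in compositions.traits.columns
    ]
    if missing:
        raise ValueError(
            f"composition table lacks columns for constituents: {missing}"
        )

    names = bands.constituents()
    sigs = np.vstack([bands.signature(c, wl) for c in names])  # (k, p)
    conc = np.column_stack(
        [compositions.values_for(CONSTITUENT_COLUMNS[c]) for c in names]
    )  # (n, k)
    n = conc.shape[0]

    # derive the spectral noise stream from a sub-seed so composition and
    # spectra generation stay independently reproducible
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    slope = 1.0 + config.scatter_slope_sd * rng.standard_normal(n)
    offset = config.scatter_offset_sd * rng.standard_normal(n)
    noise = config.noise_sd * rng.standard_normal((n, wl.size))

    clean = conc @ sigs + config.baseline(wl)[None, :]
    absorbance = slope[:, None] * clean + offset[:, None] + noise
    meta = {
        "instrument": "synthetic linear-mixing generator",
        "scan_count": 32,
        "seed": config.seed,
        "history": [],
    }
    return SpectraSet(list(compositions.sample_ids), wl, absorbance, meta)


def make_study_fixture(
    seed: int = 42,
    n_samples: int = 500,
    outdir=None,
    config: SimulationConfig | None = None,
) -> tuple[SpectraSet, ReferenceTable]:
    """The standard end-to-end fixture: ``n_samples`` accessions on the
    default grid at default noise/scatter.  If ``outdir`` is given, both
    objects are written there as ``spectra.csv`` / ``reference.csv``."""
    if config is None:
        config = SimulationConfig(n_samples=n_samples, seed=seed)
    else:
        config.n_samples = n_samples
        config.seed = seed
    reference = simulate_compositions(config)
    spectra = simulate_spectra(reference, default_band_model(), config)
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_spectra(spectra, outdir / "spectra.csv")
        write_reference(reference, outdir / "reference.csv")
    return spectra, reference
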