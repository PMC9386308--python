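"""Domain containers and file I/O for NIR spectra and reference composition data.

The two central objects are :class:`SpectraSet` (a wavelength grid plus a
sample x wavelength matrix of apparent absorbance, Log(1/R)) and
:class:`ReferenceTable` (per-sample trait values from wet chemistry).
Everything downstream — scatter correction, derivative treatments,
clustering, calibration — transforms one or both of these.

The canonical interchange format is a wide CSV: first column sample ID,
header row the wavelengths in nm.  JCAMP-DX is supported read-only for
plain AFFN ``##XYDATA=(X++(Y..Y))`` tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "ReferenceTable",
    "MathTreatment",
    "PairedData",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
    "join",
]

#: default instrument grid: 400-2,490 nm at 2 nm steps -> 1,046 points
DEFAULT_GRID = np.arange(400.0, 2492.0, 2.0)

#: trait columns the toolkit predicts, all percent dry basis
STANDARD_TRAITS = ("protein_pct", "tdf_pct", "starch_pct", "amylose_pct", "oil_pct")


@dataclass
class SpectraSet:
    """Absorbance spectra on a shared wavelength grid.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample identifiers (length n).
    wavelengths_nm
        Strictly increasing grid in nanometres (length p).
    absorbance
        (n, p) matrix of Log(1/R) values; must be finite.
    meta
        Free-form provenance.  ``meta["history"]`` is an append-only list of
        processing steps.
    """

    sample_ids: list[str]
    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValueError(f"duplicate sample ID {dup!r}")
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{n} spectra but {len(self.sample_ids)} sample IDs"
            )
        if p != self.wavelengths_nm.size:
            raise ValueError(
                f"{p} absorbance columns but {self.wavelengths_nm.size} wavelengths"
            )
        if self.wavelengths_nm.size > 1 and not np.all(
            np.diff(self.wavelengths_nm) > 0
        ):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        self.meta.setdefault("history", [])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavelengths(self) -> int:
        return int(self.wavelengths_nm.size)

    def with_absorbance(
        self,
        absorbance: np.ndarray,
        wavelengths_nm: np.ndarray | None = None,
        history_entry: str | None = None,
    ) -> "SpectraSet":
        """Return a copy with a new matrix (and optionally a trimmed grid),
        appending ``history_entry`` to the processing history."""
        meta = {k: v for k, v in self.meta.items() if k != "history"}
        meta["history"] = list(self.meta.get("history", []))
        if history_entry is not None:
            meta["history"].append(history_entry)
        wl = self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm
        return SpectraSet(list(self.sample_ids), np.array(wl), np.array(absorbance), meta)

    def subset(self, ids: list[str]) -> "SpectraSet":
        """Row subset in the given ID order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[str(s)] for s in ids]
        except KeyError as exc:
            raise KeyError(f"unknown sample ID {exc.args[0]!r}") from None
        meta = {k: v for k, v in self.meta.items() if k != "history"}
        meta["history"] = list(self.meta.get("history", []))
        return SpectraSet(
            [str(s) for s in ids],
            self.wavelengths_nm.copy(),
            self.absorbance[rows].copy(),
            meta,
        )


@dataclass
class ReferenceTable:
    """Per-sample trait values (the y side of calibration).

    ``traits`` is a DataFrame indexed by sample ID with one column per trait;
    ``units`` records the unit string for each column (``"% dry basis"`` for
    the standard traits, ``"unknown"`` for carried-through extras).
    """

    traits: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traits = self.traits.copy()
        self.traits.index = self.traits.index.astype(str)
        if self.traits.index.has_duplicates:
            dup = self.traits.index[self.traits.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r}")
        values = self.traits.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = self.traits.columns[np.argmax(~np.isfinite(values).all(axis=0))]
            raise ValueError(f"non-finite values in trait column {bad!r}")
        if (values < 0).any():
            bad = self.traits.columns[np.argmax((values < 0).any(axis=0))]
            raise ValueError(f"negative values in trait column {bad!r}")
        for col in self.traits.columns:
            self.units.setdefault(
                col, "% dry basis" if col in STANDARD_TRAITS or col == "nitrogen_pct" else "unknown"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.traits.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def values_for(self, trait: str) -> np.ndarray:
        if trait not in self.traits.columns:
            raise KeyError(f"trait {trait!r} not present (have {self.trait_names})")
        return self.traits[trait].to_numpy(dtype=float)

    def subset(self, ids: list[str]) -> "ReferenceTable":
        ids = [str(s) for s in ids]
        missing = [s for s in ids if s not in self.traits.index]
        if missing:
            raise KeyError(f"unknown sample IDs {missing[:3]}")
        return ReferenceTable(self.traits.loc[ids], dict(self.units))


@dataclass(frozen=True)
class MathTreatment:
    """WinISI-style four-integer math-treatment code ``d,g,s1,s2``.

    derivative order ``d``; gap ``g`` in grid points for the centred
    difference; ``s1``/``s2`` first and second moving-average smoothing
    widths in points (1 = no smoothing).
    """

    derivative: int
    gap: int
    smooth1: int
    smooth2: int

    def __post_init__(self) -> None:
        d, g, s1, s2 = self.derivative, self.gap, self.smooth1, self.smooth2
        if d < 0:
            raise ValueError(f"derivative order must be >= 0, got {d}")
        if g < 0 or s1 < 1 or s2 < 1:
            raise ValueError(f"invalid treatment {self.code()}")
        if d >= 1 and (g == 0 or g % 2 != 0):
            raise ValueError(
                f"gap must be a positive even point count when derivative >= 1, got {g}"
            )

    def code(self) -> str:
        return f"{self.derivative},{self.gap},{self.smooth1},{self.smooth2}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code()


@dataclass
class PairedData:
    """Inner join of a SpectraSet and a ReferenceTable on sample ID."""

    spectra: SpectraSet
    reference: ReferenceTable
    unmatched_spectra: list[str]
    unmatched_reference: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return self.spectra.sample_ids

    @property
    def n_samples(self) -> int:
        return self.spectra.n_samples


def _first_duplicate(items) -> str:
    seen = set()
    for s in items:
        if s in seen:
            return s
        seen.add(s)
    return ""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_spectra(path, format: str = "csv") -> SpectraSet:
    """Read spectra from a wide CSV or a JCAMP-DX file.

    CSV layout: first column sample ID, header row wavelengths in nm.
    Non-uniform wavelength spacing triggers a warning, not an error.
    """
    if format == "csv":
        spectra = _read_spectra_csv(path)
    elif format in ("jcamp-dx", "jcamp", "jdx"):
        spectra = _read_spectra_jcamp(path)
    else:
        raise ValueError(f"unknown spectra format {format!r}")
    wl = spectra.wavelengths_nm
    if wl.size > 2:
        steps = np.diff(wl)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            warnings.warn(
                f"non-uniform wavelength spacing in {path}", stacklevel=2
            )
    return spectra


def _read_spectra_csv(path) -> SpectraSet:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty spectra file {path}")
    try:
        wavelengths = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header in {path}: {exc}") from None
    matrix = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            matrix[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"non-numeric absorbance at sample {bad!r}, wavelength {col}"
            ) from None
    return SpectraSet(
        [str(s) for s in df.index],
        wavelengths,
        matrix,
        meta={"source": str(path), "history": []},
    )


def _read_spectra_jcamp(path) -> SpectraSet:
    """Minimal JCAMP-DX reader: AFFN ``##XYDATA=(X++(Y..Y))`` blocks only.

    Each block becomes one sample; ``##TITLE`` names the sample.  The grid is
    reconstructed from FIRSTX/LASTX/NPOINTS (or DELTAX).  Compressed
    (ASDF/DIF-DUP) ordinates are not supported.
    """
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()

    blocks: list[tuple[str, dict, list[float]]] = []
    header: dict = {}
    title = "spectrum"
    in_xy = False
    ys: list[float] = []

    def flush():
        nonlocal ys, header
        if ys:
            blocks.append((title, dict(header), ys))
        ys = []

    for raw in lines:
        line = raw.strip()
        if line.startswith("##"):
            if in_xy:
                flush()
                in_xy = False
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "TITLE":
                title = value or title
                header = {}
            elif key in ("XFACTOR", "YFACTOR", "FIRSTX", "LASTX", "DELTAX", "NPOINTS"):
                header[key] = float(value)
            elif key == "XYDATA":
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise ValueError(
                        f"unsupported XYDATA form {value!r}; only (X++(Y..Y)) is read"
                    )
                in_xy = True
        elif in_xy and line:
            try:
                numbers = [float(tok) for tok in line.replace(",", " ").split()]
            except ValueError:
                raise ValueError(
                    f"non-numeric token in XYDATA line {line!r}; "
                    "compressed JCAMP ordinates are not supported"
                ) from None
            ys.extend(numbers[1:])  # first number on each line is the abscissa
    if in_xy:
        flush()
    if not blocks:
        raise ValueError(f"no XYDATA blocks found in {path}")

    ids, rows, grid = [], [], None
    for name, hdr, y in blocks:
        yfac = hdr.get("YFACTOR", 1.0)
        xfac = hdr.get("XFACTOR", 1.0)
        n = int(hdr.get("NPOINTS", len(y)))
        if n != len(y):
            raise ValueError(
                f"JCAMP block {name!r}: NPOINTS={n} but {len(y)} ordinates read"
            )
        firstx = hdr.get("FIRSTX", 0.0) * xfac
        if "DELTAX" in hdr:
            step = hdr["DELTAX"] * xfac
        elif "LASTX" in hdr and n > 1:
            step = (hdr["LASTX"] * xfac - firstx) / (n - 1)
        else:
            step = 1.0
        wl = firstx + step * np.arange(n)
        if grid is None:
            grid = wl
        elif wl.size != grid.size or not np.allclose(wl, grid):
            raise ValueError("JCAMP blocks have differing wavelength grids")
        ids.append(name)
        rows.append(np.asarray(y, dtype=float) * yfac)

    # de-duplicate titles so they can serve as sample IDs
    seen: dict[str, int] = {}
    uniq = []
    for name in ids:
        if name in seen:
            seen[name] += 1
            uniq.append(f"{name}_{seen[name]}")
        else:
            seen[name] = 0
            uniq.append(name)
    return SpectraSet(uniq, grid, np.vstack(rows), meta={"source": str(path), "history": []})


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write a SpectraSet as wide CSV (UTF-8, '.' decimal, 12 significant digits)."""
    df = pd.DataFrame(
        spectra.absorbance,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[f"{w:g}" for w in spectra.wavelengths_nm],
    )
    df.to_csv(path, float_format="%.12g", encoding="utf-8")


def read_reference(path) -> ReferenceTable:
    """Read a reference composition CSV (first column sample ID)."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"no trait columns in {path}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            bad = df.index[numeric.isna()][0]
            raise ValueError(
                f"non-numeric or missing value in trait column {col!r} at sample {bad!r}"
            )
        df[col] = numeric
    return ReferenceTable(df)


def write_reference(reference: ReferenceTable, path) -> None:
    df = reference.traits.copy()
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.12g", encoding="utf-8")


def join(spectra: SpectraSet, reference: ReferenceTable) -> PairedData:
    """Inner join on sample ID, preserving spectra order.

    Raises on an empty intersection; counts of unmatched IDs on both sides
    are reported on the returned object.
    """
    ref_ids = set(reference.sample_ids)
    matched = [s for s in spectra.sample_ids if s in ref_ids]
    if not matched:
        raise ValueError("no sample IDs in common between spectra and reference")
    unmatched_spec = [s for s in spectra.sample_ids if s not in ref_ids]
    spec_ids = set(spectra.sample_ids)
    unmatched_ref = [s for s in reference.sample_ids if s not in spec_ids]
    return PairedData(
        spectra=spectra.subset(matched),
        reference=reference.subset(matched),
        unmatched_spectra=unmatched_spec,
        unmatched_reference=unmatched_ref,
    )
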