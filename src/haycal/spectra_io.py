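"""Reading, writing and aligning NIR spectral matrices and reference chemistry.

Spectra travel as wide CSV: first column the sample ID, remaining columns one
wavelength each (headers in nm, an ``nm`` suffix is tolerated).  Reference
chemistry is a plain CSV of sample ID x analyte.  Both are held in light
dataclasses wrapping numpy arrays; pandas does the parsing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default instrument grid: 680-2,500 nm scanned at 2 nm intervals.
DEFAULT_GRID_START = 680.0
DEFAULT_GRID_STOP = 2500.0
DEFAULT_GRID_STEP = 2.0

#: Analytes the reference tables recognise (dry matter, crude protein,
#: neutral/acid detergent fiber, in vitro dry matter digestibility).
KNOWN_ANALYTES = ("DM", "CP", "NDF", "ADF", "IVDMD")

PREP_STATES = ("ground", "unground")


class SpectraError(ValueError):
    """Base class for spectral-data integrity problems."""


class GridError(SpectraError):
    """Wavelength grid is non-numeric or not strictly increasing."""


class IntegrityError(SpectraError):
    """Duplicate IDs, non-finite values, or shape mismatches."""


class AlignmentError(SpectraError):
    """Spectra and reference tables share no sample IDs."""


def default_grid() -> np.ndarray:
    """The 911-channel default wavelength grid in nm."""
    n = int(round((DEFAULT_GRID_STOP - DEFAULT_GRID_START) / DEFAULT_GRID_STEP)) + 1
    return DEFAULT_GRID_START + DEFAULT_GRID_STEP * np.arange(n)


@dataclass
class SpectrumSet:
    """A sample x wavelength matrix of log(1/R) absorbance.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per matrix row.
    wavelengths_nm : ndarray
        Strictly increasing wavelength grid in nanometres.
    absorbance : ndarray, shape (n_samples, n_wavelengths)
        log(1/R) values; must be finite.
    prep_state : list of str, optional
        Per-sample preparation label, ``"ground"`` or ``"unground"``.
    meta : dict
        Free-form provenance (instrument, scan date, treatment applied...).
    """

    sample_ids: list[str]
    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    prep_state: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise IntegrityError(f"duplicate sample IDs: {dupes}")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise GridError("wavelength grid must be strictly increasing")
        if self.absorbance.shape != (len(self.sample_ids), self.wavelengths_nm.size):
            raise IntegrityError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavelengths_nm.size} channels"
            )
        if not np.all(np.isfinite(self.absorbance)):
            i, j = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise IntegrityError(
                f"non-finite absorbance at sample {self.sample_ids[i]!r}, "
                f"wavelength {self.wavelengths_nm[j]:g} nm"
            )
        if self.prep_state is not None:
            bad = set(self.prep_state) - set(PREP_STATES)
            if bad:
                raise IntegrityError(f"unknown prep_state labels: {sorted(bad)}")
            if len(self.prep_state) != len(self.sample_ids):
                raise IntegrityError("prep_state length does not match sample count")
        if not self.is_default_grid() and "treatment" not in self.meta:
            logger.warning(
                "wavelength grid differs from the default 680-2500 nm / 2 nm "
                "instrument grid (%d channels, %g-%g nm)",
                self.n_channels, self.wavelengths_nm[0], self.wavelengths_nm[-1],
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_channels(self) -> int:
        return int(self.wavelengths_nm.size)

    def is_default_grid(self) -> bool:
        g = default_grid()
        return self.wavelengths_nm.size == g.size and np.allclose(self.wavelengths_nm, g)

    def subset(self, indices: np.ndarray | list[int]) -> "SpectrumSet":
        """Row subset in the given order."""
        idx = np.asarray(indices, dtype=int)
        return SpectrumSet(
            sample_ids=[self.sample_ids[i] for i in idx],
            wavelengths_nm=self.wavelengths_nm.copy(),
            absorbance=self.absorbance[idx].copy(),
            prep_state=[self.prep_state[i] for i in idx] if self.prep_state else None,
            meta=dict(self.meta),
        )


@dataclass
class ReferenceTable:
    """Laboratory reference values, sample x analyte.

    ``values`` may contain NaN for missing determinations; those samples are
    excluded analyte-wise downstream.  Units are ``"g/kg"`` or ``"percent"``
    per analyte; conversion between them is a factor of exactly 10.
    """

    sample_ids: list[str]
    analytes: list[str]
    values: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise IntegrityError(f"duplicate sample IDs in reference table: {dupes}")
        if self.values.shape != (len(self.sample_ids), len(self.analytes)):
            raise IntegrityError("reference value matrix shape mismatch")
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise IntegrityError("reference values must be non-negative")
        for a in self.analytes:
            self.units.setdefault(a, "g/kg")
            if self.units[a] not in ("g/kg", "percent"):
                raise IntegrityError(f"unknown unit {self.units[a]!r} for {a}")
        self._check_bounds()

    def _check_bounds(self) -> None:
        for name, cap_gkg in (("DM", 1000.0), ("IVDMD", 1000.0)):
            if name in self.analytes:
                col = self.column(name)
                cap = cap_gkg if self.units[name] == "g/kg" else cap_gkg / 10.0
                if np.nanmax(col) > cap + 1e-9:
                    raise IntegrityError(
                        f"{name} exceeds {cap:g} {self.units[name]}"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, analyte: str, unit: str | None = None) -> np.ndarray:
        """Values for one analyte, optionally converted (g/kg <-> percent)."""
        if analyte not in self.analytes:
            raise KeyError(f"analyte {analyte!r} not in table {self.analytes}")
        col = self.values[:, self.analytes.index(analyte)].copy()
        if unit is None or unit == self.units[analyte]:
            return col
        if (self.units[analyte], unit) == ("g/kg", "percent"):
            return col / 10.0
        if (self.units[analyte], unit) == ("percent", "g/kg"):
            return col * 10.0
        raise IntegrityError(f"cannot convert {self.units[analyte]} -> {unit}")

    def subset(self, indices: np.ndarray | list[int]) -> "ReferenceTable":
        idx = np.asarray(indices, dtype=int)
        return ReferenceTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            analytes=list(self.analytes),
            values=self.values[idx].copy(),
            units=dict(self.units),
        )


@dataclass
class AlignedDataset:
    """Spectra and reference chemistry restricted to shared IDs, co-ordered."""

    spectra: SpectrumSet
    reference: ReferenceTable

    def __post_init__(self) -> None:
        if self.spectra.sample_ids != self.reference.sample_ids:
            raise AlignmentError("components of an AlignedDataset must share ID order")
        if self.spectra.n_samples == 0:
            raise AlignmentError("empty dataset")

    @property
    def n_samples(self) -> int:
        return self.spectra.n_samples

    @property
    def sample_ids(self) -> list[str]:
        return self.spectra.sample_ids

    def subset(self, indices: np.ndarray | list[int]) -> "AlignedDataset":
        return AlignedDataset(self.spectra.subset(indices), self.reference.subset(indices))

    def analyte_view(self, analyte: str, unit: str = "percent") -> "tuple[AlignedDataset, np.ndarray]":
        """Drop samples with a missing value for ``analyte``; return (subset, y)."""
        y = self.reference.column(analyte, unit=unit)
        keep = np.flatnonzero(np.isfinite(y))
        if keep.size == 0:
            raise AlignmentError(f"no finite reference values for {analyte}")
        if keep.size == self.n_samples:
            return self, y
        return self.subset(keep), y[keep]


def _parse_wavelength(header: str) -> float:
    txt = header.strip().lower().removesuffix("nm").strip().rstrip("_")
    try:
        return float(txt)
    except ValueError:
        raise GridError(f"column header {header!r} is not a wavelength in nm") from None


def read_spectra(path, value_kind: str = "absorbance") -> SpectrumSet:
    """Read a wide spectral CSV (ID column first, wavelength columns after).

    Parameters
    ----------
    path : path-like
    value_kind : {"absorbance", "reflectance"}
        ``"reflectance"`` converts cells to log10(1/R) on read.
    """
    if value_kind not in ("absorbance", "reflectance"):
        raise ValueError(f"value_kind must be absorbance|reflectance, got {value_kind!r}")
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise GridError("spectral CSV needs an ID column plus wavelength columns")
    id_col = df.columns[0]
    prep = None
    if "prep_state" in df.columns[1:]:
        prep = [str(v) for v in df["prep_state"]]
        df = df.drop(columns=["prep_state"])
    wavelengths = np.array([_parse_wavelength(c) for c in df.columns[1:]])
    mat = df.iloc[:, 1:].to_numpy()
    if mat.dtype == object or not np.issubdtype(mat.dtype, np.number):
        for i in range(df.shape[0]):
            for j, c in enumerate(df.columns[1:]):
                try:
                    float(df.iloc[i, j + 1])
                except (TypeError, ValueError):
                    raise SpectraError(
                        f"non-numeric cell at row {df.iloc[i][id_col]!r}, column {c!r}"
                    ) from None
    mat = mat.astype(float)
    if value_kind == "reflectance":
        from .preprocess import absorbance_transform

        mat = absorbance_transform(mat, base="log10")
    return SpectrumSet(
        sample_ids=[str(s) for s in df[id_col]],
        wavelengths_nm=wavelengths,
        absorbance=mat,
        prep_state=prep,
    )


def write_spectra(spectra: SpectrumSet, path) -> None:
    """Write a SpectrumSet back to wide CSV (absorbance, full precision)."""
    df = pd.DataFrame(
        spectra.absorbance,
        columns=[f"{w:g}" for w in spectra.wavelengths_nm],
    )
    df.insert(0, "sample_id", spectra.sample_ids)
    if spectra.prep_state is not None:
        df.insert(1, "prep_state", spectra.prep_state)
    df.to_csv(path, index=False, float_format="%.12g")


def read_reference(path, units: dict[str, str] | None = None) -> ReferenceTable:
    """Read a reference-chemistry CSV (ID column plus analyte columns).

    Unknown columns are ignored with a warning; empty analyte columns are
    dropped.  ``units`` maps analyte -> {"g/kg", "percent"}; a per-column
    unit may also be declared in the header as e.g. ``CP (percent)``.
    """
    df = pd.read_csv(path, dtype={0: str})
    id_col = df.columns[0]
    units = dict(units or {})
    keep: list[str] = []
    rename: dict[str, str] = {}
    for c in df.columns[1:]:
        name = c.strip()
        unit = None
        if "(" in name and name.endswith(")"):
            name, unit = name[: name.index("(")].strip(), name[name.index("(") + 1 : -1].strip()
        if name.upper() in KNOWN_ANALYTES:
            canonical = name.upper()
            keep.append(c)
            rename[c] = canonical
            if unit:
                units.setdefault(canonical, unit)
        else:
            logger.warning("ignoring unrecognised reference column %r", c)
    if not keep:
        raise IntegrityError(
            f"no recognised analyte column among {list(df.columns[1:])}; "
            f"expected a subset of {KNOWN_ANALYTES}"
        )
    sub = df[keep].rename(columns=rename).astype(float)
    empty = [c for c in sub.columns if sub[c].isna().all()]
    if empty:
        logger.warning("dropping empty analyte column(s): %s", empty)
        sub = sub.drop(columns=empty)
        if sub.shape[1] == 0:
            raise IntegrityError("all analyte columns are empty")
    return ReferenceTable(
        sample_ids=[str(s) for s in df[id_col]],
        analytes=list(sub.columns),
        values=sub.to_numpy(),
        units={a: units.get(a, "g/kg") for a in sub.columns},
    )


def write_reference(table: ReferenceTable, path) -> None:
    df = pd.DataFrame(table.values, columns=[f"{a} ({table.units[a]})" for a in table.analytes])
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, index=False, float_format="%.10g")


def align(spectra: SpectrumSet, reference: ReferenceTable) -> AlignedDataset:
    """Restrict both inputs to the sample-ID intersection, in spectra order."""
    ref_pos = {s: i for i, s in enumerate(reference.sample_ids)}
    spec_idx = [i for i, s in enumerate(spectra.sample_ids) if s in ref_pos]
    if not spec_idx:
        raise AlignmentError("spectra and reference tables share no sample IDs")
    ref_idx = [ref_pos[spectra.sample_ids[i]] for i in spec_idx]
    logger.info(
        "aligned %d of %d spectra with %d reference rows",
        len(spec_idx), spectra.n_samples, reference.n_samples,
    )
    return AlignedDataset(spectra.subset(spec_idx), reference.subset(ref_idx))
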