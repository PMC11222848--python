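"""Spectral pretreatments: log(1/R), SNV, detrend and gap-segment derivatives.

NIRS software encodes a derivative recipe as a short "math treatment" code —
derivative order, gap, smoothing — e.g. ``1,4,4``.  The pipeline applied here
is the conventional one: the spectrum is already in log(1/R) absorbance, then
scatter correction (standard normal variate, optionally followed by a
polynomial detrend), then a boxcar smooth and the gap difference operator
applied ``d`` times.  Window margins are dropped rather than padded, so no
fabricated boundary values reach the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra_io import SpectrumSet


class PreprocessError(ValueError):
    pass


class DomainError(PreprocessError):
    """Input values outside the operator's mathematical domain."""


class DegenerateSpectrumError(PreprocessError):
    """Constant spectrum cannot be SNV-normalised."""


class LengthError(PreprocessError):
    """Spectrum too short for the requested window/derivative support."""


@dataclass(frozen=True)
class MathTreatment:
    """A (derivative order, gap, smoothing) preprocessing code.

    ``derivative_order`` 0 means no derivative (and no smoothing).  ``gap``
    and ``smoothing`` are window widths in channels.  ``smoothing2`` is a
    second boxcar pass applied after the derivative, accepted for
    compatibility with four-number codes; the default 1 is a no-op.
    ``scatter_correction`` selects none, SNV alone, or SNV followed by a
    quadratic detrend (the default, matching common practice for hay).
    """

    derivative_order: int = 0
    gap: int = 1
    smoothing: int = 1
    smoothing2: int = 1
    scatter_correction: str = "snv_detrend"
    detrend_order: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.derivative_order <= 4:
            raise PreprocessError(f"derivative order must be 0-4, got {self.derivative_order}")
        if self.gap < 1 or self.smoothing < 1 or self.smoothing2 < 1:
            raise PreprocessError("gap and smoothing widths must be >= 1")
        if self.scatter_correction not in ("none", "snv", "snv_detrend"):
            raise PreprocessError(f"unknown scatter correction {self.scatter_correction!r}")
        if self.detrend_order < 0:
            raise PreprocessError("detrend polynomial order must be >= 0")

    @classmethod
    def from_string(cls, code: str, scatter_correction: str = "snv_detrend") -> "MathTreatment":
        """Parse ``"d,g,s"`` or ``"d,g,s,s2"`` notation, e.g. ``"3,16,16"``."""
        parts = [int(p) for p in code.replace(";", ",").split(",") if p.strip()]
        if len(parts) == 3:
            d, g, s = parts
            s2 = 1
        elif len(parts) == 4:
            d, g, s, s2 = parts
        else:
            raise PreprocessError(f"treatment code {code!r} needs 3 or 4 integers")
        return cls(d, g, s, s2, scatter_correction=scatter_correction)

    def __str__(self) -> str:
        base = f"{self.derivative_order},{self.gap},{self.smoothing}"
        if self.smoothing2 != 1:
            base += f",{self.smoothing2}"
        return base


def default_treatments(scatter_correction: str = "snv_detrend") -> list[MathTreatment]:
    """The conventional 12-treatment grid: d in 1..4 x (g,s) in {4,8,16}."""
    return [
        MathTreatment(d, g, g, scatter_correction=scatter_correction)
        for d in (1, 2, 3, 4)
        for g in (4, 8, 16)
    ]


def absorbance_transform(reflectance: np.ndarray, base: str = "log10") -> np.ndarray:
    """Element-wise log(1/R) in the chosen base ("log10" or "natural").

    Reflectance must lie in (0, 1]; R = 1 maps to absorbance 0.
    """
    r = np.asarray(reflectance, dtype=float)
    bad = (r <= 0) | (r > 1)
    if np.any(bad):
        idx = tuple(np.argwhere(bad)[0])
        raise DomainError(
            f"reflectance must be in (0, 1]; offending value {r[idx]!r} at index {idx}"
        )
    if base == "log10":
        return -np.log10(r)
    if base == "natural":
        return -np.log(r)
    raise PreprocessError(f"base must be log10|natural, got {base!r}")


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum to unit SD.

    Operates on the last axis; sample SD uses ddof=1.  Removes per-spectrum
    multiplicative scatter and additive offsets.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.shape[-1] < 2:
        raise PreprocessError("SNV needs spectra of length >= 2")
    sd = x.std(axis=-1, keepdims=True, ddof=1)
    if np.any(sd <= 0):
        raise DegenerateSpectrumError("constant spectrum has zero variance; cannot SNV-normalise")
    return (x - x.mean(axis=-1, keepdims=True)) / sd


def detrend(
    spectrum: np.ndarray,
    wavelengths: np.ndarray,
    poly_order: int = 2,
) -> np.ndarray:
    """Residual of a least-squares polynomial baseline fit on wavelength.

    The returned residual is orthogonal to the polynomial basis.  Wavelengths
    are rescaled to [-1, 1] internally for conditioning; the residual is
    unaffected by that reparametrisation.
    """
    if poly_order < 0:
        raise PreprocessError("poly_order must be >= 0")
    x = np.asarray(spectrum, dtype=float)
    w = np.asarray(wavelengths, dtype=float)
    if x.shape[-1] != w.size:
        raise PreprocessError("spectrum and wavelength lengths differ")
    if x.shape[-1] <= poly_order + 1:
        raise LengthError(f"need length > {poly_order + 1} for order-{poly_order} detrend")
    u = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0 if w[-1] > w[0] else w * 0.0
    basis = np.polynomial.polynomial.polyvander(u, poly_order)  # (n, order+1)
    coef, *_ = np.linalg.lstsq(basis, np.atleast_2d(x).T, rcond=None)
    resid = np.atleast_2d(x).T - basis @ coef
    return resid.T.reshape(x.shape)


def _boxcar(x: np.ndarray, width: int) -> np.ndarray:
    """Valid-mode running mean over the last axis."""
    if width == 1:
        return np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < width:
        raise LengthError(f"spectrum length {n} shorter than smoothing window {width}")
    c = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    return (c[..., width:] - c[..., :-width]) / width


def _gap_diff(x: np.ndarray, gap: int) -> np.ndarray:
    """One application of the gap difference: x[i + g] - x[i] (span g, centred).

    For even g the implied offsets around the centre are symmetric (g/2 each
    side); for odd g they are floor(g/2) and ceil(g/2).
    """
    n = x.shape[-1]
    if n <= gap:
        raise LengthError(f"spectrum length {n} too short for gap {gap}")
    return x[..., gap:] - x[..., :-gap]


def gap_derivative(
    spectrum: np.ndarray,
    d: int,
    gap: int,
    smoothing: int,
    smoothing2: int = 1,
) -> np.ndarray:
    """Gap-segment derivative: boxcar smooth, then the gap difference d times.

    Works on the last axis; output is shorter than the input by
    ``smoothing - 1 + d * gap + smoothing2 - 1`` channels (margins dropped).
    Raises :class:`LengthError` if the input cannot support that margin.
    """
    if d < 1:
        raise PreprocessError("derivative order must be >= 1 for gap_derivative")
    x = np.asarray(spectrum, dtype=float)
    required = smoothing + d * gap + smoothing2 - 1
    if x.shape[-1] < required:
        raise LengthError(
            f"gap derivative (d={d}, gap={gap}, smoothing={smoothing}) needs at "
            f"least {required} channels, got {x.shape[-1]}"
        )
    out = _boxcar(x, smoothing)
    for _ in range(d):
        out = _gap_diff(out, gap)
    return _boxcar(out, smoothing2)


def gap_derivative_wavelengths(
    wavelengths: np.ndarray, d: int, gap: int, smoothing: int, smoothing2: int = 1
) -> np.ndarray:
    """Output wavelength positions for :func:`gap_derivative`.

    Each smoothing window maps to its mean wavelength and each gap difference
    to the midpoint of its two support points, so the bookkeeping follows the
    value pipeline exactly.
    """
    w = _boxcar(np.asarray(wavelengths, dtype=float), smoothing)
    for _ in range(d):
        w = (w[gap:] + w[:-gap]) / 2.0
    return _boxcar(w, smoothing2)


def apply_treatment(spectra: SpectrumSet, t: MathTreatment) -> SpectrumSet:
    """Apply a full math treatment to every spectrum of a SpectrumSet.

    Order: SNV -> detrend (per scatter_correction) -> gap-segment derivative.
    The wavelength grid is trimmed for the margin the windows consume.
    """
    x = spectra.absorbance
    w = spectra.wavelengths_nm
    if t.scatter_correction in ("snv", "snv_detrend"):
        x = snv(x)
    if t.scatter_correction == "snv_detrend":
        x = detrend(x, w, poly_order=t.detrend_order)
    if t.derivative_order >= 1:
        x = gap_derivative(x, t.derivative_order, t.gap, t.smoothing, t.smoothing2)
        w = gap_derivative_wavelengths(w, t.derivative_order, t.gap, t.smoothing, t.smoothing2)
    meta = dict(spectra.meta)
    meta["treatment"] = str(t)
    meta["scatter_correction"] = t.scatter_correction
    return SpectrumSet(
        sample_ids=list(spectra.sample_ids),
        wavelengths_nm=w,
        absorbance=x,
        prep_state=list(spectra.prep_state) if spectra.prep_state else None,
        meta=meta,
    )
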