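"""Synthetic hay NIR datasets: reference chemistry plus Beer–Lambert-style
spectra with prep-state-dependent scatter.

The generator emulates the two hay populations the calibration workflow is
meant for — alfalfa (high protein, variable quality) and timothy (low
protein, high fiber) — using published-style descriptive statistics
(mean/SD/min/max in g/kg) for DM, CP, NDF, ADF and IVDMD.  Crude protein is
produced as N x 6.25 from a latent nitrogen draw.  Clean absorbance is a
smooth baseline plus a sum of Gaussian absorption bands weighted by
constituent mass fractions, with water bands near 1,450/1,940 nm, protein
N–H bands near 2,050/2,180 nm, and carbohydrate/cellulose bands near
1,200/2,270 nm.

Sample presentation is modelled as a distortion layer whose magnitude
depends on preparation: ground (1-mm milled, uniform packing) versus
unground (<10 cm pieces, loose packing).  Four scatter components are drawn
per sample: a multiplicative factor (1 + a), an additive offset b, a linear
tilt c·u, and a *structured* smooth random baseline (white noise convolved
to a ~60 nm correlation length).  The first three are what standard scatter
corrections (SNV, low-order detrend) remove; the structured component
emulates packing-density heterogeneity that neither those corrections nor a
finite-factor linear model can remove, and is what actually degrades
unground calibrations.  I.i.d. channel noise is added last.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra_io import (
    AlignedDataset,
    ReferenceTable,
    SpectrumSet,
    default_grid,
)


class SimulationError(ValueError):
    pass


#: Descriptive statistics (g/kg; mean, SD, min, max) the two populations target.
SPECIES_STATS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "alfalfa": {
        "DM": (918.0, 12.4, 828.0, 955.0),
        "CP": (155.0, 26.3, 85.0, 212.0),
        "NDF": (502.0, 37.1, 351.0, 616.0),
        "ADF": (349.0, 35.8, 230.0, 492.0),
        "IVDMD": (692.0, 42.1, 526.0, 784.0),
    },
    "timothy": {
        "DM": (922.0, 14.6, 870.0, 950.0),
        "CP": (53.8, 16.6, 22.0, 115.0),
        "NDF": (674.0, 17.6, 620.0, 725.0),
        "ADF": (383.0, 21.5, 237.0, 434.0),
        "IVDMD": (673.0, 17.6, 455.0, 703.0),
    },
}

#: Gaussian absorption bands (centre nm, width nm, loading per mass fraction).
#: Moisture (1000 - DM) carries the water O–H bands; protein the N–H bands;
#: the fiber fractions the C–H/O–H carbohydrate bands.  Digestibility loads
#: negatively on the cellulose/lignin region near 2,270 nm (more digestible
#: material has less lignified cell wall absorbing there).
DEFAULT_BAND_LIBRARY: dict[str, list[tuple[float, float, float]]] = {
    "MOISTURE": [(1190.0, 45.0, 0.9), (1450.0, 40.0, 2.2), (1940.0, 55.0, 2.8)],
    "CP": [(1510.0, 35.0, 0.8), (2054.0, 40.0, 1.6), (2180.0, 45.0, 1.4)],
    "NDF": [(1210.0, 60.0, 0.55), (1725.0, 45.0, 0.35), (2270.0, 50.0, 0.5)],
    "ADF": [(1680.0, 55.0, 0.30), (2270.0, 45.0, 0.45), (2330.0, 40.0, 0.35)],
    "IVDMD": [(1672.0, 60.0, -0.20), (2270.0, 50.0, -0.35)],
}

#: Latent correlation structure: one "fiber" factor drives NDF/ADF up and
#: CP/IVDMD down, giving NDF–ADF ≈ 0.85, CP–NDF ≈ −0.41, IVDMD–NDF ≈ −0.72.
_FIBER_LOADING = {"NDF": 0.92, "ADF": 0.92, "CP": -0.45, "IVDMD": -0.78, "DM": 0.0}


@dataclass(frozen=True)
class ScatterParams:
    """Per-prep-state distortion magnitudes (all SDs, absorbance units
    except the dimensionless multiplicative term)."""

    mult_sd: float = 0.02          # per-sample scale (1 + a)
    offset_sd: float = 0.01        # additive baseline offset
    tilt_sd: float = 0.01          # additive linear tilt across the grid
    structured_sd: float = 0.004   # smooth structured baseline, marginal SD

    def __post_init__(self) -> None:
        for name in ("mult_sd", "offset_sd", "tilt_sd", "structured_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")


DEFAULT_SCATTER: dict[str, ScatterParams] = {
    "ground": ScatterParams(0.02, 0.01, 0.01, 0.004),
    "unground": ScatterParams(0.08, 0.05, 0.05, 0.04),
}

#: Correlation length (nm) of the structured smooth scatter component.
_STRUCT_CORR_NM = 60.0


@dataclass
class GeneratorConfig:
    species: str = "alfalfa"
    n_samples: int = 200
    prep_state: str = "ground"
    analyte_stats: dict[str, tuple[float, float, float, float]] | None = None
    band_library: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_BAND_LIBRARY.items()}
    )
    scatter: dict[str, ScatterParams] = field(
        default_factory=lambda: dict(DEFAULT_SCATTER)
    )
    noise_sd: float = 0.0005
    seed: int = 0
    wavelengths_nm: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        if self.species not in SPECIES_STATS and self.analyte_stats is None:
            raise SimulationError(f"unknown species {self.species!r} and no analyte_stats")
        if self.n_samples < 10:
            raise SimulationError("n_samples must be >= 10")
        if self.prep_state not in ("ground", "unground"):
            raise SimulationError(f"prep_state must be ground|unground, got {self.prep_state!r}")
        if not self.band_library:
            raise SimulationError("band library must not be empty")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")

    @property
    def stats(self) -> dict[str, tuple[float, float, float, float]]:
        return self.analyte_stats or SPECIES_STATS[self.species]


def _draw_chemistry(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Correlated truncated draws of the analyte values (g/kg).

    A single latent fiber factor induces the field-typical correlations;
    rows violating any min–max bound are redrawn jointly (rejection), so
    marginal moments stay within Monte-Carlo error of the targets.  CP is
    realised as 6.25 x a latent nitrogen concentration.
    """
    stats = config.stats
    analytes = list(stats)
    n = config.n_samples

    def draw_rows(m: int) -> np.ndarray:
        zf = rng.standard_normal(m)
        out = np.empty((m, len(analytes)))
        for j, a in enumerate(analytes):
            mean, sd, _, _ = stats[a]
            lo = _FIBER_LOADING.get(a, 0.0)
            z = lo * zf + np.sqrt(max(1.0 - lo**2, 0.0)) * rng.standard_normal(m)
            if a == "CP":
                nitrogen = mean / 6.25 + (sd / 6.25) * z
                out[:, j] = 6.25 * nitrogen
            else:
                out[:, j] = mean + sd * z
        return out

    vals = draw_rows(n)
    lows = np.array([stats[a][2] for a in analytes])
    highs = np.array([stats[a][3] for a in analytes])
    for _ in range(100):
        bad = np.any((vals < lows) | (vals > highs), axis=1)
        if not bad.any():
            break
        vals[bad] = draw_rows(int(bad.sum()))
    else:
        vals = np.clip(vals, lows, highs)
    return {a: vals[:, j] for j, a in enumerate(analytes)}


def _gaussian(w: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - center) / width) ** 2)


def clean_spectra(
    chemistry: dict[str, np.ndarray], config: GeneratorConfig
) -> np.ndarray:
    """Distortion-free absorbance: baseline + Σ fraction x band response.

    Exactly linear in the constituent concentrations.
    """
    w = np.asarray(config.wavelengths_nm, dtype=float)
    v = (w - w[0]) / (w[-1] - w[0])
    n = len(next(iter(chemistry.values())))
    base = 0.30 + 0.45 * v + 0.20 * v**2
    X = np.tile(base, (n, 1))
    fractions = dict(chemistry)
    if "DM" in fractions:
        fractions["MOISTURE"] = 1000.0 - fractions["DM"]
    for analyte, bands in config.band_library.items():
        if analyte not in fractions:
            continue
        frac = fractions[analyte] / 1000.0
        response = np.zeros_like(w)
        for center, width, loading in bands:
            response += loading * _gaussian(w, center, width)
        X += np.outer(frac, response)
    return X


@dataclass
class _DistortionDraws:
    """Standard-normal draws shared across prep states; scaled per state."""

    mult: np.ndarray        # (n,)
    offset: np.ndarray      # (n,)
    tilt: np.ndarray        # (n,)
    structured: np.ndarray  # (n, n_channels), unit marginal SD, smooth
    noise: np.ndarray       # (n, n_channels)


def _smooth_unit_noise(
    n: int, wavelengths: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample-specific smooth random curves with unit marginal SD.

    White noise convolved with a Gaussian kernel of correlation length
    ``_STRUCT_CORR_NM``; being full-rank and sample-specific, this structure
    cannot be projected out by a finite-factor linear model, unlike a fixed
    low-dimensional basis.
    """
    from scipy.ndimage import gaussian_filter1d

    step = float(np.median(np.diff(wavelengths)))
    sigma = max(_STRUCT_CORR_NM / step, 1e-6)
    raw = rng.standard_normal((n, wavelengths.size))
    smooth = gaussian_filter1d(raw, sigma=sigma, axis=1, mode="nearest")
    # renormalise to unit marginal SD (interior-channel kernel norm)
    delta = np.zeros(wavelengths.size)
    delta[wavelengths.size // 2] = 1.0
    norm = np.sqrt(np.sum(gaussian_filter1d(delta, sigma=sigma, mode="nearest") ** 2))
    return smooth / norm


def _draw_distortions(
    n: int, wavelengths: np.ndarray, rng: np.random.Generator
) -> _DistortionDraws:
    return _DistortionDraws(
        mult=rng.standard_normal(n),
        offset=rng.standard_normal(n),
        tilt=rng.standard_normal(n),
        structured=_smooth_unit_noise(n, np.asarray(wavelengths, float), rng),
        noise=rng.standard_normal((n, wavelengths.size)),
    )


def _apply_distortion(
    clean: np.ndarray,
    draws: _DistortionDraws,
    params: ScatterParams,
    noise_sd: float,
    wavelengths: np.ndarray,
) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    u = (w - w[0]) / (w[-1] - w[0]) - 0.5
    a = params.mult_sd * draws.mult
    b = params.offset_sd * draws.offset
    c = params.tilt_sd * draws.tilt
    out = clean * (1.0 + a)[:, None]
    out += b[:, None] + np.outer(c, u)
    out += params.structured_sd * draws.structured
    out += noise_sd * draws.noise
    return out


def _assemble(
    chemistry: dict[str, np.ndarray],
    absorbance: np.ndarray,
    config: GeneratorConfig,
    prep_state: str,
) -> AlignedDataset:
    n = config.n_samples
    ids = [f"{config.species[:3].upper()}{i + 1:04d}" for i in range(n)]
    analytes = list(config.stats)
    spectra = SpectrumSet(
        sample_ids=ids,
        wavelengths_nm=np.asarray(config.wavelengths_nm, dtype=float),
        absorbance=absorbance,
        prep_state=[prep_state] * n,
        meta={"species": config.species, "seed": config.seed, "synthetic": True},
    )
    reference = ReferenceTable(
        sample_ids=ids,
        analytes=analytes,
        values=np.column_stack([chemistry[a] for a in analytes]),
        units={a: "g/kg" for a in analytes},
    )
    return AlignedDataset(spectra, reference)


def generate(config: GeneratorConfig) -> AlignedDataset:
    """Generate one synthetic dataset for the configured prep state."""
    rng = np.random.default_rng(config.seed)
    chemistry = _draw_chemistry(config, rng)
    clean = clean_spectra(chemistry, config)
    draws = _draw_distortions(config.n_samples, config.wavelengths_nm, rng)
    distorted = _apply_distortion(
        clean, draws, config.scatter[config.prep_state], config.noise_sd,
        config.wavelengths_nm,
    )
    return _assemble(chemistry, distorted, config, config.prep_state)


def paired_prep_states(config: GeneratorConfig) -> tuple[AlignedDataset, AlignedDataset]:
    """Ground and unground scans of the *same* samples.

    Chemistry, clean spectra, the underlying distortion draws and the channel
    noise are shared; only the per-state scatter magnitudes differ, isolating
    the sample-preparation contrast.  With equal scatter parameters the two
    datasets are identical.
    """
    rng = np.random.default_rng(config.seed)
    chemistry = _draw_chemistry(config, rng)
    clean = clean_spectra(chemistry, config)
    draws = _draw_distortions(config.n_samples, config.wavelengths_nm, rng)
    out = []
    for state in ("ground", "unground"):
        distorted = _apply_distortion(
            clean, draws, config.scatter[state], config.noise_sd, config.wavelengths_nm
        )
        out.append(_assemble(chemistry, distorted, config, state))
    return out[0], out[1]
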