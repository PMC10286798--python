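"""Spectral photon flux distributions and waveband integrals.

Light inputs arrive either as continuous spectral photon flux density (SPFD)
curves — wavelength (nm) against µmol m⁻² s⁻¹ nm⁻¹ — or as LED treatment
labels such as ``"B20G20R120FR20"`` that state the photon flux density per
waveband directly.  This module turns both into the quantities the growth and
regression machinery consumes:

* per-waveband photon flux density (PFD, µmol m⁻² s⁻¹) and irradiance
  (W m⁻²) integrals over blue (400-500 nm), green (500-600 nm),
  red (600-700 nm) and far-red (700-750 nm);
* the fraction ratios F_i — each waveband's share of the total photon flux
  (``F_{i,PFD}``) or of the total integrated irradiance (``F_{i,I}``) — which
  are the features of the quantum-use-efficiency regression;
* synthetic LED and solar-like spectra for testing and for treatments where
  only band-level photon fluxes are known.

Photon flux is converted to energy flux through the molar photon energy
N_A·h·c/λ, so a band's irradiance is ``∫ SPFD(λ)·N_A·h·c/λ · 10⁻⁶ dλ``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyBandError,
    InvalidSpectrumError,
    LabelParseError,
)

__all__ = [
    "AVOGADRO",
    "PLANCK",
    "SPEED_OF_LIGHT",
    "BAND_ORDER",
    "SpectralDistribution",
    "WavebandScheme",
    "BandSummary",
    "TreatmentLabel",
    "photon_molar_energy",
    "integrate_bands",
    "parse_treatment_label",
    "pfd_fractions",
    "irradiance_fractions",
    "synth_led_spectrum",
    "synth_solar_spectrum",
]

# CODATA 2018 exact values.
AVOGADRO = 6.02214076e23  # mol^-1
PLANCK = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 299_792_458.0  # m s^-1

#: J m mol^-1; divide by wavelength in metres to get J mol^-1 of photons.
_MOLAR_ENERGY_CONST = AVOGADRO * PLANCK * SPEED_OF_LIGHT

#: Canonical waveband ordering used for every 4-vector in the package.
BAND_ORDER = ("blue", "green", "red", "far_red")

_SPECTRUM_CSV_HEADER = ("wavelength_nm", "spfd_umol_m2_s_nm")


def photon_molar_energy(wavelength_nm):
    """Energy carried by one mole of photons at ``wavelength_nm`` (J mol⁻¹).

    Scalar or array input; raises :class:`ValueError` for non-positive
    wavelengths.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl <= 0.0):
        raise ValueError("wavelength must be positive (nm)")
    out = _MOLAR_ENERGY_CONST / (wl * 1e-9)
    return float(out) if np.isscalar(wavelength_nm) else out


@dataclass(frozen=True)
class SpectralDistribution:
    """A sampled spectral photon flux density curve.

    Attributes
    ----------
    wavelengths : ndarray
        Strictly increasing wavelength grid in nm (irregular grids allowed).
    spfd : ndarray
        Spectral photon flux density in µmol m⁻² s⁻¹ nm⁻¹, same length,
        all values non-negative.
    """

    wavelengths: np.ndarray
    spfd: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        sp = np.asarray(self.spfd, dtype=float)
        if wl.ndim != 1 or sp.shape != wl.shape:
            raise InvalidSpectrumError("wavelengths and spfd must be 1-D and equal length")
        if wl.size < 2:
            raise InvalidSpectrumError("need at least two samples to integrate")
        if np.any(np.diff(wl) <= 0):
            raise InvalidSpectrumError("wavelength grid must be strictly increasing")
        if np.any(sp < 0):
            raise InvalidSpectrumError("spectral photon flux density must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "spfd", sp)

    def scaled(self, factor: float) -> "SpectralDistribution":
        return SpectralDistribution(self.wavelengths, self.spfd * factor)

    @classmethod
    def from_csv(cls, path_or_buf) -> "SpectralDistribution":
        """Read a ``wavelength_nm,spfd_umol_m2_s_nm`` CSV export."""
        df = pd.read_csv(path_or_buf)
        missing = [c for c in _SPECTRUM_CSV_HEADER if c not in df.columns]
        if missing:
            raise InvalidSpectrumError(f"spectrum CSV missing columns: {missing}")
        return cls(df[_SPECTRUM_CSV_HEADER[0]].to_numpy(), df[_SPECTRUM_CSV_HEADER[1]].to_numpy())

    def to_csv(self, path_or_buf) -> None:
        """Write the same dialect :meth:`from_csv` reads."""
        pd.DataFrame(
            {_SPECTRUM_CSV_HEADER[0]: self.wavelengths, _SPECTRUM_CSV_HEADER[1]: self.spfd}
        ).to_csv(path_or_buf, index=False)


@dataclass(frozen=True)
class WavebandScheme:
    """Contiguous, non-overlapping waveband intervals in nm.

    Edges are half-open ``[lo, hi)`` except the far-red band, which is closed
    at 750 nm, so shared boundaries are never double counted.  The integration
    itself is over continuous intervals, where the single shared point has
    zero measure; the convention matters for classifying monochromatic lines.
    """

    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "blue": (400.0, 500.0),
            "green": (500.0, 600.0),
            "red": (600.0, 700.0),
            "far_red": (700.0, 750.0),
        }
    )

    def __post_init__(self):
        names = tuple(self.bands)
        edges = [self.bands[n] for n in names]
        for (lo, hi) in edges:
            if not lo < hi:
                raise ValueError("band intervals must have lo < hi")
        for (_, hi_prev), (lo, _) in zip(edges, edges[1:]):
            if hi_prev != lo:
                raise ValueError("bands must be contiguous and ordered")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    @property
    def lo(self) -> float:
        return next(iter(self.bands.values()))[0]

    @property
    def hi(self) -> float:
        return list(self.bands.values())[-1][1]

    def band_of(self, wavelength_nm: float) -> str | None:
        """Band containing ``wavelength_nm`` under the half-open convention."""
        names = self.names
        for i, name in enumerate(names):
            lo, hi = self.bands[name]
            if lo <= wavelength_nm < hi or (i == len(names) - 1 and wavelength_nm == hi):
                return name
        return None


DEFAULT_SCHEME = WavebandScheme()


@dataclass(frozen=True)
class BandSummary:
    """Per-waveband photon flux and irradiance integrals with fraction ratios.

    ``pfd`` entries are µmol m⁻² s⁻¹, ``irradiance`` entries W m⁻².
    ``irradiance_total`` is the integrated spectral irradiance over the whole
    analysis window (I_PAR+FR when the default scheme is used).
    """

    pfd: dict[str, float]
    irradiance: dict[str, float]

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(self.pfd)

    @property
    def pfd_total(self) -> float:
        return float(sum(self.pfd.values()))

    @property
    def irradiance_total(self) -> float:
        return float(sum(self.irradiance.values()))

    @property
    def pfd_fractions(self) -> np.ndarray:
        return pfd_fractions(self.pfd)

    @property
    def irradiance_fractions(self) -> np.ndarray:
        return irradiance_fractions(self.irradiance)

    def to_frame(self) -> pd.DataFrame:
        """One row per band plus a ``total`` row, for CSV export."""
        rows = [
            {"band": name, "pfd_umol_m2_s": self.pfd[name], "irradiance_w_m2": self.irradiance[name]}
            for name in self.band_names
        ]
        rows.append(
            {"band": "total", "pfd_umol_m2_s": self.pfd_total, "irradiance_w_m2": self.irradiance_total}
        )
        return pd.DataFrame(rows)


def _fractions(values: Mapping[str, float] | Sequence[float], what: str) -> np.ndarray:
    if isinstance(values, Mapping):
        vec = np.array([float(values.get(name, 0.0)) for name in BAND_ORDER])
    else:
        vec = np.asarray(values, dtype=float)
        if vec.shape != (len(BAND_ORDER),):
            raise ValueError(f"expected a 4-vector in {BAND_ORDER} order")
    if np.any(vec < 0):
        raise ValueError(f"{what} values must be non-negative")
    total = vec.sum()
    if total <= 0.0:
        raise EmptyBandError(f"total {what} is zero; fractions undefined")
    return vec / total


def pfd_fractions(bands: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """Photon-flux fraction ratios ``F_{i,PFD}`` in blue/green/red/far-red order.

    Accepts a mapping keyed by band name or a 4-vector; raises
    :class:`EmptyBandError` when the total flux is zero.
    """
    return _fractions(bands, "photon flux")


def irradiance_fractions(band_irradiances: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """Irradiance fraction ratios ``F_{i,I}`` in blue/green/red/far-red order."""
    return _fractions(band_irradiances, "irradiance")


def integrate_bands(
    spd: SpectralDistribution, scheme: WavebandScheme = DEFAULT_SCHEME
) -> BandSummary:
    """Integrate a spectrum into per-waveband photon flux and irradiance.

    Trapezoidal integration on the supplied grid; band edges falling between
    grid points are resolved by linear interpolation.  The energy integrand is
    ``spfd(λ) · N_A h c / λ · 10⁻⁶`` so that µmol photons become watts.

    Raises
    ------
    EmptyBandError
        If the spectrum has no support inside the scheme's window.
    """
    wl, sp = spd.wavelengths, spd.spfd
    if wl[-1] <= scheme.lo or wl[0] >= scheme.hi:
        raise EmptyBandError(
            f"spectrum [{wl[0]:g}, {wl[-1]:g}] nm lies outside "
            f"the [{scheme.lo:g}, {scheme.hi:g}] nm analysis window"
        )
    pfd: dict[str, float] = {}
    irr: dict[str, float] = {}
    energy = _MOLAR_ENERGY_CONST / (wl * 1e-9) * 1e-6  # W per (umol m^-2 s^-1)
    for name in scheme.names:
        lo, hi = scheme.bands[name]
        lo_c, hi_c = max(lo, wl[0]), min(hi, wl[-1])
        if lo_c >= hi_c:
            pfd[name] = 0.0
            irr[name] = 0.0
            continue
        inner = wl[(wl > lo_c) & (wl < hi_c)]
        grid = np.concatenate(([lo_c], inner, [hi_c]))
        sp_g = np.interp(grid, wl, sp)
        en_g = np.interp(grid, wl, sp * energy)
        pfd[name] = float(np.trapezoid(sp_g, grid))
        irr[name] = float(np.trapezoid(en_g, grid))
    return BandSummary(pfd=pfd, irradiance=irr)


@dataclass(frozen=True)
class TreatmentLabel:
    """A parsed LED treatment label.

    ``band_pfds`` gives the labelled photon flux density per band in
    µmol m⁻² s⁻¹.  Warm-white (``WW``) and equalized-white (``EQW``) labels
    state only a total flux — no per-band decomposition can be derived from
    the text — so ``resolvable`` is False and ``band_pfds`` is empty for them.
    """

    raw: str
    band_pfds: dict[str, float]
    resolvable: bool
    total_pfd: float

    @property
    def pfd_fractions(self) -> np.ndarray:
        if not self.resolvable:
            raise LabelParseError(f"label {self.raw!r} has no per-band decomposition")
        return pfd_fractions(self.band_pfds)


_TOKEN_RE = re.compile(r"(FR|B|G|R)(\d+)")
_WHITE_RE = re.compile(r"(WW|EQW)(\d+)")
_REPLICATE_RE = re.compile(r"\(\d+\)$")
_TOKEN_TO_BAND = {"B": "blue", "G": "green", "R": "red", "FR": "far_red"}


def parse_treatment_label(label: str) -> TreatmentLabel:
    """Parse labels like ``"B20G20R120FR20"``, ``"R180"`` or ``"WW180"``.

    A trailing replicate marker such as ``"(1)"`` is ignored.  Raises
    :class:`LabelParseError` for anything that is not a concatenation of
    ``B/G/R/FR`` tokens or a single ``WW``/``EQW`` token.
    """
    text = _REPLICATE_RE.sub("", label.strip())
    if not text:
        raise LabelParseError(f"empty treatment label {label!r}")
    m = _WHITE_RE.fullmatch(text)
    if m:
        return TreatmentLabel(
            raw=label, band_pfds={}, resolvable=False, total_pfd=float(m.group(2))
        )
    pos = 0
    pfds = {name: 0.0 for name in BAND_ORDER}
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise LabelParseError(f"unrecognized token in treatment label {label!r}")
        pfds[_TOKEN_TO_BAND[m.group(1)]] += float(m.group(2))
        pos = m.end()
    if pos != len(text):
        raise LabelParseError(f"unrecognized token in treatment label {label!r}")
    return TreatmentLabel(
        raw=label,
        band_pfds=pfds,
        resolvable=True,
        total_pfd=float(sum(pfds.values())),
    )


#: Typical narrow-band LED peak centres (nm) per waveband.
DEFAULT_PEAK_CENTERS = {"blue": 449.0, "green": 526.0, "red": 664.0, "far_red": 733.0}
#: Typical LED full width at half maximum (nm).
DEFAULT_PEAK_FWHM = 25.0


def synth_led_spectrum(
    band_pfds: Mapping[str, float],
    peak_centers: Mapping[str, float] | None = None,
    peak_fwhm: float | Mapping[str, float] = DEFAULT_PEAK_FWHM,
    grid_step: float = 0.5,
    scheme: WavebandScheme = DEFAULT_SCHEME,
) -> SpectralDistribution:
    """Synthesize an LED-style spectrum with one Gaussian peak per waveband.

    Each peak is truncated at its band edges and rescaled numerically so that
    :func:`integrate_bands` recovers the requested band photon fluxes to
    within round-off (well inside 0.1 %).  This emulates the narrow-band LED
    fixtures used in spectral treatment experiments where only band-level
    photon fluxes are reported.
    """
    centers = dict(DEFAULT_PEAK_CENTERS)
    if peak_centers:
        centers.update(peak_centers)
    wl = np.arange(scheme.lo, scheme.hi + grid_step / 2, grid_step)
    sp = np.zeros_like(wl)
    for name in scheme.names:
        target = float(band_pfds.get(name, 0.0))
        if target < 0:
            raise ValueError(f"band photon flux for {name} must be non-negative")
        if target == 0.0:
            continue
        lo, hi = scheme.bands[name]
        center = centers[name]
        if not lo <= center <= hi:
            raise ValueError(f"peak center {center} nm outside band {name} [{lo}, {hi}] nm")
        fwhm = peak_fwhm[name] if isinstance(peak_fwhm, Mapping) else float(peak_fwhm)
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        in_band = (wl >= lo) & (wl <= hi)
        shape = np.zeros_like(wl)
        shape[in_band] = np.exp(-0.5 * ((wl[in_band] - center) / sigma) ** 2)
        area = np.trapezoid(shape, wl)
        if area <= 0.0:
            raise ValueError(f"degenerate peak for band {name}; refine grid_step")
        sp += shape * (target / area)
    return SpectralDistribution(wl, sp)


def synth_solar_spectrum(
    total_pfd: float,
    color_temperature_k: float = 5800.0,
    grid_step: float = 1.0,
    scheme: WavebandScheme = DEFAULT_SCHEME,
) -> SpectralDistribution:
    """A smooth solar-like spectrum scaled to a total photon flux.

    Uses the photon-count form of a Planck blackbody (λ⁻⁴ weighting) at the
    given colour temperature over the analysis window, then scales so the
    integral over the window equals ``total_pfd`` (µmol m⁻² s⁻¹).  This stands
    in for measured daylight spectra, which are not packaged; atmospheric
    absorption lines are not represented.
    """
    if total_pfd < 0:
        raise ValueError("total photon flux must be non-negative")
    wl = np.arange(scheme.lo, scheme.hi + grid_step / 2, grid_step)
    lam = wl * 1e-9
    hc_over_kt = PLANCK * SPEED_OF_LIGHT / (1.380649e-23 * color_temperature_k)
    shape = lam**-4 / np.expm1(hc_over_kt / lam)
    area = np.trapezoid(shape, wl)
    return SpectralDistribution(wl, shape * (total_pfd / area))
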