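"""Synthetic SELDI-like serum spectra with planted discriminatory peaks.

Each simulated spectrum is the sum of a smooth exponentially decaying
chemical baseline, a field of Gaussian peaks shared by both classes, a few
*marker* peaks whose amplitude differs between cancer and control samples,
and additive Gaussian noise, clipped at zero (intensities are physical).

The default configuration mimics the structure of the public
high-resolution ovarian-cancer WCX2 serum dataset this pipeline targets:
12,000 m/z points spanning 700-12,000 Da, 95 controls and 121 cancers, and
low-amplitude discriminatory peaks near 8150 Da and inside the
8450-8740 Da window.  Marker amplitudes are kept at ~2% of the tallest
shared peak, reflecting how faint the informative features are relative to
the abundant serum proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .spectra import CANCER, CONTROL, MzGrid, SpectraSet, Spectrum


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian peak: centre and width in Da, per-class amplitudes."""

    center: float
    width: float
    amplitude_control: float
    amplitude_disease: float

    def __post_init__(self):
        if self.width <= 0:
            raise ConfigError(f"peak at {self.center} Da: width must be > 0")
        if self.amplitude_control < 0 or self.amplitude_disease < 0:
            raise ConfigError(f"peak at {self.center} Da: amplitudes must be >= 0")

    @property
    def delta(self) -> float:
        """Disease-minus-control amplitude gap at the peak centre."""
        return self.amplitude_disease - self.amplitude_control


def shared_peak(center: float, width: float, amplitude: float) -> PeakSpec:
    """A peak with equal amplitude in both classes (non-discriminatory)."""
    return PeakSpec(center, width, amplitude, amplitude)


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated cohort.

    ``baseline_decay`` is in 1/Da; the baseline at position mz is
    ``baseline_scale * exp(-baseline_decay * (mz - grid_min))``.
    ``noise_sd`` is the standard deviation of the additive Gaussian noise in
    the same arbitrary intensity units as the peak amplitudes.
    """

    grid_min: float = 700.0
    grid_max: float = 12000.0
    n_points: int = 12000
    n_control: int = 95
    n_disease: int = 121
    baseline_scale: float = 20.0
    baseline_decay: float = 4e-4
    shared_peaks: tuple[PeakSpec, ...] = ()
    marker_peaks: tuple[PeakSpec, ...] = ()
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")
        if self.grid_min >= self.grid_max:
            raise ConfigError("grid_min must be < grid_max")
        if self.grid_min <= 0:
            raise ConfigError("grid_min must be positive (m/z in Da)")
        if self.n_control < 0 or self.n_disease < 0:
            raise ConfigError("sample counts must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for peak in (*self.shared_peaks, *self.marker_peaks):
            if not (self.grid_min <= peak.center <= self.grid_max):
                raise ConfigError(
                    f"marker/peak centre {peak.center} Da outside grid "
                    f"[{self.grid_min}, {self.grid_max}]"
                )

    def grid(self) -> MzGrid:
        return MzGrid(np.linspace(self.grid_min, self.grid_max, self.n_points))


def default_paper_like_config(seed: int = 1234) -> SimConfig:
    """Defaults emulating the target dataset's structure.

    12,000 grid points over 700-12,000 Da; 95 controls vs 121 cancers; six
    shared serum peaks (tallest amplitude 100); four markers — one near
    8150 Da and three inside 8450-8740 Da — whose disease amplitude (2.0)
    is 2% of the tallest shared peak and whose disease-control gap equals
    three noise standard deviations (noise_sd = 0.5).
    """
    shared = tuple(
        shared_peak(c, w, a)
        for c, w, a in [
            (1500.0, 8.0, 60.0),
            (2500.0, 9.0, 40.0),
            (4000.0, 10.0, 100.0),
            (6000.0, 12.0, 30.0),
            (9000.0, 12.0, 20.0),
            (11000.0, 15.0, 10.0),
        ]
    )
    markers = tuple(
        PeakSpec(center, 4.0, amplitude_control=0.5, amplitude_disease=2.0)
        for center in (8150.0, 8500.0, 8600.0, 8700.0)
    )
    return SimConfig(shared_peaks=shared, marker_peaks=markers, seed=seed)


def _clean_signal(config: SimConfig, grid: MzGrid, cls: str) -> np.ndarray:
    """Noise-free baseline + peaks for one class."""
    mz = grid.values
    signal = config.baseline_scale * np.exp(-config.baseline_decay * (mz - config.grid_min))
    for peak in (*config.shared_peaks, *config.marker_peaks):
        amp = peak.amplitude_disease if cls == CANCER else peak.amplitude_control
        if amp == 0.0:
            continue
        signal = signal + amp * np.exp(-0.5 * ((mz - peak.center) / peak.width) ** 2)
    return signal


def generate(config: SimConfig) -> tuple[SpectraSet, pd.DataFrame]:
    """Simulate a labelled cohort plus its ground-truth marker manifest.

    Returns the :class:`~seldiclass.spectra.SpectraSet` and a frame with
    columns ``mz_index,mz,delta`` — the grid index nearest each marker
    centre and the planted disease-control amplitude gap there.  Noise for
    sample *i* comes from its own counter-derived stream
    ``default_rng([seed, i])``, so output is bit-reproducible and
    insensitive to generation order.
    """
    grid = config.grid()
    clean = {
        CONTROL: _clean_signal(config, grid, CONTROL),
        CANCER: _clean_signal(config, grid, CANCER),
    }
    spectra: list[Spectrum] = []
    labels: dict[str, str] = {}
    plan = [(CONTROL, f"control_{i:03d}") for i in range(config.n_control)]
    plan += [(CANCER, f"cancer_{i:03d}") for i in range(config.n_disease)]
    for counter, (cls, sid) in enumerate(plan):
        y = clean[cls]
        if config.noise_sd > 0:
            rng = np.random.default_rng([config.seed, counter])
            y = y + rng.normal(0.0, config.noise_sd, size=len(grid))
        spectra.append(Spectrum(sid, np.clip(y, 0.0, None)))
        labels[sid] = cls
    truth = pd.DataFrame(
        {
            "mz_index": [grid.index_of(p.center) for p in config.marker_peaks],
            "mz": [grid.values[grid.index_of(p.center)] for p in config.marker_peaks],
            "delta": [p.delta for p in config.marker_peaks],
        }
    )
    return SpectraSet(grid, spectra, labels), truth
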