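"""Spectral processing: raw two-channel PA traces to APSD spectra.

Processing chain per sample:

1. zero-phase 1 MHz high-pass filtering of both channels,
2. pulse-energy calibration — the sample trace at each wavelength is divided
   by the peak-to-peak amplitude of the same-wavelength blackbody trace,
3. Welch power spectral density (moving Hamming window),
4. compensation by the hydrophone frequency response (power domain),
5. APSD = trapezoidal integral of the calibrated PSD over 1-4 MHz, one
   value per wavelength; the 51 values compose the sample's APSD spectrum.

The wavelength x frequency matrix of calibrated PSDs (step 4) is the
physio-chemical spectrogram: the optical axis encodes chemistry, the
ultrasonic axis encodes structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .dataset import APSDSpectrum, SpectraSet
from .synth import (
    HydrophoneResponse,
    RawMeasurement,
    TissueSample,
    default_hydrophone_response,
)

DEFAULT_F0_MHZ = 1.0
DEFAULT_F1_MHZ = 4.0


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided calibrated PSD for one sample at one laser wavelength."""

    freq_mhz: np.ndarray
    psd: np.ndarray
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.psd.shape != self.freq_mhz.shape:
            raise ValueError("psd and freq_mhz must have matching shape")


@dataclass(frozen=True)
class PhysioChemicalSpectrogram:
    """Calibrated PSD indexed by optical wavelength (rows) x frequency (cols)."""

    wavelengths: np.ndarray
    freq_mhz: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        if self.psd.shape != (len(self.wavelengths), len(self.freq_mhz)):
            raise ValueError("psd must be (n_wavelengths, n_freqs)")

    def row(self, i: int) -> PowerSpectrum:
        return PowerSpectrum(self.freq_mhz, self.psd[i], float(self.wavelengths[i]))


@dataclass(frozen=True)
class ProcessingConfig:
    """Tunables of the processing chain with study defaults."""

    highpass_cutoff_hz: float = 1e6
    f0_mhz: float = DEFAULT_F0_MHZ
    f1_mhz: float = DEFAULT_F1_MHZ
    welch_window_fraction: float = 0.125
    welch_overlap: float = 0.5
    blackbody_floor: float = 1e-9
    # matches the response the synthetic generator imprints on the sample channel
    hydrophone: HydrophoneResponse = field(default_factory=default_hydrophone_response)


def highpass_filter(
    trace: np.ndarray, sampling_rate_hz: float, cutoff_hz: float = 1e6
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass along the last axis."""
    nyquist = sampling_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=sampling_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, trace, axis=-1)


def calibrate_energy(meas: RawMeasurement, floor: float = 1e-9) -> RawMeasurement:
    """Divide each sample trace by the peak-to-peak of its blackbody trace.

    Both channels share the per-shot pulse-energy factor, so this scalar
    division removes laser-energy fluctuation; the blackbody channel is kept
    unmodified.
    """
    ptp = meas.blackbody.max(axis=-1) - meas.blackbody.min(axis=-1)
    bad = np.flatnonzero(ptp < floor)
    if bad.size:
        raise ValueError(
            f"blackbody peak-to-peak below floor {floor:g} at wavelength "
            f"{meas.wavelengths[bad[0]]:g} nm"
        )
    return RawMeasurement(
        meas.wavelengths,
        meas.sampling_rate_hz,
        meas.sample / ptp[:, None],
        meas.blackbody,
        meas.energy,
    )


def welch_psd(
    trace: np.ndarray,
    sampling_rate_hz: float,
    window_len: int | None = None,
    overlap: float = 0.5,
    wavelength_nm: float | None = None,
) -> PowerSpectrum:
    """One-sided Welch PSD with a moving Hamming window.

    Default segment length is 1/8 of the trace. Frequencies are reported in
    MHz, density in power units per MHz.
    """
    trace = np.asarray(trace, float)
    n = trace.shape[-1]
    if window_len is None:
        window_len = max(8, n // 8)
    if window_len > n:
        raise ValueError("Welch window longer than the trace")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap fraction must be in [0, 1)")
    freqs_hz, psd = signal.welch(
        trace,
        fs=sampling_rate_hz,
        window="hamming",
        nperseg=window_len,
        noverlap=int(overlap * window_len),
        detrend=False,
        scaling="density",
    )
    # density per Hz -> per MHz so that integration over MHz keeps units tidy
    return PowerSpectrum(freqs_hz / 1e6, psd * 1e6, wavelength_nm)


def hydrophone_compensate(ps: PowerSpectrum, resp: HydrophoneResponse) -> PowerSpectrum:
    """Divide the PSD by the squared hydrophone sensitivity (power domain)."""
    sens = resp.at(ps.freq_mhz)
    in_band = (ps.freq_mhz >= DEFAULT_F0_MHZ) & (ps.freq_mhz <= DEFAULT_F1_MHZ)
    if np.any(sens[in_band] <= 0):
        raise ValueError("hydrophone response must be positive across 1-4 MHz")
    safe = np.where(sens > 0, sens, np.inf)
    return PowerSpectrum(ps.freq_mhz, ps.psd / safe**2, ps.wavelength_nm)


def compute_apsd(
    ps: PowerSpectrum, f0: float = DEFAULT_F0_MHZ, f1: float = DEFAULT_F1_MHZ
) -> float:
    """Area of the power spectral density: trapezoidal integral over [f0, f1] MHz.

    Band edges falling between grid points are included by linear
    interpolation so the result converges at second order in the grid step.
    """
    if f0 >= f1:
        raise ValueError("f0 must be below f1")
    f = ps.freq_mhz
    if f0 < f[0] or f1 > f[-1]:
        raise ValueError("integration band outside the PSD frequency grid")
    inner = (f > f0) & (f < f1)
    grid = np.concatenate(([f0], f[inner], [f1]))
    vals = np.concatenate(
        ([np.interp(f0, f, ps.psd)], ps.psd[inner], [np.interp(f1, f, ps.psd)])
    )
    return float(np.trapezoid(vals, grid))


def assemble_spectrogram(per_wavelength: list[PowerSpectrum]) -> PhysioChemicalSpectrogram:
    """Pack per-wavelength PSDs into a spectrogram, sorted by wavelength."""
    if any(ps.wavelength_nm is None for ps in per_wavelength):
        raise ValueError("every PSD must carry its source wavelength")
    ordered = sorted(per_wavelength, key=lambda ps: ps.wavelength_nm)
    freq = ordered[0].freq_mhz
    for ps in ordered[1:]:
        if not np.array_equal(ps.freq_mhz, freq):
            raise ValueError("all PSDs must share one frequency grid")
    wl = np.array([ps.wavelength_nm for ps in ordered])
    if len(np.unique(wl)) != len(wl):
        raise ValueError("duplicate wavelength in spectrogram input")
    return PhysioChemicalSpectrogram(wl, freq, np.stack([ps.psd for ps in ordered]))


def build_apsd_spectrum(
    spectrogram: PhysioChemicalSpectrogram,
    f0: float = DEFAULT_F0_MHZ,
    f1: float = DEFAULT_F1_MHZ,
    sample_id: str = "S000",
    label: str = "normal",
) -> APSDSpectrum:
    """Apply the APSD integral row-wise and attach sample metadata."""
    values = np.array(
        [compute_apsd(spectrogram.row(i), f0, f1) for i in range(len(spectrogram.wavelengths))]
    )
    return APSDSpectrum(sample_id, label, spectrogram.wavelengths, values)


def process_measurement(
    meas: RawMeasurement,
    cfg: ProcessingConfig | None = None,
    sample_id: str = "S000",
    label: str = "normal",
) -> tuple[PhysioChemicalSpectrogram, APSDSpectrum]:
    """Full chain from raw two-channel traces to one APSD spectrum."""
    cfg = cfg or ProcessingConfig()
    filtered = RawMeasurement(
        meas.wavelengths,
        meas.sampling_rate_hz,
        highpass_filter(meas.sample, meas.sampling_rate_hz, cfg.highpass_cutoff_hz),
        highpass_filter(meas.blackbody, meas.sampling_rate_hz, cfg.highpass_cutoff_hz),
        meas.energy,
    )
    calibrated = calibrate_energy(filtered, cfg.blackbody_floor)
    window_len = max(8, int(round(cfg.welch_window_fraction * calibrated.sample.shape[-1])))
    # one vectorized Welch call over the (wavelength, time) matrix
    freqs_hz, psd = signal.welch(
        calibrated.sample,
        fs=meas.sampling_rate_hz,
        window="hamming",
        nperseg=window_len,
        noverlap=int(cfg.welch_overlap * window_len),
        detrend=False,
        scaling="density",
        axis=-1,
    )
    freq_mhz = freqs_hz / 1e6
    psds = [
        hydrophone_compensate(
            PowerSpectrum(freq_mhz, psd[i] * 1e6, float(meas.wavelengths[i])),
            cfg.hydrophone,
        )
        for i in range(len(meas.wavelengths))
    ]
    spectrogram = assemble_spectrogram(psds)
    spectrum = build_apsd_spectrum(spectrogram, cfg.f0_mhz, cfg.f1_mhz, sample_id, label)
    return spectrogram, spectrum


def process_dataset(
    records: list[tuple[TissueSample, RawMeasurement]],
    cfg: ProcessingConfig | None = None,
) -> SpectraSet:
    """Process a whole study into a SpectraSet (one APSD spectrum per sample)."""
    spectra = [
        process_measurement(meas, cfg, tissue.sample_id, tissue.label)[1]
        for tissue, meas in records
    ]
    return SpectraSet.from_spectra(spectra)
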