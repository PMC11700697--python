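"""Synthetic multi-wavelength photoacoustic measurement generator.

Emulates the statistical structure of a two-arm murine study: 50 normal and
50 cancerous tissue samples probed at 51 NIR-II laser wavelengths, each shot
recorded on a sample channel (needle hydrophone) and a blackbody reference
channel used to normalize out pulse-energy fluctuation.

Forward model per sample, per wavelength lambda::

    sample(t)    = gain * energy(lambda) * A(lambda) * pulse(t) + noise
    blackbody(t) = energy(lambda) * bb_amplitude     * pulse(t) + noise

where ``A(lambda) = sum_i fraction_i * mu_i(lambda)`` is the composite
normalized absorption of collagen, water and lipid. The class-conditional
generative model encodes the study's findings used as planted structure:
normal tissue has a higher mean collagen fraction, the cancerous class has
larger dispersion (fraction SDs and coupling-gain SD), and collagen and
lipid fractions are more strongly correlated in cancer (shared latent
factor).

Randomness is split into independent per-sample streams (composition,
pulse-energy jitter, additive noise) so that switching one stochastic
component off leaves the others bit-identical — this is what makes the
energy-calibration invariance testable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.signal import gausspulse

from .absorption import CHROMOPHORES, absorption_table
from .grid import validate_grid, wavelength_grid

LABELS = ("normal", "cancer")


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional generative parameters for one tissue class.

    Chromophore volume fractions are drawn from (truncated) Gaussians;
    ``collagen_lipid_corr`` is induced through a shared latent factor;
    ``gain_sigma`` is the log-SD of the lognormal per-sample coupling gain.
    """

    collagen_mean: float
    collagen_sd: float
    water_mean: float
    water_sd: float
    lipid_mean: float
    lipid_sd: float
    collagen_lipid_corr: float
    gain_sigma: float


# Defaults encode the planted class structure: normal tissue collagen-rich,
# cancer more dispersed with stronger collagen-lipid coupling.
DEFAULT_NORMAL = ClassParams(
    collagen_mean=0.34,
    collagen_sd=0.05,
    water_mean=0.40,
    water_sd=0.07,
    lipid_mean=0.18,
    lipid_sd=0.04,
    collagen_lipid_corr=0.3,
    gain_sigma=0.01,
)
DEFAULT_CANCER = ClassParams(
    collagen_mean=0.24,
    collagen_sd=0.08,
    water_mean=0.40,
    water_sd=0.10,
    lipid_mean=0.18,
    lipid_sd=0.06,
    collagen_lipid_corr=0.7,
    gain_sigma=0.03,
)


@dataclass(frozen=True)
class HydrophoneResponse:
    """Relative sensitivity of the receiving hydrophone vs frequency (MHz)."""

    freq_mhz: np.ndarray
    sensitivity: np.ndarray

    def __post_init__(self) -> None:
        if self.sensitivity.shape != self.freq_mhz.shape:
            raise ValueError("sensitivity and freq_mhz must have matching shape")
        in_band = (self.freq_mhz >= 1.0) & (self.freq_mhz <= 4.0)
        if in_band.any() and np.any(self.sensitivity[in_band] <= 0):
            raise ValueError("hydrophone sensitivity must be positive over 1-4 MHz")

    def at(self, freq_mhz: np.ndarray) -> np.ndarray:
        return np.interp(freq_mhz, self.freq_mhz, self.sensitivity)


def default_hydrophone_response(freq_mhz: np.ndarray | None = None) -> HydrophoneResponse:
    """Smooth band-shaped sensitivity peaking near 3 MHz, strictly positive."""
    f = np.linspace(0.0, 10.0, 201) if freq_mhz is None else np.asarray(freq_mhz, float)
    sens = 0.55 + 0.45 * np.exp(-((f - 3.0) ** 2) / 8.0)
    return HydrophoneResponse(f, sens)


def flat_hydrophone_response() -> HydrophoneResponse:
    f = np.linspace(0.0, 130.0, 27)
    return HydrophoneResponse(f, np.ones_like(f))


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunables of the synthetic measurement model (documented defaults)."""

    wavelengths: np.ndarray = field(default_factory=wavelength_grid)
    sampling_rate_hz: float = 250e6
    trace_length: int = 4096
    pulse_center_mhz: float = 2.5
    pulse_fractional_bw: float = 0.8
    noise_sd: float = 0.005
    energy_jitter_sigma: float = 0.10
    blackbody_amplitude: float = 0.5
    apply_hydrophone: bool = True
    normal: ClassParams = DEFAULT_NORMAL
    cancer: ClassParams = DEFAULT_CANCER

    def __post_init__(self) -> None:
        validate_grid(self.wavelengths)
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.energy_jitter_sigma < 0:
            raise ValueError("energy jitter sigma must be non-negative")

    def class_params(self, label: str) -> ClassParams:
        if label == "normal":
            return self.normal
        if label == "cancer":
            return self.cancer
        raise ValueError(f"unknown class label {label!r}")


@dataclass(frozen=True)
class TissueSample:
    """Ground truth for one synthetic sample."""

    sample_id: str
    label: str
    collagen: float
    water: float
    lipid: float
    gain: float
    seed: int

    @property
    def fractions(self) -> dict[str, float]:
        return {"collagen": self.collagen, "water": self.water, "lipid": self.lipid}

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        for name, value in self.fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} fraction {value} outside [0, 1]")
        if self.collagen + self.water + self.lipid > 1.0 + 1e-9:
            raise ValueError("chromophore fractions must sum to <= 1")


@dataclass(frozen=True)
class RawMeasurement:
    """Two-channel PA time series for one sample across all wavelengths.

    ``sample`` and ``blackbody`` have shape (n_wavelengths, trace_length) and
    share the per-wavelength pulse-energy factor ``energy``.
    """

    wavelengths: np.ndarray
    sampling_rate_hz: float
    sample: np.ndarray
    blackbody: np.ndarray
    energy: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.wavelengths)
        if self.sample.shape != self.blackbody.shape or self.sample.shape[0] != n:
            raise ValueError("channel shapes must match (n_wavelengths, trace_length)")
        if self.energy.shape != (n,):
            raise ValueError("energy must have one factor per wavelength")


def emission_pulse(cfg: GeneratorConfig, shaped: bool | None = None) -> np.ndarray:
    """Unit-amplitude Gaussian-modulated bipolar pressure pulse.

    Centered in the analysis band (default 2.5 MHz, fractional bandwidth 0.8)
    so that the 1-4 MHz integration band captures most of the pulse energy.
    When ``shaped`` (default: ``cfg.apply_hydrophone``) the sample-channel
    pulse is additionally filtered by the packaged hydrophone sensitivity.
    """
    if shaped is None:
        shaped = cfg.apply_hydrophone
    return _cached_pulse(
        cfg.trace_length,
        cfg.sampling_rate_hz,
        cfg.pulse_center_mhz,
        cfg.pulse_fractional_bw,
        bool(shaped),
    ).copy()


@lru_cache(maxsize=8)
def _cached_pulse(
    n: int, fs: float, fc_mhz: float, bw: float, shaped: bool
) -> np.ndarray:
    t = np.arange(n) / fs
    t0 = t[n // 4]
    pulse = gausspulse(t - t0, fc=fc_mhz * 1e6, bw=bw)
    if shaped:
        freq_mhz = np.fft.rfftfreq(n, d=1.0 / fs) / 1e6
        resp = default_hydrophone_response().at(freq_mhz)
        pulse = np.fft.irfft(np.fft.rfft(pulse) * resp, n=n)
    return pulse


def energy_profile(wavelengths: np.ndarray) -> np.ndarray:
    """Deterministic laser fluence trend across the scan (arbitrary units)."""
    return 1.0 + 0.25 * np.sin(2.0 * np.pi * (wavelengths - 1200.0) / 500.0)


def composite_absorption(sample: TissueSample, cfg: GeneratorConfig) -> np.ndarray:
    """A(lambda) = sum of fraction-weighted normalized chromophore absorption."""
    table = absorption_table(cfg.wavelengths)
    return sum(sample.fractions[name] * table[name].values for name in CHROMOPHORES)


def dominant_chromophore(cfg: GeneratorConfig) -> np.ndarray:
    """Ground-truth dominant chromophore per wavelength.

    Argmax over chromophores of the pooled-mean-fraction-weighted normalized
    absorption — the planted dominance pattern that waveband partitioning is
    expected to recover.
    """
    table = absorption_table(cfg.wavelengths)
    pooled = {
        name: 0.5
        * (
            getattr(cfg.normal, f"{name}_mean")
            + getattr(cfg.cancer, f"{name}_mean")
        )
        for name in CHROMOPHORES
    }
    weighted = np.stack([pooled[name] * table[name].values for name in CHROMOPHORES])
    return np.array(CHROMOPHORES)[np.argmax(weighted, axis=0)]


def draw_tissue_sample(
    label: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    sample_id: str = "S000",
    seed: int = 0,
) -> TissueSample:
    """Draw one sample's composition and gain from the class-conditional model.

    Collagen and lipid fractions share a latent factor with loading
    sqrt(rho), giving correlation rho between the two; water is independent.
    Fractions are clipped to [0.01, 0.95] and jointly rescaled if their sum
    exceeds 0.98 (the sum-to-<=-1 physical constraint).
    """
    p = cfg.class_params(label)
    rho = p.collagen_lipid_corr
    shared = rng.normal()
    z_c = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.normal()
    z_l = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.normal()
    z_w = rng.normal()
    collagen = p.collagen_mean + p.collagen_sd * z_c
    lipid = p.lipid_mean + p.lipid_sd * z_l
    water = p.water_mean + p.water_sd * z_w
    frac = np.clip([collagen, water, lipid], 0.01, 0.95)
    total = frac.sum()
    if total > 0.98:
        frac = frac * (0.98 / total)
    gain = float(np.exp(rng.normal(0.0, p.gain_sigma)))
    return TissueSample(sample_id, label, float(frac[0]), float(frac[1]), float(frac[2]), gain, seed)


def synthesize_measurement(
    sample: TissueSample,
    cfg: GeneratorConfig,
    energy_rng: np.random.Generator,
    noise_rng: np.random.Generator,
) -> RawMeasurement:
    """Render the two-channel raw traces for an existing TissueSample."""
    wl = cfg.wavelengths
    energy = energy_profile(wl) * np.exp(
        energy_rng.normal(0.0, cfg.energy_jitter_sigma, size=len(wl))
        if cfg.energy_jitter_sigma > 0
        else np.zeros(len(wl))
    )
    amp = sample.gain * energy * composite_absorption(sample, cfg)
    pulse_sample = emission_pulse(cfg)
    pulse_bb = emission_pulse(cfg, shaped=False)
    shape = (len(wl), cfg.trace_length)
    sample_tr = amp[:, None] * pulse_sample[None, :]
    bb_tr = (energy * cfg.blackbody_amplitude)[:, None] * pulse_bb[None, :]
    if cfg.noise_sd > 0:
        sample_tr = sample_tr + noise_rng.normal(0.0, cfg.noise_sd, size=shape)
        bb_tr = bb_tr + noise_rng.normal(0.0, cfg.noise_sd, size=shape)
    return RawMeasurement(wl, cfg.sampling_rate_hz, sample_tr, bb_tr, energy)


def generate_sample(
    label: str,
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
    sample_id: str | None = None,
) -> tuple[TissueSample, RawMeasurement]:
    """Generate one sample: ground truth plus raw two-channel measurement.

    Identical ``(label, cfg, seed)`` reproduce identical output bit-for-bit.
    """
    cfg = cfg or GeneratorConfig()
    streams = np.random.SeedSequence(seed).spawn(3)
    comp_rng, energy_rng, noise_rng = (np.random.default_rng(s) for s in streams)
    sid = sample_id if sample_id is not None else f"{label[0].upper()}{seed:04d}"
    tissue = draw_tissue_sample(label, cfg, comp_rng, sample_id=sid, seed=seed)
    return tissue, synthesize_measurement(tissue, cfg, energy_rng, noise_rng)


def generate_dataset(
    n_normal: int = 50,
    n_cancer: int = 50,
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
) -> list[tuple[TissueSample, RawMeasurement]]:
    """Generate the full two-class study (default 50 + 50 samples).

    Per-sample seeds are derived deterministically from the master seed.
    """
    if n_normal < 1 or n_cancer < 1:
        raise ValueError("sample counts must be >= 1")
    cfg = cfg or GeneratorConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_normal + n_cancer) % (2**31)
    records = []
    for i in range(n_normal + n_cancer):
        label = "normal" if i < n_normal else "cancer"
        idx = i if i < n_normal else i - n_normal
        sid = f"{'N' if label == 'normal' else 'C'}{idx + 1:03d}"
        records.append(
            generate_sample(label, cfg, seed=int(child_seeds[i]), sample_id=sid)
        )
    return records


def save_dataset(
    records: list[tuple[TissueSample, RawMeasurement]],
    raw_path: str | Path,
    table_path: str | Path,
) -> None:
    """Write raw traces to a compressed NPZ container and ground truth to CSV."""
    arrays: dict[str, np.ndarray] = {}
    first = records[0][1]
    arrays["wavelengths"] = first.wavelengths
    arrays["sampling_rate_hz"] = np.array(first.sampling_rate_hz)
    arrays["ids"] = np.array([t.sample_id for t, _ in records])
    for tissue, meas in records:
        arrays[f"sample_{tissue.sample_id}"] = meas.sample
        arrays[f"blackbody_{tissue.sample_id}"] = meas.blackbody
        arrays[f"energy_{tissue.sample_id}"] = meas.energy
    np.savez_compressed(raw_path, **arrays)
    with open(table_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "class", "collagen", "water", "lipid", "gain", "seed"])
        for tissue, _ in records:
            writer.writerow(
                [
                    tissue.sample_id,
                    tissue.label,
                    repr(tissue.collagen),
                    repr(tissue.water),
                    repr(tissue.lipid),
                    repr(tissue.gain),
                    tissue.seed,
                ]
            )


def load_dataset(
    raw_path: str | Path, table_path: str | Path
) -> list[tuple[TissueSample, RawMeasurement]]:
    """Inverse of :func:`save_dataset`."""
    with np.load(raw_path) as data:
        wl = data["wavelengths"]
        fs = float(data["sampling_rate_hz"])
        ids = [str(s) for s in data["ids"]]
        channels = {
            sid: (data[f"sample_{sid}"], data[f"blackbody_{sid}"], data[f"energy_{sid}"])
            for sid in ids
        }
    records = []
    with open(table_path, newline="") as fh:
        for row in csv.DictReader(fh):
            tissue = TissueSample(
                row["id"],
                row["class"],
                float(row["collagen"]),
                float(row["water"]),
                float(row["lipid"]),
                float(row["gain"]),
                int(row["seed"]),
            )
            s, b, e = channels[tissue.sample_id]
            records.append((tissue, RawMeasurement(wl, fs, s, b, e)))
    return records


def without_stochastics(cfg: GeneratorConfig) -> GeneratorConfig:
    """Copy of ``cfg`` with noise and energy jitter switched off."""
    return replace(cfg, noise_sd=0.0, energy_jitter_sigma=0.0)
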