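"""Synthetic two-class multichannel EEG with controllable coupling.

Each epoch is built from band-limited Gaussian sources: a coupled channel
pair (i, j) with strength rho shares a common stochastic source,

    x_i = sqrt(rho) * s_ij + sqrt(1 - rho) * n_i  (+ 1/f background),

so the in-band coherence of the pair approaches rho (scaled down by the
background noise).  Uncoupled channels carry independent noise only.  All
foreground components are band-limited to the source band, backgrounds are
pink (1/f) noise band-limited to 0.5-30 Hz.  Two coupling maps define the
two classes: the default scenario mirrors the empirical picture in which
healthy controls show stronger fronto-central coherence than schizophrenia
patients, weakening designated pairs in the patient class.

The module also carries the closed-form coherence oracle
``analytic_coherence(snr) = snr / (1 + snr)`` for two signals sharing a
common source with independent equal-power noises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocessing import BANDS, Band, EpochSet

#: 19-electrode 10-20 montage used by default.
DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]

#: Disjoint fronto-central/temporal pairs whose coupling differs between the
#: two classes in the default scenario (indices into DEFAULT_CHANNELS).
DESIGNATED_PAIRS = [(0, 3), (1, 5), (4, 9), (2, 7)]
# (Fp1-F3), (Fp2-F4), (Fz-Cz), (F7-T7)


def default_coupling(strength: float) -> dict[tuple[int, int], float]:
    """Coupling map putting ``strength`` on the designated pairs."""
    return {pair: strength for pair in DESIGNATED_PAIRS}


@dataclass
class SynthConfig:
    """Generator settings.

    ``snr`` is the in-band power ratio of the band-limited foreground
    (source + channel noise) to the pink background; ``coupling_a`` /
    ``coupling_b`` map channel pairs to coupling strengths in [0, 1] for the
    two classes (defaults: 0.9 vs 0.2 on the designated fronto-central
    pairs).
    """

    n_channels: int = 19
    fs: float = 256.0
    epoch_sec: float = 4.0
    n_epochs_per_class: int = 100
    coupling_a: dict = field(default_factory=lambda: default_coupling(0.9))
    coupling_b: dict = field(default_factory=lambda: default_coupling(0.2))
    source_band: Band = field(default_factory=lambda: BANDS["theta"])
    snr: float = 4.0
    noise_exponent: float = 1.0
    seed: int = 0
    class_names: tuple = ("HC", "SZ")

    def __post_init__(self) -> None:
        for cmap in (self.coupling_a, self.coupling_b):
            for (i, j), rho in cmap.items():
                if not 0 <= rho <= 1:
                    raise ValueError("coupling strengths must lie in [0, 1]")
                if not (0 <= i < self.n_channels and 0 <= j < self.n_channels):
                    raise ValueError("coupling pair outside channel range")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")

    @property
    def window_len(self) -> int:
        return int(round(self.fs * self.epoch_sec))

    def channel_names(self) -> list[str]:
        if self.n_channels <= len(DEFAULT_CHANNELS):
            return DEFAULT_CHANNELS[: self.n_channels]
        return DEFAULT_CHANNELS + [
            f"X{i}" for i in range(len(DEFAULT_CHANNELS), self.n_channels)]


@dataclass
class LabeledDataset:
    """Epochs plus the ground-truth generator configuration."""

    epochs: EpochSet
    ground_truth: SynthConfig


def bandlimited_noise(n: int, fs: float, band: Band,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band``."""
    # generate with margin so the filter transient does not bias the window
    pad = int(fs)
    sos = signal.butter(4, [band.lo, band.hi], btype="bandpass", fs=fs,
                        output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:pad + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def pink_noise(n: int, fs: float, exponent: float,
               rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent noise band-limited to 0.5-30 Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(len(freqs))
                  + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sos = signal.butter(4, [0.5, 30.0], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def synth_coupled_epoch(cfg: SynthConfig,
                        coupling: dict[tuple[int, int], float],
                        rng: np.random.Generator) -> np.ndarray:
    """One ``(n_channels, window_len)`` epoch under a coupling map.

    Channels appearing in several pairs split their unit foreground power
    across the pair sources proportionally to the coupling strengths
    (couplings are rescaled if they sum past 1 on a channel).
    """
    n, T = cfg.n_channels, cfg.window_len
    # per-channel list of (source index, rho share)
    shares: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    pairs = list(coupling.items())
    totals = np.zeros(n)
    for (i, j), rho in pairs:
        totals[i] += rho
        totals[j] += rho
    scale = np.where(totals > 1.0, 1.0 / np.maximum(totals, 1e-12), 1.0)
    for k, ((i, j), rho) in enumerate(pairs):
        shares[i].append((k, rho * scale[i]))
        shares[j].append((k, rho * scale[j]))
    sources = [bandlimited_noise(T, cfg.fs, cfg.source_band, rng)
               for _ in range(len(pairs))]
    bg_amp = np.sqrt(1.0 / cfg.snr) if cfg.snr > 0 else None
    data = np.empty((n, T))
    for ch in range(n):
        rho_tot = sum(r for _, r in shares[ch])
        x = np.sqrt(max(1.0 - rho_tot, 0.0)) * bandlimited_noise(
            T, cfg.fs, cfg.source_band, rng)
        for k, r in shares[ch]:
            x = x + np.sqrt(r) * sources[k]
        if bg_amp is not None:
            x = x + bg_amp * pink_noise(T, cfg.fs, cfg.noise_exponent, rng)
        elif cfg.snr == 0:
            x = pink_noise(T, cfg.fs, cfg.noise_exponent, rng)
        data[ch] = x
    return data


def synth_two_class_dataset(cfg: SynthConfig) -> LabeledDataset:
    """Balanced two-class dataset; pure function of the config (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    epochs, labels = [], []
    name_a, name_b = cfg.class_names
    for _ in range(cfg.n_epochs_per_class):
        epochs.append(synth_coupled_epoch(cfg, cfg.coupling_a, rng))
        labels.append(name_a)
    for _ in range(cfg.n_epochs_per_class):
        epochs.append(synth_coupled_epoch(cfg, cfg.coupling_b, rng))
        labels.append(name_b)
    es = EpochSet(
        epochs=np.stack(epochs),
        labels=labels,
        fs=cfg.fs,
        channel_names=cfg.channel_names(),
        window_len=cfg.window_len,
        step=cfg.window_len,
    )
    return LabeledDataset(epochs=es, ground_truth=cfg)


def shared_source_pair(n: int, fs: float, band: Band, snr: float,
                       rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Two signals x = s + n1, y = s + n2 sharing a band-limited source.

    ``snr`` is the source-to-noise power ratio per channel; the stationary
    magnitude coherence of the pair is snr / (1 + snr) throughout the band.
    """
    s = np.sqrt(snr) * bandlimited_noise(n, fs, band, rng)
    x = s + bandlimited_noise(n, fs, band, rng)
    y = s + bandlimited_noise(n, fs, band, rng)
    return x, y


def analytic_coherence(snr: float) -> float:
    """Expected magnitude coherence of a shared-source pair at ``snr``.

    With cross-spectrum S_s and auto-spectra S_s + S_n the coherence is
    S_s / (S_s + S_n) = snr / (1 + snr); 0 at snr=0, monotonically
    approaching 1 as snr grows.
    """
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    return snr / (1.0 + snr)
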