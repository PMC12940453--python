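"""Combined X/Y amplitude spectra of displacement series in µm/Hz.

Per axis the one-sided DFT amplitude ``a(k) = (2/N) |X_k|`` is computed for
``0 < k < N/2`` (DC is excluded — the series are zero-mean), the two axes are
combined per bin as the Euclidean magnitude ``sqrt(a_x^2 + a_y^2)``, and the
result is divided by the bin width ``delta_f = fps/N`` to give an amplitude
density in µm/Hz. With no window an on-bin tone of amplitude A lands entirely
in its bin with combined amplitude exactly A, so the convention is testable
in closed form; an optional Hann window (amplitude-corrected by 2) is
available for display of off-bin-heavy content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantify import DisplacementSeries

__all__ = ["AmplitudeSpectrum", "amplitude_spectrum", "plot_spectrum"]


@dataclass
class AmplitudeSpectrum:
    """One-sided combined amplitude spectrum."""

    freqs: np.ndarray  # Hz, strictly increasing from delta_f
    density: np.ndarray  # µm/Hz
    delta_f: float  # bin width, Hz

    @property
    def amplitude(self) -> np.ndarray:
        """Per-bin combined amplitude in µm (density * delta_f)."""
        return self.density * self.delta_f

    def peak_frequency(self) -> float:
        """Frequency of the largest bin (Hz)."""
        return float(self.freqs[int(np.argmax(self.density))])

    def crop(self, f_max: float) -> "AmplitudeSpectrum":
        keep = self.freqs <= f_max
        return AmplitudeSpectrum(self.freqs[keep], self.density[keep], self.delta_f)


def _one_sided_amplitude(values: np.ndarray, window: bool) -> np.ndarray:
    n = values.size
    if window:
        w = np.hanning(n)
        spec = np.fft.rfft(values * w)
        amp = (2.0 / n) * np.abs(spec) * 2.0  # Hann amplitude correction
    else:
        spec = np.fft.rfft(values)
        amp = (2.0 / n) * np.abs(spec)
    # bins 0 < k < N/2: drop DC and, for even n, the Nyquist bin
    k_max = (n - 1) // 2
    return amp[1 : k_max + 1]


def amplitude_spectrum(
    x_series: DisplacementSeries,
    y_series: DisplacementSeries,
    window: bool = False,
    f_max: float | None = None,
) -> AmplitudeSpectrum:
    """Combined amplitude spectrum of the two in-plane displacement axes."""
    if x_series.values.size != y_series.values.size:
        raise ValueError("x and y series must have equal length")
    if x_series.fps != y_series.fps:
        raise ValueError("x and y series must share the frame rate")
    n = x_series.values.size
    if n < 16:
        raise ValueError("need at least 16 samples for a spectrum")
    fps = x_series.fps
    delta_f = fps / n
    a_x = _one_sided_amplitude(x_series.values, window)
    a_y = _one_sided_amplitude(y_series.values, window)
    combined = np.sqrt(a_x**2 + a_y**2)
    freqs = delta_f * np.arange(1, combined.size + 1)
    spec = AmplitudeSpectrum(freqs, combined / delta_f, delta_f)
    if f_max is not None:
        spec = spec.crop(f_max)
    return spec


def plot_spectrum(spec: AmplitudeSpectrum, path, title: str = "", y_max: float | None = None):
    """Save a spectrum panel (frequency vs µm/Hz amplitude density)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(spec.freqs, spec.density, lw=0.8)
    ax.set_xlabel("Frequency (Hz)")
    ax.set_ylabel("Amplitude (µm/Hz)")
    if y_max is not None:
        ax.set_ylim(0, y_max)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
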