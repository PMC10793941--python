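"""Gabor filter bank and oriented contrast energy.

The first, parameter-free stage of every model: the preprocessed image is
projected onto a quadrature Gabor bank (8 orientations spaced 22.5 deg,
8 peak frequencies log-spaced 0.75-6 cpd, 2 phases = 128 filters), the two
phase outputs are squared and summed (phase-invariant energy), energies are
summed across frequency bands with uniform weights, and the resulting map
E(x, y, theta) is downsampled to 12 px/deg.

Implementation notes: each quadrature pair is held as one complex kernel
(even + i*odd), so |conv(I, K)|^2 is the phase-summed energy in a single
FFT product. Images are padded with 0 (= mean gray) by the largest kernel
half-width before convolution, which makes the circular FFT convolution
exact, and the padded region is retained in the output map.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .stimuli import StimulusImage

N_ORIENTATIONS = 8
N_FREQUENCIES = 8
FREQ_RANGE_CPD = (0.75, 6.0)
OUT_PPD = 12.0


class GeometryError(ValueError):
    """Image and filter-bank geometry disagree."""


@dataclass
class FilterBank:
    """The 8 x 8 x 2 Gabor set at a given pixel resolution.

    `kernels[i_theta][i_f]` is a complex array: real part the even
    (cosine-phase, DC-removed) kernel, imaginary part the odd (sine-phase)
    kernel. Each filter is a 4-cycle carrier under a Gaussian window of
    SD one cycle, realized on a square support of 4 wavelengths.
    """

    orientations_deg: np.ndarray
    frequencies_cpd: np.ndarray
    ppd: float
    kernels: list  # [i_theta][i_f] -> complex 2D array

    def __post_init__(self):
        self._fft_cache: dict = {}

    @property
    def n_kernels(self) -> int:
        return len(self.orientations_deg) * len(self.frequencies_cpd) * 2

    @property
    def max_halfwidth_px(self) -> int:
        return max(k.shape[0] // 2 for row in self.kernels for k in row)

    def kernel(self, i_theta: int, i_f: int, i_phase: int) -> np.ndarray:
        """Real-valued kernel in (theta, f, phase) enumeration order."""
        c = self.kernels[i_theta][i_f]
        return np.real(c) if i_phase == 0 else np.imag(c)

    def _kernel_ffts(self, shape: tuple[int, int]) -> np.ndarray:
        """FFTs of all complex kernels at `shape`, centered at the origin."""
        if shape not in self._fft_cache:
            nt, nf = len(self.orientations_deg), len(self.frequencies_cpd)
            out = np.empty((nt, nf) + shape, dtype=complex)
            for it in range(nt):
                for jf in range(nf):
                    k = self.kernels[it][jf]
                    pad = np.zeros(shape, dtype=complex)
                    h = k.shape[0]
                    pad[:h, :h] = k
                    # center the kernel on the origin of the circular grid
                    pad = np.roll(pad, (-(h // 2), -(h // 2)), axis=(0, 1))
                    out[it, jf] = np.fft.fft2(pad)
            self._fft_cache[shape] = out
        return self._fft_cache[shape]


@dataclass
class EnergyMap:
    """Oriented contrast energy E(x, y, theta) at 12 px/deg, non-negative."""

    values: np.ndarray  # (ny, nx, n_ori)
    ppd_out: float
    orientations_deg: np.ndarray

    @property
    def n_ori(self) -> int:
        return self.values.shape[2]


def gabor_kernel(ppd: float, orientation_deg: float, freq_cpd: float) -> np.ndarray:
    """One complex quadrature pair (even + i*odd) at the given tuning.

    Support is a square of 4 carrier wavelengths; the Gaussian window SD is
    one wavelength; the even kernel's mean is removed so constant (gray)
    input yields exactly zero energy.
    """
    lam = 1.0 / freq_cpd
    half = int(round(2 * lam * ppd))
    if 2 * half + 1 < 3:
        raise GeometryError(f"filter support below 3 px at {freq_cpd} cpd, ppd={ppd}")
    ax = np.arange(-half, half + 1) / ppd
    xx, yy = np.meshgrid(ax, ax)
    th = np.deg2rad(orientation_deg)
    u = -xx * np.sin(th) + yy * np.cos(th)
    window = np.exp(-(xx**2 + yy**2) / (2 * lam**2))
    even = window * np.cos(2 * np.pi * freq_cpd * u)
    odd = window * np.sin(2 * np.pi * freq_cpd * u)
    even = even - even.mean()
    return even + 1j * odd


def build_filterbank(ppd: float) -> FilterBank:
    """Construct the 128-filter Gabor bank at resolution `ppd`."""
    if ppd < 12:
        raise GeometryError(f"ppd must be >= 12, got {ppd}")
    oris = np.arange(N_ORIENTATIONS) * (180.0 / N_ORIENTATIONS)
    freqs = np.geomspace(*FREQ_RANGE_CPD, N_FREQUENCIES)
    kernels = [[gabor_kernel(ppd, o, f) for f in freqs] for o in oris]
    return FilterBank(oris, freqs, ppd, kernels)


@lru_cache(maxsize=16)
def _downsample_matrix(n_in: int, ppd_in: float, ppd_out: float) -> np.ndarray:
    """Mean-preserving area-overlap downsampling matrix (n_out x n_in)."""
    n_out = int(round(n_in * ppd_out / ppd_in))
    # input pixel i covers [i, i+1)/ppd_in; output j covers [j, j+1)*step
    step = n_in / n_out  # input pixels per output pixel
    W = np.zeros((n_out, n_in))
    for j in range(n_out):
        lo, hi = j * step, (j + 1) * step
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        for i in range(i0, min(i1, n_in)):
            W[j, i] = min(hi, i + 1) - max(lo, i)
        W[j] /= W[j].sum()
    return W


def compute_energy(img: StimulusImage, bank: FilterBank,
                   out_ppd: float = OUT_PPD) -> EnergyMap:
    """Oriented contrast energy of a preprocessed image.

    Pads with 0 (gray) by the largest kernel half-width on all sides,
    convolves with every quadrature pair, squares and sums over phase, sums
    over frequency with uniform weights, and block-downsamples to `out_ppd`.
    """
    if abs(img.ppd - bank.ppd) > 1e-9:
        raise GeometryError(f"image ppd {img.ppd} != bank ppd {bank.ppd}")
    pad = bank.max_halfwidth_px
    I = np.pad(img.pixels, pad)
    shape = I.shape
    Ihat = np.fft.fft2(I)
    khats = bank._kernel_ffts(shape)
    nt = len(bank.orientations_deg)
    E = np.empty(shape + (nt,))
    for it in range(nt):
        acc = np.zeros(shape)
        for jf in range(len(bank.frequencies_cpd)):
            conv = np.fft.ifft2(Ihat * khats[it, jf])
            acc += np.real(conv) ** 2 + np.imag(conv) ** 2
        E[:, :, it] = acc
    W = _downsample_matrix(shape[0], bank.ppd, out_ppd)
    tmp = np.tensordot(W, E, axes=(1, 0))        # rows -> (ny_out, nx_in, t)
    Eds = np.tensordot(W, tmp, axes=(1, 1))      # cols -> (nx_out, ny_out, t)
    Eds = Eds.transpose(1, 0, 2)
    np.maximum(Eds, 0.0, out=Eds)
    return EnergyMap(Eds, out_ppd, bank.orientations_deg.copy())


def oriented_energy(E: EnergyMap) -> np.ndarray:
    """Spatial mean of E per orientation channel (length-8 vector)."""
    return E.values.mean(axis=(0, 1))


def set_energies(stim_set, bank: FilterBank, out_ppd: float = OUT_PPD) -> list[EnergyMap]:
    """Energy maps for every exemplar of a stimulus set."""
    return [compute_energy(ex, bank, out_ppd) for ex in stim_set.exemplars]
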