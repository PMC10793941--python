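"""Band-pass texture synthesis.

All stimulus families used in the encoding-model experiments are grayscale,
band-pass textures with spectral power concentrated near 3 cycles per degree
(cpd). Images are represented as preprocessed luminance: zero mean, values in
[-0.5, 0.5], with the region outside a circular aperture equal to 0
(background gray). Each stimulus is a set of exemplars that share summary
statistics but differ in their precise spatial layout.

Families
--------
snakes
    Curved band-pass contours made by low-pass filtering white noise,
    thresholding, edge detection, polarity inversion, and band-pass filtering.
gratings
    Straight parallel contours: either 1-px lines convolved with the band-pass
    kernel ("lines" mode) or 3 cpd sinusoids ("sinusoid" mode).
noise_bars
    Parallel bands filled with isotropic band-pass noise (power spread evenly
    across orientations).
waves
    Snakes filtered in the Fourier orientation domain so power concentrates
    near one orientation.
plaid / circular
    Sums of 2 or 16 sinusoidal components at equally spaced orientations,
    RMS-matched to a reference grating.

Orientation convention: 0 deg = horizontal contours (luminance varies
vertically); angles increase counterclockwise. All modules share it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.signal import fftconvolve


class StimulusError(ValueError):
    """Invalid stimulus parameters (out-of-range contrast, spacing, ...)."""


class KernelSolveError(RuntimeError):
    """No DoG parameterization satisfies the spectral contract."""


# ---------------------------------------------------------------------------
# canvas dialects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanvasDialect:
    """Display geometry: aperture size in deg and pixel resolution."""

    name: str
    size_deg: float
    n_pix: int

    @property
    def ppd(self) -> float:
        return self.n_pix / self.size_deg


#: Display geometries of the four fMRI sessions plus a scaled-down canvas
#: used as the default for simulations and tests.
DIALECTS = {
    "ds1": CanvasDialect("ds1", 12.5, 400),
    "ds2": CanvasDialect("ds2", 18.75, 600),
    "ds3": CanvasDialect("ds3", 12.5, 256),
    "ds4": CanvasDialect("ds4", 12.5, 256),
    "small": CanvasDialect("small", 6.0, 144),
}

#: Low-pass cutoffs (cpd) defining the snake density ladder, densest first.
SNAKE_DENSITY_CUTOFFS = (2.8, 1.6, 0.9, 0.5, 0.3)

#: Line spacings (deg) defining the grating/noise-bar density ladder.
GRATING_DENSITY_SPACINGS = (3.0, 2.5, 1.75, 1.0, 1.0 / 3.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StimulusImage:
    """A preprocessed grayscale image: zero-mean, range [-0.5, 0.5]."""

    pixels: np.ndarray
    ppd: float
    aperture_deg: float

    @property
    def size_deg(self) -> float:
        return self.pixels.shape[0] / self.ppd


@dataclass
class StimulusSet:
    """A family of exemplar images sharing geometry and generation params."""

    family: str
    manipulation: str
    level: float
    exemplars: list[StimulusImage]
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def ppd(self) -> float:
        return self.exemplars[0].ppd

    def scaled(self, factor: float) -> "StimulusSet":
        """Return a copy with every exemplar's pixels scaled by `factor`."""
        ex = [replace(e, pixels=e.pixels * factor) for e in self.exemplars]
        meta = dict(self.meta, rescale=factor)
        return replace(self, exemplars=ex, meta=meta)


@dataclass
class BandpassKernel:
    """Zero-mean isotropic Difference-of-Gaussians band-pass filter."""

    weights: np.ndarray
    peak_cpd: float
    ppd: float
    sigma_center_deg: float = 0.0
    sigma_surround_deg: float = 0.0


# ---------------------------------------------------------------------------
# band-pass kernel
# ---------------------------------------------------------------------------

def _dog_spectrum(f, sc, ss):
    # FT of (unit-mass Gaussian sc) - (unit-mass Gaussian ss); zero at DC.
    return np.exp(-2 * np.pi**2 * sc**2 * f**2) - np.exp(-2 * np.pi**2 * ss**2 * f**2)


def _dog_features(sc: float, ss: float) -> tuple[float, float, float]:
    """Peak frequency and half-maximum crossings of the analytic spectrum."""
    # analytic argmax of the two-Gaussian difference
    fpk = np.sqrt(np.log(ss**2 / sc**2) / (2 * np.pi**2 * (ss**2 - sc**2)))
    spk = _dog_spectrum(fpk, sc, ss)
    lo = optimize.brentq(lambda x: _dog_spectrum(x, sc, ss) - spk / 2, 1e-9, fpk)
    hi = optimize.brentq(lambda x: _dog_spectrum(x, sc, ss) - spk / 2, fpk, 1e3)
    return fpk, lo, hi


def make_bandpass_kernel(
    ppd: float,
    peak_cpd: float = 3.0,
    half_max_lo_cpd: float = 1.4,
    half_max_hi_cpd: float = 4.7,
    rtol: float = 0.10,
) -> BandpassKernel:
    """Solve a DoG whose amplitude spectrum peaks at `peak_cpd` and crosses
    half-maximum at the two stated frequencies (each within `rtol` relative).

    The two Gaussian scales are found by least squares on the log of the three
    spectral features; with two degrees of freedom against three constraints
    the fit is approximate, and the contract is verified on the realized
    discrete kernel via FFT.
    """
    if ppd <= 2 * half_max_hi_cpd:
        raise StimulusError(
            f"ppd={ppd} violates Nyquist for upper half-max {half_max_hi_cpd} cpd"
        )

    targets = np.array([peak_cpd, half_max_lo_cpd, half_max_hi_cpd])

    def resid(p):
        sc, ss = np.exp(p)
        if not ss > sc * 1.0001:
            return np.full(3, 10.0)
        try:
            feats = np.array(_dog_features(sc, ss))
        except ValueError:
            return np.full(3, 10.0)
        return np.log(feats / targets)

    best = None
    for s0 in [(0.05, 0.2), (0.03, 0.1), (0.02, 0.3), (0.06, 0.12)]:
        sol = optimize.least_squares(resid, np.log(s0), method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    sc, ss = np.exp(best.x)

    # realize on a pixel grid out to 5 surround SDs
    half = max(int(np.ceil(5 * ss * ppd)), 4)
    ax = (np.arange(-half, half + 1)) / ppd
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    w = (
        np.exp(-r2 / (2 * sc**2)) / (2 * np.pi * sc**2)
        - np.exp(-r2 / (2 * ss**2)) / (2 * np.pi * ss**2)
    )
    w = w - w.mean()  # exact zero DC on the discrete grid
    w = w / np.abs(w).max()

    kern = BandpassKernel(w, peak_cpd, ppd, sc, ss)
    pk, lo, hi = kernel_spectral_features(kern)
    for got, want in ((pk, peak_cpd), (lo, half_max_lo_cpd), (hi, half_max_hi_cpd)):
        if abs(got / want - 1) > rtol:
            raise KernelSolveError(
                f"DoG solve missed spectral contract: got peak/lo/hi = "
                f"({pk:.3f}, {lo:.3f}, {hi:.3f}) cpd for targets {tuple(targets)}"
            )
    return kern


def kernel_spectral_features(kern: BandpassKernel, n_fft: int = 512) -> tuple[float, float, float]:
    """Peak and half-maximum crossings of the realized kernel, by dense FFT.

    Computed on a radial scan of the 2-D discrete amplitude spectrum; serves
    as the independent check that the analytic solve survives discretization.
    """
    n = max(n_fft, kern.weights.shape[0])
    amp = np.abs(np.fft.fft2(kern.weights, s=(n, n)))
    f1 = np.fft.fftfreq(n, d=1.0 / kern.ppd)
    fx, fy = np.meshgrid(f1, f1)
    fr = np.hypot(fx, fy).ravel()
    a = amp.ravel()
    order = np.argsort(fr)
    fr, a = fr[order], a[order]
    # bin the radial profile
    nbins = 400
    fmax = kern.ppd / 2
    idx = np.minimum((fr / fmax * nbins).astype(int), nbins - 1)
    prof = np.bincount(idx, weights=a, minlength=nbins) / np.maximum(
        np.bincount(idx, minlength=nbins), 1
    )
    fc = (np.arange(nbins) + 0.5) * fmax / nbins
    ipk = int(np.argmax(prof))
    half = prof[ipk] / 2
    lo_i = np.where(prof[:ipk] < half)[0]
    hi_i = np.where(prof[ipk:] < half)[0]
    lo = np.interp(half, prof[lo_i[-1]: lo_i[-1] + 2], fc[lo_i[-1]: lo_i[-1] + 2]) if len(lo_i) else fc[0]
    if len(hi_i):
        j = ipk + hi_i[0]
        hi = np.interp(-half, -prof[j - 1: j + 1], fc[j - 1: j + 1])
    else:
        hi = fc[-1]
    return fc[ipk], lo, hi


# ---------------------------------------------------------------------------
# aperture
# ---------------------------------------------------------------------------

def apply_aperture(img: StimulusImage, aperture_deg: float | None = None,
                   blend_deg: float = 0.5) -> StimulusImage:
    """Zero pixels outside a circular aperture, blending the outer
    `blend_deg` of the disc into the background with a half-cosine ramp."""
    if aperture_deg is None:
        aperture_deg = img.size_deg
    n = img.pixels.shape[0]
    ax = (np.arange(n) - (n - 1) / 2) / img.ppd
    xx, yy = np.meshgrid(ax, ax)
    r = np.hypot(xx, yy)
    rad = aperture_deg / 2
    w = np.ones_like(r)
    w[r >= rad] = 0.0
    ramp = (r > rad - blend_deg) & (r < rad)
    w[ramp] = 0.5 * (1 + np.cos(np.pi * (r[ramp] - (rad - blend_deg)) / blend_deg))
    return StimulusImage(img.pixels * w, img.ppd, aperture_deg)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _coord_u(n: int, ppd: float, orientation_deg: float, offset_deg: float = 0.0):
    """Signed distance (deg) across contours of orientation `orientation_deg`."""
    ax = (np.arange(n) - (n - 1) / 2) / ppd
    xx, yy = np.meshgrid(ax, ax)
    th = np.deg2rad(orientation_deg)
    return -xx * np.sin(th) + yy * np.cos(th) + offset_deg


def _radial_freq_grid(n: int, ppd: float):
    f1 = np.fft.fftfreq(n, d=1.0 / ppd)
    fx, fy = np.meshgrid(f1, f1)
    return fx, fy


def _lowpass_noise(rng: np.random.Generator, n: int, ppd: float, cutoff_cpd: float):
    """White noise low-pass filtered at `cutoff_cpd` (raised-cosine edge)."""
    noise = rng.standard_normal((n, n))
    fx, fy = _radial_freq_grid(n, ppd)
    fr = np.hypot(fx, fy)
    edge = 0.2 * cutoff_cpd
    h = np.clip((cutoff_cpd + edge - fr) / (2 * edge), 0.0, 1.0)
    h = 0.5 * (1 - np.cos(np.pi * h))
    return np.real(np.fft.ifft2(np.fft.fft2(noise) * h))


def _bandpass(pix: np.ndarray, kern: BandpassKernel) -> np.ndarray:
    return fftconvolve(pix - pix.mean(), kern.weights, mode="same")


def _scale_to_contrast(pix: np.ndarray, contrast: float) -> np.ndarray:
    """Scale so max|pixel| = contrast/2 (contrast 1 fills [-0.5, 0.5])."""
    m = np.abs(pix).max()
    if m == 0 or contrast == 0:
        return np.zeros_like(pix)
    return pix * (contrast / 2) / m


def _check_contrast(contrast: float) -> None:
    if not 0 <= contrast <= 1:
        raise StimulusError(f"contrast must be in [0, 1], got {contrast}")


def _finalize(pix, ppd, aperture_deg, contrast, blend_deg=0.5) -> StimulusImage:
    img = StimulusImage(_scale_to_contrast(pix, contrast), ppd, aperture_deg)
    return apply_aperture(img, aperture_deg, blend_deg)


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

def synth_snakes(
    level_cpd: float,
    contrast: float,
    n_exemplars: int = 9,
    size_deg: float = 12.5,
    ppd: float = 32.0,
    seed: int = 0,
    bp_kernel: BandpassKernel | None = None,
) -> StimulusSet:
    """Curved band-pass contours ("snakes").

    Pipeline per exemplar: white noise -> low-pass at `level_cpd` ->
    threshold at the median -> first-difference edge detection (x and y,
    combined by maximum) -> polarity inversion (edges dark) -> band-pass
    filter -> contrast scaling -> aperture blend. Lower cutoffs give
    sparser contours; the density ladder uses cutoffs 2.8..0.3 cpd.
    """
    _check_contrast(contrast)
    if not 0.1 <= level_cpd <= 5.0:
        raise StimulusError(f"cutoff {level_cpd} cpd outside sane range 0.1-5")
    if bp_kernel is None:
        bp_kernel = make_bandpass_kernel(ppd)
    n = int(round(size_deg * ppd))
    rng = np.random.default_rng(seed)
    exemplars = []
    for _ in range(n_exemplars):
        lp = _lowpass_noise(rng, n, ppd, level_cpd)
        binary = (lp > np.median(lp)).astype(float)
        ex = np.abs(np.diff(binary, axis=1, prepend=binary[:, :1]))
        ey = np.abs(np.diff(binary, axis=0, prepend=binary[:1, :]))
        edges = np.maximum(ex, ey)
        pix = _bandpass(-edges, bp_kernel)
        exemplars.append(_finalize(pix, ppd, size_deg, contrast))
    return StimulusSet("snakes", "density", level_cpd, exemplars, seed)


def synth_gratings(
    spacing_deg: float,
    contrast: float,
    orientation_deg: float = 0.0,
    mode: str = "lines",
    n_exemplars: int = 9,
    size_deg: float = 12.5,
    ppd: float = 32.0,
    seed: int = 0,
    bp_kernel: BandpassKernel | None = None,
) -> StimulusSet:
    """Straight parallel contours.

    "lines" mode places 1-px parallel lines every `spacing_deg` and convolves
    with the band-pass kernel; exemplars differ by a seeded offset of the line
    comb. "sinusoid" mode ignores spacing and produces 3 cpd sinusoids whose
    exemplars differ in phase, equally spaced over [0, 2pi).
    """
    _check_contrast(contrast)
    n = int(round(size_deg * ppd))
    rng = np.random.default_rng(seed)
    exemplars = []
    if mode == "sinusoid":
        for k in range(n_exemplars):
            phase = 2 * np.pi * k / n_exemplars
            u = _coord_u(n, ppd, orientation_deg)
            pix = (contrast / 2) * np.sin(2 * np.pi * 3.0 * u + phase)
            exemplars.append(apply_aperture(StimulusImage(pix, ppd, size_deg)))
        return StimulusSet("gratings", "contrast", contrast, exemplars, seed,
                           meta={"mode": mode, "orientation_deg": orientation_deg})
    if mode != "lines":
        raise StimulusError(f"unknown grating mode {mode!r}")
    if spacing_deg < 1.0 / ppd:
        raise StimulusError(
            f"spacing {spacing_deg} deg is below one pixel ({1.0 / ppd:.4f} deg)"
        )
    if bp_kernel is None:
        bp_kernel = make_bandpass_kernel(ppd)
    for _ in range(n_exemplars):
        offset = rng.uniform(0, spacing_deg)
        u = _coord_u(n, ppd, orientation_deg, offset)
        frac = np.mod(u + spacing_deg / 2, spacing_deg) - spacing_deg / 2
        lines = (np.abs(frac) < 0.5 / ppd).astype(float)
        pix = _bandpass(lines, bp_kernel)
        exemplars.append(_finalize(pix, ppd, size_deg, contrast))
    return StimulusSet("gratings", "density", spacing_deg, exemplars, seed,
                       meta={"mode": mode, "orientation_deg": orientation_deg})


def _orientation_filter(pix: np.ndarray, ppd: float, orientation_deg: float,
                        sigma_deg: float = 20.0) -> np.ndarray:
    """Fourier-plane angular Gaussian window, symmetric over both half-planes."""
    n = pix.shape[0]
    fx, fy = _radial_freq_grid(n, ppd)
    th = np.deg2rad(orientation_deg)
    phi0 = np.arctan2(np.cos(th), -np.sin(th))  # direction of the carrier
    phi = np.arctan2(fy, fx)
    d = np.mod(phi - phi0 + np.pi / 2, np.pi) - np.pi / 2  # pi-periodic distance
    w = np.exp(-np.rad2deg(d) ** 2 / (2 * sigma_deg**2))
    w[0, 0] = 1.0
    return np.real(np.fft.ifft2(np.fft.fft2(pix) * w))


def synth_waves(
    level_cpd: float,
    contrast: float,
    orientation_deg: float = 0.0,
    n_exemplars: int = 9,
    size_deg: float = 12.5,
    ppd: float = 32.0,
    seed: int = 0,
    bp_kernel: BandpassKernel | None = None,
    angular_sigma_deg: float = 20.0,
) -> StimulusSet:
    """Snakes filtered by orientation so power concentrates near one angle."""
    snakes = synth_snakes(level_cpd, 1.0, n_exemplars, size_deg, ppd, seed, bp_kernel)
    exemplars = []
    for ex in snakes.exemplars:
        pix = _orientation_filter(ex.pixels, ppd, orientation_deg, angular_sigma_deg)
        exemplars.append(_finalize(pix, ppd, size_deg, contrast))
    return StimulusSet("waves", "density", level_cpd, exemplars, seed,
                       meta={"orientation_deg": orientation_deg})


def synth_noise_bars(
    spacing_deg: float,
    contrast: float,
    orientation_deg: float = 0.0,
    n_exemplars: int = 9,
    size_deg: float = 12.5,
    ppd: float = 32.0,
    seed: int = 0,
    bp_kernel: BandpassKernel | None = None,
    bar_halfwidth_deg: float = 1.0 / 6.0,
) -> StimulusSet:
    """Parallel bands filled with isotropic band-pass noise.

    The contrast aperture (bands every `spacing_deg`) matches the grating
    comb; each band contains noise with power spread equally across
    orientations rather than oriented contours.
    """
    _check_contrast(contrast)
    if spacing_deg < 1.0 / ppd:
        raise StimulusError(f"spacing {spacing_deg} deg below one pixel")
    if bp_kernel is None:
        bp_kernel = make_bandpass_kernel(ppd)
    n = int(round(size_deg * ppd))
    rng = np.random.default_rng(seed)
    exemplars = []
    for _ in range(n_exemplars):
        noise = _bandpass(rng.standard_normal((n, n)), bp_kernel)
        offset = rng.uniform(0, spacing_deg)
        u = _coord_u(n, ppd, orientation_deg, offset)
        frac = np.mod(u + spacing_deg / 2, spacing_deg) - spacing_deg / 2
        mask = (np.abs(frac) < bar_halfwidth_deg).astype(float)
        exemplars.append(_finalize(noise * mask, ppd, size_deg, contrast))
    return StimulusSet("noise_bars", "density", spacing_deg, exemplars, seed,
                       meta={"orientation_deg": orientation_deg})


def synth_multi_component(
    n_orientations: int,
    contrast: float,
    n_exemplars: int = 9,
    size_deg: float = 12.5,
    ppd: float = 32.0,
    seed: int = 0,
) -> StimulusSet:
    """Sum of `n_orientations` equally spaced 3 cpd sinusoids, random phases.

    n=2 gives a plaid, n=16 the "circular" family. The set is rescaled by a
    single factor so its mean RMS contrast matches a reference sinusoidal
    grating set at the same nominal contrast.
    """
    _check_contrast(contrast)
    if n_orientations < 1:
        raise StimulusError("need at least one component")
    n = int(round(size_deg * ppd))
    rng = np.random.default_rng(seed)
    ref = synth_gratings(0.0, contrast, 0.0, "sinusoid", n_exemplars, size_deg, ppd, seed)
    ref_rms = float(np.mean([np.sqrt(np.mean(e.pixels**2)) for e in ref.exemplars]))
    raw = []
    for _ in range(n_exemplars):
        pix = np.zeros((n, n))
        for k in range(n_orientations):
            ang = 180.0 * k / n_orientations
            u = _coord_u(n, ppd, ang)
            pix += np.sin(2 * np.pi * 3.0 * u + rng.uniform(0, 2 * np.pi))
        raw.append(apply_aperture(StimulusImage(pix, ppd, size_deg)))
    rms = float(np.mean([np.sqrt(np.mean(e.pixels**2)) for e in raw]))
    scale = ref_rms / rms if rms > 0 else 0.0
    exemplars = [replace(e, pixels=np.clip(e.pixels * scale, -0.5, 0.5)) for e in raw]
    family = {1: "gratings", 2: "plaid"}.get(n_orientations, "circular")
    return StimulusSet(family, "contrast", contrast, exemplars, seed,
                       meta={"n_orientations": n_orientations, "rms": ref_rms})


def apply_cross_blanks(stim: StimulusSet, blank_spacing_deg: float = 1.75,
                       duty: float = 0.25) -> StimulusSet:
    """Interrupt the contours of a grating set with periodic perpendicular
    blank regions ("cross" gratings).

    Blanks are spaced every `blank_spacing_deg` perpendicular to the line
    orientation; `duty` is the blanked fraction of each period (0.25 thin,
    0.5 thick).
    """
    if not 0 < duty < 1:
        raise StimulusError(f"duty cycle must be in (0, 1), got {duty}")
    ori = float(stim.meta.get("orientation_deg", 0.0)) + 90.0
    exemplars = []
    for e in stim.exemplars:
        n = e.pixels.shape[0]
        u = _coord_u(n, e.ppd, ori)
        frac = np.mod(u, blank_spacing_deg) / blank_spacing_deg
        mask = (frac >= duty).astype(float)
        exemplars.append(replace(e, pixels=e.pixels * mask))
    meta = dict(stim.meta, cross_blank_spacing=blank_spacing_deg, duty=duty)
    return replace(stim, family="gratings_cross", exemplars=exemplars,
                   meta=meta)


def rms_contrast(stim: StimulusSet) -> float:
    """Mean root-mean-square pixel value across exemplars."""
    return float(np.mean([np.sqrt(np.mean(e.pixels**2)) for e in stim.exemplars]))
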