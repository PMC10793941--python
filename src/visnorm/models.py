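"""The four encoding models: pooling functionals and power-law output.

Every model maps an oriented contrast-energy map E(x, y, theta) to a scalar
drive s, then to a predicted BOLD amplitude r = g * s**alpha (percent signal
change). The models differ only in the pooling stage:

ce   contrast energy: s = mean of E over space and orientation.
dn   untuned divisive normalization: each element of E is divided by
     sigma + Z, where Z is a spatial Gaussian pool of E summed over all
     orientation channels; s is the mean of the normalized map.
otn  orientation-tuned normalization: as dn, but the pool at surrounding
     locations is restricted to the same orientation channel; other
     orientations contribute only at the center pixel (cross-orientation
     suppression).
noa  normalization by orientation anisotropy: the spatially pooled energy
     per orientation channel is normalized by the spread (sum of squared
     deviations) across the 8 channels: s = mean(e^2) / (sigma^2 + V).

The Gaussian pool weights have unit peak amplitude (center weight 1) in
every orientation plane, so a uniform field E = c yields Z = 8 c W for the
untuned pool, with W the total weight of one Gaussian plane (see
`make_norm_kernel` for why peak rather than sum normalization). Any fixed
overall scale is absorbed by the fitted sigma; fixing the convention makes
sigma comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .energy import EnergyMap, oriented_energy

#: denominator floor guarding sigma = 0 on zero-energy pixels
EPS = 1e-12

#: normalization-pool Gaussian SD as a fraction of the energy-map width
NORM_SD_FRAC = 0.04

MODEL_NAMES = ("ce", "dn", "otn", "noa")

#: number of free parameters per model (g, alpha[, sigma])
N_PARAMS = {"ce": 2, "dn": 3, "otn": 3, "noa": 3}


@dataclass
class ParamVector:
    """Model parameters: gain g >= 0, exponent alpha in (0, 1), and the
    normalization semisaturation sigma (unused by the ce model)."""

    g: float
    alpha: float
    sigma: float | None = None

    def to_dict(self) -> dict:
        return {"g": self.g, "alpha": self.alpha, "sigma": self.sigma}

    @classmethod
    def from_dict(cls, d: dict) -> "ParamVector":
        return cls(d["g"], d["alpha"], d.get("sigma"))


@dataclass
class NormKernel:
    """Spatial weights of the normalization pool.

    `spatial` is a unit-sum 2D Gaussian. For the tuned variant the
    same-orientation plane uses the full Gaussian while every other
    orientation plane collapses to the center pixel (a discrete delta).
    """

    spatial: np.ndarray
    sd_px: float
    tuned: bool


def make_norm_kernel(map_width_px: int, tuned: bool,
                     sd_frac: float = NORM_SD_FRAC) -> NormKernel:
    """Gaussian pool with SD = `sd_frac` of the (padded, downsampled)
    energy-map width, truncated at 3 SD, normalized to unit PEAK (center
    weight 1).

    Peak rather than sum normalization matters for the tuned variant: the
    surround plane then carries total weight ~2*pi*sd^2 against weight 1 for
    each single-pixel cross-orientation term, so concentrating energy at one
    orientation (a grating) recruits a much larger pool than spreading it
    (a snake). With sum-normalized planes every channel would contribute
    weight 1 and the tuned pool would collapse onto the untuned one for
    spatially homogeneous textures. The absolute scale is absorbed by the
    fitted sigma.
    """
    sd = sd_frac * map_width_px
    half = max(int(np.ceil(3 * sd)), 1)
    ax = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(ax, ax)
    g = np.exp(-(xx**2 + yy**2) / (2 * sd**2))
    return NormKernel(g, sd, tuned)


def norm_pool(E: EnergyMap, kern: NormKernel) -> np.ndarray:
    """The normalizer Z(x, y, theta) for the dn / otn models.

    Untuned: Z is the Gaussian convolution of E summed over all orientation
    planes (identical across channels). Tuned: the Gaussian surround sees
    only the same-orientation plane; the remaining channels enter through
    their center-pixel (same-location) energy.
    """
    V = E.values
    if not kern.tuned:
        pooled = fftconvolve(V.sum(axis=2), kern.spatial, mode="same")
        return np.repeat(pooled[:, :, None], V.shape[2], axis=2)
    total = V.sum(axis=2)
    Z = np.empty_like(V)
    for t in range(V.shape[2]):
        same = fftconvolve(V[:, :, t], kern.spatial, mode="same")
        Z[:, :, t] = same + (total - V[:, :, t])
    return Z


def pool_ce(E: EnergyMap) -> float:
    """Mean contrast energy over space and orientation (Eq for the ce model)."""
    return float(E.values.mean())


def pool_dn(E: EnergyMap, sigma: float, kern: NormKernel) -> float:
    """Divisively normalized energy, averaged over space and orientation."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    Z = norm_pool(E, kern)
    d = E.values / np.maximum(sigma + Z, EPS)
    return float(d.mean())


def pool_otn(E: EnergyMap, sigma: float, kern: NormKernel) -> float:
    """Orientation-tuned variant of pool_dn; `kern` must be tuned."""
    return pool_dn(E, sigma, kern)


def anisotropy(e_ori: np.ndarray, sqrt_variant: bool = False) -> float:
    """Spread of energy across orientation channels.

    Default: the sum of squared deviations from the channel mean (no 1/N,
    no square root). With `sqrt_variant` the square root is taken, giving a
    quantity on the scale of the energies themselves.
    """
    v = float(np.sum((e_ori - e_ori.mean()) ** 2))
    return float(np.sqrt(v)) if sqrt_variant else v


def pool_noa(e_ori: np.ndarray, sigma: float, sqrt_variant: bool = False) -> float:
    """Normalization by orientation anisotropy.

    s = mean(e^2) / (sigma^2 + V) with V the sum of squared deviations
    across the 8 channels (numerator and sigma squared to match the squaring
    inside the anisotropy term). The `sqrt_variant` switch uses
    s = mean(e) / (sigma + sqrt(V)) instead.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    e = np.asarray(e_ori, dtype=float)
    if sqrt_variant:
        denom = max(sigma + anisotropy(e, sqrt_variant=True), EPS)
        return float(e.mean() / denom)
    denom = max(sigma**2 + anisotropy(e), EPS)
    return float(np.mean(e**2) / denom)


def respond(s: float, p: ParamVector) -> float:
    """Power-law output stage: r = g * s**alpha, in percent signal change."""
    return float(p.g * s**p.alpha)


def pool(model_name: str, E: EnergyMap, p: ParamVector,
         kern_untuned: NormKernel | None = None,
         kern_tuned: NormKernel | None = None) -> float:
    """Dispatch the pooling functional for one energy map."""
    if model_name == "ce":
        return pool_ce(E)
    if model_name == "dn":
        if kern_untuned is None:
            kern_untuned = make_norm_kernel(E.values.shape[0], tuned=False)
        return pool_dn(E, p.sigma, kern_untuned)
    if model_name == "otn":
        if kern_tuned is None:
            kern_tuned = make_norm_kernel(E.values.shape[0], tuned=True)
        return pool_otn(E, p.sigma, kern_tuned)
    if model_name == "noa":
        return pool_noa(oriented_energy(E), p.sigma)
    raise KeyError(f"unknown model {model_name!r}; registry: {MODEL_NAMES}")


def predict_stimulus(model_name: str, stim_set, bank, p: ParamVector,
                     **kern_kwargs) -> float:
    """Predicted response to a stimulus: the mean over exemplars of the
    per-exemplar predictions (pool then power law, then average)."""
    from .energy import compute_energy

    preds = [
        respond(pool(model_name, compute_energy(ex, bank), p, **kern_kwargs), p)
        for ex in stim_set.exemplars
    ]
    return float(np.mean(preds))
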