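"""Diagnostic analyses built on the model pipeline.

- energy-matched snakes/gratings "target" batteries and the snakes-to-
  gratings prediction-ratio experiment (the key qualitative dissociation:
  orientation-sensitive models predict about double the response to snakes);
- a center-surround suppression simulation distinguishing the two
  orientation-sensitive models (suppression maximal at the unit's preferred
  orientation for the tuned-surround model, at the center-stimulus
  orientation for the anisotropy model);
- an adapter for the published per-ROI beta arrays (MAT container with a
  voxels x stimuli x bootstraps "betas" array grouped by "roi"/"roilabels");
- a synthetic BOLD generator for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stimuli as st
from .energy import FilterBank, build_filterbank, compute_energy, oriented_energy, set_energies
from .fitting import ROIResponseTable, StimulusFeatures, predict_from_features, prepare_features
from .models import NormKernel, ParamVector, anisotropy, make_norm_kernel, norm_pool


class DataFormatError(ValueError):
    """A data container lacks a required field or has the wrong shape."""


# ---------------------------------------------------------------------------
# fixture batteries
# ---------------------------------------------------------------------------

#: contrast ladder shared by the target batteries (fractions of full range)
TARGET_CONTRASTS = (0.03, 0.10, 0.25, 0.50, 1.00)


def target_battery(dialect: st.CanvasDialect = st.DIALECTS["small"],
                   contrasts=TARGET_CONTRASTS, n_exemplars: int = 3,
                   seed: int = 0, bank: FilterBank | None = None,
                   match_tol: float = 0.15):
    """Energy-matched snakes/gratings target sets across a contrast ladder.

    Returns (stim_sets, labels, achieved_match) where labels are
    "snakes"/"gratings" per set and achieved_match is the grating/snake
    total-energy ratio after matching (contract: within `match_tol` of 1).
    Because energy is exactly quadratic in pixel contrast, a single sqrt
    rescale of the grating pixels achieves the match; the rescale factor is
    measured once at full contrast and applied to the whole ladder.
    """
    ppd = dialect.ppd
    if bank is None:
        bank = build_filterbank(ppd)
    bp = st.make_bandpass_kernel(ppd)
    snake_full = st.synth_snakes(0.9, 1.0, n_exemplars, dialect.size_deg, ppd,
                                 seed, bp)
    grat_full = st.synth_gratings(1.0 / 3.0, 1.0, 0.0, "lines", n_exemplars,
                                  dialect.size_deg, ppd, seed + 1, bp)
    e_snake = np.mean([compute_energy(ex, bank).values.sum()
                       for ex in snake_full.exemplars])
    e_grat = np.mean([compute_energy(ex, bank).values.sum()
                      for ex in grat_full.exemplars])
    scale = float(np.sqrt(e_snake / e_grat))
    # keep pixels within [-0.5, 0.5]: if the gratings would clip, scale the
    # snakes down instead
    grat_peak = max(np.abs(ex.pixels).max() for ex in grat_full.exemplars)
    snake_factor, grat_factor = 1.0, scale
    if grat_peak * scale > 0.5:
        snake_factor, grat_factor = 1.0 / scale, 1.0
    achieved = (e_grat * grat_factor**2) / (e_snake * snake_factor**2)

    sets, labels = [], []
    for c in contrasts:
        s = st.synth_snakes(0.9, c, n_exemplars, dialect.size_deg, ppd, seed, bp)
        g = st.synth_gratings(1.0 / 3.0, c, 0.0, "lines", n_exemplars,
                              dialect.size_deg, ppd, seed + 1, bp)
        sets.append(s.scaled(snake_factor))
        labels.append("snakes")
        sets.append(g.scaled(grat_factor))
        labels.append("gratings")
    return sets, labels, float(achieved)


def mixed_battery(dialect: st.CanvasDialect = st.DIALECTS["small"],
                  n_exemplars: int = 2, seed: int = 0):
    """A varied ~26-stimulus battery spanning the texture families.

    Snakes and gratings over contrast and density ladders, waves and
    noise-bars at several orientations, plaids and circular patterns --
    enough orientation-homogeneous and -heterogeneous stimuli to
    discriminate the four models in simulation.
    """
    ppd, size = dialect.ppd, dialect.size_deg
    bp = st.make_bandpass_kernel(ppd)
    sets = []
    for c in (0.10, 0.25, 0.50, 1.00):
        sets.append(st.synth_snakes(0.9, c, n_exemplars, size, ppd, seed, bp))
    for cut in st.SNAKE_DENSITY_CUTOFFS[1:]:
        sets.append(st.synth_snakes(cut, 0.25, n_exemplars, size, ppd, seed + 1, bp))
    for c in (0.10, 0.25, 0.50, 1.00):
        sets.append(st.synth_gratings(1.0 / 3.0, c, 0.0, "lines",
                                      n_exemplars, size, ppd, seed + 2, bp))
    for sp in st.GRATING_DENSITY_SPACINGS[1:]:
        sets.append(st.synth_gratings(sp, 0.25, 0.0, "lines",
                                      n_exemplars, size, ppd, seed + 3, bp))
    for ang in (0.0, 45.0, 90.0):
        sets.append(st.synth_waves(0.9, 0.5, ang, n_exemplars, size, ppd,
                                   seed + 4, bp))
    for sp in (1.75, 1.0, 1.0 / 3.0):
        sets.append(st.synth_noise_bars(sp, 0.5, 0.0, n_exemplars, size, ppd,
                                        seed + 5, bp))
    for n_comp, c in ((2, 0.25), (2, 1.0), (16, 0.25), (16, 1.0)):
        sets.append(st.synth_multi_component(n_comp, c, n_exemplars, size,
                                             ppd, seed + 6))
    return sets


def comparison_battery(dialect: st.CanvasDialect = st.DIALECTS["small"],
                       n_exemplars: int = 2, seed: int = 0,
                       bank: FilterBank | None = None):
    """A 30-stimulus battery for synthetic model comparison and recovery.

    Energy-matched snakes/gratings contrast ladders (the diagnostic pair),
    snake and grating density ladders, waves, noise bars, and plaid/circular
    patterns: enough variation in both overall contrast energy and
    orientation heterogeneity to separate the four models.
    """
    ppd, size = dialect.ppd, dialect.size_deg
    bp = st.make_bandpass_kernel(ppd)
    sets, labels, _ = target_battery(dialect, TARGET_CONTRASTS, n_exemplars,
                                     seed, bank)
    for cut in st.SNAKE_DENSITY_CUTOFFS:
        sets.append(st.synth_snakes(cut, 0.5, n_exemplars, size, ppd, seed + 10, bp))
        labels.append("snakes_density")
    for sp in st.GRATING_DENSITY_SPACINGS:
        sets.append(st.synth_gratings(sp, 0.5, 0.0, "lines", n_exemplars,
                                      size, ppd, seed + 11, bp))
        labels.append("gratings_density")
    for c in (0.25, 1.0):
        sets.append(st.synth_waves(0.9, c, 0.0, n_exemplars, size, ppd, seed + 12, bp))
        labels.append("waves")
        sets.append(st.synth_noise_bars(1.0, c, 0.0, n_exemplars, size, ppd,
                                        seed + 13, bp))
        labels.append("noise_bars")
        sets.append(st.synth_multi_component(2, c, n_exemplars, size, ppd, seed + 14))
        labels.append("plaid")
        sets.append(st.synth_multi_component(16, c, n_exemplars, size, ppd, seed + 15))
        labels.append("circular")
    return sets, labels


def battery_energies(sets, bank: FilterBank) -> list:
    """Exemplar energy maps for every stimulus set in a battery."""
    return [set_energies(s, bank) for s in sets]


def moderate_sigma(features: list[StimulusFeatures], model_name: str) -> float:
    """A mid-range normalization strength derived from the battery itself.

    For dn/otn: the energy-weighted geometric mean of the normalizer Z over
    all stimuli (sigma comparable to typical pool activity). For noa: the
    square root of the median anisotropy.
    """
    if model_name in ("dn", "otn"):
        logs, weights = [], []
        for f in features:
            mask = f.e_sums > 0
            logs.append(np.log(np.maximum(f.z_reps[mask], 1e-300)))
            weights.append(f.e_sums[mask])
        logs = np.concatenate(logs)
        weights = np.concatenate(weights)
        return float(np.exp(np.average(logs, weights=weights)))
    if model_name == "noa":
        v = np.concatenate([f.aniso for f in features])
        return float(np.sqrt(np.median(v)))
    raise KeyError(f"no sigma heuristic for model {model_name!r}")


# ---------------------------------------------------------------------------
# snakes / gratings ratio experiment
# ---------------------------------------------------------------------------

@dataclass
class RatioReport:
    """Mean predicted snake response over mean predicted grating response."""

    model: str
    ratio: float
    mean_snakes: float
    mean_gratings: float
    params: ParamVector


def run_ratio_experiment(model_names, energies, labels,
                         params: dict[str, ParamVector] | None = None
                         ) -> dict[str, RatioReport]:
    """Predict every stimulus under each model and form the class ratio.

    `energies` and `labels` come from an energy-matched target battery.
    If `params` is omitted, each model runs with g = 1, alpha = 1 and a
    mid-range sigma derived from the battery (`moderate_sigma`), so the
    ratio reflects the pooling stage itself.
    """
    labels = list(labels)
    reports = {}
    for name in model_names:
        feats = prepare_features(name, energies)
        if params and name in params:
            p = params[name]
        else:
            sig = None if name == "ce" else moderate_sigma(feats, name)
            p = ParamVector(1.0, 1.0, sig)
        preds = predict_from_features(name, feats, p)
        snakes = float(np.mean([r for r, l in zip(preds, labels) if l == "snakes"]))
        gratings = float(np.mean([r for r, l in zip(preds, labels) if l == "gratings"]))
        reports[name] = RatioReport(name, snakes / gratings, snakes, gratings, p)
    return reports


# ---------------------------------------------------------------------------
# center-surround simulation
# ---------------------------------------------------------------------------

@dataclass
class SurroundGeometry:
    """Hard-edged center disc plus surround annulus, 3 cpd carrier."""

    center_radius_deg: float = 1.0
    surround_inner_deg: float = 1.0
    surround_outer_deg: float = 3.0
    size_deg: float = 8.0
    ppd: float = 24.0
    freq_cpd: float = 3.0
    contrast: float = 1.0


@dataclass
class SuppressionCurve:
    surround_dirs: np.ndarray
    response: np.ndarray   # normalized by the no-surround baseline
    baseline: float
    center_dir: float
    preferred_dir: float

    @property
    def argmin_dir(self) -> float:
        return float(self.surround_dirs[int(np.argmin(self.response))])


def _center_surround_image(geom: SurroundGeometry, center_dir: float,
                           surround_dir: float | None) -> st.StimulusImage:
    n = int(round(geom.size_deg * geom.ppd))
    ax = (np.arange(n) - (n - 1) / 2) / geom.ppd
    xx, yy = np.meshgrid(ax, ax)
    r = np.hypot(xx, yy)
    amp = geom.contrast / 2
    uc = st._coord_u(n, geom.ppd, center_dir)
    pix = amp * np.sin(2 * np.pi * geom.freq_cpd * uc) * (r <= geom.center_radius_deg)
    if surround_dir is not None:
        us = st._coord_u(n, geom.ppd, surround_dir)
        ann = (r >= geom.surround_inner_deg) & (r <= geom.surround_outer_deg)
        pix = pix + amp * np.sin(2 * np.pi * geom.freq_cpd * us) * ann
    return st.StimulusImage(pix, geom.ppd, geom.size_deg)


def simulate_center_surround(model_name: str, center_dir: float,
                             surround_dirs, geom: SurroundGeometry | None = None,
                             preferred_dir: float = 0.0,
                             sigma: float | None = None,
                             bank: FilterBank | None = None) -> SuppressionCurve:
    """Response of a single model unit to center+surround composites.

    The unit readout follows the model's own normalization stage. The unit's
    drive (numerator) comes from its receptive field -- the center disc, so
    it is computed on the center-only stimulus and held fixed across
    surround conditions; the surround acts purely through the normalizer
    (denominator), computed on the full composite. For otn (and dn) the
    readout is the normalized energy d at the image-center pixel in the
    preferred-orientation channel; for noa it is the preferred channel's
    pooled center energy over sigma^2 plus the composite's anisotropy.
    The curve is normalized by the center-only baseline. If sigma is not
    given, a mid-range value is derived from the center-only stimulus.
    """
    geom = geom or SurroundGeometry()
    if bank is None:
        bank = build_filterbank(geom.ppd)
    dirs = np.asarray(surround_dirs, dtype=float)

    maps = {}
    for sd in [None] + list(dirs):
        img = _center_surround_image(geom, center_dir, sd)
        maps[sd] = compute_energy(img, bank)

    E0 = maps[None]
    i_pref = int(np.argmin(np.abs(
        (bank.orientations_deg - preferred_dir + 90) % 180 - 90)))
    ny, nx = E0.values.shape[:2]
    cy, cx = ny // 2, nx // 2

    if model_name in ("otn", "dn"):
        kern = make_norm_kernel(ny, tuned=(model_name == "otn"))
        drive = E0.values[cy, cx, i_pref]
        if sigma is None:
            Z0 = norm_pool(E0, kern)
            sigma = float(np.median(Z0[Z0 > 0]))

        def readout(E):
            Z = norm_pool(E, kern)
            return drive / max(sigma + Z[cy, cx, i_pref], 1e-300)
    elif model_name == "noa":
        drive = oriented_energy(E0)[i_pref] ** 2
        if sigma is None:
            sigma = float(np.sqrt(anisotropy(oriented_energy(E0))))

        def readout(E):
            return drive / max(sigma**2 + anisotropy(oriented_energy(E)), 1e-300)
    else:
        raise KeyError(f"no surround readout for model {model_name!r}")

    baseline = readout(E0)
    resp = np.array([readout(maps[sd]) for sd in dirs]) / baseline
    return SuppressionCurve(dirs, resp, baseline, center_dir, preferred_dir)


# ---------------------------------------------------------------------------
# ROI beta adapter / synthetic BOLD
# ---------------------------------------------------------------------------

def load_roi_betas(path, rois=("V1", "V2", "V3"),
                   stimulus_indices=None, dialect: str = "kay_mat"
                   ) -> ROIResponseTable:
    """Read a published-format MAT container of per-voxel GLM betas.

    Expects a "betas" array (voxels x stimuli x bootstraps), a per-voxel
    "roi" label index, and "roilabels" names. Voxels are averaged within an
    ROI separately for each bootstrap (noise is correlated across voxels but
    not across scans); the table holds the mean and SD across those
    per-bootstrap voxel means.
    """
    if dialect != "kay_mat":
        raise DataFormatError(f"unknown dialect {dialect!r}")
    arrays = _read_mat(path)
    for fieldname in ("betas", "roi", "roilabels"):
        if fieldname not in arrays:
            raise DataFormatError(f"missing field {fieldname!r} in {path}")
    betas = np.asarray(arrays["betas"], dtype=float)
    if betas.ndim != 3:
        raise DataFormatError(
            f"'betas' must be voxels x stimuli x bootstraps, got rank {betas.ndim}")
    roi_idx = np.asarray(arrays["roi"]).ravel().astype(int)
    labels = [str(x) for x in np.asarray(arrays["roilabels"]).ravel()]
    if stimulus_indices is None:
        stimulus_indices = np.arange(betas.shape[1])
    stimulus_indices = np.asarray(stimulus_indices, dtype=int)

    means, sds, kept = [], [], []
    for name in rois:
        try:
            lab = labels.index(name) + 1  # 1-based ROI indices
        except ValueError:
            raise DataFormatError(f"ROI {name!r} not in roilabels {labels}")
        vox = roi_idx == lab
        if not vox.any():
            raise DataFormatError(f"ROI {name!r} selects no voxels")
        per_boot = betas[vox][:, stimulus_indices, :].mean(axis=0)  # (stim, boot)
        means.append(per_boot.mean(axis=1))
        sds.append(per_boot.std(axis=1, ddof=0))
        kept.append(name)
    return ROIResponseTable(kept, [f"stim{i}" for i in stimulus_indices],
                            np.column_stack(means), np.column_stack(sds))


def _read_mat(path) -> dict:
    from scipy.io import loadmat

    try:
        raw = loadmat(path, squeeze_me=True, simplify_cells=True)
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        import h5py

        out = {}
        with h5py.File(path, "r") as f:
            for k in f:
                v = f[k][()]
                if isinstance(v, np.ndarray) and v.ndim == 3:
                    v = v.transpose(2, 1, 0)  # MATLAB v7.3 stores transposed
                out[k] = v
        return out


def synth_bold(model_name: str, params: ParamVector,
               features: list[StimulusFeatures], noise_sd: float,
               seed: int = 0, roi_name: str = "sim") -> ROIResponseTable:
    """Model predictions plus seeded additive Gaussian noise, as a
    one-ROI response table (synthetic ground truth for recovery tests)."""
    preds = predict_from_features(model_name, features, params)
    rng = np.random.default_rng(seed)
    noisy = preds + rng.normal(0.0, noise_sd, size=preds.shape)
    sd = np.full_like(preds, float(noise_sd))
    return ROIResponseTable([roi_name], [f"stim{i}" for i in range(len(preds))],
                            noisy[:, None], sd[:, None])
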