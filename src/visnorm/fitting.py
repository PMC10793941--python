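"""Parameter estimation, leave-one-out cross-validation, and accuracy.

Models are fit to per-ROI mean BOLD amplitudes by minimizing unweighted
squared error, with 40 random parameter initializations per fit to escape
local minima of the non-convex landscape. Parameters are optimized in a
transformed, unbounded space: g = exp(a) (positive gain), alpha =
sigmoid(b) (exponent in (0, 1)), sigma = exp(c) (non-negative
semisaturation).

For the sigma-dependent models the heavy filtering stage is outside the
inner loop: energies are computed once and reduced to compact per-exemplar
"features" from which the pooled drive s(sigma) can be re-evaluated cheaply
for any candidate sigma (see `prepare_features`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .energy import EnergyMap, oriented_energy
from .models import (EPS, N_PARAMS, NormKernel, ParamVector, anisotropy,
                     make_norm_kernel, norm_pool)


class OptimizationError(RuntimeError):
    """All starts failed to converge; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ROIResponseTable:
    """Per-ROI mean BOLD amplitudes (percent signal change) and bootstrap SDs."""

    roi_names: list[str]
    stim_ids: list[str]
    mean_beta: np.ndarray  # (n_stimuli, n_rois)
    sd_beta: np.ndarray    # (n_stimuli, n_rois)

    def __post_init__(self):
        self.mean_beta = np.asarray(self.mean_beta, dtype=float)
        self.sd_beta = np.asarray(self.sd_beta, dtype=float)
        if self.mean_beta.shape != self.sd_beta.shape:
            raise ValueError("mean/sd beta shapes disagree")
        if np.any(self.sd_beta < 0):
            raise ValueError("bootstrap SDs must be non-negative")


@dataclass
class FitResult:
    params: ParamVector
    sse: float
    n_starts: int
    start_seeds: list[int] = field(default_factory=list)
    start_sses: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(), "sse": self.sse,
                "n_starts": self.n_starts}


@dataclass
class CVReport:
    heldout_pred: np.ndarray
    observed: np.ndarray
    r2: float
    fold_params: list[ParamVector]

    def to_dict(self) -> dict:
        return {"heldout_pred": list(map(float, self.heldout_pred)),
                "observed": list(map(float, self.observed)),
                "r2": self.r2,
                "fold_params": [p.to_dict() for p in self.fold_params]}


# ---------------------------------------------------------------------------
# per-stimulus features
# ---------------------------------------------------------------------------

@dataclass
class StimulusFeatures:
    """Per-stimulus precomputation from which s(sigma) is cheap to evaluate.

    ce:  `s0` -- pooled drive per exemplar (sigma-independent).
    dn/otn: `e_sums`, `z_reps` -- per exemplar, the map's energy histogrammed
         into bins of the normalizer Z (bin energy totals and energy-weighted
         representative Z), so s(sigma) = sum_b e_sums/(sigma + z_reps) / N.
         Bin energy sums are exact, so the large-sigma limit is exact; for
         moderate sigma the quantization error is far below fitting noise.
    noa: `mean_e2`, `aniso` -- per exemplar, mean squared channel energy and
         the anisotropy V; s(sigma) = mean_e2 / (sigma^2 + V) exactly.
         `mean_e` (the plain mean energy) is carried for the first-power
         pooling variant.
    """

    kind: str
    s0: np.ndarray | None = None
    e_sums: np.ndarray | None = None   # (n_ex, n_bins)
    z_reps: np.ndarray | None = None   # (n_ex, n_bins)
    n_elements: int = 0
    mean_e2: np.ndarray | None = None
    aniso: np.ndarray | None = None
    mean_e: np.ndarray | None = None

    def drive(self, sigma: float | None) -> np.ndarray:
        """Pooled drive s per exemplar at the given sigma."""
        if self.kind == "ce":
            return self.s0
        if self.kind in ("dn", "otn"):
            return (self.e_sums / np.maximum(sigma + self.z_reps, EPS)).sum(axis=1) / self.n_elements
        if self.kind == "noa":
            return self.mean_e2 / np.maximum(sigma**2 + self.aniso, EPS)
        raise KeyError(self.kind)


def _compress_dn(E: EnergyMap, Z: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    e = E.values.ravel()
    z = Z.ravel()
    mask = e > 0
    e, z = e[mask], z[mask]
    if e.size == 0:
        return np.zeros(n_bins), np.ones(n_bins)
    zmin = max(z.min(), 1e-300)
    zmax = max(z.max(), zmin * (1 + 1e-12))
    edges = np.geomspace(zmin, zmax * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_bins - 1)
    e_sums = np.bincount(idx, weights=e, minlength=n_bins)
    ez = np.bincount(idx, weights=e * z, minlength=n_bins)
    z_reps = np.where(e_sums > 0, ez / np.maximum(e_sums, EPS), edges[:-1])
    return e_sums, z_reps


def prepare_features(model_name: str, energies: list[list[EnergyMap]],
                     norm_kern: NormKernel | None = None,
                     n_bins: int = 256) -> list[StimulusFeatures]:
    """Reduce per-stimulus exemplar energy maps to fitting features.

    `energies` is a list over stimuli of lists over exemplars of EnergyMap.
    """
    out = []
    for maps in energies:
        if model_name == "ce":
            out.append(StimulusFeatures(
                "ce", s0=np.array([E.values.mean() for E in maps])))
        elif model_name in ("dn", "otn"):
            if norm_kern is None:
                norm_kern = make_norm_kernel(
                    maps[0].values.shape[0], tuned=(model_name == "otn"))
            es, zs = [], []
            for E in maps:
                Z = norm_pool(E, norm_kern)
                a, b = _compress_dn(E, Z, n_bins)
                es.append(a)
                zs.append(b)
            out.append(StimulusFeatures(
                model_name, e_sums=np.array(es), z_reps=np.array(zs),
                n_elements=maps[0].values.size))
        elif model_name == "noa":
            m2, an, m1 = [], [], []
            for E in maps:
                e = oriented_energy(E)
                m2.append(np.mean(e**2))
                an.append(anisotropy(e))
                m1.append(np.mean(e))
            out.append(StimulusFeatures(
                "noa", mean_e2=np.array(m2), aniso=np.array(an),
                mean_e=np.array(m1)))
        else:
            raise KeyError(f"unknown model {model_name!r}")
    return out


class FeatureStack:
    """All stimuli's features concatenated for vectorized prediction.

    Exemplars of every stimulus are stacked along one axis; per-stimulus
    averaging of the exemplar predictions is a segment mean over `stim_ids`.
    Built once per fit so each objective evaluation is a handful of
    whole-array operations.
    """

    def __init__(self, features: list[StimulusFeatures]):
        self.kind = features[0].kind
        counts = []
        if self.kind == "ce":
            self.s0 = np.concatenate([f.s0 for f in features])
            counts = [len(f.s0) for f in features]
        elif self.kind in ("dn", "otn"):
            self.e_sums = np.vstack([f.e_sums for f in features])
            self.z_reps = np.vstack([f.z_reps for f in features])
            self.n_elements = features[0].n_elements
            counts = [f.e_sums.shape[0] for f in features]
        elif self.kind == "noa":
            self.mean_e2 = np.concatenate([f.mean_e2 for f in features])
            self.aniso = np.concatenate([f.aniso for f in features])
            counts = [len(f.mean_e2) for f in features]
        else:
            raise KeyError(self.kind)
        self.n_stimuli = len(features)
        self.stim_ids = np.repeat(np.arange(self.n_stimuli), counts)
        self.counts = np.asarray(counts, dtype=float)

    def drive(self, sigma: float | None) -> np.ndarray:
        if self.kind == "ce":
            return self.s0
        if self.kind in ("dn", "otn"):
            return (self.e_sums / np.maximum(sigma + self.z_reps, EPS)
                    ).sum(axis=1) / self.n_elements
        return self.mean_e2 / np.maximum(sigma**2 + self.aniso, EPS)

    def predict(self, p: ParamVector) -> np.ndarray:
        r_ex = p.g * np.power(np.maximum(self.drive(p.sigma), 0.0), p.alpha)
        return np.bincount(self.stim_ids, weights=r_ex,
                           minlength=self.n_stimuli) / self.counts


def predict_from_features(model_name: str, features: list[StimulusFeatures],
                          p: ParamVector) -> np.ndarray:
    """Per-stimulus predictions: exemplar drives -> power law -> average."""
    preds = np.empty(len(features))
    for i, f in enumerate(features):
        s = f.drive(p.sigma)
        preds[i] = np.mean(p.g * np.power(np.maximum(s, 0.0), p.alpha))
    return preds


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _sigmoid(x):
    from scipy.special import expit

    return expit(x)


def _unpack(x: np.ndarray, model_name: str,
            fixed: dict | None = None) -> ParamVector:
    fixed = fixed or {}
    vals = list(x)
    g = fixed["g"] if "g" in fixed else float(np.exp(np.clip(vals.pop(0), -60, 60)))
    alpha = fixed["alpha"] if "alpha" in fixed else float(_sigmoid(vals.pop(0)))
    sigma = None
    if N_PARAMS[model_name] == 3:
        sigma = fixed["sigma"] if "sigma" in fixed else float(np.exp(np.clip(vals.pop(0), -60, 60)))
    return ParamVector(g, alpha, sigma)


def fit_model(model_name: str, features: list[StimulusFeatures],
              responses: np.ndarray, n_starts: int = 40, seed: int = 0,
              fixed: dict | None = None) -> FitResult:
    """Multi-start least squares over the transformed parameter space.

    Starts are drawn from N(0, 2) per transformed parameter, seeded; the
    lowest-SSE solution wins, ties broken by earliest start. `fixed` pins
    named parameters at given values (they leave the search space).
    """
    responses = np.asarray(responses, dtype=float)
    if len(features) < N_PARAMS[model_name]:
        raise ValueError(
            f"{model_name} needs >= {N_PARAMS[model_name]} stimuli, "
            f"got {len(features)}")
    fixed = fixed or {}
    n_free = N_PARAMS[model_name] - len(fixed)
    if n_free == 0:
        p = _unpack(np.empty(0), model_name, fixed)
        sse = float(np.sum((predict_from_features(model_name, features, p) - responses) ** 2))
        return FitResult(p, sse, 0)

    stack = FeatureStack(features)

    def objective(x):
        p = _unpack(x, model_name, fixed)
        resid = stack.predict(p) - responses
        return float(resid @ resid)

    rng = np.random.default_rng(seed)
    best = None
    diagnostics = []
    sses = []
    for k in range(n_starts):
        x0 = rng.normal(0.0, 2.0, size=n_free)
        try:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B",
                options={"maxfun": 600, "ftol": 1e-12, "gtol": 1e-10})
        except (FloatingPointError, ValueError) as err:
            diagnostics.append((k, str(err)))
            continue
        sses.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise OptimizationError(
            f"all {n_starts} starts failed for {model_name}", diagnostics)
    params = _unpack(best.x, model_name, fixed)
    return FitResult(params, float(best.fun), n_starts,
                     start_seeds=[seed], start_sses=sses)


def refit_gain(model_name: str, features: list[StimulusFeatures],
               responses: np.ndarray, alpha: float,
               sigma: float | None = None) -> ParamVector:
    """Closed-form least-squares gain with alpha (and sigma) held fixed:
    g* = sum(m r) / sum(m^2) where m_i is the unit-gain prediction."""
    p1 = ParamVector(1.0, alpha, sigma)
    m = predict_from_features(model_name, features, p1)
    g = float(m @ np.asarray(responses) / max(m @ m, EPS))
    return ParamVector(g, alpha, sigma)


def loo_cv(model_name: str, features: list[StimulusFeatures],
           responses: np.ndarray, n_starts: int = 40, seed: int = 0,
           fixed: dict | None = None) -> CVReport:
    """Leave-one-out cross-validation: one fit per held-out stimulus."""
    responses = np.asarray(responses, dtype=float)
    n = len(features)
    preds = np.empty(n)
    fold_params = []
    for i in range(n):
        train_f = [f for j, f in enumerate(features) if j != i]
        train_r = np.delete(responses, i)
        fit = fit_model(model_name, train_f, train_r, n_starts=n_starts,
                        seed=seed + i, fixed=fixed)
        preds[i] = predict_from_features(model_name, [features[i]], fit.params)[0]
        fold_params.append(fit.params)
    return CVReport(preds, responses.copy(), r_squared(preds, responses),
                    fold_params)


def r_squared(pred, data) -> float:
    """Cross-validated variance explained: 1 - SSE/SST.

    Not clipped: worse-than-mean predictions give negative values.
    """
    pred = np.asarray(pred, dtype=float)
    data = np.asarray(data, dtype=float)
    sse = np.sum((data - pred) ** 2)
    sst = np.sum((data - data.mean()) ** 2)
    return float(1.0 - sse / sst)
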