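"""Stimulus and result serialization.

PNG (8-bit grayscale; gray = 128 maps to 0.0, full range to [-0.5, 0.5]),
HDF5 stimulus-set containers with metadata attributes, JSON sidecars, and
CSV fold tables for cross-validation reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

from .stimuli import StimulusImage, StimulusSet


def image_to_png(img: StimulusImage, path) -> None:
    """8-bit grayscale export: value v -> round(128 + 255*v), clipped."""
    arr = np.clip(np.round(128 + 255 * img.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))


def image_from_png(path, ppd: float, aperture_deg: float | None = None) -> StimulusImage:
    arr = np.asarray(Image.open(str(path)).convert("L"), dtype=float)
    pix = (arr - 128.0) / 255.0
    n = pix.shape[0]
    if aperture_deg is None:
        aperture_deg = n / ppd
    return StimulusImage(pix, ppd, aperture_deg)


def save_stimulus_set(stim: StimulusSet, path) -> None:
    """HDF5 container: one dataset per exemplar plus metadata attributes
    and a JSON sidecar mirroring the metadata."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for i, ex in enumerate(stim.exemplars):
            d = f.create_dataset(f"exemplar{i:02d}", data=ex.pixels)
            d.attrs["ppd"] = ex.ppd
            d.attrs["aperture_deg"] = ex.aperture_deg
        f.attrs["family"] = stim.family
        f.attrs["manipulation"] = stim.manipulation
        f.attrs["level"] = stim.level
        f.attrs["seed"] = stim.seed
        f.attrs["ppd"] = stim.ppd
    sidecar = {"family": stim.family, "manipulation": stim.manipulation,
               "level": stim.level, "seed": stim.seed, "ppd": stim.ppd,
               "n_exemplars": len(stim.exemplars)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_stimulus_set(path) -> StimulusSet:
    with h5py.File(path, "r") as f:
        keys = sorted(k for k in f if k.startswith("exemplar"))
        exemplars = [
            StimulusImage(f[k][()], float(f[k].attrs["ppd"]),
                          float(f[k].attrs["aperture_deg"]))
            for k in keys
        ]
        return StimulusSet(str(f.attrs["family"]), str(f.attrs["manipulation"]),
                           float(f.attrs["level"]), exemplars,
                           int(f.attrs["seed"]))


def save_energy_map(E, path, stimulus_id: str = "", seed: int | None = None) -> None:
    """Cache an EnergyMap: dataset "energy" (y, x, theta) with geometry attrs."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("energy", data=E.values)
        d.attrs["ppd_out"] = E.ppd_out
        d.attrs["orientations_deg"] = E.orientations_deg
        if stimulus_id:
            d.attrs["stimulus_id"] = stimulus_id
        if seed is not None:
            d.attrs["seed"] = seed


def load_energy_map(path):
    from .energy import EnergyMap

    with h5py.File(path, "r") as f:
        d = f["energy"]
        return EnergyMap(d[()], float(d.attrs["ppd_out"]),
                         np.asarray(d.attrs["orientations_deg"]))


def cv_report_to_csv(report, stim_ids, path) -> None:
    """Per-fold table: stim_id, heldout_pred, observed, fold squared error."""
    import pandas as pd

    df = pd.DataFrame({
        "stim_id": stim_ids,
        "heldout_pred": report.heldout_pred,
        "observed": report.observed,
        "fold_sse": (report.heldout_pred - report.observed) ** 2,
    })
    df.to_csv(path, index=False)
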