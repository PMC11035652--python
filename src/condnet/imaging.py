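"""Index-of-dispersion analysis of fluorescence images and phase maps.

A uniform well gives variance/mean ≈ shot-noise level, while droplets
(bright disks on dark background) inflate the variance dramatically; the
titration phase map calls a well phase-separated when its mean index of
dispersion exceeds 10% of the maximum over the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def load_image(path) -> np.ndarray:
    """Read a microscopy image (TIFF) or a saved array (.npy/.txt)."""
    p = str(path)
    if p.endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(p), dtype=float)
    if p.endswith(".npy"):
        return np.load(p).astype(float)
    return np.loadtxt(p)


def index_of_dispersion(image: np.ndarray) -> float:
    """Variance/mean of pixel intensities (population variance)."""
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if np.any(img < 0):
        raise ValueError("image intensities must be non-negative")
    mean = img.mean()
    if mean <= 0:
        raise ValueError("image mean must be positive")
    return float(img.var() / mean)


@dataclass
class PhaseMap:
    table: pd.DataFrame        # columns: well, mean_iod, positive
    threshold: float
    degenerate: bool           # single-well grid: threshold is meaningless

    def positive_wells(self) -> list:
        return list(self.table.loc[self.table.positive, "well"])


def classify_phase_map(wells: dict, threshold_fraction: float = 0.10,
                       ) -> PhaseMap:
    """Phase-separation calls from per-well image sets.

    ``wells`` maps a well key (e.g. a concentration pair) to a list of
    images.  Each well's score is the mean index of dispersion over its
    images; a well is positive when its score exceeds
    ``threshold_fraction`` of the maximum score in the grid (ties at the
    maximum are positive).
    """
    if not wells:
        raise ValueError("no wells supplied")
    rows = []
    for key, images in wells.items():
        if not images:
            raise ValueError(f"well {key!r} has no images")
        iods = [index_of_dispersion(im) for im in images]
        rows.append({"well": key, "mean_iod": float(np.mean(iods)),
                     "n_images": len(iods)})
    df = pd.DataFrame(rows)
    top = df.mean_iod.max()
    thr = threshold_fraction * top
    df["positive"] = (df.mean_iod > thr) | np.isclose(df.mean_iod, top)
    return PhaseMap(table=df, threshold=float(thr), degenerate=len(df) == 1)
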