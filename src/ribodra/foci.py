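"""Thresholded connected-component foci counting and replicate statistics.

Mirrors an ImageJ Analyze-Particles workflow on immunofluorescence
images: pixels at or above an intensity threshold form the foreground,
connected components below a minimum pixel area are discarded, and each
surviving particle is assigned to a cell from an integer label mask by
majority pixel overlap (ties go to the lower cell label).  The defaults
(threshold 50, minimum size 10 px, 8-connectivity) are the published
quantification settings for RPA2 foci.

Also provides the replicate-level summary statistics used for the
wet-bench quantifications: per-cell count binning (0/1/2/3+ intensely
stained structures), loading-control normalisation of western-blot band
densities, and an unpaired two-tailed Student's (pooled-variance) t-test
across biological replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

__all__ = [
    "FociParams",
    "count_foci",
    "bin_counts",
    "replicate_stats",
    "normalize_band_density",
]


@dataclass
class FociParams:
    """Particle-analysis settings (intensities on the 0-255 scale)."""

    threshold: float = 50
    min_size: int = 10
    connectivity: int = 8  # 8- or 4-connected neighborhoods
    exclude_edge: bool = False

    def validate(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must lie in [0, 255]")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def count_foci(image: np.ndarray, params: FociParams | None = None,
               mask: np.ndarray | None = None) -> pd.DataFrame:
    """Count discrete foci per cell in a grayscale image.

    Foreground is intensity >= threshold (inclusive, as in ImageJ
    thresholding).  Without a mask the whole image is one implicit cell
    (cell_id 1).  Returns a table with one row per labeled cell, zero
    counts included.
    """
    params = params or FociParams()
    params.validate()
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if mask is None:
        mask = np.ones(img.shape, dtype=np.uint16)
    else:
        mask = np.asarray(mask)
        if mask.shape != img.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match image {img.shape}"
            )

    fg = img >= params.threshold
    skconn = 2 if params.connectivity == 8 else 1
    labels = measure.label(fg, connectivity=skconn)

    cell_ids = np.unique(mask)
    cell_ids = cell_ids[cell_ids > 0]
    counts = {int(c): 0 for c in cell_ids}

    for region in measure.regionprops(labels):
        if region.area < params.min_size:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        if params.exclude_edge:
            h, w = img.shape
            if (rr.min() == 0 or cc.min() == 0
                    or rr.max() == h - 1 or cc.max() == w - 1):
                continue
        owners = mask[rr, cc]
        owners = owners[owners > 0]
        if owners.size == 0:
            continue  # particle entirely outside any cell
        vals, freq = np.unique(owners, return_counts=True)
        owner = int(vals[freq == freq.max()].min())  # ties -> lower label
        counts[owner] += 1

    return pd.DataFrame(
        {"cell_id": list(counts), "count": list(counts.values())}
    ).sort_values("cell_id", ignore_index=True)


def bin_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Bin per-cell counts into 0 / 1 / 2 / 3+ categories.

    The published binning starts at 1; a "0" bin is reported alongside
    because cells may lack detected structures.  Returns frequencies and
    percentages per bin (percentages over all cells).
    """
    c = counts["count"].to_numpy()
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    labels = ["0", "1", "2", "3+"]
    freq = [
        int((c == 0).sum()),
        int((c == 1).sum()),
        int((c == 2).sum()),
        int((c >= 3).sum()),
    ]
    n = len(c)
    pct = [100.0 * f / n if n else float("nan") for f in freq]
    return pd.DataFrame({"bin": labels, "frequency": freq, "percent": pct})


def replicate_stats(wt_values, mut_values):
    """Unpaired two-tailed Student's t-test across biological replicates.

    Uses the pooled-variance t statistic with n1 + n2 - 2 degrees of
    freedom (not Welch), matching replicate-level comparisons of percent
    means.  Returns a dict with group means, s.d., t, df and p.
    """
    a = np.asarray(wt_values, dtype=float)
    b = np.asarray(mut_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 replicates per genotype")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if math.isnan(t):  # both groups constant
        diff = a.mean() - b.mean()
        t, p = (0.0, 1.0) if diff == 0 else (math.copysign(math.inf, diff), 0.0)
    return {
        "mean_wt": float(a.mean()),
        "mean_mut": float(b.mean()),
        "sd_wt": float(a.std(ddof=1)),
        "sd_mut": float(b.std(ddof=1)),
        "t_stat": float(t),
        "df": float(a.size + b.size - 2),
        "p_value": float(p),
    }


def normalize_band_density(experimental, control):
    """Normalise band densities by a loading control, sample by sample.

    Returns elementwise experimental/control ratios; control densities
    must be strictly positive.
    """
    exp = pd.Series(experimental, dtype=float)
    ctl = pd.Series(control, dtype=float)
    if len(exp) != len(ctl):
        raise ValueError("experimental and control must have equal length")
    bad = ctl.index[ctl <= 0]
    if len(bad) > 0:
        raise ValueError(f"nonpositive control density for sample(s): {list(bad)}")
    return exp / ctl.to_numpy() if not exp.index.equals(ctl.index) else exp / ctl
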