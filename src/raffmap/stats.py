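"""Repeatability, precision and segment statistics for parametric maps.

Coefficient-of-variation conventions (sample SD with n-1 throughout):

* ``cv_percent`` - plain CV of a set of values (e.g. per-vial ROI means
  across repetitions).
* per myocardial segment, from a tidy (subject, repetition, slice, segment)
  table of segment-mean TRAFF2 and segment-mean SD-map values:

  - precision ``wCV``: mean over subjects and repetitions of
    (segment SD-map mean / segment TRAFF2 mean) * 100,
  - reproducibility ``wCV_bar``: mean over subjects of
    (SD across that subject's repetition means / that subject's mean) * 100,
  - inter-subject variability ``CV_bar``:
    (SD across subjects of per-subject means / grand mean) * 100.

Also here: Pearson correlation + Bland-Altman agreement, the two-standard-
deviation (2SD) scar threshold, and the AHA 16-segment partition of
short-axis myocardium (basal/mid: six 60-degree sectors; apical: four
90-degree sectors; the angular origin is the anterior RV insertion point,
counting counterclockwise in the standard short-axis orientation, with a
chirality flag for flipped data).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SEGMENTS_PER_SLICE = {"basal": tuple(range(1, 7)),
                      "mid": tuple(range(7, 13)),
                      "apical": tuple(range(13, 17))}


@dataclass
class RoiSample:
    """Per-pixel map values within one region of interest."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("ROI sample must be non-empty")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("ROI sample must contain finite values only")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else 0.0

    @property
    def summary(self) -> str:
        return f"{self.label}: {self.mean:.1f} +/- {self.sd:.1f}"


def cv_percent(values) -> float:
    """Coefficient of variation, 100 * sample SD / mean."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    mean = float(np.mean(v))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * float(np.std(v, ddof=1)) / mean


def _check_complete(table: pd.DataFrame) -> None:
    subjects = sorted(table["subject"].unique())
    reps = sorted(table["repetition"].unique())
    segs = sorted(table["segment"].unique())
    missing = []
    have = set(zip(table["subject"], table["repetition"], table["segment"]))
    for s in subjects:
        for r in reps:
            for g in segs:
                if (s, r, g) not in have:
                    missing.append((s, r, g))
    if missing:
        pairs = sorted({(_py(s), _py(r)) for s, r, _ in missing})
        raise ValueError(f"missing (subject, repetition) cells: {pairs}")


def _py(v):
    return v.item() if hasattr(v, "item") else v


def precision_reproducibility_intersubject(table: pd.DataFrame) -> pd.DataFrame:
    """Per-segment precision (wCV), reproducibility (wCV_bar) and
    inter-subject variability (CV_bar), all in percent.

    ``table`` is tidy with columns
    ``subject, repetition, slice, segment, mean_ms, sd_ms`` (``sd_ms`` may
    be NaN, in which case wCV is NaN for that segment).
    """
    required = {"subject", "repetition", "segment", "mean_ms"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table["subject"].nunique() < 2:
        raise ValueError("inter-subject variability needs >= 2 subjects")
    if table["repetition"].nunique() < 2:
        raise ValueError("reproducibility needs >= 2 repetitions")
    _check_complete(table)

    rows = []
    for seg, g in table.groupby("segment"):
        if "sd_ms" in g.columns and g["sd_ms"].notna().all():
            wcv = float(np.mean(g["sd_ms"] / g["mean_ms"])) * 100.0
        else:
            wcv = np.nan
        per_subj = g.groupby("subject")["mean_ms"]
        subj_means = per_subj.mean()
        subj_cv = per_subj.std(ddof=1) / subj_means * 100.0
        wcv_bar = float(subj_cv.mean())
        cv_bar = float(subj_means.std(ddof=1) / subj_means.mean() * 100.0)
        rows.append({"segment": int(seg), "wcv": wcv, "wcv_bar": wcv_bar,
                     "cv_bar": cv_bar})
    return pd.DataFrame(rows).set_index("segment").sort_index()


def pearson_and_bland_altman(x, y) -> dict:
    """Least-squares line + R^2 and Bland-Altman agreement of paired means.

    Returns ``{r2, slope, intercept, bias, loa_low, loa_high}`` where the
    bias is ``mean(y - x)`` and the limits of agreement are
    ``bias +/- 1.96 * SD(y - x)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("R^2 undefined: x has zero variance")
    fit = sps.linregress(x, y)
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return {
        "r2": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
    }


def scar_mask_2sd(map_img: np.ndarray, remote_roi: np.ndarray) -> np.ndarray:
    """Two-standard-deviation scar segmentation.

    Voxels whose value exceeds (remote mean + 2 * remote SD) are flagged.
    """
    map_img = np.asarray(map_img, dtype=float)
    remote_roi = np.asarray(remote_roi, dtype=bool)
    vals = map_img[remote_roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("remote ROI is empty")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    if sd == 0:
        warnings.warn("remote ROI SD is zero: degenerate 2SD threshold", stacklevel=2)
    with np.errstate(invalid="ignore"):
        return map_img > mean + 2.0 * sd


def aha16_label(myocardium_mask, lv_center, rv_insertion, slice_level: str,
                counterclockwise: bool = True) -> np.ndarray:
    """AHA 16-segment labelling of one short-axis slice.

    Every myocardial voxel receives exactly one segment label: 1-6 (basal),
    7-12 (mid) or 13-16 (apical).  The angular origin is the anterior RV
    insertion point; sectors advance counterclockwise (set
    ``counterclockwise=False`` for flipped/mirrored data).  The first sector
    counterclockwise of the insertion is the (antero)septal one.
    """
    if slice_level not in SEGMENTS_PER_SLICE:
        raise ValueError(f"slice_level must be one of {sorted(SEGMENTS_PER_SLICE)}")
    mask = np.asarray(myocardium_mask, dtype=bool)
    r0, c0 = lv_center
    ri, ci = rv_insertion
    if math.hypot(ri - r0, ci - c0) == 0:
        raise ValueError("RV insertion coincides with LV center: angle undefined")
    yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    theta = np.arctan2(-(yy - r0), xx - c0)        # CCW, y up
    theta_rv = math.atan2(-(ri - r0), ci - c0)
    rel = np.mod(theta - theta_rv, 2.0 * math.pi)
    if not counterclockwise:
        rel = np.mod(-rel, 2.0 * math.pi)

    out = np.zeros(mask.shape, dtype=int)
    if slice_level == "apical":
        sector = np.minimum((rel / (math.pi / 2.0)).astype(int), 3)
        seg = (sector + 1) % 4 + 13
    else:
        sector = np.minimum((rel / (math.pi / 3.0)).astype(int), 5)
        base = 1 if slice_level == "basal" else 7
        seg = (sector + 1) % 6 + base
    out[mask] = seg[mask]
    return out


def segment_table_from_maps(traff2_map, sd_map, label_img, subject, repetition,
                            slice_level) -> pd.DataFrame:
    """Aggregate per-voxel maps into tidy per-segment rows."""
    rows = []
    for seg in np.unique(label_img):
        if seg == 0:
            continue
        sel = label_img == seg
        vals = np.asarray(traff2_map)[sel]
        vals = vals[np.isfinite(vals)]
        sdv = np.asarray(sd_map)[sel] if sd_map is not None else np.array([])
        sdv = sdv[np.isfinite(sdv)]
        rows.append({
            "subject": subject, "repetition": repetition, "slice": slice_level,
            "segment": int(seg),
            "mean_ms": float(np.mean(vals)) if vals.size else np.nan,
            "sd_ms": float(np.mean(sdv)) if sdv.size else np.nan,
        })
    return pd.DataFrame(rows)


def bullseye_summary(table: pd.DataFrame, plot_path=None, value: str = "mean_ms") -> dict:
    """Per-segment / per-slice / global means, with an optional bullseye PNG.

    Slice means are unweighted averages of their segment means; the global
    mean is the unweighted average of the 16 segment means.
    """
    seg_means = table.groupby("segment")[value].mean()
    per_slice = {}
    for sl, segs in SEGMENTS_PER_SLICE.items():
        present = [s for s in segs if s in seg_means.index]
        if present:
            per_slice[sl] = float(np.mean([seg_means[s] for s in present]))
    report = {
        "per_segment": {int(s): float(v) for s, v in seg_means.items()},
        "per_slice": per_slice,
        "global_mean": float(seg_means.mean()),
    }
    if plot_path is not None:
        plot_bullseye(report["per_segment"], plot_path,
                      title=value, center_text=f"{report['global_mean']:.1f}")
    return report


def plot_bullseye(per_segment: dict, path, title: str = "", center_text: str = "") -> None:
    """Render a 16-segment bullseye (basal ring outside, apical inside)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = [per_segment.get(s, np.nan) for s in range(1, 17)]
    finite = [v for v in vals if np.isfinite(v)]
    vmin = min(finite) if finite else 0.0
    vmax = max(finite) if finite else 1.0
    if vmax == vmin:
        vmax = vmin + 1.0
    cmap = plt.get_cmap("viridis")

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    rings = [("basal", range(1, 7), 0.75, 1.0), ("mid", range(7, 13), 0.5, 0.75),
             ("apical", range(13, 17), 0.25, 0.5)]
    for _, segs, r0, r1 in rings:
        segs = list(segs)
        nseg = len(segs)
        width = 2 * math.pi / nseg
        for k, seg in enumerate(segs):
            v = per_segment.get(seg, np.nan)
            color = cmap((v - vmin) / (vmax - vmin)) if np.isfinite(v) else "0.8"
            ax.bar(k * width + width / 2.0, r1 - r0, width=width, bottom=r0,
                   color=color, edgecolor="w")
            if np.isfinite(v):
                ax.text(k * width + width / 2.0, (r0 + r1) / 2.0, f"{v:.0f}",
                        ha="center", va="center", fontsize=7)
    if center_text:
        ax.text(0, 0, center_text, ha="center", va="center", fontsize=11)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
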