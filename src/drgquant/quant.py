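"""Per-neuron quantification.

Implements the measurement conventions of RNAscope quantification in DRG
sections: a neuron is called positive for a probe when it contains at
least three puncta- or cluster-like structures; per-cell expression level
is the mean intensity inside a fixed-radius circular ROI (10 px / 6.3 um)
minus the image background, where the background is the average of the
mean intensities of three to five manually or automatically chosen
puncta-free regions; soma cross-sectional areas (polygon/mask pixel count
times pixel area) are binned at 100 um^2 and split into small (<650 um^2),
medium (650-900 um^2) and large (>900 um^2) classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from drgquant.imsim import FieldImage, disk_mask
from drgquant.popsim import NeuronRecord, combo_label
from drgquant.spots import SpotSet

__all__ = [
    "QuantConfig",
    "call_positive",
    "measure_mean_intensity",
    "estimate_background",
    "corrected_intensity",
    "classify_size",
    "coexpression_table",
    "marker_percentage_table",
    "measure_soma_area",
    "circular_vs_mask_intensity",
]


@dataclass(frozen=True)
class QuantConfig:
    positivity_min_puncta: int = 3
    roi_radius_px: int = 10
    px_size_um: float = 0.63
    n_background_regions: int = 4  # allowed range 3..5
    size_small_max: float = 650.0  # um^2
    size_medium_max: float = 900.0  # um^2
    hist_bin: float = 100.0  # um^2

    def __post_init__(self) -> None:
        if self.positivity_min_puncta < 1:
            raise ValueError("positivity_min_puncta must be >= 1")
        if not (0 < self.size_small_max < self.size_medium_max):
            raise ValueError("need 0 < size_small_max < size_medium_max")
        if not (3 <= self.n_background_regions <= 5):
            raise ValueError("n_background_regions must be within [3, 5]")

    @property
    def roi_radius_um(self) -> float:
        """Physical ROI radius (6.3 um with the 10 px / 0.63 um defaults)."""
        return self.roi_radius_px * self.px_size_um


def call_positive(puncta_count: int, cfg: QuantConfig = QuantConfig()) -> bool:
    """Positive iff the neuron holds >= 3 puncta/cluster structures (default)."""
    if puncta_count < 0:
        raise ValueError("puncta count must be >= 0")
    return puncta_count >= cfg.positivity_min_puncta


def _pixels(img: FieldImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, FieldImage) else np.asarray(img, dtype=float)


def measure_mean_intensity(
    img: FieldImage | np.ndarray,
    center_rc: tuple[float, float],
    cfg: QuantConfig = QuantConfig(),
    radius_px: int | None = None,
) -> float:
    """Mean pixel value inside the circular ROI centered on ``center_rc``.

    Raises if the circle is clipped by the image border (such neurons are
    excluded upstream).
    """
    px = _pixels(img)
    r = cfg.roi_radius_px if radius_px is None else radius_px
    row, col = center_rc
    if row - r < 0 or col - r < 0 or row + r > px.shape[0] - 1 or col + r > px.shape[1] - 1:
        raise ValueError(f"circular ROI of radius {r} px at {center_rc} exits the image")
    mask = disk_mask(px.shape, center_rc, r)
    return float(px[mask].mean())


def estimate_background(
    img: FieldImage | np.ndarray,
    background_centers,
    cfg: QuantConfig = QuantConfig(),
    spots: SpotSet | None = None,
    radius_px: int | None = None,
) -> float:
    """Average of the mean intensities of 3-5 puncta-free regions.

    If a :class:`SpotSet` is supplied, every region is verified to contain
    no detected peak; offending regions raise with their indices.
    """
    centers = list(background_centers)
    if not (3 <= len(centers) <= 5):
        raise ValueError(f"need 3 to 5 background regions, got {len(centers)}")
    px = _pixels(img)
    r = cfg.roi_radius_px if radius_px is None else radius_px
    if spots is not None and len(spots):
        bad = []
        for i, (row, col) in enumerate(centers):
            d2 = (spots.coords[:, 0] - row) ** 2 + (spots.coords[:, 1] - col) ** 2
            if np.any(d2 <= r**2):
                bad.append(i)
        if bad:
            raise ValueError(f"background regions {bad} contain detected puncta")
    means = [float(px[disk_mask(px.shape, c, r)].mean()) for c in centers]
    return float(np.mean(means))


def corrected_intensity(neuron_mean: float, background: float) -> float:
    """Background-subtracted per-neuron signal."""
    return neuron_mean - background


def classify_size(area_um2: float, cfg: QuantConfig = QuantConfig()) -> str:
    """Small (< 650), medium (650-900, endpoints inclusive) or large (> 900)."""
    if area_um2 <= 0:
        raise ValueError("soma area must be > 0")
    if area_um2 < cfg.size_small_max:
        return "small"
    if area_um2 <= cfg.size_medium_max:
        return "medium"
    return "large"


def coexpression_table(
    neurons: list[NeuronRecord],
    probes: tuple[str, ...],
    use: str = "called",
) -> pd.DataFrame:
    """Partition neurons over the 2^P on/off combinations of the probe panel.

    Returns a frame with one row per combination (including empty ones)
    carrying ``count`` and ``fraction``; fractions sum to 1 and counts sum
    to the number of neurons.  ``use`` selects called or ground-truth
    expression states.
    """
    attr = {"called": "called_expr", "truth": "truth_expr"}[use]
    states = []
    for nr in neurons:
        expr = getattr(nr, attr)
        for p in probes:
            if p not in expr:
                raise ValueError(f"neuron {nr.id} has no {use} state for probe {p}")
        states.append(frozenset(p for p in probes if expr[p]))
    n = len(states)
    rows = []
    for k in range(len(probes) + 1):
        for combo in itertools.combinations(probes, k):
            key = frozenset(combo)
            count = sum(s == key for s in states)
            rows.append(
                {
                    "combination": combo_label(key),
                    "count": count,
                    "fraction": count / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def marker_percentage_table(
    neurons: list[NeuronRecord], probe: str, use: str = "called"
) -> dict[str, float]:
    """Percent of each marker class called positive for ``probe``.

    Empty classes are reported as NaN (undefined), never as 0.
    """
    attr = {"called": "called_expr", "truth": "truth_expr"}[use]
    out: dict[str, float] = {}
    by_marker: dict[str, list[bool]] = {}
    for nr in neurons:
        expr = getattr(nr, attr)
        if probe not in expr:
            raise ValueError(f"neuron {nr.id} has no {use} call for probe {probe}")
        by_marker.setdefault(nr.marker, []).append(bool(expr[probe]))
    for marker, calls in by_marker.items():
        out[marker] = 100.0 * sum(calls) / len(calls)
    return out


def measure_soma_area(mask_component: np.ndarray, px_size_um: float) -> float:
    """Soma cross-sectional area: pixel count times pixel area, um^2."""
    mask = np.asarray(mask_component, dtype=bool)
    npx = int(mask.sum())
    if npx == 0:
        raise ValueError("empty mask component")
    return npx * px_size_um**2


def circular_vs_mask_intensity(
    img: FieldImage | np.ndarray,
    labels: np.ndarray,
    cfg: QuantConfig = QuantConfig(),
    radius_px: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Compare centered circular-ROI means against whole-soma-mask means.

    For each labeled soma, the circular ROI is centered on the mask
    centroid; somata too small to contain the circle are flagged and
    excluded.  Returns the paired per-neuron table and the Pearson r over
    the included neurons (error if fewer than 3 remain).
    """
    px = _pixels(img)
    labels = np.asarray(labels)
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        rr, cc = np.nonzero(mask)
        center = (float(rr.mean()), float(cc.mean()))
        r = cfg.roi_radius_px if radius_px is None else radius_px
        circle = disk_mask(px.shape, center, r)
        contained = bool(np.all(mask[circle]))
        row = {
            "label": int(lab),
            "mask_mean": float(px[mask].mean()),
            "circle_mean": float(px[circle].mean()) if contained else np.nan,
            "included": contained,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    good = table[table["included"]]
    if len(good) < 3:
        raise ValueError(f"only {len(good)} neurons usable; need >= 3 for a correlation")
    r_val = float(sps.pearsonr(good["circle_mean"], good["mask_mean"]).statistic)
    return table, r_val
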