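"""DNA-content flow-cytometry ploidy calling: gating and peak anchoring.

Events carry an area (integrated DNA-dye pulse) and a width signal.  Debris
is removed below a fraction of the dominant DNA peak; doublets — whose area
is the sum of two cells' areas while the pulse width stays near a single
cell's — are removed where log(area / width) sits above the singlet trend by
more than ``t`` robust standard deviations.  Ploidy peaks are located by
Gaussian KDE on log area (Silverman bandwidth, scale-free); the anchor peak
(2n, or 4n for a tetraploid control) fixes the DNA scale and events are
classified with the same ratio windows used for image-based calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .ploidy import DEFAULT_WINDOWS, PLOIDY_CLASSES, CalibrationModel, classify_ploidy


class GatingError(ValueError):
    """All events were gated out, or no usable peak structure was found."""


def _dominant_peak(areas: np.ndarray) -> float:
    """Position of the highest KDE peak of log area."""
    la = np.log(areas)
    kde = gaussian_kde(la, bw_method="silverman")
    grid = np.linspace(la.min() - 0.1, la.max() + 0.1, 2048)
    return float(np.exp(grid[np.argmax(kde(grid))]))


def gate_singlets(
    events: pd.DataFrame,
    debris_fraction: float = 0.3,
    doublet_t: float = 3.0,
    doublet_min_excess: float = 0.3,
) -> pd.DataFrame:
    """Assign each event exactly one gate: ``debris``, ``doublet`` or
    ``singlet`` (new ``gate`` column on a copy of the table).

    Debris: area below ``debris_fraction`` times the dominant DNA peak.
    Doublets: residual of log(area/width) above the remaining events'
    median by more than ``doublet_t`` MAD-based robust standard deviations
    AND by at least ``doublet_min_excess`` log units — a true doublet
    roughly doubles area/width (excess ~ log 2 = 0.69), so a floor well
    below that keeps ordinary measurement noise from being flagged in
    clean samples while leaving doublet sensitivity intact.
    """
    if len(events) == 0:
        raise GatingError("empty event table")
    if not {"area", "width"}.issubset(events.columns):
        raise ValueError("event table needs 'area' and 'width' columns")
    out = events.copy()
    area = out["area"].to_numpy(dtype=float)
    width = out["width"].to_numpy(dtype=float)
    if np.any(area <= 0):
        raise ValueError("retained events must have positive area")

    peak = _dominant_peak(area)
    gate = np.array(["singlet"] * len(out), dtype=object)
    gate[area < debris_fraction * peak] = "debris"

    cand = gate == "singlet"
    if not cand.any():
        raise GatingError("all events gated out as debris")
    ratio = np.log(area[cand] / width[cand])
    med = np.median(ratio)
    mad = np.median(np.abs(ratio - med))
    rsd = 1.4826 * mad
    if rsd > 0:
        cut = max(doublet_t * rsd, doublet_min_excess)
        dbl = np.zeros(len(out), dtype=bool)
        dbl[np.flatnonzero(cand)] = ratio > med + cut
        gate[dbl] = "doublet"
    if not (gate == "singlet").any():
        raise GatingError("all events gated out")
    out["gate"] = gate
    return out


@dataclass
class FlowPloidyResult:
    """Outcome of histogram-based ploidy calling on singlet events."""

    reference_2n: float
    peak_positions: list[float]
    calls: np.ndarray
    fractions: dict[str, float]
    n_singlets: int


def call_ploidy_histogram(
    areas,
    anchor: str = "2n",
    windows: tuple[float, float] = DEFAULT_WINDOWS,
    min_events: int = 500,
    peak_height_frac: float = 0.05,
    ambiguity_frac: float = 0.10,
    reference: float | None = None,
) -> FlowPloidyResult:
    """Call per-event ploidy from singlet DNA-content areas.

    KDE peaks on log area are detected; the most prominent peak is taken as
    the anchor population (2n, or 4n halved to the diploid position).  An
    error is raised when no peak exists or when the two tallest peaks are
    within ``ambiguity_frac`` of each other in density (ambiguous anchor).
    Passing an explicit diploid ``reference`` position (e.g. derived from a
    separately run tetraploid control) bypasses peak anchoring entirely.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size < min_events:
        raise GatingError(
            f"need at least {min_events} singlet events, got {areas.size}"
        )
    if reference is not None:
        model = CalibrationModel(reference=float(reference), method="external",
                                 windows=windows)
        calls = classify_ploidy(areas, model)
        fractions = {c: float(np.mean(calls == c)) for c in PLOIDY_CLASSES}
        return FlowPloidyResult(
            reference_2n=float(reference), peak_positions=[], calls=calls,
            fractions=fractions, n_singlets=int(areas.size),
        )
    la = np.log(areas)
    if np.ptp(la) < 1e-12:
        # degenerate single-value histogram: one trivial peak
        peaks_pos = np.array([float(np.exp(la[0]))])
        heights = np.array([1.0])
    else:
        kde = gaussian_kde(la, bw_method="silverman")
        grid = np.linspace(la.min() - 0.2, la.max() + 0.2, 2048)
        dens = kde(grid)
        idx, _ = find_peaks(dens, height=peak_height_frac * dens.max())
        if idx.size == 0:
            raise GatingError("no detectable DNA-content peak")
        order = np.argsort(dens[idx])[::-1]
        peaks_pos = np.exp(grid[idx][order])
        heights = dens[idx][order]
    if heights.size >= 2 and heights[1] >= (1 - ambiguity_frac) * heights[0]:
        raise GatingError(
            "anchor peak ambiguous: two peaks of comparable prominence"
        )
    anchor_pos = float(peaks_pos[0])
    if anchor == "4n":
        ref = anchor_pos / 2.0
    elif anchor == "2n":
        ref = anchor_pos
    else:
        raise ValueError("anchor must be '2n' or '4n'")
    model = CalibrationModel(reference=ref, method="kde-peak", windows=windows)
    calls = classify_ploidy(areas, model)
    fractions = {c: float(np.mean(calls == c)) for c in PLOIDY_CLASSES}
    return FlowPloidyResult(
        reference_2n=ref,
        peak_positions=sorted(float(p) for p in peaks_pos),
        calls=calls,
        fractions=fractions,
        n_singlets=int(areas.size),
    )


def analyze_events(
    events: pd.DataFrame,
    anchor: str = "2n",
    debris_fraction: float = 0.3,
    doublet_t: float = 3.0,
    windows: tuple[float, float] = DEFAULT_WINDOWS,
) -> tuple[pd.DataFrame, FlowPloidyResult]:
    """Gate then call: returns the gated table (with per-singlet ``call``
    column) and the fraction report."""
    gated = gate_singlets(events, debris_fraction, doublet_t)
    singlets = gated["gate"] == "singlet"
    result = call_ploidy_histogram(
        gated.loc[singlets, "area"].to_numpy(), anchor=anchor, windows=windows
    )
    gated["call"] = pd.NA
    gated.loc[singlets, "call"] = result.calls
    return gated, result
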