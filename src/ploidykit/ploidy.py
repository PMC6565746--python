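"""Calibration of FI values to a diploid reference and ploidy classification.

Integrated DNA-stain intensity is proportional to DNA content but carries an
arbitrary instrument scale, so classification is anchored to a population of
known ploidy (a diploid reference, or a tetraploid control whose position is
halved).  Classes are assigned from the ratio r = FI / reference using
windows placed at the geometric midpoints between the ideal positions 1x,
2x and 4x: r < 1.5 -> 2n, 1.5 <= r < 3 -> 4n, r >= 3 -> >4n.  A 3-component
Gaussian-mixture classifier on log-FI is provided as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

PLOIDY_CLASSES = ("2n", "4n", ">4n")
DEFAULT_WINDOWS = (1.5, 3.0)


@dataclass
class CalibrationModel:
    """Diploid FI reference plus ratio-window boundaries.

    ``windows = (w1, w2)``: ratios below w1 are 2n, [w1, w2) are 4n, and
    >= w2 are >4n (boundaries belong to the upper class).
    """

    reference: float
    method: str = "median"
    windows: tuple[float, float] = DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        if self.reference <= 0:
            raise ValueError("reference must be positive")
        w1, w2 = self.windows
        if not 0 < w1 < w2:
            raise ValueError("windows must be ordered positive ratios")


def kde_mode(values: np.ndarray, bw_method: str = "silverman") -> float:
    """Primary mode of a sample by Gaussian KDE on the log scale."""
    logv = np.log(values)
    kde = gaussian_kde(logv, bw_method=bw_method)
    grid = np.linspace(logv.min() - 0.1, logv.max() + 0.1, 1024)
    return float(np.exp(grid[np.argmax(kde(grid))]))


def calibrate_reference(
    fi_values,
    method: str = "median",
    anchor: str = "2n",
    windows: tuple[float, float] = DEFAULT_WINDOWS,
) -> CalibrationModel:
    """Estimate the diploid FI reference from a known-ploidy population.

    ``anchor`` is the ploidy of the reference population; a tetraploid
    anchor halves the estimated position.  ``method`` is ``median`` (robust
    location) or ``kde-mode`` (primary density mode, for reference samples
    that are themselves mixtures dominated by the anchor class).
    """
    fi = np.asarray(fi_values, dtype=float)
    if fi.size < 10:
        raise ValueError(f"need at least 10 reference values, got {fi.size}")
    if np.any(fi <= 0):
        raise ValueError("reference FI values must be positive")
    if anchor not in ("2n", "4n"):
        raise ValueError("anchor must be '2n' or '4n'")
    if method == "median":
        ref = float(np.median(fi))
    elif method == "kde-mode":
        ref = kde_mode(fi)
    else:
        raise ValueError(f"unknown calibration method {method!r}")
    if anchor == "4n":
        ref /= 2.0
    return CalibrationModel(reference=ref, method=method, windows=windows)


def classify_ploidy(fi, model: CalibrationModel):
    """Classify FI value(s) into '2n' / '4n' / '>4n' by ratio windows."""
    arr = np.asarray(fi, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("FI values must be positive")
    r = arr / model.reference
    w1, w2 = model.windows
    out = np.where(r < w1, "2n", np.where(r < w2, "4n", ">4n"))
    return out.item() if np.isscalar(fi) else out


def classify_ploidy_gmm(
    fi_values, model: CalibrationModel, random_state: int = 0
) -> np.ndarray:
    """Alternative classifier: 3-component GMM on log FI with means
    initialised at the calibrated 1x / 2x / 4x positions; each component is
    named by its fitted mean's nearest ideal position."""
    fi = np.asarray(fi_values, dtype=float)
    if np.any(fi <= 0):
        raise ValueError("FI values must be positive")
    logfi = np.log(fi[:, None])
    init = np.log(model.reference * np.array([1.0, 2.0, 4.0]))[:, None]
    gmm = GaussianMixture(
        n_components=3, means_init=init, random_state=random_state, n_init=1
    ).fit(logfi)
    comp = gmm.predict(logfi)
    ideal = np.log(model.reference * np.array([1.0, 2.0, 4.0]))
    names = np.array(PLOIDY_CLASSES)[
        np.argmin(np.abs(gmm.means_.ravel()[:, None] - ideal[None, :]), axis=1)
    ]
    return names[comp]


@dataclass
class PloidyComposition:
    """Per-group class composition with across-replicate SEM."""

    group: str
    counts: dict[str, int]
    fractions: dict[str, float]
    sem: dict[str, float]
    n_cells: int
    n_replicates: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        if sum(self.counts.values()) != self.n_cells:
            raise ValueError("counts do not sum to n_cells")


def compose(
    calls,
    groups=None,
    replicates=None,
) -> list[PloidyComposition]:
    """Compile per-group ploidy compositions.

    ``calls`` is a sequence of class labels; ``groups`` and ``replicates``
    are parallel key sequences (both default to a single pooled group /
    replicate).  Fractions are computed per replicate and averaged across
    replicates (SEM = sd / sqrt(n_replicates)); counts are pooled.
    """
    calls = np.asarray(calls, dtype=object)
    if calls.size == 0:
        raise ValueError("no ploidy calls to compose")
    groups = np.asarray(groups if groups is not None else ["all"] * calls.size)
    replicates = np.asarray(
        replicates if replicates is not None else ["rep1"] * calls.size
    )
    if not (calls.size == groups.size == replicates.size):
        raise ValueError("calls, groups and replicates must be parallel")
    df = pd.DataFrame({"call": calls, "group": groups, "replicate": replicates})
    out = []
    for g, sub in df.groupby("group", sort=True):
        per_rep = (
            sub.groupby("replicate")["call"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=PLOIDY_CLASSES, fill_value=0.0)
        )
        mean = per_rep.mean(axis=0)
        nrep = per_rep.shape[0]
        sem = per_rep.std(axis=0, ddof=1) / np.sqrt(nrep) if nrep > 1 else per_rep.iloc[0] * 0.0
        counts = sub["call"].value_counts().reindex(PLOIDY_CLASSES, fill_value=0)
        # average-of-replicates need not sum to exactly 1 under float ops
        mean = mean / mean.sum()
        out.append(
            PloidyComposition(
                group=str(g),
                counts={c: int(counts[c]) for c in PLOIDY_CLASSES},
                fractions={c: float(mean[c]) for c in PLOIDY_CLASSES},
                sem={c: float(sem[c]) for c in PLOIDY_CLASSES},
                n_cells=int(len(sub)),
                n_replicates=int(nrep),
            )
        )
    return out


def composition_frame(compositions: list[PloidyComposition]) -> pd.DataFrame:
    """Flatten compositions into a tidy report table (one row per group)."""
    rows = []
    for c in compositions:
        row = {"group": c.group, "n_cells": c.n_cells, "n_replicates": c.n_replicates}
        for cls in PLOIDY_CLASSES:
            row[f"pct_{cls}"] = 100.0 * c.fractions[cls]
            row[f"sem_{cls}"] = 100.0 * c.sem[cls]
            row[f"count_{cls}"] = c.counts[cls]
        rows.append(row)
    return pd.DataFrame(rows)
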