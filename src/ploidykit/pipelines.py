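"""End-to-end parameter-recovery harnesses.

Each harness generates synthetic data at a known ground-truth composition,
runs the full inference pipeline on it, and reports the recovered
composition — the validation strategy for a method whose real inputs
(tissue sections, cytometer events, sequencing libraries) carry no
accessible ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import flow as flowmod
from . import scrna
from .imaging import match_labels, measure_nuclei, segment_nuclei
from .ploidy import (
    PLOIDY_CLASSES,
    calibrate_reference,
    classify_ploidy,
    compose,
    composition_frame,
)
from .synth import (
    CountsSimParams,
    FlowSimParams,
    largest_remainder,
    layout_scene,
    simulate_confocal_scene,
    simulate_counts,
    simulate_flow_events,
)

_PLOIDY_OF_CLASS = {"2n": 2, "4n": 4, ">4n": 8}


@dataclass
class FlowRecovery:
    """Mean recovered fractions across replicate simulated experiments."""

    mean_fractions: dict[str, float]
    per_replicate: pd.DataFrame
    truth: dict[str, float]


def recover_flow_composition(
    fractions: tuple[float, float, float],
    n_events: int = 22_000,
    n_replicates: int = 4,
    cv: float = 0.05,
    doublet_rate: float = 0.05,
    debris_rate: float = 0.02,
    anchor: str = "2n",
    seed: int = 0,
) -> FlowRecovery:
    """Simulate replicate cytometry runs at a known composition, gate and
    call ploidy, and average the recovered class fractions."""
    rows = []
    for rep in range(n_replicates):
        params = FlowSimParams(
            n_events=n_events,
            fractions=fractions,
            cv=cv,
            doublet_rate=doublet_rate,
            debris_rate=debris_rate,
            seed=seed + rep,
        )
        events = simulate_flow_events(params)
        _, result = flowmod.analyze_events(events, anchor=anchor)
        rows.append({"replicate": rep, **result.fractions,
                     "n_singlets": result.n_singlets})
    per_rep = pd.DataFrame(rows)
    mean = {c: float(per_rep[c].mean()) for c in PLOIDY_CLASSES}
    truth = dict(zip(PLOIDY_CLASSES, fractions))
    return FlowRecovery(mean_fractions=mean, per_replicate=per_rep, truth=truth)


@dataclass
class ImagingRecovery:
    fractions: dict[str, float]
    composition: pd.DataFrame
    measurements: pd.DataFrame
    n_segmented: int
    n_excluded_by_rule: int
    truth: dict[str, float]


def recover_imaging_composition(
    fractions: tuple[float, float, float],
    n_nuclei: int = 300,
    n_reference: int = 30,
    nuclei_per_scene: int = 25,
    signal_model: str = "density",
    rule: str = "true",
    plant_tryptase_positive: int = 0,
    cell_type: str = "cardiomyocyte",
    seed: int = 0,
) -> ImagingRecovery:
    """Image-based recovery: scenes -> segmentation -> FI -> calibration ->
    classification -> composition.

    ``n_nuclei`` target nuclei are generated at exactly the requested
    2n/4n/>4n composition (largest-remainder rounding) together with
    ``n_reference`` planted diploid reference nuclei used solely to anchor
    the FI scale (the known-diploid-content calibration).  Nuclei are
    rendered in batches of ``nuclei_per_scene``, each batch acting as one
    replicate experiment.  A marker rule (e.g. ``"ckit+ AND tryptase-"``)
    is applied before composition; ``plant_tryptase_positive`` extra
    tryptase+ nuclei are added to exercise the mast-cell exclusion.
    """
    rng = np.random.default_rng(seed)
    counts = largest_remainder(fractions, n_nuclei)
    ploidies = np.repeat([2, 4, 8], counts)
    rng.shuffle(ploidies)
    roles = [("target", int(p)) for p in ploidies]
    roles += [("reference", 2)] * n_reference
    roles += [("tryptase_pos", 2)] * plant_tryptase_positive
    rng.shuffle(roles)

    frames = []
    n_excluded = 0
    for scene_i in range(0, len(roles), nuclei_per_scene):
        batch = roles[scene_i : scene_i + nuclei_per_scene]
        markers = [
            {"ckit": True, "tryptase": role == "tryptase_pos"}
            for role, _ in batch
        ]
        render_markers = ("ckit", "tryptase") if rule.strip().lower() != "true" else ()
        spec = layout_scene(
            [p for _, p in batch],
            markers=markers,
            cell_types=[role for role, _ in batch],
            signal_model=signal_model,
            marker_channels=render_markers,
            seed=int(rng.integers(2**31)),
        )
        stack, true_labels, truth = simulate_confocal_scene(spec)
        seg = segment_nuclei(stack)
        if seg.max() == 0:
            continue
        meas = measure_nuclei(stack, seg, rule=rule)
        matches = match_labels(seg, true_labels)
        meas = meas.merge(matches, left_on="nucleus_id", right_on="seg_id")
        meas = meas[meas["true_id"] > 0]
        meas = meas.merge(
            truth, left_on="true_id", right_on="nucleus_id", suffixes=("", "_true")
        )
        meas["scene"] = scene_i // nuclei_per_scene
        n_excluded += int((~meas["included"]).sum())
        frames.append(meas)
    all_meas = pd.concat(frames, ignore_index=True)

    ref = all_meas[(all_meas["cell_type"] == "reference") & all_meas["included"]]
    model = calibrate_reference(ref["fi"].to_numpy(), method="median", anchor="2n")
    target = all_meas[(all_meas["cell_type"] == "target") & all_meas["included"]]
    calls = classify_ploidy(target["fi"].to_numpy(), model)
    comps = compose(calls, groups=[cell_type] * len(calls),
                    replicates=target["scene"].tolist())
    comp_df = composition_frame(comps)
    frac = comps[0].fractions
    truth_frac = dict(zip(PLOIDY_CLASSES, fractions))
    return ImagingRecovery(
        fractions={c: float(frac[c]) for c in PLOIDY_CLASSES},
        composition=comp_df,
        measurements=all_meas,
        n_segmented=int(len(all_meas)),
        n_excluded_by_rule=n_excluded,
        truth=truth_frac,
    )


@dataclass
class ScrnaRecovery:
    proportions: dict[str, float]
    truth: dict[str, float]
    n_cells_kept: int
    n_genes_kept: int


def recover_scrna_proportions(
    type_proportions: dict[str, float],
    n_cells: int = 1036,
    seed: int = 0,
    markers: dict[str, tuple[str, ...]] | None = None,
) -> ScrnaRecovery:
    """Simulate a droplet experiment at known type proportions, QC-filter,
    and recover the proportions by marker-based typing."""
    params = CountsSimParams(
        n_cells=n_cells,
        type_proportions=dict(type_proportions),
        exact_proportions=True,
        seed=seed,
    )
    matrix, _truth = simulate_counts(params)
    filtered, report = scrna.qc_filter(matrix)
    result = scrna.assign_cell_types(filtered, markers=markers)
    return ScrnaRecovery(
        proportions=result.proportions,
        truth=dict(type_proportions),
        n_cells_kept=report.n_cells_kept,
        n_genes_kept=report.n_genes_kept,
    )
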