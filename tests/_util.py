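"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from graspmvpa.bold import NoiseModel, PatternModel, simulate_subject
from graspmvpa.design import DesignSpec, EventTable, generate_design
from graspmvpa.preprocess import preprocess_chain
from graspmvpa.sampling import (
    MiniblockSamples,
    SampleSet,
    assign_volumes_to_miniblocks,
    build_samples,
    classification_by_name,
    select_classification,
)
from graspmvpa.decoding import leave_pair_out_cv


def simulate_subject_accuracy(
    seed: int,
    effects: dict[str, float] | None = None,
    n_voxels: int = 30,
    classification: str = "grasp_type",
    spec: DesignSpec | None = None,
) -> float:
    """Reduced single-subject pipeline: simulate one ROI, decode one contrast."""
    spec = spec or DesignSpec()
    ss = np.random.SeedSequence(seed)
    design_ss, pattern_ss, noise_ss = ss.spawn(3)
    design = generate_design(spec, np.random.default_rng(design_ss))
    model = PatternModel.from_factor_effects(
        n_voxels, effects or {}, np.random.default_rng(pattern_ss)
    )
    ts = simulate_subject(design, model, noise=NoiseModel(), rng=noise_ss)["roi"]
    clean = preprocess_chain(ts)
    mapping = assign_volumes_to_miniblocks(design)
    samples = build_samples(clean, mapping, design)
    sset = select_classification(samples, classification_by_name(classification))
    return leave_pair_out_cv(sset).accuracy


def null_sampleset(rng: np.random.Generator, n_per_class: int = 18, n_voxels: int = 10) -> SampleSet:
    """Label-free Gaussian samples with +1/-1 labels (decoding null model)."""
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_voxels))
    T = np.tile([1, -1], n_per_class)
    meta = pd.DataFrame(
        {
            "miniblock_id": np.arange(n),
            "run": 1 + (np.arange(n) // (n // 2)),
            "condition": np.where(T == 1, "A", "B"),
        }
    )
    return SampleSet(X=X, T=T, meta=meta, classification="null")


def toy_event_table(
    onsets_by_block: dict[int, tuple[float, str]],
    run: int = 1,
    spec: DesignSpec | None = None,
    miniblock_size: int = 1,
) -> EventTable:
    """Hand-built schedule: block id -> (first onset, condition), 1 trial/block."""
    spec = spec or DesignSpec(
        n_runs=1, volumes_per_run=20, miniblock_size=miniblock_size,
        trials_per_condition=miniblock_size,
    )
    rows = [
        (run, b, i, onset, cond)
        for i, (b, (onset, cond)) in enumerate(sorted(onsets_by_block.items()))
    ]
    table = pd.DataFrame(
        rows, columns=["run", "miniblock_id", "trial_index", "onset", "condition"]
    )
    return EventTable(table=table, spec=spec)
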