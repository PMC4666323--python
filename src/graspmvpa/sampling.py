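"""Mini-block sample construction for the classifier.

Volumes are partitioned among mini-blocks by onset intervals; within each
block the first ``discard_volumes`` volumes (12 s at TR 3 s) are dropped to
let the hemodynamic response stabilize, and the remainder are averaged into
one pattern.  A classification selects and labels the relevant conditions
with +1 / -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import EventTable
from .timeseries import RoiTimeSeries


@dataclass(frozen=True)
class ClassificationSpec:
    """Binary contrast: conditions labeled +1 vs conditions labeled -1."""

    name: str
    positive: frozenset[str]
    negative: frozenset[str]

    def __post_init__(self) -> None:
        pos = frozenset(self.positive)
        neg = frozenset(self.negative)
        object.__setattr__(self, "positive", pos)
        object.__setattr__(self, "negative", neg)
        if not pos or not neg:
            raise ValueError(f"{self.name}: both classes must be non-empty")
        if pos & neg:
            raise ValueError(f"{self.name}: classes overlap: {sorted(pos & neg)}")


#: the study's six binary classifications
DEFAULT_CLASSIFICATIONS: tuple[ClassificationSpec, ...] = (
    ClassificationSpec(
        "object_size_grasp", frozenset({"PGS", "WHGS"}), frozenset({"PGL", "WHGL"})
    ),
    ClassificationSpec("object_size_reach", frozenset({"RS"}), frozenset({"RL"})),
    ClassificationSpec(
        "grasp_type", frozenset({"PGS", "PGL"}), frozenset({"WHGS", "WHGL"})
    ),
    ClassificationSpec(
        "congruence", frozenset({"PGS", "WHGL"}), frozenset({"PGL", "WHGS"})
    ),
    ClassificationSpec(
        "pg_vs_reach", frozenset({"PGS", "PGL"}), frozenset({"RS", "RL"})
    ),
    ClassificationSpec(
        "whg_vs_reach", frozenset({"WHGS", "WHGL"}), frozenset({"RS", "RL"})
    ),
)


def classification_by_name(name: str) -> ClassificationSpec:
    for spec in DEFAULT_CLASSIFICATIONS:
        if spec.name == name:
            return spec
    raise KeyError(name)


def assign_volumes_to_miniblocks(
    events: EventTable,
    tr: float | None = None,
    volumes_per_run: int | None = None,
    lag_volumes: int = 0,
) -> dict[int, np.ndarray]:
    """Map mini-block id -> global volume indices (partition of task volumes).

    A volume belongs to block b iff its acquisition time lies in
    [first onset of b, first onset of the next block) within the run; the
    last block of a run extends to the run end.  ``lag_volumes`` shifts the
    partition later in time, clipped at run boundaries.
    """
    spec = events.spec
    tr = spec.tr if tr is None else tr
    volumes_per_run = spec.volumes_per_run if volumes_per_run is None else volumes_per_run
    mapping: dict[int, np.ndarray] = {}
    runs = sorted(events.table["run"].unique())
    for pos, run in enumerate(runs):
        ev = events.run_events(run)
        starts = (
            ev.groupby("miniblock_id")["onset"].min().sort_values()
        )  # block id -> first onset
        block_ids = starts.index.to_numpy()
        onsets = starts.to_numpy()
        vol_times = np.arange(volumes_per_run) * tr
        # boundary index of each block: first volume at/after its first onset
        bounds = np.searchsorted(vol_times, onsets - 1e-9, side="left")
        bounds = np.append(bounds, volumes_per_run)
        offset = pos * volumes_per_run
        for b, lo, hi in zip(block_ids, bounds[:-1], bounds[1:]):
            lo_l = min(lo + lag_volumes, volumes_per_run)
            hi_l = min(hi + lag_volumes, volumes_per_run)
            mapping[int(b)] = offset + np.arange(lo_l, hi_l)
    return mapping


@dataclass
class MiniblockSamples:
    """One averaged pattern per mini-block, with per-sample metadata."""

    X: np.ndarray  # n_blocks x n_voxels
    meta: pd.DataFrame  # columns: miniblock_id, run, condition
    subject: str = ""
    roi: str = ""
    hemisphere: str = ""

    def __post_init__(self) -> None:
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("meta rows must match sample count")

    def to_tsv(self, matrix_path, meta_path) -> None:
        """Write the pattern matrix and per-sample metadata as TSV."""
        pd.DataFrame(self.X).to_csv(
            matrix_path, sep="\t", index=False, header=False, float_format="%.10g"
        )
        meta = self.meta.copy()
        meta["subject"] = self.subject
        meta["roi"] = self.roi
        meta["hemisphere"] = self.hemisphere
        meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path, meta_path) -> "MiniblockSamples":
        X = pd.read_csv(matrix_path, sep="\t", header=None).to_numpy(dtype=float)
        meta = pd.read_csv(meta_path, sep="\t")
        extras = {
            key: str(meta[key].iloc[0]) if key in meta and len(meta) else ""
            for key in ("subject", "roi", "hemisphere")
        }
        meta = meta[["miniblock_id", "run", "condition"]]
        return cls(X=X, meta=meta, **extras)


@dataclass
class SampleSet:
    """Labeled samples for one binary classification."""

    X: np.ndarray
    T: np.ndarray  # +1 / -1
    meta: pd.DataFrame
    classification: str
    subject: str = ""
    roi: str = ""
    hemisphere: str = ""

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=int)
        if not np.all(np.isin(self.T, (-1, 1))):
            raise ValueError("labels must be +1 or -1")
        if len(self.T) != self.X.shape[0] or len(self.meta) != self.X.shape[0]:
            raise ValueError("X, T, meta must agree in length")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.T == 1)), int(np.sum(self.T == -1))


def build_samples(
    ts: RoiTimeSeries,
    mapping: dict[int, np.ndarray],
    events: EventTable,
    discard_volumes: int = 4,
) -> MiniblockSamples:
    """Average each mini-block's volumes (after the discard window) into one sample."""
    conditions = (
        events.table.groupby("miniblock_id")["condition"].first().to_dict()
    )
    runs = events.table.groupby("miniblock_id")["run"].first().to_dict()
    rows = []
    vecs = []
    for block_id in sorted(mapping):
        vols = mapping[block_id]
        if len(vols) <= discard_volumes:
            raise ValueError(
                f"mini-block {block_id} has {len(vols)} volumes; "
                f"need more than discard_volumes={discard_volumes}"
            )
        keep = vols[discard_volumes:]
        vecs.append(ts.data[keep].mean(axis=0))
        rows.append(
            {
                "miniblock_id": block_id,
                "run": runs[block_id],
                "condition": conditions[block_id],
            }
        )
    return MiniblockSamples(
        X=np.vstack(vecs),
        meta=pd.DataFrame(rows),
        subject=ts.subject,
        roi=ts.roi,
        hemisphere=ts.hemisphere,
    )


def select_classification(
    samples: MiniblockSamples, spec: ClassificationSpec
) -> SampleSet:
    """Retain the contrast's conditions and attach +1 / -1 labels."""
    present = set(samples.meta["condition"].unique())
    missing = (spec.positive | spec.negative) - present
    if missing:
        raise ValueError(
            f"{spec.name}: conditions absent from data: {sorted(missing)}"
        )
    cond = samples.meta["condition"]
    keep = cond.isin(spec.positive | spec.negative).to_numpy()
    labels = np.where(cond[keep].isin(spec.positive), 1, -1)
    if not (labels == 1).any() or not (labels == -1).any():
        raise ValueError(f"{spec.name}: a class is empty after selection")
    return SampleSet(
        X=samples.X[keep],
        T=labels,
        meta=samples.meta[keep].reset_index(drop=True),
        classification=spec.name,
        subject=samples.subject,
        roi=samples.roi,
        hemisphere=samples.hemisphere,
    )
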