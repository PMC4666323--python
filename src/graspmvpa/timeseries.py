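"""Shared container for ROI voxel time series."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd


@dataclass
class RoiTimeSeries:
    """Time x voxel BOLD matrix for one ROI of one subject.

    ``run_labels`` gives the (1-based) run index of each volume; voxel order
    is fixed (ascending linear index when extracted from an image).
    """

    data: np.ndarray
    run_labels: np.ndarray
    tr: float
    roi: str = ""
    subject: str = ""
    hemisphere: str = ""
    ground_truth: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.run_labels = np.asarray(self.run_labels, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x voxel)")
        if len(self.run_labels) != self.data.shape[0]:
            raise ValueError("run_labels length must match number of volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run_labels)

    def iter_runs(self) -> Iterator[tuple[int, np.ndarray]]:
        """Yield (run, boolean volume selector) per run, in ascending order."""
        for run in self.runs:
            yield int(run), self.run_labels == run

    def copy_with(self, data: np.ndarray) -> "RoiTimeSeries":
        return RoiTimeSeries(
            data=np.array(data, dtype=float),
            run_labels=self.run_labels.copy(),
            tr=self.tr,
            roi=self.roi,
            subject=self.subject,
            hemisphere=self.hemisphere,
            ground_truth=self.ground_truth,
        )

    # -- plain-text serialization (TSV + JSON sidecar) ---------------------

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        width = len(str(self.n_voxels - 1)) if self.n_voxels else 1
        cols = [f"v{j:0{width}d}" for j in range(self.n_voxels)]
        frame = pd.DataFrame(self.data, columns=cols)
        frame.insert(0, "run", self.run_labels)
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        sidecar = {
            "tr": self.tr,
            "roi": self.roi,
            "subject": self.subject,
            "hemisphere": self.hemisphere,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RoiTimeSeries":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t")
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            data=frame.drop(columns="run").to_numpy(dtype=float),
            run_labels=frame["run"].to_numpy(dtype=int),
            tr=float(meta.get("tr", 1.0)),
            roi=str(meta.get("roi", "")),
            subject=str(meta.get("subject", "")),
            hemisphere=str(meta.get("hemisphere", "")),
        )
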