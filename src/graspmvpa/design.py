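"""Event-related design generation for the reach-to-grasp experiment.

The experiment crosses action (precision grasp PG, whole-hand grasp WHG,
reaching-only R) with object size (small S, large L), giving six conditions.
Trials of one condition come in mini-blocks of five; object size is blocked
by run parity (odd runs small, even runs large).  Onset-to-onset intervals
(SOAs) follow a truncated "long exponential" distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

CONDITIONS: tuple[str, ...] = ("PGS", "PGL", "WHGS", "WHGL", "RS", "RL")
SMALL_CONDITIONS: frozenset[str] = frozenset({"PGS", "WHGS", "RS"})
LARGE_CONDITIONS: frozenset[str] = frozenset({"PGL", "WHGL", "RL"})

#: maximum ISI-vector redraws per run before declaring overflow
MAX_SCHEDULE_REDRAWS = 1000


class ScheduleOverflowError(RuntimeError):
    """A run's trial schedule cannot fit in volumes_per_run * tr seconds."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the event-related acquisition design.

    Defaults reproduce the study layout: 4 runs of 117 volumes at TR 3 s,
    45 trials per condition in mini-blocks of 5, ISIs on [3, 8] s.
    """

    n_runs: int = 4
    tr: float = 3.0
    volumes_per_run: int = 117
    conditions: tuple[str, ...] = CONDITIONS
    trials_per_condition: int = 45
    miniblock_size: int = 5
    isi_range: tuple[float, float] = (3.0, 8.0)
    isi_mean_target: float = 4.9
    trial_duration: float = 2.0
    run_parity_rule: bool = True
    seed: int | None = None

    @property
    def run_duration(self) -> float:
        return self.volumes_per_run * self.tr

    @property
    def blocks_per_condition(self) -> int:
        return self.trials_per_condition // self.miniblock_size

    def validate(self) -> None:
        lo, hi = self.isi_range
        if self.trials_per_condition % self.miniblock_size != 0:
            raise ValueError(
                f"trials_per_condition={self.trials_per_condition} not divisible "
                f"by miniblock_size={self.miniblock_size}"
            )
        if lo < 0 or lo > hi:
            raise ValueError(f"invalid isi_range {self.isi_range}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_runs < 1 or self.volumes_per_run < 1:
            raise ValueError("n_runs and volumes_per_run must be >= 1")
        if lo < hi and not lo < self.isi_mean_target < hi:
            raise ValueError(
                f"isi_mean_target={self.isi_mean_target} outside open interval "
                f"({lo}, {hi})"
            )
        if self.run_parity_rule:
            known = SMALL_CONDITIONS | LARGE_CONDITIONS
            unknown = set(self.conditions) - known
            if unknown:
                raise ValueError(
                    f"run_parity_rule requires small/large labels; unknown: {unknown}"
                )


@dataclass
class EventTable:
    """Per-trial schedule: one row per trial, onsets in seconds from run start."""

    table: pd.DataFrame  # columns: run, miniblock_id, trial_index, onset, condition
    spec: DesignSpec

    COLUMNS = ("run", "miniblock_id", "trial_index", "onset", "condition")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"EventTable missing columns: {sorted(missing)}")

    @property
    def n_trials(self) -> int:
        return len(self.table)

    @property
    def n_miniblocks(self) -> int:
        return self.table["miniblock_id"].nunique()

    def run_events(self, run: int) -> pd.DataFrame:
        return self.table[self.table["run"] == run]

    def to_tsv(self, path: str | Path) -> None:
        """Write a BIDS-style events table (onset, duration, trial_type, ...)."""
        out = pd.DataFrame(
            {
                "onset": self.table["onset"],
                "duration": self.spec.trial_duration,
                "trial_type": self.table["condition"],
                "run": self.table["run"],
                "miniblock_id": self.table["miniblock_id"],
                "trial_index": self.table["trial_index"],
            }
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path, spec: DesignSpec | None = None) -> "EventTable":
        raw = pd.read_csv(path, sep="\t")
        spec = spec or DesignSpec()
        if "duration" in raw.columns and len(raw):
            spec = replace(spec, trial_duration=float(raw["duration"].iloc[0]))
        table = pd.DataFrame(
            {
                "run": raw["run"].astype(int),
                "miniblock_id": raw["miniblock_id"].astype(int),
                "trial_index": raw["trial_index"].astype(int),
                "onset": raw["onset"].astype(float),
                "condition": raw["trial_type"].astype(str),
            }
        )
        return cls(table=table, spec=spec)


# ---------------------------------------------------------------------------
# truncated-exponential SOA distribution


def _truncated_exp_mean(lam: float, width: float) -> float:
    # mean of Exp(lam) truncated to [0, width]; lam may be negative
    # (rising density), lam -> 0 gives the uniform limit width/2
    if lam == 0.0:
        return width / 2.0
    return 1.0 / lam - width / math.expm1(lam * width)

def solve_isi_rate(isi_range: tuple[float, float], mean_target: float) -> float:
    """Rate of the truncated exponential on ``isi_range`` with the given mean.

    The mean is monotone decreasing in the rate; negative rates (density
    increasing toward the upper bound) cover means above the interval
    midpoint.  Raises ``ValueError`` for unattainable means.
    """
    lo, hi = isi_range
    width = hi - lo
    if width == 0:
        return 0.0
    m = mean_target - lo
    if not 0 < m < width:
        raise ValueError(
            f"mean target {mean_target} not attainable on [{lo}, {hi}]"
        )
    if math.isclose(m, width / 2.0, rel_tol=0, abs_tol=1e-12):
        return 0.0
    lam_max = 500.0 / width
    if m < width / 2.0:
        lo_b, hi_b = 1e-10, lam_max
    else:
        lo_b, hi_b = -lam_max, -1e-10
    return float(
        brentq(lambda lam: _truncated_exp_mean(lam, width) - m, lo_b, hi_b)
    )


def sample_isi(
    spec: DesignSpec,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw SOAs from the truncated exponential configured in ``spec``.

    Inverse-CDF sampling; degenerate interval returns its single point.
    """
    lo, hi = spec.isi_range
    if hi == lo:
        return lo if size is None else np.full(size, float(lo))
    lam = solve_isi_rate(spec.isi_range, spec.isi_mean_target)
    width = hi - lo
    u = rng.uniform(size=size)
    if lam == 0.0:
        return lo + u * width
    # F^-1(u) = -log(1 - u (1 - e^{-lam w})) / lam, valid for either sign
    return lo - np.log1p(u * math.expm1(-lam * width)) / lam


# ---------------------------------------------------------------------------
# schedule generation


def _conditions_for_run(spec: DesignSpec, run: int) -> list[str]:
    if not spec.run_parity_rule:
        return list(spec.conditions)
    allowed = SMALL_CONDITIONS if run % 2 == 1 else LARGE_CONDITIONS
    return [c for c in spec.conditions if c in allowed]


def _block_allocation(spec: DesignSpec) -> dict[int, list[str]]:
    """Mini-block condition labels per run, balancing per-run block counts.

    Each condition's blocks are split as evenly as possible over its eligible
    runs; the remainder is rotated by condition index so run totals differ by
    at most one (13/14 under the default design).
    """
    run_blocks: dict[int, list[str]] = {r: [] for r in range(1, spec.n_runs + 1)}
    # group conditions by their eligible-run set, index within the group
    groups: dict[tuple[int, ...], list[str]] = {}
    for cond in spec.conditions:
        runs = tuple(
            r for r in range(1, spec.n_runs + 1) if cond in _conditions_for_run(spec, r)
        )
        if not runs:
            raise ValueError(f"condition {cond} has no eligible run")
        groups.setdefault(runs, []).append(cond)
    for runs, conds in groups.items():
        for j, cond in enumerate(conds):
            base, rem = divmod(spec.blocks_per_condition, len(runs))
            counts = [base] * len(runs)
            for k in range(rem):
                counts[(j + k) % len(runs)] += 1
            for r, n in zip(runs, counts):
                run_blocks[r].extend([cond] * n)
    return run_blocks


def generate_design(
    spec: DesignSpec, rng: np.random.Generator | int | None = None
) -> EventTable:
    """Randomize mini-block order and trial onsets into a full schedule.

    Mini-block order is shuffled within each run; SOAs (including an initial
    fixation gap and a trailing rest) are drawn via :func:`sample_isi`.  A
    run whose drawn schedule exceeds ``volumes_per_run * tr`` is redrawn; if
    no draw fits within ``MAX_SCHEDULE_REDRAWS`` attempts a
    :class:`ScheduleOverflowError` naming the run is raised.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    run_blocks = _block_allocation(spec)
    rows = []
    block_id = 0
    for run in range(1, spec.n_runs + 1):
        labels = list(run_blocks[run])
        rng.shuffle(labels)
        n_trials = len(labels) * spec.miniblock_size
        if n_trials == 0:
            continue
        for _ in range(MAX_SCHEDULE_REDRAWS):
            gaps = np.atleast_1d(sample_isi(spec, rng, size=n_trials + 1))
            if gaps.sum() <= spec.run_duration:
                break
        else:
            raise ScheduleOverflowError(
                f"run {run}: schedule ({n_trials} trials) does not fit "
                f"{spec.run_duration:.0f} s after {MAX_SCHEDULE_REDRAWS} redraws"
            )
        onsets = np.cumsum(gaps[:-1])
        trial = 0
        for cond in labels:
            for _ in range(spec.miniblock_size):
                rows.append((run, block_id, trial, float(onsets[trial]), cond))
                trial += 1
            block_id += 1
    table = pd.DataFrame(rows, columns=list(EventTable.COLUMNS))
    return EventTable(table=table, spec=spec)


def volumes_for_duration(duration: float, tr: float) -> int:
    """Whole volumes acquired in ``duration`` seconds at repetition time ``tr``."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    return int(math.floor(duration / tr + 1e-9))
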