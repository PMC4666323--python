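"""Synthetic event-related BOLD generation.

Signal model per voxel: baseline + sum over conditions of (trial boxcar *
HRF) scaled by a univariate amplitude plus a zero-mean multivoxel pattern
weight, plus AR(1) noise and a slow sinusoidal drift.  Runs are simulated
independently; voxel patterns are the ground truth the decoder is asked to
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

from .design import CONDITIONS, DesignSpec, EventTable
from .timeseries import RoiTimeSeries

#: factor-level membership of each condition; None = factor not defined there
FACTOR_LEVELS: dict[str, dict[str, str | None]] = {
    "grasp_type": {
        "PGS": "PG", "PGL": "PG", "WHGS": "WHG", "WHGL": "WHG",
        "RS": None, "RL": None,
    },
    "action_type": {
        "PGS": "grasp", "PGL": "grasp", "WHGS": "grasp", "WHGL": "grasp",
        "RS": "reach", "RL": "reach",
    },
    "object_size": {
        "PGS": "S", "PGL": "L", "WHGS": "S", "WHGL": "L",
        "RS": "S", "RL": "L",
    },
    # one distinct pattern per condition (fully condition-specific signal)
    "condition": {c: c for c in CONDITIONS},
}


@dataclass(frozen=True)
class HrfModel:
    """Double-gamma hemodynamic response, normalized to unit peak.

    Canonical defaults: response peak 6 s, undershoot peak 16 s, dispersions
    1 s, peak:undershoot ratio 6.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    duration: float = 32.0

    def sample(self, dt: float) -> np.ndarray:
        """Impulse response sampled every ``dt`` seconds on [0, duration)."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        t = np.arange(0.0, self.duration, dt)
        # gamma pdf mode = (shape - 1) * scale, so shape = delay/disp + 1
        # places the response peak exactly at peak_delay seconds
        peak = gamma_dist.pdf(
            t, self.peak_delay / self.peak_dispersion + 1, scale=self.peak_dispersion
        )
        under = gamma_dist.pdf(
            t,
            self.undershoot_delay / self.undershoot_dispersion + 1,
            scale=self.undershoot_dispersion,
        )
        h = peak - under / self.ratio
        return h / np.max(np.abs(h))


@dataclass(frozen=True)
class NoiseModel:
    """AR(1)-filtered white noise plus a slow sinusoidal drift.

    ``white_sd`` is the innovation standard deviation; drift defaults give
    the 0.01 Hz high-pass filter something real to remove.
    """

    white_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 1.0
    drift_period: float = 128.0

    def validate(self) -> None:
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.white_sd < 0:
            raise ValueError("white_sd must be non-negative")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be positive")


def _unit_pattern(rng: np.random.Generator, n_voxels: int) -> np.ndarray:
    """Zero-mean, unit-SD voxel weight vector."""
    v = rng.standard_normal(n_voxels)
    v -= v.mean()
    sd = v.std()
    return v / sd if sd > 0 else v


@dataclass
class PatternModel:
    """Ground-truth voxel response model for one ROI.

    ``pattern_weights`` carries the multivoxel (zero-mean across voxels)
    signal per condition; ``univariate`` a spatially uniform amplitude.
    """

    n_voxels: int
    baseline: float | np.ndarray = 0.0
    univariate: dict[str, float] = field(default_factory=dict)
    pattern_weights: dict[str, np.ndarray] = field(default_factory=dict)
    informative: bool = False

    def __post_init__(self) -> None:
        for cond, w in self.pattern_weights.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (self.n_voxels,):
                raise ValueError(f"pattern for {cond} has shape {w.shape}")
            self.pattern_weights[cond] = w

    def amplitude_matrix(self, conditions: tuple[str, ...]) -> np.ndarray:
        """Condition x voxel amplitude matrix (univariate + pattern)."""
        out = np.zeros((len(conditions), self.n_voxels))
        for i, cond in enumerate(conditions):
            out[i] += self.univariate.get(cond, 0.0)
            if cond in self.pattern_weights:
                out[i] += self.pattern_weights[cond]
        return out

    @classmethod
    def from_factor_effects(
        cls,
        n_voxels: int,
        effects: Mapping[str, float],
        rng: np.random.Generator,
        conditions: tuple[str, ...] = CONDITIONS,
        baseline: float = 0.0,
        univariate: Mapping[str, float] | None = None,
    ) -> "PatternModel":
        """Build condition patterns from per-factor multivoxel effect sizes.

        Each factor level receives one random unit pattern; a condition's
        weight vector is the sum of its levels' patterns scaled by the
        factor's effect size (per-voxel signal SD in BOLD units).
        """
        level_patterns: dict[tuple[str, str], np.ndarray] = {}
        weights: dict[str, np.ndarray] = {c: np.zeros(n_voxels) for c in conditions}
        for factor, beta in effects.items():
            if factor not in FACTOR_LEVELS:
                raise ValueError(f"unknown factor {factor!r}")
            levels = FACTOR_LEVELS[factor]
            for level in sorted({v for v in levels.values() if v is not None}):
                level_patterns[(factor, level)] = _unit_pattern(rng, n_voxels)
            for cond in conditions:
                level = levels.get(cond)
                if level is not None and beta != 0:
                    weights[cond] = weights[cond] + beta * level_patterns[(factor, level)]
        informative = any(b != 0 for b in effects.values())
        return cls(
            n_voxels=n_voxels,
            baseline=baseline,
            univariate=dict(univariate or {}),
            pattern_weights=weights,
            informative=informative,
        )


@dataclass
class GroupPatternTemplate:
    """Group-level pattern around which subject-specific patterns scatter."""

    template: PatternModel
    effects: dict[str, float]

    @classmethod
    def draw(
        cls,
        n_voxels: int,
        effects: Mapping[str, float],
        rng: np.random.Generator,
        baseline: float = 0.0,
        univariate: Mapping[str, float] | None = None,
    ) -> "GroupPatternTemplate":
        return cls(
            template=PatternModel.from_factor_effects(
                n_voxels, effects, rng, baseline=baseline, univariate=univariate
            ),
            effects=dict(effects),
        )

    def subject_model(
        self, rng: np.random.Generator, subject_sd: float = 0.3
    ) -> PatternModel:
        """Subject pattern = (template + subject_sd * fresh pattern) / norm.

        The 1/sqrt(1 + sd^2) renormalization keeps the per-voxel signal SD at
        the template's effect size regardless of between-subject scatter.
        """
        t = self.template
        scale = 1.0 / np.sqrt(1.0 + subject_sd**2)
        weights = {}
        for cond, w in t.pattern_weights.items():
            amp = np.linalg.norm(w) / np.sqrt(t.n_voxels)  # per-voxel SD of w
            if amp == 0 or subject_sd == 0:
                weights[cond] = w.copy()
            else:
                jitter = amp * subject_sd * _unit_pattern(rng, t.n_voxels)
                weights[cond] = (w + jitter) * scale
        return PatternModel(
            n_voxels=t.n_voxels,
            baseline=t.baseline,
            univariate=dict(t.univariate),
            pattern_weights=weights,
            informative=t.informative,
        )


def condition_regressors(
    events: EventTable,
    run: int,
    hrf: HrfModel,
    dt: float = 0.1,
) -> np.ndarray:
    """Volume x condition matrix of HRF-convolved condition boxcars.

    Boxcars (duration ``spec.trial_duration``) are built on a microtime grid
    of step ``dt``, convolved with the sampled HRF (scaled by ``dt`` so the
    result is dt-independent), and read out at volume acquisition times.
    """
    spec = events.spec
    n_vol = spec.volumes_per_run
    n_micro = int(round(spec.run_duration / dt))
    h = hrf.sample(dt)
    ev = events.run_events(run)
    out = np.zeros((n_vol, len(spec.conditions)))
    vol_idx = np.round(np.arange(n_vol) * spec.tr / dt).astype(int)
    for ci, cond in enumerate(spec.conditions):
        onsets = ev.loc[ev["condition"] == cond, "onset"].to_numpy()
        if len(onsets) == 0:
            continue
        neural = np.zeros(n_micro)
        for onset in onsets:
            a = int(round(onset / dt))
            b = min(int(round((onset + spec.trial_duration) / dt)), n_micro)
            neural[a:b] += 1.0
        conv = np.convolve(neural, h)[:n_micro] * dt
        out[:, ci] = conv[vol_idx]
    return out


def _as_seedsequence(rng) -> np.random.SeedSequence:
    if isinstance(rng, np.random.SeedSequence):
        return rng
    if isinstance(rng, np.random.Generator):
        # derive a child stream deterministically from the generator state
        return np.random.SeedSequence(int(rng.integers(2**31)))
    return np.random.SeedSequence(rng)


def simulate_subject(
    design: EventTable,
    patterns: Mapping[str, PatternModel] | PatternModel,
    hrf: HrfModel | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | np.random.SeedSequence | int | None = None,
    subject: str = "",
    dt: float = 0.1,
) -> dict[str, RoiTimeSeries]:
    """Simulate per-ROI voxel time series for one subject.

    Noise streams are spawned hierarchically per (ROI, run), so the series
    of one ROI/run does not depend on how many others are simulated after
    it.  Ground-truth pattern models are attached to each returned series.
    """
    hrf = hrf or HrfModel()
    noise = noise or NoiseModel()
    noise.validate()
    if isinstance(patterns, PatternModel):
        patterns = {"roi": patterns}
    spec = design.spec
    ss = _as_seedsequence(rng)
    roi_seeds = ss.spawn(len(patterns))

    regs = {
        run: condition_regressors(design, run, hrf, dt=dt)
        for run in range(1, spec.n_runs + 1)
    }
    t_vol = np.arange(spec.volumes_per_run) * spec.tr

    out: dict[str, RoiTimeSeries] = {}
    for (name, model), roi_ss in zip(patterns.items(), roi_seeds):
        amp = model.amplitude_matrix(spec.conditions)  # condition x voxel
        run_seeds = roi_ss.spawn(spec.n_runs)
        blocks = []
        labels = []
        for run, run_ss in zip(range(1, spec.n_runs + 1), run_seeds):
            g = np.random.default_rng(run_ss)
            sig = regs[run] @ amp  # volumes x voxels
            x = sig + np.asarray(model.baseline)
            if noise.white_sd > 0:
                e = g.normal(0.0, noise.white_sd, size=sig.shape)
                if noise.ar1_coef > 0:
                    e = lfilter([1.0], [1.0, -noise.ar1_coef], e, axis=0)
                x = x + e
            if noise.drift_amplitude != 0:
                phase = g.uniform(0.0, noise.drift_period, size=model.n_voxels)
                x = x + noise.drift_amplitude * np.sin(
                    2 * np.pi * (t_vol[:, None] + phase[None, :]) / noise.drift_period
                )
            blocks.append(x)
            labels.append(np.full(spec.volumes_per_run, run))
        out[name] = RoiTimeSeries(
            data=np.vstack(blocks),
            run_labels=np.concatenate(labels),
            tr=spec.tr,
            roi=name,
            subject=subject,
            ground_truth=model,
        )
    return out
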