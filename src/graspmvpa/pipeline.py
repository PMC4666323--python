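"""Config-driven experiment driver.

Simulates a group of subjects (or consumes saved simulations), runs the
preprocess -> sample -> decode chain for every configured classification,
and computes the group statistics: per-ROI t-tests against chance with FDR,
the ROI x hemisphere RM-ANOVA with post-hocs, and the classification
comparison with its linear contrast.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bold import GroupPatternTemplate, HrfModel, NoiseModel, simulate_subject
from .decoding import decode_all
from .design import DesignSpec, EventTable, generate_design
from .group_stats import (
    group_table,
    rm_anova_classification_contrast,
    rm_anova_roi_hemisphere,
)
from .preprocess import preprocess_chain
from .sampling import (
    DEFAULT_CLASSIFICATIONS,
    ClassificationSpec,
    assign_volumes_to_miniblocks,
    build_samples,
)
from .timeseries import RoiTimeSeries

logger = logging.getLogger(__name__)

CONTROL_ROI = "Control"

#: the seven frontoparietal ROIs of the study network
NETWORK_ROIS = ("SPOC", "SPLap", "hAIP", "BA1/2/3ab", "BA4p", "BA6", "BA44/45")


@dataclass
class RoiSimConfig:
    """Simulation settings for one named ROI.

    ``effects`` maps factor names (grasp_type, action_type, object_size,
    condition) to per-hemisphere multivoxel effect sizes; a plain float
    applies to both hemispheres.
    """

    name: str
    hemispheres: tuple[str, ...] = ("L", "R")
    n_voxels: int = 100
    effects: dict[str, float | dict[str, float]] = field(default_factory=dict)
    univariate: dict[str, float] = field(default_factory=dict)
    baseline: float = 0.0

    def effects_for(self, hemisphere: str) -> dict[str, float]:
        out = {}
        for factor, beta in self.effects.items():
            if isinstance(beta, Mapping):
                out[factor] = float(beta.get(hemisphere, 0.0))
            else:
                out[factor] = float(beta)
        return out


@dataclass
class StatsConfig:
    q: float = 0.05
    include_control_in_family: bool = True
    contrast_weights: tuple[float, ...] = (-1.0, 0.0, 1.0)
    contrast_classifications: tuple[str, ...] = (
        "grasp_type",
        "pg_vs_reach",
        "whg_vs_reach",
    )
    gg_correction: bool = False


@dataclass
class ExperimentConfig:
    design: DesignSpec = field(default_factory=DesignSpec)
    rois: list[RoiSimConfig] = field(default_factory=list)
    noise: NoiseModel = field(default_factory=NoiseModel)
    hrf: HrfModel = field(default_factory=HrfModel)
    n_subjects: int = 16
    classifications: tuple[ClassificationSpec, ...] = DEFAULT_CLASSIFICATIONS
    stats: StatsConfig = field(default_factory=StatsConfig)
    subject_pattern_sd: float = 0.3
    discard_volumes: int = 4
    lag_volumes: int = 0
    highpass_hz: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        self.design.validate()
        self.noise.validate()
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not self.classifications:
            raise ValueError("at least one classification required")
        if not self.rois:
            raise ValueError("at least one ROI required")

    # -- YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "design": dataclasses.asdict(self.design),
            "rois": [dataclasses.asdict(r) for r in self.rois],
            "noise": dataclasses.asdict(self.noise),
            "hrf": dataclasses.asdict(self.hrf),
            "n_subjects": self.n_subjects,
            "classifications": [
                {
                    "name": c.name,
                    "positive": sorted(c.positive),
                    "negative": sorted(c.negative),
                }
                for c in self.classifications
            ],
            "stats": dataclasses.asdict(self.stats),
            "subject_pattern_sd": self.subject_pattern_sd,
            "discard_volumes": self.discard_volumes,
            "lag_volumes": self.lag_volumes,
            "highpass_hz": self.highpass_hz,
            "seed": self.seed,
        }
        return json.loads(json.dumps(d))  # plain lists/dicts only

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        design_d = dict(d.get("design", {}))
        for key in ("conditions", "isi_range"):
            if key in design_d and isinstance(design_d[key], list):
                design_d[key] = tuple(design_d[key])
        cfg = cls(
            design=DesignSpec(**design_d),
            rois=[
                RoiSimConfig(
                    **{**r, "hemispheres": tuple(r.get("hemispheres", ("L", "R")))}
                )
                for r in d.get("rois", [])
            ],
            noise=NoiseModel(**d.get("noise", {})),
            hrf=HrfModel(**d.get("hrf", {})),
            n_subjects=int(d.get("n_subjects", 16)),
            classifications=tuple(
                ClassificationSpec(
                    c["name"], frozenset(c["positive"]), frozenset(c["negative"])
                )
                for c in d.get("classifications", [])
            )
            or DEFAULT_CLASSIFICATIONS,
            stats=StatsConfig(
                **{
                    **d.get("stats", {}),
                    "contrast_weights": tuple(
                        d.get("stats", {}).get("contrast_weights", (-1.0, 0.0, 1.0))
                    ),
                    "contrast_classifications": tuple(
                        d.get("stats", {}).get(
                            "contrast_classifications",
                            ("grasp_type", "pg_vs_reach", "whg_vs_reach"),
                        )
                    ),
                }
            ),
            subject_pattern_sd=float(d.get("subject_pattern_sd", 0.3)),
            discard_volumes=int(d.get("discard_volumes", 4)),
            lag_volumes=int(d.get("lag_volumes", 0)),
            highpass_hz=float(d.get("highpass_hz", 0.01)),
            seed=int(d.get("seed", 0)),
        )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def preset_config(
    scenario: str = "planted",
    n_voxels: int = 100,
    n_subjects: int = 16,
    seed: int = 0,
) -> ExperimentConfig:
    """Built-in synthetic scenarios.

    ``"null"``: the full ROI battery with no condition-specific signal
    anywhere — calibration runs.  ``"planted"``: a qualitative analogue of
    the study's findings on purely synthetic data — grasp-type patterns in
    the network except SPOC and right hAIP, action-type (grasp vs reach)
    patterns in every network ROI, left hemisphere stronger, and a
    signal-free out-of-brain control ROI.
    """
    rois: list[RoiSimConfig] = []
    if scenario == "null":
        for name in NETWORK_ROIS:
            rois.append(RoiSimConfig(name=name, n_voxels=n_voxels))
    elif scenario == "planted":
        grasp_beta = {"L": 0.11, "R": 0.09}
        action_beta = {"L": 0.27, "R": 0.22}
        for name in NETWORK_ROIS:
            effects: dict[str, float | dict[str, float]] = {
                "action_type": dict(action_beta)
            }
            if name == "SPOC":
                pass  # no grasp-type signal bilaterally
            elif name == "hAIP":
                effects["grasp_type"] = {"L": grasp_beta["L"], "R": 0.0}
            else:
                effects["grasp_type"] = dict(grasp_beta)
            rois.append(RoiSimConfig(name=name, n_voxels=n_voxels, effects=effects))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    rois.append(
        RoiSimConfig(name=CONTROL_ROI, hemispheres=("none",), n_voxels=n_voxels)
    )
    return ExperimentConfig(rois=rois, n_subjects=n_subjects, seed=seed)


@dataclass
class ExperimentReport:
    """All tables produced by one experiment run, plus provenance."""

    decoding: pd.DataFrame
    group_tables: dict[str, pd.DataFrame]
    anova_tables: dict[str, object]
    contrast_tables: dict[str, object]
    gaps: list[dict]
    provenance: dict

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.decoding.to_csv(outdir / "decoding.tsv", sep="\t", index=False)
        for name, table in self.group_tables.items():
            safe = name.replace("/", "-")
            table.to_csv(outdir / f"group_{safe}.tsv", sep="\t", index=False)
        anova_rows = []
        for name, res in self.anova_tables.items():
            eff = res.effects.copy()
            eff.insert(0, "classification", name)
            anova_rows.append(eff)
            if res.posthoc is not None:
                ph = res.posthoc.copy()
                ph.insert(0, "classification", name)
                ph["corrected_alpha"] = res.corrected_alpha
                ph.to_csv(
                    outdir / f"posthoc_{name.replace('/', '-')}.tsv",
                    sep="\t",
                    index=False,
                )
        if anova_rows:
            pd.concat(anova_rows).to_csv(outdir / "anova.tsv", sep="\t", index=False)
        contrast_rows = []
        for roi, res in self.contrast_tables.items():
            eff = res.effects.copy()
            eff.insert(0, "roi", roi)
            contrast_rows.append(eff)
        if contrast_rows:
            pd.concat(contrast_rows).to_csv(
                outdir / "classification_comparison.tsv", sep="\t", index=False
            )
        (outdir / "provenance.json").write_text(
            json.dumps(self.provenance, indent=1, sort_keys=True)
        )
        if self.gaps:
            pd.DataFrame(self.gaps).to_csv(outdir / "gaps.tsv", sep="\t", index=False)


def simulate_group(
    config: ExperimentConfig,
) -> dict[tuple[str, str, str], RoiTimeSeries]:
    """Simulate raw per-ROI series for every subject of the configured group.

    Seeding is hierarchical: the master seed spawns one stream per subject
    (design + patterns + acquisition noise), so adding subjects or ROIs at
    the end does not perturb earlier ones.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    template_ss, subjects_ss = master.spawn(2)
    template_rng = np.random.default_rng(template_ss)
    templates: dict[tuple[str, str], GroupPatternTemplate] = {}
    for roi in config.rois:
        for hemi in roi.hemispheres:
            templates[(roi.name, hemi)] = GroupPatternTemplate.draw(
                roi.n_voxels,
                roi.effects_for(hemi),
                template_rng,
                baseline=roi.baseline,
                univariate=roi.univariate,
            )
    out: dict[tuple[str, str, str], RoiTimeSeries] = {}
    for subj_ss in zip(range(config.n_subjects), subjects_ss.spawn(config.n_subjects)):
        i, ss = subj_ss
        subject = f"sub-{i + 1:02d}"
        design_ss, pattern_ss, noise_ss = ss.spawn(3)
        design = generate_design(config.design, np.random.default_rng(design_ss))
        pattern_rng = np.random.default_rng(pattern_ss)
        patterns = {
            key: templates[key].subject_model(pattern_rng, config.subject_pattern_sd)
            for key in templates
        }
        sims = simulate_subject(
            design,
            {f"{name}|{hemi}": m for (name, hemi), m in patterns.items()},
            hrf=config.hrf,
            noise=config.noise,
            rng=noise_ss,
            subject=subject,
        )
        mapping = assign_volumes_to_miniblocks(design, lag_volumes=config.lag_volumes)
        for key, ts in sims.items():
            name, hemi = key.split("|")
            ts.roi = name
            ts.hemisphere = hemi
            ts._design = design  # noqa: SLF001 - carried for sampling
            ts._mapping = mapping
            out[(subject, name, hemi)] = ts
    return out


def run_experiment(
    config: ExperimentConfig, outdir: str | Path | None = None
) -> ExperimentReport:
    """Execute the full chain and return (and optionally write) the report."""
    config.validate()
    raw = simulate_group(config)
    samplesets = {}
    for key, ts in raw.items():
        clean = preprocess_chain(ts, cutoff_hz=config.highpass_hz)
        samplesets[key] = build_samples(
            clean, ts._mapping, ts._design, discard_volumes=config.discard_volumes
        )
    decoding, gaps = decode_all(samplesets, config.classifications)

    exclude = () if config.stats.include_control_in_family else (CONTROL_ROI,)
    group_tables = {}
    for cspec in config.classifications:
        try:
            group_tables[cspec.name] = group_table(
                decoding, cspec.name, q=config.stats.q, exclude_rois=exclude
            )
        except ValueError as exc:
            logger.warning("no group table for %s: %s", cspec.name, exc)

    anova_tables = {}
    bilateral = decoding[decoding["hemisphere"].isin(["L", "R"])]
    n_bilateral_rois = bilateral["roi"].nunique()
    if n_bilateral_rois >= 2:
        for cspec in config.classifications:
            try:
                anova_tables[cspec.name] = rm_anova_roi_hemisphere(
                    decoding, cspec.name, q=config.stats.q
                )
            except ValueError as exc:
                logger.warning("no ANOVA for %s: %s", cspec.name, exc)

    contrast_tables = {}
    names = list(config.stats.contrast_classifications)
    have = set(decoding["classification"].unique())
    if set(names) <= have and len(names) == len(config.stats.contrast_weights):
        # accuracies per subject x classification, collapsed over hemispheres
        for roi in sorted(decoding["roi"].unique()):
            sub = decoding[
                (decoding["roi"] == roi) & decoding["classification"].isin(names)
            ]
            pivot = sub.pivot_table(
                index="subject", columns="classification", values="accuracy"
            )
            if pivot.isna().any().any() or set(pivot.columns) != set(names):
                continue
            contrast_tables[roi] = rm_anova_classification_contrast(
                pivot[names].to_numpy(), names, weights=config.stats.contrast_weights
            )

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "n_subjects": config.n_subjects,
    }
    report = ExperimentReport(
        decoding=decoding,
        group_tables=group_tables,
        anova_tables=anova_tables,
        contrast_tables=contrast_tables,
        gaps=gaps,
        provenance=provenance,
    )
    if outdir is not None:
        report.save(outdir)
    return report


def render_tables(report: ExperimentReport) -> dict[str, str]:
    """Human-readable per-classification tables in the Left/Right layout.

    One row per ROI: "mean ± SEM, t(df) = ..., p = ..." per hemisphere cell;
    degenerate (zero-variance) tests are marked as such.
    """
    out = {}
    for name, table in report.group_tables.items():
        lines = [f"{name} classification", "ROI\tLeft hemisphere\tRight hemisphere"]
        for roi in sorted(table["roi"].unique()):
            cells = []
            for hemi in ("L", "R", "none"):
                row = table[(table["roi"] == roi) & (table["hemisphere"] == hemi)]
                if row.empty:
                    continue
                r = row.iloc[0]
                if r["degenerate"]:
                    cells.append(
                        f"{r['mean_accuracy']:.3f} ± {r['sem']:.3f} (degenerate t)"
                    )
                else:
                    star = " *" if r["fdr_rejected"] else ""
                    cells.append(
                        f"{r['mean_accuracy']:.3f} ± {r['sem']:.3f}, "
                        f"t({int(r['df'])}) = {r['t']:.2f}, "
                        f"p = {r['p_one_tailed']:.4f}{star}"
                    )
            lines.append("\t".join([roi, *cells]))
        alpha = table.attrs.get("corrected_alpha")
        lines.append(
            "FDR corrected, corrected alpha = "
            + (f"{alpha:.4g}" if alpha is not None else "none (no rejections)")
        )
        out[name] = "\n".join(lines)
    return out
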