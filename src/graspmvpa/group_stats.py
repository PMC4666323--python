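"""Group-level inference on decoding accuracies.

One-tailed one-sample t-tests against the 50% chance level with
Benjamini-Hochberg FDR control, two-way repeated-measures ANOVA
(ROI x hemisphere) with partial eta squared, FDR-corrected paired
post-hocs, and a one-way RM-ANOVA with a linear trend contrast across
classifications.  Sphericity is assumed (no df correction) unless
Greenhouse-Geisser is requested.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CHANCE = 0.5


@dataclass(frozen=True)
class GroupTestResult:
    """One-sample t of per-subject accuracies against chance."""

    roi: str
    hemisphere: str
    classification: str
    mean_accuracy: float
    sem: float
    t: float
    df: int
    p_one_tailed: float
    degenerate: bool = False
    fdr_rejected: bool | None = None
    q: float | None = None


def ttest_vs_chance(
    accuracies: np.ndarray,
    chance: float = CHANCE,
    roi: str = "",
    hemisphere: str = "",
    classification: str = "",
) -> GroupTestResult:
    """t = (mean - chance) / (sd / sqrt(n)), one-tailed for mean > chance.

    Zero-variance input yields a flagged degenerate result with an infinite
    (or zero, if exactly at chance) t rather than silent NaNs.
    """
    x = np.asarray(accuracies, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of at least 2 accuracies")
    if not np.all(np.isfinite(x)):
        raise ValueError("accuracies must be finite")
    n = len(x)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        delta = mean - chance
        t = 0.0 if delta == 0 else float(np.inf) * np.sign(delta)
        p = 0.5 if delta == 0 else (0.0 if delta > 0 else 1.0)
        return GroupTestResult(roi, hemisphere, classification, mean, 0.0,
                               t, df, p, degenerate=True)
    sem = sd / np.sqrt(n)
    t = (mean - chance) / sem
    p = float(stats.t.sf(t, df))
    return GroupTestResult(roi, hemisphere, classification, mean, sem, t, df, p)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float | None]:
    """Benjamini-Hochberg step-up rejections and the realized corrected alpha.

    The corrected alpha is the largest raw p rejected (the reporting idiom
    "FDR corrected, corrected alpha = ..."); ``None`` when nothing is
    rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), None
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    corrected_alpha = float(p[reject].max()) if reject.any() else None
    return reject, corrected_alpha


def group_table(
    decoding: pd.DataFrame,
    classification: str,
    q: float = 0.05,
    chance: float = CHANCE,
    exclude_rois: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-(ROI, hemisphere) group t-tests for one classification, with FDR.

    The FDR family is every (ROI, hemisphere) cell in the table after
    dropping ``exclude_rois`` — by default the control ROI is part of the
    family.
    """
    sub = decoding[decoding["classification"] == classification]
    sub = sub[~sub["roi"].isin(exclude_rois)]
    if sub.empty:
        raise ValueError(f"no decoding rows for classification {classification!r}")
    rows = []
    for (roi, hemi), grp in sub.groupby(["roi", "hemisphere"], sort=True):
        res = ttest_vs_chance(
            grp.sort_values("subject")["accuracy"].to_numpy(),
            chance=chance, roi=roi, hemisphere=hemi, classification=classification,
        )
        rows.append(
            {
                "roi": roi,
                "hemisphere": hemi,
                "classification": classification,
                "n": len(grp),
                "mean_accuracy": res.mean_accuracy,
                "sem": res.sem,
                "t": res.t,
                "df": res.df,
                "p_one_tailed": res.p_one_tailed,
                "degenerate": res.degenerate,
            }
        )
    table = pd.DataFrame(rows)
    reject, corrected_alpha = fdr_bh(table["p_one_tailed"].to_numpy(), q=q)
    table["fdr_rejected"] = reject
    table["q"] = q
    table.attrs["corrected_alpha"] = corrected_alpha
    return table


@dataclass
class AnovaResult:
    """Effect table (F, dfs, p, partial eta squared) plus optional post-hocs."""

    effects: pd.DataFrame
    posthoc: pd.DataFrame | None = None
    corrected_alpha: float | None = None

    def effect(self, name: str) -> pd.Series:
        row = self.effects[self.effects["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def _effect_row(name: str, ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> dict:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err == 0.0:
        f = 0.0 if ss_eff == 0.0 else float(np.inf)
    else:
        f = ms_eff / ms_err
    p = float(stats.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
    denom = ss_eff + ss_err
    eta = ss_eff / denom if denom > 0 else 0.0
    return {
        "effect": name, "F": f, "df_num": df_eff, "df_den": df_err,
        "p": p, "partial_eta_sq": eta,
        "ss_effect": ss_eff, "ss_error": ss_err,
    }


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the subspace orthogonal to the mean."""
    q, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]]))
    return q[:, 1:]


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from per-subject orthonormal contrast scores."""
    k = scores.shape[1]
    if k < 2:
        return 1.0
    sigma = np.cov(scores, rowvar=False)
    sigma = np.atleast_2d(sigma)
    tr = np.trace(sigma)
    denom = k * np.sum(sigma**2)
    if denom == 0:
        return 1.0
    return float(np.clip(tr**2 / denom, 1.0 / k, 1.0))


def _apply_gg(row: dict, eps: float) -> dict:
    row = dict(row)
    df1 = row["df_num"] * eps
    df2 = row["df_den"] * eps
    row.update(
        df_num=df1, df_den=df2, gg_epsilon=eps,
        p=float(stats.f.sf(row["F"], df1, df2)) if np.isfinite(row["F"]) else 0.0,
    )
    return row


def rm_anova_two_way(
    data: np.ndarray,
    factor_a: str = "roi",
    factor_b: str = "hemisphere",
    gg_correction: bool = False,
) -> AnovaResult:
    """Two-way fully within-subject ANOVA on a (subject, A, B) array.

    Sphericity assumed by default: each effect is tested against its own
    subject-by-effect interaction, df = (levels - 1, (levels - 1)(n - 1));
    partial eta squared = SS_effect / (SS_effect + SS_error).  With
    ``gg_correction`` the dfs and p-values are Greenhouse-Geisser adjusted.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("data must be (subjects, A levels, B levels)")
    if not np.all(np.isfinite(y)):
        raise ValueError("missing cells are not supported")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_sab = np.sum(resid**2)

    rows = [
        _effect_row(factor_a, ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        _effect_row(factor_b, ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        _effect_row(
            f"{factor_a} x {factor_b}", ss_ab, (a - 1) * (b - 1),
            ss_sab, (a - 1) * (b - 1) * (n - 1),
        ),
    ]
    if gg_correction:
        c_a = _orthonormal_contrasts(a)
        c_b = _orthonormal_contrasts(b)
        rows[0] = _apply_gg(rows[0], _gg_epsilon(m_sa @ c_a))
        rows[1] = _apply_gg(rows[1], _gg_epsilon(m_sb @ c_b))
        flat = y.reshape(n, a * b)
        rows[2] = _apply_gg(rows[2], _gg_epsilon(flat @ np.kron(c_a, c_b)))
    return AnovaResult(effects=pd.DataFrame(rows))


def paired_ttests_fdr(
    data: np.ndarray,
    levels: list[str],
    q: float = 0.05,
) -> tuple[pd.DataFrame, float | None]:
    """All pairwise paired t-tests on a (subject, level) array, BH-corrected.

    Two-tailed p-values; the realized corrected alpha (largest rejected raw
    p) is returned alongside the pair table.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2 or y.shape[1] != len(levels):
        raise ValueError("data must be (subjects, levels) matching the labels")
    rows = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        diff = y[:, i] - y[:, j]
        sd = diff.std(ddof=1)
        n = len(diff)
        if sd == 0.0:
            t = 0.0 if diff.mean() == 0 else float(np.inf) * np.sign(diff.mean())
            p = 1.0 if diff.mean() == 0 else 0.0
        else:
            t = diff.mean() / (sd / np.sqrt(n))
            p = float(2 * stats.t.sf(abs(t), n - 1))
        rows.append(
            {
                "level_a": levels[i], "level_b": levels[j],
                "mean_diff": float(diff.mean()), "t": float(t),
                "df": n - 1, "p": p,
            }
        )
    table = pd.DataFrame(rows)
    reject, corrected_alpha = fdr_bh(table["p"].to_numpy(), q=q)
    table["fdr_rejected"] = reject
    return table, corrected_alpha


def rm_anova_roi_hemisphere(
    decoding: pd.DataFrame,
    classification: str,
    rois: list[str] | None = None,
    q: float = 0.05,
) -> AnovaResult:
    """ROI x hemisphere RM-ANOVA on a decoding table, with ROI post-hocs.

    ROIs are crossed with hemispheres L/R within subjects; post-hoc paired
    t-tests compare ROI means collapsed over hemisphere, BH-FDR corrected.
    """
    sub = decoding[
        (decoding["classification"] == classification)
        & decoding["hemisphere"].isin(["L", "R"])
    ]
    if rois is not None:
        sub = sub[sub["roi"].isin(rois)]
    cube = sub.pivot_table(
        index="subject", columns=["roi", "hemisphere"], values="accuracy"
    )
    if cube.isna().any().any():
        raise ValueError("incomplete subject x ROI x hemisphere design")
    roi_levels = sorted(sub["roi"].unique())
    n = len(cube)
    y = np.empty((n, len(roi_levels), 2))
    for i, roi in enumerate(roi_levels):
        for j, hemi in enumerate(["L", "R"]):
            y[:, i, j] = cube[(roi, hemi)].to_numpy()
    result = rm_anova_two_way(y, factor_a="roi", factor_b="hemisphere")
    posthoc, corrected_alpha = paired_ttests_fdr(y.mean(axis=2), roi_levels, q=q)
    result.posthoc = posthoc
    result.corrected_alpha = corrected_alpha
    return result


def rm_anova_classification_contrast(
    data: np.ndarray,
    levels: list[str],
    weights: tuple[float, ...] = (-1.0, 0.0, 1.0),
) -> AnovaResult:
    """One-way RM-ANOVA across classifications plus a linear trend contrast.

    The contrast score per subject is sum(w_k * y_k); its one-sample F
    (= t squared) against zero tests the linear trend, df = (1, n - 1).
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError("data must be (subjects, levels)")
    n, k = y.shape
    if k != len(levels) or k != len(weights):
        raise ValueError("levels/weights must match the number of columns")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = y.mean()
    m_s = y.mean(axis=1)
    m_k = y.mean(axis=0)
    ss_k = n * np.sum((m_k - grand) ** 2)
    resid = y - m_s[:, None] - m_k[None, :] + grand
    ss_err = np.sum(resid**2)
    effects = [_effect_row("classification", ss_k, k - 1, ss_err, (k - 1) * (n - 1))]

    w = np.asarray(weights, dtype=float)
    scores = y @ w
    ss_c = n * scores.mean() ** 2 / np.sum(w**2)
    ss_c_err = np.sum((scores - scores.mean()) ** 2) / np.sum(w**2)
    effects.append(_effect_row("linear_contrast", ss_c, 1, ss_c_err, n - 1))
    result = AnovaResult(effects=pd.DataFrame(effects))
    result.effects.attrs["contrast_mean"] = float(scores.mean())
    return result
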