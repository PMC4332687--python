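"""Statistical battery for group-level contrast-ratio analysis.

The parametric path mirrors the study design this package supports:
a Shapiro-Wilk gate on each group (warn when p <= 0.05; the analysis does
not switch to nonparametric tests), one-sample t-tests of each group's
contrast ratios against the 0% reference, one-way ANOVA with Tukey HSD
post-hoc across duration groups, and a Pearson correlation of etching
duration against group mean contrast ratio with a small-sample t-based
p-value. All p-values are two-tailed; alpha = 0.05.

Pearson, the one-sample t and the ANOVA decomposition are computed from
their defining formulas; the Shapiro-Wilk W statistic and the studentized
range distribution behind Tukey's adjusted p-values come from scipy.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, SampleSizeError

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "pearson_with_p",
    "one_sample_test",
    "one_way_anova",
    "tukey_hsd",
    "shapiro_wilk",
    "statistical_report",
    "ALPHA",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with its t-based two-tailed p."""

    r: float
    k: int
    t_stat: float
    df: int
    p: float


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA F test plus Tukey HSD adjusted pairwise p-values."""

    F: float
    df_between: int
    df_within: int
    p_anova: float
    pairwise: List[Tuple[int, int, float]]


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with a two-tailed p from t = r*sqrt((k-2)/(1-r^2)), df = k-2.

    Requires k >= 3 paired observations, each series with nonzero variance.
    |r| = 1 returns p = 0 (t is infinite).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SampleSizeError("x and y must be 1-D sequences of equal length")
    k = x.size
    if k < 3:
        raise SampleSizeError(f"need k >= 3 paired observations, got {k}")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0 or syy == 0:
        raise DegenerateInputError("zero variance in x or y")
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    df = k - 2
    if abs(r) == 1.0:
        return CorrelationResult(r=r, k=k, t_stat=math.inf, df=df, p=0.0)
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, k=k, t_stat=t, df=df, p=p)


def one_sample_test(values: Sequence[float], reference: float) -> Tuple[float, int, float]:
    """Two-tailed one-sample t-test of the mean against a reference value.

    Returns ``(t, df, p)`` with df = n - 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise SampleSizeError(f"need >= 2 values, got {v.size}")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero standard deviation")
    df = v.size - 1
    t = float((v.mean() - reference) / (sd / math.sqrt(v.size)))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return t, df, p


def _check_groups(groups: Sequence[Sequence[float]]) -> List[np.ndarray]:
    if len(groups) < 2:
        raise SampleSizeError(f"need >= 2 groups, got {len(groups)}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise SampleSizeError(f"group {i} has {g.size} values; need >= 2")
    return arrays


def one_way_anova(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Classical one-way ANOVA: F = MSB/MSW with the between/within
    sum-of-squares decomposition; p from the F distribution.

    The returned comparison carries an empty pairwise list; use
    :func:`tukey_hsd` for post-hoc pairs.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    grand = sum(g.sum() for g in arrays) / n_total
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in arrays)
    df_b = k - 1
    df_w = n_total - k
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0:
        # all groups internally constant: F degenerates
        f = math.inf if msb > 0 else 0.0
        p = 0.0 if msb > 0 else 1.0
    else:
        f = msb / msw
        p = float(sps.f.sf(f, df_b, df_w))
    return GroupComparison(F=float(f), df_between=df_b, df_within=df_w, p_anova=p, pairwise=[])


def tukey_hsd(
    groups: Sequence[Sequence[float]], alpha: float = ALPHA
) -> List[Tuple[int, int, float]]:
    """Tukey (Tukey-Kramer for unequal n) HSD adjusted p for every unordered
    group pair, via the studentized range distribution.

    Returns ``[(i, j, p_adj), ...]`` for i < j, one entry per pair; ``alpha``
    is carried for reporting only — all pairs are returned regardless.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    df_w = n_total - k
    msw = sum(float(((g - g.mean()) ** 2).sum()) for g in arrays) / df_w
    out: List[Tuple[int, int, float]] = []
    for i, j in combinations(range(k), 2):
        gi, gj = arrays[i], arrays[j]
        if msw == 0:
            p = 1.0 if gi.mean() == gj.mean() else 0.0
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / gi.size + 1.0 / gj.size))
            q = abs(gi.mean() - gj.mean()) / se
            p = float(sps.studentized_range.sf(q, k, df_w))
        out.append((i, j, min(max(p, 0.0), 1.0)))
    return out


def shapiro_wilk(values: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk normality test, used as a gate: a warning is logged when
    p <= 0.05 but the parametric analysis proceeds regardless."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise SampleSizeError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {v.size}")
    res = sps.shapiro(v)
    if res.pvalue <= ALPHA:
        logger.warning(
            "Shapiro-Wilk p = %.4g <= %.2f: normality assumption questionable",
            res.pvalue,
            ALPHA,
        )
    return float(res.statistic), float(res.pvalue)


def statistical_report(
    group_durations: Sequence[float],
    group_values: Sequence[Sequence[float]],
    reference: float = 0.0,
) -> dict:
    """Full group-level battery as a JSON-serializable dict.

    ``group_values[i]`` holds the per-sample contrast ratios of the group
    with duration ``group_durations[i]``.
    """
    if len(group_durations) != len(group_values):
        raise SampleSizeError("one duration per group required")
    report: dict = {"alpha": ALPHA, "groups": []}
    for dur, vals in zip(group_durations, group_values):
        v = np.asarray(vals, dtype=float)
        entry: dict = {"duration_min": float(dur), "n": int(v.size),
                       "mean_cr": float(v.mean()), "sd_cr": float(v.std(ddof=1)) if v.size > 1 else None}
        if 3 <= v.size <= 5000:
            w, p_sw = shapiro_wilk(v)
            entry["shapiro_wilk"] = {"W": w, "p": p_sw, "normal_at_alpha": p_sw > ALPHA}
        if v.size >= 2 and v.std(ddof=1) > 0:
            t, df, p = one_sample_test(v, reference)
            entry["vs_reference"] = {"reference": reference, "t": t, "df": df, "p": p}
        report["groups"].append(entry)

    if len(group_values) >= 2 and all(len(g) >= 2 for g in group_values):
        anova = one_way_anova(group_values)
        pairs = tukey_hsd(group_values)
        report["anova"] = {
            "F": anova.F,
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "p": anova.p_anova,
        }
        report["tukey"] = [
            {
                "group_a_duration": float(group_durations[i]),
                "group_b_duration": float(group_durations[j]),
                "p_adj": p,
            }
            for i, j, p in pairs
        ]
    means = [float(np.mean(g)) for g in group_values]
    if len(means) >= 3:
        corr = pearson_with_p(list(group_durations), means)
        report["pearson_duration_vs_mean_cr"] = {
            "r": corr.r, "k": corr.k, "t": corr.t_stat, "df": corr.df, "p": corr.p,
        }
    return report


def format_report_text(report: dict) -> str:
    """Human-readable text table of :func:`statistical_report` output."""
    lines = [f"Group-level analysis (alpha = {report['alpha']})", ""]
    lines.append(f"{'duration':>9} {'n':>3} {'mean CR':>9} {'sd CR':>9} {'SW p':>8} {'p vs ref':>9}")
    for g in report["groups"]:
        sw = g.get("shapiro_wilk", {}).get("p")
        pref = g.get("vs_reference", {}).get("p")
        sd = "--" if g["sd_cr"] is None else format(g["sd_cr"], ".4f")
        sw_s = "--" if sw is None else format(sw, ".4f")
        pref_s = "--" if pref is None else format(pref, ".4g")
        lines.append(
            f"{g['duration_min']:>9.0f} {g['n']:>3d} {g['mean_cr']:>9.4f} "
            f"{sd:>9} {sw_s:>8} {pref_s:>9}"
        )
    if "anova" in report:
        a = report["anova"]
        lines += ["", f"ANOVA: F({a['df_between']}, {a['df_within']}) = {a['F']:.4f}, p = {a['p']:.4g}"]
    if "tukey" in report:
        lines.append("Tukey HSD adjusted p:")
        for t in report["tukey"]:
            lines.append(
                f"  {t['group_a_duration']:.0f} min vs {t['group_b_duration']:.0f} min: "
                f"p = {t['p_adj']:.4g}"
            )
    if "pearson_duration_vs_mean_cr" in report:
        c = report["pearson_duration_vs_mean_cr"]
        lines += ["", f"Pearson duration vs group mean CR: r = {c['r']:.4f}, p = {c['p']:.4f}"]
    return "\n".join(lines) + "\n"


def write_report(report: dict, json_path: Union[str, Path], text_path: Union[str, Path, None] = None) -> None:
    Path(json_path).write_text(json.dumps(report, indent=2) + "\n")
    if text_path is not None:
        Path(text_path).write_text(format_report_text(report))
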