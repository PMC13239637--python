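"""Rank-based nonparametric statistics for factorial repeated measures.

Implements the midrank ANOVA-type statistic (ATS) for designs with one
between-subjects factor and arbitrary crossed within-subjects factors, with
p-values from the F distribution using infinite denominator degrees of
freedom, plus relative treatment effects (RTE) with subject-bootstrap
confidence intervals and Tukey-Kramer-adjusted pairwise cell comparisons.

Construction (Brunner-style): all N*d observations are jointly midranked.
With q the vector of estimated relative effects per (group x within) cell and
V the rank covariance estimate, the ATS for a hypothesis projection matrix
M = C'(CC')+C is

    A = N * q' M q / tr(M V),   A ~ F(f, inf),
    f = tr(M V)^2 / tr(M V M V)

where F(f, inf) is evaluated as a scaled chi-square. Infinite denominator
degrees of freedom avoid the type-I-error inflation of the finite-df
approximation in small samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RTEResult",
    "ATSResult",
    "relative_treatment_effects",
    "ats",
    "posthoc_cellwise",
]


# ---------------------------------------------------------------------------
# Table handling
# ---------------------------------------------------------------------------

def _cell_layout(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str],
):
    """Wide layout: subjects x within-cells, plus group assignment.

    Raises on unbalanced within-subject cells or subjects in several groups.
    """
    for col in [dv, subject, between, *within]:
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    groups = sorted(table[between].astype(str).unique())
    within_levels = [sorted(table[w].astype(str).unique()) for w in within]
    cells = list(itertools.product(*within_levels))
    d = len(cells)

    g_of = table.groupby(subject)[between].nunique()
    if (g_of > 1).any():
        raise ValueError("a subject appears in more than one group")

    subj_group = table.groupby(subject)[between].first().astype(str)
    subjects_by_group = {g: sorted(subj_group[subj_group == g].index) for g in groups}

    pivot = table.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="mean",
    )
    # enforce complete cells
    if pivot.isna().any().any() or pivot.shape[1] != d:
        raise ValueError("unbalanced within-subject cells")
    col_order = cells if len(within) > 1 else [c[0] for c in cells]
    pivot = pivot[col_order]

    mats = {g: pivot.loc[subjects_by_group[g]].to_numpy(dtype=float) for g in groups}
    return groups, within_levels, cells, mats


def _joint_midranks(mats: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    groups = list(mats)
    stacked = np.concatenate([mats[g].ravel() for g in groups])
    ranks = stats.rankdata(stacked, method="average")
    out = {}
    pos = 0
    for g in groups:
        size = mats[g].size
        out[g] = ranks[pos : pos + size].reshape(mats[g].shape)
        pos += size
    return out


def _q_and_v(rank_mats: dict[str, np.ndarray]):
    """Relative-effect vector q (length a*d) and covariance estimate V."""
    groups = list(rank_mats)
    n_total = sum(m.shape[0] for m in rank_mats.values())
    d = next(iter(rank_mats.values())).shape[1]
    scale = n_total * d
    q_parts, v_blocks = [], []
    for g in groups:
        m = rank_mats[g]
        n_i = m.shape[0]
        q_parts.append((m.mean(axis=0) - 0.5) / scale)
        if n_i > 1:
            s = np.cov(m, rowvar=False, ddof=1) / scale**2
        else:
            s = np.zeros((d, d))
        v_blocks.append(n_total * np.atleast_2d(s) / n_i)
    q = np.concatenate(q_parts)
    v = np.zeros((len(groups) * d, len(groups) * d))
    for k, blk in enumerate(v_blocks):
        v[k * d : (k + 1) * d, k * d : (k + 1) * d] = blk
    return q, v, n_total


def _projection(c: np.ndarray) -> np.ndarray:
    return c.T @ np.linalg.pinv(c @ c.T) @ c


def _effect_contrasts(
    factors: list[tuple[str, int]], effect: tuple[str, ...]
) -> np.ndarray:
    """Kronecker contrast matrix: centering for effect factors, averaging
    for the rest. ``factors`` lists (name, n_levels) in cell order."""
    mat = np.ones((1, 1))
    for name, k in factors:
        if name in effect:
            block = np.eye(k) - np.ones((k, k)) / k
        else:
            block = np.ones((1, k)) / k
        mat = np.kron(mat, block)
    return mat


# ---------------------------------------------------------------------------
# Relative treatment effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RTEResult:
    table: pd.DataFrame   # one row per cell: factor levels, rte, ci_low, ci_high


def relative_treatment_effects(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant",
    between: str = "group",
    within: list[str] | None = None,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> RTEResult:
    """Per-cell relative treatment effect with bootstrap confidence interval.

    The RTE of a cell is the probability that a random observation from that
    cell exceeds a random observation from the pooled reference distribution
    (midrank convention for ties): ``(mean cell midrank - 0.5) / N_obs``. The
    cell-size-weighted mean over all cells is exactly 0.5. Confidence
    intervals come from a seeded subject-level bootstrap within groups.
    """
    within = within or ["stimulus", "block"]
    groups, within_levels, cells, mats = _cell_layout(table, dv, subject, between, within)

    def cell_rtes(ms: dict[str, np.ndarray]) -> np.ndarray:
        ranks = _joint_midranks(ms)
        n_obs = sum(m.size for m in ms.values())
        return np.concatenate(
            [(ranks[g].mean(axis=0) - 0.5) / n_obs for g in groups]
        )

    point = cell_rtes(mats)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, point.size))
    for bi in range(n_boot):
        res = {}
        for g in groups:
            m = mats[g]
            idx = rng.integers(0, m.shape[0], size=m.shape[0])
            res[g] = m[idx]
        boots[bi] = cell_rtes(res)
    alpha = 1.0 - ci_level
    lo = np.quantile(boots, alpha / 2, axis=0)
    hi = np.quantile(boots, 1 - alpha / 2, axis=0)

    rows = []
    k = 0
    for g in groups:
        for cell in cells:
            row = {between: g}
            row.update(dict(zip(within, cell)))
            row.update({"rte": point[k], "ci_low": lo[k], "ci_high": hi[k]})
            rows.append(row)
            k += 1
    return RTEResult(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ANOVA-type statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ATSResult:
    table: pd.DataFrame   # effect, statistic, df, p


def ats(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant",
    between: str = "group",
    within: list[str] | None = None,
) -> ATSResult:
    """Rank-based ANOVA-type tests for all main effects and interactions.

    p-values use the F(f, inf) reference, i.e. the chi-square(f)/f tail.
    Constant data yields statistic 0 and p = 1 for every effect.
    """
    within = within or ["stimulus", "block"]
    groups, within_levels, cells, mats = _cell_layout(table, dv, subject, between, within)
    rank_mats = _joint_midranks(mats)
    q, v, n_total = _q_and_v(rank_mats)

    factors = [(between, len(groups))] + [
        (w, len(lv)) for w, lv in zip(within, within_levels)
    ]
    names = [name for name, _ in factors]

    rows = []
    for r in range(1, len(names) + 1):
        for effect in itertools.combinations(names, r):
            c = _effect_contrasts(factors, effect)
            m = _projection(c)
            denom = float(np.trace(m @ v))
            if denom <= 1e-300:
                stat, f_df, p = 0.0, np.nan, 1.0
            else:
                stat = n_total * float(q @ m @ q) / denom
                mv = m @ v
                f_df = denom**2 / float(np.trace(mv @ mv))
                p = float(stats.chi2.sf(f_df * stat, f_df))
            rows.append({
                "effect": ":".join(effect),
                "statistic": stat,
                "df": f_df,
                "p": p,
            })
    return ATSResult(table=pd.DataFrame(rows))


def posthoc_cellwise(
    table: pd.DataFrame,
    effect: tuple[str, ...] | str,
    dv: str = "value",
    subject: str = "participant",
    between: str = "group",
    within: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise rank-based cell comparisons with Tukey-Kramer adjustment.

    Cells are the level combinations of the named effect factor(s), averaged
    over the remaining factors on the relative-effect scale. Each pair gets a
    standardized contrast statistic, an unadjusted normal p-value, and a
    family-wise p from the studentized range with infinite df.
    """
    if isinstance(effect, str):
        effect = tuple(effect.split(":"))
    within = within or ["stimulus", "block"]
    groups, within_levels, cells, mats = _cell_layout(table, dv, subject, between, within)
    rank_mats = _joint_midranks(mats)
    q, v, n_total = _q_and_v(rank_mats)

    factors = [(between, len(groups))] + [
        (w, len(lv)) for w, lv in zip(within, within_levels)
    ]
    names = [name for name, _ in factors]
    levels = {between: groups, **dict(zip(within, within_levels))}
    unknown = set(effect) - set(names)
    if unknown:
        raise ValueError(f"unknown effect factor(s): {sorted(unknown)}")

    # averaging matrix onto the effect's cells
    eff_cells = list(itertools.product(*(levels[f] for f in effect)))
    full_cells = list(itertools.product(*(levels[name] for name, _ in factors)))
    A = np.zeros((len(eff_cells), len(full_cells)))
    for ei, ec in enumerate(eff_cells):
        match = [
            fi for fi, fc in enumerate(full_cells)
            if all(fc[names.index(f)] == lvl for f, lvl in zip(effect, ec))
        ]
        A[ei, match] = 1.0 / len(match)

    k = len(eff_cells)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        c = A[i] - A[j]
        diff = float(c @ q)
        var = float(c @ v @ c) / n_total
        if var <= 1e-300:
            z, p_raw, p_adj = 0.0, 1.0, 1.0
        else:
            z = diff / np.sqrt(var)
            p_raw = 2.0 * stats.norm.sf(abs(z))
            p_adj = float(stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, np.inf))
        rows.append({
            "cell_a": ":".join(eff_cells[i]),
            "cell_b": ":".join(eff_cells[j]),
            "estimate": diff,
            "statistic": z,
            "p_unadjusted": min(1.0, p_raw),
            "p_adjusted": min(1.0, p_adj),
        })
    return pd.DataFrame(rows)
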