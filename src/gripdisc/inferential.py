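"""Within-subject inferential statistics.

Fully-within repeated-measures ANOVA on per-participant cell means, with
partial eta squared and Greenhouse-Geisser correction where a factor has
more than two levels, plus Bonferroni-corrected pairwise follow-ups, paired
t-tests and Shapiro-Wilk normality checks — the toolkit used to compare
mean grip apertures across size / judgement-correctness / block (or vision)
cells and to compare verbal accuracy with OC%.

The ANOVA operates on cell means, not trial-level data, so unequal trial
counts per cell are irrelevant once every cell is non-empty; each within
effect is tested against its own effect-by-subject interaction.

Implementation: the cell-mean matrix (subjects x cells) is projected onto
orthonormal contrast sets built as Kronecker products over factors —
Helmert contrasts for factors in the effect, the normalised unit vector for
factors collapsed out. For an effect with contrast scores Z (subjects x
df): SS_effect = n * ||mean(Z)||^2, SS_error = sum ||Z_i - mean(Z)||^2,
which reproduces the classical sums of squares exactly on balanced designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import helmert

from .trial_data import ParticipantSet, TrialRecord

logger = logging.getLogger(__name__)

#: canonical factor levels for cell-mean tables
FACTOR_LEVELS = {
    "size": ["small", "big"],
    "verbal": ["correct", "incorrect"],
    "block": None,   # taken from the data (1..3 typically)
    "vision": ["closed_loop", "open_loop"],
}


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    sd_diff: float


def cell_means(
    pset: ParticipantSet, factors: Sequence[str], participants: set[str] | None = None
) -> pd.DataFrame:
    """Arithmetic mean MGA per participant x factor cell.

    ``factors`` are drawn from {"size", "verbal", "block", "vision"};
    ``participants`` defaults to the ANOVA-eligible set. An empty cell for
    an included participant raises (it indicates an eligibility bug
    upstream, not a data feature).
    """
    if participants is None:
        participants = pset.anova_eligible
    recs = [
        r
        for r in pset.records
        if r.valid and r.mga_mm is not None and r.participant_id in participants
    ]
    if not recs:
        raise ValueError("no usable trials for the requested participants")
    sizes = sorted({r.target_size_mm for r in recs})
    small_mm = sizes[0]

    def level(r: TrialRecord, f: str) -> object:
        if f == "size":
            return "small" if r.target_size_mm == small_mm else "big"
        if f == "verbal":
            return "correct" if r.verbal_correct else "incorrect"
        if f == "block":
            return r.block
        if f == "vision":
            return r.vision
        raise ValueError(f"unknown factor {f!r}")

    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in recs],
            "mga_mm": [r.mga_mm for r in recs],
            **{f: [level(r, f) for r in recs] for f in factors},
        }
    )
    out = (
        df.groupby(["participant_id", *factors], sort=True)["mga_mm"]
        .mean()
        .reset_index()
    )
    levels = {f: factor_levels(out, f) for f in factors}
    n_cells = int(np.prod([len(v) for v in levels.values()]))
    counts = out.groupby("participant_id").size()
    short = counts[counts < n_cells]
    if len(short):
        raise ValueError(
            f"empty design cells for participants {sorted(short.index)}; "
            "restrict to the ANOVA-eligible set first"
        )
    return out


def factor_levels(cells: pd.DataFrame, factor: str) -> list:
    fixed = FACTOR_LEVELS.get(factor)
    if fixed is not None:
        present = [lv for lv in fixed if lv in set(cells[factor])]
        return present if present else fixed
    return sorted(cells[factor].unique())


def _pivot(cells: pd.DataFrame, within: Sequence[str], dv: str) -> tuple[np.ndarray, list, dict]:
    levels = {f: factor_levels(cells, f) for f in within}
    cell_order = list(product(*[levels[f] for f in within]))
    wide = cells.pivot_table(
        index="participant_id", columns=list(within), values=dv, sort=True
    )
    cols = cell_order if len(within) > 1 else [c[0] for c in cell_order]
    try:
        wide = wide[cols]
    except KeyError as exc:
        raise ValueError(f"incomplete cell-mean table: {exc}") from None
    if wide.isna().any().any():
        raise ValueError("incomplete cell-mean table (missing cells)")
    return wide.to_numpy(dtype=float), list(wide.index), levels


def _anova_from_matrix(Y: np.ndarray, level_counts: Sequence[int], names: Sequence[str]) -> pd.DataFrame:
    """Fully-within decomposition of a subjects x cells matrix.

    ``level_counts`` gives the number of levels per factor; cells are
    ordered as the Kronecker product of factors (last factor fastest).
    """
    n, p = Y.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if p != int(np.prod(level_counts)):
        raise ValueError("cell count does not match the factor level counts")
    m = len(level_counts)
    units = [np.full((1, k), 1.0 / np.sqrt(k)) for k in level_counts]
    contrasts = [helmert(k, full=True)[1:] for k in level_counts]  # orthonormal rows

    rows = []
    for r in range(1, m + 1):
        for eff in combinations(range(m), r):
            C = np.ones((1, 1))
            for f in range(m):
                C = np.kron(C, contrasts[f] if f in eff else units[f])
            Z = Y @ C.T  # n x df
            df_eff = Z.shape[1]
            zbar = Z.mean(axis=0)
            ss_eff = n * float(zbar @ zbar)
            resid = Z - zbar
            ss_err = float((resid * resid).sum())
            df_err = (n - 1) * df_eff
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            F = ms_eff / ms_err if ms_err > 0 else np.inf
            p_unc = float(stats.f.sf(F, df_eff, df_err))
            if df_eff > 1:
                S = np.cov(Z, rowvar=False)
                tr = float(np.trace(S))
                tr2 = float(np.trace(S @ S))
                eps = tr * tr / (df_eff * tr2) if tr2 > 0 else 1.0
                eps = float(np.clip(eps, 1.0 / df_eff, 1.0))
                p_gg = float(stats.f.sf(F, df_eff * eps, df_err * eps))
            else:
                eps, p_gg = 1.0, p_unc
            rows.append(
                {
                    "effect": " x ".join(names[f] for f in eff),
                    "SS_effect": ss_eff,
                    "SS_error": ss_err,
                    "df_effect": df_eff,
                    "df_error": df_err,
                    "F": F,
                    "p": p_unc,
                    "partial_eta_sq": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
                    "gg_epsilon": eps,
                    "p_gg": p_gg,
                }
            )
    return pd.DataFrame(rows)


def rm_anova(cells: pd.DataFrame, within: Sequence[str], dv: str = "mga_mm") -> pd.DataFrame:
    """Fully-within repeated-measures ANOVA on a complete cell-mean table.

    Returns one row per main effect and interaction with SS, df, F,
    uncorrected p, partial eta squared, and — for effects involving a
    factor with more than two levels — the Greenhouse-Geisser epsilon and
    corrected p (``p_gg`` equals ``p`` for single-df effects, where
    sphericity is not at issue). Both p values are reported so either
    reading of an original analysis can be matched.
    """
    if not within:
        raise ValueError("need at least one within factor")
    Y, subjects, levels = _pivot(cells, within, dv)
    return _anova_from_matrix(Y, [len(levels[f]) for f in within], list(within))


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test (pairing by position/participant).

    Zero-variance differences with non-zero mean yield the infinite-t
    convention (p = 0, logged); all-zero differences yield t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired samples must be equal-length 1-D with n >= 2")
    d = x - y
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0, sd_diff=0.0)
        logger.warning("zero-variance differences with non-zero mean: infinite t")
        return PairedTResult(
            t=float(np.sign(mean)) * np.inf, df=n - 1, p=0.0, mean_diff=mean, sd_diff=0.0
        )
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return PairedTResult(t=float(t), df=n - 1, p=p, mean_diff=mean, sd_diff=sd)


def condition_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """Per-condition mean with a t-based confidence interval across participants."""
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    if v.size < 2:
        return mean, np.nan, np.nan
    half = float(stats.t.ppf(0.5 + level / 2.0, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size))
    return mean, mean - half, mean + half


def bonferroni_pairwise(
    cells: pd.DataFrame,
    compare: str,
    within_levels_of: str | None = None,
    family_size: int | None = None,
    dv: str = "mga_mm",
) -> pd.DataFrame:
    """Bonferroni-corrected paired comparisons decomposing an effect.

    Compares the two levels of ``compare`` (paired across participants),
    either overall or separately within each level of ``within_levels_of``
    (the usual decomposition of a two-way interaction, e.g. small vs big
    object within correct and within incorrect judgements). ``family_size``
    defaults to the number of comparisons made; ``p_adj = min(1, p * family)``.
    Per-condition means carry 95% t-based confidence intervals.
    """
    strata = (
        factor_levels(cells, within_levels_of) if within_levels_of else [None]
    )
    if family_size is None:
        family_size = len(strata)
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    lv = factor_levels(cells, compare)
    if len(lv) != 2:
        raise ValueError(f"pairwise comparison needs exactly 2 levels of {compare!r}")
    rows = []
    for s in strata:
        sub = cells if s is None else cells[cells[within_levels_of] == s]
        wide = sub.pivot_table(index="participant_id", columns=compare, values=dv)
        wide = wide.dropna()
        res = paired_t(wide[lv[0]].to_numpy(), wide[lv[1]].to_numpy())
        m0, lo0, hi0 = condition_ci(wide[lv[0]].to_numpy())
        m1, lo1, hi1 = condition_ci(wide[lv[1]].to_numpy())
        rows.append(
            {
                "stratum": "all" if s is None else s,
                "comparison": f"{lv[0]} vs {lv[1]}",
                "n": len(wide),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "p_adj": min(1.0, res.p * family_size),
                "mean_1": m0, "ci_lo_1": lo0, "ci_hi_1": hi0,
                "mean_2": m1, "ci_lo_2": lo1, "ci_hi_2": hi1,
            }
        )
    return pd.DataFrame(rows)


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p); n must be in [3, 5000].

    A constant vector has no defined W and raises — callers should treat
    that as a degenerate sample, not as evidence about normality.
    """
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0.0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)
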