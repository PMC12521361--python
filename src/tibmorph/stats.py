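"""Statistical layer: equivalence tests, rater agreement, group comparisons.

* Paired TOST (two one-sided t-tests) for landmark equivalence at a
  ±0.05 mm bound, with Bonferroni correction over the comparison family
  and the "equivalent to at least two raters" decision rule.
* ICC(2,1) — two-way random effects, absolute agreement, single measure —
  for inter-/intra-operator agreement.
* One-way ANOVA with Tukey HSD post hoc (3D morphometry), Shapiro–Wilk
  and Levene diagnostics, Games–Howell post hoc for the depth-resolved
  comparisons, and the four-color significance band used in the
  depth-profile heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

COLOR_BANDS = (
    (0.001, "red"),         # p <= 0.001
    (0.01, "orange"),       # 0.001 < p <= 0.01
    (0.05, "light_blue"),   # 0.01 < p <= 0.05
    (np.inf, "blue"),       # p > 0.05
)


def significance_color(p: float) -> str:
    """Map a p-value to the heatmap color code.

    blue: p > 0.05; light_blue: 0.01 < p <= 0.05; orange:
    0.001 < p <= 0.01; red: p <= 0.001.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of range: {p}")
    for upper, color in COLOR_BANDS:
        if p <= upper:
            return color
    return "blue"  # unreachable


@dataclass
class EquivalenceConfig:
    bound_mm: float = 0.05
    alpha: float = 0.05
    correction: str = "bonferroni"
    min_agreeing_raters: int = 2

    def __post_init__(self):
        if not self.bound_mm > 0:
            raise ValueError("equivalence bound must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")


# --------------------------------------------------------------------------
# TOST
# --------------------------------------------------------------------------

def tost_paired(x, y, bound_mm: float = 0.05, alpha: float = 0.05) -> dict:
    """Paired two one-sided tests of equivalence within ±bound.

    Tests H01: mean(x−y) <= −bound and H02: mean(x−y) >= +bound with
    one-sided paired t-tests; ``p_tost = max(p_lower, p_upper)`` and the
    pair is equivalent iff ``p_tost <= alpha``.  With zero variance and a
    mean strictly inside the bounds the t statistics diverge; p is
    reported as 0 with a degenerate-variance note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("paired TOST needs n >= 3")
    d = x - y
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    note = None
    if sd == 0:
        if abs(mean) < bound_mm:
            p_lower = p_upper = 0.0
            note = "degenerate variance: differences are constant inside the bounds"
        else:
            p_lower = 0.0 if mean > -bound_mm else 1.0
            p_upper = 0.0 if mean < bound_mm else 1.0
            note = "degenerate variance: differences are constant"
    else:
        se = sd / np.sqrt(n)
        t_lower = (mean + bound_mm) / se   # H01: mean <= -bound, reject large t
        t_upper = (mean - bound_mm) / se   # H02: mean >= +bound, reject small t
        p_lower = float(sps.t.sf(t_lower, df))
        p_upper = float(sps.t.cdf(t_upper, df))
    p_tost = max(p_lower, p_upper)
    return {
        "mean_diff": float(mean),
        "p_lower": p_lower,
        "p_upper": p_upper,
        "p_tost": p_tost,
        "equivalent": bool(p_tost <= alpha),
        "n": n,
        "note": note,
    }


def bonferroni_adjust(pvals) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    return np.minimum(1.0, p * p.size)


def model_vs_raters_equivalence(table: pd.DataFrame,
                                config: EquivalenceConfig | None = None
                                ) -> pd.DataFrame:
    """Pairwise TOST of all landmark sources with the agreement verdict.

    ``table`` is tidy: columns ``bone_id``, ``source`` (``model`` plus
    rater ids), ``landmark``, ``value_mm`` and optionally ``group``.  For
    each (landmark, group) cell, all source pairs are TOST-tested and
    Bonferroni-corrected over that family; the model is declared
    equivalent when it is equivalent to at least
    ``config.min_agreeing_raters`` raters.

    Returns one row per (landmark, group, source_a, source_b) with the
    adjusted p, plus a ``model_pass`` flag repeated within each cell.
    """
    config = config or EquivalenceConfig()
    if "group" not in table.columns:
        table = table.assign(group="all")
    raters = sorted(set(table["source"]) - {"model"})
    if len(raters) < 2:
        raise ValueError("need at least two raters")
    sources = ["model"] + raters

    out = []
    for (lm, grp), cell in table.groupby(["landmark", "group"]):
        wide = cell.pivot_table(index="bone_id", columns="source",
                                values="value_mm")
        pairs, results = [], []
        for i, a in enumerate(sources):
            for b in sources[i + 1:]:
                sub = wide[[a, b]].dropna()
                res = tost_paired(sub[a], sub[b], config.bound_mm,
                                  config.alpha)
                pairs.append((a, b))
                results.append(res)
        p_adj = bonferroni_adjust([r["p_tost"] for r in results])
        agree = sum(
            1 for (a, b), p in zip(pairs, p_adj)
            if "model" in (a, b) and p <= config.alpha
        )
        model_pass = agree >= config.min_agreeing_raters
        for (a, b), res, p in zip(pairs, results, p_adj):
            out.append({
                "landmark": lm, "group": grp, "source_a": a, "source_b": b,
                "mean_diff": res["mean_diff"], "p_tost": res["p_tost"],
                "p_adjusted": float(p),
                "equivalent": bool(p <= config.alpha),
                "model_agreements": agree, "model_pass": model_pass,
            })
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# ICC
# --------------------------------------------------------------------------

def icc(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is a subjects × raters matrix with no missing cells.  Pass
    a subjects × repeats matrix of a single rater to obtain the
    intra-operator ICC.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ratings must be subjects x raters with >=2 of each")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    if np.ptp(m) == 0:
        raise ValueError("zero total variance: ICC undefined")
    n, k = m.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": m.ravel(),
    })
    tab = pg.intraclass_corr(data=long, targets="subject", raters="rater",
                             ratings="score").set_index("Type")
    # the absolute-agreement single-measure row is labelled ICC2 or ICC(A,1)
    # depending on the pingouin release
    for label in ("ICC2", "ICC(A,1)"):
        if label in tab.index:
            return float(tab.loc[label, "ICC"])
    raise RuntimeError("ICC(2,1) row not found in pingouin output")


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

def anova_tukey(groups: dict, alpha: float = 0.05) -> dict:
    """One-way ANOVA with Tukey HSD post hoc and assumption diagnostics.

    ``groups`` maps group name → 1D samples.  Tukey pairwise p-values are
    computed only when the omnibus p <= alpha (FWER at 5 %); Shapiro–Wilk
    (per group) and Levene (across groups) are reported as diagnostics and
    never gate execution.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    for g, s in zip(names, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has n < 2")

    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        F, p = 0.0, 1.0
    else:
        F, p = sps.f_oneway(*samples)
        F, p = float(F), float(p)

    diagnostics = {
        "shapiro": {
            g: float(sps.shapiro(s).pvalue) if len(s) >= 3 else None
            for g, s in zip(names, samples)
        },
        "levene": float(sps.levene(*samples).pvalue),
    }

    pairwise = None
    if p <= alpha and F > 0:
        values = np.concatenate(samples)
        labels = np.concatenate([[g] * len(s) for g, s in zip(names, samples)])
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        uniq = list(tk.groupsunique)
        pairwise = {}
        for (i, j), pv in zip(
            [(i, j) for i in range(len(uniq)) for j in range(i + 1, len(uniq))],
            tk.pvalues,
        ):
            pairwise[(uniq[i], uniq[j])] = float(pv)
    return {"F": F, "p_omnibus": p, "pairwise": pairwise,
            "diagnostics": diagnostics}


def games_howell(groups: dict) -> dict:
    """Games–Howell pairwise comparisons (Welch statistics, studentized range).

    Suitable when group variances differ; returns {(a, b): p}.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for g in names:
        s = np.asarray(groups[g], dtype=float)
        if len(s) < 2:
            raise ValueError(f"group {g!r} has n < 2")
        rows.append(pd.DataFrame({"group": g, "value": s}))
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va = np.var(groups[a], ddof=1)
            vb = np.var(groups[b], ddof=1)
            if va == 0 and vb == 0:
                raise ValueError(f"zero variance in both groups of ({a}, {b})")
    df = pd.concat(rows, ignore_index=True)
    tab = pg.pairwise_gameshowell(data=df, dv="value", between="group")
    out = {}
    for _, r in tab.iterrows():
        out[(r["A"], r["B"])] = float(r["pval"])
    return out


# --------------------------------------------------------------------------
# depth-resolved comparison
# --------------------------------------------------------------------------

def depth_profile_comparison(profiles: dict, value_column: str = "bar_tar_pct",
                             alpha: float = 0.05) -> pd.DataFrame:
    """Per-bin omnibus + Games–Howell pairwise comparison with color codes.

    ``profiles`` maps group name → list of per-bone DataFrames from
    :func:`tibmorph.morphometry.morphometry_profile`; all profiles must
    share the identical bin grid.  Per bin: one-way ANOVA across groups;
    when significant, Games–Howell pairwise p-values; each pairwise p maps
    through the significance color bands.  Returns a tidy frame with one
    row per (bin, group pair): columns z_start_mm, group_a, group_b,
    p_omnibus, p_pairwise, color.
    """
    names = list(profiles)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    grids = {
        g: tuple(np.round(dfs[0]["z_start_mm"].to_numpy(), 9))
        for g, dfs in profiles.items()
    }
    ref_grid = grids[names[0]]
    for g, grid in grids.items():
        if grid != ref_grid:
            raise ValueError(f"bin grid of group {g!r} differs")
        for df in profiles[g]:
            if tuple(np.round(df["z_start_mm"].to_numpy(), 9)) != ref_grid:
                raise ValueError(f"bin grid mismatch within group {g!r}")

    out = []
    for bi, z_start in enumerate(ref_grid):
        samples = {
            g: np.array([df[value_column].iloc[bi] for df in profiles[g]])
            for g in names
        }
        samples = {g: s[~np.isnan(s)] for g, s in samples.items()}
        usable = {g: s for g, s in samples.items() if len(s) >= 2}
        if len(usable) < 2:
            raise ValueError(f"bin {bi}: fewer than two groups with n >= 2")
        res = anova_tukey(usable, alpha=alpha)
        p_omni = res["p_omnibus"]
        if p_omni <= alpha and res["F"] > 0:
            pairwise = games_howell(usable)
        else:
            pairwise = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if (a, b) in pairwise:
                    pp = pairwise[(a, b)]
                elif (b, a) in pairwise:
                    pp = pairwise[(b, a)]
                else:
                    pp = 1.0  # post hoc not emitted: not significant
                out.append({
                    "bin_index": bi, "z_start_mm": z_start,
                    "group_a": a, "group_b": b,
                    "p_omnibus": p_omni,
                    "p_pairwise": pp if pairwise else np.nan,
                    "color": significance_color(pp if pairwise else 1.0),
                })
    return pd.DataFrame(out)


def color_matrix(comparison: pd.DataFrame) -> pd.DataFrame:
    """Pivot a depth comparison into a (group pair) × bin color matrix."""
    comparison = comparison.assign(
        pair=comparison["group_a"].astype(str) + " vs "
        + comparison["group_b"].astype(str)
    )
    return comparison.pivot(index="pair", columns="z_start_mm",
                            values="color")
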