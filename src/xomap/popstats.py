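"""Sex/genotype comparisons and small derived statistics.

``nested_anova`` fits ``y ~ sex + sex:genotype`` with sequential (type I)
sums of squares — genotype nested within sex — and follows up with a
Tukey–Kramer honestly-significant-difference test over the sex x genotype
cell means, using the Studentized range distribution (Kramer's correction
handles unbalanced cells).  ``landscape_chisq`` compares two recombination
landscapes window by window with Pearson chi-square tests (no continuity
correction) and Benjamini–Hochberg adjusted p-values.  The remaining helpers
are exact arithmetic: percent change between group means, the ratio of
cytological focus counts to offspring CO counts (a transmitted gamete
carries on average half of the meiocyte's crossovers), and minimum chiasma
scores (rod bivalent = 1, ring bivalent = 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "nested_anova",
    "landscape_chisq",
    "percent_change",
    "foci_to_offspring_co_ratio",
    "min_chiasmata",
]


@dataclass
class AnovaResult:
    anova_table: pd.DataFrame  # term, df, sum_sq, mean_sq, F, p
    tukey: pd.DataFrame  # group1, group2, mean_diff, q, p_adj


def nested_anova(values, sex, genotype) -> AnovaResult:
    """Nested ANOVA ``y ~ sex + sex:genotype`` with Tukey–Kramer HSD.

    ``values`` are the per-offspring responses (CO counts or inter-CO
    distances); ``sex`` and ``genotype`` the matching factor labels.  Every
    sex x genotype cell must be occupied.  F tests use the residual mean
    square; the Tukey table compares all cell-mean pairs with the
    Studentized range distribution at ``k`` = number of cells.
    """
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "sex": list(sex), "genotype": list(genotype)}
    )
    if df["sex"].nunique() < 2 or df["genotype"].nunique() < 2:
        raise ValueError("need at least 2 levels per factor")
    cells = df.groupby(["sex", "genotype"]).size()
    expected = df["sex"].nunique() * df["genotype"].nunique()
    if len(cells) < expected or (cells == 0).any():
        raise ValueError("singular design: every sex x genotype cell must be occupied")

    model = smf.ols("y ~ C(sex) + C(sex):C(genotype)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(
        columns={"df": "df", "sum_sq": "sum_sq", "F": "F", "PR(>F)": "p"}
    )
    table["mean_sq"] = table["sum_sq"] / table["df"]
    table = table[["df", "sum_sq", "mean_sq", "F", "p"]]

    mse = table.loc["Residual", "mean_sq"]
    df_resid = table.loc["Residual", "df"]
    means = df.groupby(["sex", "genotype"])["y"].agg(["mean", "size"])
    k = len(means)
    rows = []
    labels = [f"{s}:{g}" for s, g in means.index]
    for (li, mi), (lj, mj) in combinations(zip(labels, means.itertuples(index=False)), 2):
        se = np.sqrt(mse / 2.0 * (1.0 / mi.size + 1.0 / mj.size))
        q = np.abs(mj.mean - mi.mean) / se if se > 0 else np.inf
        p_adj = float(stats.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
        rows.append(
            {
                "group1": li,
                "group2": lj,
                "mean_diff": mj.mean - mi.mean,
                "q": q,
                "p_adj": min(1.0, p_adj),
            }
        )
    return AnovaResult(anova_table=table, tukey=pd.DataFrame(rows))


def landscape_chisq(landscape_a: pd.DataFrame, landscape_b: pd.DataFrame, alpha=0.05):
    """Per-window Pearson chi-square comparison of two landscapes.

    Both inputs come from ``bin_landscape`` and must share the binning.  Each
    window is tested on the 2x2 table [COs in window vs COs elsewhere] x
    [group A vs group B] with no continuity correction; windows whose two
    in-window counts are both zero are skipped (NaN statistic).  Raw and
    Benjamini–Hochberg adjusted p-values are reported.
    """
    key = ["chrom", "bin"]
    a = landscape_a.set_index(key)
    b = landscape_b.set_index(key)
    if not a.index.equals(b.index):
        raise ValueError("landscapes have mismatched binning")
    tot_a = int(a["count"].sum())
    tot_b = int(b["count"].sum())
    rows = []
    for idx in a.index:
        ca, cb = int(a.loc[idx, "count"]), int(b.loc[idx, "count"])
        row = {
            "chrom": idx[0],
            "bin": idx[1],
            "count_a": ca,
            "count_b": cb,
            "rest_a": tot_a - ca,
            "rest_b": tot_b - cb,
        }
        tab = np.array([[ca, tot_a - ca], [cb, tot_b - cb]])
        if ca + cb == 0 or (tot_a - ca) + (tot_b - cb) == 0 or tot_a == 0 or tot_b == 0:
            row.update({"chi2": np.nan, "df": 1, "p": np.nan})
        else:
            chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
            row.update({"chi2": float(chi2), "df": int(dof), "p": float(p)})
        rows.append(row)
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["p_bh"] = np.nan
    if tested.any():
        out.loc[tested, "p_bh"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["significant_bh"] = out["p_bh"] < alpha
    return out


def percent_change(mean_ref, mean_alt) -> float:
    """Percent change of ``mean_alt`` relative to ``mean_ref`` (> 0)."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be > 0")
    return 100.0 * (mean_alt - mean_ref) / mean_ref


def foci_to_offspring_co_ratio(foci_mean_per_meiocyte, co_mean_per_offspring, transmitted_fraction=0.5) -> float:
    """Percent of offspring COs accounted for by per-meiocyte focus counts.

    A transmitted gamete carries on average ``transmitted_fraction`` (1/2
    under no chromatid interference) of the meiocyte's COs, so the expected
    offspring CO count explained by the foci is ``foci * transmitted_fraction``
    and the ratio is ``100 * foci * transmitted_fraction / co_mean``.  Set
    ``transmitted_fraction=1`` to compare raw counts.
    """
    if co_mean_per_offspring <= 0:
        raise ValueError("offspring CO mean must be > 0")
    return 100.0 * foci_mean_per_meiocyte * transmitted_fraction / co_mean_per_offspring


def min_chiasmata(rod_count, ring_count) -> int:
    """Minimum chiasma score: rod bivalents count 1, ring bivalents count 2."""
    if rod_count < 0 or ring_count < 0:
        raise ValueError("counts must be >= 0")
    return int(rod_count) + 2 * int(ring_count)
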