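"""Trait descriptive statistics, heritability, and the expression screen.

Works on tidy tables: phenotypes as (individual, trait, year, value) rows and
expression as (gene, stage, parent, replicate, fpkm) rows.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def trait_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per (trait, year) mean, sd, range, and Shapiro–Wilk normality test.

    Raises on groups with fewer than 3 non-missing values; constant traits
    get an undefined normality p with a flag.
    """
    rows = []
    for (trait, year), sub in table.groupby(["trait", "year"]):
        vals = sub["value"].dropna().to_numpy(dtype=float)
        if vals.size < 3:
            raise ValueError(f"trait {trait!r} year {year!r}: need >= 3 non-missing values")
        constant = np.ptp(vals) == 0
        if constant:
            warnings.warn(f"trait {trait!r} year {year!r} is constant; normality undefined", stacklevel=2)
            w, p = np.nan, np.nan
        else:
            w, p = stats.shapiro(vals)
        rows.append(
            {
                "trait": trait,
                "year": year,
                "n": vals.size,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "shapiro_w": float(w),
                "shapiro_p": float(p),
                "constant": bool(constant),
            }
        )
    return pd.DataFrame(rows)


def trait_correlations(
    wide: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlations with two-sided p-values (pairwise-complete).

    ``wide`` is individuals x variables (e.g. trait-year columns).  Pearson
    for quantitative traits; binary columns against quantitative ones reduce
    to the point-biserial coefficient, which Pearson computes.
    """
    cols = list(wide.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            sub = wide[[ci, cj]].dropna()
            if len(sub) < 3:
                r.loc[ci, cj] = r.loc[cj, ci] = np.nan
                p.loc[ci, cj] = p.loc[cj, ci] = np.nan
                continue
            x, y = sub[ci].to_numpy(float), sub[cj].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r.loc[ci, cj] = r.loc[cj, ci] = np.nan
                p.loc[ci, cj] = p.loc[cj, ci] = np.nan
                continue
            if method == "pearson":
                rr, pp = stats.pearsonr(x, y)
            elif method == "spearman":
                rr, pp = stats.spearmanr(x, y)
            else:
                raise ValueError(f"unknown method {method!r}")
            r.loc[ci, cj] = r.loc[cj, ci] = rr
            p.loc[ci, cj] = p.loc[cj, ci] = pp
    return r, p


def broad_sense_h2(table: pd.DataFrame, trait: str) -> float:
    """Broad-sense heritability from a one-way random-effects decomposition.

    Individuals are the random genotype effect, yearly values their
    replicates: H2 = sigma2_G / (sigma2_G + sigma2_E) with components from
    the one-way ANOVA mean squares (unbalanced designs use the standard
    effective replicate number), clamped to [0, 1].
    """
    sub = table[(table["trait"] == trait) & table["value"].notna()]
    if sub["year"].nunique() < 2:
        raise ValueError("broad-sense heritability needs >= 2 years of data")
    groups = [g["value"].to_numpy(float) for _, g in sub.groupby("individual") if len(g) >= 1]
    sizes = np.array([len(g) for g in groups])
    a = len(groups)
    n_total = sizes.sum()
    if a < 2 or n_total <= a:
        raise ValueError("need >= 2 individuals with replicated values")
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(n * (g.mean() - grand) ** 2 for g, n in zip(groups, sizes)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (n_total - a)
    n0 = (n_total - (sizes**2).sum() / n_total) / (a - 1)
    sigma_g = max((ms_between - ms_within) / n0, 0.0)
    sigma_e = ms_within
    if sigma_g + sigma_e == 0:
        return 0.0
    return float(np.clip(sigma_g / (sigma_g + sigma_e), 0.0, 1.0))


def early_late_compare(
    md: pd.Series | np.ndarray, fcs: pd.Series | np.ndarray, cutoff: float
) -> dict[str, float]:
    """Early vs late ripening color comparison.

    Individuals with maturity date >= ``cutoff`` are the late group; the
    one-tailed Welch t-test asks whether the early group is darker (higher
    FCS).  Raises on an empty group.
    """
    md_arr = np.asarray(md, dtype=float)
    fcs_arr = np.asarray(fcs, dtype=float)
    ok = np.isfinite(md_arr) & np.isfinite(fcs_arr)
    late = md_arr[ok] >= cutoff
    early_vals = fcs_arr[ok][~late]
    late_vals = fcs_arr[ok][late]
    if early_vals.size == 0 or late_vals.size == 0:
        raise ValueError("empty early or late group at this cutoff")
    t, p = stats.ttest_ind(early_vals, late_vals, equal_var=False, alternative="greater")
    return {
        "mean_early": float(early_vals.mean()),
        "mean_late": float(late_vals.mean()),
        "n_early": int(early_vals.size),
        "n_late": int(late_vals.size),
        "t": float(t),
        "p": float(p),
    }


def expression_screen(
    expr: pd.DataFrame, fpkm_floor: float = 10.0, alpha: float = 0.05, combine: str = "sum"
) -> pd.DataFrame:
    """Candidate-gene screen on a parental expression time course.

    Genes whose combined FPKM over all stage x parent cells is <= the floor
    are filtered out (minimal expression); surviving genes get a per-stage
    Welch t-test between the two parents over replicates, and are flagged if
    any stage's p < alpha.  ``combine`` is 'sum' (literal reading of a
    combined value) or 'mean'.  Stages with < 2 replicates in either parent
    are skipped with a warning.
    """
    required = {"gene", "stage", "parent", "replicate", "fpkm"}
    if not required.issubset(expr.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    if (expr["fpkm"] < 0).any():
        raise ValueError("FPKM must be >= 0")
    parents = sorted(expr["parent"].unique())
    if len(parents) != 2:
        raise ValueError("expression screen expects exactly two parents")
    rows = []
    for gene, sub in expr.groupby("gene"):
        cell_means = sub.groupby(["stage", "parent"])["fpkm"].mean()
        combined = float(cell_means.sum() if combine == "sum" else cell_means.mean())
        retained = combined > fpkm_floor
        flagged_stages: list = []
        if retained:
            for stage, ssub in sub.groupby("stage"):
                g1 = ssub.loc[ssub["parent"] == parents[0], "fpkm"].to_numpy(float)
                g2 = ssub.loc[ssub["parent"] == parents[1], "fpkm"].to_numpy(float)
                if len(g1) < 2 or len(g2) < 2:
                    warnings.warn(f"gene {gene} stage {stage}: <2 replicates; skipped", stacklevel=2)
                    continue
                if np.ptp(g1) == 0 and np.ptp(g2) == 0:
                    continue  # identical constants: no evidence of difference
                _, pval = stats.ttest_ind(g1, g2, equal_var=False)
                if pval < alpha:
                    flagged_stages.append(stage)
        rows.append(
            {
                "gene": gene,
                "combined_fpkm": combined,
                "retained": bool(retained),
                "flagged": bool(flagged_stages),
                "stages": flagged_stages,
            }
        )
    return pd.DataFrame(rows)
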