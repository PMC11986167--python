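"""Group-wise trait statistics: descriptives, Tukey letters, correlations.

Covers the classical analysis layer of a ripening study: per-maturity-group
min/max/mean/SD for each indicator, one-way ANOVA with Tukey's HSD at
alpha = 0.05 summarized as a compact letter display (groups sharing no
letter differ significantly), Pearson correlation matrices per group and
pooled, and the percent-difference arithmetic used to compare group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .spectra import TRAIT_NAMES, TraitTable


def percent_difference(reference_mean: float, other_mean: float) -> float:
    """How much larger the reference mean is, as a percent of itself.

    ``100 * (reference - other) / reference``, rounded to one decimal —
    the convention "group A was X% higher than group B" with the
    difference expressed relative to the first-named (larger) group.
    """
    if reference_mean == 0:
        raise ValueError("reference mean must be non-zero")
    return round(100.0 * (reference_mean - other_mean) / reference_mean, 1)


def significance_stars(p: float) -> str:
    """Report-table star convention: *, **, *** at p <= .05/.01/.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# compact letter display

def compact_letter_display(groups: list[str],
                           differs: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Insert-and-absorb letter assignment from pairwise difference calls.

    ``differs[(a, b)]`` is True when groups a and b are significantly
    different.  Letters are assigned so two groups share a letter iff they
    are not significantly different (exact for the 3-group one-way layouts
    used here; the classic insert-absorb algorithm in general).
    """
    def diff(a: str, b: str) -> bool:
        return differs.get((a, b), differs.get((b, a), False))

    # each letter is the set of groups it covers
    letters: list[set[str]] = [set(groups)]
    for a, b in [(x, y) for i, x in enumerate(groups) for y in groups[i + 1:]]:
        if not diff(a, b):
            continue
        for s in [s for s in letters if a in s and b in s]:
            letters.remove(s)
            sa, sb = s - {b}, s - {a}
            for cand in (sa, sb):
                if not any(cand <= other for other in letters):
                    letters.append(cand)
    # absorb redundant letters, then label in group order
    letters = [s for s in letters if not any(s < o for o in letters)]
    letters.sort(key=lambda s: min(groups.index(g) for g in s))
    out: dict[str, str] = {g: "" for g in groups}
    for lab, s in zip("abcdefghijklmnopqrstuvwxyz", letters):
        for g in s:
            out[g] += lab
    return {g: "".join(sorted(v)) for g, v in out.items()}


@dataclass
class GroupStats:
    """Descriptive statistics per (group, trait) plus Tukey letters."""

    table: pd.DataFrame          # columns: group, trait, n, min, max, mean, sd, letter
    anova: pd.DataFrame          # columns: trait, F, p
    tukey: pd.DataFrame          # columns: trait, group1, group2, meandiff, p_adj, reject

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")

    def letters(self, trait: str) -> dict[str, str]:
        sub = self.table[self.table["trait"] == trait]
        return dict(zip(sub["group"], sub["letter"]))


def describe_groups(traits: TraitTable, alpha: float = 0.05) -> GroupStats:
    """Per-group descriptives with one-way ANOVA and Tukey HSD letters.

    SD uses the n-1 denominator.  Groups with fewer than 2 samples get
    descriptive rows but no letters (with a warning).  The Tukey-Kramer
    adjustment applies automatically when group sizes differ.
    """
    if traits.groups is None:
        raise ValueError("trait table has no group labels")
    df = traits.to_frame()
    group_names = list(dict.fromkeys(traits.groups))
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    sizes = df.groupby("group", sort=False)["sample_id"].count()
    small = [g for g in group_names if sizes[g] < 2]
    if small:
        warnings.warn(f"groups with < 2 samples get no Tukey letters: {small}")

    rows, anova_rows, tukey_rows = [], [], []
    for trait in TRAIT_NAMES:
        vals = {g: df.loc[df["group"] == g, trait].to_numpy(dtype=float)
                for g in group_names}
        letters: dict[str, str] = {g: "" for g in group_names}
        usable = [g for g in group_names if len(vals[g]) >= 2]
        if len(usable) >= 2:
            pooled = np.concatenate([vals[g] for g in usable])
            labels = np.concatenate([[g] * len(vals[g]) for g in usable])
            if all(np.ptp(vals[g]) == 0 for g in usable) and np.ptp(pooled) == 0:
                letters = {g: "a" for g in usable}
                anova_rows.append({"trait": trait, "F": np.nan, "p": np.nan})
            else:
                F, p = stats.f_oneway(*[vals[g] for g in usable])
                anova_rows.append({"trait": trait, "F": float(F), "p": float(p)})
                hsd = pairwise_tukeyhsd(pooled, labels, alpha=alpha)
                res = pd.DataFrame(hsd.summary().data[1:],
                                   columns=hsd.summary().data[0])
                differs = {}
                for _, r in res.iterrows():
                    differs[(str(r["group1"]), str(r["group2"]))] = bool(r["reject"])
                    tukey_rows.append({
                        "trait": trait, "group1": str(r["group1"]),
                        "group2": str(r["group2"]),
                        "meandiff": float(r["meandiff"]),
                        "p_adj": float(r["p-adj"]), "reject": bool(r["reject"]),
                    })
                letters = compact_letter_display(usable, differs)
        for g in group_names:
            v = vals[g]
            rows.append({
                "group": g, "trait": trait, "n": len(v),
                "min": float(np.min(v)), "max": float(np.max(v)),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                "letter": letters.get(g, ""),
            })
    return GroupStats(table=pd.DataFrame(rows),
                      anova=pd.DataFrame(anova_rows),
                      tukey=pd.DataFrame(tukey_rows))


@dataclass
class CorrelationMatrix:
    scope: str                   # group label or "pooled"
    r: pd.DataFrame              # trait x trait Pearson r
    p: pd.DataFrame              # matching two-sided p-values

    def to_csv(self, path) -> None:
        self.r.to_csv(path, float_format="%.6g")


def pearson_matrix(traits: TraitTable, scope: str = "pooled") -> CorrelationMatrix:
    """Pairwise Pearson correlations among the four indicators.

    ``scope`` is either "pooled" or a group label.  Missing values are
    deleted pairwise; a constant trait yields NaN (flagged undefined).
    """
    df = traits.to_frame()
    if scope != "pooled":
        if traits.groups is None or scope not in set(traits.groups):
            raise ValueError(f"unknown group {scope!r}")
        df = df[df["group"] == scope]
    if len(df) < 3:
        raise ValueError("need at least 3 samples in scope")
    names = list(TRAIT_NAMES)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            x = df[a].to_numpy(dtype=float)
            y = df[b].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = float(rv)
            p.loc[a, b] = p.loc[b, a] = float(pv)
    return CorrelationMatrix(scope=scope, r=r, p=p)


def boxplot(traits: TraitTable, trait: str, ax=None):
    """Per-group box plot of one indicator (matplotlib)."""
    import matplotlib.pyplot as plt

    if traits.groups is None:
        raise ValueError("trait table has no group labels")
    if ax is None:
        _, ax = plt.subplots()
    df = traits.to_frame()
    groups = list(dict.fromkeys(traits.groups))
    data = [df.loc[df["group"] == g, trait] for g in groups]
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel(trait)
    return ax
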