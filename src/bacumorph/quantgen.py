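"""Repeatability, environmental, heritability and correlation statistics.

All functions are pure functions of tidy specimen tables with columns
``specimen_id, strain, lab, replicate_group, centroid_size, LD1`` (subsets
suffice per analysis).

Heritability here is the broad-sense, strain-level estimator used for inbred
panels: the fraction of phenotypic sum of squares explained by strain
identity in a one-way ANOVA (the model R^2).  Repeatability of size is one
minus the median coefficient of variation of centroid size across re-scanned
specimens; repeatability of shape is one minus the mean coefficient of
variation of each replicate set's Procrustes distances to every other bone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaResult:
    h2: float
    F: float
    df_between: int
    df_within: int
    p: float


def repeatability_size(replicate_groups: dict | list) -> float:
    """1 - median coefficient of variation of repeated size measurements.

    ``replicate_groups`` maps group id -> sequence of centroid sizes (or is
    a list of sequences).  The CV uses the unbiased (n-1 denominator)
    standard deviation divided by the group mean.
    """
    groups = (
        list(replicate_groups.values())
        if isinstance(replicate_groups, dict)
        else list(replicate_groups)
    )
    cvs = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        if len(g) < 2:
            raise ValueError("every replicate group needs >= 2 measurements")
        mean = g.mean()
        if mean == 0:
            raise ValueError("replicate group mean is zero; CV undefined")
        cvs.append(g.std(ddof=1) / mean)
    return float(1.0 - np.median(cvs))


def repeatability_shape(
    dist: pd.DataFrame | np.ndarray,
    replicate_groups: dict,
    others: list | None = None,
    specimen_ids: list | None = None,
) -> float:
    """Shape repeatability from a full pairwise Procrustes distance matrix.

    For each replicate group (the repeated scans of one bone) and each
    non-replicate specimen, the coefficient of variation of the distances
    from the replicates to that specimen is computed; the statistic is one
    minus the mean CV over all (group, other) pairs.  Used instead of a CV
    of the shape score itself, which spans zero.
    """
    if isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        ids = list(specimen_ids) if specimen_ids is not None else list(range(len(D)))
    index = {sid: i for i, sid in enumerate(ids)}
    replicate_members = {sid for mem in replicate_groups.values() for sid in mem}
    if others is None:
        others = [sid for sid in ids if sid not in replicate_members]
    if not others:
        raise ValueError("need at least one non-replicate specimen")
    cvs = []
    for group, members in replicate_groups.items():
        if len(members) < 2:
            raise ValueError(f"replicate group {group!r} needs >= 2 scans")
        rows = [index[m] for m in members]
        for other in others:
            d = D[rows, index[other]]
            mean = d.mean()
            if mean == 0:
                warnings.warn(
                    f"zero mean distance for group {group!r} vs {other!r}; "
                    "pair skipped",
                    stacklevel=2,
                )
                continue
            cvs.append(d.std(ddof=1) / mean)
    return float(1.0 - np.mean(cvs))


def heritability(
    table: pd.DataFrame, trait: str, min_n: int = 3
) -> AnovaResult:
    """Strain-level heritability as the one-way-ANOVA variance fraction.

    Strains with fewer than ``min_n`` individuals are excluded (mirroring
    the convention of estimating h^2 only on well-replicated strains while
    keeping every strain for mapping).  Returns h2 = SS_strain / SS_total
    together with the F statistic, degrees of freedom and p-value.
    """
    counts = table.groupby("strain")[trait].count()
    kept = counts[counts >= min_n].index
    if len(kept) < 2:
        raise ValueError(
            f"need >= 2 strains with >= {min_n} individuals; have {len(kept)}"
        )
    sub = table[table["strain"].isin(kept)]
    y = sub[trait].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    group_means = sub.groupby("strain")[trait].transform("mean").to_numpy()
    ss_within = np.sum((y - group_means) ** 2)
    ss_between = ss_total - ss_within
    df_b = len(kept) - 1
    df_w = len(sub) - len(kept)
    F = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return AnovaResult(
        h2=float(ss_between / ss_total),
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
    )


@dataclass
class NestedAnovaResult:
    F_lab: float
    df_lab: int
    df_resid: int
    p: float
    variance_fraction: float
    ss: dict


def nested_anova_env(table: pd.DataFrame, trait: str) -> NestedAnovaResult:
    """ANOVA of a trait with lab origin nested within strain.

    Sequential (type-I) sums of squares: strain first, then lab within
    strain, then residual.  Returns the F test for the nested lab term and
    the fraction of total SS attributable to lab.
    """
    sub = table.dropna(subset=[trait, "strain", "lab"]).copy()
    multi = sub.groupby("strain")["lab"].nunique()
    if not (multi > 1).any():
        raise ValueError("no strain has individuals from more than one lab")
    y = sub[trait].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    strain_means = sub.groupby("strain")[trait].transform("mean").to_numpy()
    cell_means = sub.groupby(["strain", "lab"])[trait].transform("mean").to_numpy()
    ss_strain = np.sum((strain_means - grand) ** 2)
    ss_lab = np.sum((cell_means - strain_means) ** 2)
    ss_resid = np.sum((y - cell_means) ** 2)
    df_lab = int((multi - 1).clip(lower=0).sum())
    n_cells = sub.groupby(["strain", "lab"]).ngroups
    df_resid = len(sub) - n_cells
    if df_lab == 0 or df_resid <= 0:
        raise ValueError("insufficient degrees of freedom for the nested term")
    F = (ss_lab / df_lab) / (ss_resid / df_resid) if ss_resid > 0 else np.inf
    p = float(stats.f.sf(F, df_lab, df_resid)) if np.isfinite(F) else 0.0
    return NestedAnovaResult(
        F_lab=float(F),
        df_lab=df_lab,
        df_resid=df_resid,
        p=p,
        variance_fraction=float(ss_lab / ss_total),
        ss={
            "strain": float(ss_strain),
            "lab": float(ss_lab),
            "residual": float(ss_resid),
            "total": float(ss_total),
        },
    )


def strain_mean_correlation(
    table: pd.DataFrame, size_col: str = "centroid_size", shape_col: str = "LD1"
) -> tuple[float, float]:
    """Pearson correlation between per-strain mean size and mean shape."""
    means = table.groupby("strain")[[size_col, shape_col]].mean().dropna()
    if len(means) < 3:
        raise ValueError("need >= 3 strains with both traits")
    x = means[size_col].to_numpy()
    y = means[shape_col].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in a trait; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
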