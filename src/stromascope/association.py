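"""Clinical and molecular association of slide-level TSR features.

Clinical: patients are median-split on a TSR feature (fibrosis mean score
by default) and compared with Cox proportional-hazards regression, either
univariate (group only) or multivariable adjusted for age, stage (IV vs
III) and debulking status (suboptimal vs optimal).  Hazard ratios, 95%
confidence intervals and two-sided Wald p-values are reported.

Molecular: per-gene Spearman rank correlation of normalized expression with
the TSR feature, nominal-alpha selection of positively / negatively
correlated genes, and one-sided (over-representation) Fisher/hypergeometric
enrichment of the selections against user-supplied gene sets with
Benjamini-Hochberg FDR across the collection.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def median_split(values: Sequence[float]) -> np.ndarray:
    """Label each value 'low' (<= median) or 'high' (> median).

    The empirical 50th percentile is the split point; ties at the median go
    to the low group.  All-identical input would leave one group empty and
    is rejected.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to split")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    med = float(np.median(v))
    labels = np.where(v <= med, "low", "high")
    if (labels == "low").all() or (labels == "high").all():
        raise ValueError("all values identical at the median; split yields one group")
    return labels


def _encode_design(
    records: pd.DataFrame, group: Sequence[str] | None, covariates: Sequence[str]
) -> pd.DataFrame:
    df = pd.DataFrame(
        {"time": records["time"].to_numpy(float), "event": records["event"].to_numpy(int)}
    )
    if group is not None:
        df["group_high"] = (np.asarray(group) == "high").astype(int)
    for cov in covariates:
        if cov == "age":
            df["age"] = records["age"].to_numpy(float)
        elif cov == "stage":
            df["stage_iv"] = (records["stage"].to_numpy(int) == 4).astype(int)
        elif cov == "debulking":
            df["debulking_suboptimal"] = (
                records["debulking"].astype(str) == "suboptimal"
            ).astype(int)
        else:
            df[cov] = records[cov].to_numpy(float)
    return df


def cox_fit(
    records: pd.DataFrame,
    group: Sequence[str] | None = None,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per covariate.

    ``records`` needs ``time`` (months) and ``event`` (0/1) columns plus any
    requested covariates.  ``group`` is a low/high label vector (from
    :func:`median_split`); univariate mode passes only ``group``, the
    adjusted model adds ``covariates=('age', 'stage', 'debulking')``.
    Returns hazard ratios with 95% CIs and two-sided p-values.  A group
    with zero events, or non-convergence (e.g. complete separation), raises.
    """
    if group is None and not covariates:
        raise ValueError("nothing to fit: pass a group vector and/or covariates")
    if group is not None:
        g = np.asarray(group)
        ev = records["event"].to_numpy(int)
        for name in ("low", "high"):
            sel = g == name
            if sel.sum() == 0 or ev[sel].sum() == 0:
                raise ValueError(f"group {name!r} has no events; Cox fit is undefined")
    df = _encode_design(records, group, covariates)

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:  # separation, collinearity, ...
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    out = pd.DataFrame(
        {
            "covariate": summary.index,
            "log_hr": summary["coef"].to_numpy(),
            "hr": summary["exp(coef)"].to_numpy(),
            "ci_lower": summary["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": summary["exp(coef) upper 95%"].to_numpy(),
            "p": summary["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# molecular association

def spearman_gene_scan(expression: pd.DataFrame, scores: pd.Series) -> pd.DataFrame:
    """Spearman rank correlation of every gene with the TSR feature.

    ``expression`` is genes x cases; ``scores`` is indexed by case id and
    must cover exactly the expression columns.  Ties receive average ranks.
    The p-value uses the t-distribution approximation (two-sided), the
    standard large-sample Spearman test.  Returns one row per gene with
    rho, p and direction = sign(rho).
    """
    if expression.shape[1] < 5:
        raise ValueError("need at least 5 cases for a rank correlation scan")
    if set(expression.columns) != set(scores.index):
        raise ValueError("case ids of expression matrix and score vector do not match")
    scores = scores.reindex(expression.columns)
    n = expression.shape[1]
    rank_x = stats.rankdata(expression.to_numpy(float), axis=1)
    rank_y = stats.rankdata(scores.to_numpy(float))
    rx = rank_x - rank_x.mean(axis=1, keepdims=True)
    ry = rank_y - rank_y.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / denom
    rho = np.clip(np.nan_to_num(rho, nan=0.0), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {"gene": expression.index, "rho": rho, "p": p, "direction": np.sign(rho).astype(int)}
    ).reset_index(drop=True)


def select_correlated_genes(
    rows: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Nominal-alpha selection: (positively, negatively) correlated genes."""
    if rows.empty:
        raise ValueError("empty gene association table")
    sig = rows["p"] < alpha
    positive = rows.loc[sig & (rows["rho"] > 0), "gene"].tolist()
    negative = rows.loc[sig & (rows["rho"] < 0), "gene"].tolist()
    return positive, negative


def ora_enrichment(
    selected: Sequence[str],
    gene_sets: dict[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided over-representation test of a gene selection.

    For each set, the overlap with ``selected`` is tested against the
    hypergeometric null (draw ``len(selected)`` genes from the universe;
    upper tail), equivalent to a one-sided Fisher exact test.  The
    background universe is the measured gene list (all genes on the
    expression matrix); sets are intersected with it first.
    Benjamini-Hochberg FDR is applied across the collection; rows come back
    sorted by p.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    selected_set = set(selected) & universe_set
    if not selected_set:
        raise ValueError("empty gene selection (after intersecting with the universe)")
    if not set(selected) <= universe_set:
        raise ValueError("selected genes must be a subset of the universe")
    m = len(universe_set)
    n_sel = len(selected_set)
    rows = []
    for name, genes in gene_sets.items():
        gs = set(genes) & universe_set
        k = len(gs & selected_set)
        p = float(stats.hypergeom.sf(k - 1, m, len(gs), n_sel)) if gs else 1.0
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": len(gs),
                "selected_size": n_sel,
                "universe_size": m,
                "p": min(max(p, 0.0), 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT gene-set I/O

def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file (set name, description, then member genes per line)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, Sequence[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
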