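"""Functional-gene abundance vs activity regressions and environment correlations.

qPCR copy numbers of nitrogen-cycle marker genes (archaeal and bacterial amoA
— AOA/AOB — and the denitrification genes narG, nirK, nirS, nosZ clades I/II)
are regressed against total and guild-partitioned enzyme activities. The
working hypothesis is that a marker tracks the activity of its own guild more
tightly than the bulk rate: AOA should predict archaeal nitrification better
than total nitrification, and so on.

Gene copies span zero to ~1e9 per gram across sites, so abundances enter the
regressions on a log10(copies + 1) scale by default; activities enter
untransformed, paired at site level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError
from .partition import GuildPartition

GENES = ("AOA", "AOB", "narG", "nirK", "nirS", "nosZ", "nosZII", "FnirK")

#: Default gene → activity pairings: each gene against the bulk activity and
#: against its guild-matched component.
DEFAULT_PAIRS: dict[str, tuple[str, ...]] = {
    "AOA": ("TNEA", "ANEA"),
    "AOB": ("TNEA", "BNEA"),
    "narG": ("TDEA", "BDEA"),
    "nirK": ("TDEA", "BDEA"),
}

#: Activity-name prefix per guild component, suffixed with NEA/DEA by assay.
_COMPONENT_CODE = {"total": "T", "bacterial": "B", "fungal": "F", "archaeal": "A"}


@dataclass(frozen=True)
class RegressionResult:
    gene: str
    activity_name: str
    slope: float | None
    intercept: float | None
    r_squared: float | None
    p_value: float | None
    n: int
    transform: str
    degenerate: bool = False


def transform_abundance(copies: Sequence[float], mode: str = "log10_plus1"):
    """Transform gene copy numbers for regression.

    Returns ``(values, n_excluded)``: under ``log10_positive`` zeros are
    dropped (and counted); ``log10_plus1`` keeps them at 0; ``identity``
    passes through.
    """
    x = np.asarray(copies, dtype=float)
    if np.any(x < 0):
        raise InvalidInputError("gene copies must be >= 0")
    if mode == "log10_plus1":
        return np.log10(x + 1.0), 0
    if mode == "log10_positive":
        kept = x[x > 0]
        return np.log10(kept), int((x == 0).sum())
    if mode == "identity":
        return x, 0
    raise InvalidInputError(f"unknown transform {mode!r}")


def activity_table(partitions: Sequence[GuildPartition]) -> pd.DataFrame:
    """Tidy site-level activity table with field-standard names.

    Columns: site_id, activity (TNEA/BNEA/FNEA/ANEA or TDEA/...), value.
    Clamped component values are used, matching the reported activities.
    """
    rows = []
    for p in partitions:
        suffix = "NEA" if p.assay == "nitrification" else "DEA"
        rows.append({"site_id": p.site_id, "activity": f"T{suffix}", "value": p.total})
        for comp, code in _COMPONENT_CODE.items():
            if comp == "total":
                continue
            rows.append(
                {"site_id": p.site_id, "activity": f"{code}{suffix}", "value": p.clamped[comp]}
            )
    return pd.DataFrame(rows)


def regress_gene_on_activity(
    genes: pd.DataFrame,
    activities: pd.DataFrame,
    pairs: Mapping[str, tuple[str, ...]] | None = None,
    transform: str = "log10_plus1",
    pooling: str = "site_mean",
    bh_correct: bool = False,
) -> list[RegressionResult]:
    """OLS of activity on transformed gene abundance for each configured pair.

    ``genes`` is tidy (site_id, replicate_id, gene, copies); ``activities``
    comes from :func:`activity_table`. Pairing is at site level: site-mean
    abundances against site-level activities (``pooling='site_mean'``), or
    replicate-level abundances each paired with their site's activity
    (``pooling='replicates'``). A constant predictor yields a degenerate
    record with missing statistics rather than an error, so one flat gene
    does not abort a batch.
    """
    if pooling not in ("site_mean", "replicates"):
        raise InvalidInputError(f"unknown pooling {pooling!r}")
    pairs = DEFAULT_PAIRS if pairs is None else pairs
    act = activities.pivot_table(index="site_id", columns="activity", values="value")
    results: list[RegressionResult] = []
    for gene, activity_names in pairs.items():
        sub = genes[genes["gene"] == gene]
        if sub.empty:
            continue
        if pooling == "site_mean":
            per_site = sub.groupby("site_id")["copies"].mean()
        else:
            per_site = sub.set_index("site_id")["copies"]
        for name in activity_names:
            if name not in act.columns:
                continue
            joined = pd.DataFrame({"copies": per_site}).join(act[name], how="inner").dropna()
            y = joined[name].to_numpy(dtype=float)
            x_raw = joined["copies"].to_numpy(dtype=float)
            if transform == "log10_positive":
                keep = x_raw > 0
                x_raw, y = x_raw[keep], y[keep]
            x, _ = transform_abundance(x_raw, transform)
            n = len(x)
            if n < 3:
                continue
            if np.ptp(x) == 0.0:
                results.append(
                    RegressionResult(gene, name, None, None, None, None, n, transform, True)
                )
                continue
            fit = stats.linregress(x, y)
            results.append(
                RegressionResult(
                    gene,
                    name,
                    float(fit.slope),
                    float(fit.intercept),
                    float(fit.rvalue**2),
                    float(fit.pvalue),
                    n,
                    transform,
                )
            )
    if bh_correct:
        idx = [i for i, r in enumerate(results) if r.p_value is not None]
        if idx:
            adj = multipletests([results[i].p_value for i in idx], method="fdr_bh")[1]
            for i, p in zip(idx, adj):
                r = results[i]
                results[i] = RegressionResult(
                    r.gene, r.activity_name, r.slope, r.intercept, r.r_squared,
                    float(p), r.n, r.transform, r.degenerate,
                )
    return results


def regressions_to_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def _stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def correlation_matrix(
    genes: pd.DataFrame,
    environment: pd.DataFrame,
    transform: str = "log10_plus1",
) -> pd.DataFrame:
    """Pearson correlations of transformed gene abundances vs site covariates.

    Returns a tidy frame (gene, variable, r, p, stars, n); pairs with fewer
    than 3 complete site rows or an all-missing covariate column are omitted.
    Stars follow the p < 0.10 / 0.05 / 0.01 convention.
    """
    env = environment.set_index("site_id")
    rows = []
    for gene, sub in genes.groupby("gene"):
        per_site = sub.groupby("site_id")["copies"].mean()
        x_all, _ = transform_abundance(per_site.to_numpy(), "log10_plus1" if transform != "identity" else "identity")
        x_series = pd.Series(x_all, index=per_site.index)
        for var in env.columns:
            joined = pd.DataFrame({"x": x_series, "y": env[var]}).dropna()
            if len(joined) < 3:
                continue
            if joined["x"].nunique() < 2 or joined["y"].nunique() < 2:
                continue
            r, p = stats.pearsonr(joined["x"], joined["y"])
            rows.append(
                {"gene": gene, "variable": var, "r": float(r), "p": float(p),
                 "stars": _stars(float(p)), "n": len(joined)}
            )
    return pd.DataFrame(rows)
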