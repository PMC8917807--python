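"""Complex-level co-expression, stability classes, paralog content and nulls.

Complex variability is 1 - median pairwise Pearson correlation among the
complex's quantified members.  Complexes in the top quartile of median R are
classified stable, the bottom quartile variable, the rest intermediate.
Paralog content is the fraction of members with at least one paralog — in the
genome, or within the same complex for the stricter variant.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import DEFAULT_MIN_OBS
from .io import ComplexCatalog, ExpressionDataset, GenePair, ValidationError

STABLE = "stable"
VARIABLE = "variable"
INTERMEDIATE = "intermediate"

DEFAULT_MIN_MEMBERS = 5


def _member_corr(
    dataset: ExpressionDataset, members: Sequence[str], min_obs: int
) -> pd.DataFrame:
    present = [g for g in members if g in dataset.values.index]
    sub = dataset.values.loc[present].T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return sub.corr(min_periods=max(min_obs, 2))


def _pairwise_upper(corr: pd.DataFrame) -> np.ndarray:
    vals = corr.to_numpy()
    iu = np.triu_indices(len(corr), k=1)
    return vals[iu]


def complex_coexpression(
    dataset: ExpressionDataset,
    catalog: ComplexCatalog,
    min_members: int = DEFAULT_MIN_MEMBERS,
    min_obs: int = DEFAULT_MIN_OBS,
) -> pd.DataFrame:
    """Median pairwise member correlation per complex.

    Complexes with fewer than ``min_members`` quantified members are excluded.
    A pairwise R enters the median only if itself defined (enough
    pairwise-complete observations); the complex is scored only when at least
    half of C(min_members, 2) pairwise correlations are defined.

    Returns columns complex_id, n_quantified, n_pairs_defined, median_R,
    variability.
    """
    if len(catalog) == 0:
        raise ValidationError("empty complex catalog")
    min_defined = math.comb(min_members, 2) / 2.0
    rows = []
    idx = set(dataset.values.index)
    for cid, members in sorted(catalog.items()):
        present = [g for g in members if g in idx]
        if len(present) < min_members:
            continue
        corr = _member_corr(dataset, present, min_obs)
        pair_r = _pairwise_upper(corr)
        defined = pair_r[~np.isnan(pair_r)]
        if len(defined) < min_defined:
            continue
        med = float(np.median(defined))
        rows.append((cid, len(present), len(defined), med, 1.0 - med))
    return pd.DataFrame(
        rows, columns=["complex_id", "n_quantified", "n_pairs_defined",
                       "median_R", "variability"]
    )


def classify_complex_stability(summaries: pd.DataFrame) -> pd.DataFrame:
    """Assign stable/variable/intermediate by quartiles of median_R.

    Top quartile (median_R > Q3) → stable, bottom quartile (median_R < Q1) →
    variable; boundary ties fall to intermediate.  With fewer than 4 scored
    complexes everything is intermediate (a warning is emitted).
    """
    out = summaries.copy()
    scored = out["median_R"].dropna()
    if len(scored) < 4:
        warnings.warn("fewer than 4 scored complexes; all classed intermediate")
        out["stability_class"] = INTERMEDIATE
        return out
    q1, q3 = np.quantile(scored, [0.25, 0.75])
    cls = np.where(
        out["median_R"] > q3, STABLE,
        np.where(out["median_R"] < q1, VARIABLE, INTERMEDIATE),
    )
    out["stability_class"] = np.where(out["median_R"].isna(), INTERMEDIATE, cls)
    return out


def paralog_content(
    members: Iterable[str],
    has_paralog: Mapping[str, bool] | None = None,
    pairs: Iterable[GenePair] | None = None,
    scope: str = "genome",
) -> float:
    """Fraction of complex members with at least one paralog.

    ``scope="genome"`` uses precomputed ``has_paralog`` flags; ``scope=
    "same_complex"`` counts members whose paralog partner (from ``pairs``) is
    itself a member of the complex.
    """
    members = list(members)
    if not members:
        raise ValidationError("empty complex")
    if scope == "genome":
        if has_paralog is None:
            raise ValidationError("genome scope requires has_paralog flags")
        flagged = sum(bool(has_paralog.get(g, False)) for g in members)
    elif scope == "same_complex":
        if pairs is None:
            raise ValidationError("same_complex scope requires pairs")
        mem = set(members)
        partners: dict[str, bool] = {g: False for g in members}
        for p in pairs:
            if p.gene_a in mem and p.gene_b in mem:
                partners[p.gene_a] = True
                partners[p.gene_b] = True
        flagged = sum(partners.values())
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    return flagged / len(members)


def add_paralog_content(
    summaries: pd.DataFrame,
    catalog: ComplexCatalog,
    has_paralog: Mapping[str, bool],
) -> pd.DataFrame:
    out = summaries.copy()
    out["paralog_content"] = [
        paralog_content(catalog[cid], has_paralog=has_paralog)
        for cid in out["complex_id"]
    ]
    return out


def content_variability_relation(
    summaries: pd.DataFrame,
    exclude_dimers: bool = False,
    exclude_all_paralog: bool = False,
) -> tuple[float, float]:
    """Pearson correlation (R, two-sided p) of variability vs paralog content.

    Optional filters drop heterodimers (2 quantified members) and complexes
    composed entirely of paralog-bearing genes (content = 1).
    """
    df = summaries.dropna(subset=["variability", "paralog_content"])
    if exclude_dimers:
        df = df[df["n_quantified"] > 2]
    if exclude_all_paralog:
        df = df[df["paralog_content"] < 1.0]
    if len(df) < 3:
        raise ValidationError("need at least 3 complexes")
    if df["paralog_content"].nunique() < 2 or df["variability"].nunique() < 2:
        return float("nan"), float("nan")
    res = stats.pearsonr(df["paralog_content"], df["variability"])
    return float(res.statistic), float(res.pvalue)


def subunit_median_correlation(
    dataset: ExpressionDataset,
    catalog: ComplexCatalog,
    min_members: int = DEFAULT_MIN_MEMBERS,
    min_obs: int = DEFAULT_MIN_OBS,
) -> pd.DataFrame:
    """Per-subunit median correlation with the other members of its complex.

    Columns: complex_id, gene, median_R, n_partners.
    """
    idx = set(dataset.values.index)
    rows = []
    for cid, members in sorted(catalog.items()):
        present = [g for g in members if g in idx]
        if len(present) < min_members:
            continue
        corr = _member_corr(dataset, present, min_obs)
        for g in present:
            others = corr.loc[g].drop(index=g).dropna()
            if len(others):
                rows.append((cid, g, float(others.median()), len(others)))
    return pd.DataFrame(rows, columns=["complex_id", "gene", "median_R", "n_partners"])


def random_complex_null(
    dataset: ExpressionDataset,
    catalog: ComplexCatalog,
    n_reps: int = 100,
    seed: int = 0,
    min_members: int = DEFAULT_MIN_MEMBERS,
    min_obs: int = DEFAULT_MIN_OBS,
) -> np.ndarray:
    """Null median_R distribution from randomly assembled pseudo-complexes.

    Each replicate redraws genes (without replacement within the replicate)
    into pseudo-complexes matching the real catalog's quantified-size
    spectrum, then scores them exactly as :func:`complex_coexpression`.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    idx = list(dataset.values.index)
    sizes = [
        n for n in (
            sum(g in set(idx) for g in members) for _, members in sorted(catalog.items())
        ) if n >= min_members
    ]
    if not sizes:
        raise ValidationError("no complex passes the member filter")
    if max(sizes) > len(idx):
        raise ValidationError("dataset smaller than largest complex")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        if sum(sizes) <= len(idx):
            chosen = rng.choice(len(idx), size=sum(sizes), replace=False)
            pos = 0
            for n in sizes:
                members = [idx[i] for i in chosen[pos : pos + n]]
                pos += n
                out.append(_pseudo_median_r(dataset, members, min_obs))
        else:
            for n in sizes:
                members = [idx[i] for i in rng.choice(len(idx), size=n, replace=False)]
                out.append(_pseudo_median_r(dataset, members, min_obs))
    return np.asarray([v for v in out if not np.isnan(v)])


def _pseudo_median_r(
    dataset: ExpressionDataset, members: Sequence[str], min_obs: int
) -> float:
    corr = _member_corr(dataset, members, min_obs)
    pair_r = _pairwise_upper(corr)
    defined = pair_r[~np.isnan(pair_r)]
    return float(np.median(defined)) if len(defined) else float("nan")
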