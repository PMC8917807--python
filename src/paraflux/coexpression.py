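"""Pairwise co-expression of paralog pairs and divergence classification.

A paralog pair is *divergent* when the Pearson correlation of its two
expression profiles across conditions/tissues is R <= 0, and *co-regulated*
when R > 0.  Correlations use pairwise-complete observations and are reported
as missing below ``min_obs`` observed samples (default 5) or for constant
series.  The delta score contrasts protein- and transcript-level
co-expression of the same pair: delta = R_protein - R_rna.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ComplexCatalog, ExpressionDataset, GenePair, ValidationError

CO_REGULATED = "co-regulated"
DIVERGENT = "divergent"

DEFAULT_MIN_OBS = 5


def pair_correlation(
    x: Sequence[float], y: Sequence[float], min_obs: int = DEFAULT_MIN_OBS
) -> tuple[float, int]:
    """Pearson R over pairwise-complete observations.

    Returns ``(R, n_obs)``; R is NaN when fewer than ``min_obs`` complete
    observations remain or either series is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("series length mismatch")
    mask = ~(np.isnan(x) | np.isnan(y))
    n_obs = int(mask.sum())
    if n_obs < max(min_obs, 2):
        return float("nan"), n_obs
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan"), n_obs
    r = stats.pearsonr(xs, ys).statistic
    return float(r), n_obs


def classify_divergence(r: float) -> str | None:
    """R > 0 → co-regulated; R <= 0 → divergent; missing R → None."""
    if r is None or np.isnan(r):
        return None
    return CO_REGULATED if r > 0 else DIVERGENT


def coefficient_of_variation(
    x: Sequence[float], min_obs: int = DEFAULT_MIN_OBS
) -> float:
    """CV = sample sd / mean over observed linear-scale abundances.

    Missing when fewer than ``min_obs`` observations or the mean is zero;
    negative values are rejected (linear abundances are non-negative).
    """
    x = np.asarray(x, dtype=float)
    obs = x[~np.isnan(x)]
    if (obs < 0).any():
        raise ValidationError("negative abundances on linear scale")
    if len(obs) < min_obs:
        return float("nan")
    mean = obs.mean()
    if mean == 0:
        return float("nan")
    return float(obs.std(ddof=1) / mean)


def pair_coexpression_table(
    dataset: ExpressionDataset,
    pairs: Iterable[GenePair],
    layer: str | None = None,
    min_obs: int = DEFAULT_MIN_OBS,
    catalog: ComplexCatalog | None = None,
) -> pd.DataFrame:
    """Per-pair co-expression records for one expression layer.

    Columns: gene_a, gene_b, mean_identity, layer, R, n_obs, category,
    same_complex.  Pairs with a gene absent from the dataset get missing R.
    ``same_complex`` is True when both genes co-occur in at least one complex
    of ``catalog``.
    """
    values = dataset.values
    layer_label = layer or str(dataset.meta["layer"].iloc[0])
    rows = []
    idx = set(values.index)
    same_complex_lookup = _same_complex_sets(catalog) if catalog else None
    for p in pairs:
        if p.gene_a in idx and p.gene_b in idx:
            r, n = pair_correlation(
                values.loc[p.gene_a].to_numpy(),
                values.loc[p.gene_b].to_numpy(),
                min_obs=min_obs,
            )
        else:
            r, n = float("nan"), 0
        same = (
            bool(same_complex_lookup and (p.gene_a, p.gene_b) in same_complex_lookup)
        )
        rows.append(
            (p.gene_a, p.gene_b, p.mean_identity, layer_label, r, n,
             classify_divergence(r), same)
        )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "mean_identity", "layer", "R", "n_obs",
                 "category", "same_complex"],
    )


def _same_complex_sets(catalog: ComplexCatalog) -> set[tuple[str, str]]:
    out: set[tuple[str, str]] = set()
    for _, members in catalog.items():
        mem = sorted(members)
        for i, a in enumerate(mem):
            for b in mem[i + 1:]:
                out.add((a, b))
    return out


def divergent_fraction(records: pd.DataFrame) -> float:
    """Fraction of pairs with defined R classified divergent."""
    defined = records["category"].dropna()
    if defined.empty:
        return float("nan")
    return float((defined == DIVERGENT).mean())


def random_pair_null(
    dataset: ExpressionDataset,
    n_draws: int = 10_000,
    seed: int = 0,
    min_obs: int = DEFAULT_MIN_OBS,
) -> np.ndarray:
    """Null distribution of R for uniformly sampled distinct gene pairs."""
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    genes = dataset.values.index
    if len(genes) < 2:
        raise ValidationError("fewer than 2 genes")
    rng = np.random.default_rng(seed)
    vals = dataset.values.to_numpy()
    out = np.empty(n_draws)
    for k in range(n_draws):
        i, j = rng.choice(len(genes), size=2, replace=False)
        out[k], _ = pair_correlation(vals[i], vals[j], min_obs=min_obs)
    return out


def identity_bin_compare(
    records: pd.DataFrame, bin_edges: Sequence[float]
) -> pd.DataFrame:
    """Same-complex vs other-pair R within reciprocal-identity bins.

    Bins are left-closed ``[edge, next)``; the last bin includes its right
    edge.  Each row reports the two group sizes, median R's, and a two-sided
    rank-sum (Mann-Whitney) p; bins with <2 observations on a side are marked
    untestable (p = NaN).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if not (np.diff(edges) > 0).all():
        raise ValidationError("bin edges must be increasing")
    df = records.dropna(subset=["R", "mean_identity"])
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        sel = (df["mean_identity"] >= lo) & (
            (df["mean_identity"] <= hi) if last else (df["mean_identity"] < hi)
        )
        sub = df[sel]
        in_cpx = sub.loc[sub["same_complex"], "R"]
        other = sub.loc[~sub["same_complex"], "R"]
        if len(in_cpx) >= 2 and len(other) >= 2:
            p = float(stats.mannwhitneyu(in_cpx, other, alternative="two-sided").pvalue)
        else:
            p = float("nan")
        rows.append(
            (lo, hi, len(in_cpx), len(other),
             float(in_cpx.median()) if len(in_cpx) else float("nan"),
             float(other.median()) if len(other) else float("nan"), p)
        )
    return pd.DataFrame(
        rows,
        columns=["bin_lo", "bin_hi", "n_same_complex", "n_other",
                 "median_R_same_complex", "median_R_other", "p"],
    )


def transcript_protein_delta(
    records_rna: pd.DataFrame, records_protein: pd.DataFrame
) -> pd.DataFrame:
    """Per-pair delta = R_protein - R_rna; pairs missing either layer are omitted."""
    key = ["gene_a", "gene_b"]
    merged = records_rna[key + ["R"]].merge(
        records_protein[key + ["R"]], on=key, suffixes=("_rna", "_protein")
    )
    merged = merged.dropna(subset=["R_rna", "R_protein"])
    merged["delta"] = merged["R_protein"] - merged["R_rna"]
    return merged.reset_index(drop=True)
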