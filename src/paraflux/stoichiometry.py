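"""Stoichiometric stability of complex subunits from fold changes.

For each subunit of a quantified complex, the median Euclidean distance in
log2 fold-change space between the subunit and its co-members is compared
with a null distribution of 2,500 distances from randomly assembled complexes
of the same size.  The empirical probability of observing a lower distance,

    p = (#{null < observed} + 1) / (n_null + 1),

is low for subunits tightly co-regulated with their complex (stoichiometric
stability) and high for outliers.  A complex-level co-expression score is
1 - median of the member p's.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ComplexCatalog, ExpressionDataset, ValidationError

DEFAULT_N_NULL = 2500
DEFAULT_MIN_MEMBERS = 5


def fold_changes(
    dataset: ExpressionDataset, reference: str | None = None
) -> pd.DataFrame:
    """Per-gene mean log2 fold change of every condition vs the reference.

    The reference defaults to the dataset's first condition.  Returns a gene x
    comparison frame; comparison labels are ``"<cond>_vs_<ref>"``.
    """
    if dataset.scale != "log2":
        raise ValidationError("fold changes require log2-scale data")
    conds = dataset.conditions()
    ref = reference if reference is not None else conds[0]
    if ref not in conds:
        raise ValidationError(f"unknown reference condition {ref!r}")
    meta = dataset.meta
    ref_cols = meta.index[meta["condition"] == ref]
    ref_mean = dataset.values[ref_cols].mean(axis=1)
    out = {}
    for cond in conds:
        if cond == ref:
            continue
        cols = meta.index[meta["condition"] == cond]
        out[f"{cond}_vs_{ref}"] = dataset.values[cols].mean(axis=1) - ref_mean
    return pd.DataFrame(out)


def median_fc_distance(
    subunit_fc: Sequence[float], member_fcs: Sequence[Sequence[float]]
) -> float:
    """Median Euclidean fold-change distance from a subunit to its co-members.

    Vectors are aligned on the same comparisons; for a single comparison the
    distance reduces to the absolute difference.
    """
    sub = np.atleast_1d(np.asarray(subunit_fc, dtype=float))
    members = np.atleast_2d(np.asarray(member_fcs, dtype=float))
    if members.size == 0:
        raise ValidationError("empty co-member set")
    if members.shape[1] != sub.shape[0]:
        raise ValidationError("comparison axes misaligned")
    dists = np.linalg.norm(members - sub[None, :], axis=1)
    return float(np.median(dists))


def _null_distances(
    fc: np.ndarray, size: int, n_null: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distances for random complexes of a given size.

    Each draw assembles a pseudo-complex of ``size`` distinct quantified genes
    and records one member's median distance to the others.
    """
    n_genes = fc.shape[0]
    if n_genes < size:
        raise ValidationError("too few quantified genes for the pseudo-complexes")
    out = np.empty(n_null)
    for k in range(n_null):
        pick = rng.choice(n_genes, size=size, replace=False)
        out[k] = median_fc_distance(fc[pick[0]], fc[pick[1:]])
    return out


def subunit_stability_p(
    fc_table: pd.DataFrame,
    catalog: ComplexCatalog,
    n_null: int = DEFAULT_N_NULL,
    min_members: int = DEFAULT_MIN_MEMBERS,
    seed: int = 0,
    comparisons: Sequence[str] | None = None,
    strict: bool = True,
    pool_by_size: bool = True,
) -> pd.DataFrame:
    """Empirical stability p per subunit, per comparison.

    ``fc_table`` is a gene x comparison frame of log2 fold changes (see
    :func:`fold_changes`).  The null pools ``n_null`` distances per complex
    size class (``pool_by_size=True``, the default) or draws a fresh null per
    subunit.  ``strict`` counts null distances strictly below the observed
    one, matching the probability of observing *lower* distances; the ``<=``
    variant is available for sensitivity analysis.

    Returns columns gene, complex_id, comparison, median_distance, p, n_null.
    """
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    comparisons = list(comparisons) if comparisons is not None else list(fc_table.columns)
    rng = np.random.default_rng(seed)
    rows = []
    gene_index = {g: i for i, g in enumerate(fc_table.index)}
    for comp in comparisons:
        col = fc_table[comp].dropna()
        fc = col.to_numpy()[:, None]
        quantified = set(col.index)
        local_index = {g: i for i, g in enumerate(col.index)}
        null_cache: dict[int, np.ndarray] = {}
        for cid, members in sorted(catalog.items()):
            present = sorted(g for g in members if g in quantified)
            n = len(present)
            if n < min_members:
                continue
            if pool_by_size:
                if n not in null_cache:
                    null_cache[n] = np.sort(
                        _null_distances(fc, n, n_null, rng)
                    )
                null = null_cache[n]
            else:
                null = np.sort(_null_distances(fc, n, n_null, rng))
            rows_fc = fc[[local_index[g] for g in present]]
            for i, g in enumerate(present):
                obs = median_fc_distance(
                    rows_fc[i], np.delete(rows_fc, i, axis=0)
                )
                side = "left" if strict else "right"
                lower = int(np.searchsorted(null, obs, side=side))
                p = (lower + 1) / (n_null + 1)
                rows.append((g, cid, comp, obs, p, n_null))
    return pd.DataFrame(
        rows, columns=["gene", "complex_id", "comparison", "median_distance",
                       "p", "n_null"]
    )


def complex_coexpression_score(stability: pd.DataFrame) -> pd.DataFrame:
    """Complex-level co-expression score: 1 - median member p, per comparison."""
    grouped = (
        stability.groupby(["complex_id", "comparison"])["p"]
        .median()
        .rename("median_p")
        .reset_index()
    )
    grouped["coexpression_score"] = 1.0 - grouped["median_p"]
    return grouped
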