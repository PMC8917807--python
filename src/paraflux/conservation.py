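"""Cross-species conserved paralog-substitution signature.

The pipeline works in ratio space: for every paralog pair the per-sample
log2 ratio log2(A) - log2(B) is computed wherever both genes are quantified,
changes in the ratio relative to the first condition of each time course are
tested with a moderated t (empirical-Bayes variance shrinkage), gene pairs
are aggregated to orthogroup pairs, per-comparison p-values are combined
across species with Fisher's method, and a pair is called *conserved* when it
is quantified in all species, its ratio changes share the majority sign in at
least 5 of the 7 comparisons, and the BH-adjusted combined p is <= 0.05.

Moderated t
-----------
Per pair and comparison the pooled two-sample variance s^2 with d residual
degrees of freedom is shrunk toward a prior s0^2 with d0 prior degrees of
freedom estimated from the ensemble of per-pair variances by the method of
moments (the marginal law of s^2 is a scaled F(d, d0)):

    s^2_post = (d0 * s0^2 + d * s^2) / (d0 + d),
    t = delta / (s_post * sqrt(1/n1 + 1/n2)),   df = d0 + d.

``d0 = 0`` recovers the ordinary two-sample t; when the moment equations have
no positive solution the prior is taken as infinitely informative
(s_post = s0, the ensemble mean variance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import adjust_pvalues
from .io import ExpressionDataset, GenePair, OrthogroupMap, ValidationError

DEFAULT_MIN_CONSISTENT = 5
DEFAULT_N_COMPARISONS = 7
DEFAULT_ALPHA = 0.05

_MAX_DF = 1e6  # stands in for an infinite-df (normal) reference


def ratio_profiles(
    dataset: ExpressionDataset, pairs: Iterable[GenePair]
) -> pd.DataFrame:
    """Per-sample log2 paralog ratios, one row per pair.

    Rows are indexed by (gene_a, gene_b); the ratio is log2(A) - log2(B) and
    is missing wherever either gene is unquantified in that sample.
    """
    if dataset.scale != "log2":
        raise ValidationError("ratio profiles require log2-scale data")
    vals = dataset.values
    idx = set(vals.index)
    keys, rows = [], []
    for p in pairs:
        if p.gene_a in idx and p.gene_b in idx:
            keys.append((p.gene_a, p.gene_b))
            rows.append(vals.loc[p.gene_a].to_numpy() - vals.loc[p.gene_b].to_numpy())
    out = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(keys, names=["gene_a", "gene_b"]),
        columns=vals.columns,
    )
    return out


@dataclass(frozen=True)
class VariancePrior:
    """Empirical-Bayes variance prior (d0 prior df, s0^2 prior variance)."""

    d0: float
    s0_sq: float


def estimate_variance_prior(s_sq: Sequence[float], d: float) -> VariancePrior:
    """Method-of-moments (d0, s0^2) from an ensemble of pooled variances.

    Matches the first two moments of the scaled-F marginal of the variances.
    Falls back to d0 = inf (full shrinkage to the mean variance) when the
    moment equations admit no solution with d0 > 4.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[~np.isnan(s_sq)]
    if len(s_sq) < 2:
        return VariancePrior(np.inf, float(np.mean(s_sq)) if len(s_sq) else np.nan)
    m = float(np.mean(s_sq))
    v = float(np.var(s_sq, ddof=1))
    if m <= 0 or v <= 0:
        return VariancePrior(np.inf, m)
    r = v / m**2
    denom = r * d - 2.0
    if denom <= 0:
        return VariancePrior(np.inf, m)
    d0 = (2.0 * d - 4.0 + 4.0 * r * d) / denom
    if d0 <= 4.0 or not np.isfinite(d0):
        return VariancePrior(np.inf, m)
    s0_sq = m * (d0 - 2.0) / d0
    return VariancePrior(float(d0), float(s0_sq))


def ratio_change_test(
    profiles: pd.DataFrame,
    meta: pd.DataFrame,
    species: str,
    reference: str | None = None,
    design: Sequence[tuple[str, str]] | None = None,
    d0: float | None = None,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Moderated-t test of paralog-ratio changes between conditions.

    ``profiles`` is the output of :func:`ratio_profiles`; ``meta`` the sample
    metadata of the same dataset.  The tested contrasts are, in order of
    precedence: the explicit ``design`` list of (reference_condition,
    condition) tuples; per-comparison references named ``"<cond>_ref"`` when
    present (independently acquired contrasts); otherwise every non-first
    condition against the first (time-course convention).  p-values are
    BH-adjusted within each comparison.  ``d0`` forces a fixed prior df
    (0 = ordinary t); by default the prior is estimated from the ensemble of
    per-pair variances of each comparison.

    Returns columns gene_a, gene_b, species, comparison, delta, t, df, p,
    adj_p, n_ref, n_cond.
    """
    sample_cond = meta.loc[profiles.columns, "condition"].astype(str)
    conds: list[str] = []
    for c in sample_cond:
        if c not in conds:
            conds.append(c)
    if design is None:
        refs = {c for c in conds if c.endswith("_ref")}
        if reference is None and refs:
            design = [
                (f"{c}_ref", c) for c in conds
                if c not in refs and f"{c}_ref" in refs
            ]
        else:
            ref = reference if reference is not None else conds[0]
            if ref not in conds:
                raise ValidationError(f"unknown reference condition {ref!r}")
            design = [(ref, c) for c in conds if c != ref]
    frames = []
    for ref, cond in design:
        if ref not in conds or cond not in conds:
            raise ValidationError(f"unknown condition in contrast ({ref},{cond})")
        label = cond if ref == f"{cond}_ref" else f"{cond}_vs_{ref}"
        ref_mat = profiles.loc[:, sample_cond[sample_cond == ref].index].to_numpy()
        cond_mat = profiles.loc[:, sample_cond[sample_cond == cond].index].to_numpy()
        frames.append(
            _moderated_two_sample(
                ref_mat, cond_mat, profiles.index, species, label,
                d0=d0, adjust=adjust,
            )
        )
    if not frames:
        raise ValidationError("no contrast to test")
    return pd.concat(frames, ignore_index=True)


def _moderated_two_sample(
    ref: np.ndarray,
    cond: np.ndarray,
    index: pd.MultiIndex,
    species: str,
    comparison: str,
    d0: float | None,
    adjust: str,
) -> pd.DataFrame:
    n1 = np.sum(~np.isnan(ref), axis=1)
    n2 = np.sum(~np.isnan(cond), axis=1)
    testable = (n1 >= 2) & (n2 >= 2)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(np.where(n1[:, None] > 0, ref, np.nan), axis=1)
        m2 = np.nanmean(np.where(n2[:, None] > 0, cond, np.nan), axis=1)
        ss1 = np.nansum((ref - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((cond - m2[:, None]) ** 2, axis=1)
    delta = m2 - m1
    d = n1 + n2 - 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        s_sq = np.where(testable, (ss1 + ss2) / d, np.nan)

    if not testable.any():
        prior = VariancePrior(np.inf, float("nan"))
    elif d0 is None:
        prior = estimate_variance_prior(s_sq[testable], float(np.median(d[testable])))
    else:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            prior = VariancePrior(float(d0), float(np.nanmean(s_sq)))
    d0_eff = prior.d0 if np.isfinite(prior.d0) else _MAX_DF
    if prior.d0 == 0:
        s_post = np.sqrt(s_sq)
        df_total = d
    else:
        s_post = np.sqrt((d0_eff * prior.s0_sq + d * s_sq) / (d0_eff + d))
        df_total = d0_eff + d
    se = s_post * np.sqrt(1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.inf))
    p = np.where(testable, 2.0 * stats.t.sf(np.abs(t), df_total), np.nan)
    p = np.minimum(p, 1.0)
    adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        adj[ok] = adjust_pvalues(p[ok], method=adjust)
    return pd.DataFrame(
        {
            "gene_a": index.get_level_values("gene_a"),
            "gene_b": index.get_level_values("gene_b"),
            "species": species,
            "comparison": comparison,
            "delta": delta,
            "t": np.where(testable, t, np.nan),
            "df": np.where(testable, df_total, np.nan),
            "p": p,
            "adj_p": adj,
            "n_ref": n1,
            "n_cond": n2,
        }
    )


def aggregate_to_orthogroups(
    changes: pd.DataFrame, ogmap: OrthogroupMap
) -> pd.DataFrame:
    """Map gene pairs to orthogroup pairs, averaging deltas and p-values.

    Pairs with an unmapped gene are dropped; when several gene pairs map to
    the same orthogroup pair within one comparison, the arithmetic means of
    the ratio differences and of the p-values are taken.  Orthogroup pairs
    are canonically ordered, negating the delta when the orientation flips.
    Pairs whose two genes map to the same orthogroup are dropped (their
    orientation is undefined).
    """
    rows = []
    for sp, sub in changes.groupby("species"):
        lut = ogmap.lookup(str(sp))
        og_a = sub["gene_a"].map(lut)
        og_b = sub["gene_b"].map(lut)
        keep = og_a.notna() & og_b.notna() & (og_a != og_b)
        sub = sub.loc[keep].copy()
        a, b = og_a[keep].to_numpy(), og_b[keep].to_numpy()
        flip = a > b
        sub["og_a"] = np.where(flip, b, a)
        sub["og_b"] = np.where(flip, a, b)
        sub["delta"] = np.where(flip, -sub["delta"], sub["delta"])
        rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=["og_a", "og_b", "species", "comparison", "delta", "p"]
        )
    allsub = pd.concat(rows, ignore_index=True)
    out = (
        allsub.groupby(["og_a", "og_b", "species", "comparison"], as_index=False)
        .agg(delta=("delta", "mean"), p=("p", "mean"))
    )
    return out


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: X^2 = -2 sum(ln p) ~ chi^2_{2k}."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise ValidationError("no p-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0,1]")
    x2 = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x2, 2 * len(p)))


def conserved_signature(
    og_changes: pd.DataFrame,
    n_species: int | None = None,
    min_consistent: int = DEFAULT_MIN_CONSISTENT,
    n_comparisons: int = DEFAULT_N_COMPARISONS,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Call conserved paralog substitutions from orthogroup-level ratio changes.

    Per orthogroup pair: orient so the summed delta over quantified
    comparisons is positive (positive ratios prioritized), count comparisons
    whose delta shares that majority sign (exact zeros are inconsistent),
    Fisher-combine the per-comparison p-values, BH-adjust the combined p
    across pairs, and require presence in all species, at least
    ``min_consistent`` consistent comparisons and adjusted combined
    p <= ``alpha``.

    Returns one row per orthogroup pair with per-comparison delta columns
    (``delta:<comparison>``), n_species_present, n_quantified,
    n_sign_consistent, combined_p, adj_combined_p, conserved.
    """
    if og_changes.empty:
        raise ValidationError("no orthogroup-level changes supplied")
    df = og_changes.copy()
    if n_species is None:
        n_species = df["species"].nunique()
    comparisons = sorted(df["comparison"].unique())
    if len(comparisons) > n_comparisons:
        raise ValidationError(
            f"{len(comparisons)} comparisons exceed the {n_comparisons} slots"
        )
    delta_w = df.pivot_table(
        index=["og_a", "og_b"], columns="comparison", values="delta", aggfunc="mean"
    ).reindex(columns=comparisons)
    p_w = df.pivot_table(
        index=["og_a", "og_b"], columns="comparison", values="p", aggfunc="mean"
    ).reindex(columns=comparisons)
    species_of = df.groupby(["og_a", "og_b"])["species"].nunique()

    deltas = delta_w.to_numpy()
    quantified = ~np.isnan(deltas)
    total = np.nansum(deltas, axis=1)
    orient = np.where(total < 0, -1.0, 1.0)
    deltas = deltas * orient[:, None]
    n_quant = quantified.sum(axis=1)
    n_consistent = np.nansum(deltas > 0, axis=1).astype(int)

    combined = np.empty(len(delta_w))
    pv = p_w.to_numpy()
    for i in range(len(delta_w)):
        ps = pv[i][~np.isnan(pv[i])]
        ps = np.clip(ps, 1e-300, 1.0)
        combined[i] = fisher_combine(ps) if len(ps) else np.nan
    ok = ~np.isnan(combined)
    adj = np.full_like(combined, np.nan)
    if ok.any():
        adj[ok] = adjust_pvalues(combined[ok], method="BH")

    present_all = species_of.reindex(delta_w.index).to_numpy() >= n_species
    conserved = (
        present_all
        & (n_consistent >= min_consistent)
        & np.where(np.isnan(adj), False, adj <= alpha)
    )
    out = pd.DataFrame(
        {
            "og_a": delta_w.index.get_level_values("og_a"),
            "og_b": delta_w.index.get_level_values("og_b"),
            "n_species_present": species_of.reindex(delta_w.index).to_numpy(),
            "n_quantified": n_quant,
            "n_sign_consistent": n_consistent,
            "combined_p": combined,
            "adj_combined_p": adj,
            "conserved": conserved,
        }
    )
    for j, comp in enumerate(comparisons):
        out[f"delta:{comp}"] = deltas[:, j]
    return out.reset_index(drop=True)


def ratio_pca(delta_wide: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """PCA of comparisons in paralog-ratio-difference space.

    ``delta_wide`` is pairs x comparisons; only complete-case rows are used.
    Comparisons are the observations; scores are deterministic up to sign,
    fixed so each component's largest-magnitude score is positive.
    """
    complete = delta_wide.dropna(axis=0)
    if len(complete) < 2:
        raise ValidationError("need at least 2 complete pair rows")
    X = complete.to_numpy().T  # comparisons x pairs
    X = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    for j in range(k):
        if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
            scores[:, j] *= -1
    with np.errstate(invalid="ignore", divide="ignore"):
        evr = (s**2 / np.sum(s**2))[:k] if np.sum(s**2) > 0 else np.zeros(k)
    out = pd.DataFrame(
        scores, index=complete.columns, columns=[f"PC{j + 1}" for j in range(k)]
    )
    out.attrs["explained_variance_ratio"] = evr
    return out
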