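"""Differential abundance, pair concordance, degradation classes, PSM filtering.

Differential expression uses Welch's t on log2 values with Benjamini-Hochberg
adjustment; a gene is significant when |log2 FC| > 0.58 (strict) and adjusted
p < 0.05.  Among pairs where both paralogs are differentially expressed,
concordant pairs share the fold-change sign and opposite pairs do not.
The PSM processor applies standard TMT-10plex hygiene: drop reverse and
contaminant hits, search scores below 15, and PSMs whose reporter intensities
fall below 1e3 in all 10 channels; remaining intensities are log2-transformed,
channel-median-normalized and summarized to protein groups by the median,
requiring complete 10-channel quantification and >=2 unique peptides.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import adjust_pvalues
from .io import ExpressionDataset, GenePair, ValidationError

FC_THRESHOLD = 0.58
P_THRESHOLD = 0.05

TMT_CHANNELS = [f"tmt{i}" for i in range(1, 11)]

CONCORDANT = "concordant"
OPPOSITE = "opposite"


def de_table(
    dataset: ExpressionDataset,
    condition_a: str,
    condition_b: str,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Welch-t differential abundance of condition_b vs condition_a.

    log2 FC = mean(log2 B) - mean(log2 A).  Genes lacking two observations in
    either condition get missing p.  Returns columns gene, comparison,
    log2_fc, p, adj_p, significant.
    """
    if dataset.scale != "log2":
        raise ValidationError("de_table requires log2-scale data")
    meta = dataset.meta
    for cond in (condition_a, condition_b):
        if cond not in set(meta["condition"]):
            raise ValidationError(f"unknown condition {cond!r}")
    a_cols = meta.index[meta["condition"] == condition_a]
    b_cols = meta.index[meta["condition"] == condition_b]
    a = dataset.values[a_cols].to_numpy()
    b = dataset.values[b_cols].to_numpy()
    fc = np.nanmean(b, axis=1) - np.nanmean(a, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(b, a, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    enough = (np.sum(~np.isnan(a), axis=1) >= 2) & (np.sum(~np.isnan(b), axis=1) >= 2)
    p = np.where(enough, p, np.nan)
    adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        adj[ok] = adjust_pvalues(p[ok], method="BH")
    sig = (np.abs(fc) > fc_threshold) & (adj < p_threshold)
    return pd.DataFrame(
        {
            "gene": dataset.values.index,
            "comparison": f"{condition_b}_vs_{condition_a}",
            "log2_fc": fc,
            "p": p,
            "adj_p": adj,
            "significant": np.where(np.isnan(adj), False, sig),
        }
    ).reset_index(drop=True)


def pair_concordance(
    de: pd.DataFrame, pairs: Iterable[GenePair]
) -> pd.DataFrame:
    """Classify pairs with both genes differentially expressed.

    Same fold-change sign → concordant, different → opposite; pairs with a
    zero fold change are excluded (with a warning).  Returns columns gene_a,
    gene_b, fc_a, fc_b, concordance.
    """
    sig = de[de["significant"]].set_index("gene")["log2_fc"]
    rows = []
    n_zero = 0
    for p in pairs:
        if p.gene_a not in sig.index or p.gene_b not in sig.index:
            continue
        fa, fb = float(sig[p.gene_a]), float(sig[p.gene_b])
        if fa == 0.0 or fb == 0.0:
            n_zero += 1
            continue
        cls = CONCORDANT if np.sign(fa) == np.sign(fb) else OPPOSITE
        rows.append((p.gene_a, p.gene_b, fa, fb, cls))
    if n_zero:
        warnings.warn(f"{n_zero} pair(s) with zero fold change excluded")
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "fc_a", "fc_b", "concordance"]
    )


def degradation_class_analysis(
    delta_table: pd.DataFrame,
    classes: Mapping[str, str],
    complex_membership: Mapping[str, bool],
) -> dict:
    """NED enrichment among complex members and delta-score NED/ED contrast.

    Gene-level: Fisher exact test on the NED x in-complex 2x2 contingency
    table over genes with a degradation class.  Pair-level: pairs containing
    at least one NED gene vs both-ED pairs, compared on the delta score by a
    two-sided rank-sum test.

    Returns a dict with keys ``fisher_table``, ``fisher_odds``, ``fisher_p``,
    ``delta_ned``, ``delta_ed``, ``ranksum_p``.
    """
    genes = [g for g in classes]
    ned = np.array([classes[g] == "NED" for g in genes])
    incpx = np.array([bool(complex_membership.get(g, False)) for g in genes])
    table = np.array(
        [
            [int((ned & incpx).sum()), int((ned & ~incpx).sum())],
            [int((~ned & incpx).sum()), int((~ned & ~incpx).sum())],
        ]
    )
    odds, fisher_p = stats.fisher_exact(table, alternative="two-sided")

    has_ned = delta_table.apply(
        lambda r: classes.get(r["gene_a"]) == "NED" or classes.get(r["gene_b"]) == "NED",
        axis=1,
    ) if len(delta_table) else pd.Series(dtype=bool)
    d_ned = delta_table.loc[has_ned, "delta"] if len(delta_table) else pd.Series(dtype=float)
    d_ed = delta_table.loc[~has_ned, "delta"] if len(delta_table) else pd.Series(dtype=float)
    if len(d_ned) >= 2 and len(d_ed) >= 2:
        ranksum_p = float(
            stats.mannwhitneyu(d_ned, d_ed, alternative="two-sided").pvalue
        )
    else:
        ranksum_p = float("nan")
    return {
        "fisher_table": table,
        "fisher_odds": float(odds),
        "fisher_p": float(fisher_p),
        "delta_ned": d_ned.to_numpy(),
        "delta_ed": d_ed.to_numpy(),
        "ranksum_p": ranksum_p,
    }


def psm_summarize(
    psms: pd.DataFrame,
    score_min: float = 15.0,
    intensity_floor: float = 1e3,
    min_unique_peptides: int = 2,
    channels: Sequence[str] = tuple(TMT_CHANNELS),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a TMT PSM table and summarize to protein-group quantities.

    Filters, in order: reverse/contaminant hits; search score below
    ``score_min``; reporter intensity below ``intensity_floor`` in *all*
    channels.  Retained intensities are log2-transformed, median-normalized
    per channel (subtracting the channel median), and summarized to protein
    groups by the median over PSMs.  Peptides with any missing channel are
    excluded from quantification and proteins need >= ``min_unique_peptides``
    unique peptides.

    Returns ``(protein_matrix, retained_psms)``.
    """
    channels = list(channels)
    missing_cols = [c for c in channels if c not in psms.columns]
    if missing_cols:
        raise ValidationError(f"malformed channel columns, missing {missing_cols}")
    df = psms.copy()
    df = df[~(df["is_reverse"].astype(bool) | df["is_contaminant"].astype(bool))]
    df = df[df["score"] >= score_min]
    inten = df[channels].to_numpy(dtype=float)
    below_everywhere = np.all(np.nan_to_num(inten, nan=0.0) < intensity_floor, axis=1)
    df = df[~below_everywhere]
    # completeness: quantify only peptides observed in all channels
    complete = df[channels].notna().all(axis=1)
    quant = df[complete].copy()
    retained = df.reset_index(drop=True)

    if quant.empty:
        return (
            pd.DataFrame(columns=channels, index=pd.Index([], name="protein")),
            retained,
        )
    log2 = np.log2(quant[channels].to_numpy(dtype=float))
    log2 = log2 - np.nanmedian(log2, axis=0, keepdims=True)
    for i, ch in enumerate(channels):
        quant[ch] = log2[:, i]

    pep_counts = quant.groupby("protein")["peptide"].nunique()
    keep = pep_counts.index[pep_counts >= min_unique_peptides]
    quant = quant[quant["protein"].isin(keep)]
    matrix = quant.groupby("protein")[channels].median().sort_index()
    return matrix, retained


def ranked_fc_ks(
    fc_ranking: pd.Series, gene_set: Iterable[str]
) -> tuple[float, float]:
    """Two-sample KS of a gene set's fold changes vs the rest of the ranking."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValidationError("empty gene set")
    unknown = gene_set - set(fc_ranking.index)
    if unknown:
        raise ValidationError(f"genes absent from ranking: {sorted(unknown)[:5]}")
    in_set = fc_ranking.loc[fc_ranking.index.isin(gene_set)].to_numpy()
    out_set = fc_ranking.loc[~fc_ranking.index.isin(gene_set)].to_numpy()
    if len(out_set) == 0:
        raise ValidationError("gene set covers the whole ranking")
    res = stats.ks_2samp(in_set, out_set, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
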