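"""Gene-set overrepresentation, ranked-score KS enrichment and p adjustments."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

_ADJUST_METHODS = {"BH": "fdr_bh", "Hommel": "hommel"}


def adjust_pvalues(p: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up or Hommel."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0,1]")
    if method not in _ADJUST_METHODS:
        raise ValidationError(f"unknown method {method!r}")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method=_ADJUST_METHODS[method])[1]


def fisher_ora(
    selected: Iterable[str],
    background: Iterable[str],
    sets: Mapping[str, tuple[str, frozenset[str]]],
    alternative: str = "greater",
    adjust: str = "BH",
) -> pd.DataFrame:
    """One-sided Fisher exact overrepresentation of each gene set.

    For a term with K background genes of which k are among the n selected
    (N background total), the enrichment p is the hypergeometric upper tail
    P(X >= k).  Returns columns term, name, k, n, K, N, p, adj_p.
    """
    selected = set(selected)
    background = set(background)
    if not selected <= background:
        raise ValidationError("selected genes must be a subset of the background")
    n, N = len(selected), len(background)
    rows = []
    for term, (name, genes) in sets.items():
        in_bg = genes & background
        K = len(in_bg)
        if K == 0:
            continue
        k = len(selected & in_bg)
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, n - k], [K - k, N - K - n + k]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append((term, name, k, n, K, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "name", "k", "n", "K", "N", "p"])
    df["adj_p"] = adjust_pvalues(df["p"], method=adjust) if len(df) else []
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def ks_gsea(
    scores: Mapping[str, float] | pd.Series,
    sets: Mapping[str, tuple[str, frozenset[str]]],
    adjust: str = "BH",
) -> pd.DataFrame:
    """Two-sample KS enrichment of each set's scores vs the rest.

    Terms with fewer than 2 annotated genes in the ranking (or fewer than 2
    outside) are skipped.  Results are sorted by adjusted p.
    """
    s = pd.Series(scores, dtype=float).dropna()
    rows = []
    for term, (name, genes) in sets.items():
        mask = s.index.isin(genes)
        inside, outside = s[mask], s[~mask]
        if len(inside) < 2 or len(outside) < 2:
            continue
        res = stats.ks_2samp(inside, outside, alternative="two-sided")
        rows.append((term, name, len(inside), float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["term", "name", "n_in_set", "D", "p"])
    df["adj_p"] = adjust_pvalues(df["p"], method=adjust) if len(df) else []
    return df.sort_values("adj_p", kind="stable").reset_index(drop=True)
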