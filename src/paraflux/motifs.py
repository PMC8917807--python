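"""Promoter-window PWM scanning and differential TF-score profiling.

Motifs are position probability matrices (JASPAR PFMs converted with a
background-distributed pseudocount).  A window's score is the log2-odds sum
against the background, min-max rescaled to the motif's achievable range
(*relative score*); a promoter's score for a TF is the maximum relative score
over all windows on both strands, zeroed when below the hit threshold
(default 0.8, i.e. the 80% minimal-score convention).  TFs not found in a
promoter therefore score 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from Bio import motifs as bio_motifs

from .io import GenePair, ValidationError

ALPHABET = "ACGT"
_ENC = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_THRESHOLD = 0.8
DEFAULT_PSEUDOCOUNT = 0.8
UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)


@dataclass
class MotifModel:
    """Per-position nucleotide probability matrix with background."""

    name: str
    probs: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.asarray(UNIFORM_BG, dtype=float)
    )
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValidationError("probability matrix must be width x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("probability rows must sum to 1")
        if ((self.probs <= 0) | (self.probs >= 1)).any():
            raise ValidationError("probabilities must lie strictly in (0,1)")

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.log_odds, axis=1))

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(
            self.name, self.probs[::-1, ::-1], self.background, self.pseudocount
        )

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        background: Sequence[float] = UNIFORM_BG,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "MotifModel":
        """Counts → probabilities with a background-distributed pseudocount."""
        counts = np.asarray(counts, dtype=float)
        bg = np.asarray(background, dtype=float)
        padded = counts + pseudocount * bg[None, :]
        return cls(name, padded / padded.sum(axis=1, keepdims=True), bg, pseudocount)


def read_jaspar(
    path: str | Path,
    background: Sequence[float] = UNIFORM_BG,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[MotifModel]:
    """Read JASPAR-format PFMs into :class:`MotifModel` objects."""
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.column_stack([m.counts[b] for b in ALPHABET])
            name = m.name or m.matrix_id
            out.append(
                MotifModel.from_counts(str(name), counts, background, pseudocount)
            )
    return out


def pwm_relative_score(motif: MotifModel, window: str) -> float:
    """Min-max scaled log2-odds of one window of exactly motif width.

    1.0 for the consensus, 0.0 for the anti-consensus; NaN when the window
    contains an ambiguous base.
    """
    if len(window) != motif.width:
        raise ValidationError("window width mismatch")
    lo = motif.log_odds
    enc = [_ENC.get(b, -1) for b in window.upper()]
    if any(e < 0 for e in enc):
        return float("nan")
    score = float(sum(lo[i, e] for i, e in enumerate(enc)))
    lo_min = float(lo.min(axis=1).sum())
    lo_max = float(lo.max(axis=1).sum())
    if lo_max == lo_min:
        return 1.0
    return (score - lo_min) / (lo_max - lo_min)


def _strand_max(motif: MotifModel, enc: np.ndarray) -> float:
    w = motif.width
    if len(enc) < w:
        return -np.inf
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return -np.inf
    lo = motif.log_odds
    scores = lo[np.arange(w)[None, :], windows[valid]].sum(axis=1)
    return float(scores.max())


def scan_promoter(
    motif: MotifModel,
    promoter: str,
    threshold: float = DEFAULT_THRESHOLD,
    both_strands: bool = True,
) -> float:
    """Max relative score of a motif over a promoter; 0 when below threshold.

    Slides over every position on the forward strand and (by default) the
    reverse complement; windows containing ambiguous bases are skipped.
    A promoter shorter than the motif scores 0 with a warning.
    """
    seq = promoter.upper()
    if len(seq) < motif.width:
        import warnings

        warnings.warn("promoter shorter than motif; score 0")
        return 0.0
    enc = np.fromiter((_ENC.get(b, -1) for b in seq), dtype=np.int64, count=len(seq))
    best = _strand_max(motif, enc)
    if both_strands:
        rc = seq.translate(_COMPLEMENT)[::-1]
        enc_rc = np.fromiter(
            (_ENC.get(b, -1) for b in rc), dtype=np.int64, count=len(rc)
        )
        best = max(best, _strand_max(motif, enc_rc))
    if not np.isfinite(best):
        return 0.0
    lo = motif.log_odds
    lo_min = float(lo.min(axis=1).sum())
    lo_max = float(lo.max(axis=1).sum())
    rel = 1.0 if lo_max == lo_min else (best - lo_min) / (lo_max - lo_min)
    return rel if rel >= threshold else 0.0


def promoter_score_table(
    motifs_list: Sequence[MotifModel],
    promoters: Mapping[str, str],
    threshold: float = DEFAULT_THRESHOLD,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Gene x TF matrix of max relative scores (0 below threshold)."""
    data = {
        m.name: [
            scan_promoter(m, promoters[g], threshold, both_strands)
            for g in promoters
        ]
        for m in motifs_list
    }
    return pd.DataFrame(data, index=list(promoters))


def shared_tf_fraction(
    scores_a: pd.Series | Mapping[str, float],
    scores_b: pd.Series | Mapping[str, float],
) -> tuple[float, float, float]:
    """Decompose a pair's TF hits into shared / A-only / B-only fractions.

    Presence is score > 0; fractions are over the union of hits and sum to 1.
    NaN triple when neither promoter has a hit.
    """
    a = pd.Series(scores_a, dtype=float)
    b = pd.Series(scores_b, dtype=float)
    if not a.index.equals(b.index):
        b = b.reindex(a.index)
        if b.isna().any():
            raise ValidationError("TF universes differ between the two promoters")
    pa, pb = a > 0, b > 0
    union = int((pa | pb).sum())
    if union == 0:
        return float("nan"), float("nan"), float("nan")
    shared = int((pa & pb).sum()) / union
    a_only = int((pa & ~pb).sum()) / union
    b_only = int((~pa & pb).sum()) / union
    return shared, a_only, b_only


def tf_difference_distribution(
    score_table: pd.DataFrame,
    pairs: Iterable[GenePair | tuple[str, str]],
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Per-TF distribution of score differences between pair members.

    The difference is score(first member) - score(second member) in the
    orientation the pairs are supplied (fix orientation upstream, e.g. by the
    conserved-signature convention).  Only TFs present (score > 0 in at least
    one member) in >= ``min_pairs`` pairs are reported.

    Returns columns tf, n_pairs, median_diff, q25, q75.
    """
    diffs: dict[str, list[float]] = {tf: [] for tf in score_table.columns}
    for p in pairs:
        a, b = (p.gene_a, p.gene_b) if isinstance(p, GenePair) else (p[0], p[1])
        if a not in score_table.index or b not in score_table.index:
            continue
        sa = score_table.loc[a]
        sb = score_table.loc[b]
        present = (sa > 0) | (sb > 0)
        for tf in score_table.columns[present]:
            diffs[tf].append(float(sa[tf] - sb[tf]))
    rows = []
    for tf, vals in diffs.items():
        if len(vals) < min_pairs:
            continue
        arr = np.asarray(vals)
        rows.append(
            (tf, len(arr), float(np.median(arr)),
             float(np.quantile(arr, 0.25)), float(np.quantile(arr, 0.75)))
        )
    out = pd.DataFrame(rows, columns=["tf", "n_pairs", "median_diff", "q25", "q75"])
    return out.sort_values(
        "median_diff", key=lambda s: s.abs(), ascending=False, kind="stable"
    ).reset_index(drop=True)
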