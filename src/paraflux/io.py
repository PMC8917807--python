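"""Readers, writers and canonicalization for the pipeline's tabular inputs.

All tabular formats are TSV with ``NA`` as the missing-value sentinel.  Gene
identifiers are opaque strings; the rna and protein layers of a study are
matched by identical identifiers, so inputs must be pre-mapped to a common
id space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

NA = "NA"

LAYERS = ("rna", "protein")
SCALES = ("linear", "log2")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class ExpressionDataset:
    """Feature-by-sample abundance matrix plus per-sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Features (genes) on the index, sample ids on the columns.  Missing
        quantifications are ``NaN``.
    meta : pandas.DataFrame
        Indexed by sample id, with columns ``condition``, ``replicate``,
        ``layer`` and ``species``.
    scale : str
        ``"linear"`` (e.g. TPM, iBAQ) or ``"log2"``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate feature ids")
        missing_meta = set(self.values.columns) - set(self.meta.index)
        if missing_meta:
            raise ValidationError(f"samples without metadata: {sorted(missing_meta)}")
        for col in ("condition", "replicate", "layer"):
            if col not in self.meta.columns:
                raise ValidationError(f"metadata lacks column {col!r}")
        bad_layer = set(self.meta["layer"]) - set(LAYERS)
        if bad_layer:
            raise ValidationError(f"unknown layers {sorted(bad_layer)}")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise ValidationError("negative abundances on linear scale")
        self.values.index.name = "feature"
        self.meta.index.name = "sample"

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def conditions(self) -> list[str]:
        """Condition labels in first-appearance (sample) order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(str(self.meta.loc[s, "condition"]), None)
        return list(seen)

    def subset_layer(self, layer: str) -> "ExpressionDataset":
        keep = self.meta.index[self.meta["layer"] == layer]
        cols = [s for s in self.samples if s in set(keep)]
        return ExpressionDataset(self.values[cols], self.meta.loc[cols], self.scale)

    def to_log2(self, floor: float = 0.0) -> "ExpressionDataset":
        """Return a log2-scale view; zeros (or values below ``floor``) map to NaN."""
        if self.scale == "log2":
            return self
        vals = self.values.where(self.values > floor)
        return ExpressionDataset(np.log2(vals), self.meta, "log2")


@dataclass(frozen=True, order=True)
class GenePair:
    """Canonically ordered paralog pair with reciprocal percent identities."""

    gene_a: str
    gene_b: str
    identity_ab: float = float("nan")
    identity_ba: float = float("nan")

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-pair ({self.gene_a},{self.gene_b})")
        if self.gene_a > self.gene_b:
            raise ValidationError(
                f"pair ({self.gene_a},{self.gene_b}) not canonically ordered"
            )
        for ident in (self.identity_ab, self.identity_ba):
            if not np.isnan(ident) and not 0.0 <= ident <= 100.0:
                raise ValidationError(f"identity {ident} outside [0,100]")

    @property
    def mean_identity(self) -> float:
        return (self.identity_ab + self.identity_ba) / 2.0

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class ComplexCatalog:
    """Named protein complexes as member gene sets."""

    members: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.members = {cid: frozenset(m) for cid, m in self.members.items()}

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, cid: str) -> frozenset[str]:
        return self.members[cid]

    def items(self):
        return self.members.items()

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.members.values():
            out |= m
        return frozenset(out)


@dataclass
class OrthogroupMap:
    """(gene, species) → orthogroup records; a gene maps to one orthogroup per species."""

    records: pd.DataFrame  # columns: gene, species, orthogroup

    def __post_init__(self) -> None:
        req = {"gene", "species", "orthogroup"}
        if not req <= set(self.records.columns):
            raise ValidationError(f"orthogroup map needs columns {sorted(req)}")
        dup = self.records.duplicated(subset=["gene", "species"], keep=False)
        if dup.any():
            conflicting = self.records.loc[dup]
            multi = conflicting.groupby(["gene", "species"])["orthogroup"].nunique()
            if (multi > 1).any():
                raise ValidationError("gene maps to multiple orthogroups in one species")
            self.records = self.records.drop_duplicates(subset=["gene", "species"])

    def lookup(self, species: str) -> dict[str, str]:
        sub = self.records[self.records["species"] == species]
        return dict(zip(sub["gene"], sub["orthogroup"]))


# ---------------------------------------------------------------------------
# pair-table canonicalization

def canonicalize_pairs(
    raw_pairs: Iterable[tuple[str, str, float, float]],
) -> list[GenePair]:
    """Collapse a raw pair table into unique, canonically ordered :class:`GenePair`.

    The canonical orientation is lexicographic on the identifier strings.  A
    pair listed in both orientations is kept once; the reciprocal identities
    follow the canonical orientation.  Self-pairs and identities outside
    [0, 100] raise :class:`ValidationError`.
    """
    out: dict[tuple[str, str], GenePair] = {}
    for rec in raw_pairs:
        a, b = str(rec[0]), str(rec[1])
        ia = float(rec[2]) if len(rec) > 2 else float("nan")
        ib = float(rec[3]) if len(rec) > 3 else float("nan")
        if a == b:
            raise ValidationError(f"self-pair ({a},{a})")
        if a > b:
            a, b, ia, ib = b, a, ib, ia
        pair = GenePair(a, b, ia, ib)
        prev = out.get(pair.key)
        if prev is not None:
            # duplicate (same or mirrored orientation): identities must agree
            if not _identities_close(prev, pair):
                raise ValidationError(
                    f"conflicting identities for pair ({a},{b})"
                )
        out[pair.key] = pair
    return sorted(out.values())


def _identities_close(p: GenePair, q: GenePair, tol: float = 1e-9) -> bool:
    for x, y in ((p.identity_ab, q.identity_ab), (p.identity_ba, q.identity_ba)):
        if np.isnan(x) and np.isnan(y):
            continue
        if abs(x - y) > tol:
            return False
    return True


def flag_has_paralog(genes: Iterable[str], pairs: Iterable[GenePair]) -> dict[str, bool]:
    """Gene → True iff the gene occurs in at least one paralog pair."""
    in_pairs: set[str] = set()
    for p in pairs:
        in_pairs.add(p.gene_a)
        in_pairs.add(p.gene_b)
    return {g: g in in_pairs for g in genes}


# ---------------------------------------------------------------------------
# TSV / GMT readers and writers

def read_expression(
    matrix_path: str | Path, meta_path: str | Path, scale: str = "log2"
) -> ExpressionDataset:
    values = pd.read_csv(matrix_path, sep="\t", na_values=[NA], index_col="feature")
    meta = pd.read_csv(
        meta_path, sep="\t", na_values=[NA], index_col="sample",
        dtype={"condition": str, "replicate": str, "layer": str, "species": str},
    )
    return ExpressionDataset(values, meta, scale)


def write_expression(
    ds: ExpressionDataset, matrix_path: str | Path, meta_path: str | Path
) -> None:
    ds.values.to_csv(matrix_path, sep="\t", na_rep=NA, index_label="feature")
    ds.meta.to_csv(meta_path, sep="\t", na_rep=NA, index_label="sample")


def read_pairs(path: str | Path) -> list[GenePair]:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    return canonicalize_pairs(
        df[["gene_a", "gene_b", "identity_ab", "identity_ba"]].itertuples(index=False)
    )


def write_pairs(pairs: Iterable[GenePair], path: str | Path) -> None:
    rows = [
        (p.gene_a, p.gene_b, p.identity_ab, p.identity_ba, p.mean_identity)
        for p in pairs
    ]
    pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "identity_ab", "identity_ba", "mean_identity"]
    ).to_csv(path, sep="\t", na_rep=NA, index=False)


def read_complexes(path: str | Path) -> ComplexCatalog:
    """Read a complex catalog from long TSV (complex_id, member) or GMT."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        members: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                members[parts[0]] = set(g for g in parts[2:] if g)
        return ComplexCatalog({k: frozenset(v) for k, v in members.items()})
    df = pd.read_csv(path, sep="\t")
    grouped = df.groupby("complex_id")["member"].apply(frozenset)
    return ComplexCatalog(dict(grouped))


def write_complexes(catalog: ComplexCatalog, path: str | Path) -> None:
    rows = [
        (cid, m) for cid, mem in sorted(catalog.items()) for m in sorted(mem)
    ]
    pd.DataFrame(rows, columns=["complex_id", "member"]).to_csv(
        path, sep="\t", index=False
    )


def read_orthogroups(path: str | Path) -> OrthogroupMap:
    return OrthogroupMap(pd.read_csv(path, sep="\t", na_values=[NA]))


def write_orthogroups(ogmap: OrthogroupMap, path: str | Path) -> None:
    ogmap.records.to_csv(path, sep="\t", na_rep=NA, index=False)


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT gene sets: term id → (term name, gene set)."""
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            genes = frozenset(g for g in parts[2:] if g)
            if genes:
                out[parts[0]] = (parts[1], genes)
    return out


def write_gmt(sets: Mapping[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (name, genes) in sets.items():
            fh.write("\t".join([term, name, *sorted(genes)]) + "\n")
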