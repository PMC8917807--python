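"""Seeded generators for every input the pipeline consumes.

Each generator plants known structure (divergent paralog pairs, content-coupled
complex dispersion, conserved cross-species ratio shifts, NED-linked protein
decorrelation, promoter motifs, PSM filter violations) and returns it as ground
truth, so downstream statistics can be tested as parameter-recovery problems.

Latent expression profiles are standard-normal random walks over conditions,
standardized to unit standard deviation, so ``noise_sd`` is directly the
noise-to-signal ratio in log2 units.  A single seed is expanded into
independent substreams per generator stage: adding a stage never perturbs the
draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ComplexCatalog,
    ExpressionDataset,
    GenePair,
    OrthogroupMap,
    ValidationError,
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic paralog-expression study.

    Counts and rates default to the study conditions the pipeline is exercised
    under: 2,000 pairs over 10 conditions with a 35% planted divergent
    fraction and log2 noise at 0.3x the (unit) latent sd; 4 species sharing
    7 differentiation comparisons with 50 of 1,000 orthogroup pairs carrying
    a conserved unit log2-ratio shift at replicate noise 0.25.
    """

    n_pairs: int = 2000
    n_singletons: int = 500
    n_conditions: int = 10
    n_replicates: int = 1
    divergent_fraction: float = 0.35
    noise_sd: float = 0.3
    complex_sizes: Sequence[int] = ()
    content_coupling: float = 0.0
    base_dispersion: float = 0.05
    paralog_var_boost: float = 1.0
    protein_noise_sd: float = 0.2
    ned_fraction: float = 0.0
    ned_delta_mix: float = 0.5
    n_species: int = 4
    n_comparisons: int = 7
    n_conserved: int = 50
    n_orthogroup_pairs: int = 1000
    effect_size: float = 1.0
    null_shift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "n_singletons", "n_conditions", "n_replicates",
                     "n_species", "n_comparisons", "n_conserved",
                     "n_orthogroup_pairs"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.divergent_fraction <= 1.0:
            raise ValidationError("divergent_fraction must lie in [0,1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    """Planted structure of a simulated study; fields unused by a generator stay empty."""

    divergent: dict[tuple[str, str], bool] = field(default_factory=dict)
    complex_dispersion: dict[str, float] = field(default_factory=dict)
    complex_content: dict[str, float] = field(default_factory=dict)
    degradation_class: dict[str, str] = field(default_factory=dict)
    conserved: dict[tuple[str, str], bool] = field(default_factory=dict)
    planted_signs: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    motif_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    psm_violations: dict[str, int] = field(default_factory=dict)


def _random_walk(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-sd random-walk latent over ``n`` conditions (a smooth trajectory)."""
    walk = np.cumsum(rng.standard_normal(n))
    sd = walk.std(ddof=1) if n > 1 else 1.0
    if sd == 0:
        sd = 1.0
    return (walk - walk.mean()) / sd


# ---------------------------------------------------------------------------
# paired expression study


def simulate_expression_study(
    cfg: SimulationConfig,
) -> tuple[dict[str, ExpressionDataset], list[GenePair], ComplexCatalog, GroundTruth]:
    """Simulate rna and protein abundance layers with planted pair/complex structure.

    Each paralog pair shares a latent random-walk profile; divergent pairs use
    the sign-flipped latent for the second gene.  Complexes are assembled so
    that member-profile dispersion grows with paralog content when
    ``content_coupling`` > 0.  The protein layer is the rna layer plus
    independent noise; pairs containing a NED-labelled gene are additionally
    decorrelated at the protein level (lower delta score).

    Returns ``({"rna": ds, "protein": ds}, pairs, catalog, truth)``; both
    layers are on the log2 scale.
    """
    ss = np.random.SeedSequence(cfg.seed)
    (rng_struct, rng_latent, rng_noise, rng_prot) = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n_cond, n_rep = cfg.n_conditions, cfg.n_replicates
    if n_cond < 2:
        raise ValidationError("need at least 2 conditions")

    pair_names = [(f"P{i:05d}a", f"P{i:05d}b") for i in range(cfg.n_pairs)]
    singleton_names = [f"S{i:05d}" for i in range(cfg.n_singletons)]
    genes = [g for ab in pair_names for g in ab] + singleton_names

    # planted divergence flags: exact count, random placement
    n_div = int(round(cfg.n_pairs * cfg.divergent_fraction))
    div_idx = set(rng_struct.choice(cfg.n_pairs, size=n_div, replace=False).tolist())

    # complex assembly: evenly spread paralog-content targets across complexes
    sizes = list(cfg.complex_sizes)
    catalog_members: dict[str, frozenset[str]] = {}
    complex_of_pair: dict[int, int] = {}
    complex_of_singleton: dict[int, int] = {}
    truth = GroundTruth()
    if sizes:
        if max(sizes) > len(genes):
            raise ValidationError("complex size exceeds gene count")
        contents = np.linspace(0.0, 1.0, len(sizes))
        pair_pool = list(rng_struct.permutation(cfg.n_pairs))
        singleton_pool = list(rng_struct.permutation(cfg.n_singletons))
        for j, (size, target) in enumerate(zip(sizes, contents)):
            n_para = int(round(size * target))
            n_single = size - n_para
            if n_para > len(pair_pool) or n_single > len(singleton_pool):
                raise ValidationError("not enough genes to fill complexes")
            cid = f"CPX{j:04d}"
            mem: list[str] = []
            for _ in range(n_para):
                pi = pair_pool.pop()
                complex_of_pair[pi] = j
                mem.append(pair_names[pi][0])
            for _ in range(n_single):
                si = singleton_pool.pop()
                complex_of_singleton[si] = j
                mem.append(singleton_names[si])
            catalog_members[cid] = frozenset(mem)
            disp = float(np.clip(
                cfg.base_dispersion + cfg.content_coupling * target, 0.0, 0.95
            ))
            truth.complex_dispersion[cid] = disp
            truth.complex_content[cid] = n_para / size
    catalog = ComplexCatalog(catalog_members)

    complex_latents = {
        j: _random_walk(rng_latent, n_cond) for j in set(
            list(complex_of_pair.values()) + list(complex_of_singleton.values())
        )
    }

    def _member_latent(j: int | None) -> np.ndarray:
        own = _random_walk(rng_latent, n_cond)
        if j is None:
            return own
        v = truth.complex_dispersion[f"CPX{j:04d}"]
        return np.sqrt(1.0 - v) * complex_latents[j] + np.sqrt(v) * own

    # condition-level signal per gene (log2 units around a per-gene baseline)
    signal = np.empty((len(genes), n_cond))
    baselines = rng_struct.normal(8.0, 1.0, size=len(genes))
    pairs: list[GenePair] = []
    row = {g: i for i, g in enumerate(genes)}
    for i, (ga, gb) in enumerate(pair_names):
        lat = _member_latent(complex_of_pair.get(i))
        flip = -1.0 if i in div_idx else 1.0
        amp = cfg.paralog_var_boost
        signal[row[ga]] = amp * lat
        signal[row[gb]] = amp * flip * lat
        ident = float(rng_struct.uniform(30, 100))
        jitter = float(rng_struct.uniform(-2, 2))
        ia, ib = ident, float(np.clip(ident + jitter, 0, 100))
        a, b = (ga, gb) if ga < gb else (gb, ga)
        pairs.append(GenePair(a, b, ia if a == ga else ib, ib if a == ga else ia))
        truth.divergent[(a, b)] = i in div_idx
    for i, gs in enumerate(singleton_names):
        signal[row[gs]] = _member_latent(complex_of_singleton.get(i))

    samples = [f"{c}_r{r}" for c in range(n_cond) for r in range(n_rep)]
    cond_of = np.repeat(np.arange(n_cond), n_rep)
    rna = (
        baselines[:, None]
        + signal[:, cond_of]
        + rng_noise.normal(0.0, cfg.noise_sd, size=(len(genes), len(samples)))
    )

    # protein layer: rna + independent noise, NED pairs decorrelated
    ned_genes: dict[str, str] = {}
    if cfg.ned_fraction > 0:
        labels = rng_prot.random(len(genes)) < cfg.ned_fraction
        ned_genes = {g: ("NED" if lab else "ED") for g, lab in zip(genes, labels)}
    else:
        ned_genes = {g: "ED" for g in genes}
    truth.degradation_class = ned_genes

    prot_signal = signal.copy()
    for i, (ga, gb) in enumerate(pair_names):
        if ned_genes[ga] == "NED" or ned_genes[gb] == "NED":
            w = cfg.ned_delta_mix
            indep = _random_walk(rng_prot, n_cond) * cfg.paralog_var_boost
            prot_signal[row[gb]] = (
                np.sqrt(1.0 - w) * prot_signal[row[gb]] + np.sqrt(w) * indep
            )
    protein = (
        baselines[:, None]
        + prot_signal[:, cond_of]
        + rng_prot.normal(
            0.0,
            np.sqrt(cfg.noise_sd**2 + cfg.protein_noise_sd**2),
            size=(len(genes), len(samples)),
        )
    )

    def _dataset(mat: np.ndarray, layer: str) -> ExpressionDataset:
        cols = [f"{layer}_{s}" for s in samples]
        values = pd.DataFrame(mat, index=genes, columns=cols)
        meta = pd.DataFrame(
            {
                "condition": [f"C{c:02d}" for c in cond_of],
                "replicate": [s.split("_r")[1] for s in samples],
                "layer": layer,
                "species": "synthetic",
            },
            index=cols,
        )
        return ExpressionDataset(values, meta, "log2")

    datasets = {"rna": _dataset(rna, "rna"), "protein": _dataset(protein, "protein")}
    return datasets, pairs, catalog, truth


# ---------------------------------------------------------------------------
# multi-species proteomes


def comparison_plan(n_species: int, n_comparisons: int) -> dict[str, list[str]]:
    """Partition comparison slots across species as evenly as possible.

    With 4 species and 7 comparisons the split is 2+2+2+1, mirroring a design
    where three differentiation time courses contribute two time points each
    and one contributes a single contrast.
    """
    if n_species < 2:
        raise ValidationError("need at least 2 species")
    if n_comparisons < 1:
        raise ValidationError("need at least 1 comparison")
    base = n_comparisons // n_species
    extra = n_comparisons % n_species
    plan: dict[str, list[str]] = {}
    k = 0
    for s in range(n_species):
        n_here = base + (1 if s < extra else 0)
        sp = f"sp{s + 1}"
        plan[sp] = [f"{sp}_cmp{j + 1}" for j in range(n_here)]
        k += n_here
    return plan


def simulate_multispecies_proteomes(
    cfg: SimulationConfig,
) -> tuple[dict[str, ExpressionDataset], OrthogroupMap, GroundTruth]:
    """Simulate replicate-level proteomes for several species with planted
    conserved paralog-ratio shifts.

    Each orthogroup pair is represented by one gene pair per species.  Planted
    conserved pairs receive a log2-ratio shift of ``effect_size`` with a
    consistent sign in at least 5 of the comparisons (0-2 randomly flipped);
    other pairs receive per-comparison shifts of sd ``null_shift_sd`` (zero by
    default, i.e. a pure replicate-noise null).  Abundances are log2 scale.
    Every comparison carries its own reference condition (``"<cmp>_ref"``)
    with independent replicates, emulating independently acquired contrasts.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_plant, rng_noise, rng_null = (np.random.default_rng(s) for s in ss.spawn(3))
    plan = comparison_plan(cfg.n_species, cfg.n_comparisons)
    comparisons = [c for cs in plan.values() for c in cs]
    n_og = cfg.n_orthogroup_pairs
    if cfg.n_conserved > n_og:
        raise ValidationError("n_conserved exceeds n_orthogroup_pairs")
    if cfg.n_replicates < 2:
        raise ValidationError("need >=2 replicates per condition for testing")

    og_pairs = [(f"OG{k:05d}A", f"OG{k:05d}B") for k in range(n_og)]
    planted = set(rng_plant.choice(n_og, size=cfg.n_conserved, replace=False).tolist())

    truth = GroundTruth()
    shift = np.zeros((n_og, len(comparisons)))
    for k in range(n_og):
        key = og_pairs[k]
        if k in planted and cfg.effect_size != 0:
            sign = 1 if rng_plant.random() < 0.5 else -1
            n_flip = int(rng_plant.integers(0, 3))  # 0..2 flipped of 7
            flipped = set(
                rng_plant.choice(len(comparisons), size=n_flip, replace=False).tolist()
            )
            signs = {
                c: (-sign if j in flipped else sign)
                for j, c in enumerate(comparisons)
            }
            shift[k] = [signs[c] * cfg.effect_size for c in comparisons]
            truth.conserved[key] = True
            truth.planted_signs[key] = signs
        else:
            truth.conserved[key] = False
            if cfg.null_shift_sd > 0:
                shift[k] = rng_null.normal(0, cfg.null_shift_sd, len(comparisons))

    datasets: dict[str, ExpressionDataset] = {}
    og_records: list[tuple[str, str, str]] = []
    cmp_index = {c: j for j, c in enumerate(comparisons)}
    for sp, sp_cmps in plan.items():
        genes_a = [f"{sp}_g{k:05d}a" for k in range(n_og)]
        genes_b = [f"{sp}_g{k:05d}b" for k in range(n_og)]
        for k in range(n_og):
            og_records.append((genes_a[k], sp, og_pairs[k][0]))
            og_records.append((genes_b[k], sp, og_pairs[k][1]))
        base_a = rng_noise.normal(25.0, 2.0, n_og)
        base_b = rng_noise.normal(25.0, 2.0, n_og)
        # every comparison is an independently acquired contrast: its reference
        # replicates are its own, so per-comparison tests are independent (the
        # structure the downstream Fisher combination assumes)
        conditions = []
        for cmp in sp_cmps:
            conditions += [f"{cmp}_ref", cmp]
        cols, cond_lab, rep_lab = [], [], []
        mats = []
        for cond in conditions:
            for r in range(cfg.n_replicates):
                cols.append(f"{sp}_{cond}_r{r + 1}")
                cond_lab.append(cond)
                rep_lab.append(str(r + 1))
                delta = (
                    np.zeros(n_og) if cond.endswith("_ref")
                    else shift[:, cmp_index[cond]]
                )
                col_a = base_a + delta / 2.0 + rng_noise.normal(0, cfg.noise_sd, n_og)
                col_b = base_b - delta / 2.0 + rng_noise.normal(0, cfg.noise_sd, n_og)
                mats.append(np.concatenate([col_a, col_b]))
        values = pd.DataFrame(
            np.column_stack(mats), index=genes_a + genes_b, columns=cols
        )
        meta = pd.DataFrame(
            {
                "condition": cond_lab,
                "replicate": rep_lab,
                "layer": "protein",
                "species": sp,
            },
            index=cols,
        )
        datasets[sp] = ExpressionDataset(values, meta, "log2")

    ogmap = OrthogroupMap(
        pd.DataFrame(og_records, columns=["gene", "species", "orthogroup"])
    )
    return datasets, ogmap, truth


def multispecies_gene_pairs(
    ogmap: OrthogroupMap,
    og_pairs: Sequence[tuple[str, str]],
    species: str,
) -> list[GenePair]:
    """Per-species gene pairs realizing a list of orthogroup pairs.

    For every (orthogroup_a, orthogroup_b) pair, all combinations of the
    species' genes in the two orthogroups are returned as canonical pairs.
    """
    lut = ogmap.lookup(species)
    by_og: dict[str, list[str]] = {}
    for gene, og in lut.items():
        by_og.setdefault(og, []).append(gene)
    out: list[GenePair] = []
    for og_a, og_b in og_pairs:
        for ga in by_og.get(og_a, []):
            for gb in by_og.get(og_b, []):
                a, b = (ga, gb) if ga < gb else (gb, ga)
                out.append(GenePair(a, b))
    return sorted(set(out))


# ---------------------------------------------------------------------------
# promoters


def simulate_promoters(
    n_genes: int,
    motifs: Sequence,
    planted: Mapping[str, Sequence[str]] | None = None,
    length: int = 2000,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> tuple[dict[str, str], GroundTruth]:
    """I.i.d. background promoters with motif consensus sequences embedded.

    ``planted`` maps gene id → motif names whose consensus is written at a
    random non-overlapping position.  Default window length 2,000 bp matches
    an upstream-of-TSS promoter definition.
    """
    rng = np.random.default_rng(seed)
    by_name = {m.name: m for m in motifs}
    planted = dict(planted or {})
    for m in motifs:
        if m.width > length:
            raise ValidationError(f"motif {m.name} longer than promoter")
    bases = np.array(list("ACGT"))
    p = np.asarray(composition, dtype=float)
    p = p / p.sum()
    promoters: dict[str, str] = {}
    truth = GroundTruth()
    for i in range(n_genes):
        gene = f"G{i:05d}"
        seq = rng.choice(bases, size=length, p=p)
        occupied: list[tuple[int, int]] = []
        for name in planted.get(gene, []):
            motif = by_name[name]
            cons = motif.consensus
            w = len(cons)
            for _ in range(1000):
                pos = int(rng.integers(0, length - w + 1))
                if all(pos + w <= s or pos >= e for s, e in occupied):
                    break
            else:  # pragma: no cover - pathological density
                raise ValidationError("could not place motif without overlap")
            seq[pos : pos + w] = list(cons)
            occupied.append((pos, pos + w))
            truth.motif_positions.setdefault(gene, []).append((name, pos))
        promoters[gene] = "".join(seq)
    return promoters, truth


# ---------------------------------------------------------------------------
# PSM table


def simulate_psm_table(
    n_psms: int,
    violation_rates: Mapping[str, float] | None = None,
    seed: int = 0,
    peptides_per_protein: int = 3,
    n_single_peptide_proteins: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Toy 10-plex TMT PSM table with a controlled number of filter violations.

    ``violation_rates`` gives fractions (of ``n_psms``) for keys ``reverse``,
    ``contaminant``, ``low_score`` and ``low_intensity``; violations are
    assigned to disjoint PSMs so the surviving count is exactly
    ``n_psms - sum(round(rate * n_psms))``.
    """
    rates = dict(violation_rates or {})
    for k, v in rates.items():
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"violation rate {k}={v} outside [0,1]")
    rng = np.random.default_rng(seed)

    n_multi_prot = max(1, int(np.ceil(n_psms / peptides_per_protein)))
    proteins = [f"PROT{j:03d}" for j in range(n_multi_prot)]
    records = []
    for i in range(n_psms):
        prot = proteins[i % n_multi_prot]
        pep = f"{prot}_pep{(i // n_multi_prot) % peptides_per_protein + 1}"
        records.append((f"psm{i:04d}", prot, pep))
    for j in range(n_single_peptide_proteins):
        prot = f"SINGLE{j:03d}"
        records.append((f"psm{n_psms + j:04d}", prot, f"{prot}_pep1"))

    n_total = len(records)
    df = pd.DataFrame(records, columns=["psm_id", "protein", "peptide"])
    df["is_reverse"] = False
    df["is_contaminant"] = False
    df["score"] = rng.uniform(25.0, 80.0, n_total)
    channels = [f"tmt{c + 1}" for c in range(10)]
    inten = rng.lognormal(mean=np.log(1e5), sigma=0.5, size=(n_total, 10))
    for c, ch in enumerate(channels):
        df[ch] = inten[:, c]

    order = rng.permutation(n_psms)  # violations only among the multi-peptide PSMs
    counts = {k: int(round(rates.get(k, 0.0) * n_psms)) for k in
              ("reverse", "contaminant", "low_score", "low_intensity")}
    if sum(counts.values()) > n_psms:
        raise ValidationError("violation counts exceed n_psms")
    pos = 0
    idx = {}
    for k, c in counts.items():
        idx[k] = order[pos : pos + c]
        pos += c
    df.loc[idx["reverse"], "is_reverse"] = True
    df.loc[idx["contaminant"], "is_contaminant"] = True
    df.loc[idx["low_score"], "score"] = rng.uniform(0.0, 14.9, counts["low_score"])
    if counts["low_intensity"]:
        df.loc[idx["low_intensity"], channels] = rng.uniform(
            1.0, 999.0, size=(counts["low_intensity"], 10)
        )
    truth = GroundTruth(psm_violations=counts)
    return df, truth
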