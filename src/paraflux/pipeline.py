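"""End-to-end synthetic study: generate data, run every analysis stage.

This is the narrative backbone shared by the ``analysis/`` driver scripts,
the determinism test and the acceptance script.  A single seed drives every
stage through independent substreams, so the whole study is bitwise
reproducible.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import (
    coexpression as co,
    complexes as cx,
    conservation as cv,
    differential as de,
    motifs as mo,
    stoichiometry as st,
)
from .io import flag_has_paralog
from .simulate import (
    SimulationConfig,
    multispecies_gene_pairs,
    simulate_expression_study,
    simulate_multispecies_proteomes,
    simulate_promoters,
    simulate_psm_table,
)

TOY_MOTIF_CONSENSUS: Mapping[str, str] = {
    # 12-mers: long enough that uniform background rarely reaches the 0.8
    # relative-score hit threshold, so planted sites are discriminating
    "TFA": "ACGATCACGTTG",
    "TFB": "GGATCCTTAGCA",
    "TFC": "CATGCATTGACC",
}


def toy_motifs() -> list[mo.MotifModel]:
    out = []
    for name, cons in TOY_MOTIF_CONSENSUS.items():
        counts = np.zeros((len(cons), 4))
        for i, base in enumerate(cons):
            counts[i, "ACGT".index(base)] = 12
        out.append(mo.MotifModel.from_counts(name, counts))
    return out


def run_synthetic_study(
    seed: int = 0,
    n_pairs: int = 400,
    n_singletons: int = 600,
    n_conditions: int = 10,
    n_complexes: int = 40,
    complex_size: int = 8,
    n_orthogroup_pairs: int = 400,
    n_conserved: int = 20,
    n_null_stoich: int = 500,
    n_promoter_genes: int = 30,
    n_psms: int = 40,
) -> dict:
    """Run the full analysis chain on one seeded synthetic study.

    Returns a dict of result tables keyed by stage; see the ``analysis/``
    scripts for the narrative around each.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    out: dict = {"seed": seed}

    # --- paired expression study: divergence, complexes ---------------------
    cfg = SimulationConfig(
        n_pairs=n_pairs,
        n_singletons=n_singletons,
        n_conditions=n_conditions,
        n_replicates=3,
        divergent_fraction=0.35,
        noise_sd=0.3,
        complex_sizes=[complex_size] * n_complexes,
        content_coupling=0.4,
        ned_fraction=0.3,
        ned_delta_mix=0.5,
        seed=seeds[0],
    )
    datasets, pairs, catalog, truth = simulate_expression_study(cfg)
    rec_rna = co.pair_coexpression_table(datasets["rna"], pairs, catalog=catalog)
    rec_prot = co.pair_coexpression_table(datasets["protein"], pairs, catalog=catalog)
    delta = co.transcript_protein_delta(rec_rna, rec_prot)
    out["records_rna"] = rec_rna
    out["records_protein"] = rec_prot
    out["delta"] = delta
    out["divergent_fraction_rna"] = co.divergent_fraction(rec_rna)
    out["truth_divergent_fraction"] = float(np.mean(list(truth.divergent.values())))

    flags = flag_has_paralog(datasets["rna"].values.index, pairs)
    summaries = cx.complex_coexpression(datasets["rna"], catalog)
    summaries = cx.add_paralog_content(summaries, catalog, flags)
    summaries = cx.classify_complex_stability(summaries)
    out["complex_summaries"] = summaries
    out["content_variability"] = cx.content_variability_relation(summaries)
    out["random_complex_null"] = cx.random_complex_null(
        datasets["rna"], catalog, n_reps=20, seed=seeds[1]
    )
    out["subunit_median_R"] = cx.subunit_median_correlation(datasets["rna"], catalog)

    # --- degradation classes (delta vs NED/ED) ------------------------------
    complex_genes = catalog.all_genes()
    out["degradation"] = de.degradation_class_analysis(
        delta, truth.degradation_class, {g: g in complex_genes for g in flags}
    )

    # --- differential + stoichiometry on the protein layer ------------------
    conds = datasets["protein"].conditions()
    de_tab = de.de_table(datasets["protein"], conds[0], conds[-1])
    out["de_table"] = de_tab
    out["concordance"] = de.pair_concordance(de_tab, pairs)
    fc = st.fold_changes(datasets["protein"])
    out["stoichiometry"] = st.subunit_stability_p(
        fc, catalog, n_null=n_null_stoich, seed=seeds[2],
        comparisons=[fc.columns[-1]],
    )
    out["complex_scores"] = st.complex_coexpression_score(out["stoichiometry"])

    # --- cross-species conserved signature ----------------------------------
    ms_cfg = SimulationConfig(
        n_species=4,
        n_comparisons=7,
        n_replicates=3,
        n_orthogroup_pairs=n_orthogroup_pairs,
        n_conserved=n_conserved,
        effect_size=1.0,
        noise_sd=0.25,
        seed=seeds[3],
    )
    ms_data, ogmap, ms_truth = simulate_multispecies_proteomes(ms_cfg)
    frames = []
    og_pairs = sorted(ms_truth.conserved)
    for sp, ds in ms_data.items():
        sp_pairs = multispecies_gene_pairs(ogmap, og_pairs, sp)
        prof = cv.ratio_profiles(ds, sp_pairs)
        frames.append(cv.ratio_change_test(prof, ds.meta, species=sp))
    changes = pd.concat(frames, ignore_index=True)
    og_changes = cv.aggregate_to_orthogroups(changes, ogmap)
    signature = cv.conserved_signature(og_changes, n_species=ms_cfg.n_species)
    out["conserved_signature"] = signature
    planted = {k for k, v in ms_truth.conserved.items() if v}
    called = {
        (a, b) for a, b in signature.loc[signature["conserved"], ["og_a", "og_b"]]
        .itertuples(index=False)
    }
    tp = len(called & planted)
    out["conserved_sensitivity"] = tp / len(planted) if planted else float("nan")
    out["conserved_fdp"] = (len(called) - tp) / len(called) if called else 0.0
    delta_cols = [c for c in signature.columns if c.startswith("delta:")]
    wide = signature.set_index(["og_a", "og_b"])[delta_cols]
    wide.columns = [c.removeprefix("delta:") for c in wide.columns]
    out["ratio_pca"] = cv.ratio_pca(wide)

    # --- promoter motifs -----------------------------------------------------
    motifs = toy_motifs()
    rng = np.random.default_rng(seeds[4])
    genes = [f"G{i:05d}" for i in range(n_promoter_genes)]
    planted_motifs = {
        g: [motifs[rng.integers(len(motifs))].name] for g in genes[::2]
    }
    promoters, _ = simulate_promoters(
        n_promoter_genes, motifs, planted_motifs, seed=seeds[4]
    )
    table = mo.promoter_score_table(motifs, promoters)
    out["promoter_scores"] = table
    promoter_pairs = list(zip(genes[::2], genes[1::2]))
    shared = [
        mo.shared_tf_fraction(table.loc[a], table.loc[b])
        for a, b in promoter_pairs
    ]
    out["shared_tf"] = pd.DataFrame(
        shared, columns=["shared", "a_only", "b_only"],
        index=pd.MultiIndex.from_tuples(promoter_pairs),
    )
    out["tf_differences"] = mo.tf_difference_distribution(
        table, promoter_pairs, min_pairs=3
    )

    # --- PSM toy -------------------------------------------------------------
    psms, psm_truth = simulate_psm_table(
        n_psms,
        {"reverse": 0.1, "low_score": 0.15, "low_intensity": 0.05},
        seed=seeds[5],
    )
    matrix, retained = de.psm_summarize(psms)
    out["psm_matrix"] = matrix
    out["psm_retained"] = retained
    out["psm_truth"] = psm_truth
    return out


def study_fingerprint(results: Mapping) -> str:
    """Stable digest of every tabular/array result, for determinism checks."""
    import hashlib

    h = hashlib.sha256()
    for key in sorted(k for k in results if k != "seed"):
        val = results[key]
        h.update(key.encode())
        if isinstance(val, pd.DataFrame):
            h.update(pd.util.hash_pandas_object(val, index=True).to_numpy().tobytes())
        elif isinstance(val, pd.Series):
            h.update(pd.util.hash_pandas_object(val, index=True).to_numpy().tobytes())
        elif isinstance(val, np.ndarray):
            h.update(np.ascontiguousarray(val).tobytes())
        elif isinstance(val, (tuple, list)):
            h.update(repr([round(float(v), 12) for v in val]).encode())
        elif isinstance(val, float):
            h.update(repr(round(val, 12)).encode())
    return h.hexdigest()
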