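#!/usr/bin/env python
"""Differential abundance, pair concordance, degradation classes, PSM toy.

Runs the Welch/BH differential test between the first and last conditions of
the protein layer, classifies co-regulated pairs where both members are DE
(concordant vs opposite fold-change signs), relates delta scores to NED/ED
degradation classes, and processes a toy TMT PSM table through the filtering
and summarization rules.
"""

import argparse
from pathlib import Path

import pandas as pd

from paraflux import differential as de
from paraflux import io as pio
from paraflux.simulate import simulate_psm_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int) -> None:
    ds = pio.read_expression(
        OUT / "expression_protein.tsv", OUT / "samples_protein.tsv"
    )
    pairs = pio.read_pairs(OUT / "paralog_pairs.tsv")
    conds = ds.conditions()
    tab = de.de_table(ds, conds[0], conds[-1])
    tab.to_csv(OUT / "de_table.tsv", sep="\t", index=False, na_rep="NA")
    conc = de.pair_concordance(tab, pairs)
    conc.to_csv(OUT / "pair_concordance.tsv", sep="\t", index=False)
    n_de = int(tab["significant"].sum())
    if len(conc):
        frac_opp = (conc["concordance"] == "opposite").mean()
        print(f"{n_de} DE genes; {len(conc)} DE pairs, "
              f"{frac_opp:.0%} opposite regulation")
    else:
        print(f"{n_de} DE genes; no pair with both members DE")

    psms, truth = simulate_psm_table(
        40, {"reverse": 0.1, "low_score": 0.15, "low_intensity": 0.05}, seed=seed
    )
    matrix, retained = de.psm_summarize(psms)
    matrix.to_csv(OUT / "psm_protein_matrix.tsv", sep="\t", na_rep="NA")
    print(
        f"PSM toy: {len(psms)} PSMs, violations {truth.psm_violations}, "
        f"{len(retained)} retained, {len(matrix)} protein groups quantified"
    )


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
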