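#!/usr/bin/env python
"""Simulate a three-cohort multi-ancestry study and write the fixtures.

Three cohorts of two diverged populations each share one set of population
allele frequencies and ONE polygenic trait architecture (the same causal
variants and effects, as three studies of the same trait would).  Cohort 1
additionally carries an environmental phenotype shift along the population
axis -- residual stratification that a naive analysis confounds with
genetics.  A small reference panel for PCA is split off the same
populations.  Outputs go to results/synthetic_study/.
"""

import json
import pathlib

import numpy as np

from transgwas.simdata import (
    AncestrySpec,
    TraitArchitecture,
    draw_panel,
    emit_study,
    simulate_phenotypes,
)

OUT = pathlib.Path("results/synthetic_study")
SEED = 20_240_101
M_VARIANTS = 2_000
N_PER_POP = 1_700  # 250 reference + 3 x 400 cohort samples per population
STRAT_DELTA = 0.5


def main() -> None:
    panel = draw_panel(
        [
            AncestrySpec("popA", 0.1, N_PER_POP, strat_axis_value=0.0),
            AncestrySpec("popB", 0.1, N_PER_POP, strat_axis_value=1.0),
        ],
        n_variants=M_VARIANTS,
        ld_block_spec=[(10, 0.4)],
        seed=SEED,
    )
    anc = np.array(panel.sample_ancestry)
    a_idx, b_idx = np.flatnonzero(anc == "popA"), np.flatnonzero(anc == "popB")

    ref = panel.subset_samples(np.concatenate([a_idx[:250], b_idx[:250]]))
    emit_study(ref, _pheno_stub(ref), str(OUT / "reference_panel"), seed=SEED)

    # one trait, one architecture: phenotypes drawn on the pooled cohort
    # samples so every cohort sees the same causal variants and effects
    cohort_all = panel.subset_samples(
        np.concatenate([a_idx[250:], b_idx[250:]])
    )
    arch = TraitArchitecture(n_causal=20, h2=0.3)
    pheno_all, truth = simulate_phenotypes(cohort_all, arch, seed=SEED)
    pheno_all = pheno_all.set_index("sample_id")

    manifest = {"seed": SEED, "strat_delta": STRAT_DELTA, "cohorts": []}
    pos = {sid: i for i, sid in enumerate(cohort_all.sample_ids)}
    for c in range(3):
        keep = [
            sid for sid in cohort_all.sample_ids
            if (pos[sid] % 3) == c
        ]
        cohort = cohort_all.subset_samples([pos[s] for s in keep])
        pheno = pheno_all.loc[keep].reset_index()
        if c == 0:  # the stratified cohort: environmental shift on the axis
            pheno["phenotype"] = pheno["phenotype"] + STRAT_DELTA * pheno["axis"]
        emit_study(cohort, pheno, str(OUT / f"cohort_{c + 1}"),
                   truth=truth, seed=SEED + c)
        manifest["cohorts"].append(
            {"name": f"cohort_{c + 1}", "n": cohort.n_samples,
             "strat_delta": STRAT_DELTA if c == 0 else 0.0}
        )
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"wrote reference panel (n={ref.n_samples}) and 3 cohorts "
          f"(n={cohort.n_samples} each, {M_VARIANTS} variants) under {OUT}")
    print(f"shared architecture: 20 causal variants, h2=0.3; cohort_1 "
          f"carries the injected stratification (delta={STRAT_DELTA})")


def _pheno_stub(panel):
    import pandas as pd

    return pd.DataFrame({"sample_id": panel.sample_ids})


if __name__ == "__main__":
    main()
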