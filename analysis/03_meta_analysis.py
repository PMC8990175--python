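#!/usr/bin/env python
"""Genomic-control corrected IVW meta-analysis of the three cohorts.

Reports each cohort's inflation factor lambda, pools the cohorts with
fixed-effect inverse-variance weights, and writes the meta summary with
heterogeneity (Q, I^2) and direction strings.
"""

import pathlib

from transgwas.io import read_summary, write_summary
from transgwas.meta import genomic_lambda, meta_analyze

STUDY = pathlib.Path("results/synthetic_study")


def main() -> None:
    frames = [read_summary(str(STUDY / f"gwas_cohort_{c}.tsv")) for c in (1, 2, 3)]
    for c, df in enumerate(frames, 1):
        lam = genomic_lambda(df)
        print(f"cohort_{c}: lambda = {lam:.3f}")
    meta = meta_analyze(frames, gc=True)
    write_summary(meta, str(STUDY / "meta.tsv"))
    meta.to_csv(STUDY / "meta_full.tsv", sep="\t", index=False)
    n_gws = int((meta["P"] < 5e-8).sum())
    print(f"meta-analysis over {len(meta)} variants: {n_gws} genome-wide "
          f"significant; median I2 = {meta['I2'].median():.1f}")


if __name__ == "__main__":
    main()
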