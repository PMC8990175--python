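#!/usr/bin/env python
"""Summary-statistic conditional analysis of the strongest association region.

Takes the best meta-analysis lead, builds a +-100 kb region with in-sample
LD from the reference panel, runs forward stepwise selection, and
conditions the remaining region variants on the selected set to flag any
secondary signals.
"""

import pathlib

from transgwas.cojo import condition_on_known, stepwise_select
from transgwas.io import read_summary
from transgwas.ld import ld_from_panel
from transgwas.simdata import read_study

STUDY = pathlib.Path("results/synthetic_study")


def main() -> None:
    meta = read_summary(str(STUDY / "meta.tsv"))
    ref, _, _ = read_study(str(STUDY / "reference_panel"))
    lead = meta.sort_values("P").iloc[0]
    window = meta.loc[(meta["CHR"].astype(str) == str(lead["CHR"]))
                      & ((meta["POS"] - lead["POS"]).abs() <= 100_000)]
    ld = ld_from_panel(ref, window["SNP"].tolist())
    sel = stepwise_select(window, ld)
    print(f"region around {lead['SNP']} ({len(window)} variants): "
          f"selected {sel.selected} with joint p {list(map(float, sel.joint_p))}")

    others = [s for s in window["SNP"] if s not in sel.selected]
    cond = condition_on_known(others, sel.selected, ld, window)
    n_new = int(cond["new_signal"].sum())
    cond.to_csv(STUDY / "conditional.tsv", sep="\t", index=False)
    print(f"conditioned {len(others)} variants on the selected set: "
          f"{n_new} remain genome-wide significant (secondary signals)")


if __name__ == "__main__":
    main()
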