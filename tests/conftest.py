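import pytest

from transgwas.simdata import AncestrySpec, draw_panel


@pytest.fixture(scope="session")
def small_panel():
    """300 samples, 60 variants, two mildly diverged populations."""
    return draw_panel(
        [
            AncestrySpec("A", 0.05, 150, strat_axis_value=0.0),
            AncestrySpec("B", 0.05, 150, strat_axis_value=1.0),
        ],
        n_variants=60,
        ld_block_spec=[(4, 0.5)],
        seed=101,
    )


@pytest.fixture(scope="session")
def ld_panel():
    """Single-population panel with blocky LD for LD-dependent tests."""
    return draw_panel(
        [AncestrySpec("pop", 0.0, 800)],
        n_variants=40,
        ld_block_spec=[(5, 0.6)],
        ancestral_maf_dist=lambda r, k: r.uniform(0.2, 0.8, k),
        seed=202,
    )
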