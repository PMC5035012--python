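import pytest

from r2scan.syngenome import (InsertionSpec, build_target_reference,
                              insert_copies, simulate_element_family)

CLADES = ("R2A", "R2B", "R2C", "R2D")


@pytest.fixture(scope="session")
def target():
    """Synthetic 28S reference with 200 bp flanks (canonical site at 220)."""
    return build_target_reference(flank_len=200, seed=1)


@pytest.fixture(scope="session")
def families(target):
    """One simulated family per clade; the R2B family carries a 28S-derived
    3' UTR segment (150 bp at 85% identity) and the R2A family a ribozyme."""
    return {
        clade: simulate_element_family(
            clade,
            seed=3,
            family_id=f"fam_{clade}",
            target=target,
            ribozyme=(clade == "R2A"),
            utr3_target_segment=(150, 0.85) if clade == "R2B" else None,
        )
        for clade in CLADES
    }


@pytest.fixture(scope="session")
def demo_bundle(target, families):
    """A small array: canonical R2A, 110-bp-shifted R2B, 130-bp-shifted R2C,
    one non-specific R2D copy, with 5% decay on two of them."""
    specs = [
        InsertionSpec("fam_R2A", divergence=0.05),
        InsertionSpec("fam_R2B", offset5=110, divergence=0.05),
        InsertionSpec("fam_R2C", offset5=130),
        InsertionSpec("fam_R2D", nonspecific=True, divergence=0.05),
    ]
    return insert_copies(target, list(families.values()), specs,
                         n_units=4, spacer_len=400, seed=11)
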