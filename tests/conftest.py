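"""Shared fixtures: panels and small simulated datasets.

Everything is generated programmatically with fixed seeds; nothing is
read from disk.
"""

import numpy as np
import pytest

from sctdh import simulate as sim


@pytest.fixture(scope="session")
def panel():
    """The default 47-SNP two-region panel (specs, ld)."""
    return sim.default_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """A study-sized null cohort (130 SCT + 185 twin pairs)."""
    specs, ld = panel
    return sim.generate_cohort(sim.CohortScenario(), seed=1234, specs=specs, ld=ld)


@pytest.fixture(scope="session")
def genotypes_500(panel):
    """500 unrelated individuals on the default panel."""
    specs, ld = panel
    return sim.generate_genotypes(specs, ld, 500, seed=99)


def make_single_snp_panel(maf=0.3, n_snps=1, r2=0.0, gene="GENE1"):
    """Tiny helper panel used across test modules."""
    specs = [
        sim.SnpSpec(f"s{i + 1}", "1", 100 + i, maf, gene) for i in range(n_snps)
    ]
    target = np.full((n_snps, n_snps), r2, dtype=float)
    np.fill_diagonal(target, 1.0)
    return specs, sim.LdBlockSpec(target)
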