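import numpy as np
import pandas as pd
import pytest

import ailqtl as aq


def make_panel(n_markers=31, spacing=2.0, chrom="1"):
    pos = np.arange(n_markers) * spacing
    return pd.DataFrame({"marker": [f"{chrom}m{i:03d}" for i in range(n_markers)],
                         "chrom": chrom, "cm": pos})


@pytest.fixture(scope="session")
def panel():
    return make_panel()


@pytest.fixture(scope="session")
def gmap(panel):
    return aq.GeneticMap(panel)


@pytest.fixture(scope="session")
def f14_cohort(panel):
    """400-animal F14 cohort from the 48-pair cascade design."""
    design = aq.AILDesign(48, 14, seed=3)
    ped = aq.simulate_pedigree(design, n_final=400)
    geno = aq.simulate_genotypes(ped, panel, seed=4)
    term = ped[ped["generation"] == 14]
    return geno.subset(term["id"].tolist()), term


@pytest.fixture(scope="session")
def fixtures():
    return aq.synth_fixtures(seed=11)
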