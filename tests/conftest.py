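import numpy as np
import pandas as pd
import pytest

import sevscan as sv


@pytest.fixture(scope="session")
def small_manifest():
    return sv.generate_manifest(600, n_chromosomes=3, genes_per_chromosome=20, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_manifest):
    beta, sheet, det_p, beads = sv.generate_cohort(
        small_manifest, n_cases=10, n_controls=14, seed=12
    )
    return beta, sheet, det_p, beads


@pytest.fixture()
def toy_manifest():
    """Hand-built 12-probe manifest: one chromosome, three genes, no flags."""
    probes = [f"p{i:02d}" for i in range(12)]
    genes = ["", "g1", "g1", "g1", "g1", "g2", "g2", "g2", "", "g3;g4", "g3;g4", ""]
    man = pd.DataFrame(
        {
            "chromosome": "chr1",
            "position": np.arange(12) * 1000 + 500,
            "gene": genes,
            "island_relation": "open_sea",
            "snp_affected": False,
            "multi_mapping": False,
            "non_cpg": False,
            "sex_chromosome": False,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return man
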