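import numpy as np
import pytest

from coanpipe import (
    CopyingParams,
    GeneticMap,
    coancestry_square,
    default_c_factor,
    simulate_structured_panel,
)
from coanpipe.simdata import DemeSpec, DemographicScenario, DonorSpec, GenomeSpec


@pytest.fixture(scope="session")
def params():
    return CopyingParams()


@pytest.fixture
def tiny_map():
    cm = np.array([0.0, 1.5, 3.0, 4.2, 5.5, 7.0])
    return GeneticMap(
        np.array(["chr1"] * 6), (cm * 1e6).astype(np.int64) + 1, cm
    )


@pytest.fixture(scope="session")
def three_deme():
    """Three strongly drifted demes of 20 diploids with their coancestry
    matrices and data-driven c-factor."""
    scenario = DemographicScenario(
        demes=[
            DemeSpec("A", 20, drift=0.2),
            DemeSpec("B", 20, drift=0.2),
            DemeSpec("C", 20, drift=0.2),
        ],
        genome=GenomeSpec(n_chrom=2, chrom_length_cm=100.0, snps_per_chrom=150),
        seed=1,
    )
    panel, truth = simulate_structured_panel(scenario)
    p = CopyingParams()
    lengths = coancestry_square(panel, p)
    counts = coancestry_square(panel, p, measure="count")
    c = default_c_factor(lengths, counts)
    return {
        "panel": panel,
        "truth": truth,
        "lengths": lengths,
        "counts": counts,
        "c": c,
    }


@pytest.fixture(scope="session")
def donor_panel():
    """Two diverged donor pools next to two base-pool demes."""
    scenario = DemographicScenario(
        demes=[
            DemeSpec("U", 8, drift=0.0, pool="base"),
            DemeSpec("V", 8, drift=0.0, pool="base"),
        ],
        donors=[
            DonorSpec("D1", 8, divergence=0.4),
            DonorSpec("D2", 8, divergence=0.4),
        ],
        genome=GenomeSpec(n_chrom=2, chrom_length_cm=80.0, snps_per_chrom=160),
        seed=11,
    )
    panel, _ = simulate_structured_panel(scenario)
    roles = panel.metadata["role"]
    study = panel.subset_by_ids(list(roles[roles == "deme"].index))
    donors = panel.subset_by_ids(list(roles[roles == "donor"].index))
    return {"panel": panel, "study": study, "donors": donors}
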