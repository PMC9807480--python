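import numpy as np
import pandas as pd
import pytest

from mbrisk import CallingThresholds, CopyNumberProfile, load_default_genome
from mbrisk.genome import Arm, GenomeModel, Locus


@pytest.fixture(scope="session")
def genome():
    return load_default_genome()


@pytest.fixture(scope="session")
def thresholds():
    return CallingThresholds()


@pytest.fixture(scope="session")
def toy_genome():
    """Tiny two-chromosome genome with small coordinates for brute-force oracles."""
    arms = [
        Arm("chrA", "p", 0, 1000),
        Arm("chrA", "q", 1200, 3000),
        Arm("chrB", "p", 0, 800),
        Arm("chrB", "q", 900, 2000),
    ]
    loci = {"AMP1": Locus("AMP1", "chrA", 1500, 1560)}
    return GenomeModel(arms, loci, build="toy")


def make_profile(bins, sample_id="S1"):
    df = pd.DataFrame(bins, columns=["chrom", "start", "end", "log2"])
    return CopyNumberProfile(sample_id, df)


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def simple_cohort():
    """Small hand-built cohort table for counting-process and model tests."""
    rng = np.random.default_rng(7)
    n = 120
    rows = []
    for i in range(n):
        x = rng.random() < 0.5
        T = rng.exponential(3.0 if x else 6.0)
        C = rng.uniform(1.0, 10.0)
        obs = min(T, C)
        rows.append({
            "patient_id": f"p{i}", "age_years": rng.uniform(1, 15),
            "m_stage": "M+" if x else "M0", "resection": "R0", "histology": "CMB",
            "therapy": "primary_CSI", "pfs_years": obs, "pfs_event": T <= C,
            "os_years": obs, "os_event": T <= C,
            "rt_start_years": 0.25 if rng.random() < 0.8 else np.nan,
            "myc_amp": rng.random() < 0.1, "mycn_amp": rng.random() < 0.1,
            "group": "Group3" if rng.random() < 0.4 else "Group4",
            "subgroup": rng.choice(["II", "VII", "VIII"]),
            "wca_phenotype": "FR" if rng.random() < 0.2 else "SR",
            "cm": rng.choice(["LR", "SR", "HR", "VHR"]),
        })
    return pd.DataFrame(rows)
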