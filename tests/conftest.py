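import numpy as np
import pandas as pd
import pytest

from crocdiag import GenotypeMatrix, SimConfig, find_diagnostic_loci, simulate_dataset


def build_matrix(calls, marker_class="snp", sample_ids=None, populations=None,
                 depth=None, reproducibility=None, sample_extra=None):
    """Hand-build a GenotypeMatrix from a nested list of call codes (−1 missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_loci, n_samples = calls.shape
    if sample_ids is None:
        sample_ids = [f"S{j + 1:02d}" for j in range(n_samples)]
    mc = [marker_class] * n_loci if isinstance(marker_class, str) else list(marker_class)
    loci = pd.DataFrame(
        {
            "contig": ["c1"] * n_loci,
            "position": np.arange(1, n_loci + 1) * 100,
            "ref": ["A"] * n_loci,
            "alt": ["G"] * n_loci,
            "depth": [10.0] * n_loci if depth is None else list(depth),
            "reproducibility": [1.0] * n_loci if reproducibility is None
            else list(reproducibility),
            "call_rate": 1.0,
            "marker_class": mc,
        },
        index=pd.Index([f"L{i + 1:03d}" for i in range(n_loci)], name="locus_id"),
    )
    samples = pd.DataFrame(
        {"population": ["CANDIDATE"] * n_samples if populations is None
         else list(populations)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if sample_extra:
        for col, vals in sample_extra.items():
            samples[col] = vals
    return GenotypeMatrix(calls, loci, samples)


@pytest.fixture(scope="session")
def reciprocal_cohort():
    """1000 reciprocally fixed loci, complete calls, parents plus a small
    pedigree of every hybrid class — the workhorse for panel/classifier and
    clustering checks."""
    cfg = SimConfig(
        n_loci=1000, frac_reciprocal_fixed=1.0, frac_focal_fixed_other_poly=0.0,
        frac_shared_poly=0.0, missing_rate=0.0, seed=11,
        n_A=10, n_B=10, n_B_au=5,
        pedigree_counts={"F1": 4, "F2": 4, "BC1_toA": 4, "BC1_toB": 4,
                         "BC2_toA": 4, "BC2_toB": 4},
    )
    m, truth = simulate_dataset(cfg)
    parents = m.take_samples((m.samples["population"] != "CANDIDATE").to_numpy())
    panel = find_diagnostic_loci(parents, mode="strict_absent")
    return m, truth, parents, panel


@pytest.fixture(scope="session")
def mixed_dataset():
    """Realistic mixed-category dataset with PA loci and missing calls."""
    cfg = SimConfig(n_loci=1500, frac_pa=0.3, missing_rate=0.03, seed=5)
    m, truth = simulate_dataset(cfg)
    return m, truth, cfg
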