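import numpy as np
import pytest

import hapscan
from hapscan.io import gl_to_dosage
from hapscan.pipeline import discover_haploblocks, genotype_and_validate

SCENARIO_SEED = 1


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic scenario: 8 pops x 25 samples, planted inversion
    (windows 20-29, d = 0.3, arrangement cline 0.2 -> 0.8), 4x coverage."""
    cfg = hapscan.SimulationConfig()
    truth, glm, depth = hapscan.simulate_dataset(cfg, SCENARIO_SEED)
    return cfg, truth, glm, depth


@pytest.fixture(scope="session")
def default_discovery(default_dataset):
    cfg, truth, glm, depth = default_dataset
    res = discover_haploblocks(
        glm, cfg.contig_lengths, mean_depth=depth.mean(axis=1), seed=SCENARIO_SEED
    )
    return cfg, truth, res


@pytest.fixture(scope="session")
def lowcov_discovery():
    """Same scenario at 1x mean coverage."""
    cfg = hapscan.SimulationConfig(coverage=1.0)
    truth, glm, depth = hapscan.simulate_dataset(cfg, SCENARIO_SEED)
    res = discover_haploblocks(
        glm, cfg.contig_lengths, mean_depth=depth.mean(axis=1), seed=SCENARIO_SEED
    )
    return cfg, truth, glm, res


@pytest.fixture(scope="session")
def null_dataset():
    """Negative control: d = 0 (the 'inversion' interval carries no
    arrangement signal)."""
    cfg = hapscan.SimulationConfig(inversion=hapscan.InversionSpec(d=0.0))
    truth, glm, depth = hapscan.simulate_dataset(cfg, SCENARIO_SEED)
    res = discover_haploblocks(
        glm, cfg.contig_lengths, mean_depth=depth.mean(axis=1), seed=SCENARIO_SEED
    )
    return cfg, truth, glm, res


def genotype_concordance(labels, truth_genotype):
    """Concordance of aa/ab/bb calls with the truth arrangement count,
    maximized over the two arrangement polarities."""
    m = {"aa": 0, "ab": 1, "bb": 2, "missing": -1}
    ours = np.array([m[l] for l in labels])
    t = np.asarray(truth_genotype)
    return max(float(np.mean(ours == t)), float(np.mean(ours == 2 - t)))


def force_genotype_truth_region(glm, region, seed=SCENARIO_SEED):
    """Run the genotyping/validation machinery on an explicit region."""
    dos = gl_to_dosage(glm).dosage
    chrom = glm.sites["chrom"].to_numpy()
    pos = glm.sites["pos"].to_numpy()
    return genotype_and_validate(glm, dos, chrom, pos, region, seed=seed)
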