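import numpy as np
import pandas as pd
import pytest

from strainmask import SimulationConfig, build_design
from strainmask.arrayio import ArrayDesign, PairTable
from strainmask.config import DyeBias, FamilySpec


@pytest.fixture
def tiny_config():
    """Small but non-degenerate study: 4 supercontigs x 25 genes x 4 probes."""
    return SimulationConfig(
        n_supercontigs=4,
        genes_per_supercontig=25,
        strain_divergences={"low": 0.05, "high": 1.5},
        seed=7,
    )


@pytest.fixture
def tiny_design(tiny_config):
    return build_design(tiny_config)


@pytest.fixture
def plain_config():
    """No families, no CNV, no dye bias, no UTR effect: pure noise model."""
    return SimulationConfig(
        n_supercontigs=4,
        genes_per_supercontig=25,
        strain_divergences={"null": 0.0},
        utr_rate_multiplier=1.0,
        family_specs=[],
        cnv_events=[],
        dye_bias=DyeBias(0.0, 0.0),
        seed=11,
    )


def make_pair_table(probe_ids, intensities, channel="Cy3", strain="s"):
    return PairTable(
        pd.DataFrame({"probe_id": probe_ids, "seq_id": ["x"] * len(probe_ids), "intensity": intensities}),
        channel=channel,
        strain=strain,
    )


def make_linear_design(n_probes, chrom="Sctg_00", seq_size=4, region="CDS"):
    """One chromosome of consecutively placed probes, one sequence per 4."""
    ids = [f"P{i:06d}" for i in range(n_probes)]
    return ArrayDesign(
        pd.DataFrame(
            {
                "probe_id": ids,
                "seq_id": [f"S{i // seq_size:06d}" for i in range(n_probes)],
                "region": region,
                "chrom": chrom,
                "position": np.arange(n_probes) * 10,
                "families": "",
            }
        )
    )
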