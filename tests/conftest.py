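import numpy as np
import pandas as pd
import pytest

from mztenh import simulate


@pytest.fixture(scope="session")
def small_config():
    """A fast small-genome configuration shared by integration tests."""
    return simulate.SimulationConfig(regions_per_class=40, depth=250_000,
                                     seed=simulate.DEFAULT_SEED)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Generated truth + coverage for a small synthetic study."""
    spec = simulate.default_genome_spec(n_genes=160,
                                        seed=small_config.seed)
    profiles = simulate.default_profiles()
    truth = simulate.generate_regions(spec, small_config)
    fragments, spikes = simulate.simulate_coverage(
        truth, profiles, small_config, dict(spec.chromosomes))
    return {"spec": spec, "config": small_config, "profiles": profiles,
            "truth": truth, "fragments": fragments, "spikes": spikes}


@pytest.fixture()
def toy_regions():
    """Three hand-built regions with flanks on one 100-kb chromosome."""
    df = pd.DataFrame({
        "region_id": ["atac_L00001", "atac_L00002", "atac_L00003"],
        "chrom": ["chr1"] * 3,
        "start": [10_000, 30_000, 50_000],
        "end": [10_500, 30_600, 50_400],
        "source": ["L"] * 3,
        "taxonomy": ["distal"] * 3,
    })
    df["left_flank_start"] = df["start"] - 500
    df["left_flank_end"] = df["start"]
    df["right_flank_start"] = df["end"]
    df["right_flank_end"] = df["end"] + 500
    df["downstream_is_right"] = True
    return df


def brute_force_overlap_counts(fragments: pd.DataFrame, intervals) -> list:
    """O(F x R) oracle for interval overlap counting."""
    out = []
    for chrom, start, end in intervals:
        n = 0
        for _, f in fragments.iterrows():
            if f["chrom"] == chrom and f["start"] < end and f["end"] > start:
                n += 1
        out.append(n)
    return out
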