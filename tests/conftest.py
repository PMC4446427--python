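import pytest

from tractvar import map_variants, scan_sequence
from tractvar import simulate as sim


@pytest.fixture(scope="session")
def small_sim():
    """A small planted genome with variants, mapped end to end.

    50 tracts per (class, n, flank-pair) stratum: 2,000 tracts total,
    with SNVs, slippage and indels drawn from the default mutation model.
    """
    genome, truth = sim.simulate_genome(sim.default_placements(50), seed=1)
    variants, var_truth = sim.simulate_variants(genome, truth, seed=2)
    tracts = sorted(
        scan_sequence("synth1", genome["synth1"]), key=lambda t: (t.chrom, t.start)
    )
    assignments = map_variants(tracts, variants, genome)
    return {
        "genome": genome,
        "truth": truth,
        "variants": variants,
        "var_truth": var_truth,
        "tracts": tracts,
        "assignments": assignments,
    }
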