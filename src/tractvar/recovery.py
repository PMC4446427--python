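"""Canonical parameter-recovery experiments on synthetic data.

These run the full pipeline (generate -> scan -> census -> map ->
statistics) against the generator's known parameters and report how well
each is recovered.  They are the package's self-check that the
statistics estimate what they claim to estimate, at sample sizes where
the estimates should be tight.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .ncp import (classify_extrema, dyad_profile, estimate_period,
                  group_tracts_by_extrema, max_min_comparison,
                  pair_tracts_midpoints)
from .spectra import positional_spectrum, slippage_stats
from .tracts import build_census, scan_sequence
from .variants import map_variants
from . import simulate as sim


def run_mutation_recovery(seed: int, per_stratum: int = 2500) -> dict:
    """Full spectra pipeline on a planted genome; recovers the positional
    rate profile, the flank-direction probability and the slippage peak.

    ``per_stratum`` tracts per (class, length, flank-pair) stratum: the
    default plants 100,000 tracts (10 lengths x 2 classes x 2 flank
    pairs).
    """
    model = sim.MutationModel()
    genome, truth = sim.simulate_genome(
        sim.default_placements(per_stratum), seed=seed
    )
    variants, _ = sim.simulate_variants(genome, truth, model=model, seed=seed + 1)
    tracts = sorted(
        scan_sequence("synth1", genome["synth1"]), key=lambda t: (t.chrom, t.start)
    )
    census = build_census(tracts)
    assignments = map_variants(tracts, variants, genome)

    spec = positional_spectrum(assignments, census).table
    interior = spec[(spec.position >= 1) & (spec.position <= spec.n)]
    cell = (
        interior.groupby(["tract_class", "n", "position"])["percent"].sum().reset_index()
    )
    profile_r = {}
    for cls, g in cell.groupby("tract_class"):
        w = [model.positional_weight(cls, int(r.n), int(r.position))
             for r in g.itertuples(index=False)]
        profile_r[cls] = float(stats.pearsonr(g.percent, w).statistic)

    theta_hat, theta_se, n_theta = sim.estimate_theta(assignments)

    slip = slippage_stats(assignments, census)
    slip_peak = {
        cls: int(g.loc[g.f_slip.idxmax(), "n"]) for cls, g in slip.groupby("tract_class")
    }

    return {
        "n_tracts": len(tracts),
        "n_variants": len(variants),
        "model": model,
        "census": census,
        "assignments": assignments,
        "profile_r": profile_r,
        "theta_hat": theta_hat,
        "theta_se": theta_se,
        "n_theta_snvs": n_theta,
        "slippage_peak": slip_peak,
        "slippage_table": slip,
    }


def run_ncp_recovery(
    seed: int,
    n_tracts: int = 20000,
    period: float = 10.5,
    amplitude: float = 0.5,
    minima_excess: float = 0.2,
) -> dict:
    """Nucleosome phasing pipeline on tracts with one midpoint each.

    Places length-5 A-tracts with a cosine rotational preference of the
    given period/amplitude, injects an SNV rate ``minima_excess`` higher
    for tracts sitting at rotational minima, and recovers both the
    period and the minima-vs-maxima difference.
    """
    genome, truth = sim.simulate_genome(
        [("A", 5, "T", "T", n_tracts)], seed=seed, sep_min=150, sep_max=250
    )
    mids, ncp_truth = sim.simulate_ncp(
        truth, period=period, amplitude=amplitude, seed=seed + 1, one_per_tract=True
    )
    d_map = {
        (r.chrom, r.start, r.end): r.d for r in ncp_truth.itertuples(index=False)
    }

    def modifier(t):
        d = d_map[(t.chrom, t.start, t.end)]
        return 1.0 + minima_excess * (1 - np.cos(2 * np.pi * d / period)) / 2

    model = sim.MutationModel(snv_base=0.05)
    variants, _ = sim.simulate_variants(
        genome, truth, model=model, seed=seed + 2, rate_modifier=modifier
    )
    tracts = sorted(
        scan_sequence("synth1", genome["synth1"]), key=lambda t: (t.chrom, t.start)
    )
    assignments = map_variants(tracts, variants, genome)

    profile = dyad_profile(tracts, mids, unit="center")
    period_hat, period_p = estimate_period(profile.counts, profile.d, seed=seed + 3)
    maxima, minima = classify_extrema(profile, smoothing_window=3)
    pairs = pair_tracts_midpoints(tracts, mids)
    groups = group_tracts_by_extrema(pairs, maxima, minima)
    comparison = max_min_comparison(assignments, groups)

    return {
        "n_tracts": len(tracts),
        "n_midpoints": len(mids),
        "profile": profile,
        "period_hat": period_hat,
        "period_p": period_p,
        "maxima": maxima,
        "minima": minima,
        "comparison": comparison,
    }
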