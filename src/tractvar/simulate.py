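"""Synthetic genomes, variant sets, NCP placements and step ensembles.

The generator plants maximal homopolymer tracts with controlled length
and flank composition in a run-free random background, then draws
variants from a mutation model with the statistical structure the
analyses assume: position-dependent SNV rates with hotspots at the tract
edges (A-tracts) or at positions 2-3 (G-tracts), flank-directed A-tract
substitutions, bell-shaped slippage rates over tract length, and
plateauing indel rates.  Every simulated event is recorded in a truth
table so the full pipeline (scan -> census -> map -> spectra) can be
checked for exact recovery.

All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .structure import StepParamSeries
from .tracts import COMPLEMENT, Tract
from .variants import VariantRecord

BASES = "ACGT"


def _bell(n: float, mu: float, sigma: float) -> float:
    return float(np.exp(-((n - mu) ** 2) / (2 * sigma**2)))


@dataclass
class MutationModel:
    """Generative model for tract-associated variation.

    Positional SNV rates are ``snv_base * weight(class, n, p)`` per
    tract base; the weight profile places a ``hotspot_fold``-fold excess
    at positions 1 and n of A-tracts and positions 2-3 of G-tracts,
    modulated over tract length by a Gaussian bell peaking at
    ``snv_peak_n``.  A-tract alts point at the nearer flanking base with
    probability ``theta`` and are uniform over the three non-tract bases
    otherwise; G-tract alts follow ``g_spectrum``.  The slippage bell is
    parameterized on the normalized F-slip scale (per-tract probability
    = n * height * bell(n)), so the configured peak length is the argmax
    of F slip.  Indel rates are zero below ``indel_min_n`` and constant
    (on the F-Indel scale) above it.
    """

    snv_base: float = 0.01
    hotspot_fold: float = 10.0
    snv_peak_n: dict = field(default_factory=lambda: {"A": 9.0, "G": 8.0})
    snv_sigma: float = 1.5
    theta: float = 0.9
    g_spectrum: dict = field(
        default_factory=lambda: {"T": 0.45, "C": 0.35, "A": 0.20}
    )
    flank_snv_rate: float = 0.01
    slippage_height: float = 0.02
    slippage_peak_n: dict = field(default_factory=lambda: {"A": 8.0, "G": 9.0})
    slippage_sigma: float = 1.5
    plus_minus_ratio: float = 2.0
    indel_level: dict = field(default_factory=lambda: {"A": 0.003, "G": 0.03})
    indel_flank_level: dict = field(default_factory=lambda: {"A": 0.01, "G": 0.05})
    indel_min_n: int = 7
    indel_del_geom_p: float = 0.5

    def positional_weight(self, tract_class: str, n: int, p: int) -> float:
        """Relative SNV weight at interior position p (1..n)."""
        hot = {1, n} if tract_class == "A" else ({2, 3} if n >= 3 else {1, 2})
        excess = (self.hotspot_fold - 1.0) * _bell(
            n, self.snv_peak_n[tract_class], self.snv_sigma
        )
        return 1.0 + excess if p in hot else 1.0

    def snv_rate(self, tract_class: str, n: int, p: int) -> float:
        return min(self.snv_base * self.positional_weight(tract_class, n, p), 0.9)

    def slippage_prob(self, tract_class: str, n: int) -> float:
        f = self.slippage_height * _bell(
            n, self.slippage_peak_n[tract_class], self.slippage_sigma
        )
        return min(n * f, 0.9)

    def indel_prob(self, tract_class: str, n: int) -> float:
        if n < self.indel_min_n:
            return 0.0
        return min(n * self.indel_level[tract_class], 0.9)

    def indel_flank_prob(self, tract_class: str, n: int) -> float:
        if n < self.indel_min_n:
            return 0.0
        return min(self.indel_flank_level[tract_class], 0.9)

    def validate(self) -> None:
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must lie in [0, 1]")
        s = sum(self.g_spectrum.values())
        if not np.isclose(s, 1.0):
            raise ValueError("g_spectrum weights must sum to 1")
        for v in (self.snv_base, self.flank_snv_rate, self.slippage_height):
            if v < 0:
                raise ValueError("rates must be non-negative")


# ---------------------------------------------------------------------------
# Genome


def default_placements(
    per_stratum: int,
    lengths: Sequence[int] = tuple(range(4, 14)),
    a_flanks: Sequence[tuple[str, str]] = (("T", "T"), ("C", "C")),
    g_flanks: Sequence[tuple[str, str]] = (("C", "T"), ("T", "A")),
) -> list[tuple[str, int, str, str, int]]:
    """Uniform placement request across classes, lengths and flank pairs."""
    out = []
    for n in lengths:
        for f5, f3 in a_flanks:
            out.append(("A", n, f5, f3, per_stratum))
        for f5, f3 in g_flanks:
            out.append(("G", n, f5, f3, per_stratum))
    return out


def simulate_genome(
    placements: Sequence[tuple[str, int, str, str, int]],
    seed: int,
    gc: float = 0.4,
    sep_min: int = 5,
    sep_max: int = 20,
    chrom: str = "synth1",
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant maximal tracts in a run-free random background.

    ``placements`` rows are (tract_class, n, flank5, flank3, count) with
    flanks on the purine strand.  Each planted tract is embedded with its
    two flank bases and separated from its neighbours by ``sep_min`` to
    ``sep_max`` background bases; the background never contains a
    same-base run of 4+ and never extends a planted unit, so a scan of
    the genome recovers exactly the planted tracts.  Orientation
    (purine strand + or -) is drawn 50/50.

    Returns ({chrom: sequence}, truth table).
    """
    rng = np.random.default_rng(seed)
    units: list[tuple[str, str, int, str, str, str]] = []
    for tract_class, n, f5, f3, count in placements:
        base = "A" if tract_class == "A" else "G"
        if f5 == base or f3 == base:
            raise ValueError(f"flank equals tract base in ({tract_class},{n},{f5},{f3})")
        if not 4 <= n <= 13:
            raise ValueError(f"tract length {n} outside 4..13")
        for _ in range(count):
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                s = f5 + base * n + f3
            else:
                s = COMPLEMENT[f3] + COMPLEMENT[base] * n + COMPLEMENT[f5]
            units.append((s, tract_class, n, strand, f5, f3))
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def background(length: int, forbid_first: str | None, forbid_last: str | None,
                   prev_tail: str) -> str:
        if length <= 0:
            return ""
        out = [BASES[i] for i in rng.choice(4, size=length, p=probs)]

        def redraw(i: int, *avoid: str | None) -> None:
            while out[i] in avoid or _would_run(i):
                out[i] = BASES[rng.choice(4, p=probs)]

        def _would_run(i: int) -> bool:
            ctx = (prev_tail + "".join(out[max(0, i - 3) : i]))[-3:]
            return len(ctx) == 3 and ctx == out[i] * 3

        redraw(0, forbid_first, forbid_last if length == 1 else None)
        for i in range(1, length):
            if _would_run(i) or (i == length - 1 and out[i] == forbid_last):
                redraw(i, forbid_last if i == length - 1 else None)
        return "".join(out)

    parts: list[str] = []
    truth_rows = []
    pos = 0
    lead = background(int(rng.integers(sep_min, sep_max + 1)),
                      None, units[0][0][0] if units else None, "")
    parts.append(lead)
    pos += len(lead)
    for i, (s, tract_class, n, strand, f5, f3) in enumerate(units):
        start = pos + 1  # run starts after the embedded 5' flank base
        truth_rows.append((chrom, start, start + n, n, tract_class, strand, f5, f3))
        parts.append(s)
        pos += len(s)
        nxt = units[i + 1][0][0] if i + 1 < len(units) else None
        sep = background(int(rng.integers(sep_min, sep_max + 1)), s[-1], nxt, s[-3:])
        parts.append(sep)
        pos += len(sep)
    seq = "".join(parts)
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "n", "tract_class", "purine_strand",
                 "flank5", "flank3"],
    )
    return {chrom: seq}, truth


def truth_to_tracts(truth: pd.DataFrame) -> list[Tract]:
    return [
        Tract(r.chrom, r.start, r.end, r.tract_class, r.purine_strand, r.flank5, r.flank3)
        for r in truth.itertuples(index=False)
    ]


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Variants


def simulate_variants(
    genome: dict[str, str],
    truth_tracts: pd.DataFrame | Sequence[Tract],
    model: MutationModel | None = None,
    seed: int = 0,
    rate_modifier: Callable[[Tract], float] | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Draw variants from the mutation model over the planted tracts.

    Returns normalized, coordinate-sorted, duplicate-free records plus a
    truth table listing every event's intended category, purine-strand
    position/junction/location and substitution.  ``rate_modifier`` can
    scale a tract's SNV rate (used e.g. to inject nucleosome effects).

    Events whose classification would be ambiguous under apply-and-rescan
    (e.g. a flank deletion that merges runs) are rejected and redrawn as
    a different event type or skipped.
    """
    model = model or MutationModel()
    model.validate()
    rng = np.random.default_rng(seed)
    if isinstance(truth_tracts, pd.DataFrame):
        tracts = truth_to_tracts(truth_tracts)
    else:
        tracts = list(truth_tracts)

    variants: list[VariantRecord] = []
    truth_rows: list[tuple] = []
    used: set[tuple[str, int, str, str]] = set()

    def emit(v: VariantRecord, tract: Tract, category: str, position, location,
             substitution: str) -> None:
        key = (v.chrom, v.pos, v.ref, v.alt)
        if key in used:
            return
        used.add(key)
        variants.append(v)
        truth_rows.append(
            (tract.chrom, tract.start, tract.end, tract.n, tract.tract_class,
             category, position, location, substitution, v.size)
        )

    for t in tracts:
        seq = genome[t.chrom]
        mult = rate_modifier(t) if rate_modifier is not None else 1.0
        _sim_snvs(t, seq, model, rng, mult, emit)
        _sim_flank_snvs(t, seq, model, rng, emit)
        _sim_slippage(t, seq, model, rng, emit)
        _sim_indels(t, seq, model, rng, emit)

    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "n", "tract_class", "category",
                 "position", "location", "substitution", "indel_size"],
    )
    return variants, truth


def _purine_coord(t: Tract, p: int) -> int:
    """Forward-strand coordinate of purine-strand position p (0..n+1)."""
    if t.purine_strand == "+":
        return t.start + p - 1
    return t.end - p


def _sim_snvs(t: Tract, seq: str, model: MutationModel, rng, mult, emit) -> None:
    base = t.tract_class
    for p in range(1, t.n + 1):
        rate = min(model.snv_rate(base, t.n, p) * mult, 0.95)
        if rng.random() >= rate:
            continue
        if base == "A":
            flank = t.flank5 if p <= (t.n + 1) / 2 else t.flank3
            if flank in "CGT" and rng.random() < model.theta:
                alt_p = flank
            else:
                alt_p = "CGT"[rng.integers(3)]
        else:
            tos = list(model.g_spectrum)
            alt_p = tos[rng.choice(len(tos), p=list(model.g_spectrum.values()))]
        x = _purine_coord(t, p)
        ref_f = seq[x]
        alt_f = alt_p if t.purine_strand == "+" else COMPLEMENT[alt_p]
        emit(
            VariantRecord(t.chrom, x + 1, ref_f, alt_f),
            t, "tract_SNV", p, "", f"{base}>{alt_p}",
        )


def _sim_flank_snvs(t: Tract, seq: str, model: MutationModel, rng, emit) -> None:
    for p in (0, t.n + 1):
        if rng.random() >= model.flank_snv_rate:
            continue
        x = _purine_coord(t, p)
        if x < 0 or x >= len(seq):
            continue
        ref_f = seq[x]
        alt_f = rng.choice([b for b in BASES if b != ref_f])
        ref_p = ref_f if t.purine_strand == "+" else COMPLEMENT[ref_f]
        alt_p = alt_f if t.purine_strand == "+" else COMPLEMENT[alt_f]
        emit(
            VariantRecord(t.chrom, x + 1, ref_f, str(alt_f)),
            t, "flank_SNV", p, "", f"{ref_p}>{alt_p}",
        )


def _sim_slippage(t: Tract, seq: str, model: MutationModel, rng, emit) -> None:
    if rng.random() >= model.slippage_prob(t.tract_class, t.n):
        return
    rb = seq[t.start]
    anchor = seq[t.start - 1]
    rho = model.plus_minus_ratio
    plus = rng.random() < rho / (1.0 + rho)
    if plus:
        v = VariantRecord(t.chrom, t.start, anchor, anchor + rb)
        j = 0 if t.purine_strand == "+" else t.n
        emit(v, t, "slippage_plus", j, "", "")
    else:
        v = VariantRecord(t.chrom, t.start, anchor + rb, anchor)
        emit(v, t, "slippage_minus", None, "in_tract", "")


def _sim_indels(t: Tract, seq: str, model: MutationModel, rng, emit) -> None:
    rb = seq[t.start]
    if rng.random() < model.indel_prob(t.tract_class, t.n):
        if rng.random() < 0.5 and t.n >= 3:
            # deletion of >= 2 run bases: stays an indel, never slippage;
            # emitted at the leftmost (normalized) placement
            size = min(int(2 + rng.geometric(model.indel_del_geom_p) - 1), t.n)
            anchor = seq[t.start - 1]
            v = VariantRecord(t.chrom, t.start, anchor + rb * size, anchor)
            emit(v, t, "indel_del", None, "in_tract", "")
        else:
            # interior single-base insertion of a non-run base: splits the run
            j = int(rng.integers(1, t.n)) if t.n >= 2 else 1
            ins = rng.choice([b for b in BASES if b != rb])
            a0 = t.start + j - 1 if t.purine_strand == "+" else t.end - j - 1
            v = VariantRecord(t.chrom, a0 + 1, seq[a0], seq[a0] + str(ins))
            emit(v, t, "indel_ins", j, "", "")
    # flank-adjacent indels
    for side in ("before", "after"):
        if rng.random() >= model.indel_flank_prob(t.tract_class, t.n):
            continue
        if t.purine_strand == "+":
            coord = t.start - 1 if side == "before" else t.end
        else:
            coord = t.end if side == "before" else t.start - 1
        if rng.random() < 0.5:
            # delete the flank base; reject layouts where runs would merge
            if coord - 1 < 0 or coord + 1 >= len(seq):
                continue
            if seq[coord - 1] == seq[coord] or seq[coord + 1] == seq[coord - 1]:
                continue
            if coord == t.start - 1 and seq[coord - 1] == rb:
                continue
            if coord == t.end and seq[coord + 1] == rb:
                continue
            v = VariantRecord(t.chrom, coord, seq[coord - 1] + seq[coord], seq[coord - 1])
            emit(v, t, "indel_del", None, f"{side}_tract", "")
        else:
            # insert a non-run, non-anchor base at the outermost junction
            jj = 0 if side == "before" else t.n
            if t.purine_strand == "+":
                a0 = t.start - 1 if side == "before" else t.end - 1
            else:
                a0 = t.end - 1 if side == "before" else t.start - 1
            choices = [b for b in BASES if b != rb and b != seq[a0]]
            ins = rng.choice(choices)
            v = VariantRecord(t.chrom, a0 + 1, seq[a0], seq[a0] + str(ins))
            emit(v, t, "indel_ins", jj, "", "")


def write_vcf(
    records: Sequence[VariantRecord], path: str, contigs: dict[str, int]
) -> None:
    """Minimal VCF 4.2 writer for simulated call sets."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tractvar-simulate\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in records:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# NCP placements


def simulate_ncp(
    tracts: Sequence[Tract] | pd.DataFrame,
    period: float = 10.5,
    amplitude: float = 0.5,
    orientation_bias: float = 0.0,
    n_midpoints: int = 20000,
    seed: int = 0,
    one_per_tract: bool = False,
) -> tuple[list[tuple[str, int]], pd.DataFrame]:
    """Place nucleosome midpoints around tract centers with a cosine
    rotational preference.

    Offsets d (tract center minus midpoint) are drawn from a density
    proportional to 1 + amplitude*cos(2*pi*d/period) on [-73, 73].  With
    ``orientation_bias`` b > 0 the tract paired at offset d is taken from
    the C-forward pool with odds (1 + b*cos(2*pi*d/period)) : 1, so the
    C/G orientation ratio oscillates with amplitude ~b.  Returns the
    midpoint list and a placement truth table.

    With ``one_per_tract`` every tract receives exactly one midpoint (as
    for uniquely well-positioned nucleosomes) and ``n_midpoints`` is
    ignored.
    """
    if not 8 <= period <= 13:
        raise ValueError("period must lie in [8, 13]")
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must lie in [0, 1)")
    if orientation_bias < 0:
        raise ValueError("orientation bias must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(tracts, pd.DataFrame):
        tracts = truth_to_tracts(tracts)
    tracts = [t for t in tracts if t.center >= 73]  # keep midpoints on-sequence
    if not tracts:
        raise ValueError("no tracts far enough from the sequence start")
    d_axis = np.arange(-73, 74)
    dens = 1.0 + amplitude * np.cos(2 * np.pi * d_axis / period)
    dens = dens / dens.sum()
    n_place = len(tracts) if one_per_tract else n_midpoints
    ds = rng.choice(d_axis, size=n_place, p=dens)

    c_pool = [t for t in tracts if t.purine_strand == "-"]
    g_pool = [t for t in tracts if t.purine_strand == "+"]
    midpoints: list[tuple[str, int]] = []
    rows = []
    for i, d in enumerate(ds):
        if one_per_tract:
            t = tracts[i]
        elif orientation_bias > 0 and c_pool and g_pool:
            r = 1.0 + orientation_bias * np.cos(2 * np.pi * d / period)
            pool = c_pool if rng.random() < r / (1.0 + r) else g_pool
            t = pool[int(rng.integers(len(pool)))]
        else:
            t = tracts[int(rng.integers(len(tracts)))]
        m = t.center - int(d)
        midpoints.append((t.chrom, m))
        rows.append((t.chrom, t.start, t.end, int(d), t.purine_strand))
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "d", "purine_strand"])
    return midpoints, truth


def write_midpoints_bed(midpoints: Sequence[tuple[str, int]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, pos in midpoints:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


# ---------------------------------------------------------------------------
# Step-parameter ensembles


def simulate_step_params(
    mean: Sequence[float],
    cov: np.ndarray,
    n_frames: int,
    seed: int = 0,
    label: str = "sim",
) -> StepParamSeries:
    """Multivariate-normal step-parameter frames with known covariance."""
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if mean.shape != (6,) or cov.shape != (6, 6):
        raise ValueError("mean must be length 6 and cov 6x6")
    eig = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eig.min() < -1e-10:
        raise ValueError("covariance must be positive semi-definite")
    rng = np.random.default_rng(seed)
    frames = rng.multivariate_normal(mean, cov, size=n_frames, method="svd")
    return StepParamSeries(label, frames)


# ---------------------------------------------------------------------------
# Recovery reporting


def recovery_report(rows: Iterable[dict]) -> pd.DataFrame:
    """Truth-vs-estimate comparison with normal CIs and |z| <= 3 flags.

    Each row dict needs: parameter, truth, estimate, se (se may be 0 for
    exact quantities, which then must match within 1e-9).
    """
    out = []
    for r in rows:
        truth, est, se = float(r["truth"]), float(r["estimate"]), float(r["se"])
        if se > 0:
            z = (est - truth) / se
            ok = abs(z) <= 3
            lo, hi = est - 1.96 * se, est + 1.96 * se
        else:
            z = 0.0 if abs(est - truth) <= 1e-9 else np.inf
            ok = np.isfinite(z)
            lo = hi = est
        out.append((r["parameter"], truth, est, se, lo, hi, z, ok))
    return pd.DataFrame(
        out,
        columns=["parameter", "truth", "estimate", "se", "ci_low", "ci_high", "z", "pass"],
    )


def estimate_theta(assignments) -> tuple[float, float, int]:
    """Recover the flank-direction probability from A-tract SNVs.

    Uses tracts whose two flanks are the same non-N base B: the fraction
    f of alts equal to B satisfies f = theta + (1 - theta)/3 under the
    model (a uniform draw hits B one time in three), so
    theta = (3f - 1)/2.  Returns (theta_hat, se, count).
    """
    from .variants import assignments_to_frame

    df = assignments if isinstance(assignments, pd.DataFrame) else assignments_to_frame(assignments)
    df = df[
        (df.category == "tract_SNV")
        & (df.tract_class == "A")
        & (df.flank5 == df.flank3)
        & (df.flank5 != "N")
    ]
    m = len(df)
    if m == 0:
        return np.nan, np.nan, 0
    alt = df.substitution.str.split(">").str[1]
    f = float((alt == df.flank5).mean())
    se_f = np.sqrt(max(f * (1 - f), 1e-12) / m)
    return (3 * f - 1) / 2, 1.5 * se_f, m
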