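"""Nucleosome core particle (NCP) phasing analyses.

A nucleosome wraps 147 bp around the histone octamer; positions are
expressed as the signed distance d (-73..+73 bp) from the central dyad
axis.  The analyses here profile where homopolymer tracts sit along that
axis, compare SNV rates between tracts centered at profile maxima versus
minima, measure the strand-orientation (C-containing / G-containing)
ratio of G-tracts along the particle, smooth profiles with a loess fit,
and estimate the dominant rotational period (~10.5 bp, the DNA helical
repeat) with a permutation significance test.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracts import Tract

HALF_NCP = 73  # bp either side of the dyad


@dataclass
class NCPProfile:
    """Per-d counts along the nucleosome, d in [-73, +73]."""

    d: np.ndarray
    counts: np.ndarray
    c_forward: np.ndarray | None = None
    g_forward: np.ndarray | None = None
    ratio: np.ndarray | None = None
    snv_ratio: np.ndarray | None = None
    smoothed: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"d": self.d, "count": self.counts}
        for name in ("c_forward", "g_forward", "ratio", "snv_ratio", "smoothed"):
            v = getattr(self, name)
            if v is not None:
                data[name] = v
        return pd.DataFrame(data)


def _midpoints_by_chrom(midpoints: Iterable[tuple[str, int]]) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for chrom, pos in midpoints:
        by.setdefault(chrom, []).append(pos)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by.items()}


def read_midpoints_bed(path: str) -> list[tuple[str, int]]:
    """Midpoints from BED/bedGraph intervals (midpoint = interval center)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            s, e = int(f[1]), int(f[2])
            out.append((f[0], s + (e - s - 1) // 2))
    return out


def pair_tracts_midpoints(
    tracts: Sequence[Tract],
    midpoints: Iterable[tuple[str, int]],
    nearest_only: bool = False,
) -> list[tuple[Tract, int]]:
    """(tract, d) pairs for tracts whose center lies within +/-73 bp of a
    midpoint; d = center - midpoint.  A tract near several midpoints
    contributes to each unless ``nearest_only``."""
    mids = _midpoints_by_chrom(midpoints)
    pairs: list[tuple[Tract, int]] = []
    for t in tracts:
        pos = mids.get(t.chrom)
        if pos is None:
            continue
        c = t.center
        lo = int(np.searchsorted(pos, c - HALF_NCP, side="left"))
        hi = int(np.searchsorted(pos, c + HALF_NCP, side="right"))
        if lo >= hi:
            continue
        cands = pos[lo:hi]
        if nearest_only:
            cands = [cands[int(np.argmin(np.abs(cands - c)))]]
        for m in cands:
            pairs.append((t, int(c - m)))
    return pairs


def dyad_profile(
    tracts: Sequence[Tract],
    midpoints: Iterable[tuple[str, int]],
    unit: str = "bp",
    nearest_only: bool = False,
) -> NCPProfile:
    """Counts of tract base pairs (unit='bp') or tract centers
    (unit='center') at each dyad distance d."""
    if unit not in ("bp", "center"):
        raise ValueError("unit must be 'bp' or 'center'")
    d_axis = np.arange(-HALF_NCP, HALF_NCP + 1)
    counts = np.zeros(d_axis.size, dtype=np.int64)
    for t, d in pair_tracts_midpoints(tracts, midpoints, nearest_only=nearest_only):
        if unit == "center":
            counts[d + HALF_NCP] += 1
        else:
            mid = t.center - d  # midpoint coordinate
            for x in range(t.start, t.end):
                dx = x - mid
                if -HALF_NCP <= dx <= HALF_NCP:
                    counts[dx + HALF_NCP] += 1
    return NCPProfile(d=d_axis, counts=counts)


# ---------------------------------------------------------------------------
# Extrema


def classify_extrema(
    profile: NCPProfile | np.ndarray, smoothing_window: int = 3
) -> tuple[list[int], list[int]]:
    """Local maxima and minima (d positions) of the smoothed count series.

    The series is smoothed with a centered moving average of odd width.
    Flat-topped extrema count once, represented by the in-run position
    closest to the dyad; a constant or monotone series has no interior
    extrema.
    """
    if isinstance(profile, NCPProfile):
        d, y = profile.d, profile.counts.astype(float)
    else:
        y = np.asarray(profile, dtype=float)
        d = np.arange(len(y)) - (len(y) - 1) // 2
    if smoothing_window % 2 == 0 or smoothing_window < 1:
        raise ValueError("smoothing window must be odd and >= 1")
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        yp = np.pad(y, pad, mode="edge")
        y = np.convolve(yp, kernel, mode="valid")

    # values within a tiny relative tolerance count as tied, so that
    # analytically flat-topped extrema (e.g. half-integer cosine peaks)
    # resolve deterministically toward the dyad
    eps = 1e-9 * max(1.0, float(np.max(np.abs(y))) if len(y) else 1.0)
    maxima: list[int] = []
    minima: list[int] = []
    i = 1
    while i < len(y) - 1:
        j = i
        while j < len(y) - 1 and abs(y[j + 1] - y[j]) <= eps:
            j += 1
        if j >= len(y) - 1:
            break
        left, right = y[i - 1], y[j + 1]
        if y[i] > left + eps and y[i] > right + eps:
            run = d[i : j + 1]
            maxima.append(int(run[np.argmin(np.abs(run))]))
        elif y[i] < left - eps and y[i] < right - eps:
            run = d[i : j + 1]
            minima.append(int(run[np.argmin(np.abs(run))]))
        i = j + 1
    return maxima, minima


def group_tracts_by_extrema(
    pairs: Sequence[tuple[Tract, int]],
    maxima: Sequence[int],
    minima: Sequence[int],
    tol: int = 1,
) -> dict[tuple[str, int], list[Tract]]:
    """Group tracts by the extremum their center coincides with (+/- tol bp).

    Keys are ('max', d) / ('min', d); a tract matching several extrema is
    attached to the closest one.
    """
    sites = [("max", d) for d in maxima] + [("min", d) for d in minima]
    groups: dict[tuple[str, int], list[Tract]] = {s: [] for s in sites}
    for t, d in pairs:
        best = None
        for kind, sd in sites:
            dist = abs(d - sd)
            if dist <= tol and (best is None or dist < best[0]):
                best = (dist, (kind, sd))
        if best is not None:
            groups[best[1]].append(t)
    return groups


@dataclass
class MaxMinComparison:
    per_position: pd.DataFrame
    overall_t: float
    overall_p: float


def max_min_comparison(
    assignments,
    groups: Mapping[tuple[str, int], Sequence[Tract]],
) -> MaxMinComparison:
    """Compare %SNV per tract position between maxima- and minima-centered
    tracts.

    %SNV at position p for a group = tract-SNV count at p / tract count
    x 100.  The percent increase at minima relative to maxima is
    (min - max)/max x 100.  Paired t-tests pair the k-th maximum site
    with the k-th minimum site ordered by d, per position, with
    Benjamini-Hochberg adjustment across positions; the overall test
    pairs site-level mean %SNV.
    """
    from statsmodels.stats.multitest import multipletests

    from .variants import assignments_to_frame

    adf = assignments if isinstance(assignments, pd.DataFrame) else assignments_to_frame(assignments)
    adf = adf[adf.category == "tract_SNV"]
    counts_by_tract: dict[tuple, dict[int, int]] = {}
    for row in adf.itertuples(index=False):
        key = (row.chrom, row.start, row.end)
        counts_by_tract.setdefault(key, {})
        counts_by_tract[key][row.position] = counts_by_tract[key].get(row.position, 0) + 1

    n_positions = max((t.n for ts in groups.values() for t in ts), default=0)
    site_rows = []  # (kind, d, position, pct)
    for (kind, sd), ts in groups.items():
        if not ts:
            continue
        denom = len(ts)
        pos_counts = np.zeros(n_positions + 1)
        for t in ts:
            for p, k in counts_by_tract.get((t.chrom, t.start, t.end), {}).items():
                if 1 <= p <= n_positions:
                    pos_counts[p] += k
        for p in range(1, n_positions + 1):
            site_rows.append((kind, sd, p, pos_counts[p] / denom * 100.0))
    site_df = pd.DataFrame(site_rows, columns=["kind", "d", "position", "pct"])
    if site_df.empty:
        return MaxMinComparison(pd.DataFrame(), np.nan, np.nan)

    max_sites = sorted(site_df[site_df.kind == "max"].d.unique())
    min_sites = sorted(site_df[site_df.kind == "min"].d.unique())
    k = min(len(max_sites), len(min_sites))
    max_sites, min_sites = max_sites[:k], min_sites[:k]

    rows = []
    for p in range(1, n_positions + 1):
        mx = site_df[(site_df.kind == "max") & (site_df.position == p)].set_index("d").pct
        mn = site_df[(site_df.kind == "min") & (site_df.position == p)].set_index("d").pct
        a = np.array([mx.get(d, 0.0) for d in max_sites])
        b = np.array([mn.get(d, 0.0) for d in min_sites])
        pct_max, pct_min = a.mean(), b.mean()
        inc = (pct_min - pct_max) / pct_max * 100.0 if pct_max > 0 else np.nan
        if k >= 2 and np.ptp(b - a) > 0:
            t_stat, p_val = stats.ttest_rel(b, a)
        else:
            t_stat, p_val = 0.0, 1.0
        rows.append((p, pct_max, pct_min, inc, t_stat, p_val))
    per_pos = pd.DataFrame(
        rows, columns=["position", "pct_max", "pct_min", "percent_increase", "t", "p"]
    )
    per_pos["p_adj"] = multipletests(per_pos["p"].values, method="fdr_bh")[1]

    mean_by_site = site_df.groupby(["kind", "d"]).pct.mean()
    a = np.array([mean_by_site.get(("max", d), 0.0) for d in max_sites])
    b = np.array([mean_by_site.get(("min", d), 0.0) for d in min_sites])
    if k >= 2 and np.ptp(b - a) > 0:
        t_all, p_all = stats.ttest_rel(b, a)
    else:
        t_all, p_all = 0.0, 1.0
    return MaxMinComparison(per_pos, float(t_all), float(p_all))


# ---------------------------------------------------------------------------
# Orientation


def orientation_ratio_profile(
    tracts: Sequence[Tract],
    midpoints: Iterable[tuple[str, int]],
    snv_assignments=None,
    nearest_only: bool = False,
) -> NCPProfile:
    """C-containing/G-containing ratio of G-tracts per dyad distance d.

    A '-' purine strand means the forward strand carries the C-run
    (C-containing); '+' means the G-run (G-containing).  The ratio is
    count(C-forward)/count(G-forward), undefined (NaN) where no G-forward
    tract covers d.  With SNV assignments, the %SNV ratio at position 1
    of C-preceded (CG[n]) tracts is computed per d as well.
    """
    gtracts = [t for t in tracts if t.tract_class == "G"]
    pairs = pair_tracts_midpoints(gtracts, midpoints, nearest_only=nearest_only)
    d_axis = np.arange(-HALF_NCP, HALF_NCP + 1)
    c_fwd = np.zeros(d_axis.size, dtype=np.int64)
    g_fwd = np.zeros(d_axis.size, dtype=np.int64)
    for t, d in pairs:
        if t.purine_strand == "-":
            c_fwd[d + HALF_NCP] += 1
        else:
            g_fwd[d + HALF_NCP] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(g_fwd > 0, c_fwd / np.maximum(g_fwd, 1), np.nan)

    snv_ratio = None
    if snv_assignments is not None:
        from .variants import assignments_to_frame

        adf = (
            snv_assignments
            if isinstance(snv_assignments, pd.DataFrame)
            else assignments_to_frame(snv_assignments)
        )
        adf = adf[
            (adf.category == "tract_SNV")
            & (adf.tract_class == "G")
            & (adf.position == 1)
            & (adf.flank5 == "C")
        ]
        hit = set(zip(adf.chrom, adf.start, adf.end))
        num = {"+": np.zeros(d_axis.size), "-": np.zeros(d_axis.size)}
        den = {"+": np.zeros(d_axis.size), "-": np.zeros(d_axis.size)}
        for t, d in pairs:
            if t.flank5 != "C":
                continue
            den[t.purine_strand][d + HALF_NCP] += 1
            if (t.chrom, t.start, t.end) in hit:
                num[t.purine_strand][d + HALF_NCP] += 1
        with np.errstate(divide="ignore", invalid="ignore"):
            pct_c = np.where(den["-"] > 0, num["-"] / np.maximum(den["-"], 1), np.nan)
            pct_g = np.where(den["+"] > 0, num["+"] / np.maximum(den["+"], 1), np.nan)
            snv_ratio = np.where(pct_g > 0, pct_c / np.where(pct_g > 0, pct_g, 1), np.nan)

    return NCPProfile(
        d=d_axis, counts=c_fwd + g_fwd, c_forward=c_fwd, g_forward=g_fwd,
        ratio=ratio, snv_ratio=snv_ratio,
    )


# ---------------------------------------------------------------------------
# Smoothing and periodicity


def smooth_profile(
    y: Sequence[float],
    x: Sequence[float] | None = None,
    span: float = 0.100,
    degree: int = 3,
) -> np.ndarray:
    """Loess: locally weighted polynomial regression with tricube weights.

    At each point the ``span`` fraction of nearest neighbours is fitted
    with a degree-``degree`` polynomial weighted by (1 - u^3)^3 of the
    scaled distance u.  Defaults follow the sampling proportion 0.100 and
    polynomial degree 3 used for the orientation-ratio fits.
    """
    y = np.asarray(y, dtype=float)
    x = np.arange(len(y), dtype=float) if x is None else np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    xs, ys = x[ok], y[ok]
    n = len(xs)
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    out = np.full(len(y), np.nan)
    idx_ok = np.flatnonzero(ok)
    for oi, xi in zip(idx_ok, x[ok]):
        dist = np.abs(xs - xi)
        order = np.argsort(dist, kind="stable")[:k]
        h = dist[order].max()
        u = dist[order] / h if h > 0 else np.zeros(k)
        w = (1 - np.clip(u, 0, 1) ** 3) ** 3
        V = np.vander(xs[order] - xi, degree + 1, increasing=True)
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * W[:, None], ys[order] * W, rcond=None)
        out[oi] = coef[0]
    return out


def estimate_period(
    series: Sequence[float],
    positions: Sequence[float] | None = None,
    period_range: tuple[float, float] = (8.0, 13.0),
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Dominant period (bp) of a positional series, with a permutation p.

    The mean-subtracted series' periodogram is evaluated on a dense
    period grid within ``period_range``; the maximum is refined by
    quadratic interpolation of the three surrounding grid points.
    Significance comes from shuffling positions ``n_perm`` times and
    comparing maximal in-range power.  Returns (period, p_value).
    """
    y = np.asarray(series, dtype=float)
    x = np.arange(len(y), dtype=float) if positions is None else np.asarray(positions, float)
    ok = np.isfinite(y)
    y, x = y[ok], x[ok]
    y = y - y.mean()
    periods = np.linspace(period_range[0], period_range[1], 2001)
    omega = 2 * np.pi / periods
    E = np.exp(-1j * np.outer(omega, x))
    power = np.abs(E @ y) ** 2
    i = int(np.argmax(power))
    if 0 < i < len(periods) - 1:
        p0, p1, p2 = periods[i - 1 : i + 2]
        f0, f1, f2 = power[i - 1 : i + 2]
        denom = (f0 - 2 * f1 + f2)
        offset = 0.5 * (f0 - f2) / denom if denom != 0 else 0.0
        best = p1 + offset * (p1 - p0)
    else:
        best = periods[i]
    obs = power[i]

    rng = np.random.default_rng(seed)
    count = 0
    coarse = E[::4]
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if np.max(np.abs(coarse @ perm) ** 2) >= obs:
            count += 1
    p_val = (count + 1) / (n_perm + 1)
    return float(best), float(p_val)


# ---------------------------------------------------------------------------
# Packaged annotation


def load_ncp_annotation(path: str | None = None) -> pd.DataFrame:
    """Minor-groove-inward flags and iSAT signs per dyad distance d.

    The packaged default is a synthetic stand-in: a 10.5-bp periodic sign
    pattern with the minor groove facing the octamer at the dyad, meant
    to be replaced with a crystal-structure-derived table for real-data
    work.  Columns: d, minor_groove_inward (0/1), isat_sign (-1/ +1).
    """
    if path is None:
        ref = importlib.resources.files("tractvar.data") / "ncp_annotation_synthetic.tsv"
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")
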