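"""Flexibility and geometry statistics from tabulated trajectory data.

Inputs are pre-tabulated molecular-dynamics outputs: per-frame base-pair
step parameter vectors (shift, slide, rise in Angstrom; tilt, roll,
twist in degrees), labeled phosphate coordinates, and per-frame counts
of minor-groove bridging waters.  Trajectory generation and parameter
extraction from atomic coordinates are outside this package's scope.

The central statistic is V_step, a step-flexibility volume: the product
of the square roots of the six eigenvalues of the step-parameter sample
covariance matrix, which equals sqrt(det Sigma) exactly.  Larger V_step
means a floppier base-pair step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STEP_PARAMS = ["shift", "slide", "rise", "tilt", "roll", "twist"]


@dataclass
class StepParamSeries:
    """Per-frame six-parameter vectors for one base-pair step."""

    label: str
    frames: np.ndarray  # (n_frames, 6)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != 6:
            raise ValueError("frames must be an (n, 6) array")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("step parameters must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def covariance(self) -> np.ndarray:
        """Unbiased (n-1) 6x6 sample covariance."""
        return np.cov(self.frames, rowvar=False, ddof=1)


def v_step(series: StepParamSeries | np.ndarray) -> float:
    """Step-flexibility volume: prod_i sqrt(lambda_i) of the covariance
    eigenvalues (units A^3 deg^3); equals sqrt(det Sigma).

    A rank-deficient covariance (fewer than 7 frames, or degenerate
    sampling) yields 0 with a warning.
    """
    if isinstance(series, StepParamSeries):
        if series.n_frames < 7:
            warnings.warn(
                f"{series.label}: {series.n_frames} frames cannot give a "
                "full-rank 6x6 covariance", stacklevel=2,
            )
        cov = series.covariance()
    else:
        cov = np.asarray(series, dtype=float)
    eig = np.linalg.eigvalsh(cov)
    if np.any(eig <= 0):
        if np.min(eig) < -1e-8 * max(1.0, np.max(np.abs(eig))):
            raise ValueError("covariance is not positive semi-definite")
        warnings.warn("singular covariance; V_step = 0", stacklevel=2)
        return 0.0
    return float(np.prod(np.sqrt(eig)))


def read_step_params(path: str) -> list[StepParamSeries]:
    """Step-parameter TSV (frame, step_label, shift..twist) -> series list."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for label, g in df.groupby("step_label", sort=False):
        g = g.sort_values("frame")
        out.append(StepParamSeries(str(label), g[STEP_PARAMS].to_numpy()))
    return out


# ---------------------------------------------------------------------------
# Groove width


def groove_width(
    trace: pd.DataFrame,
    convention: str = "cross_strand",
    offset: int = 3,
    subtract: float = 0.0,
) -> pd.DataFrame:
    """Per-position mean +/- SD phosphate-phosphate distance (Angstrom).

    ``trace`` columns: frame, strand (1/2), resid, x, y, z.
    'cross_strand' pairs strand-1 residue i with strand-2 residue
    i+offset; 'within_strand' pairs residue i with i+offset on the same
    strand (reported per strand).  ``subtract`` removes a constant (e.g.
    twice the phosphate radius) from every distance.  Frames missing a
    residue are skipped for that position and logged.
    """
    if convention not in ("cross_strand", "within_strand"):
        raise ValueError("convention must be 'cross_strand' or 'within_strand'")
    coords: dict[tuple[int, int, int], np.ndarray] = {}
    for row in trace.itertuples(index=False):
        coords[(int(row.frame), int(row.strand), int(row.resid))] = np.array(
            [row.x, row.y, row.z], dtype=float
        )
    frames = sorted({int(f) for f in trace["frame"]})
    resids = sorted({int(r) for r in trace["resid"]})
    strands = sorted({int(s) for s in trace["strand"]})
    if convention == "cross_strand" and set(strands) != {1, 2}:
        raise ValueError("cross-strand convention requires both strands")

    rows = []
    if convention == "cross_strand":
        pairings = [((1, i), (2, i + offset), i) for i in resids]
    else:
        pairings = [((s, i), (s, i + offset), i) for s in strands for i in resids]
    for (s1, r1), (s2, r2), pos in pairings:
        dists = []
        missing = 0
        for f in frames:
            a = coords.get((f, s1, r1))
            b = coords.get((f, s2, r2))
            if a is None or b is None:
                missing += 1
                continue
            dists.append(float(np.linalg.norm(a - b)) - subtract)
        if missing and dists:
            logger.info("position %d: %d frames skipped (missing residue)", pos, missing)
        if dists:
            rows.append(
                (pos, s1 if convention == "within_strand" else 0,
                 float(np.mean(dists)), float(np.std(dists)), len(dists))
            )
    out = pd.DataFrame(rows, columns=["position", "strand", "mean", "sd", "n_frames"])
    if convention == "cross_strand":
        out = out.drop(columns=["strand"])
    return out


def read_phosphate_trace(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Water bridges


def bridge_occupancy(counts: pd.DataFrame) -> pd.DataFrame:
    """Fractions of frames with exactly one and exactly two bridging
    waters per position.

    ``counts`` columns: frame, position, count.  f1 + f2 <= 1 by
    construction.
    """
    if counts.empty:
        raise ValueError("need at least one frame")
    g = counts.groupby("position")["count"]
    out = pd.DataFrame(
        {
            "position": list(g.groups),
            "f1": g.apply(lambda s: float(np.mean(s == 1))).values,
            "f2": g.apply(lambda s: float(np.mean(s == 2))).values,
            "n_frames": g.size().values,
        }
    )
    return out.reset_index(drop=True)


def read_bridge_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
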