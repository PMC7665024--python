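"""Flexibility metrics on distance distributions.

Width of P(r) is the structural-flexibility readout: a rigid conformation
gives a narrow inter-label distribution, a flexible one a broad or
multimodal distribution.  The headline metric is the full width at half
maximum, defined here between the *outermost* crossings of half the global
maximum so that multimodal distributions report the full extent of the
conformational ensemble rather than the width of a single peak.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dipolar_model import DistanceDistribution
from .errors import (
    BoundaryTruncationWarning,
    GridMismatchError,
    MissingReferenceError,
    UndefinedModeError,
)
from .inversion import InversionResult


def _check_usable(dist: DistanceDistribution) -> None:
    if dist.is_empty or dist.p.max() <= 0:
        raise UndefinedModeError("statistics undefined on an empty-solution distribution")


def mode_distance(dist: DistanceDistribution) -> float:
    """Most probable distance: grid point of maximum density, ties toward smaller r."""
    _check_usable(dist)
    return float(dist.grid.r[int(np.argmax(dist.p))])


def fwhm(dist: DistanceDistribution) -> float:
    """Full width at half maximum between the outermost half-max crossings.

    Crossings are located by linear interpolation between adjacent grid
    points.  If the density is still above half maximum at a grid edge, the
    width is clamped to that edge and a
    :class:`BoundaryTruncationWarning` is issued.
    """
    _check_usable(dist)
    r, p = dist.grid.r, dist.p
    half = p.max() / 2.0
    above = p >= half
    idx = np.flatnonzero(above)
    i_first, i_last = idx[0], idx[-1]
    truncated = False
    if i_first == 0:
        left = r[0]
        truncated |= p[0] > half
    else:
        f = (half - p[i_first - 1]) / (p[i_first] - p[i_first - 1])
        left = r[i_first - 1] + f * dist.grid.dr
    if i_last == len(r) - 1:
        right = r[-1]
        truncated |= p[-1] > half
    else:
        f = (p[i_last] - half) / (p[i_last] - p[i_last + 1])
        right = r[i_last] + f * dist.grid.dr
    if truncated:
        warnings.warn(
            "density above half maximum at a grid edge; FWHM clamped to the grid",
            BoundaryTruncationWarning,
            stacklevel=2,
        )
    return float(right - left)


def distribution_moments(dist: DistanceDistribution) -> tuple[float, float]:
    """Mean and standard deviation of the distance distribution, in nm."""
    _check_usable(dist)
    w = dist.p * dist.grid.dr
    mean = float(np.sum(dist.grid.r * w))
    var = float(np.sum((dist.grid.r - mean) ** 2 * w))
    return mean, float(np.sqrt(max(var, 0.0)))


def overlap(a: DistanceDistribution, b: DistanceDistribution) -> float:
    """Shared probability mass: integral of min(p_a, p_b); 1 for identical."""
    if a.grid != b.grid:
        raise GridMismatchError("overlap requires a common distance grid")
    return float(np.sum(np.minimum(a.p, b.p)) * a.grid.dr)


def flexibility_report(
    results: list[tuple[str, InversionResult]],
    reference_label: str,
    use: str = "mem",
) -> pd.DataFrame:
    """Per-condition summary table of mode, width and overlap vs a reference.

    ``use`` selects the distribution the statistics are computed on:
    ``"mem"`` (the refined distribution, default) or ``"tikhonov"``.
    Row order follows input order.
    """
    if not results:
        raise MissingReferenceError("no results supplied")
    labels = [lab for lab, _ in results]
    if reference_label not in labels:
        raise MissingReferenceError(f"reference label {reference_label!r} not present")

    def pick(res: InversionResult) -> DistanceDistribution:
        return res.p_mem if use == "mem" else res.p_tikhonov

    ref = pick(dict(results)[reference_label])
    rows = []
    for label, res in results:
        dist = pick(res)
        mean, sd = distribution_moments(dist)
        rows.append(
            {
                "label": label,
                "mode_nm": mode_distance(dist),
                "fwhm_nm": fwhm(dist),
                "mean_nm": mean,
                "sd_nm": sd,
                "overlap_vs_ref": overlap(dist, ref),
            }
        )
    return pd.DataFrame(rows)
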