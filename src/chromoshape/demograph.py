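"""Population demographs: stacked per-cell fold-increase profiles.

A demograph is a heatmap whose rows are the per-cell intensity profiles
along the common ori-anchored length axis (position 0 = origin of
replication), stacked over the population with rows ordered by decreasing
contrast so common trends are visible at a glance.  The column-wise mean
(ignoring unobserved bins) is the population's average normalized profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbone import ContourProfile
from .errors import InputError, ParameterError


def contrast(profile: ContourProfile, channel: str, method: str = "michelson") -> float:
    """Profile contrast used as the demograph ordering key.

    Default is a robust Michelson contrast ``(q95 - q5) / (q95 + q5)`` of the
    fold-increase values over observed bins, which lies in [0, 1) and is
    invariant to intensity rescaling; ``method='cv'`` (std/mean) is the
    alternative.  Profiles with fewer than 2 observed bins have no defined
    contrast.
    """
    if profile.fold_increase is None:
        raise ParameterError("profile must be oriented (align_and_flip) first")
    vals = profile.fold_increase[channel]
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ParameterError("contrast needs at least 2 observed bins")
    if method == "cv":
        m = vals.mean()
        return float(vals.std() / m) if m > 0 else 0.0
    q5, q95 = np.quantile(vals, [0.05, 0.95])
    denom = q95 + q5
    return float((q95 - q5) / denom) if denom > 0 else 0.0


@dataclass
class Demograph:
    """Cell-by-length matrix of fold-increase values for one channel."""

    matrix: np.ndarray  # (n_cells, n_bins), NaN for unobserved bins
    length_axis_um: np.ndarray
    cell_ids: list[int]
    order_keys: np.ndarray
    channel: str
    mean_profile: np.ndarray  # column-wise mean ignoring NaN


def build_demograph(
    profiles: list[ContourProfile],
    channel: str,
    order: str = "contrast",
    contrast_method: str = "michelson",
) -> Demograph:
    """Stack oriented profiles into a contrast-ordered demograph.

    All profiles must share the same bin grid and representative length.
    Cells whose contrast is undefined (fewer than 2 observed bins) are
    dropped with a warning.  The ordering is canonical (key descending,
    ties broken by cell id), so permuting the input leaves the matrix
    unchanged.
    """
    if not profiles:
        raise InputError("no profiles to stack")
    axis = profiles[0].length_axis_um
    for p in profiles[1:]:
        if p.length_axis_um.shape != axis.shape or not np.allclose(
            p.length_axis_um, axis
        ):
            raise InputError("profiles have mixed bin grids")
    rows = []
    for p in profiles:
        try:
            key = contrast(p, channel, contrast_method) if order == "contrast" else 0.0
        except ParameterError:
            warnings.warn(
                f"cell {p.cell_id}: contrast undefined, dropped from demograph",
                stacklevel=2,
            )
            continue
        rows.append((key, p.cell_id, p.fold_increase[channel]))
    if not rows:
        raise InputError("no profiles with defined contrast")
    rows.sort(key=lambda r: (-r[0], r[1]))
    matrix = np.vstack([r[2] for r in rows])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_profile = np.nanmean(matrix, axis=0)
    return Demograph(
        matrix=matrix,
        length_axis_um=axis.copy(),
        cell_ids=[r[1] for r in rows],
        order_keys=np.array([r[0] for r in rows]),
        channel=channel,
        mean_profile=mean_profile,
    )


def demograph_to_frame(dg: Demograph) -> pd.DataFrame:
    """Demograph matrix as a DataFrame (rows = cells, columns = s in µm)."""
    return pd.DataFrame(
        dg.matrix,
        index=pd.Index(dg.cell_ids, name="cell_id"),
        columns=[f"{s:.3f}" for s in dg.length_axis_um],
    )


def render_demograph(dg: Demograph, path, cmap: str = "inferno") -> None:
    """Optional PNG heatmap with a fold-increase colorbar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        dg.matrix,
        aspect="auto",
        interpolation="nearest",
        cmap=cmap,
        extent=(
            dg.length_axis_um[0],
            dg.length_axis_um[-1] + (dg.length_axis_um[1] - dg.length_axis_um[0]),
            dg.matrix.shape[0],
            0,
        ),
    )
    ax.set_xlabel("distance from ori (µm)")
    ax.set_ylabel("cell (ordered by contrast)")
    fig.colorbar(im, ax=ax, label="fold-increase")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
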