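"""Feasible-region grids for the inverse (contra-Bayes) mapping.

At a fixed prevalence p, only some (PPV, NPV) pairs can arise from an
informative test with sensitivity and specificity in [0, 1].  The
feasible set is bounded on the left by PPV = p (a positive result that
does not raise the prior probability, LR+ = 1) and at the bottom by
NPV = 1 - p (LR- = 1).  Approaching the left edge the inverse solution
degenerates to (SN, SP) -> (1, 0); approaching the bottom edge, to
(0, 1); every uninformative test collapses to the corner (p, 1 - p).
This module evaluates the inverse mapping on a rectangular grid — in
predictive-value axes or on the NNT scale (log-spaced) — flags infeasible
nodes without clamping, and exports the result as tidy CSV for plotting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes_maps import Prevalence, forward_arrays, contra_arrays
from .exceptions import DomainError

__all__ = [
    "RegionGrid",
    "compute_region",
    "equal_sn_sp_locus",
    "export_region",
    "read_region",
]

AXIS_KINDS = ("pv", "nnt")
_HEADER_PREFIX = "# nntplan-region"


@dataclass(frozen=True)
class RegionGrid:
    """A grid of inverse-mapping evaluations at one prevalence.

    ``table`` columns: ``x``, ``y`` (axis coordinates — predictive values
    for ``axis_kind="pv"``, NNT_Pos/NNT_Neg for ``"nnt"``), the raw
    ``sensitivity`` and ``specificity`` from the inverse mapping
    (unclamped; out-of-range on infeasible nodes), ``feasible`` and the
    ``infeasible_side`` tag ("none", "positive", "negative" or "both").
    """

    prevalence: Prevalence
    axis_kind: str
    table: pd.DataFrame


def _node_values(axis_kind, x, y):
    """Translate axis coordinates into (ppv, npv)."""
    if axis_kind == "pv":
        return x, y
    # NNT axes: x = NNT_Pos = 1/PPV, y = NNT_Neg = 1/(1-NPV)
    return 1.0 / x, 1.0 - 1.0 / y


def compute_region(
    prev: Prevalence,
    axis_kind: str = "pv",
    resolution: int = 201,
    nnt_bounds: tuple[float, float] = (1.05, 1000.0),
    x_values=None,
    y_values=None,
) -> RegionGrid:
    """Evaluate the inverse mapping on a grid.

    ``axis_kind="pv"`` uses a uniform grid strictly inside (0, 1) on both
    axes; ``"nnt"`` uses log-spaced NNT_Pos and NNT_Neg between
    ``nnt_bounds``.  ``x_values``/``y_values`` override the default grids
    (useful for probing specific nodes).  Infeasible nodes are flagged and
    keep their raw algebraic sensitivity/specificity.
    """
    if axis_kind not in AXIS_KINDS:
        raise DomainError(f"axis_kind must be one of {AXIS_KINDS}, got {axis_kind!r}")
    if resolution < 2:
        raise DomainError(f"resolution must be >= 2, got {resolution!r}")
    if x_values is None:
        if axis_kind == "pv":
            x_values = np.linspace(0.0, 1.0, resolution + 2)[1:-1]
        else:
            x_values = np.geomspace(nnt_bounds[0], nnt_bounds[1], resolution)
    if y_values is None:
        if axis_kind == "pv":
            y_values = np.linspace(0.0, 1.0, resolution + 2)[1:-1]
        else:
            y_values = np.geomspace(nnt_bounds[0], nnt_bounds[1], resolution)
    x_values = np.asarray(x_values, dtype=float)
    y_values = np.asarray(y_values, dtype=float)

    xg, yg = np.meshgrid(x_values, y_values, indexing="ij")
    x = xg.ravel()
    y = yg.ravel()
    ppv, npv = _node_values(axis_kind, x, y)

    odds = prev.odds
    with np.errstate(divide="ignore"):
        ppo = np.where(ppv == 1.0, np.inf, ppv / np.where(ppv == 1.0, 1.0, 1.0 - ppv))
        npo_inv = (1.0 - npv) / npv
    pos_ok = ppo > odds
    neg_ok = odds > npo_inv
    feasible = pos_ok & neg_ok
    side = np.where(
        feasible, "none",
        np.where(pos_ok, "negative", np.where(neg_ok, "positive", "both")),
    )
    sn, sp = contra_arrays(ppv, npv, odds)

    table = pd.DataFrame({
        "x": x, "y": y,
        "sensitivity": sn, "specificity": sp,
        "feasible": feasible, "infeasible_side": side,
    })
    return RegionGrid(prevalence=prev, axis_kind=axis_kind, table=table)


def equal_sn_sp_locus(prev: Prevalence, n_points: int = 101) -> pd.DataFrame:
    """The locus of predictive values where sensitivity equals specificity.

    For SN = SP = s the predictive values are feasible exactly when
    s > 1/2 (a worse-than-random test reverses the odds).  The locus runs
    from the purely random test s = 1/2, mapping to (PPV, NPV) =
    (prevalence, 1 - prevalence), up to the perfect test s = 1 mapping to
    (1, 1).  Columns: ``ppv``, ``npv``, ``level`` (the common s value).
    """
    if n_points < 2:
        raise DomainError(f"n_points must be >= 2, got {n_points!r}")
    s = np.linspace(0.5, 1.0, n_points)
    ppv, npv = forward_arrays(s, s, prev.value)
    return pd.DataFrame({"ppv": ppv, "npv": npv, "level": s})


def export_region(grid: RegionGrid, path) -> None:
    """Write a grid as tidy CSV with a one-line metadata header.

    The header comment records the prevalence and axis kind so
    :func:`read_region` can reconstruct the full :class:`RegionGrid`;
    floats are written at full repr precision and round-trip exactly.
    """
    buf = io.StringIO()
    buf.write(f"{_HEADER_PREFIX} schema=1 prevalence={grid.prevalence.value!r} "
              f"axes={grid.axis_kind}\n")
    grid.table.to_csv(buf, index=False)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())
    except OSError as exc:
        raise DomainError(f"cannot write region CSV to {path!r}: {exc}") from exc


def read_region(path) -> RegionGrid:
    """Read a CSV written by :func:`export_region` back into a grid."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith(_HEADER_PREFIX):
            raise DomainError(f"{path!r} is not an nntplan region export")
        meta = dict(tok.split("=", 1) for tok in header[len(_HEADER_PREFIX):].split())
        # exact float parsing so the round trip reproduces the grid bit-for-bit
        table = pd.read_csv(fh, float_precision="round_trip")
    return RegionGrid(
        prevalence=Prevalence(float(meta["prevalence"])),
        axis_kind=meta["axes"],
        table=table,
    )


def plot_region(grid: RegionGrid, locus: pd.DataFrame | None = None, ax=None):
    """Shade the feasible region and draw SN/SP contours (needs matplotlib).

    A convenience layer over the exported grid; the tested artifact is the
    grid data itself.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = grid.table
    nx = t["x"].nunique()
    ny = t["y"].nunique()
    x = t["x"].to_numpy().reshape(nx, ny)
    y = t["y"].to_numpy().reshape(nx, ny)
    sn = np.where(t["feasible"], t["sensitivity"], np.nan).reshape(nx, ny)
    sp = np.where(t["feasible"], t["specificity"], np.nan).reshape(nx, ny)
    feas = t["feasible"].to_numpy().reshape(nx, ny).astype(float)
    ax.contourf(x, y, feas, levels=[0.5, 1.5], colors=["#eef6ee"])
    cs_sn = ax.contour(x, y, sn, levels=np.arange(0.1, 1.0, 0.1), colors="firebrick",
                       linewidths=0.8)
    cs_sp = ax.contour(x, y, sp, levels=np.arange(0.1, 1.0, 0.1), colors="steelblue",
                       linewidths=0.8)
    ax.clabel(cs_sn, fontsize=6)
    ax.clabel(cs_sp, fontsize=6)
    if locus is not None and grid.axis_kind == "pv":
        ax.plot(locus["ppv"], locus["npv"], color="black", lw=1.2)
    if grid.axis_kind == "nnt":
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("NNT in test-positive group")
        ax.set_ylabel("NNT in test-negative group")
    else:
        ax.set_xlabel("positive predictive value")
        ax.set_ylabel("negative predictive value")
    return ax
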