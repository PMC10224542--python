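"""BOILED-Egg classification in the (TPSA, WLOGP) plane.

The "white" region predicts passive gastrointestinal absorption, the "yolk"
passive blood-brain-barrier permeation. Two membership modes are exposed:

- ``ellipse`` (default): the published best-fit ellipses;
- ``rectangle``: the two scalar thresholds quoted alongside the model
  (WLOGP <= 5.88 and TPSA <= 131.6, inclusive), which circumscribe the
  white ellipse on the WLOGP axis but cut it short on the TPSA axis.

The two modes can disagree for points between TPSA 131.6 and the ellipse's
TPSA extent; disagreements over a roster are logged, never raised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .config import DEFAULT_CONFIG, EggModel, EllipseSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EggPoint:
    code: str
    wlogp: float
    tpsa: float
    pgp_substrate: Optional[bool] = None


@dataclass(frozen=True)
class EggClassification:
    in_white: bool
    in_yolk: bool

    @property
    def outside(self) -> bool:
        return not (self.in_white or self.in_yolk)


def _in_ellipse(tpsa: float, wlogp: float, e: EllipseSpec) -> bool:
    th = math.radians(e.angle_deg)
    dx, dy = tpsa - e.cx, wlogp - e.cy
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return (u / (e.width / 2)) ** 2 + (v / (e.height / 2)) ** 2 <= 1.0


def classify(point: EggPoint, mode: str | None = None,
             model: EggModel | None = None) -> EggClassification:
    """Classify one point into white/yolk membership.

    Rectangle mode replaces the white ellipse with the inclusive scalar
    thresholds; yolk membership always uses the yolk ellipse (whose TPSA
    extent lies well below the white bound).
    """
    model = model or DEFAULT_CONFIG.egg
    mode = mode or model.mode
    if mode not in ("ellipse", "rectangle"):
        raise ValueError(f"unknown egg mode {mode!r}")
    if not (math.isfinite(point.wlogp) and math.isfinite(point.tpsa)):
        raise ValueError(f"non-finite egg point for {point.code!r}")
    in_yolk = _in_ellipse(point.tpsa, point.wlogp, model.yolk)
    if mode == "rectangle":
        in_white = (point.wlogp <= model.rect_wlogp_max
                    and point.tpsa <= model.rect_tpsa_max)
    else:
        in_white = _in_ellipse(point.tpsa, point.wlogp, model.white)
    return EggClassification(in_white=in_white, in_yolk=in_yolk)


_COLORS = {True: "blue", False: "red", None: "gray"}  # Pgp substrate flag


def egg_report(descriptors: pd.DataFrame,
               score_table: Optional[pd.DataFrame] = None,
               mode: str | None = None,
               model: EggModel | None = None) -> pd.DataFrame:
    """Plot-data table: one row per compound with coordinates, region flags
    and a dot colour keyed on the (external) Pgp-substrate flag.

    Rows with missing descriptors are flagged, not dropped. When both modes
    disagree for a compound the fact is logged.
    """
    model = model or DEFAULT_CONFIG.egg
    mode = mode or model.mode
    rows = []
    for code, r in descriptors.iterrows():
        wl, tp = r.get("wlogp"), r.get("tpsa")
        pgp: Optional[bool] = None
        if score_table is not None and code in score_table.index:
            raw = score_table.loc[code].get("pgp_substrate")
            if isinstance(raw, str):
                pgp = raw.strip().lower() in ("yes", "y", "true", "1")
        row = {"code": code, "group": r.get("scaffold", ""),
               "wlogp": wl, "tpsa": tp,
               "pgp": {True: "Yes", False: "No", None: "unknown"}[pgp],
               "color": _COLORS[pgp], "flagged": False}
        if wl is None or tp is None or not (
                math.isfinite(float(wl)) and math.isfinite(float(tp))):
            row.update(in_white=None, in_yolk=None, flagged=True)
        else:
            p = EggPoint(code=str(code), wlogp=float(wl), tpsa=float(tp),
                         pgp_substrate=pgp)
            c = classify(p, mode, model)
            other = classify(p, "rectangle" if mode == "ellipse" else "ellipse",
                             model)
            if (c.in_white, c.in_yolk) != (other.in_white, other.in_yolk):
                logger.info("egg modes disagree for %s: %s=%s, other=%s",
                            code, mode, (c.in_white, c.in_yolk),
                            (other.in_white, other.in_yolk))
            row.update(in_white=c.in_white, in_yolk=c.in_yolk)
        rows.append(row)
    cols = ["code", "group", "wlogp", "tpsa", "in_white", "in_yolk",
            "pgp", "color", "flagged"]
    df = pd.DataFrame(rows, columns=cols)
    return df.set_index("code", drop=False)


def plot_egg(report: pd.DataFrame, path, model: EggModel | None = None) -> None:
    """Optional scatter rendering of the egg diagram, split by scaffold
    group as in the study's two-panel figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    model = model or DEFAULT_CONFIG.egg
    groups = [g for g in report["group"].unique() if g] or [""]
    fig, axes = plt.subplots(len(groups), 1,
                             figsize=(7, 4 * len(groups)), squeeze=False)
    for ax, group in zip(axes.ravel(), groups):
        sub = report[report["group"] == group] if group else report
        for spec, fc in ((model.white, "white"), (model.yolk, "gold")):
            ax.add_patch(Ellipse((spec.cx, spec.cy), spec.width, spec.height,
                                 angle=spec.angle_deg, facecolor=fc,
                                 edgecolor="k", alpha=0.6, zorder=0))
        ax.scatter(sub["tpsa"], sub["wlogp"], c=sub["color"], s=25, zorder=2)
        for _, r in sub.iterrows():
            ax.annotate(r["code"], (r["tpsa"], r["wlogp"]), fontsize=6)
        ax.set_xlabel("TPSA (A^2)")
        ax.set_ylabel("WLOGP")
        ax.set_title(group or "roster")
        ax.set_xlim(-10, 200)
        ax.set_ylim(-4, 8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
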