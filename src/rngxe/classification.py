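"""Sire environmental-sensitivity classification from reaction-norm slopes.

Sires are classified by how far their posterior-mean slope lies from the
population of sire slopes, in SD units: Extremely Robust (ER, within 1 SD),
Robust (R, above 1 and below 2), Plastic (P, at or above 2 and below 3) and
Extremely Plastic (EP, at or above 3).  The reference centre is the mean of
the retained sires' slope means (a ``center="zero"`` option measures from
zero instead) and the scale is their between-sire SD (denominator n-1), so
the scheme is invariant to affine transformations of the slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CLASSES = ("ER", "R", "P", "EP")


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class SireClassification:
    sire: object
    n_progeny: int
    mean_slope: float
    slope_sd_units: float
    cls: str

    @property
    def robust(self) -> bool:
        return self.cls in ("ER", "R")


def _class_of(sd_units: float) -> str:
    if sd_units <= 1.0:
        return "ER"
    if sd_units < 2.0:
        return "R"
    if sd_units < 3.0:
        return "P"
    return "EP"


def classify_sires(
    slopes: Mapping,
    min_progeny: int = 3,
    progeny_counts: Mapping | None = None,
    center: str = "mean",
) -> list:
    """Classify each sire by |slope - centre| / SD of retained sires' slopes.

    ``slopes`` maps sire id to the posterior mean of its reaction-norm
    slope; sires with fewer than ``min_progeny`` recorded progeny (when
    counts are supplied) are excluded before the centre and scale are
    computed.  If every retained slope is identical the scale is degenerate:
    all sires are ER and a warning is issued.
    """
    if center not in ("mean", "zero"):
        raise ClassificationError(f"unknown center {center!r}")
    counts = progeny_counts or {}
    retained = [
        s for s in slopes if counts.get(s, min_progeny) >= min_progeny
    ]
    if len(retained) < 2:
        raise ClassificationError("need at least 2 sires after the progeny filter")
    vals = np.array([slopes[s] for s in retained], dtype=float)
    mu = vals.mean() if center == "mean" else 0.0
    sd = vals.std(ddof=1)
    out = []
    if sd == 0.0:
        warnings.warn("all sire slopes identical: degenerate scale, every sire ER")
    for s, v in zip(retained, vals):
        units = 0.0 if sd == 0.0 else abs(v - mu) / sd
        out.append(
            SireClassification(
                sire=s,
                n_progeny=int(counts.get(s, 0)),
                mean_slope=float(v),
                slope_sd_units=float(units),
                cls=_class_of(units),
            )
        )
    return out


def class_percentages(classifications: Sequence[SireClassification]) -> dict:
    """Percentage of sires per class; zero-count classes are reported as 0."""
    if len(classifications) == 0:
        raise ClassificationError("no classifications supplied")
    n = len(classifications)
    return {
        c: 100.0 * sum(1 for s in classifications if s.cls == c) / n for c in CLASSES
    }


def sire_progeny_counts(records) -> dict:
    """Progeny-with-record counts per known sire from phenotype records."""
    counts: dict = {}
    for r in records:
        if r.sire is not None:
            counts[r.sire] = counts.get(r.sire, 0) + 1
    return counts


def classification_frame(classifications: Sequence[SireClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sire": c.sire,
                "n_progeny": c.n_progeny,
                "mean_slope": c.mean_slope,
                "sd_units": c.slope_sd_units,
                "class": c.cls,
            }
            for c in classifications
        ]
    )


def save_classification(
    classifications: Sequence[SireClassification], out_dir, plot: bool = False
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    classification_frame(classifications).to_csv(out_dir / "sire_classes.csv", index=False)
    pct = class_percentages(classifications)
    pd.DataFrame([{"class": c, "percentage": pct[c]} for c in CLASSES]).to_csv(
        out_dir / "class_percentages.csv", index=False
    )
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(CLASSES, [pct[c] for c in CLASSES], color="steelblue")
        ax.set_ylabel("% of sires")
        ax.set_xlabel("environmental-sensitivity class")
        fig.tight_layout()
        fig.savefig(out_dir / "class_percentages.png", dpi=150)
        plt.close(fig)
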