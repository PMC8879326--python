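"""Virtual-screening triage: probabilities, thresholds and the shortlist.

A fitted classifier scores each library molecule with ``Prob_active`` (the
vote fraction for the active class). Two thresholds structure the triage:

* a *confidence* threshold derived from a labeled hold-out set — the largest
  Prob_active among its false positives, so that every prediction scoring
  strictly above it on that set was a true positive;
* a *shortlist* threshold (default 0.68) marking the molecules forwarded to
  downstream structure-based work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .qsar import ACTIVE, INACTIVE, QsarError

#: Default Prob_active level for shortlist selection.
DEFAULT_SHORTLIST_THRESHOLD = 0.68


class ScreeningError(QsarError):
    pass


@dataclass
class ScreeningHit:
    molecule_id: str
    predicted_class: str
    prob_active: float
    above_confidence: bool = False
    shortlist: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob_active <= 1.0):
            raise ScreeningError(
                f"Prob_active must lie in [0,1], got {self.prob_active}"
            )


def predict_library(model, X, ids: Sequence[str] | None = None) -> list[ScreeningHit]:
    """Score a featurized library; one hit per molecule, input order kept.

    ``X`` must carry the descriptor columns the model was trained on (a
    missing column is an error naming it). ``ids`` defaults to the matrix row
    index when available.
    """
    if ids is None:
        frame = X.values if hasattr(X, "missing_mask") else X  # DescriptorMatrix
        index = getattr(frame, "index", None)
        if index is None:
            raise ScreeningError("ids must be given when X has no row index")
        ids = [str(i) for i in index]
    if len(ids) == 0:
        return []
    probs = model.prob_active(X)
    classes = model.predict_class(X)
    if len(ids) != len(probs):
        raise ScreeningError("ids and matrix row count differ")
    return [
        ScreeningHit(molecule_id=i, predicted_class=c, prob_active=float(p))
        for i, c, p in zip(ids, classes, probs)
    ]


def derive_confidence_threshold(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    prob_active: Sequence[float],
) -> float:
    """Largest Prob_active over false positives of a labeled prediction set.

    Guarantee on that set: every molecule predicted active with Prob_active
    strictly above the returned value is a true positive. With no false
    positive present, falls back to the largest Prob_active among
    inactive-truth molecules (the guarantee then holds vacuously).
    """
    yt, yp = np.asarray(y_true), np.asarray(y_pred)
    p = np.asarray(prob_active, dtype=float)
    if len(p) == 0:
        raise ScreeningError("cannot derive a threshold from an empty prediction set")
    fp = (yt == INACTIVE) & (yp == ACTIVE)
    if fp.any():
        return float(p[fp].max())
    inactive = yt == INACTIVE
    if inactive.any():
        return float(p[inactive].max())
    return 0.0


def prob_diagnostics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    prob_active: Sequence[float],
) -> dict[str, float | None]:
    """Mean Prob_active per confusion cell (TP/FP/TN/FN); empty cell -> None."""
    yt, yp = np.asarray(y_true), np.asarray(y_pred)
    p = np.asarray(prob_active, dtype=float)
    cells = {
        "TP": (yt == ACTIVE) & (yp == ACTIVE),
        "FP": (yt == INACTIVE) & (yp == ACTIVE),
        "TN": (yt == INACTIVE) & (yp == INACTIVE),
        "FN": (yt == ACTIVE) & (yp == INACTIVE),
    }
    return {
        cell: (float(p[m].mean()) if m.any() else None) for cell, m in cells.items()
    }


def shortlist(
    hits: Sequence[ScreeningHit],
    theta_dock: float = DEFAULT_SHORTLIST_THRESHOLD,
    theta_conf: float | None = None,
) -> list[ScreeningHit]:
    """Flag shortlist membership and return hits ordered for reporting.

    A hit enters the shortlist iff it is predicted active and its
    Prob_active is at or above ``theta_dock`` (boundary included). When
    ``theta_conf`` is given, ``above_confidence`` is set for predicted
    actives scoring strictly above it. Output is ordered by decreasing
    Prob_active, ties broken by molecule id.
    """
    if not (0.0 <= theta_dock <= 1.0):
        raise ScreeningError(f"theta_dock must lie in [0,1], got {theta_dock}")
    out = []
    for h in hits:
        active = h.predicted_class == ACTIVE
        out.append(
            ScreeningHit(
                molecule_id=h.molecule_id,
                predicted_class=h.predicted_class,
                prob_active=h.prob_active,
                above_confidence=bool(
                    active and theta_conf is not None and h.prob_active > theta_conf
                ),
                shortlist=bool(active and h.prob_active >= theta_dock),
            )
        )
    out.sort(key=lambda h: (-h.prob_active, h.molecule_id))
    return out


def hits_to_frame(hits: Sequence[ScreeningHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [h.molecule_id for h in hits],
            "predicted_class": [h.predicted_class for h in hits],
            "prob_active": [h.prob_active for h in hits],
            "above_confidence": [h.above_confidence for h in hits],
            "shortlist": [h.shortlist for h in hits],
        }
    )


def write_hits_csv(hits: Sequence[ScreeningHit], path) -> None:
    hits_to_frame(hits).to_csv(path, index=False)


def read_hits_csv(path) -> list[ScreeningHit]:
    df = pd.read_csv(path, dtype={"id": str})
    return [
        ScreeningHit(
            molecule_id=row["id"],
            predicted_class=row["predicted_class"],
            prob_active=float(row["prob_active"]),
            above_confidence=bool(row["above_confidence"]),
            shortlist=bool(row["shortlist"]),
        )
        for _, row in df.iterrows()
    ]


def ugml_to_micromolar(conc_ugml: float, mw: float) -> float:
    """Convert a ug/mL concentration to uM given the molar mass in g/mol."""
    if mw <= 0:
        raise ScreeningError(f"molar mass must be positive, got {mw}")
    return 1000.0 * conc_ugml / mw
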