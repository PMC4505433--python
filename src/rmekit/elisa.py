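"""Quantification of biotinylation-ELISA plates.

Surface-resident protein is captured on NeutrAvidin plates after cell-surface
biotinylation and read as absorbance at 450 nm. Each biological repeat is one
lysate loaded in triplicate; quantification is triplicate mean, blank
subtraction, then averaging and fold-change/percent-of-reference estimation
across repeats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenes import ElisaPlate

log = logging.getLogger(__name__)

__all__ = [
    "SurfaceExpression",
    "quantify_plate",
    "fold_change",
    "pct_of_reference",
]


@dataclass
class SurfaceExpression:
    condition: str
    level: float  # blank-subtracted mean absorbance, a.u.
    sem: float
    n: int
    repeat_levels: tuple[float, ...] = ()
    fold_vs_control: float = float("nan")
    fold_sem: float = float("nan")
    pct_of_reference: float = float("nan")
    pct_sem: float = float("nan")
    flags: tuple[str, ...] = ()


def _per_lysate(plate: ElisaPlate, blank: float | None) -> pd.DataFrame:
    df = plate.wells
    if blank is None:
        blanks = df[df["condition"] == "blank"]["absorbance"]
        if blanks.empty:
            raise ValueError("no blank wells present and no blank level configured")
        blank = float(blanks.mean())
    cond = df[df["condition"] != "blank"]
    if "protein_scale" in cond.columns:
        cond = cond.assign(absorbance=cond["absorbance"] / cond["protein_scale"])
    per = (
        cond.groupby(["condition", "repeat"], sort=False)["absorbance"]
        .mean()
        .reset_index()
    )
    per["level"] = per["absorbance"] - blank
    neg = per["level"] < 0
    if neg.any():
        log.warning(
            "%d lysate level(s) below blank; floored at 0", int(neg.sum())
        )
        per.loc[neg, "level"] = 0.0
    return per


def quantify_plate(
    plate: ElisaPlate, blank: float | None = None
) -> dict[str, SurfaceExpression]:
    """Per-condition blank-subtracted surface-expression levels.

    Each lysate (condition x biological repeat) is summarised by the mean of
    its replicate wells minus the blank mean; the condition level is the mean
    over repeats with SEM across repeats. Dedicated blank wells are used when
    present, otherwise a scalar ``blank`` must be given. Negative
    blank-subtracted levels are floored at 0 with a warning.
    """
    per = _per_lysate(plate, blank)
    out: dict[str, SurfaceExpression] = {}
    for cond, grp in per.groupby("condition", sort=False):
        levels = grp["level"].to_numpy()
        n = len(levels)
        sem = float(levels.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        out[cond] = SurfaceExpression(
            condition=cond, level=float(levels.mean()), sem=sem, n=n,
            repeat_levels=tuple(float(v) for v in levels),
        )
    return out


def fold_change(
    expressions: dict[str, SurfaceExpression], control: str
) -> dict[str, SurfaceExpression]:
    """Fold change of every condition versus ``control``.

    The default estimate pairs biological repeats (repeat i of the condition
    against repeat i of the control), averages the per-repeat folds, and takes
    the SEM across repeats. When repeat counts differ the fold is the ratio of
    mean levels with a first-order (delta-method) SEM; that propagated SEM is
    also what the control itself gets (its paired folds are identically 1).
    """
    if control not in expressions:
        raise ValueError(f"control condition {control!r} missing")
    ctrl = expressions[control]
    if ctrl.level <= 0:
        raise ValueError("control level must be > 0")
    for cond, e in expressions.items():
        paired = (
            len(e.repeat_levels) == len(ctrl.repeat_levels)
            and len(e.repeat_levels) > 1
            and all(c > 0 for c in ctrl.repeat_levels)
            and cond != control
        )
        if paired:
            folds = np.array(
                [a / c for a, c in zip(e.repeat_levels, ctrl.repeat_levels)]
            )
            e.fold_vs_control = float(folds.mean())
            e.fold_sem = float(folds.std(ddof=1) / math.sqrt(len(folds)))
        else:
            e.fold_vs_control = e.level / ctrl.level
            # delta method: var(a/c) ~ (a/c)^2 (va/a^2 + vc/c^2)
            ra = (e.sem / e.level) ** 2 if e.level > 0 and e.sem == e.sem else 0.0
            rc = (ctrl.sem / ctrl.level) ** 2 if ctrl.sem == ctrl.sem else 0.0
            if cond == control:
                ra = rc  # identical repeats; variability is the control's own
            e.fold_sem = abs(e.fold_vs_control) * math.sqrt(ra + rc)
    return expressions


def pct_of_reference(
    expressions: dict[str, SurfaceExpression], reference: str
) -> dict[str, SurfaceExpression]:
    """Constitutive surface expression as a percentage of ``reference``."""
    if reference not in expressions:
        raise ValueError(f"reference condition {reference!r} missing")
    ref = expressions[reference]
    if ref.level <= 0:
        raise ValueError("reference level must be > 0")
    for cond, e in expressions.items():
        e.pct_of_reference = 100.0 * e.level / ref.level
        ra = (e.sem / e.level) ** 2 if e.level > 0 and e.sem == e.sem else 0.0
        rr = (ref.sem / ref.level) ** 2 if ref.sem == ref.sem else 0.0
        if cond == reference:
            ra = 0.0
            rr = 0.0
        e.pct_sem = abs(e.pct_of_reference) * math.sqrt(ra + rr)
        if e.level == 0:
            e.flags = e.flags + ("low-expression",)
    return expressions
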