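"""Rule-based orthostatic-hypotension phenotyping from active-stand vitals.

One subject's panel is a supine reading of systolic/diastolic blood pressure
(SBP/DBP, mmHg) and heart rate (HR, bpm) followed by standing readings at
minutes 1, 3 and 5.  From it we derive:

* postural deltas, Delta x(t) = x_stand(t) - x_supine, and their average over
  the standing minutes that are present (falls are negative deltas);
* classic orthostatic hypotension (OH): a fall in SBP >= 20 mmHg and/or in
  DBP >= 10 mmHg within 3 min of standing (consensus criterion);
* delayed OH: the qualifying fall occurs only at minute 5;
* neurogenic qualification, by either of two criteria: the ratio of average
  HR change to the magnitude of the average SBP fall is <= 0.5, or the
  average SBP fall is >= 30 mmHg.  Membership of a (+)OH subgroup requires
  OH (classic or delayed) plus at least one neurogenic criterion — this
  guards against purely medication- or volume-driven falls, for which HR
  compensation is typically preserved;
* supine hypertension: supine SBP >= 140 mmHg or DBP >= 90 mmHg;
* mean arterial pressure, MAP = (SBP + 2 DBP) / 3, the standard clinical
  estimate.

All boundary comparisons are inclusive (>=).  Missing standing timepoints
are simply left out of averages; a panel with no standing data at all is
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

__all__ = [
    "Vitals",
    "OrthostaticPanel",
    "PosturalDeltas",
    "AutonomicLabel",
    "STANDING_MINUTES",
    "mean_arterial_pressure",
    "postural_deltas",
    "classify_oh",
    "neurogenic_criteria",
    "supine_hypertension",
    "label_subject",
]

STANDING_MINUTES = (1, 3, 5)

SBP_FALL_MMHG = 20.0
DBP_FALL_MMHG = 10.0
NEUROGENIC_RATIO = 0.5
LARGE_FALL_MMHG = 30.0
SUPINE_HTN_SBP = 140.0
SUPINE_HTN_DBP = 90.0


class Vitals(NamedTuple):
    """One blood-pressure/heart-rate reading."""

    sbp: float
    dbp: float
    hr: float


def _check_reading(v: Vitals, where: str) -> None:
    if not (v.sbp > 0 and v.dbp > 0 and v.hr > 0):
        raise ValueError(f"{where}: all vitals must be positive, got {v}")
    if v.sbp <= v.dbp:
        raise ValueError(f"{where}: SBP must exceed DBP, got SBP={v.sbp}, DBP={v.dbp}")


@dataclass
class OrthostaticPanel:
    """Supine and minute-resolved standing vitals for one active-stand test."""

    supine: Vitals
    standing: dict[int, Optional[Vitals]]

    def __post_init__(self) -> None:
        self.supine = Vitals(*self.supine)
        _check_reading(self.supine, "supine")
        clean: dict[int, Optional[Vitals]] = {}
        for t in STANDING_MINUTES:
            v = self.standing.get(t)
            if v is not None:
                v = Vitals(*v)
                _check_reading(v, f"standing minute {t}")
            clean[t] = v
        extra = set(self.standing) - set(STANDING_MINUTES)
        if extra:
            raise ValueError(f"unexpected standing minutes {sorted(extra)}")
        self.standing = clean

    @property
    def present_minutes(self) -> tuple[int, ...]:
        return tuple(t for t in STANDING_MINUTES if self.standing[t] is not None)


@dataclass
class PosturalDeltas:
    """Per-minute and averaged stand-minus-supine changes (falls negative)."""

    delta_sbp: dict[int, float]
    delta_dbp: dict[int, float]
    delta_map: dict[int, float]
    delta_hr: dict[int, float]
    avg_delta_sbp: float
    avg_delta_dbp: float
    avg_delta_map: float
    avg_delta_hr: float
    minutes_used: tuple[int, ...]


@dataclass
class AutonomicLabel:
    """Categorical autonomic phenotype plus the quantities it was read from."""

    oh_class: str  # "none" | "classic" | "delayed"
    neurogenic_ratio_met: bool
    large_fall_met: bool
    oh_subgroup_positive: bool
    supine_htn: bool
    avg_delta_map: float
    avg_delta_sbp: float
    avg_delta_hr: float
    hr_sbp_ratio: Optional[float]


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """MAP = (SBP + 2 DBP) / 3; requires SBP > DBP > 0."""
    if dbp <= 0:
        raise ValueError(f"DBP must be positive, got {dbp}")
    if sbp <= dbp:
        raise ValueError(f"SBP must exceed DBP, got SBP={sbp}, DBP={dbp}")
    return (sbp + 2.0 * dbp) / 3.0


def postural_deltas(panel: OrthostaticPanel) -> PosturalDeltas:
    """Stand-minus-supine deltas per present minute, averaged over those minutes."""
    minutes = panel.present_minutes
    if not minutes:
        raise ValueError("no standing timepoints present; deltas undefined")
    sup = panel.supine
    sup_map = mean_arterial_pressure(sup.sbp, sup.dbp)
    d_sbp: dict[int, float] = {}
    d_dbp: dict[int, float] = {}
    d_map: dict[int, float] = {}
    d_hr: dict[int, float] = {}
    for t in minutes:
        v = panel.standing[t]
        assert v is not None
        d_sbp[t] = v.sbp - sup.sbp
        d_dbp[t] = v.dbp - sup.dbp
        d_map[t] = mean_arterial_pressure(v.sbp, v.dbp) - sup_map
        d_hr[t] = v.hr - sup.hr
    n = len(minutes)
    return PosturalDeltas(
        delta_sbp=d_sbp,
        delta_dbp=d_dbp,
        delta_map=d_map,
        delta_hr=d_hr,
        avg_delta_sbp=sum(d_sbp.values()) / n,
        avg_delta_dbp=sum(d_dbp.values()) / n,
        avg_delta_map=sum(d_map.values()) / n,
        avg_delta_hr=sum(d_hr.values()) / n,
        minutes_used=minutes,
    )


def _fall_qualifies(deltas: PosturalDeltas, t: int) -> bool:
    return (-deltas.delta_sbp[t] >= SBP_FALL_MMHG) or (
        -deltas.delta_dbp[t] >= DBP_FALL_MMHG
    )


def classify_oh(panel: OrthostaticPanel, require_minute3: bool = False) -> str:
    """Classify the panel as "none", "classic" or "delayed" OH.

    Classic: the consensus fall threshold (SBP >= 20 or DBP >= 10 mmHg) is met
    at minute 1 or minute 3 (with ``require_minute3``, it must be met at
    minute 3, a stricter reading of "sustained").  Delayed: not classic and
    the threshold is met at minute 5.
    """
    deltas = postural_deltas(panel)
    present = set(deltas.minutes_used)
    if require_minute3:
        classic = 3 in present and _fall_qualifies(deltas, 3)
    else:
        classic = any(t in present and _fall_qualifies(deltas, t) for t in (1, 3))
    if classic:
        return "classic"
    if 5 in present and _fall_qualifies(deltas, 5):
        return "delayed"
    return "none"


def neurogenic_criteria(
    panel: OrthostaticPanel,
) -> tuple[bool, bool, Optional[float]]:
    """Evaluate the two neurogenic-OH qualifiers.

    Returns ``(ratio_met, large_fall_met, hr_sbp_ratio)``.  The ratio is
    mean Delta HR / |mean Delta SBP|, defined only when the mean SBP change
    is a fall (< 0); under a pressor response it is undefined and the
    criterion is simply not met.
    """
    deltas = postural_deltas(panel)
    mean_d_sbp = deltas.avg_delta_sbp
    mean_d_hr = deltas.avg_delta_hr
    if mean_d_sbp < 0:
        ratio: Optional[float] = mean_d_hr / abs(mean_d_sbp)
        ratio_met = ratio <= NEUROGENIC_RATIO
    else:
        ratio = None
        ratio_met = False
    large_fall_met = -mean_d_sbp >= LARGE_FALL_MMHG
    return ratio_met, large_fall_met, ratio


def supine_hypertension(panel: OrthostaticPanel) -> bool:
    """Supine SBP >= 140 mmHg or DBP >= 90 mmHg."""
    return panel.supine.sbp >= SUPINE_HTN_SBP or panel.supine.dbp >= SUPINE_HTN_DBP


def label_subject(
    panel: OrthostaticPanel, require_minute3: bool = False
) -> AutonomicLabel:
    """Compose all classification rules into one label.

    (+)OH subgroup membership = (classic or delayed OH) AND (ratio criterion
    OR large-fall criterion).
    """
    deltas = postural_deltas(panel)
    oh_class = classify_oh(panel, require_minute3=require_minute3)
    ratio_met, large_fall_met, ratio = neurogenic_criteria(panel)
    return AutonomicLabel(
        oh_class=oh_class,
        neurogenic_ratio_met=ratio_met,
        large_fall_met=large_fall_met,
        oh_subgroup_positive=(oh_class != "none") and (ratio_met or large_fall_met),
        supine_htn=supine_hypertension(panel),
        avg_delta_map=deltas.avg_delta_map,
        avg_delta_sbp=deltas.avg_delta_sbp,
        avg_delta_hr=deltas.avg_delta_hr,
        hr_sbp_ratio=ratio,
    )
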