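"""Hand-crafted active-stand vignettes with rule-derived expected labels.

Each entry is ``(name, panel, expected)`` where ``expected`` maps
AutonomicLabel field names to the value the classification rules dictate.
The set covers the rule boundaries: classic OH at minute 1, classic via the
DBP arm, delayed-only OH at minute 5, the neurogenic HR/SBP ratio boundary
at 0.5, the 30-mmHg average-fall boundary, a pressor response (undefined
ratio), the supine-hypertension boundaries at 140/90 mmHg, and missing
standing timepoints.
"""

from __future__ import annotations

from typing import Optional

from .autonomic import OrthostaticPanel, Vitals

__all__ = ["VIGNETTES"]


def _panel(supine, m1=None, m3=None, m5=None) -> OrthostaticPanel:
    return OrthostaticPanel(
        supine=Vitals(*supine),
        standing={
            1: Vitals(*m1) if m1 else None,
            3: Vitals(*m3) if m3 else None,
            5: Vitals(*m5) if m5 else None,
        },
    )


VIGNETTES: list[tuple[str, OrthostaticPanel, dict]] = [
    (
        "classic OH at minute 1 (SBP fall 25), brisk HR, not neurogenic",
        _panel((140, 80, 70), (115, 75, 85), (130, 76, 82), (132, 77, 80)),
        # avg dSBP = -14.33, avg dHR = +12.33 -> ratio 0.86
        {"oh_class": "classic", "neurogenic_ratio_met": False,
         "large_fall_met": False, "oh_subgroup_positive": False},
    ),
    (
        "classic OH via DBP arm only (DBP fall 11 at minute 3)",
        _panel((140, 80, 70), (135, 78, 72), (134, 69, 74), (135, 78, 72)),
        {"oh_class": "classic"},
    ),
    (
        "delayed OH: qualifying fall only at minute 5",
        _panel((140, 80, 70), (132, 75, 74), (130, 74, 76), (118, 73, 80)),
        {"oh_class": "delayed"},
    ),
    (
        "no OH: all falls below both thresholds",
        _panel((140, 80, 70), (125, 75, 78), (126, 74, 78), (125, 75, 78)),
        {"oh_class": "none", "oh_subgroup_positive": False},
    ),
    (
        "neurogenic ratio exactly 0.5 (inclusive boundary): met",
        # dSBP -30 each minute, dHR +15 each minute -> ratio 15/30 = 0.5
        _panel((140, 80, 70), (110, 70, 85), (110, 70, 85), (110, 70, 85)),
        {"oh_class": "classic", "neurogenic_ratio_met": True,
         "large_fall_met": True, "oh_subgroup_positive": True,
         "hr_sbp_ratio": 0.5},
    ),
    (
        "ratio just above 0.5 and fall below 30: OH but subgroup negative",
        # dSBP -22, dHR +11.5 -> ratio 0.5227
        _panel((140, 80, 70), (118, 74, 81.5), (118, 74, 81.5), (118, 74, 81.5)),
        {"oh_class": "classic", "neurogenic_ratio_met": False,
         "large_fall_met": False, "oh_subgroup_positive": False},
    ),
    (
        "ratio exactly 0.5 at a 22-mmHg fall: subgroup positive via ratio",
        _panel((140, 80, 70), (118, 74, 81), (118, 74, 81), (118, 74, 81)),
        {"oh_class": "classic", "neurogenic_ratio_met": True,
         "large_fall_met": False, "oh_subgroup_positive": True},
    ),
    (
        "average fall exactly 30 mmHg (inclusive boundary): large fall met",
        _panel((150, 85, 70), (120, 75, 72), (120, 75, 72), (120, 75, 72)),
        {"oh_class": "classic", "large_fall_met": True,
         "oh_subgroup_positive": True, "avg_delta_sbp": -30.0},
    ),
    (
        "average fall 29 mmHg with brisk HR: classic OH, subgroup negative",
        _panel((150, 85, 70), (121, 75, 90), (121, 75, 90), (121, 75, 90)),
        {"oh_class": "classic", "neurogenic_ratio_met": False,
         "large_fall_met": False, "oh_subgroup_positive": False},
    ),
    (
        "pressor response: ratio undefined, both criteria unmet",
        _panel((140, 80, 70), (144, 82, 72), (144, 82, 72), (144, 82, 72)),
        {"oh_class": "none", "neurogenic_ratio_met": False,
         "large_fall_met": False, "oh_subgroup_positive": False,
         "hr_sbp_ratio": None},
    ),
    (
        "supine 139/89: just below both hypertension boundaries",
        _panel((139, 89, 70), (138, 88, 72), (138, 88, 72), (138, 88, 72)),
        {"supine_htn": False},
    ),
    (
        "supine 140/70: SBP boundary inclusive",
        _panel((140, 70, 70), (138, 69, 72), (138, 69, 72), (138, 69, 72)),
        {"supine_htn": True},
    ),
    (
        "supine 120/92: DBP arm alone triggers supine hypertension",
        _panel((120, 92, 70), (118, 90, 72), (118, 90, 72), (118, 90, 72)),
        {"supine_htn": True},
    ),
    (
        "minute 3 missing: classic via minute 1, average over minutes 1 and 5",
        _panel((140, 80, 70), (115, 75, 80), None, (110, 74, 82)),
        {"oh_class": "classic", "avg_delta_sbp": -27.5},
    ),
    (
        "only minute 5 recorded with a qualifying fall: delayed",
        _panel((140, 80, 70), None, None, (118, 73, 80)),
        {"oh_class": "delayed"},
    ),
]
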