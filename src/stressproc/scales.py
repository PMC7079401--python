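"""Scoring of the screening instruments used in the cohort.

The package scores four instruments:

* **EPDS** — Edinburgh Postnatal Depression Scale, 10 items each coded 0-3
  toward distress, total 0-30.  A total of 12-16 screens positive for
  possible antenatal depression; totals of 17 or more trigger exclusion
  from analysis (with referral), and any endorsement of item 10
  (self-harm) or a total of 13+ triggers referral.
* **OSSS-3** — Oslo Social Support Scale, three items (ranges 1-4, 1-5,
  1-5), total 3-14; a total below 9 is classed "poor" support.
* **PCI-4** — a four-item pregnancy-specific coping inventory, items
  coded 0-3, total 0-12, reported as median/IQR (no cutoff).
* **MUAC** — mid-upper-arm circumference in cm, classified by a named,
  swappable rule set.

Scorers are pure: they accept already direction-coded responses and raw
numeric values; the CSV layer applies the published direction key
(:data:`EPDS_REVERSE_CODED_ITEMS`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SubjectRecord",
    "ScaleScore",
    "EPDS_REVERSE_CODED_ITEMS",
    "MUAC_RULESETS",
    "score_epds",
    "score_osss3",
    "score_pci4",
    "classify_muac",
    "cronbach_alpha",
    "apply_eligibility",
]

#: 1-based EPDS items whose published response options run from distress to
#: no-distress, i.e. raw option index k (0-3) codes to 3-k.  Items 1, 2 and
#: 4 are coded in presentation order.  Applied by the CSV reader, never by
#: the scorer.
EPDS_REVERSE_CODED_ITEMS: frozenset[int] = frozenset({3, 5, 6, 7, 8, 9, 10})

#: Per-item (min, max) of the OSSS-3 response scales; the total therefore
#: spans 3-14 ("summed to 14 points").
OSSS3_ITEM_RANGES: tuple[tuple[int, int], ...] = ((1, 4), (1, 5), (1, 5))

# EPDS decision thresholds (analysis cutoff, referral and exclusion).
EPDS_POSSIBLE_DEPRESSION = 12
EPDS_REFERRAL = 13
EPDS_EXCLUSION = 17

OSSS3_POOR_BELOW = 9


@dataclass(frozen=True)
class ScaleScore:
    """A scored instrument: integer total, cutoff category, rule flags."""

    total: int
    category: str | None
    flags: frozenset[str] = field(default_factory=frozenset)

    def has_flag(self, name: str) -> bool:
        return name in self.flags


@dataclass
class SubjectRecord:
    """One participant's item responses, stressors, mediators and covariates.

    Items are stored direction-coded.  Ordinal codings follow the packaged
    data dictionary: ``marital_agreement`` 1 (never) .. 4 (most of the
    time); ``partner_support`` 1 (never) .. 5 (always);
    ``pregnancy_intention`` in {"planned", "untimed", "unintended"}.
    """

    subject_id: str
    epds_items: Sequence[int]
    osss3_items: Sequence[int]
    pci4_items: Sequence[int]
    partner_support: int
    marital_agreement: int
    food_access_difficulty: int
    pregnancy_intention: str
    fear_of_birth: int
    history_cmd: int
    gestational_weeks: int
    muac_cm: float
    cluster_id: str
    covariates: dict = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.epds_items) != 10 or any(
            not (0 <= int(v) <= 3) for v in self.epds_items
        ):
            raise ValueError(f"{self.subject_id}: invalid EPDS items")
        for v, (lo, hi) in zip(self.osss3_items, OSSS3_ITEM_RANGES, strict=True):
            if not (lo <= int(v) <= hi):
                raise ValueError(f"{self.subject_id}: OSSS-3 item out of range")
        if len(self.pci4_items) != 4 or any(
            not (0 <= int(v) <= 3) for v in self.pci4_items
        ):
            raise ValueError(f"{self.subject_id}: invalid PCI-4 items")
        if not 1 <= int(self.partner_support) <= 5:
            raise ValueError(f"{self.subject_id}: partner_support out of 1..5")
        if not 1 <= int(self.marital_agreement) <= 4:
            raise ValueError(f"{self.subject_id}: marital_agreement out of 1..4")
        if self.pregnancy_intention not in ("planned", "untimed", "unintended"):
            raise ValueError(f"{self.subject_id}: bad pregnancy_intention")
        if not 13 <= int(self.gestational_weeks) <= 42:
            raise ValueError(
                f"{self.subject_id}: gestational_weeks outside 2nd/3rd trimester"
            )
        if not self.muac_cm > 0:
            raise ValueError(f"{self.subject_id}: non-positive MUAC")


def _check_items(responses: Sequence, n: int, lo: int, hi: int, name: str) -> np.ndarray:
    try:
        arr = np.asarray(responses, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{name}: non-numeric item response") from exc
    if arr.shape != (n,):
        raise ValueError(f"{name}: expected {n} items, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError(f"{name}: missing item response (no imputation)")
    if not np.all(arr == np.round(arr)):
        raise ValueError(f"{name}: non-integer item response")
    arr = arr.astype(int)
    if arr.min() < lo or arr.max() > hi:
        raise ValueError(f"{name}: response outside {lo}..{hi}")
    return arr


def score_epds(responses: Sequence[int]) -> ScaleScore:
    """Score ten direction-coded EPDS responses.

    Categories: ``none`` (<12), ``possible_depression`` (12-16),
    ``excluded_high`` (>=17).  ``self_harm_flag`` is set when item 10 is
    endorsed at all; ``referral_flag`` when the total reaches 13 or the
    self-harm flag is set.
    """
    items = _check_items(responses, 10, 0, 3, "EPDS")
    total = int(items.sum())
    if total < EPDS_POSSIBLE_DEPRESSION:
        category = "none"
    elif total < EPDS_EXCLUSION:
        category = "possible_depression"
    else:
        category = "excluded_high"
    flags = set()
    if items[9] > 0:
        flags.add("self_harm_flag")
    if total >= EPDS_REFERRAL or "self_harm_flag" in flags:
        flags.add("referral_flag")
    if total >= EPDS_EXCLUSION:
        flags.add("exclusion_flag")
    return ScaleScore(total=total, category=category, flags=frozenset(flags))


def score_osss3(responses: Sequence[int]) -> ScaleScore:
    """Score the three OSSS-3 items; total < 9 is "poor" support."""
    arr = np.asarray(responses)
    if arr.shape != (3,):
        raise ValueError(f"OSSS-3: expected 3 items, got shape {arr.shape}")
    items = []
    for v, (lo, hi) in zip(arr, OSSS3_ITEM_RANGES, strict=True):
        try:
            fv = float(v)
        except (TypeError, ValueError) as exc:
            raise ValueError("OSSS-3: non-numeric item response") from exc
        if fv != fv:
            raise ValueError("OSSS-3: missing item response")
        iv = int(fv)
        if iv != fv or not lo <= iv <= hi:
            raise ValueError(f"OSSS-3: response {v!r} outside {lo}..{hi}")
        items.append(iv)
    total = sum(items)
    category = "poor" if total < OSSS3_POOR_BELOW else "moderate_to_strong"
    return ScaleScore(total=total, category=category)


def score_pci4(responses: Sequence[int]) -> ScaleScore:
    """Score the four PCI-4 coping items (0-3 each, total 0-12, no cutoff)."""
    items = _check_items(responses, 4, 0, 3, "PCI-4")
    return ScaleScore(total=int(items.sum()), category=None)


#: Named MUAC classification rules, label -> list of (low, high, label)
#: closed intervals in cm.  "printed" preserves the study's published rule
#: verbatim (18-22 normal, 22.5-31 underweight), which inverts common field
#: practice; "conventional" is the usual reading (<= 22 underweight).
#: Values falling in no interval classify as "out_of_range" (the printed
#: rule leaves 22-22.5 unassigned).
MUAC_RULESETS: Mapping[str, tuple[tuple[float, float, str], ...]] = {
    "printed": ((18.0, 22.0, "normal"), (22.5, 31.0, "underweight")),
    "conventional": ((18.0, 22.0, "underweight"), (22.5, 31.0, "normal")),
}


def classify_muac(muac_cm: float, ruleset: str = "printed") -> str:
    """Classify a MUAC measurement (cm) under a named rule set."""
    if not muac_cm > 0:
        raise ValueError("MUAC must be positive")
    for lo, hi, label in MUAC_RULESETS[ruleset]:
        if lo <= muac_cm <= hi:
            return label
    return "out_of_range"


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha for a subjects x items score matrix.

    Uses population (divide-by-n) variances throughout:
    ``alpha = k/(k-1) * (1 - sum_i var(item_i) / var(total))``.
    Returns ``nan`` when the total score has zero variance.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("need >= 3 subjects and >= 2 items")
    if np.isnan(x).any():
        raise ValueError("missing values not allowed")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=0)
    total_var = x.sum(axis=1).var(ddof=0)
    if total_var <= 0:
        return math.nan
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def apply_eligibility(
    records: Iterable[SubjectRecord],
) -> tuple[list[SubjectRecord], list[SubjectRecord], list[SubjectRecord]]:
    """Partition records into (analysis set, excluded set, referral list).

    Exclusion: EPDS total >= 17.  Referral: EPDS total >= 13 or any
    endorsement of item 10 (the excluded are also referred).  The first two
    outputs partition the input exactly; the referral list may overlap both.
    """
    analysis: list[SubjectRecord] = []
    excluded: list[SubjectRecord] = []
    referral: list[SubjectRecord] = []
    for rec in records:
        score = score_epds(rec.epds_items)
        (excluded if score.total >= EPDS_EXCLUSION else analysis).append(rec)
        if score.has_flag("referral_flag"):
            referral.append(rec)
    return analysis, excluded, referral
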