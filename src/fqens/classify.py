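"""Conformer classification and ensemble summaries.

Every complete conformer receives exactly one label:

* ``NonContact`` — fewer than ``contact_cutoff_q`` (default 5) total
  quencher-fluorophore heavy-atom contacts (Q_Tq).
* ``StackX`` / ``StackP`` — the quencher ring passes the pi-stacking test
  (centroid distance, interplanar angle and slip offset all within the
  criteria) against the xanthene / phenyl ring.
* ``ContactUnstacked`` — in contact but stacked on neither ring.

If both stacking tests pass, the ring with the smaller centroid distance
wins (tie -> StackX) and the conflict is recorded in the rationale.
Ensemble fractions carry 95% Wilson score intervals; two ensembles are
compared class-by-class with a two-proportion z statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .geometry import ConformerProfile

__all__ = [
    "Label",
    "StackingCriteria",
    "ConformerLabel",
    "EnsembleSummary",
    "ClassDelta",
    "classify_conformer",
    "summarize_ensemble",
    "compare_ensembles",
    "DEFAULT_CONTACT_CUTOFF_Q",
]

DEFAULT_CONTACT_CUTOFF_Q = 5  # Q_Tq >= 5 defines the contact group


class Label(str, Enum):
    STACK_X = "StackX"
    STACK_P = "StackP"
    CONTACT_UNSTACKED = "ContactUnstacked"
    NON_CONTACT = "NonContact"


LABEL_ORDER: tuple[Label, ...] = (
    Label.STACK_X,
    Label.STACK_P,
    Label.CONTACT_UNSTACKED,
    Label.NON_CONTACT,
)


@dataclass(frozen=True)
class StackingCriteria:
    """Thresholds of the pi-stacking test (conventional pi-pi geometry).

    A ring pair counts as stacked when centroid distance <=
    ``max_centroid_distance``, interplanar angle <= ``max_interplanar_angle``
    and slip offset <= ``max_lateral_offset``. All three are configurable.
    """

    max_centroid_distance: float = 4.5  # A
    max_interplanar_angle: float = 30.0  # degrees
    max_lateral_offset: float = 2.0  # A

    def __post_init__(self):
        if min(self.max_centroid_distance, self.max_interplanar_angle,
               self.max_lateral_offset) <= 0:
            raise ValueError("stacking criteria must all be positive")

    def passes(self, d: float, angle: float, offset: float) -> bool:
        return (
            d <= self.max_centroid_distance
            and angle <= self.max_interplanar_angle
            and offset <= self.max_lateral_offset
        )


@dataclass
class ConformerLabel:
    """Assigned class plus a rationale of which criteria fired."""

    label: Label
    rationale: dict


def classify_conformer(
    profile: ConformerProfile,
    criteria: StackingCriteria = StackingCriteria(),
    contact_cutoff_q: int = DEFAULT_CONTACT_CUTOFF_Q,
) -> ConformerLabel:
    """Assign exactly one of the four conformer classes."""
    if not profile.complete:
        raise ValueError(
            f"model {profile.model_index}: incomplete profile (quencher absent) "
            "cannot be classified"
        )
    c, g = profile.contacts, profile.geometry
    rationale: dict = {"q_tq": c.q_tq, "contact_cutoff_q": contact_cutoff_q}
    if c.q_tq < contact_cutoff_q:
        rationale["reason"] = f"Q_Tq {c.q_tq} < {contact_cutoff_q}"
        return ConformerLabel(Label.NON_CONTACT, rationale)

    stack_x = criteria.passes(g.d_xq, g.angle_xq, g.offset_xq)
    stack_p = criteria.passes(g.d_pq, g.angle_pq, g.offset_pq)
    rationale.update(stack_x_test=stack_x, stack_p_test=stack_p)
    if stack_x and stack_p:
        rationale["conflict"] = "both stacking tests passed; smaller centroid distance wins"
        label = Label.STACK_X if g.d_xq <= g.d_pq else Label.STACK_P
    elif stack_x:
        label = Label.STACK_X
    elif stack_p:
        label = Label.STACK_P
    else:
        label = Label.CONTACT_UNSTACKED
        rationale["reason"] = "in contact; both stacking tests failed"
    return ConformerLabel(label, rationale)


@dataclass
class EnsembleSummary:
    """Counts, fractions and Wilson 95% intervals per conformer class."""

    n_total: int
    counts: dict[str, int]
    fractions: dict[str, float] = field(init=False)
    intervals: dict[str, tuple[float, float]] = field(init=False)
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_total < 1:
            raise ValueError("empty ensemble")
        if sum(self.counts.values()) != self.n_total:
            raise ValueError("class counts do not sum to n_total")
        self.fractions = {k: v / self.n_total for k, v in self.counts.items()}
        self.intervals = {}
        for k, v in self.counts.items():
            lo, hi = proportion_confint(v, self.n_total, alpha=0.05, method="wilson")
            self.intervals[k] = (float(lo), float(hi))


def summarize_ensemble(
    labels: Iterable[ConformerLabel | Label | str],
    settings: dict | None = None,
) -> EnsembleSummary:
    """Tally labels over the fixed four-class vocabulary."""
    counts = {lbl.value: 0 for lbl in LABEL_ORDER}
    n = 0
    for item in labels:
        lbl = item.label if isinstance(item, ConformerLabel) else Label(item)
        counts[lbl.value] += 1
        n += 1
    if n == 0:
        raise ValueError("cannot summarize an empty label list")
    return EnsembleSummary(n, counts, settings=dict(settings or {}))


@dataclass
class ClassDelta:
    """Per-class change between two ensembles (bound minus free)."""

    label: str
    fraction_a: float
    fraction_b: float
    delta: float
    delta_ci95: tuple[float, float]
    z_statistic: float
    p_value: float


def compare_ensembles(
    summary_a: EnsembleSummary, summary_b: EnsembleSummary
) -> list[ClassDelta]:
    """Class-by-class fraction differences (B - A) with propagated 95% CI
    and a pooled two-proportion z statistic."""
    if set(summary_a.counts) != set(summary_b.counts):
        raise ValueError(
            f"label vocabularies differ: {sorted(summary_a.counts)} vs "
            f"{sorted(summary_b.counts)}"
        )
    out: list[ClassDelta] = []
    for lbl in summary_a.counts:
        ca, na = summary_a.counts[lbl], summary_a.n_total
        cb, nb = summary_b.counts[lbl], summary_b.n_total
        pa, pb = ca / na, cb / nb
        delta = pb - pa
        se = np.sqrt(pa * (1 - pa) / na + pb * (1 - pb) / nb)
        ci = (float(delta - 1.959963984540054 * se), float(delta + 1.959963984540054 * se))
        if ca + cb in (0, na + nb):  # degenerate pooled proportion
            z, p = float("nan"), float("nan")
        else:
            z, p = proportions_ztest([cb, ca], [nb, na])
        out.append(ClassDelta(lbl, pa, pb, float(delta), ci, float(z), float(p)))
    return out


def labels_from_profiles(
    profiles: Sequence[ConformerProfile],
    criteria: StackingCriteria = StackingCriteria(),
    contact_cutoff_q: int = DEFAULT_CONTACT_CUTOFF_Q,
) -> tuple[list[ConformerLabel], list[int]]:
    """Classify all complete profiles; return labels and skipped model indices."""
    labels: list[ConformerLabel] = []
    skipped: list[int] = []
    for p in profiles:
        if not p.complete:
            skipped.append(p.model_index)
            continue
        labels.append(classify_conformer(p, criteria, contact_cutoff_q))
    return labels, skipped
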