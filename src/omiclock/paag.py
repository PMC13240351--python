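"""Personalized-context-aware age gap (PAAG) and aging-group stratification.

The conventional age gap, predicted minus chronological age, confounds a
model's systematic bias at a given age with an individual's deviation from
peers. PAAG removes that bias: samples are grouped by chronological age,
each group's anchor is the mean predicted biological age of its members,
and a sample's gap is its own prediction minus its group anchor:

    g_i = a_hat_i - mu_bio(a_i)

By construction the gaps sum to zero within every anchor group, so any
group-level shift of predictions (the typical clock bias pattern) cancels.
Positive gaps mean faster-than-peers aging. Cohorts are stratified at a
threshold epsilon equal to the sample standard deviation of the gaps:
accelerated (g > eps), decelerated (g < -eps), otherwise normal.

The metric is clock-agnostic: :func:`apply_paag_to_external_clock` runs the
identical computation on any other model's predicted ages.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from omiclock.errors import ValidationError

logger = logging.getLogger(__name__)

GROUP_LABELS = ("decelerated", "normal", "accelerated")


@dataclass(frozen=True)
class PAAGResult:
    """Per-sample gaps with anchors, threshold and (optional) group labels.

    ``anchors`` maps group key (left bucket edge in years) to the group's
    mean predicted biological age. ``conventional_gap`` carries the plain
    predicted-minus-chronological age gap for comparison; it is NOT the
    PAAG. ``group_label`` is filled by :func:`stratify`.
    """

    gap: np.ndarray
    predicted_age: np.ndarray
    chronological_age: np.ndarray
    group_key: np.ndarray
    anchors: dict[float, float]
    group_width: float
    conventional_gap: np.ndarray
    epsilon: float | None = None
    group_label: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.gap.shape[0]

    def to_frame(self, sample_ids=None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "chronological_age": self.chronological_age,
                "predicted_age": self.predicted_age,
                "paag": self.gap,
                "anchor": [self.anchors[k] for k in self.group_key],
                "conventional_age_gap": self.conventional_gap,
            }
        )
        if self.group_label is not None:
            frame["group"] = self.group_label
        if sample_ids is not None:
            frame.insert(0, "sample_id", list(sample_ids))
        return frame


def _group_keys(
    ages: np.ndarray, group_width: float, min_group_size: int
) -> np.ndarray:
    """Assign anchor-group keys; undersized groups merge into 10-year bins."""
    if np.isinf(group_width):
        return np.zeros(ages.shape[0])
    keys = np.floor(ages / group_width) * group_width
    if min_group_size > 1:
        unique, counts = np.unique(keys, return_counts=True)
        small = set(unique[counts < min_group_size])
        if small:
            logger.info(
                "merging %d anchor groups smaller than %d into 10-year bins",
                len(small),
                min_group_size,
            )
            coarse = np.floor(ages / 10.0) * 10.0
            keys = np.where(np.isin(keys, list(small)), coarse, keys)
    return keys


def compute_paag(
    predicted_ages,
    chronological_ages,
    group_width: float = 1.0,
    min_group_size: int = 5,
) -> PAAGResult:
    """Context-aware age gaps relative to chronological-age-group anchors.

    Samples are grouped by ``floor(age / group_width)`` (default 1-year
    groups, i.e. exact integer age); groups smaller than ``min_group_size``
    are merged into their enclosing 10-year bin to keep anchors stable
    (set ``min_group_size=1`` to disable). ``group_width=np.inf`` puts the
    whole cohort in one group, so the gap is the prediction minus the
    global mean prediction.
    """
    predicted = np.asarray(predicted_ages, dtype=float)
    ages = np.asarray(chronological_ages, dtype=float)
    if predicted.ndim != 1 or predicted.shape != ages.shape:
        raise ValidationError("predicted and chronological ages must be equal-length vectors")
    if predicted.size == 0:
        raise ValidationError("empty input")
    if group_width <= 0:
        raise ValidationError("group_width must be > 0")
    keys = _group_keys(ages, group_width, min_group_size)
    anchors: dict[float, float] = {}
    gap = np.empty_like(predicted)
    for key in np.unique(keys):
        members = keys == key
        anchor = float(predicted[members].mean())
        anchors[float(key)] = anchor
        gap[members] = predicted[members] - anchor
    return PAAGResult(
        gap=gap,
        predicted_age=predicted,
        chronological_age=ages,
        group_key=keys,
        anchors=anchors,
        group_width=group_width,
        conventional_gap=predicted - ages,
    )


def stratify(paag: PAAGResult) -> PAAGResult:
    """Label samples decelerated / normal / accelerated at epsilon = SD(gaps).

    Epsilon is the sample standard deviation (N-1 divisor) of all gaps in
    the cohort. Accelerated means g > eps (strict), decelerated g < -eps;
    everything else, including the boundaries, is normal.
    """
    if paag.n_samples < 2:
        raise ValidationError("stratification needs >= 2 samples for a standard deviation")
    epsilon = float(np.std(paag.gap, ddof=1))
    labels = np.full(paag.n_samples, "normal", dtype=object)
    labels[paag.gap > epsilon] = "accelerated"
    labels[paag.gap < -epsilon] = "decelerated"
    return dataclasses.replace(paag, epsilon=epsilon, group_label=labels)


def apply_paag_to_external_clock(
    external_predicted_ages,
    chronological_ages,
    group_width: float = 1.0,
    min_group_size: int = 5,
) -> PAAGResult:
    """PAAG for predictions from any other aging clock (same computation)."""
    return compute_paag(
        external_predicted_ages, chronological_ages, group_width, min_group_size
    )
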