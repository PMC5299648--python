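"""Individual transfer functions (ITFs) and their coefficient-averaged
generalized transfer functions (GTFs).

One ITF is estimated per subject and period pair from the R-aligned SAECG
pair; the GTF for a pair is the per-order arithmetic mean of all subjects'
ITF coefficients (the monic leading denominator coefficient stays exactly 1).
Evaluation simulates each subject's input SAECG through both models and
scores each simulation against the measured output SAECG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, InstabilityError, ParameterError
from .model_selection import PeriodPair
from .preprocess import SAECG
from .sysid import (
    DiscreteTransferFunction,
    FitResult,
    estimate_tf,
    goodness_of_fit,
    simulate_tf,
)

__all__ = [
    "SubjectSAECGs",
    "GeneralizedTF",
    "EvaluationTable",
    "pair_saecgs",
    "fit_itf",
    "average_itfs",
    "evaluate_models",
]

_MIN_OVERLAP = 10


@dataclass(frozen=True)
class SubjectSAECGs:
    """One subject's three period SAECGs (before, during, after)."""

    subject_id: str
    before: SAECG
    during: SAECG
    after: SAECG

    def __post_init__(self):
        fss = {self.before.fs, self.during.fs, self.after.fs}
        if len(fss) != 1:
            raise ParameterError("all three SAECGs must share the sampling frequency")

    def get(self, period: str) -> SAECG:
        try:
            return {"before": self.before, "during": self.during, "after": self.after}[
                period
            ]
        except KeyError:
            raise ParameterError(f"unknown period {period!r}") from None


@dataclass(frozen=True)
class GeneralizedTF:
    """Coefficient-averaged transfer function for one period pair."""

    pair: str
    tf: DiscreteTransferFunction
    n_subjects: int
    source_ids: tuple[str, ...]


def pair_saecgs(
    input_saecg: SAECG, output_saecg: SAECG
) -> tuple[np.ndarray, np.ndarray]:
    """R-align two SAECGs and truncate to their common overlap.

    Both are shifted so the R peaks coincide; the head is trimmed to the
    shorter pre-R span and the tail to the shorter post-R span, yielding
    equal-length vectors with the R peak at the same index.
    """
    if input_saecg.fs != output_saecg.fs:
        raise ParameterError("SAECGs must share the sampling frequency")
    pre = min(input_saecg.r_offset, output_saecg.r_offset)
    post = min(
        len(input_saecg) - input_saecg.r_offset,
        len(output_saecg) - output_saecg.r_offset,
    )
    if pre + post < _MIN_OVERLAP:
        raise AlignmentError(
            f"aligned overlap of {pre + post} samples is below {_MIN_OVERLAP}"
        )
    x = input_saecg.samples[input_saecg.r_offset - pre : input_saecg.r_offset + post]
    y = output_saecg.samples[
        output_saecg.r_offset - pre : output_saecg.r_offset + post
    ]
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def fit_itf(
    subject: SubjectSAECGs,
    pair: PeriodPair,
    num_order: int,
    den_order: int,
) -> FitResult:
    """Estimate one subject's transfer function for one period pair."""
    x, y = pair_saecgs(subject.get(pair.input_period), subject.get(pair.output_period))
    fit = estimate_tf(x, y, num_order, den_order)
    fit.subject_id = subject.subject_id
    fit.pair = pair.label
    return fit


def average_itfs(
    itfs: Sequence[FitResult | DiscreteTransferFunction],
    pair: str | PeriodPair | None = None,
) -> GeneralizedTF:
    """Per-order arithmetic mean of the ITF coefficients.

    All ITFs must share the same (num_order, den_order).  Since every
    denominator is monic, averaging keeps the leading coefficient exactly 1
    and preserves the no-feedthrough structure; the operation is idempotent
    and order-independent over the ITF list.
    """
    if not itfs:
        raise ParameterError("need at least one ITF to average")
    tfs = [it.tf if isinstance(it, FitResult) else it for it in itfs]
    orders = {(t.num_order, t.den_order) for t in tfs}
    if len(orders) != 1:
        raise ParameterError(f"mixed ITF orders: {sorted(orders)}")
    num = np.mean([t.num for t in tfs], axis=0)
    den_tail = np.mean([t.den[1:] for t in tfs], axis=0)
    ids = tuple(
        it.subject_id if isinstance(it, FitResult) and it.subject_id else f"itf{i}"
        for i, it in enumerate(itfs)
    )
    label = pair.label if isinstance(pair, PeriodPair) else pair
    if label is None:
        labels = {it.pair for it in itfs if isinstance(it, FitResult) and it.pair}
        label = labels.pop() if len(labels) == 1 else ""
    return GeneralizedTF(
        pair=label,
        tf=DiscreteTransferFunction(num=tuple(num), den=(1.0, *den_tail)),
        n_subjects=len(tfs),
        source_ids=ids,
    )


@dataclass
class EvaluationTable:
    """Per-subject ITF vs GTF goodness of fit for one period pair.

    ``per_subject`` has one row per subject with ``gf_itf`` and ``gf_gtf``
    columns.  Summary statistics use the sample standard deviation (n-1).
    The sign of the difference is unconstrained: the GTF can beat a
    subject's own ITF.
    """

    pair: str
    per_subject: pd.DataFrame

    @property
    def mean_itf(self) -> float:
        return float(self.per_subject["gf_itf"].mean())

    @property
    def mean_gtf(self) -> float:
        return float(self.per_subject["gf_gtf"].mean())

    @property
    def sd_itf(self) -> float:
        return float(self.per_subject["gf_itf"].std(ddof=1))

    @property
    def sd_gtf(self) -> float:
        return float(self.per_subject["gf_gtf"].std(ddof=1))

    @property
    def mean_difference(self) -> float:
        """Mean GF(ITF) minus mean GF(GTF) over subjects."""
        return self.mean_itf - self.mean_gtf


def evaluate_models(
    subjects: Sequence[SubjectSAECGs],
    itfs: Sequence[FitResult],
    gtf: GeneralizedTF,
    pair: PeriodPair,
) -> EvaluationTable:
    """Score each subject's ITF and the pair GTF against the measured output.

    For every subject, the subject's own aligned input SAECG is simulated
    through (a) that subject's ITF and (b) the shared GTF; both simulations
    are scored with the goodness of fit against the measured output SAECG.
    """
    itf_by_subject = {f.subject_id: f for f in itfs}
    first_orders = (gtf.tf.num_order, gtf.tf.den_order)
    rows = []
    for subject in subjects:
        fit = itf_by_subject.get(subject.subject_id)
        if fit is None:
            raise ParameterError(f"no ITF supplied for subject {subject.subject_id}")
        if (fit.tf.num_order, fit.tf.den_order) != first_orders:
            raise ParameterError("GTF orders do not match the ITF orders")
        x, y = pair_saecgs(
            subject.get(pair.input_period), subject.get(pair.output_period)
        )

        def score(tf) -> float:
            # an unstable model can overflow on a finite window; score it NaN
            # (excluded from the column means) rather than aborting the table
            try:
                return goodness_of_fit(y, simulate_tf(tf, x))
            except InstabilityError:
                return float("nan")

        rows.append(
            {
                "subject_id": subject.subject_id,
                "gf_itf": score(fit.tf),
                "gf_gtf": score(gtf.tf),
            }
        )
    frame = pd.DataFrame.from_records(rows).set_index("subject_id")
    return EvaluationTable(pair=pair.label, per_subject=frame)
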