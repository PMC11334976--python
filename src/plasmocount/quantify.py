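"""Per-class particle counts with propagated classification errors.

Given predicted labels and the validation confusion matrix ``c`` of the
classifier that produced them, the error bar on the count of class ``k``
sums the expected false-positive inflow and false-negative outflow:

    delta_k = sum_{i != k} c[i, k] * n_i  +  n_k * sum_{j != k} c[k, j]

where ``n_i`` is the observed (plug-in) count of class ``i``. With a
perfect (identity) confusion matrix every ``delta_k`` is zero; both terms
scale linearly in the counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ConfusionMatrix, DEFAULT_CLASS_SET
from .errors import InvalidInputError

__all__ = ["ClassCountReport", "count_classes", "classification_error"]


def count_classes(predicted_labels, class_set=DEFAULT_CLASS_SET) -> dict[str, int]:
    """Exact multiset counts per class; classes absent from input get 0."""
    counts = {name: 0 for name in class_set}
    for lab in predicted_labels:
        if lab not in counts:
            raise InvalidInputError(f"unknown label {lab!r}; classes are {list(class_set)}")
        counts[lab] += 1
    return counts


@dataclass
class ClassCountReport:
    """Per-class predicted counts ``n_k`` with error bars ``delta_k``."""

    class_set: tuple[str, ...]
    counts: dict[str, int]
    errors: dict[str, float]
    confusion: ConfusionMatrix

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.class_set),
                "count": [self.counts[k] for k in self.class_set],
                "error": [self.errors[k] for k in self.class_set],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary_lines(self) -> list[str]:
        """Human-readable ``n ± Δ`` lines, errors rounded to integers."""
        return [
            f"{self.counts[k]} ± {round(self.errors[k])} {k}"
            for k in self.class_set
        ]


def classification_error(
    counts: dict[str, int],
    confusion: ConfusionMatrix,
) -> ClassCountReport:
    """Propagate confusion-matrix misclassification rates into count errors."""
    class_set = confusion.class_set
    if set(counts) != set(class_set):
        raise InvalidInputError(
            f"count classes {sorted(counts)} do not match confusion classes {sorted(class_set)}"
        )
    confusion.validate_rows()
    c = confusion.c
    n = np.array([counts[k] for k in class_set], dtype=float)
    k_ = len(class_set)
    off = ~np.eye(k_, dtype=bool)
    errors = {}
    for k in range(k_):
        inflow = float((c[:, k] * n)[off[:, k]].sum())  # others labelled k
        outflow = float(n[k] * c[k, off[k, :]].sum())  # k labelled others
        errors[class_set[k]] = inflow + outflow
    return ClassCountReport(
        class_set=class_set,
        counts={k: int(counts[k]) for k in class_set},
        errors=errors,
        confusion=confusion,
    )
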