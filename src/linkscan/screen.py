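"""Per-column co-segregation screen of an alignment against a binary trait.

Each alignment column is scored by how well the residue identity at that
column classifies the sequences into two predefined groups (here: regular vs
elongated linker).  The primary statistic is the exact optimum over all
symbol-to-class assignments, which for a single column is achieved by the
per-symbol majority rule:

    best_accuracy = sum_over_symbols max(count_in_class0, count_in_class1) / n

This provably upper-bounds any classifier that sees only the one column, so
a maximum-margin (linear SVM) cross-check on the one-hot encoding of the
column is kept as a consistency oracle rather than as the statistic itself.
The association strength ``r`` is the Matthews correlation coefficient of the
2x2 confusion table of the induced prediction.

A perfectly co-segregating p-loop column — lysine in every regular-linker
sequence, leucine/isoleucine in every elongated-linker sequence — shows up
as best_accuracy 1.0 and r = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .errors import AlignmentError
from .family import GAP, AlignedFamily
from .linker import LinkerClassing

__all__ = [
    "ColumnScreenResult",
    "ScreenReport",
    "CosegregationScreen",
    "column_best_partition",
    "column_correlation",
    "margin_classifier_check",
    "screen_alignment",
]


@dataclass
class ColumnScreenResult:
    """Screen outcome for one alignment column (1-based index)."""

    column: int
    ref_residue: int | None
    best_accuracy: float
    r: float
    partition: dict[str, str]  # symbol -> predicted class
    counts: dict[str, tuple[int, int]]  # symbol -> (n_class0, n_class1)


@dataclass
class ScreenReport:
    """Ranked per-column results; ties broken by ascending column index."""

    results: list[ColumnScreenResult]
    perfect_columns: list[int]
    classes: tuple[str, str]
    seed: int
    excluded_columns: list[int] = field(default_factory=list)

    @property
    def best(self) -> ColumnScreenResult:
        return self.results[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "column": r.column,
                "ref_residue": r.ref_residue,
                "best_accuracy": r.best_accuracy,
                "r": r.r,
                "partition": ";".join(f"{s}>{c}" for s, c in sorted(r.partition.items())),
            }
            for r in self.results
        ])


def _validate_two_class(labels: np.ndarray, classes=None) -> tuple[str, str]:
    uniq = list(pd.unique(labels))
    if classes is None:
        classes = tuple(sorted(map(str, uniq)))
    if len(uniq) != 2 or set(map(str, uniq)) != set(classes):
        raise ValueError(f"need exactly the two classes {classes}, got {uniq}")
    return classes  # (class0, class1); ties go to class0


def column_best_partition(symbols, labels, classes=None) -> tuple[float, dict[str, str]]:
    """Exact best symbol-to-class partition of one column.

    Per-symbol majority assignment is optimal over all 2^k symbol-to-class
    maps; ties are assigned to ``classes[0]``.  Returns (accuracy, partition).
    """
    symbols = np.asarray(symbols, dtype="U1")
    labels = np.asarray(labels)
    if symbols.shape != labels.shape:
        raise ValueError("symbols and labels must have equal length")
    c0, c1 = _validate_two_class(labels, classes)
    is1 = labels.astype(str) == c1
    partition: dict[str, str] = {}
    correct = 0
    for sym in np.unique(symbols):
        mask = symbols == sym
        n1 = int(np.count_nonzero(is1[mask]))
        n0 = int(np.count_nonzero(mask)) - n1
        partition[str(sym)] = c1 if n1 > n0 else c0
        correct += max(n0, n1)
    return correct / symbols.size, partition


def column_correlation(predicted, truth, classes=None) -> float:
    """Matthews correlation coefficient of predicted vs true binary labels.

    Returns 0.0 when any margin of the 2x2 confusion table is zero.
    """
    predicted = np.asarray(predicted).astype(str)
    truth = np.asarray(truth).astype(str)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    c0, c1 = _validate_two_class(np.concatenate([predicted, truth]), classes)
    tp = np.count_nonzero((predicted == c1) & (truth == c1))
    tn = np.count_nonzero((predicted == c0) & (truth == c0))
    fp = np.count_nonzero((predicted == c1) & (truth == c0))
    fn = np.count_nonzero((predicted == c0) & (truth == c1))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def margin_classifier_check(symbols, labels, classes=None) -> float:
    """Training accuracy of a linear maximum-margin classifier on one column.

    The column is one-hot encoded (one indicator per symbol, gaps included)
    and fitted with a weakly regularised linear-kernel SVM; its training
    accuracy equals the exact best-partition accuracy and is used as a
    cross-check of the closed-form statistic.
    """
    symbols = np.asarray(symbols, dtype="U1")
    labels = np.asarray(labels).astype(str)
    c0, c1 = _validate_two_class(labels, classes)
    uniq = list(np.unique(symbols))
    X = np.zeros((symbols.size, len(uniq)))
    for j, sym in enumerate(uniq):
        X[symbols == sym, j] = 1.0
    y = (labels == c1).astype(int)
    clf = SVC(kernel="linear", C=1e6)
    clf.fit(X, y)
    return float(np.mean(clf.predict(X) == y))


def _predicted_from_partition(symbols: np.ndarray, partition: dict[str, str],
                              default: str) -> np.ndarray:
    return np.array([partition.get(str(s), default) for s in symbols])


def screen_alignment(family: AlignedFamily, classing: LinkerClassing | pd.Series,
                     ref_id: str | None = None, seed: int = 0,
                     max_gap_fraction: float = 0.5) -> ScreenReport:
    """Score every alignment column against the linker classes.

    Sequence order is shuffled with ``seed`` before scoring (the statistic is
    order-invariant; the shuffle guards against order-dependent bugs).
    Columns whose gap fraction exceeds ``max_gap_fraction`` are excluded;
    within a kept column the gap is treated as an ordinary 21st symbol.
    Results are ranked by best_accuracy descending, ties by ascending column.
    """
    labels = classing.classes if isinstance(classing, LinkerClassing) else classing
    labels = labels.loc[family.ids].to_numpy().astype(str)
    classes = _validate_two_class(labels, ("regular", "elongated"))

    rng = np.random.default_rng(seed)
    order = rng.permutation(family.n_sequences)
    mat = family.to_matrix()[order]
    labels = labels[order]

    results: list[ColumnScreenResult] = []
    excluded: list[int] = []
    n = family.n_sequences
    for col in range(1, family.alignment_length + 1):
        symbols = mat[:, col - 1]
        if np.count_nonzero(symbols == GAP) / n > max_gap_fraction:
            excluded.append(col)
            continue
        acc, part = column_best_partition(symbols, labels, classes)
        pred = _predicted_from_partition(symbols, part, classes[0])
        r = column_correlation(pred, labels, classes)
        counts = {}
        is1 = labels == classes[1]
        for sym in np.unique(symbols):
            mask = symbols == sym
            n1 = int(np.count_nonzero(is1[mask]))
            counts[str(sym)] = (int(np.count_nonzero(mask)) - n1, n1)
        ref_res = family.residue_at_column(ref_id, col) if ref_id is not None else None
        results.append(ColumnScreenResult(
            column=col, ref_residue=ref_res, best_accuracy=acc, r=r,
            partition=part, counts=counts,
        ))
    if not results:
        raise AlignmentError("all columns excluded by the gap-fraction filter")
    results.sort(key=lambda r: (-r.best_accuracy, r.column))
    perfect = [r.column for r in results if r.best_accuracy == 1.0]
    return ScreenReport(results=results, perfect_columns=sorted(perfect),
                        classes=classes, seed=seed, excluded_columns=excluded)


class CosegregationScreen(BaseEstimator, ClassifierMixin):
    """Alignment-column screen as a single-column classifier.

    ``fit`` ranks all columns of the aligned input against the binary labels
    and keeps the best column's symbol partition; ``predict`` classifies new
    aligned sequences by their symbol at that column.

    Parameters
    ----------
    max_gap_fraction : float, default 0.5
        Columns with a larger gap fraction are excluded from the screen.
    random_state : int, default 0
        Seed of the order shuffle applied before scoring.

    Attributes
    ----------
    report_ : ScreenReport
        Full ranked screen.
    best_column_ : int
        1-based index of the top-ranked column.
    best_accuracy_, best_r_ : float
        Its exact partition accuracy and Matthews correlation.
    perfect_columns_ : list of int
        All columns with accuracy exactly 1.0.
    classes_ : ndarray
        The two class labels, (class0, class1).
    """

    def __init__(self, max_gap_fraction: float = 0.5, random_state: int = 0):
        self.max_gap_fraction = max_gap_fraction
        self.random_state = random_state

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        if isinstance(X, AlignedFamily):
            return X.to_matrix()
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], str):
            return np.array([list(s) for s in X], dtype="U1")
        return np.asarray(X, dtype="U1")

    def fit(self, X, y) -> "CosegregationScreen":
        mat = self._as_matrix(X)
        ids = [f"s{i}" for i in range(mat.shape[0])]
        y = pd.Series(np.asarray(y).astype(str), index=ids)
        classes = tuple(sorted(y.unique()))
        fam = AlignedFamily(ids=ids, seqs=["".join(row) for row in mat])
        report = screen_alignment(
            fam, y, seed=self.random_state, max_gap_fraction=self.max_gap_fraction,
        ) if classes == ("elongated", "regular") else self._screen_generic(fam, y, classes)
        self.report_ = report
        self.best_column_ = report.best.column
        self.best_accuracy_ = report.best.best_accuracy
        self.best_r_ = report.best.r
        self.perfect_columns_ = report.perfect_columns
        self.classes_ = np.array(report.classes)
        self._partition = report.best.partition
        return self

    def _screen_generic(self, fam: AlignedFamily, y: pd.Series,
                        classes: tuple[str, str]) -> ScreenReport:
        # same screen for arbitrary binary label values
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(fam.n_sequences)
        mat = fam.to_matrix()[order]
        labels = y.to_numpy()[order]
        results, excluded = [], []
        for col in range(1, fam.alignment_length + 1):
            symbols = mat[:, col - 1]
            if np.count_nonzero(symbols == GAP) / len(labels) > self.max_gap_fraction:
                excluded.append(col)
                continue
            acc, part = column_best_partition(symbols, labels, classes)
            pred = _predicted_from_partition(symbols, part, classes[0])
            results.append(ColumnScreenResult(
                column=col, ref_residue=None, best_accuracy=acc,
                r=column_correlation(pred, labels, classes), partition=part, counts={},
            ))
        if not results:
            raise AlignmentError("all columns excluded by the gap-fraction filter")
        results.sort(key=lambda r: (-r.best_accuracy, r.column))
        perfect = [r.column for r in results if r.best_accuracy == 1.0]
        return ScreenReport(results=results, perfect_columns=sorted(perfect),
                            classes=classes, seed=self.random_state,
                            excluded_columns=excluded)

    def predict(self, X) -> np.ndarray:
        mat = self._as_matrix(X)
        symbols = mat[:, self.best_column_ - 1]
        return _predicted_from_partition(symbols, self._partition, str(self.classes_[0]))

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y).astype(str)))
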