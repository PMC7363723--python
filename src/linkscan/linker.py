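"""Interdomain linker delimitation, length statistics, and composition.

A two-domain family is partitioned per sequence into NTD / linker / CTD by
mapping reference boundary residues (e.g. the ScKti12 boundaries: NTD ends at
residue 183, CTD starts at 214) onto alignment columns and counting ungapped
residues of every other sequence in the three column windows.  A motif-based
fallback locates the Walker A pattern [AG]-x(4)-G-K-[ST] (signature position
allowed to vary to K/L/I/V/A) when no reference boundary is available.

Lengths are binned into the field's customary "center +/- halfwidth" baskets,
classified regular vs elongated by a length threshold (default 45 residues,
the midpoint of the empty band between the ~30 and 55-60 populations), and
compared across groups with Welch's unequal-variance two-tailed t test.
Composition profiling reports per-class residue frequencies over linker
residues only and their log2 elongated/regular ratios with a pseudocount.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError
from .family import AMINO_ACIDS, GAP, AlignedFamily

__all__ = [
    "DomainPartition",
    "LinkerClassing",
    "TestResult",
    "partition_domains",
    "find_walker_a",
    "bin_linker_lengths",
    "classify_linkers",
    "compare_groups",
    "linker_composition",
    "ELONGATED_THRESHOLD",
]

ELONGATED_THRESHOLD = 45
WALKER_A_PATTERN = re.compile(r"[AG].{4}G[KLIVA][ST]")


@dataclass
class DomainPartition:
    """Per-sequence NTD/linker/CTD spans, 1-based inclusive on ungapped residues.

    A span of ``None`` means the sequence has no residues in that window.
    """

    spans: pd.DataFrame  # index id; ntd_start..ctd_end, linker_length
    ntd_end_col: int  # 1-based alignment columns of the boundaries
    ctd_start_col: int

    @property
    def linker_lengths(self) -> pd.Series:
        return self.spans["linker_length"]


@dataclass
class LinkerClassing:
    """Regular/elongated assignment by length threshold (elongated iff >=)."""

    classes: pd.Series  # index id, values "regular"/"elongated"
    threshold: int

    @property
    def counts(self) -> dict[str, int]:
        c = self.classes.value_counts()
        return {"regular": int(c.get("regular", 0)), "elongated": int(c.get("elongated", 0))}


@dataclass
class TestResult:
    """Two-sample test outcome."""

    statistic: float
    p_value: float
    df: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def partition_domains(family: AlignedFamily, ref_id: str,
                      ref_ntd_end: int, ref_ctd_start: int) -> DomainPartition:
    """Delimit NTD/linker/CTD for every sequence via reference boundaries.

    ``ref_ntd_end`` and ``ref_ctd_start`` are 1-based residue positions on the
    ungapped reference sequence; they are mapped to alignment columns, and
    each sequence's linker is its ungapped residues in the columns strictly
    between the two boundary columns.
    """
    if ref_ctd_start <= ref_ntd_end:
        raise AlignmentError("ref_ctd_start must exceed ref_ntd_end")
    ntd_end_col = family.column_of_residue(ref_id, ref_ntd_end)
    ctd_start_col = family.column_of_residue(ref_id, ref_ctd_start)
    # column_of_residue only lands on residues, never gaps, but the two
    # boundary columns must keep their order in the alignment
    if ctd_start_col <= ntd_end_col:
        raise AlignmentError("boundary columns are not ordered in the alignment")

    rows = []
    for seq_id in family.ids:
        seq = family.sequence(seq_id)
        n_ntd = sum(1 for ch in seq[:ntd_end_col] if ch != GAP)
        n_link = sum(1 for ch in seq[ntd_end_col:ctd_start_col - 1] if ch != GAP)
        n_total = sum(1 for ch in seq if ch != GAP)
        n_ctd = n_total - n_ntd - n_link
        if n_link == 0:
            warnings.warn(f"{seq_id}: no residues in the linker window", stacklevel=2)
        rows.append({
            "id": seq_id,
            "ntd_start": 1 if n_ntd else None,
            "ntd_end": n_ntd if n_ntd else None,
            "linker_start": n_ntd + 1 if n_link else None,
            "linker_end": n_ntd + n_link if n_link else None,
            "ctd_start": n_ntd + n_link + 1 if n_ctd else None,
            "ctd_end": n_total if n_ctd else None,
            "linker_length": n_link,
        })
    spans = pd.DataFrame(rows).set_index("id")
    return DomainPartition(spans=spans, ntd_end_col=ntd_end_col, ctd_start_col=ctd_start_col)


def find_walker_a(sequence: str) -> tuple[int, int] | None:
    """Locate the Walker A motif on an ungapped sequence.

    Returns the 1-based (start, signature_position) of the first match of
    [AG]-x(4)-G-[KLIVA]-[ST], or None.  The signature position (canonically
    the p-loop lysine) is offset 6 within the 8-residue match.
    """
    m = WALKER_A_PATTERN.search(sequence.replace(GAP, ""))
    if m is None:
        return None
    return m.start() + 1, m.start() + 7


def bin_linker_lengths(lengths, centers, halfwidth: int) -> pd.DataFrame:
    """Count lengths into "center +/- halfwidth" baskets.

    Baskets are ``[center - halfwidth, center + halfwidth]`` and must not
    overlap; lengths outside every basket are tallied under center NaN.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    centers = list(centers)
    if any(b - a < 2 * halfwidth + 1 for a, b in zip(centers, centers[1:])):
        raise ValueError("baskets overlap: centers must be spaced >= 2*halfwidth+1")
    if sorted(centers) != centers:
        raise ValueError("centers must be strictly increasing")
    lengths = np.asarray(list(lengths))
    rows = []
    assigned = np.zeros(lengths.size, dtype=bool)
    for c in centers:
        in_basket = (lengths >= c - halfwidth) & (lengths <= c + halfwidth)
        assigned |= in_basket
        rows.append({"center": c, "halfwidth": halfwidth, "count": int(in_basket.sum())})
    rows.append({"center": np.nan, "halfwidth": halfwidth,
                 "count": int((~assigned).sum())})
    return pd.DataFrame(rows)


def classify_linkers(partition: DomainPartition,
                     threshold: int = ELONGATED_THRESHOLD) -> LinkerClassing:
    """Threshold linker lengths into regular (<) vs elongated (>=)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    classes = partition.linker_lengths.map(
        lambda n: "elongated" if n >= threshold else "regular"
    )
    return LinkerClassing(classes=classes.rename("class"), threshold=threshold)


def compare_groups(lengths_a, lengths_b) -> TestResult:
    """Welch unequal-variance two-tailed t test between two length samples."""
    a = np.asarray(list(lengths_a), dtype=float)
    b = np.asarray(list(lengths_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return TestResult(0.0, 1.0, float(a.size + b.size - 2),
                              float(a.mean()), float(b.mean()), a.size, b.size)
        raise ValueError("both groups degenerate (zero variance) with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def linker_composition(family: AlignedFamily, partition: DomainPartition,
                       classing: LinkerClassing,
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-class linker residue frequencies and elongated/regular log2 ratios.

    Frequencies are over linker residues only (gaps excluded), normalised
    within class; ratios use ``pseudocount`` added to every residue count so
    that unobserved residues stay finite.
    """
    counts = {"regular": np.zeros(20), "elongated": np.zeros(20)}
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    lo, hi = partition.ntd_end_col, partition.ctd_start_col  # exclusive window
    for seq_id in family.ids:
        cls = classing.classes[seq_id]
        window = family.sequence(seq_id)[lo:hi - 1]
        for ch in window:
            if ch in aa_index:
                counts[cls][aa_index[ch]] += 1
    for cls, vec in counts.items():
        if vec.sum() == 0:
            raise ValueError(f"class {cls!r} has no linker residues")
    freq = {cls: vec / vec.sum() for cls, vec in counts.items()}
    smoothed = {
        cls: (vec + pseudocount) / (vec.sum() + 20 * pseudocount)
        for cls, vec in counts.items()
    }
    return pd.DataFrame({
        "residue": list(AMINO_ACIDS),
        "count_regular": counts["regular"].astype(int),
        "count_elongated": counts["elongated"].astype(int),
        "freq_regular": freq["regular"],
        "freq_elongated": freq["elongated"],
        "log2_ratio": np.log2(smoothed["elongated"] / smoothed["regular"]),
    }).set_index("residue")
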