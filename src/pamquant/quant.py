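"""Indel calling and per-sample indel-frequency quantification.

Pipeline per read: orient + align, anchor-identity filter, edit calls
within a +/-60 bp window around the cut site, read classification.  The
per-sample frequency is (reads with an in-window indel) / (reads passing
the anchor filter); a total-read count below the threshold (default 1000)
flags the sample as excluded.  Mismatches are called and reported but
never count toward the indel frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .align import (
    DELETION,
    INSERTION,
    MISMATCH,
    AlignParams,
    AlignmentResult,
    AmpliconRef,
    anchor_identity,
    orient_and_align,
)

EDITED_INDEL = "edited_indel"
UNEDITED = "unedited"


@dataclass(frozen=True)
class EditCall:
    """One alignment-derived edit.

    For deletions and mismatches ``start``/``end`` is the 0-based half-open
    reference interval; for insertions ``start == end`` is the inter-base
    coordinate where the inserted bases sit.
    """

    type: str
    start: int
    end: int
    length: int
    in_window: bool

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("edit length must be >= 1")


@dataclass
class SampleIndelResult:
    total_reads: int
    filtered_reads: int
    indel_reads: int
    indel_frequency: Optional[float]
    excluded: bool
    min_reads_threshold: int = 1000
    # secondary convention: denominator = all reads, reported alongside
    indel_frequency_total: Optional[float] = None
    missing_reason: Optional[str] = None
    per_read: Optional[pd.DataFrame] = None
    per_edit: Optional[pd.DataFrame] = None


def infer_cut_site(ref: AmpliconRef, cut_offset: int = 18) -> int:
    """Inter-base cut coordinate after ``cut_offset`` protospacer bases
    counted from the PAM-proximal end, on the annotated strand."""
    length = ref.protospacer_end - ref.protospacer_start
    if not 0 < cut_offset <= length:
        raise ValueError(
            f"cut_offset {cut_offset} outside protospacer length {length}"
        )
    if ref.site_strand == "+":
        return ref.protospacer_start + cut_offset
    return ref.protospacer_end - cut_offset


def call_edits(aln: AlignmentResult, ref: AmpliconRef,
               cut_site: Optional[int] = None,
               window_halfwidth: int = 60,
               cut_offset: int = 18) -> list[EditCall]:
    """Turn every insertion/deletion/mismatch op into an EditCall, flagging
    whether it intersects the closed window [cut - w, cut + w]."""
    if cut_site is None:
        cut_site = infer_cut_site(ref, cut_offset)
    lo = cut_site - window_halfwidth
    hi = cut_site + window_halfwidth
    calls = []
    for op, length, pos in aln.ops:
        if op == INSERTION:
            in_window = lo <= pos <= hi
            calls.append(EditCall(INSERTION, pos, pos, length, in_window))
        elif op == DELETION:
            in_window = pos <= hi and pos + length - 1 >= lo
            calls.append(EditCall(DELETION, pos, pos + length, length, in_window))
        elif op == MISMATCH:
            in_window = pos <= hi and pos + length - 1 >= lo
            calls.append(EditCall(MISMATCH, pos, pos + length, length, in_window))
    return calls


def classify_read(calls: Iterable[EditCall]) -> str:
    """A read is edited iff it carries >= 1 in-window insertion or deletion;
    mismatches alone never make a read edited."""
    for call in calls:
        if call.in_window and call.type in (INSERTION, DELETION):
            return EDITED_INDEL
    return UNEDITED


def quantify_sample(reads: Iterable[tuple[str, str]],
                    ref: AmpliconRef,
                    params: Optional[AlignParams] = None,
                    cut_offset: int = 18,
                    window_halfwidth: int = 60,
                    min_reads: int = 1000,
                    anchor_len: int = 20,
                    anchor_threshold: float = 0.75,
                    collect_details: bool = True) -> SampleIndelResult:
    """Quantify one sample from (read_id, sequence) pairs.

    Returns counts at every stage plus the indel frequency over
    anchor-passing reads (and, for reference, over all reads).
    """
    if params is None:
        params = AlignParams()
    cut = infer_cut_site(ref, cut_offset)

    total = 0
    filtered = 0
    edited = 0
    read_rows = []
    edit_rows = []
    for read_id, seq in reads:
        total += 1
        aln = orient_and_align(seq, ref, params, read_id=read_id)
        identity, passed = anchor_identity(aln, ref, anchor_len, anchor_threshold)
        label = None
        n_inwindow_indels = 0
        if passed:
            filtered += 1
            calls = call_edits(aln, ref, cut_site=cut,
                               window_halfwidth=window_halfwidth)
            label = classify_read(calls)
            if label == EDITED_INDEL:
                edited += 1
            n_inwindow_indels = sum(
                1 for c in calls
                if c.in_window and c.type in (INSERTION, DELETION))
            if collect_details:
                for c in calls:
                    edit_rows.append((read_id, c.type, c.start, c.end,
                                      c.length, c.in_window))
        if collect_details:
            read_rows.append((read_id, aln.orientation, aln.score,
                              round(identity, 6), passed,
                              n_inwindow_indels,
                              label if label is not None else "anchor_fail"))

    if filtered > 0:
        freq: Optional[float] = edited / filtered
        reason = None
    else:
        freq = None
        reason = "no reads passed the anchor filter"
    freq_total = edited / total if total > 0 else None

    per_read = per_edit = None
    if collect_details:
        per_read = pd.DataFrame(
            read_rows,
            columns=["read_id", "orientation", "score", "anchor_identity",
                     "anchor_pass", "n_inwindow_indels", "classification"])
        per_edit = pd.DataFrame(
            edit_rows,
            columns=["read_id", "type", "start", "end", "length", "in_window"])

    return SampleIndelResult(
        total_reads=total,
        filtered_reads=filtered,
        indel_reads=edited,
        indel_frequency=freq,
        excluded=total < min_reads,
        min_reads_threshold=min_reads,
        indel_frequency_total=freq_total,
        missing_reason=reason,
        per_read=per_read,
        per_edit=per_edit,
    )
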