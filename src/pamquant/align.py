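"""Read-to-amplicon alignment.

Semiglobal alignment with affine gaps (free end gaps on the reference, the
read aligned in full), orientation selection against both strands, and the
anchor-identity filter over the first bases of the reference amplicon.

Coordinates are 0-based half-open throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._dp import NEG, fill_matrices

_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MATCH = "match"
MISMATCH = "mismatch"
INSERTION = "insertion"
DELETION = "deletion"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N as 0..4; anything else is rejected."""
    try:
        return np.array([_CODES[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme: positive match reward, non-negative penalties.

    A gap of length L costs ``gap_open + gap_extend * L``.
    """

    match_score: int = 1
    mismatch_penalty: int = 1
    gap_open_penalty: int = 2
    gap_extend_penalty: int = 1

    def __post_init__(self):
        if self.match_score <= 0:
            raise ValueError("match_score must be > 0")
        for name in ("mismatch_penalty", "gap_open_penalty", "gap_extend_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AmpliconRef:
    """Reference amplicon with protospacer/PAM annotation.

    ``protospacer_start``/``protospacer_end`` and ``pam_start``/``pam_end``
    are 0-based half-open intervals on the forward strand.  ``site_strand``
    is the strand carrying the protospacer; on ``+`` the PAM immediately
    precedes the protospacer, on ``-`` it immediately follows it (both on
    the forward axis).
    """

    name: str
    sequence: str
    protospacer_start: int
    protospacer_end: int
    pam_start: int
    pam_end: int
    site_strand: str = "+"

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq or set(seq) - set("ACGTN"):
            raise ValueError("amplicon sequence must be non-empty over A/C/G/T/N")
        if self.site_strand not in "+-":
            raise ValueError("site_strand must be '+' or '-'")
        if not (0 <= self.protospacer_start < self.protospacer_end <= len(seq)):
            raise ValueError("protospacer interval outside amplicon bounds")
        if not (0 <= self.pam_start < self.pam_end <= len(seq)):
            raise ValueError("PAM interval outside amplicon bounds")
        if not 2 <= self.pam_end - self.pam_start <= 4:
            raise ValueError("PAM must be 2-4 nt")
        if self.site_strand == "+" and self.pam_end != self.protospacer_start:
            raise ValueError("on '+' the PAM must abut the protospacer start")
        if self.site_strand == "-" and self.pam_start != self.protospacer_end:
            raise ValueError("on '-' the PAM must abut the protospacer end")

    @property
    def protospacer(self) -> str:
        return self.sequence[self.protospacer_start : self.protospacer_end]

    @property
    def pam(self) -> str:
        """PAM sequence read 5'->3' on the annotated strand."""
        fwd = self.sequence[self.pam_start : self.pam_end]
        return fwd if self.site_strand == "+" else reverse_complement(fwd)


@dataclass
class AlignmentResult:
    """Operation-level alignment of one read against the forward reference.

    ``ops`` is an ordered list of ``(op, length, ref_pos)`` where ``op`` is
    one of match/mismatch/insertion/deletion; ``ref_pos`` is the 0-based
    start of the reference interval consumed (for insertions, the
    inter-base coordinate at which the inserted bases sit).  Adjacent ops
    differ in kind.
    """

    read_id: str
    orientation: str
    score: int
    ops: list = field(default_factory=list)
    ref_start: int = 0
    ref_end: int = 0
    read_length: int = 0

    def validate(self) -> None:
        ref_consumed = sum(l for op, l, _ in self.ops if op in (MATCH, MISMATCH, DELETION))
        read_consumed = sum(l for op, l, _ in self.ops if op in (MATCH, MISMATCH, INSERTION))
        if ref_consumed != self.ref_end - self.ref_start:
            raise AssertionError("reference-consuming op lengths do not sum to span width")
        if read_consumed != self.read_length:
            raise AssertionError("read-consuming op lengths do not sum to read length")
        for (a, la, _), (b, _, _) in zip(self.ops, self.ops[1:]):
            if a == b:
                raise AssertionError("adjacent ops of identical kind")
        if any(l < 1 for _, l, _ in self.ops):
            raise AssertionError("op length < 1")


def semiglobal_align(read: str, ref: str, params: Optional[AlignParams] = None,
                     read_id: str = "", orientation: str = "+") -> AlignmentResult:
    """Optimal affine-gap semiglobal alignment of ``read`` within ``ref``.

    End gaps on the reference are free; the read is aligned end to end.
    Traceback tie-breaking is fixed (diagonal > deletion > insertion, and
    the leftmost optimal end column), so output is deterministic.
    """
    if params is None:
        params = AlignParams()
    if not read or not ref:
        raise ValueError("empty sequence")
    rcodes = encode(read)
    fcodes = encode(ref)
    M, X, Y, pM, pX, pY = fill_matrices(
        rcodes, fcodes,
        params.match_score, params.mismatch_penalty,
        params.gap_open_penalty, params.gap_extend_penalty,
    )
    m, n = len(read), len(ref)
    best = NEG
    end_j = 0
    end_state = 0
    for j in range(n + 1):  # strict > keeps the leftmost end column on ties
        if M[m, j] > best:
            best, end_j, end_state = int(M[m, j]), j, 0
        if X[m, j] > best:
            best, end_j, end_state = int(X[m, j]), j, 1

    i, j, state = m, end_j, end_state
    steps: list[tuple[str, int]] = []
    while i > 0:
        if state == 0:
            kind = MATCH if (rcodes[i - 1] == fcodes[j - 1] and rcodes[i - 1] < 4) else MISMATCH
            steps.append((kind, j - 1))
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            steps.append((INSERTION, j))
            state = pX[i, j]
            i -= 1
        else:
            steps.append((DELETION, j - 1))
            state = pY[i, j]
            j -= 1
    ref_span_start = j

    ops: list[tuple[str, int, int]] = []
    for kind, pos in reversed(steps):
        if ops and ops[-1][0] == kind:
            prev_kind, prev_len, prev_pos = ops[-1]
            ops[-1] = (prev_kind, prev_len + 1, prev_pos)
        else:
            ops.append((kind, 1, pos))

    result = AlignmentResult(
        read_id=read_id,
        orientation=orientation,
        score=best,
        ops=ops,
        ref_start=ref_span_start,
        ref_end=end_j,
        read_length=m,
    )
    return result


def orient_and_align(read: str, ref: AmpliconRef,
                     params: Optional[AlignParams] = None,
                     read_id: str = "") -> AlignmentResult:
    """Align the read and its reverse complement; keep the better score.

    On an exact score tie the forward orientation wins.  The returned
    alignment is always expressed on the forward reference axis.
    """
    fwd = semiglobal_align(read, ref.sequence, params, read_id=read_id, orientation="+")
    rev = semiglobal_align(reverse_complement(read), ref.sequence, params,
                           read_id=read_id, orientation="-")
    return fwd if fwd.score >= rev.score else rev


def anchor_identity(aln: AlignmentResult, ref: AmpliconRef,
                    anchor_len: int = 20,
                    threshold: float = 0.75) -> tuple[float, bool]:
    """Fraction of the first ``anchor_len`` reference positions aligned as
    a match, and whether it reaches ``threshold`` (inclusive).

    Anchor positions that are unaligned (reference end-gap), deleted, or
    mismatched count as non-match.
    """
    if anchor_len > len(ref.sequence):
        raise ValueError("anchor_len exceeds reference length")
    matched = 0
    for op, length, pos in aln.ops:
        if op == MATCH:
            lo = max(pos, 0)
            hi = min(pos + length, anchor_len)
            if hi > lo:
                matched += hi - lo
    identity = matched / anchor_len
    return identity, identity >= threshold
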