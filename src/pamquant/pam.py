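"""PAM-preference profiling and target-site scanning.

Activity panels in which the base at one PAM position is varied
systematically are aggregated into per-position base-ratio matrices
(per-target normalization before averaging, so strong targets do not
dominate), distilled into IUPAC consensus patterns, and used to scan
sequences for candidate target sites.

PAM positions are labeled -4..-1 with -1 adjacent to the protospacer;
in a 4-nt PAM string the leftmost character is position -4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .align import reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
SET_TO_IUPAC = {frozenset(bases): code for code, bases in IUPAC.items()}
BASES = "ACGT"
PAM_POSITIONS = (-4, -3, -2, -1)


@dataclass(frozen=True)
class PAMPattern:
    """IUPAC PAM pattern; the rightmost symbol is position -1."""

    iupac: str

    def __post_init__(self):
        pat = self.iupac.upper()
        object.__setattr__(self, "iupac", pat)
        if not 2 <= len(pat) <= 6:
            raise ValueError("PAM pattern length must be 2-6")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.iupac)


def match_pam(seq: str, pattern: PAMPattern | str) -> bool:
    """True iff each base of ``seq`` is in the IUPAC set of the
    corresponding pattern symbol."""
    if isinstance(pattern, str):
        pattern = PAMPattern(pattern)
    seq = seq.upper()
    if len(seq) != len(pattern):
        raise ValueError(
            f"sequence length {len(seq)} != pattern length {len(pattern)}")
    if set(seq) - set(BASES):
        return False
    return all(base in IUPAC[sym] for base, sym in zip(seq, pattern.iupac))


@dataclass
class PreferenceMatrix:
    """Position x base ratio matrix for one nuclease.

    ``ratios[position][base]`` sums to 1 over the four bases at each
    position (sum normalization); ``n_targets`` counts the complete target
    quartets contributing at each position.
    """

    nuclease: str
    ratios: dict = field(default_factory=dict)
    n_targets: dict = field(default_factory=dict)
    n_dropped: dict = field(default_factory=dict)
    normalization: str = "sum"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in sorted(self.ratios):
            for base in BASES:
                rows.append((self.nuclease, pos, base,
                             self.ratios[pos][base], self.n_targets[pos]))
        return pd.DataFrame(
            rows, columns=["nuclease", "position", "base", "ratio", "n_targets"])


def _position_index(position: int, pam_len: int = 4) -> int:
    if position not in PAM_POSITIONS:
        raise ValueError(f"position must be one of {PAM_POSITIONS}")
    return pam_len + position


def position_preference(records: pd.DataFrame, position: int,
                        normalization: str = "sum") -> tuple[dict, int, int]:
    """Per-base activity ratios at one varied PAM position.

    Within each target the four base-variant activities are normalized
    (to their sum by default, to their max with ``normalization='max'``),
    then averaged over targets with equal weight.  Targets lacking a
    complete four-base quartet, or with all-zero activity, are dropped and
    counted.  Returns (ratios, n_targets, n_dropped).
    """
    if normalization not in ("sum", "max"):
        raise ValueError("normalization must be 'sum' or 'max'")
    idx = _position_index(position)
    sub = records[records["varied_position"] == position]
    per_target_ratios = []
    n_dropped = 0
    for _, grp in sub.groupby("target_id", sort=True):
        by_base = grp.assign(base=grp["pam"].str[idx]).groupby("base")["activity"].mean()
        if set(by_base.index) != set(BASES):
            n_dropped += 1
            continue
        denom = by_base.sum() if normalization == "sum" else by_base.max()
        if denom <= 0:
            n_dropped += 1
            continue
        per_target_ratios.append(by_base / denom)
    if not per_target_ratios:
        raise ValueError(
            f"no complete target quartet at position {position}")
    mean_ratios = pd.concat(per_target_ratios, axis=1).mean(axis=1)
    return ({base: float(mean_ratios[base]) for base in BASES},
            len(per_target_ratios), n_dropped)


def build_preference_matrix(records: pd.DataFrame, nuclease: str | None = None,
                            normalization: str = "sum") -> PreferenceMatrix:
    """Aggregate an activity table into a PreferenceMatrix.

    If ``nuclease`` is given the table is filtered to it; otherwise the
    table must contain a single nuclease label.
    """
    if nuclease is not None:
        records = records[records["nuclease"] == nuclease]
    labels = sorted(set(records["nuclease"]))
    if len(labels) != 1:
        raise ValueError(f"expected one nuclease, got {labels}")
    matrix = PreferenceMatrix(nuclease=labels[0], normalization=normalization)
    for pos in sorted(set(records["varied_position"])):
        ratios, n_targets, n_dropped = position_preference(
            records, int(pos), normalization)
        matrix.ratios[int(pos)] = ratios
        matrix.n_targets[int(pos)] = n_targets
        matrix.n_dropped[int(pos)] = n_dropped
    return matrix


def consensus_from_matrix(matrix: PreferenceMatrix,
                          include_threshold: float = 0.15) -> PAMPattern:
    """IUPAC consensus: at each position the bases with ratio >=
    ``include_threshold`` form the allowed set, mapped to its minimal
    IUPAC symbol."""
    symbols = []
    for pos in sorted(matrix.ratios):
        allowed = frozenset(
            b for b in BASES if matrix.ratios[pos][b] >= include_threshold)
        if not allowed:
            raise ValueError(
                f"no base reaches threshold {include_threshold} at position {pos}")
        symbols.append(SET_TO_IUPAC[allowed])
    return PAMPattern("".join(symbols))


@dataclass(frozen=True)
class TargetSite:
    """Candidate site: PAM and protospacer intervals are 0-based half-open
    on the forward strand; for '-' sites the protospacer lies 5' of the
    PAM on the forward axis."""

    strand: str
    pam_start: int
    pam_end: int
    protospacer_start: int
    protospacer_end: int


def enumerate_target_sites(sequence: str, pattern: PAMPattern | str,
                           spacer_len: int = 23) -> list[TargetSite]:
    """Scan both strands for PAM matches followed (3' on that strand) by a
    full-length protospacer.  Windows containing N never match.  Sites are
    returned in deterministic ascending order."""
    if isinstance(pattern, str):
        pattern = PAMPattern(pattern)
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence alphabet must be A/C/G/T/N")
    plen = len(pattern)
    sites = []
    for i in range(len(seq) - plen + 1):
        window = seq[i : i + plen]
        if "N" in window:
            continue
        # forward: protospacer 3' of PAM on the + strand
        if i + plen + spacer_len <= len(seq) and match_pam(window, pattern):
            sites.append(TargetSite("+", i, i + plen,
                                    i + plen, i + plen + spacer_len))
        # reverse: PAM read on the - strand, protospacer 5' on the + axis
        if i - spacer_len >= 0 and match_pam(reverse_complement(window), pattern):
            sites.append(TargetSite("-", i, i + plen, i - spacer_len, i))
    sites.sort(key=lambda s: (s.pam_start, s.strand))
    return sites


def sites_to_bed(sites: Iterable[TargetSite], sequence: str,
                 chrom: str) -> list[str]:
    """BED6 rows over the protospacer interval; the name column carries
    the PAM sequence as read on the site strand."""
    rows = []
    for s in sites:
        pam_seq = sequence[s.pam_start : s.pam_end]
        if s.strand == "-":
            pam_seq = reverse_complement(pam_seq)
        rows.append("\t".join(map(str, (
            chrom, s.protospacer_start, s.protospacer_end,
            f"PAM:{pam_seq}", 0, s.strand))))
    return rows
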