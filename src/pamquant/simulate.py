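"""Seeded synthetic inputs with known ground truth.

Three simulators feed the downstream stages without any external data:
edited amplicon reads (FASTQ + truth table), reporter-assay plates, and
PAM-panel activity tables.  All randomness flows from an explicit seed via
``numpy.random.Generator``; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .align import AmpliconRef, reverse_complement
from .pam import BASES, PAM_POSITIONS
from .quant import infer_cut_site

_BASE_ARR = np.array(list("ACGT"))


def default_size_distribution(max_len: int = 20, p: float = 0.5) -> dict[int, float]:
    """Truncated geometric indel-size distribution over 1..max_len.

    A placeholder shape, not a claim about any real spectrum.
    """
    raw = np.array([(1 - p) ** (k - 1) * p for k in range(1, max_len + 1)])
    raw /= raw.sum()
    return {k: float(v) for k, v in zip(range(1, max_len + 1), raw)}


@dataclass(frozen=True)
class EditSpectrum:
    """What fraction of reads carry an edit and what the edits look like.

    ``center_offset`` shifts edit placement away from the cut site (used
    to probe the search window); default 0 centers edits on the cut.
    """

    indel_rate: float = 0.2
    deletion_weight: float = 0.6
    size_distribution: dict = field(default_factory=default_size_distribution)
    position_jitter: int = 5
    center_offset: int = 0

    def __post_init__(self):
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        if not 0.0 <= self.deletion_weight <= 1.0:
            raise ValueError("deletion_weight must be in [0, 1]")
        if self.position_jitter < 0:
            raise ValueError("position_jitter must be >= 0")
        if any(k < 1 for k in self.size_distribution):
            raise ValueError("indel sizes must be >= 1")
        total = sum(self.size_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"size_distribution sums to {total}, not 1")


@dataclass(frozen=True)
class ErrorModel:
    substitution_rate: float = 0.001
    quality_char: str = "I"

    def __post_init__(self):
        if not 0.0 <= self.substitution_rate <= 0.1:
            raise ValueError("substitution_rate must be in [0, 0.1]")
        if len(self.quality_char) != 1:
            raise ValueError("quality_char must be a single character")


TRUTH_COLUMNS = ["read_id", "edited", "edit_type", "edit_length",
                 "edit_position", "orientation"]


def make_amplicon(length: int = 240, protospacer_start: int = 100,
                  spacer_len: int = 23, pam: str = "TTTA",
                  strand: str = "+", seed: int = 0,
                  name: str = "sim_amplicon") -> AmpliconRef:
    """Random amplicon with a PAM+protospacer site planted at fixed
    coordinates (PAM 5' of the protospacer on the annotated strand)."""
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(_BASE_ARR, size=length))
    proto_end = protospacer_start + spacer_len
    if strand == "+":
        pam_start, pam_end = protospacer_start - len(pam), protospacer_start
        planted = pam
    elif strand == "-":
        pam_start, pam_end = proto_end, proto_end + len(pam)
        planted = reverse_complement(pam)
    else:
        raise ValueError("strand must be '+' or '-'")
    if pam_start < 0 or pam_end > length:
        raise ValueError("PAM does not fit in the amplicon")
    seq[pam_start:pam_end] = list(planted)
    # avoid an accidental second PAM-proximal T-run right before the planted one
    return AmpliconRef(name=name, sequence="".join(seq),
                       protospacer_start=protospacer_start,
                       protospacer_end=proto_end,
                       pam_start=pam_start, pam_end=pam_end,
                       site_strand=strand)


def simulate_amplicon_reads(ref: AmpliconRef, n_reads: int,
                            spectrum: EditSpectrum, errors: ErrorModel,
                            orientation_mix: float = 0.5,
                            seed: int = 0,
                            cut_offset: int = 18):
    """Simulate full-length amplicon reads with at most one indel each.

    Returns ``(records, truth)`` where records are ``(read_id, sequence,
    quality)`` triples and truth is a DataFrame (TRUTH_COLUMNS).  Edited
    reads carry one indel placed at cut_site + center_offset + U[-j, +j];
    insertions use RNG bases at an inter-base coordinate, deletions remove
    the reference interval starting there.  Reverse-orientation reads are
    reverse-complemented after substitution noise is applied.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0.0 <= orientation_mix <= 1.0:
        raise ValueError("orientation_mix must be in [0, 1]")
    cut = infer_cut_site(ref, cut_offset)
    max_len = max(spectrum.size_distribution)
    center = cut + spectrum.center_offset
    lo = center - spectrum.position_jitter
    hi = center + spectrum.position_jitter
    if lo < 0 or hi + max_len > len(ref.sequence) or hi > len(ref.sequence):
        raise ValueError(
            "edit placement window extends outside the amplicon; reduce "
            "position_jitter/center_offset or indel sizes")

    rng = np.random.default_rng(seed)
    sizes = np.array(sorted(spectrum.size_distribution), dtype=int)
    size_p = np.array([spectrum.size_distribution[int(k)] for k in sizes])

    records = []
    truth_rows = []
    refseq = ref.sequence
    for i in range(n_reads):
        read_id = f"read{i:06d}"
        edited = rng.random() < spectrum.indel_rate
        edit_type = "none"
        edit_len = 0
        edit_pos = -1
        if edited:
            edit_type = ("deletion" if rng.random() < spectrum.deletion_weight
                         else "insertion")
            edit_len = int(rng.choice(sizes, p=size_p))
            edit_pos = int(rng.integers(lo, hi + 1))
            if edit_type == "deletion":
                seq = refseq[:edit_pos] + refseq[edit_pos + edit_len:]
            else:
                ins = "".join(rng.choice(_BASE_ARR, size=edit_len))
                seq = refseq[:edit_pos] + ins + refseq[edit_pos:]
        else:
            seq = refseq

        if errors.substitution_rate > 0:
            arr = np.array(list(seq))
            hits = np.flatnonzero(rng.random(arr.size) < errors.substitution_rate)
            for h in hits:
                choices = [b for b in BASES if b != arr[h]]
                arr[h] = choices[rng.integers(0, 3)]
            seq = "".join(arr)

        reverse = rng.random() < orientation_mix
        orientation = "-" if reverse else "+"
        if reverse:
            seq = reverse_complement(seq)

        records.append((read_id, seq, errors.quality_char * len(seq)))
        truth_rows.append((read_id, edited, edit_type, edit_len,
                           edit_pos, orientation))

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return records, truth


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def read_fastq(path):
    """Minimal strict 4-line FASTQ reader yielding (read_id, sequence)."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record near {header!r}")
            yield header[1:].split()[0], seq


def simulate_assay_plate(true_disruption: float, control_gfp_mean: float,
                         control_gfp_sd: float, n_replicates: int,
                         seed: int = 0) -> pd.DataFrame:
    """One plate: negative-control wells ~ truncated Normal on [0, 100],
    sample wells with expected GFP% = control_mean * (1 - disruption)."""
    if not 0.0 <= true_disruption <= 1.0:
        raise ValueError("true_disruption must be in [0, 1]")
    if control_gfp_sd <= 0:
        raise ValueError("control_gfp_sd must be > 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)

    def trunc(mean, sd, size):
        a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                                   random_state=rng)

    sample_mean = control_gfp_mean * (1.0 - true_disruption)
    ctrl = trunc(control_gfp_mean, control_gfp_sd, n_replicates)
    samp = trunc(sample_mean, control_gfp_sd, n_replicates)
    mcherry = trunc(40.0, 5.0, 2 * n_replicates)

    rows = []
    for r in range(n_replicates):
        rows.append(("control", r + 1, float(ctrl[r]), float(mcherry[r]),
                     "negative_control", 1))
    for r in range(n_replicates):
        rows.append(("sample", r + 1, float(samp[r]),
                     float(mcherry[n_replicates + r]), "sample", 1))
    return pd.DataFrame(
        rows, columns=["condition", "replicate", "gfp_pct", "mcherry_pct",
                       "role", "day"])


def simulate_pam_panel(base_weights: dict, n_targets: int,
                       target_effect_sd: float = 0.5,
                       noise_sd: float = 0.1, seed: int = 0,
                       nuclease: str = "sim") -> pd.DataFrame:
    """Activity table for a panel in which one PAM position is varied at a
    time.

    ``base_weights`` maps position (-4..-1) -> base -> relative activity.
    Each target gets a lognormal target-specific scale; each record gets
    multiplicative lognormal noise.  The unvaried positions carry the
    highest-weight base of their column.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    for pos, weights in base_weights.items():
        if pos not in PAM_POSITIONS:
            raise ValueError(f"invalid PAM position {pos}")
        if any(w < 0 for w in weights.values()):
            raise ValueError(f"negative weight at position {pos}")
        if not any(w > 0 for w in weights.values()):
            raise ValueError(f"no positive weight at position {pos}")
    rng = np.random.default_rng(seed)
    scales = np.exp(rng.normal(0.0, target_effect_sd, size=n_targets))

    backbone = {}
    for pos in PAM_POSITIONS:
        weights = base_weights.get(pos, {"T": 1.0})
        backbone[pos] = max(BASES, key=lambda b: (weights.get(b, 0.0), b))

    rows = []
    for t in range(n_targets):
        target_id = f"target{t + 1:02d}"
        for pos in sorted(base_weights):
            weights = base_weights[pos]
            idx = pos + 4
            for base in BASES:
                pam = "".join(base if p == pos else backbone[p]
                              for p in PAM_POSITIONS)
                assert pam[idx] == base
                noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
                activity = float(scales[t] * weights.get(base, 0.0) * noise)
                rows.append((target_id, nuclease, pam, pos, activity))
    return pd.DataFrame(
        rows, columns=["target_id", "nuclease", "pam", "varied_position",
                       "activity"])
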