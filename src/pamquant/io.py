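"""File-format helpers: annotated reference FASTA, atomic writes, checksums.

The amplicon FASTA header carries the site annotation as key=value tokens,
with 1-based inclusive coordinates (converted to 0-based half-open
internally), e.g.::

    >ampA protospacer=101..123 pam=97..100 strand=+
"""

from __future__ import annotations

import hashlib
import os
import re
import tempfile
from pathlib import Path

from Bio import SeqIO

from .align import AmpliconRef

_TOKEN = re.compile(r"(\w+)=(\S+)")
_RANGE = re.compile(r"^(\d+)\.\.(\d+)$")


def _parse_range(value: str, key: str) -> tuple[int, int]:
    m = _RANGE.match(value)
    if not m:
        raise ValueError(f"bad {key} range {value!r}; expected start..end (1-based)")
    start, end = int(m.group(1)), int(m.group(2))
    return start - 1, end  # to 0-based half-open


def read_amplicon_fasta(path) -> AmpliconRef:
    """Read the first record of an annotated amplicon FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rec = records[0]
    tokens = dict(_TOKEN.findall(rec.description))
    for key in ("protospacer", "pam"):
        if key not in tokens:
            raise ValueError(
                f"FASTA header of {path} lacks the {key}=start..end annotation")
    ps, pe = _parse_range(tokens["protospacer"], "protospacer")
    gs, ge = _parse_range(tokens["pam"], "pam")
    return AmpliconRef(name=rec.id, sequence=str(rec.seq),
                       protospacer_start=ps, protospacer_end=pe,
                       pam_start=gs, pam_end=ge,
                       site_strand=tokens.get("strand", "+"))


def write_amplicon_fasta(ref: AmpliconRef, path, width: int = 70) -> None:
    header = (f">{ref.name} protospacer={ref.protospacer_start + 1}.."
              f"{ref.protospacer_end} pam={ref.pam_start + 1}..{ref.pam_end} "
              f"strand={ref.site_strand}")
    lines = [header] + [ref.sequence[i : i + width]
                        for i in range(0, len(ref.sequence), width)]
    atomic_write_text(path, "\n".join(lines) + "\n")


def atomic_write_text(path, text: str) -> None:
    """Write via a temp file + rename so partial outputs never appear."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
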