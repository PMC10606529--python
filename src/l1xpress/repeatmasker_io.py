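"""Parse RepeatMasker ``.out`` annotation of reads and select candidate
reads by L1 divergence.

Candidate selection keeps every read carrying at least one LINE/L1
annotation whose ``div`` column (percent divergence from the subfamily
consensus, a proxy for element age) is strictly below the threshold
(default 10%). Young, potentially retrotransposition-competent L1 copies
sit well under this bound; older fragments are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

PathLike = Union[str, Path]


class RMOutParseError(ValueError):
    """Raised for an unparseable `.out` data row; message names the line."""


@dataclass(frozen=True)
class RepeatMaskerHit:
    """One annotation row linking a read to a repeat.

    Read coordinates are 1-based inclusive as printed by RepeatMasker.
    ``orientation`` is '+' or 'C' (complement).
    """

    sw_score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    query_id: str
    query_start: int
    query_end: int
    orientation: str
    repeat_name: str
    repeat_class_family: str

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError("query_start must be <= query_end")
        if not (0.0 <= self.pct_div <= 100.0):
            raise ValueError("pct_div must lie in [0, 100]")


def _looks_like_header(fields: Sequence[str]) -> bool:
    # The standard 3-line header starts "SW perc perc perc query ..." and
    # its continuation/blank lines never begin with an integer score.
    try:
        int(fields[0])
        return False
    except ValueError:
        return True


def parse_rm_out(path: PathLike) -> list[RepeatMaskerHit]:
    """Parse a standard 15/16-column RepeatMasker ``.out`` table.

    Header and blank lines are skipped; a trailing ``*`` (overlap marker)
    column is tolerated. Rows of every repeat class are retained —
    filtering is a separate step.
    """
    hits: list[RepeatMaskerHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or _looks_like_header(fields):
                continue
            if len(fields) < 11:
                raise RMOutParseError(f"{path}:{lineno}: expected >=11 columns, got {len(fields)}")
            try:
                hits.append(
                    RepeatMaskerHit(
                        sw_score=int(fields[0]),
                        pct_div=float(fields[1]),
                        pct_del=float(fields[2]),
                        pct_ins=float(fields[3]),
                        query_id=fields[4],
                        query_start=int(fields[5]),
                        query_end=int(fields[6]),
                        orientation=fields[8],
                        repeat_name=fields[9],
                        repeat_class_family=fields[10],
                    )
                )
            except ValueError as exc:
                raise RMOutParseError(f"{path}:{lineno}: {exc}") from None
    return hits


def select_reads_by_divergence(
    hits: Iterable[RepeatMaskerHit],
    max_div: float = 10.0,
    class_prefix: str = "LINE/L1",
) -> set[str]:
    """Read identifiers with >=1 hit of the given class below ``max_div``.

    The divergence comparison is strict (<): a hit at exactly the
    threshold does not qualify. Class matching is by prefix so
    subfamily-qualified values (e.g. ``LINE/L1/L1HS``) match. A read with
    several annotations qualifies if any one of them does.
    """
    if not (0.0 < max_div <= 100.0):
        raise ValueError("max_div must lie in (0, 100]")
    return {
        h.query_id
        for h in hits
        if h.repeat_class_family.startswith(class_prefix) and h.pct_div < max_div
    }


def write_read_ids(ids: Iterable[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rid in sorted(ids):
            fh.write(rid + "\n")


def filter_fasta_by_ids(
    reads_path: PathLike, ids: set[str], out_path: PathLike
) -> int:
    """Write the subset of a FASTA whose record ids are in ``ids``.

    Returns the number of records written.
    """
    from Bio import SeqIO

    n = 0
    with open(out_path, "w") as out:
        for rec in SeqIO.parse(str(reads_path), "fasta"):
            if rec.id in ids:
                SeqIO.write(rec, out, "fasta")
                n += 1
    return n
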