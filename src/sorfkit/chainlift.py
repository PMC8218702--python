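"""Native UCSC chain-file interpreter and coordinate homogenization.

Every genomic coordinate of an entry (start, stop, each splice-block bound)
is remapped independently through the chain.  An entry fails the liftover
when (checked in this fixed order) a coordinate has no chain interval
(``fail_unmapped``), the remapped positions disagree on strand
(``fail_strand``) — a uniform strand flip of all positions together is
accepted — the chromosome changes (``fail_chromosome``), or the nucleotide
distance between start and stop codons changes (``fail_distance``).
Failed entries are dropped and tallied.

Chain coordinates follow the UCSC convention: 0-based half-open, with
query coordinates counted on the reverse-complemented sequence when the
query strand is '-'.  The backend is pluggable: any object with the same
``map_position`` contract can replace :class:`ChainMap`.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .model import ORFRecord, SpliceBlock

STATUS_OK = "ok"
FAIL_UNMAPPED = "fail_unmapped"
FAIL_STRAND = "fail_strand"
FAIL_CHROMOSOME = "fail_chromosome"
FAIL_DISTANCE = "fail_distance"


@dataclass
class _Chain:
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    # aligned blocks as parallel arrays of (t_block_start, q_block_start, size)
    t_starts: list[int]
    q_starts: list[int]
    sizes: list[int]

    def map0(self, p0: int) -> Optional[tuple[str, int, str]]:
        """Map a 0-based target position; returns (q_name, 0-based fwd pos, q_strand)."""
        i = bisect_right(self.t_starts, p0) - 1
        if i < 0:
            return None
        off = p0 - self.t_starts[i]
        if off >= self.sizes[i]:
            return None
        q0 = self.q_starts[i] + off
        if self.q_strand == "-":
            q0 = self.q_size - 1 - q0
        return self.q_name, q0, self.q_strand


class ChainMap:
    """All chains of a UCSC chain file, indexed by target chromosome."""

    def __init__(self, chains: Sequence[_Chain]):
        self._by_chrom: dict[str, list[_Chain]] = {}
        for chain in sorted(chains, key=lambda c: -c.score):
            self._by_chrom.setdefault(chain.t_name, []).append(chain)

    @classmethod
    def read(cls, path: str | Path) -> "ChainMap":
        chains: list[_Chain] = []
        header: Optional[list[str]] = None
        t_cur = q_cur = 0
        t_starts: list[int] = []
        q_starts: list[int] = []
        sizes: list[int] = []

        def flush() -> None:
            nonlocal header
            if header is None:
                return
            chains.append(
                _Chain(
                    score=float(header[1]),
                    t_name=header[2],
                    t_size=int(header[3]),
                    t_start=int(header[5]),
                    t_end=int(header[6]),
                    q_name=header[7],
                    q_size=int(header[8]),
                    q_strand=header[9],
                    q_start=int(header[10]),
                    t_starts=list(t_starts),
                    q_starts=list(q_starts),
                    sizes=list(sizes),
                )
            )
            header = None

        with Path(path).open() as fh:
            for line in fh:
                fields = line.split()
                if not fields:
                    continue
                if fields[0] == "chain":
                    flush()
                    header = fields
                    if header[4] != "+":
                        raise ValueError("chain target strand must be '+'")
                    t_cur = int(header[5])
                    q_cur = int(header[10])
                    t_starts, q_starts, sizes = [], [], []
                else:
                    size = int(fields[0])
                    t_starts.append(t_cur)
                    q_starts.append(q_cur)
                    sizes.append(size)
                    if len(fields) == 3:
                        t_cur += size + int(fields[1])
                        q_cur += size + int(fields[2])
        flush()
        return cls(chains)

    def map_position(self, chromosome: str, position: int) -> Optional[tuple[str, int, str]]:
        """Map a 1-based position; returns (chromosome, 1-based position, strand) or None."""
        for chain in self._by_chrom.get(chromosome, []):
            hit = chain.map0(position - 1)
            if hit is not None:
                name, p0, strand = hit
                return name, p0 + 1, strand
        return None


@dataclass
class LiftResult:
    record: ORFRecord
    status: str


def lift_record(record: ORFRecord, chain: ChainMap) -> LiftResult:
    """Remap one entry, applying the three failure criteria in fixed order."""
    positions: list[int] = []
    if record.start_pos is not None:
        positions.append(record.start_pos)
    if record.stop_pos is not None:
        positions.append(record.stop_pos)
    for block in record.splice_blocks:
        positions.extend((block.start, block.end))

    if not positions:
        return LiftResult(record, FAIL_UNMAPPED)

    mapped: dict[int, tuple[str, int, str]] = {}
    for pos in positions:
        hit = chain.map_position(record.chromosome, pos)
        if hit is None:
            return LiftResult(record, FAIL_UNMAPPED)
        mapped[pos] = hit

    strands = {s for _, _, s in mapped.values()}
    if len(strands) > 1:
        return LiftResult(record, FAIL_STRAND)
    chroms = {c for c, _, _ in mapped.values()}
    if len(chroms) > 1 or chroms != {record.chromosome}:
        return LiftResult(record, FAIL_CHROMOSOME)

    q_strand = strands.pop()
    new_start = mapped[record.start_pos][1] if record.start_pos is not None else None
    new_stop = mapped[record.stop_pos][1] if record.stop_pos is not None else None
    if new_start is not None and new_stop is not None:
        if abs(new_start - new_stop) != abs(record.start_pos - record.stop_pos):
            return LiftResult(record, FAIL_DISTANCE)

    new_strand = record.strand
    if q_strand == "-" and record.strand is not None:
        new_strand = "-" if record.strand == "+" else "+"

    new_blocks = sorted(
        SpliceBlock(*sorted((mapped[b.start][1], mapped[b.end][1])))
        for b in record.splice_blocks
    )
    lifted = record.copy(
        strand=new_strand,
        start_pos=new_start,
        stop_pos=new_stop,
        splice_blocks=new_blocks,
    )
    return LiftResult(lifted, STATUS_OK)


def lift_catalog(records: Sequence[ORFRecord],
                 chain: ChainMap) -> tuple[list[ORFRecord], Counter]:
    """Lift all records; failed entries are dropped and tallied by status."""
    kept: list[ORFRecord] = []
    tally: Counter = Counter()
    for rec in records:
        result = lift_record(rec, chain)
        if result.status == STATUS_OK:
            kept.append(result.record)
        else:
            tally[result.status] += 1
    return kept, tally


# ---------------------------------------------------------------------------
# chain construction helpers (used by the fixture generator and tests)
# ---------------------------------------------------------------------------

def write_chain(path: str | Path,
                blocks_by_chrom: dict[str, list[tuple[int, int, int]]],
                chrom_sizes: dict[str, int]) -> None:
    """Write a plus-strand chain file from explicit aligned blocks.

    ``blocks_by_chrom`` maps chromosome -> list of ``(t_start0, q_start0, size)``
    aligned blocks in increasing target order (0-based).
    """
    with Path(path).open("w") as fh:
        for cid, (chrom, blocks) in enumerate(sorted(blocks_by_chrom.items()), start=1):
            size = chrom_sizes[chrom]
            t_end = blocks[-1][0] + blocks[-1][2]
            q_end = blocks[-1][1] + blocks[-1][2]
            fh.write(
                f"chain 1000 {chrom} {size} + {blocks[0][0]} {t_end} "
                f"{chrom} {size} + {blocks[0][1]} {q_end} {cid}\n"
            )
            for i, (ts, qs, bs) in enumerate(blocks):
                if i + 1 < len(blocks):
                    nts, nqs, _ = blocks[i + 1]
                    fh.write(f"{bs} {nts - ts - bs} {nqs - qs - bs}\n")
                else:
                    fh.write(f"{bs}\n")
            fh.write("\n")


def identity_blocks(chrom_sizes: dict[str, int]) -> dict[str, list[tuple[int, int, int]]]:
    return {chrom: [(0, 0, size)] for chrom, size in chrom_sizes.items()}


def shift_blocks(chrom_sizes: dict[str, int], shift: int) -> dict[str, list[tuple[int, int, int]]]:
    """Uniform rigid shift: target position p maps to p + shift."""
    out = {}
    for chrom, size in chrom_sizes.items():
        if shift >= 0:
            out[chrom] = [(0, shift, size - shift)]
        else:
            out[chrom] = [(-shift, 0, size + shift)]
    return out


def invert_blocks(blocks_by_chrom: dict[str, list[tuple[int, int, int]]]
                  ) -> dict[str, list[tuple[int, int, int]]]:
    """Swap target and query roles of a plus-strand block set."""
    return {
        chrom: sorted((qs, ts, size) for ts, qs, size in blocks)
        for chrom, blocks in blocks_by_chrom.items()
    }
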