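"""Paired-FASTQ to construct-count processing.

The pipeline mirrors how dual-guide amplicon reads identify a construct:

1. pairs carrying a recombination diagnostic motif (a single-cassette
   product) are excluded;
2. fixed-coordinate trimming removes the amplicon context — the first 74 and
   last 18 bases of read 1, the first 59 and last 33 bases of read 2 —
   leaving the spacer cores;
3. the read-2 core is reverse-complemented into construct orientation and the
   two cores are joined (the two spacer slots are disjoint, so the default is
   concatenation; an overlap-merging mode is available for designs where the
   mates overlap);
4. the joined core is assigned to the construct whose reference core is the
   unique nearest neighbour by Hamming distance, allowing up to 3 mismatches.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .library import LibraryDesign
from .simulate import MOTIF_R1, MOTIF_R2, reference_core, revcomp

__all__ = [
    "ReadPair",
    "AssignmentResult",
    "ProcessingReport",
    "read_fastq_pairs",
    "filter_recombined",
    "trim_pair",
    "merge_cores",
    "assign_construct",
    "reference_cores",
    "count_reads",
]

MAX_MISMATCHES = 3
TRIM = dict(r1_head=74, r1_tail=18, r2_head=59, r2_tail=33)


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str = ""
    r2_qual: str = ""


@dataclass(frozen=True)
class AssignmentResult:
    read_id: str
    construct_id: str | None
    mismatches: int
    status: str  # assigned | recombined | unassigned | ambiguous | too_short | unmerged


@dataclass
class ProcessingReport:
    """Per-category read tallies; categories always sum to ``total``."""

    total: int = 0
    recombined: int = 0
    too_short: int = 0
    unmerged: int = 0
    unassigned: int = 0
    ambiguous: int = 0
    assigned: int = 0

    def as_dict(self) -> dict:
        return dict(
            total=self.total, recombined=self.recombined,
            too_short=self.too_short, unmerged=self.unmerged,
            unassigned=self.unassigned, ambiguous=self.ambiguous,
            assigned=self.assigned,
        )

    def check(self) -> None:
        parts = (self.recombined + self.too_short + self.unmerged
                 + self.unassigned + self.ambiguous + self.assigned)
        if parts != self.total:
            raise AssertionError(f"report categories sum to {parts}, not {self.total}")


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(fastq_r1: str | Path, fastq_r2: str | Path) -> Iterator[ReadPair]:
    """Stream synchronized 4-line FASTQ records from both mates."""
    with _open_maybe_gz(fastq_r1) as f1, _open_maybe_gz(fastq_r2) as f2:
        idx = 0
        while True:
            rec1 = [f1.readline() for _ in range(4)]
            rec2 = [f2.readline() for _ in range(4)]
            if not rec1[0] and not rec2[0]:
                return
            if not rec1[0] or not rec2[0]:
                raise ValueError(f"FASTQ mates out of sync at record {idx}")
            if not rec1[0].startswith("@") or not rec2[0].startswith("@"):
                raise ValueError(f"malformed FASTQ record at index {idx}")
            if not rec1[3] or not rec2[3]:
                raise ValueError(f"truncated FASTQ record at index {idx}")
            yield ReadPair(
                read_id=rec1[0][1:].split()[0].removesuffix("/1"),
                r1_seq=rec1[1].strip().upper(),
                r2_seq=rec2[1].strip().upper(),
                r1_qual=rec1[3].strip(),
                r2_qual=rec2[3].strip(),
            )
            idx += 1


def filter_recombined(
    pairs: Iterable[ReadPair],
    motif_r1: str = MOTIF_R1,
    motif_r2: str = MOTIF_R2,
    logic: str = "or",
) -> tuple[list[ReadPair], int]:
    """Drop pairs flagged by the recombination diagnostic motifs.

    With the default ``logic="or"`` a pair is removed when either mate shows
    its motif (a recombined product corrupts the pair regardless of which
    mate reveals it); ``logic="and"`` requires both mates to match.
    """
    if not motif_r1 or not motif_r2:
        raise ValueError("motifs must be non-empty")
    if logic not in ("or", "and"):
        raise ValueError(f"unknown motif logic {logic!r}")
    kept: list[ReadPair] = []
    removed = 0
    for p in pairs:
        in1 = motif_r1 in p.r1_seq
        in2 = motif_r2 in p.r2_seq
        hit = (in1 or in2) if logic == "or" else (in1 and in2)
        if hit:
            removed += 1
        else:
            kept.append(p)
    return kept, removed


def trim_pair(
    pair: ReadPair,
    r1_head: int = TRIM["r1_head"],
    r1_tail: int = TRIM["r1_tail"],
    r2_head: int = TRIM["r2_head"],
    r2_tail: int = TRIM["r2_tail"],
) -> tuple[str, str] | None:
    """Cut the fixed amplicon context, returning (r1_core, r2_core).

    Coordinates count removed bases from each end; returns None when either
    mate is too short to leave a non-empty core.
    """
    if len(pair.r1_seq) <= r1_head + r1_tail or len(pair.r2_seq) <= r2_head + r2_tail:
        return None
    r1_core = pair.r1_seq[r1_head: len(pair.r1_seq) - r1_tail]
    r2_core = pair.r2_seq[r2_head: len(pair.r2_seq) - r2_tail]
    return r1_core, r2_core


def merge_cores(
    r1_core: str,
    r2_core: str,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
    mode: str = "concat",
) -> str | None:
    """Join the two trimmed cores into one construct-orientation sequence.

    ``r2_core`` is supplied in sequencing orientation and is reverse-
    complemented first.  In ``concat`` mode (the default: the two spacer
    slots are disjoint amplicon intervals) the cores are simply joined in
    construct order.  In ``overlap`` mode the offset minimising mismatches
    with overlap >= ``min_overlap`` and mismatch fraction <=
    ``max_mismatch_frac`` is chosen and a consensus returned; ties and
    failures give None.
    """
    r2 = revcomp(r2_core)
    if mode == "concat":
        return r1_core + r2
    if mode != "overlap":
        raise ValueError(f"unknown merge mode {mode!r}")

    best: tuple[int, int] | None = None  # (mismatches, overlap)
    best_offset: int | None = None
    tie = False
    # r2 starts at offset within/after r1: offset in [0, len(r1)]
    for offset in range(0, len(r1_core) - min_overlap + 1):
        ov = min(len(r1_core) - offset, len(r2))
        if ov < min_overlap:
            continue
        mm = sum(
            1 for a, b in zip(r1_core[offset:offset + ov], r2[:ov]) if a != b
        )
        if mm / ov > max_mismatch_frac:
            continue
        key = (mm, -ov)
        if best is None or key < best:
            best, best_offset, tie = key, offset, False
        elif key == best:
            tie = True
    if best is None or tie:
        return None
    offset = best_offset
    # consensus: r1 prefix + r2 (r1 wins inside the overlap; with 0
    # mismatches the two agree)
    return r1_core[:offset] + r2


def reference_cores(library: LibraryDesign) -> dict[str, str]:
    """construct_id -> identifying core sequence (pos1 core + pos2 core)."""
    refs = {c.construct_id: reference_core(c, library) for c in library.constructs}
    if len(set(refs.values())) != len(refs):
        # duplicate cores cannot be told apart (the concatenated strategy's
        # repeated NTC-NTC blocks); reads credit the first occurrence
        seen: dict[str, str] = {}
        for cid, core in refs.items():
            seen.setdefault(core, cid)
        refs = {cid: core for core, cid in seen.items()}
    return refs


class _ReferenceIndex:
    """Vectorized Hamming-distance lookup over equal-length reference cores."""

    def __init__(self, reference: Mapping[str, str]):
        if not reference:
            raise ValueError("empty reference")
        lengths = {len(s) for s in reference.values()}
        if len(lengths) != 1:
            raise ValueError("reference cores must share one length")
        self.length = lengths.pop()
        self.ids = list(reference)
        self.matrix = np.frombuffer(
            "".join(reference[i] for i in self.ids).encode(), dtype=np.uint8
        ).reshape(len(self.ids), self.length)
        self.exact = {reference[i]: i for i in self.ids}

    def lookup(self, core: str, max_mismatches: int) -> tuple[str | None, int, str]:
        if len(core) != self.length:
            return None, -1, "unassigned"
        hit = self.exact.get(core)
        if hit is not None:
            return hit, 0, "assigned"
        q = np.frombuffer(core.encode(), dtype=np.uint8)
        dists = (self.matrix != q).sum(axis=1)
        best = int(dists.min())
        if best > max_mismatches:
            return None, best, "unassigned"
        winners = np.nonzero(dists == best)[0]
        if winners.size > 1:
            return None, best, "ambiguous"
        return self.ids[int(winners[0])], best, "assigned"


def assign_construct(
    core_seq: str,
    reference: Mapping[str, str],
    max_mismatches: int = MAX_MISMATCHES,
    read_id: str = "",
) -> AssignmentResult:
    """Assign a merged core to its unique nearest reference construct."""
    index = reference if isinstance(reference, _ReferenceIndex) else _ReferenceIndex(reference)
    cid, mm, status = index.lookup(core_seq, max_mismatches)
    return AssignmentResult(read_id=read_id, construct_id=cid, mismatches=mm, status=status)


def count_reads(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    library: LibraryDesign,
    sample_name: str = "sample",
    max_mismatches: int = MAX_MISMATCHES,
    motif_r1: str = MOTIF_R1,
    motif_r2: str = MOTIF_R2,
    motif_logic: str = "or",
    trim: Mapping[str, int] | None = None,
    merge_mode: str = "concat",
) -> tuple[pd.DataFrame, ProcessingReport]:
    """Process one paired-FASTQ sample into per-construct counts.

    Returns a one-column count DataFrame indexed by construct_id and a
    ProcessingReport whose categories sum to the number of input pairs.
    """
    trim = dict(TRIM, **(trim or {}))
    index = _ReferenceIndex(reference_cores(library))
    counts = {cid: 0 for cid in index.ids}
    report = ProcessingReport()

    for pair in read_fastq_pairs(fastq_r1, fastq_r2):
        report.total += 1
        kept, removed = filter_recombined([pair], motif_r1, motif_r2, motif_logic)
        if removed:
            report.recombined += 1
            continue
        cores = trim_pair(pair, **trim)
        if cores is None:
            report.too_short += 1
            continue
        merged = merge_cores(cores[0], cores[1], mode=merge_mode)
        if merged is None:
            report.unmerged += 1
            continue
        res = assign_construct(merged, index, max_mismatches, read_id=pair.read_id)
        if res.status == "assigned":
            counts[res.construct_id] += 1
            report.assigned += 1
        elif res.status == "ambiguous":
            report.ambiguous += 1
        else:
            report.unassigned += 1

    report.check()
    df = pd.DataFrame(
        {sample_name: [counts.get(c.construct_id, 0) for c in library.constructs]},
        index=pd.Index([c.construct_id for c in library.constructs], name="construct_id"),
    )
    return df, report
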