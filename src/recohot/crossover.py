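"""Genotype-block segmentation and crossover-event calling.

Each sample's genotype sequence along a chromosome is converted into
maximal runs of identical non-missing parental state (a, b or h); missing
calls are skipped and do not break a run.  Block boundaries fall at the
midpoint between the bounding markers, so blocks tile the marker-covered
span.  Every state change between consecutive blocks is emitted as a
candidate crossover event whose breakpoint interval runs from the last
marker of the left block to the first marker of the right block.

Filters mirror the study's rules: an event passes only if both flanking
blocks span at least 10 kb; events adjacent to a block of ≤ 200 kb are
flagged for review (retained, separable, optionally dropped); events whose
allelic assignment is ambiguous — impure flanking blocks after smoothing —
are excluded outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CODE_MISSING, GenotypeMatrix

__all__ = [
    "GenotypeBlock",
    "CrossoverEvent",
    "segment_blocks",
    "call_crossovers",
    "count_events",
    "events_frame",
    "STATUS_PASS",
    "STATUS_SHORT_FLANK",
    "STATUS_SMALL_BLOCK",
    "STATUS_AMBIGUOUS",
]

logger = logging.getLogger(__name__)

STATUS_PASS = "pass"
STATUS_SHORT_FLANK = "short_flank"
STATUS_SMALL_BLOCK = "small_block_flag"
STATUS_AMBIGUOUS = "ambiguous_excluded"

_STATE_CHAR = {0: "a", 1: "b", 2: "h"}


@dataclass(frozen=True)
class GenotypeBlock:
    """A maximal same-state run of one sample on one chromosome."""

    sample: str
    chrom: str
    start: int
    end: int
    state: str  # 'a' | 'b' | 'h'
    n_markers: int
    first_pos: int  # position of the first supporting marker
    last_pos: int  # position of the last supporting marker
    minority_frac: float = 0.0  # impurity introduced by smoothing

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CrossoverEvent:
    """One inferred breakpoint between two adjacent genotype blocks.

    The breakpoint interval [start, end) runs from the last marker of the
    left block to the first marker of the right block.
    """

    sample: str
    chrom: str
    start: int
    end: int
    left_state: str
    right_state: str
    left_span: int
    right_span: int
    status: str

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _runs(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(run start indices, run values) of a 1-D array."""
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate(([0], change))
    return starts, states[starts]


def segment_blocks(
    gm: GenotypeMatrix,
    sample: str,
    chrom: str | None = None,
    smooth_min_markers: int = 1,
) -> list[GenotypeBlock]:
    """Convert one sample's calls into parental/heterozygous blocks.

    ``smooth_min_markers`` > 1 absorbs runs supported by fewer markers into
    their neighbours when both neighbours share a state (single-marker
    blips); absorbed markers are counted as within-block minority calls so
    downstream purity checks can flag the block.  Chromosomes whose calls
    are all missing yield no blocks (logged).
    """
    j = gm.sample_index(sample)
    chroms = [chrom] if chrom is not None else gm.chroms
    blocks: list[GenotypeBlock] = []
    for c in chroms:
        pos, calls = gm.chrom_slice(c)
        g = calls[:, j]
        keep = g != CODE_MISSING
        if not keep.any():
            logger.info("sample %s: all calls missing on %s", sample, c)
            continue
        p = pos[keep]
        s = g[keep].astype(np.int64)

        starts, values = _runs(s)
        ends = np.concatenate([starts[1:], [s.size]])
        minority = np.zeros(starts.size, dtype=np.int64)

        if smooth_min_markers > 1 and starts.size >= 3:
            starts, ends, values, minority = _absorb_blips(starts, ends, values, smooth_min_markers)

        for k in range(starts.size):
            i0, i1 = int(starts[k]), int(ends[k]) - 1
            left_bp = int(p[i0]) if k == 0 else int((p[i0 - 1] + p[i0]) // 2)
            right_bp = int(p[i1]) + 1 if k == starts.size - 1 else int((p[i1] + p[i1 + 1]) // 2)
            n = i1 - i0 + 1
            blocks.append(
                GenotypeBlock(
                    sample=sample,
                    chrom=c,
                    start=left_bp,
                    end=right_bp,
                    state=_STATE_CHAR[int(values[k])],
                    n_markers=n,
                    first_pos=int(p[i0]),
                    last_pos=int(p[i1]),
                    minority_frac=float(minority[k]) / n,
                )
            )
    return blocks


def _absorb_blips(starts, ends, values, min_markers):
    """Merge runs shorter than ``min_markers`` into matching neighbours."""
    starts = list(starts)
    ends = list(ends)
    values = list(values)
    minority = [0] * len(starts)
    changed = True
    while changed:
        changed = False
        for k in range(1, len(starts) - 1):
            if ends[k] - starts[k] < min_markers and values[k - 1] == values[k + 1] != values[k]:
                minority[k - 1] += (ends[k] - starts[k]) + minority[k] + minority[k + 1]
                ends[k - 1] = ends[k + 1]
                del starts[k : k + 2], ends[k : k + 2], values[k : k + 2], minority[k : k + 2]
                changed = True
                break
    return (np.array(starts), np.array(ends), np.array(values), np.array(minority))


def call_crossovers(
    blocks: list[GenotypeBlock],
    min_flank_span: int = 10_000,
    small_block: int = 200_000,
    purity: float = 0.9,
    breakpoint_max_width: int | None = None,
    drop_small_blocks: bool = False,
) -> list[CrossoverEvent]:
    """Call crossover events at every state change between adjacent blocks.

    Status assignment, in order of precedence:

    * ``ambiguous_excluded`` — a flanking block's minority-call fraction
      exceeds 1 − ``purity`` (conflicting within-block calls), or both
      flanks are heterozygous;
    * ``short_flank`` — either flanking block spans < ``min_flank_span``
      (the ≥ 10 kb both-sides rule fails);
    * ``small_block_flag`` — a flanking block spans ≤ ``small_block``
      (retained for review; dropped entirely if ``drop_small_blocks``);
    * ``pass`` otherwise.

    ``breakpoint_max_width`` optionally also demands that the breakpoint
    interval itself be no wider than the given bp (an alternative reading
    of the flank rule, off by default).
    """
    events: list[CrossoverEvent] = []
    by_key: dict[tuple[str, str], list[GenotypeBlock]] = {}
    for b in blocks:
        by_key.setdefault((b.sample, b.chrom), []).append(b)
    for (sample, chrom), bl in by_key.items():
        bl = sorted(bl, key=lambda b: b.start)
        for left, right in zip(bl, bl[1:]):
            impure = max(left.minority_frac, right.minority_frac) > (1.0 - purity) + 1e-12
            if impure or (left.state == "h" and right.state == "h"):
                status = STATUS_AMBIGUOUS
            elif min(left.span, right.span) < min_flank_span:
                status = STATUS_SHORT_FLANK
            elif min(left.span, right.span) <= small_block:
                if drop_small_blocks:
                    continue
                status = STATUS_SMALL_BLOCK
            else:
                status = STATUS_PASS
            if (
                status == STATUS_PASS
                and breakpoint_max_width is not None
                and right.first_pos - left.last_pos > breakpoint_max_width
            ):
                status = STATUS_SHORT_FLANK
            events.append(
                CrossoverEvent(
                    sample=sample,
                    chrom=chrom,
                    start=left.last_pos,
                    end=right.first_pos,
                    left_state=left.state,
                    right_state=right.state,
                    left_span=left.span,
                    right_span=right.span,
                    status=status,
                )
            )
    return events


def events_frame(events: list[CrossoverEvent]) -> pd.DataFrame:
    """Events as a BED-like frame (chrom, start, end, sample, status, states)."""
    return pd.DataFrame(
        [
            (e.chrom, e.start, e.end, e.sample, e.status, e.left_state, e.right_state)
            for e in events
        ],
        columns=["chrom", "start", "end", "sample", "status", "left_state", "right_state"],
    )


def count_events(
    events: list[CrossoverEvent] | pd.DataFrame,
    by: str = "genome",
    statuses: tuple[str, ...] = (STATUS_PASS,),
) -> pd.Series | int:
    """Tally events with the given statuses per sample, chromosome or genome."""
    df = events if isinstance(events, pd.DataFrame) else events_frame(events)
    df = df[df["status"].isin(statuses)] if len(df) else df
    if by == "genome":
        return int(len(df))
    if by == "sample":
        return df.groupby("sample").size() if len(df) else pd.Series(dtype=np.int64)
    if by == "chrom":
        return df.groupby("chrom").size() if len(df) else pd.Series(dtype=np.int64)
    raise ValueError(f"unknown grouping {by!r}")
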