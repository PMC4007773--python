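"""Read preprocessing: 3' adapter trimming, length window, median-quality filter.

Small-RNA libraries sequence a short insert (a mature miRNA, ~22 nt) followed
by the 3' sequencing adapter, so almost every informative read contains the
adapter and must be trimmed back to the insert before counting. After
trimming, reads are kept only if they fall in the 15-27 nt window that mature
miRNAs occupy and if the median Phred score of the retained bases is at least
30.

Adapter matching semantics: the leftmost alignment of an adapter *prefix*
(length >= ``min_adapter_overlap``) against the read wins, provided its
mismatch fraction is at most ``max_adapter_error_rate``; the read is truncated
at the alignment start, qualities in lockstep. A read without a qualifying
occurrence is returned unchanged — the length window then removes untrimmed
full-length reads.

The median of an even-length quality list is the arithmetic mean of the two
middle order statistics; this decides accept/reject exactly at the Phred-30
boundary and is therefore fixed here, not configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Iterator, Optional

from .fastq_io import Read

#: Illumina TruSeq Small RNA 3' adapter (RA3). The library kit the default
#: targets; always configurable.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing stage (all lengths in nucleotides)."""

    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    min_len: int = 15
    max_len: int = 27
    min_median_phred: int = 30
    max_adapter_error_rate: float = 0.1
    min_adapter_overlap: int = 3

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if not (0.0 <= self.max_adapter_error_rate < 1.0):
            raise ValueError("max_adapter_error_rate must be in [0, 1)")
        if self.min_adapter_overlap < 1:
            raise ValueError("min_adapter_overlap must be >= 1")


@dataclass
class PreprocessStats:
    """Per-stage read accounting for one sample."""

    n_raw: int = 0
    n_adapter_trimmed: int = 0
    n_pass_length: int = 0
    n_accepted: int = 0
    reject_reasons: dict = field(default_factory=dict)


def find_adapter_start(sequence: str, cfg: PreprocessConfig) -> Optional[int]:
    """Position of the leftmost qualifying 3' adapter occurrence, else None.

    An occurrence at position ``i`` aligns ``adapter[:min(la, n - i)]``
    against ``sequence[i:]``; it qualifies when the overlap is at least
    ``min_adapter_overlap`` and mismatches / overlap <=
    ``max_adapter_error_rate``.
    """
    adapter = cfg.adapter
    n = len(sequence)
    la = len(adapter)
    last_start = n - cfg.min_adapter_overlap
    for i in range(0, last_start + 1):
        overlap = min(la, n - i)
        allowed = int(cfg.max_adapter_error_rate * overlap)
        mismatches = 0
        for a, b in zip(adapter, sequence[i:i + overlap]):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return i
    return None


def trim_adapter(read: Read, cfg: PreprocessConfig) -> Read:
    """Truncate a read (and its qualities) at the 3' adapter, if present."""
    start = find_adapter_start(read.sequence, cfg)
    if start is None:
        return read
    return Read(read.read_id, read.sequence[:start], read.qualities[:start])


def filter_read(read: Read, cfg: PreprocessConfig) -> tuple[bool, Optional[str]]:
    """Accept/reject a trimmed read.

    Accept iff ``min_len <= len <= max_len`` and the median Phred score of
    the retained bases is at least ``min_median_phred``. Rejections carry a
    reason in {"too_short", "too_long", "low_quality"}.
    """
    n = len(read)
    if n < cfg.min_len:
        return False, "too_short"
    if n > cfg.max_len:
        return False, "too_long"
    if median(read.qualities) < cfg.min_median_phred:
        return False, "low_quality"
    return True, None


def preprocess_sample(
    reads: Iterable[Read], cfg: PreprocessConfig | None = None,
    stats: PreprocessStats | None = None,
) -> tuple[Iterator[Read], PreprocessStats]:
    """Trim and filter a read stream, accounting per stage.

    Returns a lazy, order-preserving iterator of accepted reads together with
    a :class:`PreprocessStats` that is updated as the iterator is consumed
    (final once the stream is exhausted). Trim positions depend only on the
    sequence, so they are memoized across the (highly duplicated) stream.
    """
    cfg = cfg or PreprocessConfig()
    if stats is None:
        stats = PreprocessStats()
    trim_cache: dict[str, Optional[int]] = {}

    def _generator() -> Iterator[Read]:
        for read in reads:
            stats.n_raw += 1
            seq = read.sequence
            try:
                start = trim_cache[seq]
            except KeyError:
                start = find_adapter_start(seq, cfg)
                trim_cache[seq] = start
            if start is not None:
                stats.n_adapter_trimmed += 1
                read = Read(read.read_id, seq[:start], read.qualities[:start])
            n = len(read)
            if n < cfg.min_len:
                stats.reject_reasons["too_short"] = (
                    stats.reject_reasons.get("too_short", 0) + 1)
                continue
            if n > cfg.max_len:
                stats.reject_reasons["too_long"] = (
                    stats.reject_reasons.get("too_long", 0) + 1)
                continue
            stats.n_pass_length += 1
            if median(read.qualities) < cfg.min_median_phred:
                stats.reject_reasons["low_quality"] = (
                    stats.reject_reasons.get("low_quality", 0) + 1)
                continue
            stats.n_accepted += 1
            yield read

    return _generator(), stats
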