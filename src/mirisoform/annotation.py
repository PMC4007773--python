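"""miRBase-style reference handling and isoform annotation.

Classifies an isoform sequence against a reference of mature "entry"
sequences (the database's canonical most-frequent isoform of each miRNA) and
hairpin (pre-miRNA) sequences:

* ``entry_isoform`` — the sequence and some mature entry contain one another
  as an exact substring. Containment is read bidirectionally: a trimmed
  isoform is often 1-3 nt shorter than the entry, so requiring the read to
  contain the full entry would misclassify ordinary 3'-trimmed isomiRs.
* ``hairpin_isoform`` — the sequence occurs inside some hairpin allowing up
  to ``max_hairpin_mismatch`` substitutions (no indels).
* ``uncharacterized`` — neither. Note this is judged against the provided
  reference only (no genome alignment), so it is a superset of what a
  genome-wide pipeline would call uncharacterized.

Also provides the desk-scale "closest family member" counter (pipeline-A
surrogate): reads are matched against mature references allowing one
substitution and credited to *every* matching reference, mirroring a
multi-target short-read alignment; the number of reads with at least one
match is the sample's mapped-read denominator for RPM.

An N in a read never matches any reference base.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .fastq_io import Read, canonicalize_sequence
from .isoform_counting import IsoformCountMatrix

ENTRY_ISOFORM = "entry_isoform"
HAIRPIN_ISOFORM = "hairpin_isoform"
UNCHARACTERIZED = "uncharacterized"


@dataclass
class ReferenceSet:
    """Named mature entry sequences and hairpin sequences, DNA alphabet."""

    mature: dict[str, str]
    hairpins: dict[str, str] = field(default_factory=dict)
    version_label: str = ""

    def __post_init__(self) -> None:
        for label, mapping in (("mature", self.mature),
                               ("hairpin", self.hairpins)):
            for name, seq in mapping.items():
                if not seq:
                    raise ValueError(f"{label} sequence {name!r} is empty")
                mapping[name] = canonicalize_sequence(seq)


@dataclass(frozen=True)
class AnnotationRecord:
    sequence: str
    status: str
    matched_names: tuple[str, ...]
    n_mismatches_best: Optional[int]


def _read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in records:
            raise ValueError(f"{path}: duplicate FASTA name {name!r}")
        records[name] = canonicalize_sequence(str(rec.seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def load_reference(
    mature_fasta: str | Path,
    hairpin_fasta: str | Path | None = None,
    version_label: str = "",
) -> ReferenceSet:
    """Load mature (and optionally hairpin) FASTA files into a ReferenceSet.

    Names are the first whitespace-delimited header token and must be unique
    within each file; RNA is converted to DNA at load.
    """
    mature = _read_fasta(mature_fasta)
    hairpins = _read_fasta(hairpin_fasta) if hairpin_fasta is not None else {}
    return ReferenceSet(mature, hairpins, version_label)


def mismatches_at(needle: str, hay: str, offset: int, limit: int) -> int:
    """Substitution count aligning ``needle`` at ``hay[offset:]``.

    Early-exits past ``limit``; an N on either side always counts as a
    mismatch.
    """
    mm = 0
    for a, b in zip(needle, hay[offset:offset + len(needle)]):
        if a != b or a == "N":
            mm += 1
            if mm > limit:
                break
    return mm


def best_occurrence(needle: str, hay: str, max_mismatch: int
                    ) -> Optional[tuple[int, int]]:
    """Best substitutions-only occurrence of ``needle`` inside ``hay``.

    Returns ``(mismatches, offset)`` minimizing mismatches (leftmost wins
    ties) or None if no offset achieves <= ``max_mismatch``. Requires
    ``len(needle) <= len(hay)``.
    """
    ln = len(needle)
    if ln > len(hay) or ln == 0:
        return None
    best: Optional[tuple[int, int]] = None
    limit = max_mismatch
    for offset in range(len(hay) - ln + 1):
        mm = mismatches_at(needle, hay, offset, limit)
        if mm <= limit:
            if best is None or mm < best[0]:
                best = (mm, offset)
                if mm == 0:
                    break
                limit = mm - 1  # only strictly better occurrences matter now
    return best


def _match_either_way(seq: str, ref: str, max_mismatch: int
                      ) -> Optional[int]:
    """Mismatches of the best alignment of the shorter string within the longer."""
    if len(seq) <= len(ref):
        hit = best_occurrence(seq, ref, max_mismatch)
    else:
        hit = best_occurrence(ref, seq, max_mismatch)
    return None if hit is None else hit[0]


def annotate_sequence(
    seq: str, ref: ReferenceSet, max_hairpin_mismatch: int = 1
) -> AnnotationRecord:
    """Classify one isoform sequence against the reference set."""
    entry_hits = [name for name, entry in ref.mature.items()
                  if seq in entry or entry in seq]
    if entry_hits:
        return AnnotationRecord(seq, ENTRY_ISOFORM, tuple(entry_hits), 0)
    hairpin_hits: list[tuple[str, int]] = []
    for name, hairpin in ref.hairpins.items():
        hit = best_occurrence(seq, hairpin, max_hairpin_mismatch)
        if hit is not None:
            hairpin_hits.append((name, hit[0]))
    if hairpin_hits:
        best_mm = min(mm for _, mm in hairpin_hits)
        return AnnotationRecord(
            seq, HAIRPIN_ISOFORM, tuple(n for n, _ in hairpin_hits), best_mm)
    return AnnotationRecord(seq, UNCHARACTERIZED, (), None)


def match_mature_names(seq: str, ref: ReferenceSet, max_mismatch: int = 1
                       ) -> list[str]:
    """All mature references matching ``seq`` within ``max_mismatch``
    substitutions, aligning the shorter string inside the longer."""
    return [name for name, entry in ref.mature.items()
            if _match_either_way(seq, entry, max_mismatch) is not None]


def closest_family_counts(
    reads: Iterable[Read | str], ref: ReferenceSet, max_mismatch: int = 1
) -> tuple[Counter, int]:
    """Pipeline-A surrogate: per-reference read counts with multi-target credit.

    Every read increments each mature reference it matches (substring either
    way, <= ``max_mismatch`` substitutions, no indels). Returns the counts
    and ``n_mapped``, the number of reads with at least one match — the
    mapped-read denominator for pipeline-A RPM.
    """
    seq_tally: Counter = Counter()
    for read in reads:
        seq_tally[read if isinstance(read, str) else read.sequence] += 1
    counts: Counter = Counter()
    n_mapped = 0
    for seq, n in seq_tally.items():
        names = match_mature_names(seq, ref, max_mismatch)
        if names:
            n_mapped += n
            for name in names:
                counts[name] += n
    return counts, n_mapped


def family_report(
    matrix: IsoformCountMatrix, ref: ReferenceSet,
    max_mismatch: int = 1, max_hairpin_mismatch: int = 1,
) -> pd.DataFrame:
    """Per-isoform annotation table with multi-member ambiguity flags.

    One row per matrix sequence: annotation status, the mature references the
    sequence matches within ``max_mismatch`` substitutions, an ``ambiguous``
    flag when more than one mature reference matches (the miR-30 situation:
    closely related family members one or two substitutions apart), and the
    per-sample counts.
    """
    rows = []
    for seq in matrix.counts.index:
        record = annotate_sequence(seq, ref, max_hairpin_mismatch)
        family = match_mature_names(seq, ref, max_mismatch)
        rows.append({
            "sequence": seq,
            "status": record.status,
            "matched_names": ";".join(record.matched_names),
            "family_members": ";".join(family),
            "ambiguous": len(family) > 1,
            **{s: int(matrix.counts.at[seq, s]) for s in matrix.sample_ids},
        })
    columns = ["sequence", "status", "matched_names", "family_members",
               "ambiguous", *matrix.sample_ids]
    return pd.DataFrame(rows, columns=columns)
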