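"""Mapping-free isoform counting (pipeline B).

Each distinct trimmed read sequence is one isoform (isomiR): counting is an
exact-string tally, deliberately database-free, so 5'/3' offset variants and
substitution variants of a mature miRNA are kept apart. Per-sample tallies
are assembled into a cohort count matrix, noise rows are removed with the
median-prevalence filter (keep a sequence only if it is detected in at least
half of the samples), and counts are normalized to reads per million:

    RPM = R_miR / R_all * 10^6

where ``R_miR`` is the count of one sequence in one sample and ``R_all`` is
that sample's denominator. For pipelines B/C the denominator is the number of
accepted (post-preprocessing) reads in the sample; the pipeline-A surrogate
instead uses the number of reference-mapped reads (see
:mod:`mirisoform.annotation`).

Matrices are pandas DataFrames (rows = sequences, columns = samples) wrapped
with their per-sample denominators; row order is lexicographic for
reproducible output.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .fastq_io import Read

RPM_SCALE = 1_000_000


@dataclass
class IsoformCountMatrix:
    """Unique-sequence x sample integer count table with per-sample denominators.

    ``counts``: integer DataFrame, rows keyed by sequence (or seed, after
    collapsing), columns by sample id. ``denominators``: positive per-sample
    totals (``R_all``). ``members`` optionally maps a collapsed row key to the
    member sequences it sums over.
    """

    counts: pd.DataFrame
    denominators: pd.Series
    members: Optional[dict[str, list[str]]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate row keys")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.denominators = self.denominators.reindex(self.counts.columns)
        if self.denominators.isna().any():
            raise ValueError("denominator missing for some sample")
        if (self.denominators <= 0).any():
            raise ValueError("denominators must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sequences(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class RpmMatrix:
    """Reads-per-million abundance table; same keying as the count matrix."""

    values: pd.DataFrame
    denominators: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def count_isoforms(reads: Iterable[Read | str]) -> Counter:
    """Exact-string tally of read sequences.

    Accepts :class:`Read` objects or bare sequence strings. The sum of the
    tally equals the number of input reads. Sequences containing N are
    counted verbatim as distinct strings (surfaced downstream, never hidden).
    """
    tally: Counter = Counter()
    for read in reads:
        tally[read if isinstance(read, str) else read.sequence] += 1
    return tally


def build_matrix(
    tallies: Mapping[str, Mapping[str, int]],
    denominators: Mapping[str, int],
) -> IsoformCountMatrix:
    """Assemble per-sample tallies into a cohort count matrix.

    Rows are the union of all observed sequences, ordered lexicographically;
    absent cells are zero. ``denominators`` supplies ``R_all`` per sample.
    """
    sample_ids = list(tallies)
    for s in sample_ids:
        if s not in denominators:
            raise ValueError(f"no denominator for sample {s!r}")
        if denominators[s] <= 0:
            raise ValueError(f"denominator for sample {s!r} must be positive")
    all_seqs = sorted(set().union(*(tallies[s].keys() for s in sample_ids))
                      if sample_ids else set())
    counts = pd.DataFrame(
        {s: [tallies[s].get(seq, 0) for seq in all_seqs] for s in sample_ids},
        index=pd.Index(all_seqs, name="sequence"),
        dtype="int64",
    )
    denom = pd.Series({s: int(denominators[s]) for s in sample_ids},
                      dtype="int64")
    return IsoformCountMatrix(counts, denom)


def median_prevalence_filter(m: IsoformCountMatrix) -> IsoformCountMatrix:
    """Keep a row only if detected (count >= 1) in at least half of the samples.

    "At least half" is read inclusively: the threshold is ``ceil(n/2)``
    samples, so with 20 samples a sequence must appear in 10, and a sequence
    present in exactly half the cohort is kept. Columns and denominators are
    unchanged. Idempotent.
    """
    threshold = math.ceil(m.n_samples / 2)
    detected_in = (m.counts >= 1).sum(axis=1)
    keep = detected_in >= threshold
    members = None
    if m.members is not None:
        members = {k: v for k, v in m.members.items() if keep.get(k, False)}
    return IsoformCountMatrix(m.counts.loc[keep], m.denominators.copy(),
                              members)


def rpm_normalize(m: IsoformCountMatrix) -> RpmMatrix:
    """Normalize counts to reads per million: count / denominator * 10^6.

    When the denominators are the per-sample column totals, each RPM column
    sums to 10^6 (up to float rounding).
    """
    values = m.counts.div(m.denominators, axis=1) * RPM_SCALE
    return RpmMatrix(values, m.denominators.copy())


# ---------------------------------------------------------------------------
# TSV serialization: first column is the row key, one column per sample, with
# an optional "#denominator" line above the header carrying R_all per sample.

def write_matrix_tsv(m: IsoformCountMatrix | RpmMatrix, path: str | Path) -> None:
    table = m.counts if isinstance(m, IsoformCountMatrix) else m.values
    key_name = table.index.name or "sequence"
    with open(path, "w") as fh:
        fh.write("#denominator\t" +
                 "\t".join(str(int(v)) for v in m.denominators) + "\n")
        fh.write(key_name + "\t" + "\t".join(table.columns) + "\n")
        for key, row in table.iterrows():
            fh.write(str(key) + "\t" + "\t".join(map(str, row.to_list())) + "\n")


def read_matrix_tsv(path: str | Path, *, as_rpm: bool = False):
    """Read a matrix TSV written by :func:`write_matrix_tsv`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#denominator"):
            raise ValueError(f"{path}: missing #denominator line")
        denom_fields = first.split("\t")[1:]
        header = fh.readline().rstrip("\n").split("\t")
        key_name, sample_ids = header[0], header[1:]
        if len(denom_fields) != len(sample_ids):
            raise ValueError(f"{path}: denominator/sample column mismatch")
        keys, rows = [], []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            keys.append(fields[0])
            rows.append(fields[1:])
    dtype = float if as_rpm else "int64"
    table = pd.DataFrame(rows, index=pd.Index(keys, name=key_name),
                         columns=sample_ids).astype(dtype)
    denom = pd.Series(dict(zip(sample_ids, map(int, denom_fields))),
                      dtype="int64")
    if as_rpm:
        return RpmMatrix(table, denom)
    return IsoformCountMatrix(table, denom)
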