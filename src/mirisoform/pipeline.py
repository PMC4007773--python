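"""Pipeline orchestration: wire the stages into the three analysis routes.

* ``B`` — mapping-free isoform profiling: preprocess each sample, tally
  exact sequences, assemble the cohort matrix, median-prevalence filter,
  RPM with accepted-read denominators (optionally annotate rows).
* ``C`` — seed analysis: pipeline B, then collapse isoform rows sharing the
  5' 8-mer, RPM from the same denominators.
* ``A_surrogate`` — closest-family-member profiling against a provided
  mature reference: preprocess, count reads per reference allowing one
  substitution with multi-target credit, RPM with mapped-read denominators.

Each run writes a manifest recording the tool version, the configuration,
input checksums and per-stage record counts, so outputs are auditable and
reruns comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from collections import Counter
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .annotation import ReferenceSet, closest_family_counts, family_report
from .diffexp import SampleMeta
from .fastq_io import read_fastq
from .isoform_counting import (
    IsoformCountMatrix,
    RpmMatrix,
    build_matrix,
    count_isoforms,
    median_prevalence_filter,
    rpm_normalize,
    write_matrix_tsv,
)
from .preprocess import PreprocessConfig, PreprocessStats, preprocess_sample
from .seed_analysis import DEFAULT_SEED_LENGTH, collapse_by_seed

PIPELINE_A = "A_surrogate"
PIPELINE_B = "B"
PIPELINE_C = "C"


@dataclasses.dataclass
class PipelineResult:
    pipeline: str
    counts: IsoformCountMatrix
    filtered: IsoformCountMatrix
    rpm: RpmMatrix
    preprocess_stats: dict[str, PreprocessStats]
    seed_matrix: Optional[IsoformCountMatrix] = None
    seed_rpm: Optional[RpmMatrix] = None


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def preprocess_tally(
    fastq_path: str | Path, cfg: PreprocessConfig
) -> tuple[Counter, PreprocessStats]:
    """Preprocess one sample file and tally accepted sequences."""
    accepted, stats = preprocess_sample(read_fastq(fastq_path), cfg)
    tally = count_isoforms(accepted)
    return tally, stats


def run_pipeline(
    pipeline: str,
    samples: Sequence[tuple[str, str | Path]],
    out_dir: str | Path,
    preprocess_cfg: PreprocessConfig | None = None,
    reference: Optional[ReferenceSet] = None,
    seed_length: int = DEFAULT_SEED_LENGTH,
    max_mismatch: int = 1,
    meta: Optional[Sequence[SampleMeta]] = None,
    apply_median_filter: bool = True,
) -> PipelineResult:
    """Run one analysis pipeline over ``(sample_id, fastq_path)`` pairs.

    Writes count/RPM matrices (and the seed matrix for pipeline C, the
    annotation report when a reference is given) plus ``manifest.json`` to
    ``out_dir``. Deterministic for fixed inputs and configuration.
    """
    if pipeline not in (PIPELINE_A, PIPELINE_B, PIPELINE_C):
        raise ValueError(f"unknown pipeline {pipeline!r}")
    if pipeline == PIPELINE_A and reference is None:
        raise ValueError("pipeline A_surrogate requires a mature reference")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = preprocess_cfg or PreprocessConfig()

    stats_by_sample: dict[str, PreprocessStats] = {}
    tallies: dict[str, Counter] = {}
    denominators: dict[str, int] = {}
    for sample_id, fastq_path in samples:
        if pipeline == PIPELINE_A:
            accepted, stats = preprocess_sample(read_fastq(fastq_path), cfg)
            counts, n_mapped = closest_family_counts(
                accepted, reference, max_mismatch)
            if n_mapped == 0:
                raise ValueError(
                    f"sample {sample_id}: no reads mapped to the reference")
            tallies[sample_id] = counts
            denominators[sample_id] = n_mapped
        else:
            tally, stats = preprocess_tally(fastq_path, cfg)
            tallies[sample_id] = tally
            denominators[sample_id] = max(stats.n_accepted, 1)
        stats_by_sample[sample_id] = stats

    matrix = build_matrix(tallies, denominators)
    if pipeline == PIPELINE_A:
        matrix.counts.index.name = "reference"
    filtered = median_prevalence_filter(matrix) if apply_median_filter else matrix
    rpm = rpm_normalize(filtered)

    write_matrix_tsv(matrix, out_dir / "counts.tsv")
    write_matrix_tsv(filtered, out_dir / "counts.filtered.tsv")
    write_matrix_tsv(rpm, out_dir / "rpm.tsv")

    result = PipelineResult(pipeline, matrix, filtered, rpm, stats_by_sample)

    if pipeline == PIPELINE_C:
        seed_matrix = collapse_by_seed(filtered, seed_length)
        seed_rpm = rpm_normalize(seed_matrix)
        _write_seed_matrix(seed_matrix, out_dir / "seed_counts.tsv")
        write_matrix_tsv(seed_rpm, out_dir / "seed_rpm.tsv")
        result.seed_matrix = seed_matrix
        result.seed_rpm = seed_rpm

    if reference is not None and pipeline != PIPELINE_A:
        report = family_report(filtered, reference, max_mismatch)
        report.to_csv(out_dir / "annotation.tsv", sep="\t", index=False)

    _write_manifest(out_dir, pipeline, cfg, samples, stats_by_sample, result,
                    seed_length, max_mismatch, meta)
    return result


def _write_seed_matrix(m: IsoformCountMatrix, path: Path) -> None:
    """Seed matrix TSV with member count and member list columns."""
    members = m.members or {}
    with open(path, "w") as fh:
        fh.write("#denominator\t\t\t" +
                 "\t".join(str(int(v)) for v in m.denominators) + "\n")
        fh.write("seed\tn_members\tmembers\t" +
                 "\t".join(m.sample_ids) + "\n")
        for seed, row in m.counts.iterrows():
            mem = members.get(seed, [])
            fh.write(f"{seed}\t{len(mem)}\t{';'.join(mem)}\t"
                     + "\t".join(map(str, row.to_list())) + "\n")


def _write_manifest(out_dir, pipeline, cfg, samples, stats_by_sample, result,
                    seed_length, max_mismatch, meta) -> None:
    manifest = {
        "tool": "mirisoform",
        "version": __version__,
        "pipeline": pipeline,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "preprocess_config": dataclasses.asdict(cfg),
        "seed_length": seed_length,
        "max_mismatch": max_mismatch,
        "inputs": {
            str(sid): {"path": str(p), "sha256": _sha256(Path(p))}
            for sid, p in samples
        },
        "conditions": ({m.sample_id: m.condition for m in meta}
                       if meta else None),
        "per_sample_counts": {
            sid: dataclasses.asdict(st) for sid, st in stats_by_sample.items()
        },
        "n_rows_unfiltered": int(result.counts.counts.shape[0]),
        "n_rows_filtered": int(result.filtered.counts.shape[0]),
        "n_seed_groups": (int(result.seed_matrix.counts.shape[0])
                          if result.seed_matrix is not None else None),
    }
    with open(Path(out_dir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
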