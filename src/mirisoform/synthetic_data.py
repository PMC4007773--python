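"""Synthetic small-RNA sequencing cohorts with exact ground truth.

Emulates the read structure a small-RNA library produces: each read is a
mature-miRNA isoform (the miRBase-style entry sequence varied by 5'/3'
offsets within its hairpin and by point substitutions), followed by the 3'
sequencing adapter, padded to the instrument read length, with per-base
Phred scores drawn from a Gaussian quality model. A configurable fraction of
reads comes from a pool of uncharacterized background species (random
sequences rejection-sampled away from the reference). Two condition groups
are generated; per-entry case/control abundance ratios are programmable, so
fold-change recovery can be scored against truth.

Everything is driven by one seeded generator stream: a fixed ``rng_seed``
reproduces the cohort byte-for-byte.

What the generator deliberately does *not* model: position-dependent
Illumina error profiles, PCR duplicates and ligation bias. Passing tests
demonstrate correctness of the counting/annotation machinery under the
stated read structure, not robustness to those artifacts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np

from .annotation import ReferenceSet
from .fastq_io import Read, write_fastq
from .preprocess import TRUSEQ_SMALL_RNA_ADAPTER

_BASES = "ACGT"
BACKGROUND = "__background__"


def _default_offset5() -> dict[int, float]:
    return {-2: 0.05, -1: 0.15, 0: 0.60, 1: 0.15, 2: 0.05}


def _default_offset3() -> dict[int, float]:
    return {-2: 0.10, -1: 0.20, 0: 0.40, 1: 0.20, 2: 0.10}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort generation parameters.

    Defaults describe a 20-sample two-condition cohort (10 vs 10, the
    contrast design of a small patient study), 10^5 reads per sample with
    ~30% log-normal depth variation across samples, ~22 nt mature sequences
    inside ~72 nt hairpins, a 20% uncharacterized background, modest isomiR
    offset spread, a 1% per-base substitution rate and Phred ~N(38, 3) base
    qualities.
    """

    references: Optional[ReferenceSet] = None
    n_hairpins: int = 20
    hairpin_length: int = 72
    mature_length: int = 22
    arm_flank: int = 12
    conditions: tuple[str, str] = ("FA", "FTC")  # (control, case)
    n_samples_per_condition: int = 10
    reads_per_sample: int = 100_000
    library_size_sigma: float = 0.3
    offset5_probs: Mapping[int, float] = field(default_factory=_default_offset5)
    offset3_probs: Mapping[int, float] = field(default_factory=_default_offset3)
    substitution_rate: float = 0.01
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    read_length: int = 50
    quality_mean: float = 38.0
    quality_sd: float = 3.0
    fraction_background: float = 0.2
    n_background_species: int = 50
    fold_changes: Mapping[str, float] = field(default_factory=dict)
    base_abundance: Optional[Mapping[str, float]] = None
    rng_seed: int = 0
    track_provenance: bool = False

    def __post_init__(self) -> None:
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if not (0.0 <= self.fraction_background < 1.0):
            raise ValueError("fraction_background must be in [0, 1)")
        for label, probs in (("offset5", self.offset5_probs),
                             ("offset3", self.offset3_probs)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{label}_probs sum to {total}, not 1")
        max_isoform = (self.mature_length
                       - min(self.offset5_probs)
                       + max(self.offset3_probs))
        if max_isoform > self.read_length:
            raise ValueError(
                f"longest isoform ({max_isoform} nt) exceeds read length "
                f"({self.read_length} nt)")
        if not (0.0 <= self.substitution_rate < 1.0):
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.library_size_sigma < 0:
            raise ValueError("library_size_sigma must be non-negative")


@dataclass
class GroundTruth:
    """Exact description of an emitted cohort.

    ``expected_tallies`` maps each sample to the multiset of insert
    sequences it emitted — exactly what preprocessing + exact counting
    should recover; its per-sample total is that sample's emitted depth
    (``reads_per_sample`` exactly when ``library_size_sigma`` is 0).
    ``expected_fold_changes`` are compositional case/control abundance
    ratios in read-proportion space (the quantity RPM fold changes
    estimate); they differ from the programmed ratios only by the
    renormalization constant of the case mixture.
    """

    sample_conditions: dict[str, str] = field(default_factory=dict)
    expected_tallies: dict[str, Counter] = field(default_factory=dict)
    entry_read_counts: dict[str, Counter] = field(default_factory=dict)
    programmed_fold_changes: dict[str, float] = field(default_factory=dict)
    expected_fold_changes: dict[str, float] = field(default_factory=dict)
    source_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    provenance: dict[str, list] = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, length))


@dataclass(frozen=True)
class _Locus:
    """Placement of a mature arm inside its hairpin."""

    mature_name: str
    hairpin_name: str
    start: int
    end: int


def generate_reference(cfg: SimulationConfig,
                       rng: np.random.Generator) -> tuple[ReferenceSet, dict]:
    """Random hairpins with embedded 5p/3p mature arms, plus arm placements."""
    mature: dict[str, str] = {}
    hairpins: dict[str, str] = {}
    loci: dict[str, _Locus] = {}
    for i in range(cfg.n_hairpins):
        hp_name = f"syn-mir-{i + 1:03d}"
        hp = _random_dna(rng, cfg.hairpin_length)
        hairpins[hp_name] = hp
        s5 = cfg.arm_flank
        e5 = s5 + cfg.mature_length
        s3 = cfg.hairpin_length - cfg.arm_flank - cfg.mature_length
        e3 = s3 + cfg.mature_length
        for arm, (s, e) in (("5p", (s5, e5)), ("3p", (s3, e3))):
            name = f"syn-miR-{i + 1:03d}-{arm}"
            mature[name] = hp[s:e]
            loci[name] = _Locus(name, hp_name, s, e)
    return ReferenceSet(mature, hairpins, version_label="synthetic"), loci


def _locate_in_hairpins(ref: ReferenceSet) -> dict:
    """Place user-supplied mature entries inside their hairpins (exact find)."""
    loci: dict[str, _Locus] = {}
    for name, entry in ref.mature.items():
        for hp_name, hp in ref.hairpins.items():
            pos = hp.find(entry)
            if pos >= 0:
                loci[name] = _Locus(name, hp_name, pos, pos + len(entry))
                break
    return loci


def _background_pool(cfg: SimulationConfig, ref: ReferenceSet,
                     rng: np.random.Generator) -> list[str]:
    """Random 15-27 nt species rejection-sampled away from the reference."""
    pool: list[str] = []
    seen: set[str] = set()
    hairpin_seqs = list(ref.hairpins.values())
    mature_seqs = list(ref.mature.values())
    while len(pool) < cfg.n_background_species:
        seq = _random_dna(rng, int(rng.integers(15, 28)))
        if seq in seen:
            continue
        if any(seq in hp for hp in hairpin_seqs):
            continue
        if any(m in seq or seq in m for m in mature_seqs):
            continue
        seen.add(seq)
        pool.append(seq)
    return pool


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


class CohortSimulation:
    """Deterministic cohort generator; samples are produced on demand.

    Usage::

        sim = CohortSimulation(cfg)
        for sample_id, condition, reads in sim.iter_samples():
            ...
        truth = sim.ground_truth   # complete once iteration finishes
    """

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.rng_seed)
        if cfg.references is not None:
            self.reference = cfg.references
            self.loci = _locate_in_hairpins(cfg.references)
        else:
            self.reference, self.loci = generate_reference(cfg, self.rng)
        self._check_offsets_feasible()
        self.background = (_background_pool(cfg, self.reference, self.rng)
                           if cfg.fraction_background > 0 else [])
        self.entry_names = list(self.reference.mature)
        self._build_mixtures()
        self.ground_truth = GroundTruth(
            programmed_fold_changes=dict(cfg.fold_changes),
            expected_fold_changes=self._expected_fold_changes(),
            source_probs={c: dict(zip(self.entry_names, p))
                          for c, p in self._entry_probs.items()},
        )

    # -- mixture construction -------------------------------------------------

    def _check_offsets_feasible(self) -> None:
        cfg = self.cfg
        needs_context = min(cfg.offset5_probs) < 0 or max(cfg.offset3_probs) > 0
        if not needs_context:
            return
        missing = [n for n in self.reference.mature if n not in self.loci]
        if missing:
            raise ValueError(
                "offset distributions extend beyond the mature sequence but "
                f"these entries have no hairpin context: {missing}")

    def _build_mixtures(self) -> None:
        cfg = self.cfg
        n = len(self.entry_names)
        if cfg.base_abundance is not None:
            base = np.array([cfg.base_abundance[e] for e in self.entry_names],
                            dtype=float)
            base = base / base.sum()
        else:
            base = _zipf_weights(n)
            # decouple abundance rank from name order
            self.rng.shuffle(base)
        control, case = cfg.conditions
        fc = np.array([cfg.fold_changes.get(e, 1.0) for e in self.entry_names])
        self._entry_probs = {
            control: base / base.sum(),
            case: (base * fc) / (base * fc).sum(),
        }
        self._background_probs = (_zipf_weights(len(self.background))
                                  if self.background else np.array([]))

    def _expected_fold_changes(self) -> dict[str, float]:
        control, case = self.cfg.conditions
        pc, pk = self._entry_probs[control], self._entry_probs[case]
        return {e: float(pk[i] / pc[i])
                for i, e in enumerate(self.entry_names)}

    # -- read emission --------------------------------------------------------

    def _isoform(self, entry: str, off5: int, off3: int) -> str:
        locus = self.loci.get(entry)
        if locus is None:
            seq = self.reference.mature[entry]
            return seq[-off5 if off5 > 0 else 0:
                       len(seq) + off3 if off3 < 0 else len(seq)]
        hp = self.reference.hairpins[locus.hairpin_name]
        return hp[locus.start + off5:locus.end + off3]

    def _mutate(self, seq: str, n_subs: int) -> str:
        positions = self.rng.choice(len(seq), size=n_subs, replace=False)
        chars = list(seq)
        for pos in positions:
            current = chars[pos]
            choices = [b for b in _BASES if b != current]
            chars[pos] = choices[int(self.rng.integers(0, 3))]
        return "".join(chars)

    def _sample_ids(self) -> list[tuple[str, str]]:
        control, case = self.cfg.conditions
        ids = []
        for cond in (control, case):
            for i in range(self.cfg.n_samples_per_condition):
                ids.append((f"{cond}_{i + 1:02d}", cond))
        return ids

    def iter_samples(self) -> Iterator[tuple[str, str, list[Read]]]:
        cfg = self.cfg
        for sample_id, condition in self._sample_ids():
            reads = self._emit_sample(sample_id, condition)
            yield sample_id, condition, reads

    def _emit_sample(self, sample_id: str, condition: str) -> list[Read]:
        cfg, rng = self.cfg, self.rng
        # per-sample depth: log-normal around reads_per_sample (mean-preserving)
        if cfg.library_size_sigma > 0:
            sigma = cfg.library_size_sigma
            n = max(1, int(round(cfg.reads_per_sample
                                 * np.exp(rng.normal(0.0, sigma)
                                          - sigma ** 2 / 2))))
        else:
            n = cfg.reads_per_sample
        entry_p = self._entry_probs[condition] * (1.0 - cfg.fraction_background)
        bg_p = self._background_probs * cfg.fraction_background
        probs = np.concatenate([entry_p, bg_p])
        source_counts = rng.multinomial(n, probs)
        off5_vals = np.array(list(cfg.offset5_probs))
        off5_p = np.array(list(cfg.offset5_probs.values()))
        off3_vals = np.array(list(cfg.offset3_probs))
        off3_p = np.array(list(cfg.offset3_probs.values()))

        qmat = np.clip(
            np.rint(rng.normal(cfg.quality_mean, cfg.quality_sd,
                               (n, cfg.read_length))), 2, 41
        ).astype(np.int64)
        pad_pool = _random_dna(rng, 2 * cfg.read_length)

        tally: Counter = Counter()
        entry_counts: Counter = Counter()
        provenance: list = []
        inserts: list[str] = []
        isoform_cache: dict[tuple[str, int, int], str] = {}

        n_entries = len(self.entry_names)
        for src_idx, count in enumerate(source_counts):
            if count == 0:
                continue
            if src_idx < n_entries:
                entry = self.entry_names[src_idx]
                entry_counts[entry] += int(count)
                offs5 = rng.choice(off5_vals, size=count, p=off5_p)
                offs3 = rng.choice(off3_vals, size=count, p=off3_p)
                bases = []
                for j in range(count):
                    key = (entry, int(offs5[j]), int(offs3[j]))
                    base = isoform_cache.get(key)
                    if base is None:
                        base = self._isoform(*key)
                        isoform_cache[key] = base
                    bases.append(base)
                if cfg.substitution_rate > 0:
                    n_subs_arr = rng.binomial(
                        np.array([len(b) for b in bases]),
                        cfg.substitution_rate)
                else:
                    n_subs_arr = np.zeros(count, dtype=int)
                for j, base in enumerate(bases):
                    n_subs = int(n_subs_arr[j])
                    insert = self._mutate(base, n_subs) if n_subs else base
                    inserts.append(insert)
                    if cfg.track_provenance:
                        provenance.append(
                            (entry, int(offs5[j]), int(offs3[j]), n_subs))
            else:
                species = self.background[src_idx - n_entries]
                entry_counts[BACKGROUND] += int(count)
                for _ in range(count):
                    inserts.append(species)
                    if cfg.track_provenance:
                        provenance.append((BACKGROUND, 0, 0, 0))

        # interleave sources deterministically so file order is not blocked
        order = rng.permutation(len(inserts))
        reads: list[Read] = []
        for rank, idx in enumerate(order):
            insert = inserts[idx]
            tally[insert] += 1
            full = insert + cfg.adapter
            if len(full) < cfg.read_length:
                full += pad_pool[:cfg.read_length - len(full)]
            else:
                full = full[:cfg.read_length]
            reads.append(Read(f"{sample_id}_r{rank}", full,
                              tuple(qmat[rank, :len(full)].tolist())))

        self.ground_truth.sample_conditions[sample_id] = condition
        self.ground_truth.expected_tallies[sample_id] = tally
        self.ground_truth.entry_read_counts[sample_id] = entry_counts
        if cfg.track_provenance:
            self.ground_truth.provenance[sample_id] = [
                provenance[idx] for idx in order]
        return reads


def simulate_cohort(cfg: SimulationConfig, out_dir: str | Path
                    ) -> tuple[GroundTruth, dict[str, Path]]:
    """Write a full synthetic cohort to ``out_dir`` and return its truth.

    Emits one ``<sample>.fastq.gz`` per sample, ``mature.fa`` and
    ``hairpin.fa`` references, a ``samples.tsv`` sheet (seed recorded in its
    header) and ``ground_truth.tsv`` with per-sample source read counts.
    Deterministic given ``cfg.rng_seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = CohortSimulation(cfg)
    paths: dict[str, Path] = {}
    sheet_rows = []
    for sample_id, condition, reads in sim.iter_samples():
        fq = out_dir / f"{sample_id}.fastq.gz"
        write_fastq(reads, fq)
        paths[sample_id] = fq
        sheet_rows.append((sample_id, condition, fq.name))

    with open(out_dir / "mature.fa", "w") as fh:
        for name, seq in sim.reference.mature.items():
            fh.write(f">{name}\n{seq}\n")
    with open(out_dir / "hairpin.fa", "w") as fh:
        for name, seq in sim.reference.hairpins.items():
            fh.write(f">{name}\n{seq}\n")

    with open(out_dir / "samples.tsv", "w") as fh:
        fh.write(f"# rng_seed={cfg.rng_seed}\n")
        fh.write("sample_id\tcondition\tfastq\n")
        for row in sheet_rows:
            fh.write("\t".join(row) + "\n")

    truth = sim.ground_truth
    sources = sorted({s for c in truth.entry_read_counts.values() for s in c})
    with open(out_dir / "ground_truth.tsv", "w") as fh:
        samples = list(truth.entry_read_counts)
        fh.write("source\texpected_fold_change\t" + "\t".join(samples) + "\n")
        for src in sources:
            fc = truth.expected_fold_changes.get(src, float("nan"))
            row = [str(truth.entry_read_counts[s].get(src, 0))
                   for s in samples]
            fh.write(f"{src}\t{fc:.6g}\t" + "\t".join(row) + "\n")
    return truth, paths


# ---------------------------------------------------------------------------
# miR-30-style ambiguity fixture

#: Real entry sequences (DNA form) for hsa-miR-30e/a/d-5p; the "30c" slot is
#: a synthetic 4-substitution variant of 30e-5p so the family realizes
#: pairwise Hamming distances {1, 2, 4} from the 30e anchor without the
#: length heterogeneity of the genuine 30c entry.
MIR30_FAMILY: dict[str, str] = {
    "hsa-miR-30e-5p": "TGTAAACATCCTTGACTGGAAG",
    "hsa-miR-30a-5p": "TGTAAACATCCTCGACTGGAAG",
    "hsa-miR-30d-5p": "TGTAAACATCCCCGACTGGAAG",
    "syn-miR-30c-5p": "TGTAAACATCCTAGGCTTGCAG",
}

#: Programmed family read ratio 30e : 30d : 30a = 1 : 2 : 7.
MIR30_RATIO: dict[str, float] = {
    "hsa-miR-30e-5p": 1 / 10,
    "hsa-miR-30d-5p": 2 / 10,
    "hsa-miR-30a-5p": 7 / 10,
}


def make_mir30_fixture(
    n_reads: int = 2000, seed: int = 0,
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER, read_length: int = 50,
) -> tuple[ReferenceSet, list[Read], dict[str, float]]:
    """A 4-member miR-30-like family plus reads at a programmed 1:2:7 ratio.

    The family's entry sequences sit at Hamming distances 1 (30a), 2 (30d)
    and 4 (synthetic 30c) from the 30e anchor, recreating the annotation
    ambiguity of heavily overlapping mature families. Reads are error-free
    entry-sequence inserts with adapter, drawn multinomially from
    30e : 30d : 30a = 1 : 2 : 7.
    """
    rng = np.random.default_rng(seed)
    hairpins = {}
    for name, entry in MIR30_FAMILY.items():
        flank5, flank3 = _random_dna(rng, 15), _random_dna(rng, 15)
        hairpins[name.replace("miR", "mir") + "-hp"] = flank5 + entry + flank3
    ref = ReferenceSet(dict(MIR30_FAMILY), hairpins,
                       version_label="synthetic miR-30-like fixture")
    names = list(MIR30_RATIO)
    probs = np.array([MIR30_RATIO[n] for n in names])
    counts = rng.multinomial(n_reads, probs)
    reads: list[Read] = []
    i = 0
    for name, count in zip(names, counts):
        insert = MIR30_FAMILY[name]
        full = (insert + adapter)[:read_length]
        if len(full) < read_length:
            full += _random_dna(rng, read_length - len(full))
        quals = tuple([40] * len(full))
        for _ in range(count):
            reads.append(Read(f"mir30_r{i}", full, quals))
            i += 1
    order = rng.permutation(len(reads))
    return ref, [reads[j] for j in order], dict(MIR30_RATIO)
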