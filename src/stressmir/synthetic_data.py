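"""Seeded generator of a miniature flax-like stress miRNA-seq study.

Emulates the four-condition design (CK control; AS alkaline, AS2
alkaline-salt, NSS neutral-salt stress): a small random genome with planted
known-miRNA precursor hairpins and novel hairpin loci, four small-RNA
libraries with planted per-condition fold changes, a degradome library with
tag bursts at planted cleavage positions, transcript-level direction calls
inverse to each planted target's miRNA, and a qPCR Ct table consistent with
the planted fold factors.  Every planted entity is recorded in a
:class:`GroundTruth` so each pipeline stage can be scored against it.

Determinism: every output stream derives its own RNG from the master seed
and a stable label hash, so regenerating one file never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    SequenceRecord,
    revcomp,
    to_dna,
    to_rna,
    write_fasta,
    write_fastq,
    write_gff3,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CapacityError",
    "generate_genome",
    "generate_srna_libraries",
    "generate_degradome",
    "generate_dge_calls",
    "generate_qpcr",
    "generate_dataset",
]

# 3' adapter of small-RNA library preps (Illumina TruSeq small RNA prefix).
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

# Read-length mixture for background small RNAs, modes at 21 and 24 nt.
_LENGTHS = np.arange(18, 31)
_LENGTH_PROBS = np.array(
    [0.03, 0.04, 0.07, 0.22, 0.09, 0.08, 0.20, 0.08, 0.06, 0.05, 0.04, 0.02, 0.02]
)

_FAMILIES = [156, 159, 160, 162, 164, 166, 167, 168, 169, 171, 172, 319,
             390, 393, 394, 395, 396, 397, 398, 399, 408, 530, 828]


class CapacityError(ValueError):
    """Planted loci do not fit into the configured genome length."""


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 30000
    n_known_mirnas: int = 20
    n_novel_loci: int = 5
    n_transcripts: int = 30
    transcript_length: int = 400
    library_labels: tuple[str, ...] = ("CK", "AS", "AS2", "NSS")
    library_depth: int = 10000
    mature_len: int = 21
    loop_len: int = 12
    star_mismatches: int = 2
    # fraction of each library's reads budgeted to known-miRNA loci
    known_fraction: float = 0.5
    novel_mature_mean: float = 60.0
    novel_star_mean: float = 10.0
    # NB dispersion phi: var = mu + phi * mu^2; 0 degenerates to Poisson
    dispersion: float = 0.01
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 49
    # planted differential expression (multiplicative vs CK)
    n_paired_de: int = 6       # DE miRNAs that also get a cleavage-validated target
    n_unpaired_de: int = 4     # DE miRNAs without a planted target
    up_factor: float = 4.0
    down_factor: float = 0.25
    # fraction of miRNA species whose mature starts with U
    u5_fraction: float = 0.85
    # degradome
    degradome_burst: int = 50
    degradome_background: int = 200
    # explicit overrides (None -> planted automatically as described above)
    planted_fold_changes: dict | None = None
    planted_cleavage: list | None = None

    def __post_init__(self) -> None:
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if self.planted_fold_changes:
            for factors in self.planted_fold_changes.values():
                if any(f <= 0 for f in factors.values()):
                    raise ValueError("fold factors must be positive")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(l for l in self.library_labels[1:])

    @property
    def control(self) -> str:
        return self.library_labels[0]


@dataclass
class KnownLocus:
    name: str
    family: str
    mature: str            # RNA
    precursor: str         # RNA
    mature_start: int      # 1-based within precursor
    genome_start: int      # 1-based, + strand
    genome_end: int


@dataclass
class NovelLocus:
    name: str
    mature: str            # RNA
    star: str              # RNA, the 2-nt-3'-overhang star read sequence
    genome_start: int      # 1-based hairpin start, + strand
    genome_end: int
    mature_genome_start: int
    star_genome_start: int


@dataclass
class GroundTruth:
    genome_seq: str = ""
    known: list[KnownLocus] = field(default_factory=list)
    novel: list[NovelLocus] = field(default_factory=list)
    transcripts: dict[str, str] = field(default_factory=dict)  # id -> DNA seq
    # mirna name -> condition -> multiplicative factor vs control
    fold_factors: dict[str, dict[str, float]] = field(default_factory=dict)
    # mirna name -> condition -> "Up"/"Down"/None
    directions: dict[str, dict[str, str | None]] = field(default_factory=dict)
    # mirna name -> library -> expected read count
    expected_counts: dict[str, dict[str, float]] = field(default_factory=dict)
    # planted cleavage sites: (mirna, transcript, 1-based position, burst)
    cleavage: list[tuple[str, str, int, int]] = field(default_factory=list)
    # planted inverse pairs: (mirna, transcript)
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _stream_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _nb_draw(rng: np.random.Generator, mean: float, phi: float) -> int:
    """Over-dispersed count: gamma-Poisson with var = mu + phi mu^2."""
    if mean <= 0:
        return 0
    if phi <= 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return int(rng.poisson(lam))


def _random_mature(rng: np.random.Generator, length: int, force_u: bool) -> str:
    """Random RNA mature with roughly balanced GC (stable hairpin stems)."""
    bases = np.array(list("ACGU"))
    while True:
        seq = "".join(rng.choice(bases, size=length))
        if force_u:
            seq = "U" + seq[1:]
        gc = sum(seq.count(b) for b in "GC")
        if 0.40 <= gc / length <= 0.62:
            return seq


def _star_arm(rng: np.random.Generator, mature: str, k: int) -> str:
    """Reverse complement of the mature with k interior substitutions."""
    arm = list(to_rna(revcomp(to_dna(mature))))
    if k > 0:
        positions = rng.choice(np.arange(4, len(arm) - 4), size=k, replace=False)
        for p in positions:
            arm[p] = rng.choice([b for b in "ACGU" if b != arm[p]])
    return "".join(arm)


def _plant_fold_factors(cfg: SimulationConfig, names: list[str],
                        rng: np.random.Generator) -> dict[str, dict[str, float]]:
    if cfg.planted_fold_changes is not None:
        return {
            n: {c: cfg.planted_fold_changes.get(n, {}).get(c, 1.0)
                for c in cfg.conditions}
            for n in names
        }
    factors: dict[str, dict[str, float]] = {}
    for i, name in enumerate(names):
        if i < cfg.n_paired_de:
            # target-paired miRNAs move in every condition
            factors[name] = {
                c: float(rng.choice([cfg.up_factor, cfg.down_factor]))
                for c in cfg.conditions
            }
        elif i < cfg.n_paired_de + cfg.n_unpaired_de:
            cond = cfg.conditions[i % len(cfg.conditions)]
            factors[name] = {
                c: float(rng.choice([cfg.up_factor, cfg.down_factor]))
                if c == cond else 1.0
                for c in cfg.conditions
            }
        else:
            factors[name] = {c: 1.0 for c in cfg.conditions}
    return factors


def generate_genome(cfg: SimulationConfig) -> tuple[SequenceRecord, GroundTruth]:
    """Random genome with planted known precursors and novel hairpin loci.

    Hairpins are (mature)(loop)(reverse-complement-of-mature-with-k-
    mismatches) so that folding recovers a stem-loop; two extra downstream
    nucleotides give the star read its 2-nt 3' overhang.
    """
    rng = _stream_rng(cfg.seed, "genome")
    L = cfg.mature_len
    pad = 5
    known_span = pad + L + cfg.loop_len + L + pad
    novel_span = L + cfg.loop_len + L + 2
    n_loci = cfg.n_known_mirnas + cfg.n_novel_loci
    spacing = 600
    if n_loci and (max(known_span, novel_span) + spacing) * n_loci > cfg.genome_length:
        raise CapacityError(
            f"{n_loci} loci need more than {cfg.genome_length} nt of genome"
        )

    genome = list("".join(_stream_rng(cfg.seed, "background").choice(
        np.array(list("ACGT")), size=cfg.genome_length)))

    truth = GroundTruth()
    slot = cfg.genome_length // max(n_loci, 1)
    order = rng.permutation(n_loci) if n_loci else np.array([], dtype=int)

    fams = list(_FAMILIES)
    n_u5 = round(cfg.u5_fraction * cfg.n_known_mirnas)
    loci: list[tuple[str, object]] = []
    for i in range(cfg.n_known_mirnas):
        fam = fams[i % len(fams)]
        letter = chr(ord("a") + i // len(fams))
        name = f"lus-miR{fam}{letter}"
        mature = _random_mature(rng, L, force_u=i < n_u5)
        arm = _star_arm(rng, mature, cfg.star_mismatches)
        pad5 = "".join(rng.choice(np.array(list("ACGU")), size=pad))
        pad3 = "".join(rng.choice(np.array(list("ACGU")), size=pad))
        precursor = pad5 + mature + "".join(
            rng.choice(np.array(list("ACGU")), size=cfg.loop_len)) + arm + pad3
        loci.append(("known", (name, fam, mature, precursor)))
    for j in range(cfg.n_novel_loci):
        mature = _random_mature(rng, L, force_u=True)
        arm = _star_arm(rng, mature, cfg.star_mismatches)
        loop = "".join(rng.choice(np.array(list("ACGU")), size=cfg.loop_len))
        loci.append(("novel", (f"planted_novel_{j + 1}", mature, loop, arm)))

    for idx, (kind, payload) in enumerate(loci):
        slot_i = int(order[idx])
        span = known_span if kind == "known" else novel_span
        offset = slot_i * slot + int(rng.integers(0, max(slot - span, 1)))
        if kind == "known":
            name, fam, mature, precursor = payload
            dna = to_dna(precursor)
            genome[offset:offset + len(dna)] = list(dna)
            truth.known.append(KnownLocus(
                name=name, family=f"miR{fam}", mature=mature,
                precursor=precursor, mature_start=pad + 1,
                genome_start=offset + 1, genome_end=offset + len(dna),
            ))
        else:
            name, mature, loop, arm = payload
            hairpin = to_dna(mature + loop + arm)
            genome[offset:offset + len(hairpin)] = list(hairpin)
            arm_start0 = offset + L + cfg.loop_len
            # star read: arm shifted +2, the canonical 2-nt 3' overhang
            star_dna = "".join(genome[arm_start0 + 2:arm_start0 + 2 + L])
            truth.novel.append(NovelLocus(
                name=name, mature=mature, star=to_rna(star_dna),
                genome_start=offset + 1, genome_end=offset + len(hairpin) + 2,
                mature_genome_start=offset + 1,
                star_genome_start=arm_start0 + 3,
            ))

    truth.known.sort(key=lambda k: k.genome_start)
    truth.novel.sort(key=lambda n: n.genome_start)

    names = [k.name for k in truth.known]
    fold_rng = _stream_rng(cfg.seed, "fold")
    truth.fold_factors = _plant_fold_factors(cfg, names, fold_rng)
    truth.directions = {
        n: {c: ("Up" if f > 1 else "Down" if f < 1 else None)
            for c, f in facs.items()}
        for n, facs in truth.fold_factors.items()
    }

    # transcripts, with the reverse-complement target site of each paired
    # miRNA inserted so the cleavage position is known exactly
    trng = _stream_rng(cfg.seed, "transcripts")
    paired = names[:cfg.n_paired_de]
    mature_by_name = {k.name: k.mature for k in truth.known}
    for t in range(cfg.n_transcripts):
        tid = f"Lus{10000000 + t + 1}"
        seq = list("".join(trng.choice(np.array(list("ACGT")),
                                       size=cfg.transcript_length)))
        if t < len(paired):
            mirna = paired[t]
            site = revcomp(to_dna(mature_by_name[mirna]))
            offset = int(trng.integers(60, cfg.transcript_length - 60 - L))
            seq[offset:offset + L] = list(site)
            pos = offset + L - 9  # transcript nt paired with miRNA position 10
            truth.cleavage.append((mirna, tid, pos, cfg.degradome_burst))
            truth.pairs.append((mirna, tid))
        truth.transcripts[tid] = "".join(seq)

    if cfg.planted_cleavage is not None:
        truth.cleavage = [tuple(c) for c in cfg.planted_cleavage]
        truth.pairs = [(m, t) for m, t, *_ in truth.cleavage]
    for _, tid, pos, _ in truth.cleavage:
        if pos < 1 or pos + 20 > len(truth.transcripts[tid]):
            raise ValueError(f"cleavage position {pos} outside transcript {tid}")

    truth.genome_seq = "".join(genome)
    return SequenceRecord(id="chr1", seq=truth.genome_seq), truth


def generate_srna_libraries(cfg: SimulationConfig, truth: GroundTruth
                            ) -> dict[str, list[SequenceRecord]]:
    """One read list per library with planted abundances and fold changes.

    Reads are exact locus substrings (mostly the mature, some 1-nt-shifted
    isomiRs, plus novel-locus star reads) with the 3' adapter appended and
    the whole read capped at the instrument read length; the remainder of
    each library is random genome windows with the 21/24-nt modal length mix.
    """
    weights_rng = _stream_rng(cfg.seed, "abundance")
    w = weights_rng.lognormal(mean=0.0, sigma=0.6, size=cfg.n_known_mirnas)
    budget = cfg.known_fraction * cfg.library_depth
    baselines = {k.name: budget * wi / w.sum()
                 for k, wi in zip(truth.known, w)}

    libraries: dict[str, list[SequenceRecord]] = {}
    for label in cfg.library_labels:
        rng = _stream_rng(cfg.seed, f"library:{label}")
        reads: list[str] = []
        for locus in truth.known:
            factor = 1.0 if label == cfg.control else \
                truth.fold_factors[locus.name].get(label, 1.0)
            mean = baselines[locus.name] * factor
            truth.expected_counts.setdefault(locus.name, {})[label] = mean
            n = _nb_draw(rng, mean, cfg.dispersion)
            n_exact = int(rng.binomial(n, 0.8)) if n else 0
            reads.extend([to_dna(locus.mature)] * n_exact)
            for _ in range(n - n_exact):
                shift = int(rng.choice([-1, 1]))
                s0 = locus.mature_start - 1 + shift
                reads.append(to_dna(locus.precursor[s0:s0 + cfg.mature_len]))
        for locus in truth.novel:
            n_m = _nb_draw(rng, cfg.novel_mature_mean, cfg.dispersion)
            n_s = _nb_draw(rng, cfg.novel_star_mean, cfg.dispersion)
            reads.extend([to_dna(locus.mature)] * n_m)
            reads.extend([to_dna(locus.star)] * n_s)

        n_background = max(cfg.library_depth - len(reads), 0)
        reads.extend(_background_reads(cfg, truth, rng, n_background))
        rng.shuffle(reads)
        records = []
        for i, insert in enumerate(reads):
            full = (insert + cfg.adapter)
            if len(full) < cfg.read_length:
                fill = "".join(rng.choice(np.array(list("ACGT")),
                                          size=cfg.read_length - len(full)))
                full += fill
            records.append(SequenceRecord(
                id=f"{label}_read_{i + 1}", seq=full[:cfg.read_length],
                qual="I" * min(len(full), cfg.read_length)))
        libraries[label] = records
    return libraries


def _background_reads(cfg: SimulationConfig, truth: GroundTruth,
                      rng: np.random.Generator, n: int) -> list[str]:
    genome = truth.genome_seq
    lengths = rng.choice(_LENGTHS, size=n, p=_LENGTH_PROBS)
    starts = rng.integers(0, cfg.genome_length - 31, size=n)
    strands = rng.random(n) < 0.5
    out = []
    for ln, st, minus in zip(lengths, starts, strands):
        frag = genome[st:st + ln]
        out.append(revcomp(frag) if minus else frag)
    return out


def generate_degradome(cfg: SimulationConfig, truth: GroundTruth
                       ) -> list[SequenceRecord]:
    """Degradome 5'-tag FASTA: planted bursts plus count-1 background.

    Each planted cleavage (m, t, p) yields a burst of 20-21 nt tags whose 5'
    ends all sit exactly at p; background tags are placed at distinct
    positions so every unplanted occupied position has raw count 1.
    """
    rng = _stream_rng(cfg.seed, "degradome")
    tags: list[str] = []
    planted_positions = set()
    for mirna, tid, pos, burst in truth.cleavage:
        tx = truth.transcripts[tid]
        if pos < 1 or pos - 1 + 20 > len(tx):
            raise ValueError(f"cleavage position {pos} outside {tid}")
        planted_positions.add((tid, pos))
        for b in range(burst):
            ln = 20 if b % 2 == 0 else 21
            if pos - 1 + ln > len(tx):
                ln = 20
            tags.append(tx[pos - 1:pos - 1 + ln])

    tids = list(truth.transcripts)
    seen = set(planted_positions)
    attempts = 0
    while len(seen) < len(planted_positions) + cfg.degradome_background:
        attempts += 1
        if attempts > 50 * cfg.degradome_background:
            break
        tid = tids[int(rng.integers(len(tids)))]
        tx = truth.transcripts[tid]
        pos = int(rng.integers(1, len(tx) - 21 + 1))
        if (tid, pos) in seen:
            continue
        seen.add((tid, pos))
        ln = int(rng.choice([20, 21]))
        tags.append(tx[pos - 1:pos - 1 + ln])

    return [SequenceRecord(id=f"deg_{i + 1}", seq=t) for i, t in enumerate(tags)]


def generate_dge_calls(cfg: SimulationConfig, truth: GroundTruth) -> "pd.DataFrame":
    """Transcript direction calls per condition (TSV schema).

    Planted target transcripts are called inverse to their miRNA's planted
    direction in every condition; all other transcripts are random.
    """
    import pandas as pd

    rng = _stream_rng(cfg.seed, "dge")
    target_of = {tid: m for m, tid in truth.pairs}
    rows = []
    for tid in truth.transcripts:
        if tid in target_of:
            dirs = truth.directions[target_of[tid]]
            row = {c: ("Down" if dirs[c] == "Up" else "Up")
                   for c in cfg.conditions}
        else:
            row = {c: str(rng.choice(["Up", "Down"])) for c in cfg.conditions}
        rows.append({"transcript": tid, **row})
    return pd.DataFrame(rows).set_index("transcript")


def generate_qpcr(cfg: SimulationConfig, truth: GroundTruth,
                  n_replicates: int = 3) -> "pd.DataFrame":
    """Stem-loop qPCR Ct table consistent with the planted fold factors.

    U6-style reference held at Ct 18; the target Ct in each stressed sample
    is shifted by -log2(fold factor) from the control so that 2^-ddCt
    recovers the planted factor exactly.
    """
    import pandas as pd

    rows = []
    base_ct = 25.0
    assayed = [n for n, facs in truth.fold_factors.items()
               if all(f != 1.0 for f in facs.values())]
    for name in assayed:
        for label in cfg.library_labels:
            factor = 1.0 if label == cfg.control else \
                truth.fold_factors[name].get(label, 1.0)
            ct_t = base_ct - float(np.log2(factor))
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "mirna": name, "sample": label, "replicate": rep,
                    "ct_target": round(ct_t, 4), "ct_reference": 18.0,
                })
    return pd.DataFrame(rows)


def generate_dataset(cfg: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Generate and write the full dataset; returns the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, truth = generate_genome(cfg)
    write_fasta([genome], outdir / "genome.fa")

    features = [
        {"seqid": "chr1", "type": "miRNA_primary_transcript",
         "start": k.genome_start, "end": k.genome_end, "strand": "+",
         "attributes": {"ID": k.name, "class": "known"}}
        for k in truth.known
    ] + [
        {"seqid": "chr1", "type": "miRNA_primary_transcript",
         "start": n.genome_start, "end": n.genome_end, "strand": "+",
         "attributes": {"ID": n.name, "class": "novel"}}
        for n in truth.novel
    ]
    write_gff3(features, outdir / "loci.gff3")

    write_fasta(
        [SequenceRecord(id=k.name, seq=k.mature, description="mature")
         for k in truth.known],
        outdir / "mature.fa")
    write_fasta(
        [SequenceRecord(id=k.name, seq=k.precursor, description="precursor")
         for k in truth.known],
        outdir / "hairpin.fa")
    write_fasta(
        [SequenceRecord(id=tid, seq=seq) for tid, seq in truth.transcripts.items()],
        outdir / "transcripts.fa")

    libraries = generate_srna_libraries(cfg, truth)
    for label, records in libraries.items():
        write_fastq(records, outdir / f"{label}.fastq.gz")

    write_fasta(generate_degradome(cfg, truth), outdir / "degradome.fa")
    generate_dge_calls(cfg, truth).to_csv(outdir / "dge_calls.tsv", sep="\t")
    generate_qpcr(cfg, truth).to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json())
    return truth
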