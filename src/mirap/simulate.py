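"""Monte-Carlo sRNA-seq library simulator with ground truth.

The simulator plays two roles. First, it regenerates an artificial
evaluation dataset of 778,072 adapter-free reads drawn from the major small
RNA classes — miRNA (39.7%), rRNA (29.3%), tRNA (12.6%), snoRNA (10.1%) and
an 8.3% remainder of random-sequence reads — with a small fraction of reads
carrying random substitutions. Second, it produces adapter-ligated
libraries (insert + 3' adapter, read-through model, truncated at the
instrument read length) for exercising adapter inference and trimming.

Every read's true class, source molecule and the per-mature-miRNA true
counts are returned as :class:`GroundTruth`, so recovery of the simulated
signal can be measured exactly.

Class counts are allocated by largest-remainder rounding, not multinomial
draws, so the composition targets are hit exactly; all remaining randomness
flows from a single seeded ``numpy`` generator, making output byte-identical
across reruns with the same seed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .fastq_io import MirnaAnnotation, ReadRecord

logger = logging.getLogger("mirap")

#: Class composition of the artificial evaluation dataset. The four named
#: small-RNA classes sum to 91.7%; the remaining 8.3% ("other") stands in
#: for unlisted species as random-sequence reads.
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "miRNA": 0.397,
    "rRNA": 0.293,
    "tRNA": 0.126,
    "snoRNA": 0.101,
    "other": 0.083,
}

#: Total read count of the artificial evaluation dataset.
ARTIFICIAL_DATASET_N_READS = 778_072

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Parameters of one simulated library.

    ``mismatch_read_fraction`` of reads receive ``mismatches_per_read``
    uniform random substitutions (sequencing-error model). When ``adapter``
    is ``None`` reads are emitted at their insert length (the artificial
    dataset is adapter-free); otherwise each read is insert + adapter,
    padded with random bases and truncated to ``read_length``.
    """

    n_reads: int = ARTIFICIAL_DATASET_N_READS
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    adapter: str | None = None
    read_length: int = 50
    mismatch_read_fraction: float = 0.02
    mismatches_per_read: int = 1
    low_quality_tail_prob: float = 0.0
    expression_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        fracs = list(self.class_fractions.values())
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {sum(fracs)})")


@dataclass
class GroundTruth:
    """Per-read truth plus per-mature-miRNA true counts for one library."""

    read_class: dict[str, str] = field(default_factory=dict)
    read_source: dict[str, str] = field(default_factory=dict)
    class_counts: Counter = field(default_factory=Counter)
    mirna_counts: Counter = field(default_factory=Counter)


def allocate_largest_remainder(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Split ``n`` into integer class counts hitting ``fractions`` exactly.

    Each class gets the floor of its ideal share; leftover units go to the
    classes with the largest fractional parts (ties broken by insertion
    order). Deterministic, and counts always sum to ``n``.
    """
    ideal = {c: n * f for c, f in fractions.items()}
    counts = {c: int(v) for c, v in ideal.items()}
    leftover = n - sum(counts.values())
    order = sorted(
        fractions, key=lambda c: ideal[c] - counts[c], reverse=True
    )
    for c in order[:leftover]:
        counts[c] += 1
    return counts


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def build_reference_pool(
    n_mirna: int = 50, n_other_per_class: int = 30, seed: int = 0
) -> tuple[MirnaAnnotation, dict[str, dict[str, str]]]:
    """Generate a synthetic reference: miRNA hairpins plus other-class pools.

    Hairpins are random 60–90 nt sequences, each carrying one or two
    embedded matures of 20–23 nt (a 5p arm and, for half the hairpins, a 3p
    arm). Companion pools: rRNA fragments of 18–40 nt (post-fragmentation),
    tRNAs of 70–90 nt, snoRNAs of 60–300 nt and random "other" molecules of
    18–30 nt. Deterministic for a given seed.
    """
    if n_mirna < 1 or n_other_per_class < 1:
        raise ValueError("pool sizes must be >= 1")
    rng = np.random.default_rng(seed)
    hairpins: dict[str, str] = {}
    matures: dict[str, tuple[str, int, int]] = {}
    for i in range(n_mirna):
        hid = f"sim-mir-{i + 1}"
        hlen = int(rng.integers(60, 91))
        seq = _random_dna(rng, hlen)
        hairpins[hid] = seq
        len5 = int(rng.integers(20, 24))
        start5 = int(rng.integers(1, 6))  # near the 5' end
        matures[f"sim-miR-{i + 1}-5p"] = (hid, start5, start5 + len5 - 1)
        if i % 2 == 0:  # half the hairpins carry a 3p arm too
            len3 = int(rng.integers(20, 24))
            start3 = hlen - len3 - int(rng.integers(0, 5)) + 1
            if start3 > start5 + len5:  # keep the two arms disjoint
                matures[f"sim-miR-{i + 1}-3p"] = (hid, start3, start3 + len3 - 1)
    annotation = MirnaAnnotation(hairpins, matures)
    annotation.validate()

    pools: dict[str, dict[str, str]] = {"miRNA": dict(hairpins)}
    ranges = {"rRNA": (18, 40), "tRNA": (70, 90), "snoRNA": (60, 300), "other": (18, 30)}
    for cls, (lo, hi) in ranges.items():
        pools[cls] = {
            f"sim-{cls}-{j + 1}": _random_dna(rng, int(rng.integers(lo, hi + 1)))
            for j in range(n_other_per_class)
        }
    return annotation, pools


def _quality_string(rng: np.random.Generator, length: int, tail_prob: float) -> str:
    q = rng.integers(30, 41, size=length)
    if tail_prob > 0 and rng.random() < tail_prob:
        tail = int(rng.integers(1, 6))
        q[-tail:] = rng.integers(2, 11, size=tail)
    return (q + 33).astype(np.uint8).tobytes().decode()


def _apply_mismatches(rng: np.random.Generator, seq: str, n_mismatches: int) -> str:
    arr = list(seq)
    positions = rng.choice(len(arr), size=min(n_mismatches, len(arr)), replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(arr)


def simulate_library(
    config: SimulationConfig,
    pool: dict[str, dict[str, str]],
    annotation: MirnaAnnotation,
) -> tuple[list[ReadRecord], GroundTruth]:
    """Simulate one library and its ground truth.

    miRNA reads are mature sequences with occasional ±1 nt 3' trimming
    variants (isomiR-like); rRNA reads take a whole fragment; tRNA/snoRNA
    reads take a random 18–40 nt fragment of the molecule; "other" reads
    take the whole random molecule. Per-mature read counts follow a
    log-normal expression profile (``expression_sigma``). Substitution
    errors are applied to the final read sequence.
    """
    rng = np.random.default_rng(config.seed)
    fractions = config.class_fractions
    for cls, frac in fractions.items():
        if frac > 0 and not pool.get(cls):
            raise ValueError(f"class {cls!r} has fraction {frac} but an empty pool")
    class_counts = allocate_largest_remainder(config.n_reads, fractions)

    truth = GroundTruth()
    truth.class_counts = Counter(class_counts)

    # Per-class source assignment: log-normal expression over matures for
    # miRNA, uniform multinomial for the other classes.
    assignments: dict[str, list[str]] = {}
    mature_ids = sorted(annotation.matures)
    for cls, count in class_counts.items():
        if count == 0:
            assignments[cls] = []
            continue
        if cls == "miRNA":
            weights = rng.lognormal(mean=0.0, sigma=config.expression_sigma,
                                    size=len(mature_ids))
            probs = weights / weights.sum()
            per_source = rng.multinomial(count, probs)
            sources = np.repeat(mature_ids, per_source)
            truth.mirna_counts = Counter(dict(zip(mature_ids, map(int, per_source))))
        else:
            ids = sorted(pool[cls])
            per_source = rng.multinomial(count, np.full(len(ids), 1.0 / len(ids)))
            sources = np.repeat(ids, per_source)
        rng.shuffle(sources)
        assignments[cls] = list(sources)

    # Interleave classes deterministically: one global shuffled order.
    class_of_read = np.repeat(
        list(class_counts), [class_counts[c] for c in class_counts]
    )
    rng.shuffle(class_of_read)
    cursor = {c: 0 for c in class_counts}

    n_mm_reads = round(config.n_reads * config.mismatch_read_fraction)
    mismatch_flags = np.zeros(config.n_reads, dtype=bool)
    if n_mm_reads:
        mismatch_flags[
            rng.choice(config.n_reads, size=n_mm_reads, replace=False)
        ] = True

    reads: list[ReadRecord] = []
    for i in range(config.n_reads):
        cls = str(class_of_read[i])
        source = assignments[cls][cursor[cls]]
        cursor[cls] += 1
        if cls == "miRNA":
            hid, start, end = annotation.matures[source]
            hairpin = annotation.hairpins[hid]
            u = rng.random()
            if u < 0.20 and end - start >= 18:  # 3' trimmed isomiR
                end -= 1
            elif u < 0.30 and end < len(hairpin):  # 3' templated extension
                end += 1
            insert = hairpin[start - 1 : end]
        else:
            molecule = pool[cls][source]
            if cls in ("tRNA", "snoRNA") and len(molecule) > 18:
                frag_len = int(rng.integers(18, min(41, len(molecule) + 1)))
                offset = int(rng.integers(0, len(molecule) - frag_len + 1))
                insert = molecule[offset : offset + frag_len]
            else:
                insert = molecule
        if config.adapter is None:
            seq = insert
        else:
            seq = insert + config.adapter
            if len(seq) < config.read_length:
                seq += _random_dna(rng, config.read_length - len(seq))
            seq = seq[: config.read_length]
        if mismatch_flags[i] and len(seq) > 0:
            seq = _apply_mismatches(rng, seq, config.mismatches_per_read)
        read_id = f"simread_{i + 1:07d}"
        reads.append(
            ReadRecord(read_id, seq,
                       _quality_string(rng, len(seq), config.low_quality_tail_prob))
        )
        truth.read_class[read_id] = cls
        truth.read_source[read_id] = source
    return reads, truth


def write_ground_truth(truth: GroundTruth, reads_path, counts_path) -> None:
    """Write the per-read truth and true mature counts as TSV files."""
    with open(reads_path, "w") as handle:
        handle.write("read_id\tclass\tsource_id\n")
        for rid, cls in truth.read_class.items():
            handle.write(f"{rid}\t{cls}\t{truth.read_source[rid]}\n")
    with open(counts_path, "w") as handle:
        handle.write("mature_id\tcount\n")
        for mid in sorted(truth.mirna_counts):
            handle.write(f"{mid}\t{truth.mirna_counts[mid]}\n")
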