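"""Ungapped read alignment to references and mature-miRNA counting.

Alignment uses an exact 12 nt seed (the read's first 12 bases) against a
k-mer index of the targets on both strands, extended over the full read
allowing at most ``max_mismatch`` substitutions; all hits in the best
stratum (fewest mismatches) are reported. This is a desk-scale stand-in for
a seed-and-extend short-read aligner, adequate for the ~20-23 nt reads and
kilobase-scale references the pipeline works with.

A read is attributed to a mature miRNA when its plus-strand hit interval
lies within the mature interval extended by a small flank (2 nt upstream,
5 nt downstream — the convention of miRDeep2-style quantifiers, which
tolerates templated isomiR ends). Multi-mapping reads add one count to
every matching mature, while the distinct-read "quantified" tally counts
each read once.

Counts are reported raw, as reads per million (RPM, denominator = the
sample's summed mature counts) and as log2(RPM + 1).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fastq_io import MirnaAnnotation

logger = logging.getLogger("mirap")

SEED_LENGTH = 12
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentHit:
    """One ungapped read placement on a target (1-based inclusive)."""

    read_id: str
    target_id: str
    start: int
    end: int
    strand: str
    mismatches: int


class KmerIndex:
    """Exact-seed index over a set of target sequences (both strands)."""

    def __init__(self, targets: dict[str, str], seed_len: int = SEED_LENGTH):
        self.targets = targets
        self.seed_len = seed_len
        self.index: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
        for tid, seq in targets.items():
            for pos in range(len(seq) - seed_len + 1):
                self.index[seq[pos : pos + seed_len]].append((tid, pos, "+"))
            rc = reverse_complement(seq)
            for pos in range(len(rc) - seed_len + 1):
                self.index[rc[pos : pos + seed_len]].append((tid, pos, "-"))
        self.index.default_factory = None  # freeze
        self._rc_cache = {tid: reverse_complement(seq) for tid, seq in targets.items()}

    def lookup(self, seed: str) -> list[tuple[str, int, str]]:
        return self.index.get(seed, [])


def _mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                break
    return n


def align_reads(reads, targets: dict[str, str], max_mismatch: int = 1,
                seed_len: int = SEED_LENGTH, index: KmerIndex | None = None):
    """Yield best-stratum :class:`AlignmentHit` for each read.

    Reads shorter than the seed are skipped. A hit requires the read's
    first ``seed_len`` bases to occur exactly in the target (either strand)
    and at most ``max_mismatch`` substitutions over the full read.
    Reverse-strand coordinates refer to the forward target.
    """
    if index is None:
        index = KmerIndex(targets, seed_len)
    for read in reads:
        seq = read.sequence
        lr = len(seq)
        if lr < seed_len:
            continue
        hits: list[AlignmentHit] = []
        best = max_mismatch
        for tid, pos, strand in index.lookup(seq[:seed_len]):
            ref = targets[tid] if strand == "+" else index._rc_cache[tid]
            if pos + lr > len(ref):
                continue
            mm = _mismatches(seq, ref[pos : pos + lr], best)
            if mm > max_mismatch:
                continue
            if strand == "+":
                start, end = pos + 1, pos + lr
            else:
                tl = len(targets[tid])
                start, end = tl - (pos + lr) + 1, tl - pos
            hits.append(AlignmentHit(read.read_id, tid, start, end, strand, mm))
        if not hits:
            continue
        best = min(h.mismatches for h in hits)
        for hit in hits:
            if hit.mismatches == best:
                yield hit


def assign_and_count(
    hits,
    annotation: MirnaAnnotation,
    flank_up: int = 2,
    flank_down: int = 5,
) -> tuple[Counter, int, int]:
    """Attribute plus-strand hairpin hits to mature miRNAs.

    Returns ``(mature_counts, n_quantified_reads, n_unannotated_hits)``
    where a read counts toward every mature whose flank-extended interval
    contains its hit, and the quantified tally counts distinct reads
    attributed to at least one mature.
    """
    windows: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    for mid, (hid, start, end) in annotation.matures.items():
        windows[hid].append((mid, start - flank_up, end + flank_down))
    counts: Counter = Counter()
    quantified: set[str] = set()
    unannotated = 0
    seen: set[tuple[str, str]] = set()  # avoid double-counting duplicate hits
    for hit in hits:
        if hit.strand != "+":
            continue
        if hit.target_id not in windows:
            unannotated += 1
            continue
        for mid, lo, hi in windows[hit.target_id]:
            if lo <= hit.start and hit.end <= hi and (hit.read_id, mid) not in seen:
                seen.add((hit.read_id, mid))
                counts[mid] += 1
                quantified.add(hit.read_id)
    return counts, len(quantified), unannotated


@dataclass
class CountTable:
    """Per-mature-miRNA raw counts, RPM and log2-RPM across samples."""

    raw: pd.DataFrame  # rows = mature ids, columns = samples
    rpm: pd.DataFrame
    log2_rpm: pd.DataFrame

    def to_tsv(self, outdir, prefix: str = "counts") -> None:
        self.raw.to_csv(f"{outdir}/{prefix}_raw.tsv", sep="\t")
        self.rpm.to_csv(f"{outdir}/{prefix}_rpm.tsv", sep="\t")
        self.log2_rpm.to_csv(f"{outdir}/{prefix}_log2rpm.tsv", sep="\t")


def normalize_rpm(raw: pd.DataFrame) -> CountTable:
    """Build a :class:`CountTable` from raw counts.

    RPM scales each sample by 10^6 over its summed mature counts; a sample
    whose counts are all zero keeps RPM 0 with a logged warning.
    log2_rpm = log2(RPM + 1).
    """
    totals = raw.sum(axis=0)
    zero_samples = totals[totals == 0].index.tolist()
    if zero_samples:
        logger.warning("samples with zero mature counts: %s", zero_samples)
    safe_totals = totals.replace(0, 1)
    rpm = raw * 1e6 / safe_totals
    return CountTable(raw=raw, rpm=rpm, log2_rpm=np.log2(rpm + 1.0))


def counts_to_frame(counts: Counter, sample: str,
                    all_matures=None) -> pd.DataFrame:
    """One-sample raw count matrix, optionally over a fixed mature universe."""
    index = sorted(all_matures) if all_matures is not None else sorted(counts)
    return pd.DataFrame(
        {sample: [counts.get(m, 0) for m in index]}, index=pd.Index(index, name="mature_id")
    )
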