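"""Read preprocessing: quality trimming, adapter removal, k-mer cleansing.

Each read passes through three stages. (1) 3'-end quality trimming by the
standard running-sum rule. (2) Removal of the best full (or end-anchored
partial) adapter occurrence. (3) For reads the full pass left untouched, a
cleansing loop that applies every contiguous k-mer of the adapter (default
length 10) in 5'→3' order as a trim pattern, rescuing reads contaminated by
fragmented adapter left over from the ligation/sequencing process.

Reads are then classified four ways: ``mappable`` (full-adapter trimmed,
length within bounds), ``mappable_cleansed`` (rescued by the k-mer loop),
``without_adapter`` (no adapter content found — discarded as likely
sequencing artifacts when an adapter is in force) and ``too_short``
(adapter-trimmed but below the minimum length). When the adapter call says
the library is adapter-free, the discard rule is disabled and every
quality-trimmed read within the length bounds is emitted as mappable.

Reads that exceed the maximum length after trimming are tallied separately
as ``too_long`` but folded into ``without_adapter`` in the four-way class
fractions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

logger = logging.getLogger("mirap")

if TYPE_CHECKING:  # pragma: no cover
    from .adapter_detect import AdapterCall

READ_CLASSES = ("mappable", "mappable_cleansed", "without_adapter", "too_short")


@dataclass
class PreprocessConfig:
    """Trimming parameters (defaults follow common sRNA-seq practice)."""

    quality_threshold: int = 20
    min_len: int = 18
    max_len: int = 50
    cleanse_kmer_len: int = 10
    error_rate: float = 0.10
    min_overlap: int = 3
    side: str = "3prime"

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.cleanse_kmer_len < 1:
            raise ValueError("cleanse_kmer_len must be >= 1")


@dataclass
class TrimmedRead:
    """A read after preprocessing, with its class label and trim metadata."""

    read_id: str
    sequence: str
    quality: str
    read_class: str = "mappable"
    trimmed_by: str = "none"  # full_adapter | kmer:<index> | none
    bases_removed_quality: int = 0
    bases_removed_adapter: int = 0


@dataclass
class PreprocessStats:
    """Per-library preprocessing accounting."""

    total_reads: int = 0
    class_counts: Counter = field(default_factory=Counter)
    too_long: int = 0
    bases_removed_quality: int = 0
    bases_removed_adapter: int = 0
    length_hist_before: Counter = field(default_factory=Counter)
    length_hist_after: Counter = field(default_factory=Counter)

    def class_fractions(self) -> dict[str, float]:
        """Four-way fractions summing to 1 (too_long folded into without_adapter)."""
        if self.total_reads == 0:
            return {cls: 0.0 for cls in READ_CLASSES}
        fractions = {
            cls: self.class_counts.get(cls, 0) / self.total_reads
            for cls in READ_CLASSES
        }
        fractions["without_adapter"] += self.too_long / self.total_reads
        return fractions


def quality_trim_3prime(sequence: str, quality: str, threshold: int) -> tuple[str, str]:
    """Trim low-quality 3' bases by the running-sum rule.

    Walking from the 3' end, accumulate (threshold - Q_i); cut at the
    position where the partial sum is maximal and positive. Identical to
    the BWA-style trimming used by standard read trimmers.
    """
    if not sequence or ord(min(quality)) - 33 >= threshold:
        return sequence, quality
    best_sum, running, cut = 0, 0, len(sequence)
    for i in range(len(sequence) - 1, -1, -1):
        running += threshold - (ord(quality[i]) - 33)
        if running > best_sum:
            best_sum, cut = running, i
    return sequence[:cut], quality[:cut]


def _count_mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance between equal-length strings, early-exit above limit."""
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > limit:
                return mismatches
    return mismatches


def find_adapter_match(
    sequence: str,
    adapter: str,
    side: str = "3prime",
    error_rate: float = 0.10,
    min_overlap: int = 3,
) -> tuple[int, int] | None:
    """Locate the best adapter occurrence; ``None`` when absent.

    3' side: candidates are every full-adapter occurrence, plus every
    adapter *prefix* of length >= ``min_overlap`` terminating at the read's
    3' end; a candidate is valid when its mismatches <= floor(error_rate x
    matched length). Among valid candidates the fewest mismatches win, then
    the leftmost cut. Returns ``(cut_position, errors)`` where the kept read
    is ``sequence[:cut_position]``.

    5' side is the mirror: full occurrences or adapter *suffixes* anchored
    at the read's 5' end; the kept read is ``sequence[cut_position:]``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    la, ls = len(adapter), len(sequence)
    if ls == 0:
        return None
    max_full_err = int(error_rate * la)
    best: tuple[int, int] | None = None  # (errors, cut)

    if side == "3prime":
        # fast path: exact full occurrence is always fewest-errors and leftmost
        idx = sequence.find(adapter)
        if idx >= 0:
            return idx, 0
        for start in range(ls - la + 1):
            err = _count_mismatches(sequence[start : start + la], adapter, max_full_err)
            if err <= max_full_err and (best is None or (err, start) < best):
                best = (err, start)
        for overlap in range(min(la - 1, ls), min_overlap - 1, -1):
            err = _count_mismatches(
                sequence[ls - overlap :], adapter[:overlap], int(error_rate * overlap)
            )
            if err <= int(error_rate * overlap):
                cand = (err, ls - overlap)
                if best is None or cand < best:
                    best = cand
    elif side == "5prime":
        for start in range(ls - la + 1):
            err = _count_mismatches(sequence[start : start + la], adapter, max_full_err)
            if err <= max_full_err and (best is None or (err, start + la) < best):
                best = (err, start + la)
        for overlap in range(min(la - 1, ls), min_overlap - 1, -1):
            err = _count_mismatches(
                sequence[:overlap], adapter[la - overlap :], int(error_rate * overlap)
            )
            if err <= int(error_rate * overlap):
                cand = (err, overlap)
                if best is None or cand < best:
                    best = cand
    else:
        raise ValueError(f"side must be 3prime or 5prime, got {side!r}")
    return (best[1], best[0]) if best is not None else None


def adapter_kmers(adapter: str, k: int) -> list[str]:
    """All contiguous k-mers of the adapter in 5'→3' order of start offset."""
    return [adapter[i : i + k] for i in range(len(adapter) - k + 1)]


def kmer_cleanse(
    reads: Iterable[TrimmedRead],
    adapter: str,
    cfg: PreprocessConfig,
) -> list[TrimmedRead]:
    """Apply the adapter's k-mers sequentially to reads the full pass missed.

    Each k-mer acts as a 3'-side trim pattern via :func:`find_adapter_match`
    (same error rate and minimum overlap). A read trimmed by k-mer ``i`` is
    marked ``trimmed_by="kmer:i"``, classed ``mappable_cleansed`` and leaves
    the loop; reads already trimmed are never reprocessed.
    """
    if len(adapter) < cfg.cleanse_kmer_len:
        raise ValueError("adapter shorter than the cleansing k-mer length")
    kmers = adapter_kmers(adapter, cfg.cleanse_kmer_len)
    out = []
    for read in reads:
        if read.trimmed_by == "none":
            for i, kmer in enumerate(kmers):
                match = find_adapter_match(
                    read.sequence, kmer, "3prime", cfg.error_rate, cfg.min_overlap
                )
                if match is not None:
                    cut, _ = match
                    read.bases_removed_adapter += len(read.sequence) - cut
                    read.sequence = read.sequence[:cut]
                    read.quality = read.quality[:cut]
                    read.trimmed_by = f"kmer:{i}"
                    read.read_class = "mappable_cleansed"
                    break
        out.append(read)
    return out


def _classify(read: TrimmedRead, cfg: PreprocessConfig, adapter_free: bool,
              stats: PreprocessStats) -> bool:
    """Set the final class; return True when the read should be emitted."""
    n = len(read.sequence)
    if read.trimmed_by == "none" and not adapter_free:
        read.read_class = "without_adapter"
        stats.class_counts["without_adapter"] += 1
        return False
    if n < cfg.min_len:
        read.read_class = "too_short"
        stats.class_counts["too_short"] += 1
        return False
    if n > cfg.max_len:
        stats.too_long += 1
        return False
    if read.read_class != "mappable_cleansed":
        read.read_class = "mappable"
    stats.class_counts[read.read_class] += 1
    return True


def preprocess_library(
    reads: Iterable,
    adapter_call: "AdapterCall",
    cfg: PreprocessConfig | None = None,
) -> tuple[list[TrimmedRead], PreprocessStats]:
    """Run the full preprocessing chain over a library.

    Per read: quality trim → full-adapter removal → (if untrimmed) k-mer
    cleansing → classification. When ``adapter_call.provenance == "none"``
    (adapter-free library) the without-adapter discard rule is disabled.
    Returns the emitted (mappable) reads and the per-class statistics.
    """
    cfg = cfg or PreprocessConfig()
    adapter = adapter_call.sequence
    adapter_free = adapter_call.provenance == "none" or not adapter
    side = getattr(adapter_call, "side", cfg.side) if not adapter_free else cfg.side
    kmers = (
        adapter_kmers(adapter, cfg.cleanse_kmer_len)
        if not adapter_free and len(adapter) >= cfg.cleanse_kmer_len
        else []
    )
    stats = PreprocessStats()
    emitted: list[TrimmedRead] = []
    for read in reads:
        stats.total_reads += 1
        stats.length_hist_before[len(read.sequence)] += 1
        seq, qual = quality_trim_3prime(
            read.sequence, read.quality, cfg.quality_threshold
        )
        trimmed = TrimmedRead(
            read.read_id, seq, qual,
            bases_removed_quality=len(read.sequence) - len(seq),
        )
        stats.bases_removed_quality += trimmed.bases_removed_quality
        if not adapter_free and trimmed.sequence:
            match = find_adapter_match(
                trimmed.sequence, adapter, side, cfg.error_rate, cfg.min_overlap
            )
            if match is not None:
                cut, _ = match
                if side == "3prime":
                    removed = len(trimmed.sequence) - cut
                    trimmed.sequence = trimmed.sequence[:cut]
                    trimmed.quality = trimmed.quality[:cut]
                else:
                    removed = cut
                    trimmed.sequence = trimmed.sequence[cut:]
                    trimmed.quality = trimmed.quality[cut:]
                trimmed.bases_removed_adapter = removed
                trimmed.trimmed_by = "full_adapter"
            elif kmers and side == "3prime":
                for i, kmer in enumerate(kmers):
                    km_match = find_adapter_match(
                        trimmed.sequence, kmer, "3prime", cfg.error_rate, cfg.min_overlap
                    )
                    if km_match is not None:
                        cut, _ = km_match
                        trimmed.bases_removed_adapter = len(trimmed.sequence) - cut
                        trimmed.sequence = trimmed.sequence[:cut]
                        trimmed.quality = trimmed.quality[:cut]
                        trimmed.trimmed_by = f"kmer:{i}"
                        trimmed.read_class = "mappable_cleansed"
                        break
        stats.bases_removed_adapter += trimmed.bases_removed_adapter
        if _classify(trimmed, cfg, adapter_free, stats):
            stats.length_hist_after[len(trimmed.sequence)] += 1
            emitted.append(trimmed)
    return emitted, stats


def length_histograms(
    stats: PreprocessStats,
) -> tuple[dict[int, int], dict[int, int], dict[str, float]]:
    """Paired before/after length histograms plus four-way class fractions."""
    before = dict(sorted(stats.length_hist_before.items()))
    after = dict(sorted(stats.length_hist_after.items()))
    return before, after, stats.class_fractions()
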