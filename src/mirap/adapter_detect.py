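"""Adapter resolution for a small RNA-seq library.

Precedence follows the pipeline's contract: a user-supplied adapter is used
verbatim; otherwise the 3' adapter is inferred de novo from k-mer
frequencies and cross-referenced against a library of known adapters. A
known adapter matching the inferred candidate at >= 90% ungapped similarity
replaces it in full; failing that the inferred 12-mer itself is used; and a
library can be declared adapter-free.

De novo inference rests on the observation that in read-through sRNA-seq
libraries the most frequent k-mers lie inside the 3' adapter. The default
mode calls the most frequent 12-mer the candidate when it occurs in at
least ``ratio_threshold`` of the sampled reads. Exhaustive mode scans
k in {9..12} and admission thresholds {0.2, 0.3, 0.4, 0.5}, trial-trims the
sample with every admitted candidate, and keeps the candidate whose
trimmed reads most often land in the miRNA-sized window [18, 26] nt —
which also reliably prefers the adapter's 5'-most k-mer over interior ones.
A library is declared adapter-free when no candidate trims convincingly
(best score < ``no_adapter_score``) and the best candidate is rare
(frequency ratio < ``no_adapter_ratio``).

Sampling takes the first ``sample_size`` reads, so inference is
deterministic without a seed.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .fastq_io import ReadRecord
from .preprocess import find_adapter_match

logger = logging.getLogger("mirap")

DEFAULT_SAMPLE_SIZE = 50_000
DEFAULT_RATIO_THRESHOLD = 0.4
EXHAUSTIVE_KS = (9, 10, 11, 12)
EXHAUSTIVE_THRESHOLDS = (0.2, 0.3, 0.4, 0.5)
SCORE_LENGTH_WINDOW = (18, 26)
NO_ADAPTER_SCORE = 0.20
NO_ADAPTER_RATIO = 0.05
SCORE_SAMPLE_SIZE = 5_000
TOP_CANDIDATES_PER_K = 5
LIBRARY_MATCH_MIN_SIMILARITY = 90.0


@dataclass
class AdapterCall:
    """Resolved adapter for one library."""

    sequence: str
    side: str = "3prime"  # 3prime | 5prime
    provenance: str = "none"  # user | library_match | de_novo_12mer | none
    matched_library_name: str | None = None
    similarity_percent: float = 0.0
    inferred_kmer: str | None = None

    def __post_init__(self) -> None:
        if self.provenance == "none" and self.sequence:
            raise ValueError("provenance 'none' requires an empty sequence")
        if self.provenance == "library_match" and (
            self.similarity_percent < LIBRARY_MATCH_MIN_SIMILARITY
            or not self.matched_library_name
        ):
            raise ValueError("library_match requires similarity >= 90 and a name")
        if self.provenance == "de_novo_12mer" and len(self.sequence) != 12:
            raise ValueError("de_novo_12mer requires a 12 nt sequence")


def count_kmers(reads: Iterable[ReadRecord], k: int) -> Counter:
    """Count every k-mer occurrence over full read sequences.

    k-mers containing N are excluded. Reads shorter than k contribute
    nothing; if every read is shorter than k the map is empty.
    """
    if k < 1:
        raise ValueError("k must be positive")
    counts: Counter = Counter()
    for read in reads:
        seq = read.sequence
        counts.update(seq[i : i + k] for i in range(len(seq) - k + 1))
    for kmer in [km for km in counts if "N" in km]:
        del counts[kmer]
    return counts


def _presence_counts(sequences: Sequence[str], k: int) -> Counter:
    """Number of reads containing each k-mer at least once (N-free k-mers)."""
    counts: Counter = Counter()
    for seq in sequences:
        counts.update({seq[i : i + k] for i in range(len(seq) - k + 1)})
    for kmer in [km for km in counts if "N" in km]:
        del counts[kmer]
    return counts


def _trim_score(
    sequences: Sequence[str],
    candidate: str,
    error_rate: float = 0.1,
    min_overlap: int = 3,
    window: tuple[int, int] = SCORE_LENGTH_WINDOW,
) -> float:
    """Fraction of reads that trim with ``candidate`` to a length in ``window``."""
    if not sequences:
        return 0.0
    lo, hi = window
    hits = 0
    for seq in sequences:
        match = find_adapter_match(seq, candidate, "3prime", error_rate, min_overlap)
        if match is not None and lo <= match[0] <= hi:
            hits += 1
    return hits / len(sequences)


def _extend_to_12mer(candidate: str, counts12: Counter) -> str:
    """Extend a short candidate to the most frequent 12-mer containing it."""
    if len(candidate) >= 12:
        return candidate
    best = max(
        ((cnt, km) for km, cnt in counts12.items() if candidate in km),
        default=None,
    )
    return best[1] if best is not None else candidate


def infer_adapter(
    reads: Iterable[ReadRecord],
    k: int = 12,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    exhaustive: bool = False,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    no_adapter_score: float = NO_ADAPTER_SCORE,
    no_adapter_ratio: float = NO_ADAPTER_RATIO,
    score_sample_size: int = SCORE_SAMPLE_SIZE,
) -> AdapterCall:
    """Infer the 3' adapter de novo from k-mer frequencies.

    Returns an :class:`AdapterCall` with provenance ``de_novo_12mer`` (the
    candidate, extended to 12 nt if inferred at a shorter k) or ``none``
    when the library appears adapter-free. See the module docstring for the
    default/exhaustive decision rules.
    """
    sample = [r.sequence for r in itertools.islice(iter(reads), sample_size)]
    if not sample:
        logger.warning("adapter inference: empty library; declaring adapter-free")
        return AdapterCall("", provenance="none")
    n = len(sample)

    if not exhaustive:
        counts = _presence_counts(sample, k)
        if not counts:
            return AdapterCall("", provenance="none")
        count, kmer = max((cnt, km) for km, cnt in counts.items())
        ratio = count / n
        if ratio >= ratio_threshold:
            return AdapterCall(kmer, provenance="de_novo_12mer", inferred_kmer=kmer)
        logger.info(
            "adapter inference: top %d-mer %s at ratio %.3f < %.3f; adapter-free",
            k, kmer, ratio, ratio_threshold,
        )
        return AdapterCall("", provenance="none")

    # Exhaustive mode: k x threshold grid, trial-trim scoring.
    score_sample = sample[:score_sample_size]
    counts_by_k = {kk: _presence_counts(sample, kk) for kk in EXHAUSTIVE_KS}
    candidates: dict[str, float] = {}  # kmer -> frequency ratio
    for kk in EXHAUSTIVE_KS:
        top = sorted(
            counts_by_k[kk].items(), key=lambda item: (-item[1], item[0])
        )[:TOP_CANDIDATES_PER_K]
        for km, cnt in top:
            ratio = cnt / n
            if any(ratio >= t for t in EXHAUSTIVE_THRESHOLDS):
                candidates.setdefault(km, ratio)
    if not candidates:
        return AdapterCall("", provenance="none")
    scored = sorted(
        ((_trim_score(score_sample, km), len(km), km) for km in candidates),
        key=lambda item: (-item[0], -item[1], item[2]),
    )
    best_score, _, best_kmer = scored[0]
    best_ratio = max(candidates.values())
    if best_score < no_adapter_score and best_ratio < no_adapter_ratio:
        return AdapterCall("", provenance="none")
    final = _extend_to_12mer(best_kmer, counts_by_k[12])
    if len(final) != 12:
        # degenerate libraries (reads shorter than 12 nt): report adapter-free
        logger.warning("adapter inference: candidate %s could not reach 12 nt", best_kmer)
        return AdapterCall("", provenance="none")
    return AdapterCall(final, provenance="de_novo_12mer", inferred_kmer=final)


def match_known_library(
    candidate: str, library: Sequence[tuple[str, str]]
) -> tuple[str | None, float]:
    """Best ungapped containment match of ``candidate`` in the adapter library.

    The candidate is slid along each library sequence at every offset with
    full containment; similarity = 100 x matches / len(candidate), maximised
    over offsets and entries. Ties go to the earlier library entry. An empty
    library yields ``(None, 0.0)``.
    """
    if not candidate:
        raise ValueError("candidate adapter must be non-empty")
    best_name, best_sim = None, 0.0
    lc = len(candidate)
    for name, seq in library:
        for offset in range(len(seq) - lc + 1):
            matches = sum(
                1 for a, b in zip(candidate, seq[offset : offset + lc]) if a == b
            )
            sim = 100.0 * matches / lc
            if sim > best_sim:
                best_name, best_sim = name, sim
    return best_name, best_sim


def resolve_adapter(
    user_adapter: str | None,
    user_side: str,
    reads: Iterable[ReadRecord],
    library: Sequence[tuple[str, str]],
    exhaustive: bool = False,
    **inference_kwargs,
) -> AdapterCall:
    """Resolve the adapter with precedence user > library match > de novo > none.

    Inference runs only for the 3' side; a matched library entry replaces
    the inferred candidate with the full known adapter sequence.
    """
    if user_adapter:
        seq = user_adapter.upper()
        if not set(seq) <= set("ACGT"):
            raise ValueError(f"user adapter contains non-DNA characters: {user_adapter!r}")
        if user_side not in ("3prime", "5prime"):
            raise ValueError(f"adapter side must be 3prime or 5prime, got {user_side!r}")
        return AdapterCall(seq, side=user_side, provenance="user")

    call = infer_adapter(reads, exhaustive=exhaustive, **inference_kwargs)
    if call.provenance == "none" or not library:
        return call
    name, similarity = match_known_library(call.sequence, library)
    if name is not None and similarity >= LIBRARY_MATCH_MIN_SIMILARITY:
        full = dict(library)[name]
        return AdapterCall(
            full,
            provenance="library_match",
            matched_library_name=name,
            similarity_percent=similarity,
            inferred_kmer=call.inferred_kmer,
        )
    call.matched_library_name = name
    call.similarity_percent = similarity
    return call
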