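"""Readers and writers for the file formats the pipeline consumes.

Everything downstream works on the types defined here: :class:`ReadRecord`
for sequencing reads and :class:`MirnaAnnotation` for the hairpin/mature
reference. Supported formats are 4-line Phred+33 FASTQ (optionally gzipped),
FASTA (hairpin and mature references, ``U`` converted to ``T``), a miRBase-style
GFF3 dialect for mature coordinates, plain-text adapter libraries and TSV
condition tables.

Coordinates are 1-based inclusive throughout, following the miRBase GFF3
convention.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger("mirap")

_DNA = set("ACGTN")


@dataclass
class ReadRecord:
    """One sequencing read: identifier, DNA sequence and Phred+33 qualities."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MirnaAnnotation:
    """Hairpin sequences plus mature miRNA intervals on each hairpin.

    ``matures`` maps a mature id to ``(hairpin_id, start, end)`` with 1-based
    inclusive hairpin-local coordinates, so the mature sequence is
    ``hairpins[hairpin_id][start - 1:end]``.
    """

    hairpins: dict[str, str] = field(default_factory=dict)
    matures: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    n_skipped: int = 0

    def mature_sequence(self, mature_id: str) -> str:
        hid, start, end = self.matures[mature_id]
        return self.hairpins[hid][start - 1 : end]

    def validate(self) -> None:
        for mid, (hid, start, end) in self.matures.items():
            if hid not in self.hairpins:
                raise ValueError(f"mature {mid!r} references unknown hairpin {hid!r}")
            if not (1 <= start <= end <= len(self.hairpins[hid])):
                raise ValueError(
                    f"mature {mid!r}: interval ({start},{end}) outside hairpin "
                    f"{hid!r} of length {len(self.hairpins[hid])}"
                )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` from a FASTQ(.gz) file in file order.

    Raises ``ValueError`` on malformed 4-line blocks or length mismatches
    (via Biopython's FASTQ parser) and ``FileNotFoundError`` on missing files.
    """
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield ReadRecord(title, seq.upper(), qual)


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as 4-line FASTQ; returns the number of records written.

    Round-trips byte-identically with :func:`read_fastq` for files this
    writer produced.
    """
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as ``{id: uppercase DNA sequence}`` with U→T."""
    out: dict[str, str] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            out[rec.id] = str(rec.seq).upper().replace("U", "T")
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n{seq}\n")


# --- hairpin / mature pairing ------------------------------------------------

def _norm_mirna_id(name: str) -> str:
    # case-fold and collapse the mir/miR distinction so hsa-mir-21 prefixes
    # hsa-miR-21-5p
    return name.casefold()


def _pair_by_substring(
    hairpins: dict[str, str], matures: dict[str, str]
) -> tuple[dict[str, tuple[str, int, int]], int]:
    """Locate each mature by exact substring search.

    The hairpin whose (normalized) identifier is a prefix of the mature
    identifier is tried first; remaining hairpins follow in lexicographic
    order. First exact hit wins.
    """
    intervals: dict[str, tuple[str, int, int]] = {}
    skipped = 0
    all_ids = sorted(hairpins)
    for mid, mseq in matures.items():
        norm_mid = _norm_mirna_id(mid)
        preferred = sorted(
            h for h in hairpins if norm_mid.startswith(_norm_mirna_id(h))
        )
        candidates = preferred + [h for h in all_ids if h not in set(preferred)]
        for hid in candidates:
            pos = hairpins[hid].find(mseq)
            if pos >= 0:
                intervals[mid] = (hid, pos + 1, pos + len(mseq))
                break
        else:
            skipped += 1
            logger.warning("mature %s not found in any hairpin; skipped", mid)
    return intervals, skipped


def _pair_by_gff3(
    gff3: str | Path, hairpins: dict[str, str]
) -> dict[str, tuple[str, int, int]]:
    """Join miRBase GFF3 ``miRNA`` rows to their precursor via Derives_from.

    Genomic coordinates are converted to hairpin-local ones using the
    precursor row; minus-strand precursors are flipped so local coordinates
    always run 5'→3' along the hairpin sequence.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    precursors: dict[str, tuple[str, int, int, str]] = {}
    for feat in db.features_of_type("miRNA_primary_transcript"):
        name = feat.attributes.get("Name", [feat.id])[0]
        precursors[feat.id] = (name, feat.start, feat.end, feat.strand)
    intervals: dict[str, tuple[str, int, int]] = {}
    for feat in db.features_of_type("miRNA"):
        if "Derives_from" not in feat.attributes:
            continue
        name = feat.attributes.get("Name", [feat.id])[0]
        parent_id = feat.attributes["Derives_from"][0]
        if parent_id not in precursors:
            logger.warning("mature %s derives from unknown precursor %s", name, parent_id)
            continue
        pname, pstart, pend, strand = precursors[parent_id]
        if strand == "-":
            local = (pend - feat.end + 1, pend - feat.start + 1)
        else:
            local = (feat.start - pstart + 1, feat.end - pstart + 1)
        if pname in hairpins:
            intervals[name] = (pname, local[0], local[1])
    return intervals


def load_mirna_annotation(
    hairpin_fasta: str | Path,
    mature_fasta: str | Path,
    gff3: str | Path | None = None,
) -> MirnaAnnotation:
    """Build a :class:`MirnaAnnotation` from miRBase-style reference files.

    With a GFF3, mature intervals come from its ``miRNA`` rows joined
    hairpin-local; otherwise each mature sequence is located by exact
    substring search in its same-prefix-named hairpin, then in all hairpins.
    Matures that cannot be placed (or whose GFF3 interval disagrees with the
    mature FASTA sequence) are skipped with a logged warning and counted in
    ``n_skipped``.
    """
    hairpins = read_fasta(hairpin_fasta)
    matures = read_fasta(mature_fasta)
    if gff3 is not None:
        intervals = _pair_by_gff3(gff3, hairpins)
        skipped = 0
        checked: dict[str, tuple[str, int, int]] = {}
        for mid, (hid, start, end) in intervals.items():
            sub = hairpins[hid][start - 1 : end]
            if mid in matures and sub != matures[mid]:
                logger.warning(
                    "mature %s: GFF3 interval sequence disagrees with mature FASTA; skipped",
                    mid,
                )
                skipped += 1
                continue
            checked[mid] = (hid, start, end)
        skipped += sum(1 for mid in matures if mid not in intervals)
        ann = MirnaAnnotation(hairpins, checked, skipped)
    else:
        intervals, skipped = _pair_by_substring(hairpins, matures)
        ann = MirnaAnnotation(hairpins, intervals, skipped)
    ann.validate()
    return ann


def load_adapter_library(path: str | Path) -> list[tuple[str, str]]:
    """Load a known-adapter library: one adapter per line, ``#`` comments.

    Lines are either ``name<TAB or space>SEQUENCE`` or a bare sequence (the
    name then defaults to ``adapter_<line number>``). Order-preserving;
    sequences upper-cased; non-DNA characters raise with the line number.
    """
    entries: list[tuple[str, str]] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) >= 2:
                name, seq = parts[0], parts[1].upper()
            else:
                name, seq = f"adapter_{lineno}", parts[0].upper()
            if not set(seq) <= set("ACGT"):
                raise ValueError(
                    f"{path}:{lineno}: adapter sequence contains non-DNA characters: {seq!r}"
                )
            entries.append((name, seq))
    return entries


def read_conditions_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>condition`` table (no header required)."""
    out: dict[str, str] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            out[parts[0]] = parts[1]
    return out
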