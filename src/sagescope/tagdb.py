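"""Virtual SAGE tag database built from a reference transcriptome.

SAGE libraries are constructed by digesting cDNA with NlaIII (recognition
site CATG) and sequencing a short tag immediately downstream of the
3'-most site of each transcript.  To map observed tags back to genes we
predict, for every reference transcript, the *virtual tag* that library
construction would produce: the 3'-most CATG anchor plus the following
``tag_length - 4`` bases, read 5'->3' on the sense strand.

Tags arising from different transcripts of the same gene collapse into a
single database entry; a tag shared by transcripts of *different* genes is
flagged ambiguous, and downstream quantification discards it (only tags
mapping unambiguously to a single gene identifier are counted).
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

ANCHOR = "CATG"
VALID_BASES = frozenset("ACGTN")
DEFAULT_TAG_LENGTH = 27  # CATG + 23 nt, SOLiD-SAGE scale
DEFAULT_GENE_REGEX = r"gene=(\S+)"


@dataclass(frozen=True)
class TranscriptRecord:
    """One reference transcript with its gene assignment."""

    transcript_id: str
    gene_id: str
    sequence: str

    def validate(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.transcript_id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"transcript {self.transcript_id}: invalid bases {sorted(bad)!r}"
            )


@dataclass
class VirtualTag:
    """A predicted tag and the gene(s) whose transcripts produce it."""

    tag_sequence: str
    gene_ids: set[str]
    anchor_offset: int  # 0-based anchor start in the first contributing transcript

    @property
    def ambiguous(self) -> bool:
        return len(self.gene_ids) > 1


@dataclass
class ExtractionStats:
    """Per-run tallies of transcripts that contributed no tag."""

    n_transcripts: int = 0
    n_tagged: int = 0
    n_no_anchor: int = 0
    n_short_tail: int = 0
    n_ambiguous_window: int = 0  # window contained N
    n_rejected: int = 0  # invalid alphabet


@dataclass
class VirtualTagDB:
    """Collection of virtual tags keyed by tag sequence."""

    tag_length: int
    entries: dict[str, VirtualTag] = field(default_factory=dict)
    n_genes_total: int = 0
    transcriptome_digest: str = ""
    stats: ExtractionStats = field(default_factory=ExtractionStats)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[VirtualTag]:
        # deterministic, lexicographic by tag sequence
        for tag in sorted(self.entries):
            yield self.entries[tag]

    @property
    def n_ambiguous(self) -> int:
        return sum(1 for e in self.entries.values() if e.ambiguous)

    def unambiguous_genes(self) -> set[str]:
        return {g for e in self.entries.values() if not e.ambiguous for g in e.gene_ids}


def _qualifying_anchor(seq: str, tag_length: int, anchor: str, fallback: bool) -> int | None:
    """Return the anchor offset to use, or None if no usable window.

    The 3'-most anchor wins.  Without fallback, a 3'-most anchor whose
    downstream window is too short (or contains N) disqualifies the
    transcript, mirroring physical library construction where only the
    3'-most restriction fragment is captured.
    """
    pos = seq.rfind(anchor)
    while pos != -1:
        window = seq[pos : pos + tag_length]
        if len(window) == tag_length and "N" not in window:
            return pos
        if not fallback:
            return pos  # caller inspects the window and skips
        pos = seq.rfind(anchor, 0, pos)
    return None


def extract_virtual_tags(
    transcriptome: Iterable[TranscriptRecord],
    tag_length: int = DEFAULT_TAG_LENGTH,
    anchor: str = ANCHOR,
    allow_fallback: bool = False,
) -> VirtualTagDB:
    """Build a :class:`VirtualTagDB` from reference transcripts.

    Parameters
    ----------
    transcriptome:
        Transcript records; invalid-alphabet records are rejected with a
        logged diagnostic and counted, not fatal.
    tag_length:
        Total tag length including the 4-base anchor (>= 5).
    allow_fallback:
        If True, an unusable 3'-most window (short tail or N base) falls
        back to the next anchor toward 5'.  Off by default.
    """
    if tag_length < 5:
        raise ValueError(f"tag_length must be >= 5, got {tag_length}")

    db = VirtualTagDB(tag_length=tag_length)
    stats = db.stats
    genes: set[str] = set()
    digest = hashlib.sha256()

    for rec in transcriptome:
        stats.n_transcripts += 1
        try:
            rec.validate()
        except ValueError as exc:
            logger.warning("rejected record: %s", exc)
            stats.n_rejected += 1
            continue
        genes.add(rec.gene_id)
        digest.update(f"{rec.transcript_id}\t{rec.sequence}\n".encode())

        pos = _qualifying_anchor(rec.sequence, tag_length, anchor, allow_fallback)
        if pos is None:
            stats.n_no_anchor += 1
            continue
        window = rec.sequence[pos : pos + tag_length]
        if len(window) < tag_length:
            stats.n_short_tail += 1
            continue
        if "N" in window:
            stats.n_ambiguous_window += 1
            continue

        stats.n_tagged += 1
        entry = db.entries.get(window)
        if entry is None:
            db.entries[window] = VirtualTag(window, {rec.gene_id}, pos)
        else:
            entry.gene_ids.add(rec.gene_id)

    db.n_genes_total = len(genes)
    db.transcriptome_digest = digest.hexdigest()[:16]
    return db


# ---------------------------------------------------------------------------
# FASTA input


def parse_gene_id(description: str, record_id: str, gene_regex: str = DEFAULT_GENE_REGEX) -> str:
    m = re.search(gene_regex, description)
    return m.group(1) if m else record_id


def read_transcriptome_fasta(
    path: str | Path, gene_regex: str = DEFAULT_GENE_REGEX
) -> list[TranscriptRecord]:
    """Load transcripts from FASTA; gene id parsed from the description line."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate transcript_id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            TranscriptRecord(
                transcript_id=rec.id,
                gene_id=parse_gene_id(rec.description, rec.id, gene_regex),
                sequence=str(rec.seq).upper(),
            )
        )
    return records


# ---------------------------------------------------------------------------
# On-disk format: TSV with a metadata header line


def db_write(db: VirtualTagDB, destination: str | Path) -> None:
    """Write the database as tab-separated text with a metadata header."""
    path = Path(destination)
    with path.open("w") as fh:
        fh.write(
            f"#tag_length={db.tag_length}\tn_genes_total={db.n_genes_total}"
            f"\tdigest={db.transcriptome_digest}\n"
        )
        fh.write("tag_sequence\tgene_ids\tanchor_offset\tambiguous\n")
        for entry in db:  # sorted
            fh.write(
                f"{entry.tag_sequence}\t{','.join(sorted(entry.gene_ids))}"
                f"\t{entry.anchor_offset}\t{int(entry.ambiguous)}\n"
            )


def db_read(source: str | Path) -> VirtualTagDB:
    """Read a database written by :func:`db_write`; validates invariants."""
    path = Path(source)
    with path.open() as fh:
        meta_line = fh.readline().rstrip("\n")
        if not meta_line.startswith("#tag_length="):
            raise ValueError(f"{path}:1: missing metadata header line")
        meta = dict(item.split("=", 1) for item in meta_line.lstrip("#").split("\t"))
        db = VirtualTagDB(
            tag_length=int(meta["tag_length"]),
            n_genes_total=int(meta.get("n_genes_total", 0)),
            transcriptome_digest=meta.get("digest", ""),
        )
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["tag_sequence", "gene_ids"]:
            raise ValueError(f"{path}:2: unexpected column header {header!r}")
        for lineno, line in enumerate(fh, start=3):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            tag, gene_ids, offset, _ambiguous = parts
            if len(tag) != db.tag_length:
                raise ValueError(
                    f"{path}:{lineno}: tag {tag!r} has length {len(tag)}, "
                    f"expected {db.tag_length}"
                )
            if tag in db.entries:
                raise ValueError(f"{path}:{lineno}: duplicate tag {tag!r}")
            db.entries[tag] = VirtualTag(tag, set(gene_ids.split(",")), int(offset))
    return db
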