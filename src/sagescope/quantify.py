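"""Tag extraction from reads, mismatch-tolerant gene assignment, and TPM.

Observed tags are assigned to genes against a :class:`~sagescope.tagdb.VirtualTagDB`
with a bounded Hamming-distance search (default allowance: 2 mismatches).
Exact hits are resolved by hash lookup; on an exact miss, all database
entries within the allowance are scanned and only the minimal-distance
hits vote on gene identity.  A tag whose best hits span more than one
gene — or whose exact hit is itself an ambiguous database entry — is
discarded as ambiguous and never contributes to counts.

Per-gene counts are normalised to TPM (tags per million): the count
scaled by 1e6 over the total of *assigned* tags in the library, so that
TPM sums to 1e6 for every non-empty profile.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

from .tagdb import ANCHOR, VirtualTagDB

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c


@dataclass(frozen=True)
class TagObservation:
    """A distinct tag sequence and the number of reads that yielded it."""

    tag_sequence: str
    count: int


@dataclass(frozen=True)
class Assignment:
    tag_sequence: str
    status: str  # exact | mismatch | ambiguous | unassigned
    gene_id: str | None = None
    n_mismatches: int | None = None

    def __post_init__(self) -> None:
        if self.status in ("ambiguous", "unassigned") and self.gene_id is not None:
            raise ValueError(f"{self.status} assignment must carry no gene_id")
        if self.status == "exact" and self.n_mismatches != 0:
            raise ValueError("exact assignment must have 0 mismatches")


@dataclass
class AssignmentSummary:
    """Read-weighted tallies of assignment outcomes for one library."""

    n_exact: int = 0
    n_mismatch: int = 0
    n_ambiguous: int = 0
    n_unassigned: int = 0
    n_genes_detected: int = 0

    @property
    def n_total(self) -> int:
        return self.n_exact + self.n_mismatch + self.n_ambiguous + self.n_unassigned

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def tpm(count: int, total_mapped: int) -> float:
    """Tags per million: ``count * 1e6 / total_mapped``.

    One tag in a library of five million mapped tags is 0.2 TPM — the
    unit the zero-handling pseudo-count rule is expressed in.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if not 0 <= count <= total_mapped:
        raise ValueError(f"count {count} outside [0, {total_mapped}]")
    return count * 1_000_000 / total_mapped


@dataclass
class ExpressionProfile:
    """Per-gene raw counts and TPM for one library."""

    library_id: str
    counts: dict[str, int] = field(default_factory=dict)
    total_mapped: int = 0
    tpm: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, library_id: str, counts: Mapping[str, int]) -> "ExpressionProfile":
        counts = {g: int(c) for g, c in sorted(counts.items()) if c > 0}
        total = sum(counts.values())
        tpms = {g: tpm(c, total) for g, c in counts.items()} if total else {}
        return cls(library_id=library_id, counts=counts, total_mapped=total, tpm=tpms)

    @property
    def n_genes(self) -> int:
        return len(self.counts)


def extract_read_tag(
    read_sequence: str,
    tag_length: int,
    anchor: str = ANCHOR,
    trim5: int = 0,
) -> str | None:
    """First ``tag_length`` bases of the read if anchored, else None.

    SAGE reads start at the restriction site, so a valid read begins with
    the anchor (after an optional fixed 5' trim for adapter remnants).
    """
    seq = read_sequence[trim5:].upper()
    if len(seq) < tag_length:
        return None
    if not seq.startswith(anchor):
        return None
    return seq[:tag_length]


# ---------------------------------------------------------------------------
# Matcher


def _encode(tags: list[str], length: int) -> np.ndarray:
    """Byte-encode tags to a (n, L) uint8 matrix of 2-bit base codes."""
    arr = np.frombuffer("".join(tags).encode(), dtype=np.uint8).reshape(len(tags), length)
    codes = _ENCODE_LUT[arr]
    if (codes == 255).any():
        bad = np.unique(arr[codes == 255]).tobytes().decode()
        raise ValueError(f"cannot encode bases {bad!r} for mismatch search")
    return codes


def _pack(codes: np.ndarray) -> np.ndarray:
    """Pack (n, L) 2-bit codes into uint64 words, L <= 32."""
    weights = (np.uint64(4) ** np.arange(codes.shape[1], dtype=np.uint64))
    return (codes.astype(np.uint64) * weights).sum(axis=1)


class TagMatcher:
    """Assigns observed tags to genes against a virtual-tag database.

    Exact lookups go through a hash table.  The mismatch search packs each
    tag into a 64-bit word (2 bits per base, tags up to 32 nt) and computes
    Hamming distances for whole query batches via XOR + popcount; longer
    tags fall back to a byte-matrix comparison.
    """

    def __init__(self, db: VirtualTagDB):
        if not db.entries:
            raise ValueError("empty tag database")
        self.db = db
        self.tag_length = db.tag_length
        self._tags = sorted(db.entries)
        self._genes: list[tuple[str, ...]] = [
            tuple(sorted(db.entries[t].gene_ids)) for t in self._tags
        ]
        self._ambiguous = np.array([len(g) > 1 for g in self._genes])
        self._codes = _encode(self._tags, self.tag_length)
        self._packed = _pack(self._codes) if self.tag_length <= 32 else None
        self._exact = {t: i for i, t in enumerate(self._tags)}

    # -- distance kernels ---------------------------------------------------

    def _distances(self, q_codes: np.ndarray, q_packed: np.ndarray | None) -> np.ndarray:
        """(n_query, n_entries) Hamming distance matrix for one batch."""
        if self._packed is not None and q_packed is not None:
            x = q_packed[:, None] ^ self._packed[None, :]
            # mark differing 2-bit base pairs, then count them
            pair = (x | (x >> np.uint64(1))) & np.uint64(0x5555555555555555)
            return np.bitwise_count(pair).astype(np.int16)
        return (q_codes[:, None, :] != self._codes[None, :, :]).sum(axis=2, dtype=np.int16)

    # -- public API ---------------------------------------------------------

    def match(self, tag: str, max_mismatch: int = 2) -> Assignment:
        if len(tag) != self.tag_length:
            raise ValueError(
                f"tag length {len(tag)} != database tag length {self.tag_length}"
            )
        return self.match_many([tag], max_mismatch)[0]

    def match_many(self, tags: list[str], max_mismatch: int = 2) -> list[Assignment]:
        """Vectorised assignment of a batch of distinct tags."""
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        results: list[Assignment | None] = [None] * len(tags)
        pending: list[int] = []
        for i, tag in enumerate(tags):
            if len(tag) != self.tag_length:
                raise ValueError(
                    f"tag length {len(tag)} != database tag length {self.tag_length}"
                )
            j = self._exact.get(tag)
            if j is not None:
                if self._ambiguous[j]:
                    results[i] = Assignment(tag, "ambiguous")
                else:
                    results[i] = Assignment(tag, "exact", self._genes[j][0], 0)
            else:
                pending.append(i)

        if not pending or max_mismatch == 0:
            for i in pending:
                results[i] = Assignment(tags[i], "unassigned")
            return results  # type: ignore[return-value]

        chunk = 2048
        for start in range(0, len(pending), chunk):
            idx = pending[start : start + chunk]
            batch = [tags[i] for i in idx]
            try:
                codes = _encode(batch, self.tag_length)
            except ValueError:
                # batch contains non-ACGT tags; handle those individually
                for i in idx:
                    if set(tags[i]) <= set("ACGT"):
                        continue
                    results[i] = Assignment(tags[i], "unassigned")
                batch_idx = [i for i in idx if results[i] is None]
                if not batch_idx:
                    continue
                idx = batch_idx
                batch = [tags[i] for i in idx]
                codes = _encode(batch, self.tag_length)
            packed = _pack(codes) if self._packed is not None else None
            dist = self._distances(codes, packed)
            dmin = dist.min(axis=1)
            argmin = dist.argmin(axis=1)
            n_at_min = (dist == dmin[:, None]).sum(axis=1)
            for row, i in enumerate(idx):
                d = int(dmin[row])
                if d > max_mismatch:
                    results[i] = Assignment(tags[i], "unassigned")
                elif n_at_min[row] == 1:
                    j = int(argmin[row])
                    if self._ambiguous[j]:
                        results[i] = Assignment(tags[i], "ambiguous")
                    else:
                        results[i] = Assignment(tags[i], "mismatch", self._genes[j][0], d)
                else:
                    hits = np.flatnonzero(dist[row] == d)
                    genes = {g for j in hits for g in self._genes[j]}
                    if len(genes) == 1:
                        results[i] = Assignment(tags[i], "mismatch", genes.pop(), d)
                    else:
                        results[i] = Assignment(tags[i], "ambiguous")
        return results  # type: ignore[return-value]


def match_tag(tag: str, db: VirtualTagDB, max_mismatch: int = 2) -> Assignment:
    """Assign a single tag; the matcher index is cached on the database."""
    matcher = getattr(db, "_matcher", None)
    if matcher is None or matcher.db is not db:
        matcher = TagMatcher(db)
        db._matcher = matcher  # type: ignore[attr-defined]
    return matcher.match(tag, max_mismatch)


def count_library(
    tag_stream: Iterable[TagObservation],
    db: VirtualTagDB,
    max_mismatch: int = 2,
    library_id: str = "library",
    min_count: int = 1,
) -> tuple[ExpressionProfile, AssignmentSummary]:
    """Aggregate assigned tags per gene and normalise to TPM.

    Only unambiguously assigned tags enter the counts, and ``total_mapped``
    (the TPM denominator) counts assigned tags only.  ``min_count`` drops
    tags observed fewer times than the threshold before assignment
    (default 1, i.e. no filtering).
    """
    tally: Counter[str] = Counter()
    for obs in tag_stream:
        if obs.count < 1:
            raise ValueError(f"observation {obs.tag_sequence!r} has count < 1")
        tally[obs.tag_sequence] += obs.count
    tags = sorted(t for t, c in tally.items() if c >= min_count)

    summary = AssignmentSummary()
    counts: Counter[str] = Counter()
    if tags:
        matcher = TagMatcher(db)
        for assn in matcher.match_many(tags, max_mismatch):
            c = tally[assn.tag_sequence]
            if assn.status == "exact":
                summary.n_exact += c
                counts[assn.gene_id] += c
            elif assn.status == "mismatch":
                summary.n_mismatch += c
                counts[assn.gene_id] += c
            elif assn.status == "ambiguous":
                summary.n_ambiguous += c
            else:
                summary.n_unassigned += c

    profile = ExpressionProfile.from_counts(library_id, counts)
    summary.n_genes_detected = profile.n_genes
    return profile, summary


# ---------------------------------------------------------------------------
# Input readers and profile IO


def tags_from_reads(
    path: str | Path,
    tag_length: int,
    fmt: str = "fastq",
    anchor: str = ANCHOR,
    trim5: int = 0,
) -> tuple[list[TagObservation], dict[str, int]]:
    """Tally anchored tags from a FASTQ/FASTA file.

    Returns observations plus counters for reads skipped as too short or
    lacking the anchor.
    """
    tally: Counter[str] = Counter()
    skipped = {"short": 0, "no_anchor": 0}
    for rec in SeqIO.parse(str(path), fmt):
        seq = str(rec.seq)
        if len(seq) - trim5 < tag_length:
            skipped["short"] += 1
            continue
        tag = extract_read_tag(seq, tag_length, anchor, trim5)
        if tag is None:
            skipped["no_anchor"] += 1
            continue
        tally[tag] += 1
    obs = [TagObservation(t, c) for t, c in sorted(tally.items())]
    return obs, skipped


def read_tag_tsv(path: str | Path) -> list[TagObservation]:
    """Read a pre-tallied 2-column TSV (tag_sequence, count)."""
    obs = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("tag_sequence"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            obs.append(TagObservation(parts[0], int(parts[1])))
    return obs


def write_tag_tsv(observations: Iterable[TagObservation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("tag_sequence\tcount\n")
        for obs in sorted(observations, key=lambda o: o.tag_sequence):
            fh.write(f"{obs.tag_sequence}\t{obs.count}\n")


def write_profile(profile: ExpressionProfile, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"#library_id={profile.library_id}\ttotal_mapped={profile.total_mapped}\n")
        fh.write("gene_id\traw_count\ttpm\n")
        for gene in sorted(profile.counts):
            fh.write(f"{gene}\t{profile.counts[gene]}\t{profile.tpm[gene]:.6g}\n")


def read_profile(path: str | Path) -> ExpressionProfile:
    path = Path(path)
    with path.open() as fh:
        meta_line = fh.readline().rstrip("\n")
        if not meta_line.startswith("#library_id="):
            raise ValueError(f"{path}:1: missing profile metadata header")
        meta = dict(item.split("=", 1) for item in meta_line.lstrip("#").split("\t"))
        fh.readline()  # column header
        counts = {}
        for line in fh:
            gene, raw, _tpm = line.rstrip("\n").split("\t")
            counts[gene] = int(raw)
    return ExpressionProfile.from_counts(meta["library_id"], counts)


def iter_observations(counts: Mapping[str, int]) -> Iterator[TagObservation]:
    """Convenience: turn a mapping tag -> count into observations."""
    for t, c in sorted(counts.items()):
        yield TagObservation(t, c)
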