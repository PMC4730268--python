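"""Sequence and pair-list I/O plus length-based filtering.

Proteins come in as standard FASTA (ids taken up to the first whitespace
of the header); labeled pairs as a 3-column TSV ``id_a  id_b  label`` with
labels 1 / -1 (the token "0" is accepted as an alias for -1).  Proteins
shorter than 50 residues, or longer than a configurable maximum, are
dropped together with every pair that touches them, mirroring common
curation of interaction benchmarks.

Sequence-identity redundancy filtering is intentionally not part of this
module: removing near-duplicate proteins requires all-vs-all alignment or
clustering and is treated as an upstream curation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "PairDataset",
    "FilterResult",
    "read_fasta",
    "write_fasta",
    "read_pairs",
    "write_pairs",
    "filter_by_length",
]

DEFAULT_MIN_LEN = 50
DEFAULT_MAX_LEN = 5000


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty protein id")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PairDataset:
    """Ordered list of (id_a, id_b, label) with label +1/-1."""

    entries: list[tuple[str, str, int]]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def labels(self) -> list[int]:
        return [label for _, _, label in self.entries]

    def protein_ids(self) -> set[str]:
        ids: set[str] = set()
        for a, b, _ in self.entries:
            ids.add(a)
            ids.add(b)
        return ids


def _validate_fasta_layout(path: Path) -> None:
    """Light pre-pass so format errors carry a line number."""
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if len(stripped) == 1:
                    raise ValueError(f"{path}:{lineno}: header with no id")
                seen_header = True
            elif not seen_header:
                raise ValueError(
                    f"{path}:{lineno}: sequence data before any '>' header"
                )
    if not seen_header:
        raise ValueError(f"{path}: no FASTA records found")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read FASTA into :class:`ProteinRecord` objects (sequences upper-cased)."""
    path = Path(path)
    _validate_fasta_layout(path)
    records = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    duplicates = sorted(rid for rid, count in seen.items() if count > 1)
    if duplicates:
        raise ValueError(f"{path}: duplicate protein ids: {duplicates}")
    return records


def write_fasta(records, path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    writer_format = "fasta" if width else "fasta-2line"
    SeqIO.write(seq_records, str(path), writer_format)


_LABEL_ALIASES = {"1": 1, "+1": 1, "-1": -1, "0": -1}


def read_pairs(path: str | Path, provenance: str | None = None) -> PairDataset:
    """Read a 3-column TSV of labeled pairs (header required)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["id_a", "id_b", "label"]
    if list(frame.columns[:3]) != required:
        raise ValueError(
            f"{path}: expected columns {required}, got {list(frame.columns)}"
        )
    entries: list[tuple[str, str, int]] = []
    for row_idx, (id_a, id_b, raw) in enumerate(
        frame[required].itertuples(index=False)
    ):
        token = str(raw).strip()
        if token not in _LABEL_ALIASES:
            # +2: one for the header, one for 1-based numbering
            raise ValueError(f"{path}:{row_idx + 2}: unknown label token {token!r}")
        entries.append((str(id_a), str(id_b), _LABEL_ALIASES[token]))
    return PairDataset(entries=entries, provenance=provenance or str(path))


def write_pairs(pairs: PairDataset, path: str | Path) -> None:
    frame = pd.DataFrame(pairs.entries, columns=["id_a", "id_b", "label"])
    frame.to_csv(path, sep="\t", index=False)


@dataclass
class FilterResult:
    records: list[ProteinRecord]
    pairs: PairDataset
    removal_log: list[dict] = field(default_factory=list)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.removal_log, columns=["kind", "item", "reason"]
        )


def filter_by_length(
    records,
    pairs: PairDataset,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> FilterResult:
    """Drop out-of-range proteins and every pair referencing them.

    The removal log records one row per removed protein and per removed
    pair; filtering is idempotent.
    """
    log: list[dict] = []
    kept_records = []
    removed_ids = set()
    for rec in records:
        n = len(rec)
        if n < min_len:
            removed_ids.add(rec.id)
            log.append(
                {"kind": "protein", "item": rec.id,
                 "reason": f"length {n} < min_len {min_len}"}
            )
        elif n > max_len:
            removed_ids.add(rec.id)
            log.append(
                {"kind": "protein", "item": rec.id,
                 "reason": f"length {n} > max_len {max_len}"}
            )
        else:
            kept_records.append(rec)
    kept_entries = []
    for id_a, id_b, label in pairs:
        gone = {id_a, id_b} & removed_ids
        if gone:
            log.append(
                {"kind": "pair", "item": f"{id_a}\t{id_b}",
                 "reason": f"references removed protein(s) {sorted(gone)}"}
            )
        else:
            kept_entries.append((id_a, id_b, label))
    return FilterResult(
        records=kept_records,
        pairs=PairDataset(entries=kept_entries, provenance=pairs.provenance),
        removal_log=log,
    )
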