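"""Reading and writing of the formats the pipeline touches.

FASTA in/out (via Bio.SeqIO), tabular/JSON annotation output, newick trees
(via dendropy).  Internal coordinates throughout the package are 0-based
half-open; everything serialized for human consumption is 1-based inclusive.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import dendropy
from Bio import SeqIO

#: the 20 standard residues; the ambiguity code X is additionally accepted
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

FASTA_LINE_WIDTH = 60


class FastaError(ValueError):
    pass


class EmptyInputError(FastaError):
    pass


class DuplicateIdError(FastaError):
    pass


class InvalidAlphabetError(FastaError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence flowing through every stage of the screen."""

    id: str
    sequence: str
    species: str = "unknown"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaError(f"record id must be a non-empty token, got {self.id!r}")
        if len(self.sequence) < 1:
            raise FastaError(f"record {self.id}: empty sequence")
        bad = next((i for i, c in enumerate(self.sequence) if c not in VALID_RESIDUES), None)
        if bad is not None:
            raise InvalidAlphabetError(
                f"record {self.id}: invalid residue {self.sequence[bad]!r} at position {bad + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive interval."""
    return start + 1, end


def from_one_based(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open interval."""
    return first - 1, last


def read_fasta(
    path: str | Path,
    species_hint: str = "unknown",
    species_regex: str | None = None,
) -> list[ProteinRecord]:
    """Read a protein FASTA file.

    Sequences are upper-cased; a single terminal ``*`` stop character is
    stripped.  ``species_hint`` tags every record unless ``species_regex``
    (a pattern with one capture group, matched against the full header)
    extracts a species token for it.

    Raises EmptyInputError for a file without entries, DuplicateIdError when
    two entries share an id, and InvalidAlphabetError for residues outside
    the 20 standard codes plus X.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    pattern = re.compile(species_regex) if species_regex else None
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if entry.id in seen:
            raise DuplicateIdError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        species = species_hint
        if pattern is not None:
            m = pattern.search(entry.description)
            if m and m.group(1):
                species = m.group(1)
        description = entry.description[len(entry.id):].strip()
        records.append(ProteinRecord(id=entry.id, sequence=seq, species=species,
                                     description=description))
    if not records:
        raise EmptyInputError(f"no FASTA entries found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> Path:
    """Write records as plain FASTA, wrapped at 60 columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), FASTA_LINE_WIDTH):
                fh.write(rec.sequence[i:i + FASTA_LINE_WIDTH] + "\n")
    return path


#: stable column order of the per-protein annotation table
ANNOTATION_COLUMNS = (
    "id", "species", "family", "n_ef_hands", "ef1_template",
    "ef1_start", "ef1_end", "ef1_score", "x_residue", "post_minus_z",
    "spacer12", "myristoylation", "cys3", "n_cys_nterm", "fpsf_position",
    "naf_present", "naf_score", "kinase_verdict",
)


def _format_cell(value: Any) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_annotations(
    rows: Sequence[dict],
    path: str | Path,
    format: str = "tsv",
    columns: Sequence[str] = ANNOTATION_COLUMNS,
    header_comments: Sequence[str] = (),
) -> Path:
    """Serialize one annotation row per protein.

    TSV keeps the stable flat column order; JSON keeps every key of every row
    (a lossless nesting of the same results).  Coordinates in the rows are
    expected to be 1-based inclusive already.
    """
    path = Path(path)
    if format == "tsv":
        with path.open("w", newline="") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(columns)
            for row in rows:
                writer.writerow([_format_cell(row.get(col)) for col in columns])
    elif format == "json":
        payload = {"comments": list(header_comments), "rows": list(rows)}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unsupported annotation format {format!r}")
    return path


def read_annotations_json(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())["rows"]


def write_newick(tree: dendropy.Tree, path: str | Path) -> Path:
    """Serialize an (unrooted) tree with branch lengths as newick."""
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tree has duplicate leaf labels")
    path = Path(path)
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True)
    path.write_text(text)
    return path


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
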