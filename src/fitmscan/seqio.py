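"""Input/output for sequences, topology annotations, group tables and reports.

Sequences come in as plain FASTA (read through Biopython). Membrane topologies
are per-residue state strings over the alphabet ``i`` (cytoplasmic / "inside"),
``M`` (membrane) and ``o`` (luminal / "outside"), accepted either as a minimal
two-column ``id<TAB>states`` format or as TOPCONS-style consensus output
blocks. Reports are written as TSV (one row per protein, stable column order)
or as a lossless JSON dump that includes every motif hit span.

All coordinates in reports are 1-based inclusive spans, matching the residue
numbering convention used for point mutants in the literature (e.g. H178).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

#: The 20 canonical residues plus tolerated ambiguity codes.
CANONICAL = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS = frozenset("XUBZ")
ALPHABET = CANONICAL | AMBIGUOUS

TOPOLOGY_STATES = frozenset("iMo")


class SeqIOError(ValueError):
    """Raised for malformed sequence, topology or report input."""


@dataclass
class ProteinRecord:
    """An identified amino-acid sequence plus provenance.

    ``sequence`` is stored uppercase with no whitespace; ``source`` records
    where the record came from (``file``, ``synthetic`` or ``fetched``).
    """

    id: str
    sequence: str
    description: str = ""
    source: str = "file"

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("protein record id must be non-empty")
        if not self.sequence:
            raise SeqIOError(f"{self.id}: sequence must be non-empty")
        self.sequence = self.sequence.upper()
        bad = [(i, c) for i, c in enumerate(self.sequence, start=1) if c not in ALPHABET]
        if bad:
            pos, char = bad[0]
            raise SeqIOError(f"{self.id}: illegal character {char!r} at residue {pos}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GroupTable:
    """Mapping of protein id to family/group label (one label per id)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.mapping.values():
            if lab not in seen:
                seen.append(lab)
        return seen

    def members(self, label: str) -> list[str]:
        return [pid for pid, lab in self.mapping.items() if lab == label]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Lowercase residues are uppercased and a single terminal ``*`` is stripped.
    Empty files, duplicate ids, internal ``*`` and characters outside the
    tolerated alphabet are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            raise SeqIOError(f"{entry.id}: internal '*' at residue {seq.index('*') + 1}")
        if entry.id in seen:
            raise SeqIOError(f"duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(id=entry.id, sequence=seq, description=entry.description, source="file")
        )
    if not records:
        raise SeqIOError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA (wrap at ``width`` columns)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _normalise_states(states: str, ident: str) -> str:
    # Reentrant-helix states from TOPCONS ('I'/'O') collapse onto i/o.
    states = states.replace("I", "i").replace("O", "o")
    for pos, char in enumerate(states, start=1):
        if char not in TOPOLOGY_STATES:
            raise SeqIOError(f"{ident}: unknown topology state {char!r} at position {pos}")
    return states


def read_topology_annotation(
    path: str | Path, sequences: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Parse per-residue topology state strings, keyed by protein id.

    Two dialects are accepted and auto-detected:

    * minimal: one ``id<TAB>statestring`` per line;
    * TOPCONS-style consensus blocks, where the state string follows a
      ``TOPCONS predicted topology:`` line inside a ``Sequence name:`` block.

    When ``sequences`` is given, each state string must match the length of
    the corresponding sequence.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    result: dict[str, str] = {}

    tabbed = [ln for ln in lines if ln.strip() and "\t" in ln]
    if tabbed and all("\t" in ln for ln in lines if ln.strip()):
        for ln in tabbed:
            ident, states = ln.split("\t", 1)
            ident = ident.strip()
            result[ident] = _normalise_states(states.strip(), ident)
    else:
        current: str | None = None
        collecting = False
        buffer: list[str] = []

        def flush() -> None:
            nonlocal buffer, collecting
            if current is not None and buffer:
                result[current] = _normalise_states("".join(buffer), current)
            buffer = []
            collecting = False

        for ln in lines:
            stripped = ln.strip()
            if stripped.lower().startswith("sequence name:"):
                flush()
                current = stripped.split(":", 1)[1].strip()
            elif stripped.lower().startswith("topcons predicted topology:"):
                buffer = []
                collecting = True
            elif collecting:
                if stripped and all(c in "iMoIOS" for c in stripped):
                    buffer.append(stripped)
                else:
                    flush()
        flush()

    if not result:
        raise SeqIOError(f"no topology annotations in {path}")
    if sequences is not None:
        for ident, states in result.items():
            if ident in sequences and len(states) != len(sequences[ident]):
                raise SeqIOError(
                    f"{ident}: topology length {len(states)} != sequence length {len(sequences[ident])}"
                )
    return result


def write_topology_annotation(states: Mapping[str, str], path: str | Path) -> None:
    """Write the minimal ``id<TAB>states`` topology dialect."""
    with open(path, "w") as fh:
        for ident, st in states.items():
            fh.write(f"{ident}\t{st}\n")


def read_group_table(path: str | Path) -> GroupTable:
    """Read a two-column TSV of ``id<TAB>group label`` (header optional)."""
    mapping: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise SeqIOError(f"group table line has no label: {ln!r}")
        ident, label = parts[0].strip(), parts[1].strip()
        if ident.lower() == "id" and label.lower() in {"group", "label", "family"}:
            continue
        if ident in mapping:
            raise SeqIOError(f"duplicate id in group table: {ident!r}")
        mapping[ident] = label
    return GroupTable(mapping)


#: Stable column order for the per-protein TSV report.
REPORT_COLUMNS = [
    "id",
    "n_diarg_total",
    "n_diarg_cyto",
    "cterm_motif",
    "localization",
    "kxn_present",
    "kxn_has_K",
    "cys_pair_34",
    "h1_pos",
    "h1_res",
    "h2_pos",
    "h2_res",
    "third_pos",
    "third_res",
    "c2_middle",
    "context_score",
    "triad_class",
]


def write_report(profiles: list, path: str | Path, format: str = "tsv") -> None:
    """Write retention profiles as TSV (stable columns) or lossless JSON.

    Profile objects must provide ``to_row()`` (flat dict over
    :data:`REPORT_COLUMNS`) and ``to_dict()`` (nested dump with motif spans).
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(REPORT_COLUMNS) + "\n")
            for prof in profiles:
                row = prof.to_row()
                fh.write(
                    "\t".join("" if row.get(c) is None else str(row.get(c)) for c in REPORT_COLUMNS)
                    + "\n"
                )
    elif format == "json":
        with open(path, "w") as fh:
            json.dump([prof.to_dict() for prof in profiles], fh, indent=1)
            fh.write("\n")
    else:
        raise SeqIOError(f"unknown report format {format!r}")


def read_report_json(path: str | Path) -> list[dict]:
    """Read back a JSON report as a list of profile dictionaries."""
    with open(path) as fh:
        return json.load(fh)
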