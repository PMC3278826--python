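"""Protein records, site annotations, and Glu-centered window extraction.

Carboxylation (Gla) sites occur on glutamate (E) residues.  Every Glu in a
carboxylated protein yields one fragment: a ``2n+1`` residue window centered
on the Glu, labeled *positive* when the position is experimentally annotated
and *negative* otherwise.  Windows that run past a terminus are padded with
``'-'``, the 21st alphabet symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from Bio import SeqIO

#: The 20 standard amino acids, alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Terminal padding symbol (the 21st fragment symbol).
PAD = "-"
#: Placeholder for unknown/non-standard residues.
UNKNOWN = "X"
#: Fragment alphabet: 20 amino acids plus the terminal signal.
ALPHABET21 = AMINO_ACIDS + PAD

Label = Literal["positive", "negative"]


class FormatError(ValueError):
    """Raised for malformed input files (FASTA, TSV annotations)."""


class SiteValidationError(ValueError):
    """Raised when an annotated site violates the Glu invariant."""


@dataclass
class ProteinRecord:
    """A protein sequence with its annotated carboxylation positions.

    Positions are 1-based; each must point at an ``'E'`` residue.
    """

    id: str
    sequence: str
    carboxylation_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        bad = set(self.sequence) - set(AMINO_ACIDS + UNKNOWN)
        if bad:
            raise ValueError(
                f"{self.id}: sequence contains invalid symbols {sorted(bad)}"
            )
        seen: set[int] = set()
        for p in self.carboxylation_positions:
            if not 1 <= p <= len(self.sequence):
                raise SiteValidationError(
                    f"{self.id}: position {p} outside sequence of length "
                    f"{len(self.sequence)}"
                )
            if self.sequence[p - 1] != "E":
                raise SiteValidationError(
                    f"{self.id}: position {p} is "
                    f"'{self.sequence[p - 1]}', not a Glu residue"
                )
            if p in seen:
                raise SiteValidationError(f"{self.id}: duplicate position {p}")
            seen.add(p)
        self.carboxylation_positions = sorted(seen)


@dataclass(frozen=True)
class WindowConfig:
    """Window half-width ``n``; fragments span ``2n+1`` residues.

    The default ``n=7`` (15-mer) is the length selected by the window sweep.
    """

    n: int = 7

    def __post_init__(self) -> None:
        if not 4 <= self.n <= 10:
            raise ValueError(f"window half-width n must be in 4..10, got {self.n}")

    @property
    def window_length(self) -> int:
        return 2 * self.n + 1

    @property
    def offsets(self) -> range:
        """Window offsets -n..+n with 0 at the central Glu."""
        return range(-self.n, self.n + 1)


@dataclass(frozen=True)
class SiteFragment:
    """A ``2n+1`` window centered on a Glu residue, with its class label."""

    protein_id: str
    center: int  # 1-based position of the central Glu in the parent protein
    window: str  # over ALPHABET21 + 'X'; '-' only as contiguous prefix/suffix
    label: Label

    def __post_init__(self) -> None:
        if len(self.window) % 2 != 1:
            raise ValueError("fragment window length must be odd")
        mid = len(self.window) // 2
        if self.window[mid] != "E":
            raise ValueError(
                f"{self.protein_id}@{self.center}: window center must be 'E', "
                f"got '{self.window[mid]}'"
            )
        core = self.window.strip(PAD)
        if PAD in core:
            raise ValueError("padding '-' must be a contiguous prefix/suffix")
        if self.label not in ("positive", "negative"):
            raise ValueError(f"invalid label {self.label!r}")

    @property
    def n(self) -> int:
        return len(self.window) // 2

    @property
    def is_positive(self) -> bool:
        return self.label == "positive"

    @property
    def core(self) -> str:
        """The window with terminal padding stripped."""
        return self.window.strip(PAD)


def _clean_sequence(raw: str) -> str:
    up = raw.upper()
    return "".join(c if c in AMINO_ACIDS else UNKNOWN for c in up)


def read_fasta(path) -> list[ProteinRecord]:
    """Parse a FASTA file into :class:`ProteinRecord` objects (no sites).

    Sequences are uppercased and any symbol outside the 20 standard amino
    acids is mapped to ``'X'``.  The record id is the first
    whitespace-delimited token of the header.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, _clean_sequence(str(rec.seq))))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def read_site_annotations(path, records: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Attach 1-based carboxylation positions from a 2-column TSV.

    Rows are ``protein_id <TAB> position``.  Every position is validated
    against the Glu invariant of the matching record; unknown ids, positions
    outside the sequence, or positions not on an 'E' raise
    :class:`SiteValidationError` naming the offender.
    """
    by_id = {r.id: r for r in records}
    sites: dict[str, list[int]] = {r_id: [] for r_id in by_id}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            pid, pos_str = parts[0], parts[1]
            if pid not in by_id:
                raise SiteValidationError(
                    f"{path}:{lineno}: unknown protein id '{pid}'"
                )
            try:
                pos = int(pos_str)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: position '{pos_str}' is not an integer"
                ) from exc
            sites[pid].append(pos)
    return [
        ProteinRecord(r.id, r.sequence, sites[r.id]) for r in by_id.values()
    ]


def extract_fragments(record: ProteinRecord, cfg: WindowConfig) -> list[SiteFragment]:
    """One fragment per Glu residue; positive iff the center is annotated.

    Non-annotated Glu residues of a carboxylated protein form the negative
    set.  Windows truncated at a terminus are padded with ``'-'``.
    """
    n = cfg.n
    seq = record.sequence
    annotated = set(record.carboxylation_positions)
    fragments: list[SiteFragment] = []
    for i, aa in enumerate(seq, start=1):
        if aa != "E":
            continue
        left = seq[max(0, i - 1 - n) : i - 1]
        right = seq[i : i + n]
        window = PAD * (n - len(left)) + left + "E" + right + PAD * (n - len(right))
        label: Label = "positive" if i in annotated else "negative"
        fragments.append(SiteFragment(record.id, i, window, label))
    return fragments


def extract_all_fragments(
    records: Iterable[ProteinRecord], cfg: WindowConfig
) -> list[SiteFragment]:
    """Concatenated fragments of every record, in record order."""
    out: list[SiteFragment] = []
    for rec in records:
        out.extend(extract_fragments(rec, cfg))
    return out


def write_fragments_tsv(fragments: Iterable[SiteFragment], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcenter\twindow\tlabel\n")
        for f in fragments:
            fh.write(f"{f.protein_id}\t{f.center}\t{f.window}\t{f.label}\n")


def read_fragments_tsv(path) -> list[SiteFragment]:
    fragments: list[SiteFragment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["protein_id", "center", "window", "label"]:
            raise FormatError(f"{path}: unexpected fragment TSV header {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            pid, center, window, label = parts
            fragments.append(SiteFragment(pid, int(center), window, label))  # type: ignore[arg-type]
    return fragments
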