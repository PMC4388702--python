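"""Sequence and site I/O, fragment extraction, and shared domain types.

S-glutathionylation is a cysteine post-translational modification; every
annotated site therefore sits on a 'C' residue.  A candidate site is
represented to the rest of the pipeline as a :class:`SiteFragment` — a
window of ``2n + 1`` residues centred on the cysteine, padded with ``'X'``
where the window runs off either terminus of the protein.

Coordinates are 1-based everywhere in files and reports (the convention of
site nomenclature such as "Cys-73"); window offsets relative to the centre
run from ``-n`` to ``+n`` with the cysteine at offset 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Default half-window size: fragments are 21-mers (offsets -10 .. +10).
DEFAULT_HALF_WINDOW = 10

#: The 20 standard residues in the package's canonical feature order.
#: Glycine first and alanine second, matching the orthogonal binary
#: convention in which G -> 10000000000000000000 and A -> 01...0.
AA_ORDER = "GAVLIPFMWSTCYNQDEKRH"

#: Padding / unknown-residue symbol.
PAD = "X"

#: 21-letter alphabet: the 20 standard residues plus the terminal pad.
ALPHABET21 = AA_ORDER + PAD

#: Ambiguity / non-standard codes normalised to 'X' on input.
NON_STANDARD = set("BZUO*J")

Label = Literal["positive", "negative"]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; the message names the offending entry or line."""


@dataclass(frozen=True)
class Site:
    """A labelled cysteine site: 1-based position and its class label."""

    position: int
    label: Label


@dataclass
class ProteinRecord:
    """A protein sequence with zero or more labelled cysteine sites.

    Invariants (enforced by :meth:`validate`): every site position lies in
    ``[1, len(sequence)]`` and the residue there is ``'C'``.
    """

    accession: str
    sequence: str
    sites: list[Site] = field(default_factory=list)

    def validate(self) -> None:
        for site in self.sites:
            if not 1 <= site.position <= len(self.sequence):
                raise ValueError(
                    f"{self.accession}: site position {site.position} outside "
                    f"sequence of length {len(self.sequence)}"
                )
            if self.sequence[site.position - 1] != "C":
                raise ValueError(
                    f"{self.accession}: residue at position {site.position} is "
                    f"{self.sequence[site.position - 1]!r}, expected 'C'"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteFragment:
    """A ``2n + 1`` residue window centred on a candidate cysteine.

    ``residues`` is over the 21-letter alphabet (20 amino acids plus 'X');
    'X' appears only as a contiguous prefix and/or suffix, filling window
    positions that fall outside the protein.
    """

    accession: str
    position: int
    residues: str
    label: Label
    n: int = DEFAULT_HALF_WINDOW

    def __post_init__(self) -> None:
        if len(self.residues) != 2 * self.n + 1:
            raise ValueError(
                f"fragment length {len(self.residues)} != 2n+1 = {2 * self.n + 1}"
            )
        if self.residues[self.n] != "C":
            raise ValueError(
                f"fragment centre holds {self.residues[self.n]!r}, expected 'C'"
            )
        core = self.residues.strip(PAD)
        if PAD in core:
            raise ValueError("'X' may only pad the fragment ends")

    def residue_at(self, offset: int) -> str:
        """Residue at window offset in ``[-n, +n]`` (0 is the centre cysteine)."""
        return self.residues[self.n + offset]


def window_offsets(n: int = DEFAULT_HALF_WINDOW, include_center: bool = False) -> list[int]:
    """Window offsets -n..+n, by default excluding the invariant centre 0."""
    offsets = list(range(-n, n + 1))
    if not include_center:
        offsets.remove(0)
    return offsets


def _normalize_sequence(accession: str, raw: str) -> str:
    seq = raw.upper()
    bad = sorted(set(seq) & NON_STANDARD)
    if bad:
        logger.warning(
            "%s: non-standard residues %s replaced by 'X'", accession, ",".join(bad)
        )
        for ch in bad:
            seq = seq.replace(ch, PAD)
    unknown = set(seq) - set(ALPHABET21)
    if unknown:
        raise ParseError(
            f"{accession}: unrecognised sequence characters {sorted(unknown)}"
        )
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Sequences are upper-cased; non-standard residue codes (B, Z, U, O, J, *)
    are replaced by 'X' with a logged warning.  An empty file yields an
    empty list; an entry with an empty sequence is a :class:`ParseError`.
    """
    records: list[ProteinRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if not rec.id:
                raise ParseError(f"{path}: FASTA entry with empty header")
            seq = _normalize_sequence(rec.id, str(rec.seq))
            if not seq:
                raise ParseError(f"{path}: entry {rec.id!r} has an empty sequence")
            records.append(ProteinRecord(accession=rec.id, sequence=seq))
    except ValueError as exc:  # Biopython signals malformed FASTA via ValueError
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (inverse of :func:`read_fasta` on normalised input)."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.accession, description="")
        for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_sites(
    path: str | Path, proteins: list[ProteinRecord]
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Attach labelled sites from a TSV (columns accession, position, label).

    Returns new records with sites attached, plus a report DataFrame of
    rejected rows (those whose position does not hold a 'C' in the named
    sequence).  Duplicate (accession, position) rows collapse to the first
    occurrence.  An unknown accession or label is an error.
    """
    table = pd.read_csv(path, sep="\t", dtype={"accession": str})
    required = {"accession", "position", "label"}
    if not required.issubset(table.columns):
        raise ParseError(
            f"{path}: sites TSV must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    by_acc = {rec.accession: rec for rec in proteins}
    sites: dict[str, list[Site]] = {acc: [] for acc in by_acc}
    seen: set[tuple[str, int]] = set()
    rejected: list[dict] = []
    for row in table.itertuples(index=False):
        acc, pos, label = str(row.accession), int(row.position), str(row.label)
        if acc not in by_acc:
            raise ParseError(f"{path}: unknown accession {acc!r}")
        if label not in ("positive", "negative"):
            raise ParseError(f"{path}: invalid label {label!r} for {acc}:{pos}")
        if (acc, pos) in seen:
            continue
        seen.add((acc, pos))
        seq = by_acc[acc].sequence
        if not (1 <= pos <= len(seq)) or seq[pos - 1] != "C":
            residue = seq[pos - 1] if 1 <= pos <= len(seq) else ""
            rejected.append(
                {"accession": acc, "position": pos, "label": label,
                 "residue": residue, "reason": "not a cysteine position"}
            )
            continue
        sites[acc].append(Site(position=pos, label=label))  # type: ignore[arg-type]
    out = [replace_sites(by_acc[acc], sites[acc]) for acc in by_acc]
    report = pd.DataFrame(
        rejected, columns=["accession", "position", "label", "residue", "reason"]
    )
    if len(report):
        logger.warning("%s: rejected %d non-cysteine site rows", path, len(report))
    return out, report


def replace_sites(record: ProteinRecord, sites: list[Site]) -> ProteinRecord:
    """Copy of ``record`` with ``sites`` attached (validated)."""
    rec = ProteinRecord(record.accession, record.sequence, list(sites))
    rec.validate()
    return rec


def extract_fragment(
    protein: ProteinRecord,
    position: int,
    n: int = DEFAULT_HALF_WINDOW,
    label: Label = "negative",
) -> SiteFragment:
    """Extract the ``2n + 1`` window centred on a cysteine at a 1-based position.

    Window positions outside the protein are filled with 'X'.
    """
    seq = protein.sequence
    if not (1 <= position <= len(seq)) or seq[position - 1] != "C":
        raise ValueError(
            f"{protein.accession}: position {position} is not a cysteine"
        )
    idx = position - 1
    left = max(0, idx - n)
    right = min(len(seq), idx + n + 1)
    residues = PAD * (n - (idx - left)) + seq[left:right] + PAD * (n - (right - 1 - idx))
    return SiteFragment(
        accession=protein.accession, position=position,
        residues=residues, label=label, n=n,
    )


def enumerate_cysteines(protein: ProteinRecord) -> list[int]:
    """All 1-based positions holding 'C', in ascending order."""
    return [i + 1 for i, ch in enumerate(protein.sequence) if ch == "C"]


def site_fragments(
    proteins: Iterable[ProteinRecord], n: int = DEFAULT_HALF_WINDOW
) -> list[SiteFragment]:
    """Fragments for every labelled site of every protein, input order preserved."""
    frags: list[SiteFragment] = []
    for rec in proteins:
        for site in rec.sites:
            frags.append(extract_fragment(rec, site.position, n=n, label=site.label))
    return frags
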