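"""Feature encodings mapping a site fragment to a fixed-length numeric vector.

Seven encodings are provided, plus the hybrid that concatenates BLOSUM62
positional scores with amino-acid pair composition (the scheme used for the
final classifier):

==================  =========================  ==========================
scheme              dimension (n = 10)         auxiliary input
==================  =========================  ==========================
binary              (2n+1) x 20 = 420          --
aac                 20                         --
aapc                21 x 21 = 441              --
blosum62            (2n+1) x 20 = 420          bundled BLOSUM62 matrix
blosum62_aapc       420 + 441 = 861            bundled BLOSUM62 matrix
pwm                 2n+1 = 21                  PWM built from training set
pssm                20 x 20 = 400              PSI-BLAST profile
asa                 2n+1 = 21                  per-residue ASA table
==================  =========================  ==========================

Residue order within positional 20-blocks follows
:data:`sglut.seq_data.AA_ORDER` (glycine first, alanine second).  The 'X'
pad contributes zeros to positional encodings and is the 21st symbol of the
pair-composition and PWM alphabets.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seq_data import AA_ORDER, ALPHABET21, PAD, ParseError, SiteFragment

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
_AA21_INDEX = {aa: i for i, aa in enumerate(ALPHABET21)}


@dataclass(frozen=True)
class FeatureVector:
    """An encoded fragment: the values, the scheme name, and its dimension."""

    values: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def dimension(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: 21 rows (20 residues + 'X') by ``w`` columns.

    Each column holds the relative frequencies of the symbols at that window
    position among the fragments the matrix was built from; columns sum to 1.
    """

    matrix: np.ndarray
    w: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (21, self.w):
            raise ValueError(f"PWM shape {m.shape} != (21, {self.w})")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("PWM entries must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV: one row per symbol, columns -n..+n."""
        n = (self.w - 1) // 2
        header = "symbol\t" + "\t".join(str(o) for o in range(-n, n + 1))
        lines = [header]
        for i, sym in enumerate(ALPHABET21):
            lines.append(sym + "\t" + "\t".join(f"{v:.6f}" for v in self.matrix[i]))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class PSSMProfile:
    """A per-residue evolutionary profile for one protein.

    ``scores`` has one row per residue of the protein and 20 columns of
    position-specific scores, column order :data:`AA_ORDER`.
    """

    accession: str
    sequence: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.shape != (len(self.sequence), 20):
            raise ValueError(
                f"{self.accession}: profile shape {s.shape} does not cover "
                f"sequence of length {len(self.sequence)}"
            )


class ASATable:
    """Per-residue solvent-accessibility percentages, keyed by accession."""

    def __init__(self, values: Mapping[str, Sequence[float]]):
        self._values = {acc: np.asarray(v, dtype=float) for acc, v in values.items()}
        for acc, v in self._values.items():
            if (v < 0).any():
                raise ValueError(f"{acc}: negative ASA values")

    def __contains__(self, accession: str) -> bool:
        return accession in self._values

    def __getitem__(self, accession: str) -> np.ndarray:
        return self._values[accession]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ASATable":
        """Read an ASA TSV with columns accession, position (1-based), asa_percent."""
        import pandas as pd

        table = pd.read_csv(path, sep="\t", dtype={"accession": str})
        required = {"accession", "position", "asa_percent"}
        if not required.issubset(table.columns):
            raise ParseError(f"{path}: ASA TSV needs columns {sorted(required)}")
        values: dict[str, np.ndarray] = {}
        for acc, grp in table.groupby("accession", sort=False):
            pos = grp["position"].to_numpy(int)
            if sorted(pos) != list(range(1, len(pos) + 1)):
                raise ParseError(f"{path}: {acc}: positions must be 1..L contiguous")
            arr = np.empty(len(pos))
            arr[pos - 1] = grp["asa_percent"].to_numpy(float)
            values[str(acc)] = arr
        return cls(values)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["accession\tposition\tasa_percent"]
        for acc, arr in self._values.items():
            for i, v in enumerate(arr, start=1):
                lines.append(f"{acc}\t{i}\t{v:.2f}")
        Path(path).write_text("\n".join(lines) + "\n")


@lru_cache(maxsize=1)
def blosum62_matrix():
    """The standard BLOSUM62 substitution matrix, loaded from the bundled file."""
    with resources.as_file(
        resources.files("sglut.data").joinpath("BLOSUM62")
    ) as path:
        return substitution_matrices.read(str(path))


@lru_cache(maxsize=1)
def _blosum62_rows() -> dict[str, np.ndarray]:
    mat = blosum62_matrix()
    rows = {
        aa: np.array([mat[aa, bb] for bb in AA_ORDER], dtype=float)
        for aa in AA_ORDER
    }
    rows[PAD] = np.zeros(20)
    return rows


def encode_binary(fragment: SiteFragment) -> FeatureVector:
    """Orthogonal binary (one-hot) positional coding, dimension (2n+1) x 20.

    Each window position contributes a 20-vector with a single 1 at its
    residue's index; 'X' contributes all zeros.
    """
    w = len(fragment.residues)
    out = np.zeros((w, 20))
    for i, aa in enumerate(fragment.residues):
        if aa != PAD:
            out[i, _AA_INDEX[aa]] = 1.0
    return FeatureVector(out.ravel(), "binary")


def encode_aac(fragment: SiteFragment) -> FeatureVector:
    """Amino-acid composition: 20 occurrence frequencies over the window.

    The denominator is the full window length 2n+1, so 'X' pads dilute the
    composition without occupying any of the 20 entries.
    """
    w = len(fragment.residues)
    out = np.zeros(20)
    for aa in fragment.residues:
        if aa != PAD:
            out[_AA_INDEX[aa]] += 1.0
    return FeatureVector(out / w, "aac")


def encode_aapc(fragment: SiteFragment) -> FeatureVector:
    """Amino-acid pair composition: 441 = 21 x 21 adjacent ordered dipeptide frequencies.

    Entry (a, b) counts window positions i with residue a at i and b at
    i + 1, divided by the 2n adjacent pairs; 'X' participates as the 21st
    symbol, so the entries always sum to 1.
    """
    w = len(fragment.residues)
    out = np.zeros((21, 21))
    for i in range(w - 1):
        a, b = fragment.residues[i], fragment.residues[i + 1]
        out[_AA21_INDEX[a], _AA21_INDEX[b]] += 1.0
    return FeatureVector(out.ravel() / (w - 1), "aapc")


def encode_blosum62(fragment: SiteFragment) -> FeatureVector:
    """Positional BLOSUM62 coding: each position contributes its residue's
    20 substitution scores against the standard residues; 'X' contributes zeros."""
    rows = _blosum62_rows()
    out = np.concatenate([rows[aa] for aa in fragment.residues])
    return FeatureVector(out, "blosum62")


def encode_blosum62_aapc(fragment: SiteFragment) -> FeatureVector:
    """Hybrid coding: BLOSUM62 positional block followed by the AAPC block."""
    values = np.concatenate(
        [encode_blosum62(fragment).values, encode_aapc(fragment).values]
    )
    return FeatureVector(values, "blosum62_aapc")


def build_pwm(fragments: Sequence[SiteFragment]) -> PWM:
    """Relative symbol frequency per window position over a fragment set."""
    if not fragments:
        raise ValueError("cannot build a PWM from an empty fragment set")
    w = len(fragments[0].residues)
    if any(len(f.residues) != w for f in fragments):
        raise ValueError("fragments must share a single window size")
    counts = np.zeros((21, w))
    for frag in fragments:
        for i, aa in enumerate(frag.residues):
            counts[_AA21_INDEX[aa], i] += 1.0
    return PWM(counts / len(fragments), w)


def encode_pwm(fragment: SiteFragment, pwm: PWM) -> FeatureVector:
    """Per-position lookup of the fragment's residues in a training PWM (dimension 2n+1)."""
    if len(fragment.residues) != pwm.w:
        raise ValueError(
            f"fragment window {len(fragment.residues)} != PWM window {pwm.w}"
        )
    out = np.array(
        [pwm.matrix[_AA21_INDEX[aa], i] for i, aa in enumerate(fragment.residues)]
    )
    return FeatureVector(out, "pwm")


# --- PSI-BLAST ASCII profile reader -----------------------------------------
#
# The ASCII PSSM emitted by PSI-BLAST has free-form header lines, then a
# column-header line naming 20 residues (twice, when percentages are
# appended), then one line per residue:
#
#     <index> <residue> <20 integer scores> [...ignored columns...]
#
# No library in the stack parses this dialect, so a small reader lives here.

def read_psiblast_pssm(path: str | Path, accession: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM into a :class:`PSSMProfile`.

    Only the first 20 score columns are consumed.  Scores are re-ordered from
    the file's residue column order into :data:`AA_ORDER`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    col_order: list[str] | None = None
    rows: list[np.ndarray] = []
    sequence: list[str] = []
    expected_index = 1
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if col_order is None:
            if len(tokens) >= 20 and all(t in _AA_INDEX for t in tokens[:20]):
                col_order = tokens[:20]
            continue
        if not tokens:
            continue
        if not tokens[0].lstrip("-").isdigit():
            break  # footer (Lambda/K statistics)
        if len(tokens) < 22:
            raise ParseError(f"{path}:{lineno}: truncated PSSM row")
        index, residue = int(tokens[0]), tokens[1]
        if index != expected_index:
            raise ParseError(
                f"{path}:{lineno}: residue index {index}, expected {expected_index}"
            )
        try:
            scores = np.array([float(t) for t in tokens[2:22]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
        rows.append(scores)
        sequence.append(residue)
        expected_index += 1
    if col_order is None or not rows:
        raise ParseError(f"{path}: no PSSM table found")
    # reorder file columns into canonical AA_ORDER
    perm = [col_order.index(aa) for aa in AA_ORDER]
    scores = np.vstack(rows)[:, perm]
    return PSSMProfile(
        accession=accession or path.stem, sequence="".join(sequence), scores=scores
    )


def encode_pssm(fragment: SiteFragment, profile: PSSMProfile) -> FeatureVector:
    """Collapse the windowed PSSM into a 20 x 20 logistic-normalised matrix.

    The (2n+1) x 20 score window centred on the site ('X' positions
    contribute zero rows) is summed row-wise by the residue type occupying
    each window position, divided by the window length, then squashed
    elementwise through 1 / (1 + e^-x) and flattened to dimension 400.
    Window positions holding 'X' (including genuine pads) are skipped, so
    they add nothing to any residue-type row.
    """
    w = len(fragment.residues)
    n = fragment.n
    center = fragment.position - 1
    collapsed = np.zeros((20, 20))
    for offset in range(-n, n + 1):
        aa = fragment.residue_at(offset)
        if aa == PAD:
            continue
        row = center + offset
        if not 0 <= row < profile.scores.shape[0]:
            raise ValueError(
                f"{fragment.accession}: profile does not cover window offset {offset}"
            )
        collapsed[_AA_INDEX[aa]] += profile.scores[row]
    collapsed /= w
    return FeatureVector((1.0 / (1.0 + np.exp(-collapsed))).ravel(), "pssm")


def encode_asa(fragment: SiteFragment, asa: ASATable) -> FeatureVector:
    """Per-position accessibility percentages scaled to [0, 1]; 'X' positions are 0."""
    if fragment.accession not in asa:
        raise KeyError(f"no ASA values for {fragment.accession}")
    values = asa[fragment.accession]
    n = fragment.n
    center = fragment.position - 1
    out = np.zeros(2 * n + 1)
    for i, offset in enumerate(range(-n, n + 1)):
        if fragment.residue_at(offset) == PAD:
            continue
        out[i] = np.clip(values[center + offset] / 100.0, 0.0, 1.0)
    return FeatureVector(out, "asa")


# --- encoder registry --------------------------------------------------------

#: Fragment-only schemes usable without auxiliary profiles.
SCHEMES: dict[str, Callable[[SiteFragment], FeatureVector]] = {
    "binary": encode_binary,
    "aac": encode_aac,
    "aapc": encode_aapc,
    "blosum62": encode_blosum62,
    "blosum62_aapc": encode_blosum62_aapc,
}


def scheme_dimension(scheme: str, n: int) -> int:
    """Declared output dimension of a scheme at half-window ``n``."""
    w = 2 * n + 1
    dims = {
        "binary": w * 20,
        "aac": 20,
        "aapc": 441,
        "blosum62": w * 20,
        "blosum62_aapc": w * 20 + 441,
        "pwm": w,
        "pssm": 400,
        "asa": w,
    }
    return dims[scheme]


def get_encoder(
    scheme: str,
    training_fragments: Iterable[SiteFragment] | None = None,
) -> Callable[[SiteFragment], np.ndarray]:
    """Return a fragment -> ndarray encoder for a named scheme.

    ``pwm`` requires the positive training fragments the matrix is built
    from; profile-backed schemes (``pssm``, ``asa``) are bound to their
    tables by the caller and are not dispatched here.
    """
    if scheme in SCHEMES:
        fn = SCHEMES[scheme]
        return lambda frag: fn(frag).values
    if scheme == "pwm":
        if training_fragments is None:
            raise ValueError("the pwm scheme requires training fragments")
        pwm = build_pwm(list(training_fragments))
        return lambda frag: encode_pwm(frag, pwm).values
    raise ValueError(f"unknown feature scheme {scheme!r}")
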