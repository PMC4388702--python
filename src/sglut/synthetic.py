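"""Synthetic proteome generator with planted site motifs.

Generates protein sequences, labelled cysteine sites, per-residue ASA
tables, and PSI-BLAST-style profile files — exactly the formats the rest
of the pipeline consumes — with full control over the motif structure of
the positive class.  Each positive site's flanking window is rewritten to
carry one or more planted motifs (a residue group at a fixed offset) with
a configurable penetrance, against an otherwise i.i.d. background; negative
sites keep pure background flanks.

A motif here models a substrate sub-population, not just one residue:
a site that carries a motif (decided per site with the motif's penetrance)
gets the motif residue at the planted offset *and* draws the rest of its
flanking window from a background tilted toward the motif's residue group
(``context_tilt``).  The tilt is what makes a planted motif discoverable by
dependence decomposition: chi-square between two window positions responds
to sub-population structure that is shared across positions, not to a
marginal enrichment at a single column.  At penetrance 0 no site carries a
motif and positive flanks are statistically identical to negative ones.

Labelled sites are spaced at least one full window apart within a protein,
so planted flanks never overlap another labelled site's window.  ASA values
are drawn from truncated normals on [0, 100]: flanks of positive sites get
a higher mean than background (modified sites sit in locally exposed
neighbourhoods), and the site cysteines themselves get a lower mean
(cysteine is the least exposed residue in either class).

Everything derives from one integer seed; a fixed seed reproduces the
output files byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .features import ASATable, PSSMProfile
from .mdd import AAGrouping, GROUP_ORDER
from .seq_data import (
    AA_ORDER,
    DEFAULT_HALF_WINDOW,
    ProteinRecord,
    Site,
    write_fasta,
)

#: Column order of the emitted profile files (the classic PSI-BLAST layout).
_PSSM_COLS = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class MotifSpec:
    """A planted motif: one residue group (or explicit residue set) at one offset.

    ``penetrance`` is the probability that a positive fragment carries the
    motif.
    """

    position: int
    group: str | None = None
    residues: str | None = None
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if (self.group is None) == (self.residues is None):
            raise ValueError("specify exactly one of group or residues")
        if self.group is not None and self.group not in GROUP_ORDER:
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        if self.position == 0:
            raise ValueError("offset 0 is the site cysteine itself")

    def residue_pool(self, grouping: AAGrouping) -> str:
        return self.residues if self.residues is not None else grouping.members(self.group)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic proteome."""

    n_proteins: int = 50
    length_range: tuple[int, int] = (250, 400)
    positives_per_protein: int = 2
    negatives_per_protein: int = 8
    motifs: tuple[MotifSpec, ...] = ()
    #: "exclusive": each positive site is assigned one motif uniformly at
    #: random and carries it with that motif's penetrance (distinct
    #: subpopulations, the regime MDD is built for).  "independent": every
    #: motif is planted independently on every positive site.
    motif_mode: Literal["exclusive", "independent"] = "exclusive"
    #: Weight of the carrier sub-population's compositional shift toward its
    #: motif group: carrier flanks sample from
    #: (1 - tilt) * background + tilt * uniform-over-group.
    context_tilt: float = 0.4
    background: Literal["uniform", "swissprot"] = "uniform"
    n: int = DEFAULT_HALF_WINDOW
    seed: int = 0
    asa_background_mean: float = 42.0
    asa_positive_flank_mean: float = 58.0
    asa_site_mean: float = 25.0
    asa_sd: float = 15.0

    def __post_init__(self) -> None:
        w = 2 * self.n + 1
        for motif in self.motifs:
            if not -self.n <= motif.position <= self.n:
                raise ValueError(
                    f"motif offset {motif.position} outside window [-{self.n}, +{self.n}]"
                )
        sites = self.positives_per_protein + self.negatives_per_protein
        lo = self.length_range[0]
        if lo - self.n - (sites - 1) * w < self.n + 1 + sites:
            raise ValueError(
                "length_range too short to place "
                f"{sites} non-overlapping {w}-mer windows"
            )


def background_frequencies(kind: str = "uniform") -> np.ndarray:
    """Residue sampling probabilities in AA_ORDER order.

    ``swissprot`` loads the bundled table of database-wide residue
    frequencies; ``uniform`` is 1/20 each.
    """
    if kind == "uniform":
        return np.full(20, 1.0 / 20.0)
    if kind == "swissprot":
        text = resources.files("sglut.data").joinpath("background_freqs.tsv").read_text()
        freqs = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#") or line.startswith("residue"):
                continue
            aa, val = line.split("\t")
            freqs[aa] = float(val)
        probs = np.array([freqs[aa] for aa in AA_ORDER])
        return probs / probs.sum()
    raise ValueError(f"unknown background {kind!r}")


@dataclass
class SyntheticData:
    """In-memory result of one generation run."""

    proteins: list[ProteinRecord]
    asa: ASATable
    profiles: dict[str, PSSMProfile]
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def positive_count(self) -> int:
        return sum(
            sum(s.label == "positive" for s in rec.sites) for rec in self.proteins
        )


def _spaced_positions(
    rng: np.random.Generator, k: int, lo: int, hi: int, min_gap: int
) -> list[int]:
    """k sorted positions in [lo, hi] with consecutive gaps >= min_gap."""
    span_hi = hi - (k - 1) * min_gap
    base = rng.choice(np.arange(lo, span_hi + 1), size=k, replace=False)
    base.sort()
    return [int(b + i * min_gap) for i, b in enumerate(base)]


def generate_records(config: SyntheticConfig) -> SyntheticData:
    """Sample a proteome under the configured conditions (in memory)."""
    rng = np.random.default_rng(config.seed)
    grouping = AAGrouping.default()
    probs = background_frequencies(config.background)
    aa_array = np.array(list(AA_ORDER))
    n = config.n
    w = 2 * n + 1
    n_sites = config.positives_per_protein + config.negatives_per_protein

    proteins: list[ProteinRecord] = []
    asa_values: dict[str, np.ndarray] = {}
    profiles: dict[str, PSSMProfile] = {}

    for pi in range(config.n_proteins):
        acc = f"SYN{pi + 1:04d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = rng.choice(aa_array, size=length, p=probs)
        positions = _spaced_positions(
            rng, n_sites, lo=n + 1, hi=length - n, min_gap=w
        )
        which_positive = rng.permutation(n_sites) < config.positives_per_protein
        sites: list[Site] = []
        for pos, is_pos in zip(positions, which_positive):
            seq[pos - 1] = "C"
            label = "positive" if is_pos else "negative"
            sites.append(Site(position=pos, label=label))
            if is_pos and config.motifs:
                if config.motif_mode == "exclusive":
                    chosen = [config.motifs[int(rng.integers(len(config.motifs)))]]
                else:
                    chosen = list(config.motifs)
                carried = [m for m in chosen if rng.random() < m.penetrance]
                if carried:
                    # carrier sub-population: re-draw the flanking window
                    # from the tilted background, then fix the motif
                    # residues themselves
                    flank_probs = probs.copy()
                    for motif in carried:
                        pool = motif.residue_pool(grouping)
                        pool_probs = np.array(
                            [1.0 / len(pool) if aa in pool else 0.0 for aa in AA_ORDER]
                        )
                        flank_probs = (
                            (1.0 - config.context_tilt) * flank_probs
                            + config.context_tilt * pool_probs
                        )
                    planted = {m.position for m in carried}
                    for off in range(-n, n + 1):
                        if off == 0 or off in planted:
                            continue
                        seq[pos - 1 + off] = rng.choice(aa_array, p=flank_probs)
                    for motif in carried:
                        pool = motif.residue_pool(grouping)
                        seq[pos - 1 + motif.position] = pool[
                            int(rng.integers(len(pool)))
                        ]
        sequence = "".join(seq)
        rec = ProteinRecord(accession=acc, sequence=sequence, sites=sorted(
            sites, key=lambda s: s.position
        ))
        rec.validate()
        proteins.append(rec)

        # ASA: background mean everywhere, raised in positive-site flanks,
        # lowered at the site cysteines themselves.
        means = np.full(length, config.asa_background_mean)
        for site in rec.sites:
            if site.label == "positive":
                lo_i = max(0, site.position - 1 - n)
                hi_i = min(length, site.position + n)
                means[lo_i:hi_i] = config.asa_positive_flank_mean
        for site in rec.sites:
            means[site.position - 1] = config.asa_site_mean
        a = (0.0 - means) / config.asa_sd
        b = (100.0 - means) / config.asa_sd
        asa_values[acc] = truncnorm.rvs(
            a, b, loc=means, scale=config.asa_sd, random_state=rng
        )

        # Profile scores echo the realised sequence (self-conservation) with
        # small integer noise, so planted motif residues score high at their
        # planted positions.
        scores = np.full((length, 20), -1.0)
        for i, aa in enumerate(sequence):
            scores[i, AA_ORDER.index(aa)] = 4.0
        scores += rng.integers(-1, 2, size=scores.shape)
        profiles[acc] = PSSMProfile(accession=acc, sequence=sequence, scores=scores)

    return SyntheticData(
        proteins=proteins, asa=ASATable(asa_values), profiles=profiles, config=config
    )


def write_pssm_ascii(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII PSSM dialect."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(_PSSM_COLS) + "   " + "  ".join(_PSSM_COLS),
    ]
    order = [AA_ORDER.index(aa) for aa in _PSSM_COLS]
    for i, aa in enumerate(profile.sequence):
        scores = profile.scores[i][order]
        score_str = " ".join(f"{int(s):3d}" for s in scores)
        pct_str = " ".join(f"{0:3d}" for _ in range(20))
        lines.append(f"{i + 1:5d} {aa}  {score_str}  {pct_str}")
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def generate(config: SyntheticConfig, outdir: str | Path) -> SyntheticData:
    """Generate a proteome and write it to ``outdir``.

    Emits ``proteins.fasta``, ``sites.tsv``, ``asa.tsv``, and one
    ``pssm/<accession>.pssm`` per protein.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_records(config)
    write_fasta(data.proteins, outdir / "proteins.fasta")
    rows = [
        {"accession": rec.accession, "position": site.position, "label": site.label}
        for rec in data.proteins
        for site in rec.sites
    ]
    pd.DataFrame(rows, columns=["accession", "position", "label"]).to_csv(
        outdir / "sites.tsv", sep="\t", index=False
    )
    data.asa.to_tsv(outdir / "asa.tsv")
    pssm_dir = outdir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for acc, profile in data.profiles.items():
        write_pssm_ascii(profile, pssm_dir / f"{acc}.pssm")
    return data
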