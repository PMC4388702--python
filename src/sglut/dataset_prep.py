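"""Training-set construction: negative balancing, homology reduction, deduplication.

Experimentally identified glutathionylation sites are heavily outnumbered
by the unmodified cysteines on the same proteins.  Rather than discarding
negatives at random, :func:`kmeans_balance` clusters the negative fragments
(K set to the positive count) and keeps one representative per cluster, so
the retained subset spans the diversity of the full negative pool.

Homology between a training set and an independent test set inflates
apparent performance; :func:`reduce_homology` removes test-set sites whose
surrounding fragment is identical to a training fragment on a homologous
protein (protein-level identity above 30% from a global alignment with
BLOSUM62 scoring).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from sklearn.cluster import KMeans

from .features import blosum62_matrix, encode_binary
from .seq_data import (
    DEFAULT_HALF_WINDOW,
    ProteinRecord,
    SiteFragment,
    extract_fragment,
    site_fragments,
)


@dataclass(frozen=True)
class BalancedDataset:
    """Equal-sized positive and negative fragment sets plus the balancing seed."""

    positives: list[SiteFragment]
    negatives: list[SiteFragment]
    seed: int

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError(
                f"unbalanced dataset: {len(self.positives)} positives vs "
                f"{len(self.negatives)} negatives"
            )

    @property
    def fragments(self) -> list[SiteFragment]:
        return list(self.positives) + list(self.negatives)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {"accession": f.accession, "position": f.position,
             "label": f.label, "fragment": f.residues}
            for f in self.fragments
        ]
        return pd.DataFrame(rows, columns=["accession", "position", "label", "fragment"])


def _embed(fragments: Sequence[SiteFragment]) -> np.ndarray:
    """One-hot embedding: squared Euclidean distance is twice the mismatch count."""
    return np.vstack([encode_binary(f).values for f in fragments])


def kmeans_balance(
    negatives: Sequence[SiteFragment], k: int, seed: int
) -> list[SiteFragment]:
    """Select ``k`` representative fragments by K-means on one-hot embeddings.

    Each cluster contributes the member nearest its centroid (ties broken by
    input order).  K-means can leave clusters empty; those slots are
    backfilled greedily with the unchosen fragments farthest (max-min
    distance) from the representatives already selected, so the output size
    is exactly ``k``.  Deterministic for a fixed seed and input order.
    """
    if k > len(negatives):
        raise ValueError(f"k={k} exceeds negative pool of {len(negatives)}")
    if k == len(negatives):
        return list(negatives)
    X = _embed(negatives)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    chosen: list[int] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if len(members) == 0:
            continue
        d = ((X[members] - km.cluster_centers_[c]) ** 2).sum(axis=1)
        chosen.append(int(members[np.argmin(d)]))  # argmin keeps first on ties
    if len(chosen) < k:
        remaining = [i for i in range(len(negatives)) if i not in set(chosen)]
        while len(chosen) < k:
            dmin = np.array([
                ((X[i] - X[chosen]) ** 2).sum(axis=1).min() for i in remaining
            ])
            pick = remaining.pop(int(np.argmax(dmin)))
            chosen.append(pick)
    return [negatives[i] for i in sorted(chosen)]


def balance_dataset(
    proteins: Sequence[ProteinRecord],
    seed: int,
    n: int = DEFAULT_HALF_WINDOW,
) -> BalancedDataset:
    """Extract site fragments and balance negatives to the positive count.

    Negatives come only from the labelled negative cysteines on the same
    (positive-bearing) proteins.
    """
    frags = dedupe_sites(site_fragments(proteins, n=n))
    positives = [f for f in frags if f.label == "positive"]
    negatives = [f for f in frags if f.label == "negative"]
    if not positives:
        raise ValueError("no positive sites in the input")
    kept = kmeans_balance(negatives, k=len(positives), seed=seed)
    return BalancedDataset(positives=positives, negatives=kept, seed=seed)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = blosum62_matrix()
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global BLOSUM62 alignment (gap open -11 / extend -1).

    Identity is matched columns over total alignment length (gap columns
    included), as a percentage.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(seq_a, seq_b)[0]
    gapped_a, gapped_b = str(alignment[0]), str(alignment[1])
    matches = sum(a == b and a != "-" for a, b in zip(gapped_a, gapped_b))
    return 100.0 * matches / len(gapped_a)


def reduce_homology(
    train: Sequence[ProteinRecord],
    test: Sequence[ProteinRecord],
    protein_threshold: float = 30.0,
    n: int = DEFAULT_HALF_WINDOW,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Drop test sites whose fragment duplicates a training fragment on a homolog.

    For every (train, test) protein pair with identity strictly above
    ``protein_threshold`` percent, site fragments (same half-window ``n``)
    are compared; a test fragment string identical to a training fragment
    string is removed from the test set.  The training set is never
    modified.  Returns the filtered test records and a removal report.
    """
    train_frag_index: dict[str, list[tuple[str, int]]] = {}
    train_by_acc = {rec.accession: rec for rec in train}
    for frag in site_fragments(train, n=n):
        train_frag_index.setdefault(frag.residues, []).append(
            (frag.accession, frag.position)
        )
    removals: list[dict] = []
    filtered: list[ProteinRecord] = []
    for test_rec in test:
        homologs = [
            rec for rec in train_by_acc.values()
            if pairwise_identity(rec.sequence, test_rec.sequence) > protein_threshold
        ]
        if not homologs or not test_rec.sites:
            filtered.append(test_rec)
            continue
        homolog_accs = {rec.accession for rec in homologs}
        kept_sites = []
        for site in test_rec.sites:
            residues = extract_fragment(test_rec, site.position, n=n).residues
            hits = [
                (acc, pos) for acc, pos in train_frag_index.get(residues, [])
                if acc in homolog_accs
            ]
            if hits:
                removals.append({
                    "test_accession": test_rec.accession,
                    "test_position": site.position,
                    "label": site.label,
                    "train_accession": hits[0][0],
                    "train_position": hits[0][1],
                })
            else:
                kept_sites.append(site)
        filtered.append(ProteinRecord(test_rec.accession, test_rec.sequence, kept_sites))
    report = pd.DataFrame(
        removals,
        columns=["test_accession", "test_position", "label",
                 "train_accession", "train_position"],
    )
    return filtered, report


def dedupe_sites(fragments: Sequence[SiteFragment]) -> list[SiteFragment]:
    """Keep the first fragment per (accession, position); order preserved."""
    seen: set[tuple[str, int]] = set()
    out: list[SiteFragment] = []
    for frag in fragments:
        key = (frag.accession, frag.position)
        if key in seen:
            continue
        seen.add(key)
        out.append(frag)
    return out
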