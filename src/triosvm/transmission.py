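"""Per-site transmission-distortion scores: the SVM feature space.

Each trio-site pair is scored as observed minus Mendelian-expected rare-allele
transmission given the two parental genotypes, the conditioning used by
family-based association tests.  Under additive coding a parent carrying g
rare alleles transmits g/2 in expectation, so the score is
``child - (father + mother) / 2`` with range {-1, -0.5, 0, +0.5, +1} and zero
mean over the Mendelian offspring distribution.  Only heterozygous parents can
produce a nonzero score, which is what makes the encoding immune to population
stratification: allele-frequency differences between subpopulations shift
parental genotypes, not transmission distortion.

For case-control data without parents the same machinery is used on raw
rare-allele counts per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .pedio import MISSING, GenotypeTable, Trio

log = logging.getLogger(__name__)


class UntestableGeneError(ValueError):
    """Raised when no informative score columns survive for a gene."""


@dataclass
class ScoreMatrix:
    """N rows x M informative columns of features, with class labels.

    ``labels`` uses the SVM vertex convention: -1 affected, +1 unaffected.
    In trio mode every value lies in [-1, 1]; in case-control mode values are
    rare-allele counts.  Zero-variance columns are removed on construction by
    the builders, never silently here.
    """

    values: np.ndarray
    labels: np.ndarray
    site_ids: list[str]
    trio_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, m = self.values.shape
        if len(self.labels) != n or len(self.trio_ids) != n or len(self.site_ids) != m:
            raise ValueError("inconsistent ScoreMatrix dimensions")
        if not np.isin(self.labels, (-1, 1)).all():
            raise ValueError("labels must be -1 or +1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class TransmissionQC:
    """Per-gene accounting of removed sites and zeroed trio-site pairs."""

    n_sites_input: int = 0
    n_sites_removed: int = 0
    n_missing_parent: int = 0
    n_missing_child: int = 0
    n_mendel_inconsistent: int = 0


def expected_transmission(parent_count: int) -> float:
    """Mendelian expectation of rare alleles transmitted by one parent."""
    if parent_count not in (0, 1, 2):
        raise ValueError(f"parent count must be 0, 1 or 2, got {parent_count}")
    return parent_count / 2.0


def trio_site_score(father_g: int, mother_g: int, child_g: int) -> float:
    """Observed minus expected transmission for one trio at one site.

    Missing child genotype and Mendelian-inconsistent combinations score 0
    (uninformative); matrix construction counts them in the QC report.
    Parental counts must be non-missing here — use the matrix builder for
    data with missing parents.
    """
    for g in (father_g, mother_g):
        if g not in (0, 1, 2):
            raise ValueError(f"parental count must be 0, 1 or 2, got {g}")
    if child_g == MISSING:
        return 0.0
    if child_g not in (0, 1, 2):
        raise ValueError(f"child count must be 0, 1, 2 or missing, got {child_g}")
    lo = (father_g == 2) + (mother_g == 2)
    hi = (father_g >= 1) + (mother_g >= 1)
    if not lo <= child_g <= hi:
        return 0.0  # Mendelian inconsistency
    return child_g - (father_g + mother_g) / 2.0


def _score_arrays(
    F: np.ndarray, M: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, TransmissionQC]:
    """Vectorised scoring with missing / inconsistency bookkeeping."""
    for arr in (F, M, C):
        if not np.isin(arr, (0, 1, 2, MISSING)).all():
            raise ValueError("genotype counts must be in {0, 1, 2} or missing")
    miss_par = (F == MISSING) | (M == MISSING)
    miss_child = (C == MISSING) & ~miss_par
    valid = ~miss_par & ~miss_child
    lo = (F == 2).astype(int) + (M == 2).astype(int)
    hi = (F >= 1).astype(int) + (M >= 1).astype(int)
    incons = valid & ((C < lo) | (C > hi))
    X = C.astype(float) - (F + M) / 2.0
    X[~valid | incons] = 0.0
    qc = TransmissionQC(
        n_missing_parent=int(miss_par.sum()),
        n_missing_child=int(miss_child.sum()),
        n_mendel_inconsistent=int(incons.sum()),
    )
    return X, qc


def _drop_noninformative(X: np.ndarray, site_ids: list[str]) -> tuple[np.ndarray, list[str], int]:
    keep = np.ptp(X, axis=0) > 0
    removed = int((~keep).sum())
    return X[:, keep], [s for s, k in zip(site_ids, keep) if k], removed


def build_score_matrix(
    trios: list[Trio], site_indices: list[int]
) -> tuple[ScoreMatrix, TransmissionQC]:
    """Score every trio at the selected sites and drop noninformative columns.

    A column is noninformative when its score is constant across trios, which
    subsumes "no rare allele transmitted" (no heterozygous parent anywhere).
    Raises :class:`UntestableGeneError` when nothing survives.
    """
    if not trios:
        raise ValueError("no trios supplied")
    idx = np.asarray(site_indices, dtype=int)
    F = np.stack([t.father_g[idx] for t in trios]).astype(np.int16)
    M = np.stack([t.mother_g[idx] for t in trios]).astype(np.int16)
    C = np.stack([t.child_g[idx] for t in trios]).astype(np.int16)
    X, qc = _score_arrays(F, M, C)
    qc.n_sites_input = len(site_indices)

    site_ids = [f"site{j}" for j in site_indices]
    X, site_ids, qc.n_sites_removed = _drop_noninformative(X, site_ids)
    if X.shape[1] == 0:
        raise UntestableGeneError(
            f"all {qc.n_sites_input} sites noninformative (no transmission variance)"
        )
    labels = np.array([t.label for t in trios])
    sm = ScoreMatrix(X, labels, site_ids, [t.child_id for t in trios])
    return sm, qc


def case_control_encode(
    table: GenotypeTable, site_indices: list[int]
) -> tuple[ScoreMatrix, TransmissionQC]:
    """Encode unrelated individuals by raw rare-allele counts per site.

    The case-control analogue of the trio encoding: rows are individuals with
    a known affection status, values are counts in {0, 1, 2} (missing -> 0),
    labels -1 affected / +1 unaffected, zero-variance columns removed.
    """
    s = table.samples
    rows = [i for i, a in enumerate(s["affection"]) if a is not None]
    if not rows:
        raise ValueError("no individuals with known affection status")
    idx = np.asarray(site_indices, dtype=int)
    X = table.genotypes[np.ix_(rows, idx)].astype(float)
    qc = TransmissionQC(
        n_sites_input=len(site_indices),
        n_missing_child=int((X == MISSING).sum()),
    )
    X[X == MISSING] = 0.0

    site_ids = [f"site{j}" for j in site_indices]
    X, site_ids, qc.n_sites_removed = _drop_noninformative(X, site_ids)
    if X.shape[1] == 0:
        raise UntestableGeneError(
            f"all {qc.n_sites_input} sites noninformative (no count variance)"
        )
    labels = np.array(
        [-1 if s["affection"].iloc[i] else +1 for i in rows]
    )
    ids = [
        f"{s['family_id'].iloc[i]}:{s['individual_id'].iloc[i]}" for i in rows
    ]
    sm = ScoreMatrix(X, labels, site_ids, ids)
    return sm, qc
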