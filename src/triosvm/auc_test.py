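"""Gene-level AUC test on composite SVM scores, and the per-gene pipeline.

The composite scores of affected and unaffected children are compared with
the Mann-Whitney AUC statistic theta: the probability that a randomly chosen
case shows more transmission distortion than a randomly chosen control, ties
counted one half.  The null is theta <= 0.5 against the one-sided alternative
theta > 0.5; the test statistic is z = (theta - 0.5) / SE(theta), treated as
standard normal.  The standard error is the DeLong placement-value estimator:

    SE^2 = S10 / n1 + S01 / n0,

where S10 is the sample variance over cases of the fraction of controls each
case beats (ties half) and S01 is the symmetric quantity over controls.  It
is distribution-free and invariant to monotone transforms of the scores, as
is theta itself.

Orientation: the SVM assigns vertex -1 to affected children, so its decision
scores are negated before the AUC — greater distortion among cases then maps
to theta > 0.5, matching the one-sided alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .pedio import (
    GeneRegion,
    GenotypeTable,
    compute_maf,
    extract_trios,
    select_sites,
    trios_to_table,
)
from .svm_core import KernelConfig, _penalty_search, solve_dual
from .transmission import (
    TransmissionQC,
    UntestableGeneError,
    build_score_matrix,
    case_control_encode,
)

log = logging.getLogger(__name__)


@dataclass
class AucResult:
    """One gene's test output, mirroring a results-table row."""

    gene: str
    n_case: int = 0
    n_control: int = 0
    n_sites_input: int = 0
    n_sites_used: int = 0
    penalty_chosen: float = np.nan
    theta_hat: float = np.nan
    se: float = np.nan
    z: float = np.nan
    p_one_sided: float = np.nan
    reason: str = ""
    qc: TransmissionQC | None = None

    @property
    def testable(self) -> bool:
        return self.reason == ""


def auc_mann_whitney(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """AUC over all (case, control) pairs: wins 1, ties 1/2, losses 0.

    Computed via midranks, which is exactly the normalised pair count.
    """
    case = np.asarray(case_scores, float)
    control = np.asarray(control_scores, float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both score groups must be nonempty")
    ranks = rankdata(np.concatenate([case, control]))
    r1 = ranks[: case.size].sum()
    n1, n0 = case.size, control.size
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _placements(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-case fraction of controls beaten and the symmetric control values."""
    gt = case[:, None] > control[None, :]
    eq = case[:, None] == control[None, :]
    case_pl = (gt + 0.5 * eq).mean(axis=1)
    control_pl = ((~gt & ~eq) + 0.5 * eq).mean(axis=0)
    return case_pl, control_pl


def auc_se(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """DeLong standard error of the AUC; 0 signals a degenerate configuration
    (e.g. perfect separation or all-tied scores), where the Gaussian
    asymptotics do not apply."""
    case = np.asarray(case_scores, float)
    control = np.asarray(control_scores, float)
    if case.size < 2 or control.size < 2:
        raise ValueError("need at least 2 scores per group for a standard error")
    case_pl, control_pl = _placements(case, control)
    s10 = case_pl.var(ddof=1)
    s01 = control_pl.var(ddof=1)
    return float(np.sqrt(s10 / case.size + s01 / control.size))


def auc_z_test(theta_hat: float, se: float) -> tuple[float, float]:
    """One-sided Gaussian test of theta <= 0.5 against theta > 0.5."""
    if not np.isfinite(se) or se <= 0:
        raise ValueError("standard error must be positive (degenerate input)")
    z = (theta_hat - 0.5) / se
    return float(z), float(norm.sf(z))


def cross_validated_auc(
    oriented_scores: np.ndarray, labels: np.ndarray, fold_ids: np.ndarray
) -> tuple[float, float]:
    """AUC of out-of-fold scores with a dependence-aware standard error.

    The AUC is computed within each fold (each fold's scores come from one
    model, so the DeLong estimator applies there) and averaged.  Fold AUCs
    are positively correlated: every fold's model is trained on largely the
    same data, so all of them partially track the same accidental
    label-feature alignments.  Treating them as independent understates the
    variance of the averaged AUC; the combined variance is therefore inflated
    by the cross-validation correction factor

        1 + (F - 1) * n_test / n_train  =  2   (for equal-sized folds),

    after Nadeau & Bengio's corrected resampled estimator.  Without it, a
    null simulation at these sample sizes rejects at roughly twice the
    nominal rate.

    Returns (theta_hat, se); se is 0 when every fold is degenerate.
    """
    oriented_scores = np.asarray(oriented_scores, float)
    labels = np.asarray(labels)
    fold_ids = np.asarray(fold_ids)
    case = labels == -1
    folds = np.unique(fold_ids)
    thetas, variances = [], []
    for f in folds:
        m = fold_ids == f
        c = oriented_scores[m & case]
        u = oriented_scores[m & ~case]
        thetas.append(auc_mann_whitney(c, u))
        variances.append(auc_se(c, u) ** 2)
    n_folds = len(folds)
    theta = float(np.mean(thetas))
    correction = 2.0  # 1 + (F-1) * (1/(F-1)); equal-sized CV folds
    se = float(np.sqrt(correction * np.sum(variances)) / n_folds)
    return theta, se


def gene_test(
    data,
    region: GeneRegion,
    maf_threshold: float,
    config: KernelConfig | None = None,
    mode: str = "trio",
    resubstitution: bool = False,
) -> AucResult:
    """Run the full per-gene pipeline and return a populated result row.

    ``data`` is a :class:`GenotypeTable` (trios are extracted from it in trio
    mode) or, in trio mode, a list of :class:`Trio` built elsewhere.  An
    untestable gene (no rare sites, no informative columns, classes too small
    for the folds, or degenerate SE) yields a result with ``p_one_sided`` NaN
    and a reason code — never an exception.

    ``resubstitution`` scores the training data with a full-data refit at the
    selected C instead of out-of-fold scores; it exists for comparison only,
    since resubstitution AUCs of a Gaussian SVM are optimistically biased.
    """
    if config is None:
        config = KernelConfig()
    if mode not in ("trio", "case_control"):
        raise ValueError(f"unknown mode {mode!r}")

    if isinstance(data, GenotypeTable):
        table = data
    else:
        if mode != "trio":
            raise ValueError("case_control mode requires a GenotypeTable")
        table = trios_to_table(list(data), chromosome=region.chromosome)
    if any(s.maf is None for s in table.sites):
        compute_maf(table)

    result = AucResult(gene=region.gene)
    idx = select_sites(table, region, maf_threshold)
    result.n_sites_input = len(idx)
    if not idx:
        result.reason = "no_rare_sites"
        return result

    try:
        if mode == "trio":
            trios = extract_trios(table)
            if not trios:
                result.reason = "no_trios"
                return result
            features, qc = build_score_matrix(trios, idx)
        else:
            features, qc = case_control_encode(table, idx)
    except UntestableGeneError:
        result.reason = "no_informative_sites"
        return result
    result.qc = qc
    result.n_sites_used = features.m
    result.n_case = int((features.labels == -1).sum())
    result.n_control = int((features.labels == +1).sum())
    # each fold needs >= 2 scores per class for its DeLong variance
    if min(result.n_case, result.n_control) < 2 * config.folds:
        result.reason = "too_few_per_class"
        return result

    search = _penalty_search(features, config)
    result.penalty_chosen = search.chosen_penalty
    scores = search.scores_by_penalty[search.chosen_penalty]
    oriented = -scores
    case = features.labels == -1
    if resubstitution:
        model = solve_dual(
            search.kernel, features.labels, search.chosen_penalty,
            rows=features.values, sigma2=config.sigma2,
        )
        oriented = -((model.alphas * features.labels) @ search.kernel + model.offset)
        result.theta_hat = auc_mann_whitney(oriented[case], oriented[~case])
        result.se = auc_se(oriented[case], oriented[~case])
    else:
        result.theta_hat, result.se = cross_validated_auc(
            oriented, features.labels, search.fold_ids
        )
    if result.se <= 0:
        result.reason = "degenerate_se"
        return result
    result.z, result.p_one_sided = auc_z_test(result.theta_hat, result.se)
    return result


def results_to_frame(results: list[AucResult]) -> pd.DataFrame:
    """Tabulate per-gene results in the layout of a published results table."""
    cols = [
        "gene", "n_case", "n_control", "n_sites_input", "n_sites_used",
        "penalty_chosen", "theta_hat", "se", "z", "p_one_sided", "reason",
    ]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in results], columns=cols
    )


def qc_to_frame(results: list[AucResult]) -> pd.DataFrame:
    """Per-gene QC counts: sites read/removed, inconsistencies, zeroings."""
    rows = []
    for r in results:
        qc = r.qc or TransmissionQC()
        rows.append(
            {
                "gene": r.gene,
                "n_sites_input": qc.n_sites_input,
                "n_sites_removed_noninformative": qc.n_sites_removed,
                "n_mendel_inconsistent": qc.n_mendel_inconsistent,
                "n_missing_parent_zeroed": qc.n_missing_parent,
                "n_missing_child_zeroed": qc.n_missing_child,
            }
        )
    return pd.DataFrame(rows)
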