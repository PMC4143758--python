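"""Synthetic trio generator and the type-I-error / power experiment harness.

The generator emulates the statistical structure the trio test assumes:

* per-site minor-allele frequencies drawn uniformly from a configurable rare
  spectrum (0.001-0.03 by default, the rarer of the two published filters);
* parental genotypes Binomial(2, MAF) under Hardy-Weinberg equilibrium,
  children receiving one allele per parent with probability count/2
  (Mendelian transmission);
* a logistic disease model on the child's causal-allele counts,
  P(affected) = expit(baseline + sum_j beta_j * count_j), with mixed-sign
  effects allowed so individual rare variants may confer risk or protection;
* ascertainment: trios are drawn until quotas of affected-child ("case") and
  unaffected-child ("control") trios are filled — 66 and 209 by default, the
  published sample shape;
* optional two-subpopulation stratification: draws alternate between
  subpopulations whose MAF vectors differ by a multiplier and whose baseline
  log-odds may differ, the stress test a transmission-based statistic should
  shrug off;
* bootstrap resampling of whole trios (label-preserving) to larger counts.

The experiment harness runs the full gene test on independent replicates and
reports rejection rates: with causal effects a power estimate, with none a
type-I-error estimate — the same harness for both, as in the published
design.  Replicate seeds derive deterministically from (master seed,
replicate index), so runs are reproducible and order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.special import expit

from .auc_test import AucResult, gene_test
from .pedio import GeneRegion, Trio, trios_to_table
from .svm_core import KernelConfig

log = logging.getLogger(__name__)


class AscertainmentError(RuntimeError):
    """Quotas could not be filled within the draw cap."""

    def __init__(self, n_case: int, n_control: int, cap: int):
        self.achieved = (n_case, n_control)
        super().__init__(
            f"draw cap {cap} exceeded with {n_case} case / {n_control} control "
            "trios ascertained; check baseline_logodds"
        )


@dataclass
class SimConfig:
    """Generative model for one gene's worth of trio data.

    Defaults reproduce the published experimental shape: 50 rare sites with
    MAF uniform on [0.001, 0.03], no causal effects (a null gene), and
    ascertainment to 66 affected-child and 209 unaffected-child trios.
    ``baseline_logodds`` = logit(0.2) puts disease prevalence near the
    affected fraction of that sample.  ``effect_sizes`` are per-causal-site
    log odds ratios (mixed signs welcome) and must have length ``n_causal``.
    """

    n_sites: int = 50
    maf_low: float = 0.001
    maf_high: float = 0.03
    n_causal: int = 0
    effect_sizes: tuple = ()
    baseline_logodds: float = -1.3863  # logit(0.2)
    n_case_trios: int = 66
    n_control_trios: int = 209
    n_subpops: int = 1
    subpop_maf_multiplier: float = 1.0
    subpop_logodds_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if not 0 <= self.n_causal <= self.n_sites:
            raise ValueError("n_causal must be between 0 and n_sites")
        if len(self.effect_sizes) != self.n_causal:
            raise ValueError("effect_sizes must have length n_causal")
        if self.n_case_trios < 0 or self.n_control_trios < 0:
            raise ValueError("trio quotas must be nonnegative")
        if self.n_subpops not in (1, 2):
            raise ValueError("n_subpops must be 1 or 2")
        if self.subpop_maf_multiplier <= 0:
            raise ValueError("subpop_maf_multiplier must be positive")


@dataclass
class ExperimentResult:
    """Rejection rates (one per alpha level) with Monte-Carlo uncertainty."""

    replicates: int
    alpha_levels: tuple
    rejection_rates: np.ndarray
    mc_se: np.ndarray
    n_na: int = 0
    p_values: np.ndarray = field(default_factory=lambda: np.array([]))
    theta_hats: np.ndarray = field(default_factory=lambda: np.array([]))
    penalties: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "alpha": list(self.alpha_levels),
                "rejection_rate": self.rejection_rates,
                "mc_se": self.mc_se,
                "replicates_used": self.replicates - self.n_na,
            }
        )


def simulate_gene(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-site MAFs and the full-length causal-effect vector.

    Causal sites are chosen uniformly without replacement; noncausal sites
    get effect 0.  Deterministic given the config seed (or supplied rng).
    """
    rng = default_rng(config.seed) if rng is None else rng
    mafs = rng.uniform(config.maf_low, config.maf_high, size=config.n_sites)
    effects = np.zeros(config.n_sites)
    if config.n_causal:
        causal = rng.choice(config.n_sites, size=config.n_causal, replace=False)
        effects[causal] = np.asarray(config.effect_sizes, float)
    return mafs, effects


def _draw_batch(
    p: np.ndarray,
    effects: np.ndarray,
    baseline: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised draw of B trios: parental HWE genotypes, Mendelian
    transmission, logistic affection.  ``p`` is (B, M) of per-row MAFs and
    ``baseline`` length-B log odds."""
    F = rng.binomial(2, p)
    M = rng.binomial(2, p)
    C = rng.binomial(1, F / 2.0) + rng.binomial(1, M / 2.0)
    risk = baseline + C @ effects
    affected = rng.random(p.shape[0]) < expit(risk)
    return F.astype(np.int8), M.astype(np.int8), C.astype(np.int8), affected


def simulate_trio(
    mafs: np.ndarray,
    effects: np.ndarray,
    baseline_logodds: float,
    rng: np.random.Generator,
    trio_id: str = "T0",
) -> Trio:
    """Draw a single trio (parents under HWE, child by Mendelian transmission,
    affection from the logistic liability model)."""
    mafs = np.asarray(mafs, float)
    F, M, C, affected = _draw_batch(
        mafs[None, :], np.asarray(effects, float),
        np.array([baseline_logodds]), rng,
    )
    return Trio(
        child_id=f"{trio_id}:3",
        father_id=f"{trio_id}:1",
        mother_id=f"{trio_id}:2",
        child_g=C[0],
        father_g=F[0],
        mother_g=M[0],
        affected=bool(affected[0]),
    )


def _subpop_mafs(config: SimConfig, mafs: np.ndarray) -> np.ndarray:
    """(n_subpops, M) MAF matrix; subpopulation 1 scaled and clipped at 0.5."""
    if config.n_subpops == 1:
        return mafs[None, :]
    scaled = np.clip(mafs * config.subpop_maf_multiplier, 0.0, 0.5)
    return np.stack([mafs, scaled])


def simulate_trio_sample(
    config: SimConfig,
    mafs: np.ndarray | None = None,
    effects: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[Trio]:
    """Ascertain trios into the case and control quotas.

    Draws alternate between subpopulations when ``n_subpops`` is 2.  Trios
    are accepted into whichever quota their child's affection status fills,
    discarded once that quota is full.  Raises :class:`AscertainmentError`
    if the total draw cap (1000 draws per requested trio) is exceeded.
    """
    rng = default_rng(config.seed) if rng is None else rng
    if mafs is None or effects is None:
        mafs, effects = simulate_gene(config, rng)
    maf_by_pop = _subpop_mafs(config, mafs)
    base_by_pop = np.array(
        [
            config.baseline_logodds + s * config.subpop_logodds_shift
            for s in range(config.n_subpops)
        ]
    )

    want_case = config.n_case_trios
    want_control = config.n_control_trios
    cap = max(1000 * (want_case + want_control), 1000)
    trios: list[Trio] = []
    n_case = n_control = 0
    drawn = 0
    batch = max(64, min(1024, 4 * (want_case + want_control)))
    while n_case < want_case or n_control < want_control:
        if drawn >= cap:
            raise AscertainmentError(n_case, n_control, cap)
        b = min(batch, cap - drawn)
        pops = (drawn + np.arange(b)) % config.n_subpops
        F, M, C, affected = _draw_batch(
            maf_by_pop[pops], effects, base_by_pop[pops], rng
        )
        drawn += b
        for i in range(b):
            if affected[i]:
                if n_case >= want_case:
                    continue
                n_case += 1
            else:
                if n_control >= want_control:
                    continue
                n_control += 1
            k = len(trios)
            trios.append(
                Trio(
                    child_id=f"F{k}:3",
                    father_id=f"F{k}:1",
                    mother_id=f"F{k}:2",
                    child_g=C[i],
                    father_g=F[i],
                    mother_g=M[i],
                    affected=bool(affected[i]),
                )
            )
            if n_case >= want_case and n_control >= want_control:
                break
    return trios


def bootstrap_trios(
    trios: list[Trio], n: int, rng: np.random.Generator
) -> list[Trio]:
    """Sample n trios with replacement, preserving each trio's label.

    Resampled trios get fresh family ids so the result can be reassembled
    into a pedigree table without id collisions.
    """
    if not trios:
        raise ValueError("source trio list is empty")
    idx = rng.integers(0, len(trios), size=int(n))
    out = []
    for k, i in enumerate(idx):
        t = trios[i]
        suffix = t.child_id.split(":", 1)[1]
        out.append(
            dc_replace(
                t,
                child_id=f"B{k}:{suffix}",
                father_id=f"B{k}:{t.father_id.split(':', 1)[1]}",
                mother_id=f"B{k}:{t.mother_id.split(':', 1)[1]}",
            )
        )
    return out


def _replicate_seeds(master_seed: int, replicate: int) -> tuple:
    """Deterministic per-replicate randomness: a generator for the data and
    an int seed for the fold assignment."""
    children = SeedSequence(entropy=(int(master_seed), int(replicate))).spawn(2)
    rng = default_rng(children[0])
    fold_seed = int(children[1].generate_state(1)[0] % (2**31))
    return rng, fold_seed


def run_replicate(
    config: SimConfig,
    replicate: int,
    kernel: KernelConfig,
    maf_threshold: float,
    n_bootstrap: int | None = None,
) -> AucResult:
    """Simulate one gene + trio sample and run the full gene test on it."""
    rng, fold_seed = _replicate_seeds(config.seed, replicate)
    mafs, effects = simulate_gene(config, rng)
    trios = simulate_trio_sample(config, mafs=mafs, effects=effects, rng=rng)
    if n_bootstrap is not None:
        trios = bootstrap_trios(trios, n_bootstrap, rng)
    table = trios_to_table(trios, chromosome="1")
    region = GeneRegion("simgene", "1", 1, config.n_sites)
    rep_kernel = dc_replace(kernel, seed=fold_seed)
    return gene_test(table, region, maf_threshold, rep_kernel, mode="trio")


def run_experiment(
    config: SimConfig,
    replicates: int,
    alpha_levels: tuple = (0.05, 0.01, 0.001, 0.0001),
    kernel: KernelConfig | None = None,
    maf_threshold: float = 0.03,
    n_bootstrap: int | None = None,
) -> ExperimentResult:
    """Rejection rates of the gene test over independent replicates.

    With ``config.n_causal`` = 0 this estimates the type-I error at each
    alpha; with causal effects it estimates power.  Untestable replicates
    (NA p-values) are excluded from the denominator with a warning, since
    frequent exclusions could bias the rates.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    kernel = kernel or KernelConfig()
    ps = np.empty(replicates)
    thetas = np.empty(replicates)
    pens = np.empty(replicates)
    for r in range(replicates):
        res = run_replicate(config, r, kernel, maf_threshold, n_bootstrap)
        ps[r] = res.p_one_sided
        thetas[r] = res.theta_hat
        pens[r] = res.penalty_chosen
    valid = np.isfinite(ps)
    n_na = int((~valid).sum())
    if n_na:
        log.warning("%d of %d replicates untestable; excluded from rates", n_na, replicates)
    denom = int(valid.sum())
    alpha_levels = tuple(alpha_levels)
    if denom:
        rates = np.array([float((ps[valid] < a).mean()) for a in alpha_levels])
        mc_se = np.sqrt(rates * (1.0 - rates) / denom)
    else:
        rates = np.full(len(alpha_levels), np.nan)
        mc_se = np.full(len(alpha_levels), np.nan)
    return ExperimentResult(
        replicates=replicates,
        alpha_levels=alpha_levels,
        rejection_rates=rates,
        mc_se=mc_se,
        n_na=n_na,
        p_values=ps,
        theta_hats=thetas,
        penalties=pens,
    )
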