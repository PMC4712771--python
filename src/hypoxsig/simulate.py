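"""Seeded generators for synthetic study inputs.

Two generators cover the two halves of the pipeline:

* ``simulate_counts`` — bulk RNA-seq gene counts for the three-condition
  cell-line design (untreated / CoCl2 / hypoxia, 3 replicates each).
  Counts are negative-binomial with sample-specific size factors,
  gene-specific dispersions following alpha(mu) = a0 + a1/mu with
  log-normal gene-to-gene scatter, and per-condition differential
  programs: a broad/moderate program for hypoxia (30% of genes,
  |log2fc| ~ N(1, 0.3^2)) and a narrow/strong one for CoCl2 (2% of
  genes at |log2fc| = 3).
* ``simulate_cohort`` — a tumour/normal cohort on a normalized
  log-normal expression scale, with a global tumour program and, in the
  recurred/progressed outcome group, signature genes shifted in the
  direction of their weights.

Every generator draws from a single ``numpy.random.Generator`` seeded
per call; truth tables carry everything recovery checks need.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ClinicalTable, CountMatrix, ExpressionMatrix
from .signature import HypoxiaSignature

__all__ = [
    "EffectArchitecture",
    "SimulationDesign",
    "CohortDesign",
    "SimTruth",
    "simulate_counts",
    "simulate_cohort",
]


@dataclass
class EffectArchitecture:
    """Differential program of one condition against the reference.

    ``pi`` is the fraction of affected genes; |log2fc| is drawn
    N(l2fc_mean, l2fc_sd^2) truncated at 0 (``l2fc_sd = 0`` gives the
    fixed-magnitude case) with random sign unless ``sign`` is ±1.
    """

    pi: float
    l2fc_mean: float
    l2fc_sd: float = 0.0
    sign: int = 0  # 0 = random, +1 up only, -1 down only

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValidationError("pi must lie in [0, 1]")
        if self.l2fc_sd < 0:
            raise ValidationError("l2fc_sd must be >= 0")


@dataclass
class SimulationDesign:
    """Three-condition bulk RNA-seq design mirroring the cell-line study."""

    n_genes: int = 2000
    replicates: dict[str, int] = field(
        default_factory=lambda: {"untreated": 3, "cocl2": 3, "hypoxia": 3}
    )
    reference: str = "untreated"
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    baseline_log_mean: float = float(np.log(200.0))
    baseline_log_sd: float = 1.0
    dispersion_a0: float = 0.01
    dispersion_a1: float = 1.0
    dispersion_log_sd: float = 0.2
    effects: dict[str, EffectArchitecture] = field(
        default_factory=lambda: {
            "hypoxia": EffectArchitecture(pi=0.3, l2fc_mean=1.0, l2fc_sd=0.3),
            "cocl2": EffectArchitecture(pi=0.02, l2fc_mean=3.0, l2fc_sd=0.0),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if any(r < 1 for r in self.replicates.values()):
            raise ValidationError("replicate counts must be >= 1")
        if self.reference not in self.replicates:
            raise ValidationError(
                f"reference condition {self.reference!r} not in replicates"
            )
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValidationError("size_factor_range must be positive")
        for scale in (self.dispersion_a0, self.dispersion_a1):
            if scale < 0:
                raise ValidationError("dispersion curve coefficients must be >= 0")
        for cond in self.effects:
            if cond not in self.replicates or cond == self.reference:
                raise ValidationError(
                    f"effect condition {cond!r} must be a non-reference condition"
                )


@dataclass
class SimTruth:
    """Ground truth of one count simulation."""

    genes: pd.DataFrame       # baseline_mean, dispersion, true_l2fc_*, is_de_*
    size_factors: pd.Series   # per-sample truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) with variance mu + alpha*mu^2 via gamma-Poisson;
    alpha = 0 degenerates to Poisson."""
    out = np.empty(mu.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        shape = 1.0 / alpha[~pois]
        lam = rng.gamma(shape, mu[~pois] / shape)
        out[~pois] = rng.poisson(lam)
    return out


def simulate_counts(design: SimulationDesign) -> tuple[CountMatrix, SimTruth]:
    """Draw a count matrix and its ground truth from the design.

    k_ij ~ NB(mean = s_j * q_i * 2**l2fc_i(condition_j), alpha_i), fully
    reproducible from ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    genes = [f"g{i:05d}" for i in range(design.n_genes)]
    samples, conditions = [], {}
    for cond, reps in design.replicates.items():
        for r in range(1, reps + 1):
            name = f"{cond}_{r}"
            samples.append(name)
            conditions[name] = cond

    q = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd,
                      design.n_genes)
    alpha = (design.dispersion_a0 + design.dispersion_a1 / q) * rng.lognormal(
        0.0, design.dispersion_log_sd, design.n_genes
    )
    lo, hi = design.size_factor_range
    s = rng.uniform(lo, hi, len(samples))

    truth = pd.DataFrame({"baseline_mean": q, "dispersion": alpha}, index=genes)
    fold = {design.reference: np.zeros(design.n_genes)}
    for cond in design.replicates:
        if cond == design.reference:
            continue
        eff = design.effects.get(cond)
        l2fc = np.zeros(design.n_genes)
        if eff is not None and eff.pi > 0:
            n_de = int(round(eff.pi * design.n_genes))
            de_idx = rng.choice(design.n_genes, size=n_de, replace=False)
            mag = np.abs(rng.normal(eff.l2fc_mean, eff.l2fc_sd, n_de)) \
                if eff.l2fc_sd > 0 else np.full(n_de, eff.l2fc_mean)
            sign = (np.full(n_de, eff.sign) if eff.sign
                    else rng.choice([-1.0, 1.0], size=n_de))
            l2fc[de_idx] = sign * mag
        fold[cond] = l2fc
        truth[f"true_l2fc_{cond}"] = l2fc
        truth[f"is_de_{cond}"] = l2fc != 0

    mu = np.empty((design.n_genes, len(samples)))
    for j, smp in enumerate(samples):
        mu[:, j] = s[j] * q * 2.0 ** fold[conditions[smp]]
    counts = _nb_draw(rng, mu, np.repeat(alpha[:, None], len(samples), axis=1))

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        condition_of=conditions,
    )
    return cm, SimTruth(
        genes=truth,
        size_factors=pd.Series(s, index=samples, name="size_factor"),
    )


@dataclass
class CohortDesign:
    """Tumour/normal cohort with an outcome split among tumours.

    Expression is log-normal on an RSEM-like normalized scale: per-gene
    baselines b_g ~ N(log2 300, 1.5^2) in log2 units with within-group
    noise sd 1.0 (log2). A fraction of genes carries a tumour-vs-normal
    shift; ``signature_coupling`` additionally shifts signature genes in
    tumours along their weights, coupling the tumour program to the
    hypoxia program. Recurred/progressed tumours get every signature
    gene shifted by ``outcome_effect_sd`` within-group standard
    deviations in the direction of its weight.
    """

    n_tumour: int = 100
    n_normal: int = 20
    recurred_fraction: float = 0.5
    n_genes: int = 2000
    baseline_log2_mean: float = float(np.log2(300.0))
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 1.0
    tumour_program_fraction: float = 0.3
    tumour_shift_log2_sd: float = 1.0
    signature_coupling: float = 0.0
    outcome_effect_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumour < 2:
            raise ValidationError("n_tumour must be >= 2")
        if self.n_normal < 0:
            raise ValidationError("n_normal must be >= 0")
        if not 0.0 <= self.recurred_fraction <= 1.0:
            raise ValidationError("recurred_fraction must lie in [0, 1]")
        if not np.isfinite(self.outcome_effect_sd):
            raise ValidationError("outcome_effect_sd must be finite")


def simulate_cohort(
    design: CohortDesign,
    signature: HypoxiaSignature,
    gene_ids=None,
) -> tuple[ExpressionMatrix, ClinicalTable, pd.DataFrame]:
    """Draw a cohort expression matrix, clinical table and gene truth.

    The gene universe is the signature's genes plus background genes up
    to ``design.n_genes``; pass ``gene_ids`` to share a universe with
    other matrices (e.g. the cell-line counts) instead of anonymous
    background genes. Returns per-gene truth columns ``baseline_log2``,
    ``tumour_shift_log2`` and ``recurred_shift_log2``.
    """
    if len(signature) == 0:
        raise ValidationError("signature must be non-empty")
    rng = np.random.default_rng(design.seed)
    sig_genes = list(signature.weights.index)
    if gene_ids is not None:
        others = [g for g in gene_ids if g not in signature.genes]
    else:
        others = []
    n_bg = max(design.n_genes - len(sig_genes) - len(others), 0)
    genes = sig_genes + others + [f"bg{i:05d}" for i in range(n_bg)]
    n_genes = len(genes)

    n_rec = int(round(design.n_tumour * design.recurred_fraction))
    tumour_ids = [f"tumour_{i + 1:03d}" for i in range(design.n_tumour)]
    normal_ids = [f"normal_{i + 1:03d}" for i in range(design.n_normal)]
    samples = tumour_ids + normal_ids
    outcomes = (["recurred_progressed"] * n_rec
                + ["disease_free"] * (design.n_tumour - n_rec)
                + ["unknown"] * design.n_normal)
    tissues = ["tumour"] * design.n_tumour + ["normal"] * design.n_normal

    b = rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, n_genes)
    tumour_shift = np.zeros(n_genes)
    n_prog = int(round(design.tumour_program_fraction * n_genes))
    if n_prog > 0:
        prog_idx = rng.choice(n_genes, size=n_prog, replace=False)
        tumour_shift[prog_idx] = rng.normal(
            0.0, design.tumour_shift_log2_sd, n_prog
        )
    w = signature.weights.to_numpy(dtype=float)
    if design.signature_coupling != 0.0:
        tumour_shift[: len(sig_genes)] += design.signature_coupling * w

    recurred_shift = np.zeros(n_genes)
    recurred_shift[: len(sig_genes)] = (
        design.outcome_effect_sd * design.noise_log2_sd * np.sign(w)
    )

    log2x = (
        b[:, None]
        + np.outer(tumour_shift, np.array(tissues) == "tumour")
        + np.outer(recurred_shift,
                   np.array(outcomes) == "recurred_progressed")
        + rng.normal(0.0, design.noise_log2_sd, (n_genes, len(samples)))
    )
    values = pd.DataFrame(2.0**log2x, index=genes, columns=samples)

    clinical = ClinicalTable(
        table=pd.DataFrame(
            {"tissue": tissues, "outcome": outcomes},
            index=pd.Index(samples, name="sample"),
        )
    )
    truth = pd.DataFrame(
        {
            "baseline_log2": b,
            "tumour_shift_log2": tumour_shift,
            "recurred_shift_log2": recurred_shift,
        },
        index=genes,
    )
    return ExpressionMatrix(values=values), clinical, truth
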