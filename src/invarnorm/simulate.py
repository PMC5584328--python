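"""Synthetic expression datasets with known ground truth.

The generator emulates a small bacterial RNA-seq study — by default three
conditions with three replicates each and 2,000 genes — with the features
the normalization method is built to handle:

* a planted core of invariant genes: condition-constant, free of biological
  replicate noise (that is what makes a gene a usable reference), and
  roughly evenly spaced in log(expression) space over the moderately-to-
  highly expressed range (a weakly expressed gene cannot be a reliable
  reference because counting noise dominates its signal);
* asymmetric differential expression (more genes up than down in the
  treated conditions), which biases global scaling factors;
* per-sample sequencing-depth factors; and
* a mild per-sample monotone quadratic distortion of the log2 abundance
  scale, x = a_s + b_s * u + c_s * u^2, emulating intensity-dependent
  technical bias, with curvature |c_s| small enough that gene order is
  preserved over the simulated range.

The latent abundance u is length-normalized (the quantity RPKM estimates),
so the distortion lives on the same scale the normalizer corrects; gene
length enters the read counts multiplicatively (longer transcripts collect
more reads). Counts are drawn Poisson around the distorted, depth- and
length-scaled expectation; negative-binomial overdispersion is available as
an option (real data are overdispersed, Poisson keeps test expectations
analytic). Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset", "make_toy_matrix"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults model a 2,000-gene, 3 condition x 3 replicate design under a
    genome-wide perturbation: every non-invariant gene drifts between
    conditions (``background_effect_sd`` 0.6 on the log2 scale) and ~35%
    are strongly differentially expressed, skewed 4:1 toward up-regulation
    with log2 effects uniform in [0.5, 3] — only the 30 planted reference
    genes are truly condition-constant. Biological replicate noise sd is
    0.25 log2 (~19% CV), depth factors are uniform in [0.5, 1.5], and the
    per-sample distortion has slopes in [0.92, 1.08] with curvature capped
    at |c_s| <= 0.04 (clipped further whenever needed to keep it monotone
    over the simulated range). With ``count_scale`` 10.0 libraries land at
    roughly 10-30 million reads, typical of bulk bacterial RNA-seq.
    """

    n_genes: int = 2000
    conditions: tuple[tuple[str, int], ...] = (("A", 3), ("B", 3), ("C", 3))
    n_invariant: int = 30
    fraction_de: float = 0.35
    responder_fraction: float = 0.7  # chance a DE gene responds in a given condition
    fraction_up: float = 0.8
    effect_size_log2: tuple[float, float] = (0.5, 3.0)
    background_effect_sd: float = 0.6
    log_abundance_range: tuple[float, float] = (2.0, 12.0)
    invariant_abundance_range: tuple[float, float] = (5.0, 12.0)
    distortion_offset: tuple[float, float] = (-0.5, 0.5)
    distortion_slope: tuple[float, float] = (0.92, 1.08)
    distortion_curvature: float = 0.04
    noise_sd: float = 0.25
    invariant_noise_sd: float = 0.0
    depth_range: tuple[float, float] = (0.5, 1.5)
    count_scale: float = 10.0
    count_noise: str = "poisson"  # "poisson" | "nb" | "none"
    nb_dispersion: float = 0.05
    length_range: tuple[int, int] = (200, 5000)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.conditions or any(reps < 1 for _, reps in self.conditions):
            raise ValueError("every condition needs at least one replicate")
        if not 0 <= self.n_invariant <= self.n_genes:
            raise ValueError("n_invariant must lie in [0, n_genes]")
        if self.count_noise not in ("poisson", "nb", "none"):
            raise ValueError("count_noise must be poisson, nb or none")
        if self.count_scale <= 0:
            raise ValueError("count_scale must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cond}{rep + 1}" for cond, reps in self.conditions for rep in range(reps)
        ]

    @property
    def condition_of_sample(self) -> dict[str, str]:
        return {
            f"{cond}{rep + 1}": cond
            for cond, reps in self.conditions
            for rep in range(reps)
        }


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not.

    ``true_log`` holds each gene's latent length-normalized log2 abundance
    per sample — biological replicate noise included, distortion and depth
    excluded. Planted invariant genes are condition-constant and noise-free
    there by construction.
    """

    true_log: pd.DataFrame
    invariant_gene_ids: list[str]
    de_effects: dict[str, dict[str, float]]  # gene -> condition -> log2 effect
    distortion: dict[str, tuple[float, float, float]]  # sample -> (a, b, c)
    depth: dict[str, float]
    config: SimulationConfig

    def to_jsonable(self) -> dict:
        cfg = asdict(self.config)
        cfg["conditions"] = [list(c) for c in self.config.conditions]
        return {
            "invariant_gene_ids": self.invariant_gene_ids,
            "de_effects": self.de_effects,
            "distortion": {s: list(v) for s, v in self.distortion.items()},
            "depth": self.depth,
            "config": cfg,
            "true_log": {
                "index": list(self.true_log.index),
                "columns": list(self.true_log.columns),
                "values": self.true_log.to_numpy().tolist(),
            },
        }


def _monotone_curvature(c: float, slope: float, u_max: float) -> float:
    """Clip c so that d/du (b u + c u^2) = b + 2 c u > 0 on [0, u_max]."""
    if u_max <= 0:
        return c
    limit = 0.9 * slope / (2.0 * u_max)
    return float(np.clip(c, -limit, limit))


def simulate_dataset(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Draw one dataset: (counts matrix, gene lengths, ground truth)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    samples = config.sample_ids
    cond_of = config.condition_of_sample
    cond_names = [c for c, _ in config.conditions]

    digits = len(str(n))
    gene_ids = [f"g{str(i).zfill(digits)}" for i in range(n)]

    lo, hi = config.log_abundance_range
    base = rng.uniform(lo, hi, size=n)
    inv_mask = np.zeros(n, dtype=bool)
    invariant_ids: list[str] = []
    if config.n_invariant:
        inv_idx = rng.choice(n, size=config.n_invariant, replace=False)
        inv_idx.sort()
        ilo, ihi = config.invariant_abundance_range
        base[inv_idx] = np.linspace(ilo, ihi, config.n_invariant)
        inv_mask[inv_idx] = True
        invariant_ids = [gene_ids[i] for i in inv_idx]

    # differential expression: the first condition is the reference
    de_effects: dict[str, dict[str, float]] = {}
    effect = np.zeros((n, len(cond_names)))
    candidates = np.flatnonzero(~inv_mask)
    # every non-invariant gene drifts a little between conditions: the
    # invariant core is rare, as under a genome-wide perturbation
    if config.background_effect_sd > 0:
        effect[candidates, 1:] = rng.normal(
            0.0, config.background_effect_sd, size=(len(candidates), len(cond_names) - 1)
        )
    n_de = int(round(config.fraction_de * len(candidates)))
    de_idx = rng.choice(candidates, size=n_de, replace=False)
    e_lo, e_hi = config.effect_size_log2
    for gi in de_idx:
        per_cond: dict[str, float] = {}
        for ci, cond in enumerate(cond_names[1:], start=1):
            if rng.random() < config.responder_fraction:
                sign = 1.0 if rng.random() < config.fraction_up else -1.0
                per_cond[cond] = float(sign * rng.uniform(e_lo, e_hi))
                effect[gi, ci] += per_cond[cond]
        if per_cond:
            de_effects[gene_ids[gi]] = per_cond

    # per-sample nuisance parameters
    distortion: dict[str, tuple[float, float, float]] = {}
    depth: dict[str, float] = {}
    u_max = hi + max(abs(e_lo), abs(e_hi)) + 4 * config.noise_sd
    for s in samples:
        a = rng.uniform(*config.distortion_offset)
        b = rng.uniform(*config.distortion_slope)
        c = _monotone_curvature(
            rng.uniform(-config.distortion_curvature, config.distortion_curvature),
            b,
            u_max,
        )
        distortion[s] = (float(a), float(b), float(c))
        depth[s] = float(rng.uniform(*config.depth_range))

    lengths = pd.Series(
        rng.integers(config.length_range[0], config.length_range[1] + 1, size=n),
        index=gene_ids,
        name="length_nt",
    )
    len_kb = lengths.to_numpy() / 1000.0

    noise_sd = np.where(inv_mask, config.invariant_noise_sd, config.noise_sd)
    cond_index = {c: i for i, c in enumerate(cond_names)}
    true_log = np.empty((n, len(samples)))
    counts = np.empty((n, len(samples)))
    for si, s in enumerate(samples):
        u = base + effect[:, cond_index[cond_of[s]]]
        if (noise_sd > 0).any():
            u = u + rng.normal(0.0, 1.0, size=n) * noise_sd
        true_log[:, si] = u
        a, b, c = distortion[s]
        x = a + b * u + c * u * u
        mu = np.exp2(x) * len_kb * depth[s] * config.count_scale
        if config.count_noise == "poisson":
            counts[:, si] = rng.poisson(mu)
        elif config.count_noise == "nb":
            # NB with mean mu, variance mu + disp * mu^2
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mu / shape)
            counts[:, si] = rng.poisson(lam)
        else:
            counts[:, si] = mu

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=samples),
        "counts",
        dict(cond_of),
    )
    truth = GroundTruth(
        true_log=pd.DataFrame(true_log, index=gene_ids, columns=samples),
        invariant_gene_ids=invariant_ids,
        de_effects=de_effects,
        distortion=distortion,
        depth=depth,
        config=config,
    )
    return matrix, lengths, truth


def make_toy_matrix(
    values,
    gene_ids=None,
    sample_ids=None,
    kind: str = "rpkm",
    conditions: dict | None = None,
) -> ExpressionMatrix:
    """Build an exact small matrix from literal values for hand computation."""
    rows = [list(r) for r in values]
    if not rows or any(len(r) == 0 for r in rows):
        raise ValueError("toy matrix needs at least one non-empty row")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged rows in toy matrix")
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(len(rows))]
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(width)]
    df = pd.DataFrame(np.asarray(rows, dtype=float), index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(df, kind, conditions)
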