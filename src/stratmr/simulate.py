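"""Synthetic linked GWAS summary statistics with known ground truth.

The generator emulates the three-table structure of a biologically stratified
two-sample MR study: an exposure biomarker, a downstream indicator trait, and
an outcome, measured in three independent samples.  Variants fall into
latent classes:

* class **A** / class **B** — forward-causal instruments with per-allele
  exposure effects γ_j ~ N(0, exposure_effect_sd²); their indicator effect
  is γ_j scaled by a class-specific coefficient (opposite signs across
  classes encode bioaction vs resistance) and their outcome effect is
  θ_class · γ_j plus optional pleiotropy;
* **reverse** — variants acting on the outcome first (direct effect
  δ_j ~ N(0, reverse_effect_sd²), with sd large enough that the outcome
  effect is detectable at biobank scale) and an attenuated induced exposure
  effect (0.3 · δ_j by default), so their variance explained is larger in
  the outcome than in the exposure and Steiger filtering can be scored
  against truth.

Directional pleiotropy α_j is defined relative to the exposure-increasing
allele (the outcome effect gains sign(γ_j)·α_j), so after orientation the
MR-Egger intercept targets the pleiotropy mean; α is drawn independently of
γ (InSIDE) unless the correlated switch is set.

Traits are simulated in standardized units, so the sampling standard error
of a per-allele beta has the closed form 1/√(2·eaf·(1−eaf)·n) and observed
betas are true effects plus independent Gaussian noise per study.  All
randomness derives from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .sumstats import LDReference, SummaryStatsTable

# ordered non-palindromic allele pairs (effect, other)
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

_POSITION_SPACING = 50_000  # bp between consecutive simulated variants


@dataclass
class SimulationConfig:
    """Study conditions for one simulated two-sample MR dataset.

    Defaults describe a well-powered stratified study: 50 independent
    instruments, biobank-scale samples (100k exposure/outcome, 200k
    indicator), common variants (MAF 0.05–0.5), strong instruments
    (exposure effects with sd 0.1 on the standardized scale), and two
    equally likely variant classes whose causal effects on the outcome are
    θ_A = −0.5 and θ_B = +0.3 with opposite indicator signs — the
    constellation in which pooled and stratified analyses disagree.
    Pleiotropy and reverse causation are off unless requested.
    """

    n_variants: int = 50
    n_exposure: int = 100_000
    n_indicator: int = 200_000
    n_outcome: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_effect_sd: float = 0.1
    class_probs: Mapping[str, float] = field(default_factory=lambda: {"A": 0.5, "B": 0.5})
    theta_A: float = -0.5
    theta_B: float = 0.3
    indicator_gamma_A: float = 0.5
    indicator_gamma_B: float = -0.5
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.02
    pleiotropy_correlated: bool = False
    reverse_frac: float = 0.0
    reverse_effect_sd: float = 0.3
    reverse_attenuation: float = 0.3
    observation_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        for name in ("n_exposure", "n_indicator", "n_outcome"):
            if getattr(self, name) <= 2:
                raise ConfigurationError(f"{name} must be > 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.exposure_effect_sd <= 0 or self.reverse_effect_sd <= 0 or self.pleiotropy_sd < 0:
            raise ConfigurationError("effect sds must be positive (pleiotropy_sd >= 0)")
        pa = self.class_probs.get("A", 0.0)
        pb = self.class_probs.get("B", 0.0)
        if pa < 0 or pb < 0 or pa + pb <= 0 or pa + pb > 1 + 1e-12:
            raise ConfigurationError(f"class_probs must be nonnegative and sum in (0, 1], got {dict(self.class_probs)}")
        for name in ("pleiotropy_frac", "reverse_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_probs"] = dict(self.class_probs)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SimulationResult:
    exposure: SummaryStatsTable
    indicator: SummaryStatsTable
    outcome: SummaryStatsTable
    truth: pd.DataFrame  # variant_id, class_label, beta_x_true, alpha, beta_z_true, beta_y_true


def theoretical_se(eaf: float, n: int) -> float:
    """Sampling se of a per-allele beta on a standardized trait.

    se = 1/√(2·eaf·(1−eaf)·n) — the large-sample se of a simple-regression
    coefficient on allele count when the trait has unit variance.
    """
    eaf = float(eaf)
    if not (0 < eaf < 1):
        raise ConfigurationError(f"eaf must be strictly inside (0, 1), got {eaf}")
    if n <= 2:
        raise ConfigurationError(f"n must be > 2, got {n}")
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def variant_ids(n: int) -> list[str]:
    return [f"rs{j + 1:06d}" for j in range(n)]


def variant_position(j: int) -> tuple[str, int]:
    """Deterministic placement: one chromosome, evenly spaced variants."""
    return "1", 1 + j * _POSITION_SPACING


def simulate_two_sample_study(config: SimulationConfig) -> SimulationResult:
    """Draw one linked exposure/indicator/outcome dataset plus ground truth.

    Noise draws for the three studies come from distinct child seeds of
    ``config.seed`` (two-sample independence); the same seed reproduces the
    tables bit-for-bit.
    """
    config.validate()
    L = config.n_variants
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_x, rng_z, rng_y = (np.random.default_rng(s) for s in ss.spawn(4))

    ids = variant_ids(L)
    chroms, positions = zip(*(variant_position(j) for j in range(L)))
    pair_idx = rng_struct.integers(0, len(_ALLELE_PAIRS), size=L)
    eff = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oth = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    maf = rng_struct.uniform(config.maf_range[0], config.maf_range[1], size=L)

    # latent classes
    u = rng_struct.random(L)
    is_reverse = u < config.reverse_frac
    pa = config.class_probs.get("A", 0.0)
    pb = config.class_probs.get("B", 0.0)
    p_a_given_forward = pa / (pa + pb)
    is_a = rng_struct.random(L) < p_a_given_forward
    labels = np.where(is_reverse, "reverse", np.where(is_a, "A", "B"))

    gamma = rng_struct.normal(0.0, config.exposure_effect_sd, size=L)
    delta = rng_struct.normal(0.0, config.reverse_effect_sd, size=L)
    has_pleio = rng_struct.random(L) < config.pleiotropy_frac
    if config.pleiotropy_correlated:
        # violate InSIDE: pleiotropy tracks instrument strength
        mu_abs = config.exposure_effect_sd * np.sqrt(2 / np.pi)
        sd_abs = config.exposure_effect_sd * np.sqrt(1 - 2 / np.pi)
        alpha = config.pleiotropy_mean + config.pleiotropy_sd * (np.abs(gamma) - mu_abs) / sd_abs
    else:
        alpha = rng_struct.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=L)
    alpha = np.where(has_pleio & ~is_reverse, alpha, 0.0)

    theta = np.where(labels == "A", config.theta_A, config.theta_B)
    ind_gamma = np.where(labels == "A", config.indicator_gamma_A, config.indicator_gamma_B)

    beta_x_true = np.where(is_reverse, config.reverse_attenuation * delta, gamma)
    beta_z_true = np.where(is_reverse, 0.0, ind_gamma * gamma)
    # directional pleiotropy is defined on the exposure-increasing allele
    beta_y_true = np.where(is_reverse, delta, theta * gamma + np.sign(gamma) * alpha)

    tables = {}
    for study, n, rng, true in (
        ("exposure", config.n_exposure, rng_x, beta_x_true),
        ("indicator", config.n_indicator, rng_z, beta_z_true),
        ("outcome", config.n_outcome, rng_y, beta_y_true),
    ):
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
        noise = rng.normal(0.0, se) if config.observation_noise else np.zeros(L)
        beta = true + noise
        pval = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
        df = pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": chroms,
                "pos": positions,
                "effect_allele": eff,
                "other_allele": oth,
                "eaf": maf,
                "beta": beta,
                "se": se,
                "pval": pval,
                "n": np.full(L, n, dtype=np.int64),
            }
        )
        df["pos"] = df["pos"].astype(np.int64)
        tables[study] = SummaryStatsTable(df=df, trait_name=study, trait_units="SD")

    truth = pd.DataFrame(
        {
            "variant_id": ids,
            "class_label": labels,
            "beta_x_true": beta_x_true,
            "alpha": alpha,
            "beta_z_true": beta_z_true,
            "beta_y_true": beta_y_true,
        }
    )
    return SimulationResult(
        exposure=tables["exposure"],
        indicator=tables["indicator"],
        outcome=tables["outcome"],
        truth=truth,
    )


def simulate_ld_blocks(
    config: SimulationConfig, block_size: int, within_block_r2: float
) -> LDReference:
    """LD reference with block-diagonal structure over the simulated variants.

    Variants are grouped into consecutive blocks of ``block_size``; every
    within-block pair carries ``within_block_r2``; across-block pairs are
    absent (unknown r²).  Positions match :func:`simulate_two_sample_study`.
    """
    if block_size < 1:
        raise ConfigurationError(f"block_size must be >= 1, got {block_size}")
    if not (0 <= within_block_r2 <= 1):
        raise ConfigurationError(f"within_block_r2 must be in [0, 1], got {within_block_r2}")
    ld = LDReference()
    ids = variant_ids(config.n_variants)
    for j, vid in enumerate(ids):
        chrom, pos = variant_position(j)
        ld.add_position(vid, chrom, pos)
    for start in range(0, config.n_variants, block_size):
        block = ids[start : start + block_size]
        for i in range(len(block)):
            for k in range(i + 1, len(block)):
                ld.add_pair(block[i], block[k], within_block_r2)
    return ld
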