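"""Closed-form two-sample MR estimators and heterogeneity diagnostics.

All four estimators operate on the per-variant summary associations of a
harmonized instrument set: SNP–exposure effects β_x with standard errors
se_x, and SNP–outcome effects β_y with standard errors se_y, all expressed on
the exposure-increasing effect allele.

* IVW — weighted regression of β_y on β_x through the origin, weights
  1/se_y²; equivalently the inverse-variance-weighted mean of the per-SNP
  Wald ratios.  The random-effects variant inflates the fixed-effect standard
  error by a multiplicative over-dispersion factor √(Q/(L−1)), floored at 1.
* MR-Egger — the same regression with a free intercept; the intercept
  estimates the mean directional pleiotropic effect, and the slope remains
  consistent under the InSIDE condition.  Standard errors carry the
  analogous √(Q_E/(L−2)) floor-at-1 scale; p-values use the t distribution
  with L−2 degrees of freedom.
* Weighted median — the 50% point of the inverse-variance-weighted empirical
  distribution of Wald ratios; consistent when ≥ 50% of weight comes from
  valid instruments.  Standard error by seeded parametric bootstrap.
* Penalized weighted median — the weighted median after down-weighting
  instruments whose heterogeneity contribution is improbably large:
  w*_j = w_j · min(1, k · p_j) with p_j the upper χ²₁ tail of
  q_j = w_j (ratio_j − β̂_WM)² and penalty constant k (default 20).

Heterogeneity: Cochran's Q = Σ w_j (β_y,j − fitted_j)² on the model's fitted
values, referred to χ² with L−1 (IVW) or L−2 (Egger) df, and
I² = max(0, (Q − df)/Q) · 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .harmonize import HarmonizedSet

DEFAULT_N_BOOT = 1000
DEFAULT_PENALTY_K = 20.0

MIN_INSTRUMENTS = {"IVW": 1, "Egger": 3, "WM": 1, "PWM": 1}


@dataclass
class RatioEstimate:
    """Per-SNP Wald ratio β_y/β_x with first-order delta-method se."""

    variant_id: str
    ratio: float
    ratio_se: float

    @property
    def weight(self) -> float:
        return 1.0 / self.ratio_se**2


@dataclass
class MREstimate:
    """One model's causal-effect estimate with diagnostics.

    ``status`` is ``"ok"`` for a computed estimate, ``"no-instruments"`` or
    ``"insufficient-instruments"`` for a structured refusal (numeric fields
    are NaN then).  Intercept fields are populated only for Egger.
    """

    method: str
    beta: float = np.nan
    se: float = np.nan
    pval: float = np.nan
    n_snps: int = 0
    Q: float = np.nan
    Q_pval: float = np.nan
    I2: float = np.nan
    intercept: float = np.nan
    intercept_se: float = np.nan
    intercept_pval: float = np.nan
    status: str = "ok"

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se
        return (self.beta - half, self.beta + half)


def _arrays(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    bx = np.array([r.beta_x for r in hset.records], dtype=float)
    sx = np.array([r.se_x for r in hset.records], dtype=float)
    by = np.array([r.beta_y for r in hset.records], dtype=float)
    sy = np.array([r.se_y for r in hset.records], dtype=float)
    ids = [r.variant_id for r in hset.records]
    return bx, sx, by, sy, ids


def _two_sided_norm_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def ratio_estimates(hset: HarmonizedSet) -> list[RatioEstimate]:
    """Wald ratios β_y/β_x with se = se_y/|β_x| (first-order delta method).

    Records with β_x = 0 are excluded (no finite ratio); orientation
    upstream normally guarantees none exist.
    """
    out = []
    for r in hset.records:
        if r.beta_x == 0:
            continue
        out.append(
            RatioEstimate(
                variant_id=r.variant_id,
                ratio=r.beta_y / r.beta_x,
                ratio_se=r.se_y / abs(r.beta_x),
            )
        )
    return out


def ivw_estimate(hset: HarmonizedSet, random_effects: bool = True) -> MREstimate:
    """Inverse-variance weighted estimate (regression through the origin).

    β̂ = Σ β_x β_y/se_y² / Σ β_x²/se_y²; fixed-effect se is the usual WLS
    slope se with scale fixed at 1; under ``random_effects`` the se is
    multiplied by max(1, √(Q/(L−1))).  Two-sided p from the normal
    distribution.  A single instrument degenerates to its Wald ratio.
    """
    bx, _, by, sy, _ = _arrays(hset)
    L = len(bx)
    if L == 0:
        return MREstimate(method="IVW", status="no-instruments")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom**-0.5
    Q = float(np.sum(w * (by - beta * bx) ** 2))
    if L >= 2:
        Q_pval = float(stats.chi2.sf(Q, L - 1))
        I2 = max(0.0, (Q - (L - 1)) / Q) * 100.0 if Q > 0 else 0.0
        scale = max(1.0, np.sqrt(Q / (L - 1))) if random_effects else 1.0
    else:
        Q_pval, I2, scale = np.nan, np.nan, 1.0
    se = se_fixed * scale
    return MREstimate(
        method="IVW",
        beta=beta,
        se=se,
        pval=_two_sided_norm_p(beta / se),
        n_snps=L,
        Q=Q if L >= 2 else np.nan,
        Q_pval=Q_pval,
        I2=I2,
    )


def egger_estimate(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of β_y on β_x with a free intercept.

    Requires ≥ 3 instruments oriented to the exposure-increasing allele (the
    intercept is only meaningful under a common sign convention).  Slope and
    intercept ses carry the multiplicative over-dispersion scale
    max(1, √(Q_E/(L−2))); p-values from t with L−2 df.
    """
    bx, _, by, sy, _ = _arrays(hset)
    L = len(bx)
    if L == 0:
        return MREstimate(method="Egger", status="no-instruments")
    if L < MIN_INSTRUMENTS["Egger"]:
        return MREstimate(method="Egger", n_snps=L, status="insufficient-instruments")
    w = 1.0 / sy**2
    sw = float(np.sum(w))
    swx = float(np.sum(w * bx))
    swy = float(np.sum(w * by))
    swxx = float(np.sum(w * bx * bx))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx**2
    if det <= 0:
        return MREstimate(method="Egger", n_snps=L, status="degenerate-design")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    fitted = intercept + slope * bx
    Q = float(np.sum(w * (by - fitted) ** 2))
    df = L - 2
    scale = max(1.0, np.sqrt(Q / df))
    se_slope = np.sqrt(sw / det) * scale
    se_intercept = np.sqrt(swxx / det) * scale
    p_slope = float(min(1.0, 2.0 * stats.t.sf(abs(slope / se_slope), df)))
    p_intercept = float(min(1.0, 2.0 * stats.t.sf(abs(intercept / se_intercept), df)))
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return MREstimate(
        method="Egger",
        beta=slope,
        se=se_slope,
        pval=p_slope,
        n_snps=L,
        Q=Q,
        Q_pval=float(stats.chi2.sf(Q, df)),
        I2=I2,
        intercept=intercept,
        intercept_se=se_intercept,
        intercept_pval=p_intercept,
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50% point of the weighted empirical ratio distribution.

    Orders ratios ascending, forms standardized mid-cumulative weights
    s_j = (Σ_{k≤j} w_k − w_j/2)/Σw, and linearly interpolates at s = 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def _bootstrap_se(
    ratios: np.ndarray,
    ratio_ses: np.ndarray,
    weights: np.ndarray,
    n_boot: int,
    seed: int,
    penalty_k: float | None = None,
) -> float:
    """Parametric bootstrap: resample each ratio from N(ratio, ratio_se²)."""
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        r_star = rng.normal(ratios, ratio_ses)
        if penalty_k is None:
            draws[b] = _weighted_median(r_star, weights)
        else:
            draws[b] = _weighted_median(r_star, _penalized_weights(r_star, weights, penalty_k))
    return float(np.std(draws, ddof=1))


def _penalized_weights(ratios: np.ndarray, weights: np.ndarray, penalty_k: float) -> np.ndarray:
    wm = _weighted_median(ratios, weights)
    q = weights * (ratios - wm) ** 2
    p = stats.chi2.sf(q, df=1)
    return weights * np.minimum(1.0, penalty_k * p)


def weighted_median_estimate(
    hset: HarmonizedSet, n_boot: int = DEFAULT_N_BOOT, seed: int = 0
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap se."""
    if n_boot < 100:
        raise ValidationError(f"n_boot must be >= 100, got {n_boot}")
    ests = ratio_estimates(hset)
    if not ests:
        return MREstimate(method="WM", status="no-instruments")
    ratios = np.array([e.ratio for e in ests])
    ses = np.array([e.ratio_se for e in ests])
    w = 1.0 / ses**2
    beta = _weighted_median(ratios, w)
    se = _bootstrap_se(ratios, ses, w, n_boot, seed)
    pval = _two_sided_norm_p(beta / se) if se > 0 else np.nan
    return MREstimate(method="WM", beta=beta, se=se, pval=pval, n_snps=len(ests))


def penalized_weighted_median_estimate(
    hset: HarmonizedSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    penalty_k: float = DEFAULT_PENALTY_K,
) -> MREstimate:
    """Weighted median with outlier-penalized weights (penalty constant k)."""
    if n_boot < 100:
        raise ValidationError(f"n_boot must be >= 100, got {n_boot}")
    ests = ratio_estimates(hset)
    if not ests:
        return MREstimate(method="PWM", status="no-instruments")
    ratios = np.array([e.ratio for e in ests])
    ses = np.array([e.ratio_se for e in ests])
    w = 1.0 / ses**2
    w_star = _penalized_weights(ratios, w, penalty_k)
    beta = _weighted_median(ratios, w_star)
    se = _bootstrap_se(ratios, ses, w, n_boot, seed, penalty_k=penalty_k)
    pval = _two_sided_norm_p(beta / se) if se > 0 else np.nan
    return MREstimate(method="PWM", beta=beta, se=se, pval=pval, n_snps=len(ests))


def penalized_weights(hset: HarmonizedSet, penalty_k: float = DEFAULT_PENALTY_K) -> dict[str, tuple[float, float]]:
    """Per-variant (raw, penalized) ratio weights — diagnostic helper."""
    ests = ratio_estimates(hset)
    ratios = np.array([e.ratio for e in ests])
    w = np.array([e.weight for e in ests])
    w_star = _penalized_weights(ratios, w, penalty_k)
    return {e.variant_id: (float(wi), float(wsi)) for e, wi, wsi in zip(ests, w, w_star)}


def heterogeneity(hset: HarmonizedSet, model: str = "IVW") -> tuple[float, float, float]:
    """Cochran's Q, its p-value, and Higgins' I² for the named model's fit.

    Q = Σ w_j (β_y,j − fitted_j)², w_j = 1/se_y,j², with fitted values from
    the IVW (df = L−1) or Egger (df = L−2) fit; I² = max(0, (Q−df)/Q)·100.
    """
    if model not in ("IVW", "Egger"):
        raise ValidationError(f"model must be 'IVW' or 'Egger', got {model!r}")
    L = len(hset.records)
    df = L - 1 if model == "IVW" else L - 2
    if df <= 0:
        raise ValidationError(f"{model} heterogeneity needs at least {2 if model == 'IVW' else 3} instruments, got {L}")
    est = ivw_estimate(hset, random_effects=False) if model == "IVW" else egger_estimate(hset)
    return est.Q, est.Q_pval, est.I2


def estimate_all(
    hset: HarmonizedSet,
    random_effects: bool = True,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    penalty_k: float = DEFAULT_PENALTY_K,
) -> dict[str, MREstimate]:
    """Run IVW, Egger, WM and PWM on one instrument set."""
    return {
        "IVW": ivw_estimate(hset, random_effects=random_effects),
        "Egger": egger_estimate(hset),
        "WM": weighted_median_estimate(hset, n_boot=n_boot, seed=seed),
        "PWM": penalized_weighted_median_estimate(
            hset, n_boot=n_boot, seed=seed, penalty_k=penalty_k
        ),
    }
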