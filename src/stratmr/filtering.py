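"""Instrument filters: Steiger directionality and biological-effect strata.

Steiger filtering discards an instrument when it explains more trait variance
in the outcome than in the exposure — the signature of a reverse-causal
variant.  Variance explained is approximated from summary statistics as

    r² = z² / (z² + n − 2),    z = beta / se,

the square of the correlation a t-statistic of that size implies at sample
size n.  The default rule compares point estimates (kept iff r²_x > r²_y),
with no significance gate.

Biological-effect stratification partitions the (exposure-increasing-
oriented) instruments by the *sign* of their association with a third,
downstream indicator trait that indexes the biomarker's action — glucose for
insulin, childhood height for IGF-1.  Biomarker-raising alleles whose
indicator effect is concordant with the biomarker's established action tag
bioaction; discordant alleles tag hormone resistance.  No p-value threshold
is applied to the indicator association: direction alone classifies, and a
zero or missing indicator beta leaves the instrument unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .harmonize import HarmonizedRecord, HarmonizedSet


@dataclass
class SteigerResult:
    variant_id: str
    r2_exposure: float
    r2_outcome: float
    kept: bool
    reason: str = ""


@dataclass
class StratifiedGroups:
    """Partition of instruments by indicator-association sign.

    ``labels`` maps the raw sign strata onto the biology, e.g. for fasting
    insulin ``{"positive": "resistance", "negative": "bioaction"}`` (an
    insulin-raising allele that also raises glucose marks resistance), and
    the reverse for IGF-1 against childhood height.
    """

    positive: list[HarmonizedRecord] = field(default_factory=list)
    negative: list[HarmonizedRecord] = field(default_factory=list)
    unclassified: list[HarmonizedRecord] = field(default_factory=list)
    labels: dict[str, str] = field(
        default_factory=lambda: {"positive": "positive", "negative": "negative"}
    )

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "positive": len(self.positive),
            "negative": len(self.negative),
            "unclassified": len(self.unclassified),
        }

    def __len__(self) -> int:
        return len(self.positive) + len(self.negative) + len(self.unclassified)

    def named(self) -> dict[str, list[HarmonizedRecord]]:
        """Strata keyed by their biological labels."""
        return {
            self.labels.get("positive", "positive"): self.positive,
            self.labels.get("negative", "negative"): self.negative,
            "unclassified": self.unclassified,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stratum, recs in (
            ("positive", self.positive),
            ("negative", self.negative),
            ("unclassified", self.unclassified),
        ):
            label = self.labels.get(stratum, stratum)
            for r in recs:
                rows.append(
                    {
                        "variant_id": r.variant_id,
                        "stratum": stratum,
                        "label": label if stratum != "unclassified" else "unclassified",
                        "beta_z": float("nan") if r.beta_z is None else r.beta_z,
                    }
                )
        return pd.DataFrame(rows, columns=["variant_id", "stratum", "label", "beta_z"])


def variance_explained(beta: float, se: float, n: int) -> float:
    """Trait variance explained by one variant, from its summary statistics.

    r² = z²/(z² + n − 2) with z = beta/se; lies in [0, 1) for n > 2.
    """
    if se <= 0:
        raise ValidationError(f"se must be > 0, got {se}")
    if n <= 2:
        raise ValidationError(f"n must be > 2 for variance explained, got {n}")
    z2 = (beta / se) ** 2
    return z2 / (z2 + n - 2)


def steiger_filter(
    hset: HarmonizedSet, on_missing_n: str = "drop"
) -> tuple[HarmonizedSet, list[SteigerResult]]:
    """Keep instruments with more variance explained in exposure than outcome.

    Strict comparison: kept iff r²_x > r²_y.  Records lacking a usable sample
    size are dropped with reason ``steiger-no-n`` (``on_missing_n="keep"``
    retains them with a warning reason instead).
    """
    if on_missing_n not in ("drop", "keep"):
        raise ValidationError(f"on_missing_n must be 'drop' or 'keep', got {on_missing_n!r}")
    kept_records: list[HarmonizedRecord] = []
    results: list[SteigerResult] = []
    for rec in hset.records:
        if rec.n_x is None or rec.n_y is None or rec.n_x <= 2 or rec.n_y <= 2:
            keep = on_missing_n == "keep"
            results.append(
                SteigerResult(
                    rec.variant_id,
                    float("nan"),
                    float("nan"),
                    kept=keep,
                    reason="steiger-no-n",
                )
            )
            if keep:
                kept_records.append(rec)
            continue
        r2x = variance_explained(rec.beta_x, rec.se_x, rec.n_x)
        r2y = variance_explained(rec.beta_y, rec.se_y, rec.n_y)
        keep = r2x > r2y
        results.append(SteigerResult(rec.variant_id, r2x, r2y, kept=keep))
        if keep:
            kept_records.append(rec)
    return HarmonizedSet(records=kept_records, provenance=hset.provenance), results


def stratify_by_indicator(
    hset: HarmonizedSet, labels: dict[str, str] | None = None
) -> StratifiedGroups:
    """Partition oriented instruments by the sign of the indicator beta.

    ``beta_z > 0`` → positive stratum, ``beta_z < 0`` → negative, missing or
    exactly zero → unclassified.  The three strata always partition the
    input.
    """
    groups = StratifiedGroups(labels=labels or {"positive": "positive", "negative": "negative"})
    for rec in hset.records:
        if rec.beta_z is None or rec.beta_z == 0:
            groups.unclassified.append(rec)
        elif rec.beta_z > 0:
            groups.positive.append(rec)
        else:
            groups.negative.append(rec)
    return groups


def steiger_results_frame(results: list[SteigerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "r2_exposure": r.r2_exposure,
                "r2_outcome": r.r2_outcome,
                "kept": r.kept,
                "reason": r.reason,
            }
            for r in results
        ],
        columns=["variant_id", "r2_exposure", "r2_outcome", "kept", "reason"],
    )
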