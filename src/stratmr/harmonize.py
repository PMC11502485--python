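"""Build the analysis-ready instrument set.

Instruments are exposure variants below a genome-wide significance threshold
(strict ``pval < p_threshold``).  Each instrument's indicator- and
outcome-trait associations are looked up in the companion tables, with an LD
proxy substituted (highest r², then nearest, then lexicographically smallest
id) when a variant is absent; alleles are aligned to a common effect allele
(strand flips resolved by complement, palindromic A/T and G/C variants
resolved by allele-frequency concordance or dropped when ambiguous); and the
whole record is oriented so the exposure-increasing allele is the effect
allele.  Every selected instrument ends up either in the harmonized set or in
the provenance log with a drop reason — counts always conserve.

LD clumping is *not* performed: inputs are assumed to be pre-resolved
independent signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sumstats import (
    LDReference,
    SummaryStatsTable,
    VariantAssociation,
)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_P_THRESHOLD = 5.0e-8
DEFAULT_R2_MIN = 0.7
DEFAULT_MAX_DIST = 1_000_000
DEFAULT_PALINDROME_WINDOW = 0.08


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and G/C variants: strand cannot be told from allele labels."""
    return COMPLEMENT[a1] == a2


@dataclass
class AlignmentResult:
    status: str  # "ok" | "dropped"
    record: VariantAssociation | None = None
    reason: str | None = None


@dataclass
class ProxyDecision:
    proxy_id: str | None
    r2: float | None = None
    reason: str | None = None  # set when proxy_id is None


@dataclass
class HarmonizedRecord:
    """A variant's aligned exposure (x) / indicator (z) / outcome (y) triple.

    All three betas refer to the same ``effect_allele``; after orientation
    ``beta_x >= 0`` (the effect allele is exposure-increasing).  The indicator
    association may be missing (``beta_z is None``) — such records remain in
    unstratified analyses and fall in the unclassified stratum.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta_x: float
    se_x: float
    p_x: float
    n_x: int
    beta_y: float
    se_y: float
    n_y: int
    beta_z: float | None = None
    se_z: float | None = None
    n_z: int | None = None
    proxy_of: str | None = None
    indicator_proxy: str | None = None


@dataclass
class HarmonizedSet:
    """Harmonized records plus a per-instrument provenance log.

    Invariant: every selected instrument appears exactly once in
    ``provenance`` with status ``kept``, ``proxied-kept`` or ``dropped``;
    kept statuses correspond one-to-one with ``records``.
    """

    records: list[HarmonizedRecord] = field(default_factory=list)
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "variant_id",
                "status",
                "reason",
                "outcome_proxy",
                "outcome_r2",
                "indicator_proxy",
                "indicator_r2",
            ]
        )
    )

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "variant_id": r.variant_id,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "eaf": np.nan if r.eaf is None else r.eaf,
                    "beta_x": r.beta_x,
                    "se_x": r.se_x,
                    "p_x": r.p_x,
                    "n_x": r.n_x,
                    "beta_z": np.nan if r.beta_z is None else r.beta_z,
                    "se_z": np.nan if r.se_z is None else r.se_z,
                    "n_z": np.nan if r.n_z is None else r.n_z,
                    "beta_y": r.beta_y,
                    "se_y": r.se_y,
                    "n_y": r.n_y,
                    "proxy_of": "" if r.proxy_of is None else r.proxy_of,
                    "indicator_proxy": "" if r.indicator_proxy is None else r.indicator_proxy,
                }
            )
        cols = [
            "variant_id", "effect_allele", "other_allele", "eaf",
            "beta_x", "se_x", "p_x", "n_x",
            "beta_z", "se_z", "n_z",
            "beta_y", "se_y", "n_y",
            "proxy_of", "indicator_proxy",
        ]
        return pd.DataFrame(rows, columns=cols)

    def subset(self, variant_ids: Iterable[str]) -> "HarmonizedSet":
        keep = set(variant_ids)
        return HarmonizedSet(
            records=[r for r in self.records if r.variant_id in keep],
            provenance=self.provenance,
        )


def select_instruments(
    exposure: SummaryStatsTable, p_threshold: float = DEFAULT_P_THRESHOLD
) -> list[VariantAssociation]:
    """Exposure records with ``pval`` strictly below the threshold."""
    if not (0 < p_threshold <= 1):
        raise ValidationError(f"p_threshold must be in (0, 1], got {p_threshold}")
    mask = exposure.df["pval"] < p_threshold
    return [rec for rec, keep in zip(exposure.records(), mask) if keep]


def align_alleles(
    reference: VariantAssociation,
    other: VariantAssociation,
    palindrome_window: float = DEFAULT_PALINDROME_WINDOW,
) -> AlignmentResult:
    """Express ``other``'s beta/eaf on ``reference``'s effect allele.

    Matching alleles pass through; swapped alleles negate beta and complement
    eaf; opposite-strand labels are complemented first.  Palindromic variants
    are resolved by eaf concordance, and dropped as ``palindromic-ambiguous``
    when either eaf is missing or within ``0.5 ± palindrome_window`` in
    either table.
    """
    ref_e, ref_o = reference.effect_allele, reference.other_allele
    oth_e, oth_o = other.effect_allele, other.other_allele

    if is_palindromic(ref_e, ref_o):
        if {oth_e, oth_o} != {ref_e, ref_o}:
            return AlignmentResult("dropped", reason="allele-mismatch")
        for eaf in (reference.eaf, other.eaf):
            if eaf is None or abs(eaf - 0.5) <= palindrome_window:
                return AlignmentResult("dropped", reason="palindromic-ambiguous")
        # eafs informative: same side of 0.5 means same allele measured
        concordant = (reference.eaf - 0.5) * (other.eaf - 0.5) > 0
        if concordant:
            aligned = replace(other, effect_allele=ref_e, other_allele=ref_o)
        else:
            aligned = replace(
                other,
                effect_allele=ref_e,
                other_allele=ref_o,
                beta=-other.beta,
                eaf=1 - other.eaf,
            )
        return AlignmentResult("ok", record=aligned)

    if {oth_e, oth_o} != {ref_e, ref_o}:
        flipped = {COMPLEMENT[oth_e], COMPLEMENT[oth_o]}
        if flipped != {ref_e, ref_o}:
            return AlignmentResult("dropped", reason="allele-mismatch")
        # opposite strand: relabel, no sign change
        oth_e, oth_o = COMPLEMENT[oth_e], COMPLEMENT[oth_o]

    if oth_e == ref_e:
        aligned = replace(other, effect_allele=ref_e, other_allele=ref_o)
    else:
        aligned = replace(
            other,
            effect_allele=ref_e,
            other_allele=ref_o,
            beta=-other.beta,
            eaf=None if other.eaf is None else 1 - other.eaf,
        )
    return AlignmentResult("ok", record=aligned)


def orient_to_exposure_increasing(record: HarmonizedRecord) -> HarmonizedRecord:
    """Flip the record so the effect allele increases the exposure.

    Idempotent; ``beta_x == 0`` has no defined increasing allele and raises.
    """
    if record.beta_x == 0:
        raise ValidationError(
            f"{record.variant_id}: beta_x = 0, exposure-increasing allele undefined"
        )
    if record.beta_x > 0:
        return record
    return replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        eaf=None if record.eaf is None else 1 - record.eaf,
        beta_x=-record.beta_x,
        beta_z=None if record.beta_z is None else -record.beta_z,
        beta_y=-record.beta_y,
    )


def find_proxy(
    variant_id: str,
    target: SummaryStatsTable,
    ld: LDReference,
    r2_min: float = DEFAULT_R2_MIN,
    max_dist: int = DEFAULT_MAX_DIST,
) -> ProxyDecision:
    """Best LD proxy for ``variant_id`` among variants present in ``target``.

    Candidates need known r² strictly above ``r2_min``, the same chromosome,
    and a distance of at most ``max_dist``; the winner has the highest r²,
    ties broken by smaller distance then lexicographically smaller id.  A
    variant present in the target is its own proxy (r² = 1).
    """
    if variant_id in target:
        return ProxyDecision(proxy_id=variant_id, r2=1.0)
    index_pos = ld.position(variant_id)
    if index_pos is None:
        return ProxyDecision(proxy_id=None, reason="no-position")
    chrom, pos = index_pos
    candidates: list[tuple[float, int, str]] = []
    for other_id, r2 in ld.neighbors(variant_id).items():
        if r2 <= r2_min or other_id not in target:
            continue
        other_pos = ld.position(other_id)
        if other_pos is None or other_pos[0] != chrom:
            continue
        dist = abs(other_pos[1] - pos)
        if dist > max_dist:
            continue
        candidates.append((r2, dist, other_id))
    if not candidates:
        return ProxyDecision(proxy_id=None, reason="no-proxy")
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    r2, _, proxy_id = candidates[0]
    return ProxyDecision(proxy_id=proxy_id, r2=r2)


def _aligned_proxy_association(
    index: VariantAssociation, proxy: VariantAssociation
) -> VariantAssociation | None:
    """Orient a (different-id) proxy's beta onto the index variant's alleles.

    With distinct variants the allele labels carry no alignment information;
    the proxy's effect allele is taken to tag the index effect allele when
    their eafs fall on the same side of 0.5 (high LD makes frequencies
    nearly equal).  Returns ``None`` when either eaf is missing or exactly
    0.5 (concordance undefined).
    """
    if index.eaf is None or proxy.eaf is None:
        return None
    d = (index.eaf - 0.5) * (proxy.eaf - 0.5)
    if d == 0:
        return None
    if d > 0:
        return proxy
    return replace(proxy, beta=-proxy.beta, eaf=1 - proxy.eaf)


def build_instrument_set(
    exposure: SummaryStatsTable,
    indicator: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDReference | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_min: float = DEFAULT_R2_MIN,
    max_dist: int = DEFAULT_MAX_DIST,
    palindrome_window: float = DEFAULT_PALINDROME_WINDOW,
) -> HarmonizedSet:
    """Select, proxy, align and orient instruments into a harmonized set.

    The outcome association is mandatory (a missing variant without a proxy
    drops the instrument, reason ``no-proxy``); the indicator association is
    optional (record kept, marked indicator-missing).  Provenance lists every
    selected instrument exactly once.
    """
    if ld is None:
        ld = LDReference()
    instruments = select_instruments(exposure, p_threshold)
    records: list[HarmonizedRecord] = []
    prov_rows: list[dict] = []

    for inst in instruments:
        prow = {
            "variant_id": inst.variant_id,
            "status": "",
            "reason": "",
            "outcome_proxy": "",
            "outcome_r2": np.nan,
            "indicator_proxy": "",
            "indicator_r2": np.nan,
        }

        # --- outcome association (mandatory, proxy allowed) ---
        decision = find_proxy(inst.variant_id, outcome, ld, r2_min, max_dist)
        if decision.proxy_id is None:
            prow.update(status="dropped", reason=decision.reason or "no-proxy")
            prov_rows.append(prow)
            continue
        out_assoc = outcome.get(decision.proxy_id)
        proxied = decision.proxy_id != inst.variant_id
        if proxied:
            aligned_y = _aligned_proxy_association(inst, out_assoc)
            if aligned_y is None:
                prow.update(status="dropped", reason="proxy-eaf-ambiguous")
                prov_rows.append(prow)
                continue
            prow.update(outcome_proxy=decision.proxy_id, outcome_r2=decision.r2)
        else:
            res = align_alleles(inst, out_assoc, palindrome_window)
            if res.status != "ok":
                prow.update(status="dropped", reason=res.reason)
                prov_rows.append(prow)
                continue
            aligned_y = res.record

        # --- indicator association (optional, proxy allowed) ---
        aligned_z: VariantAssociation | None = None
        ind_proxy_id: str | None = None
        decision_z = find_proxy(inst.variant_id, indicator, ld, r2_min, max_dist)
        if decision_z.proxy_id is not None:
            ind_assoc = indicator.get(decision_z.proxy_id)
            if decision_z.proxy_id != inst.variant_id:
                aligned_z = _aligned_proxy_association(inst, ind_assoc)
                if aligned_z is not None:
                    ind_proxy_id = decision_z.proxy_id
                    prow.update(
                        indicator_proxy=decision_z.proxy_id, indicator_r2=decision_z.r2
                    )
            else:
                res_z = align_alleles(inst, ind_assoc, palindrome_window)
                if res_z.status == "ok":
                    aligned_z = res_z.record

        record = HarmonizedRecord(
            variant_id=inst.variant_id,
            effect_allele=inst.effect_allele,
            other_allele=inst.other_allele,
            eaf=inst.eaf,
            beta_x=inst.beta,
            se_x=inst.se,
            p_x=inst.pval,
            n_x=inst.n,
            beta_y=aligned_y.beta,
            se_y=aligned_y.se,
            n_y=aligned_y.n,
            beta_z=None if aligned_z is None else aligned_z.beta,
            se_z=None if aligned_z is None else aligned_z.se,
            n_z=None if aligned_z is None else aligned_z.n,
            proxy_of=inst.variant_id if proxied else None,
            indicator_proxy=ind_proxy_id,
        )
        try:
            record = orient_to_exposure_increasing(record)
        except ValidationError:
            prow.update(status="dropped", reason="zero-exposure-effect")
            prov_rows.append(prow)
            continue

        reason = "" if aligned_z is not None else "indicator-missing"
        prow.update(status="proxied-kept" if proxied else "kept", reason=reason)
        prov_rows.append(prow)
        records.append(record)

    provenance = pd.DataFrame(
        prov_rows,
        columns=[
            "variant_id",
            "status",
            "reason",
            "outcome_proxy",
            "outcome_r2",
            "indicator_proxy",
            "indicator_r2",
        ],
    )
    return HarmonizedSet(records=records, provenance=provenance)


def harmonize_aligned(
    exposure: SummaryStatsTable,
    indicator: SummaryStatsTable | None,
    outcome: SummaryStatsTable,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> HarmonizedSet:
    """Vectorized harmonization for tables already on a common allele coding.

    Requires every shared variant to carry identical effect/other alleles in
    all tables (as simulator output does) — only instrument selection,
    merging and orientation remain.  Use :func:`build_instrument_set` for
    real-world tables needing strand/eaf resolution or LD proxies.
    """
    if not (0 < p_threshold <= 1):
        raise ValidationError(f"p_threshold must be in (0, 1], got {p_threshold}")
    ex = exposure.df
    sel = ex.loc[ex["pval"] < p_threshold] if p_threshold < 1 else ex
    merged = sel.merge(outcome.df, on="variant_id", suffixes=("_x", "_y"), how="inner")
    mismatch = (merged["effect_allele_x"] != merged["effect_allele_y"]) | (
        merged["other_allele_x"] != merged["other_allele_y"]
    )
    if mismatch.any():
        bad = merged.loc[mismatch, "variant_id"].iloc[0]
        raise ValidationError(
            f"harmonize_aligned requires identical allele coding; {bad!r} differs "
            "(use build_instrument_set)"
        )
    if indicator is not None:
        ind = indicator.df[["variant_id", "effect_allele", "other_allele", "beta", "se", "n"]]
        merged = merged.merge(
            ind.rename(
                columns={
                    "effect_allele": "effect_allele_z",
                    "other_allele": "other_allele_z",
                    "beta": "beta_z",
                    "se": "se_z",
                    "n": "n_z",
                }
            ),
            on="variant_id",
            how="left",
        )
        with_z = merged["beta_z"].notna()
        mismatch_z = with_z & (
            (merged["effect_allele_x"] != merged["effect_allele_z"])
            | (merged["other_allele_x"] != merged["other_allele_z"])
        )
        if mismatch_z.any():
            bad = merged.loc[mismatch_z, "variant_id"].iloc[0]
            raise ValidationError(
                f"harmonize_aligned requires identical allele coding; {bad!r} differs "
                "(use build_instrument_set)"
            )
    else:
        merged["beta_z"] = np.nan
        merged["se_z"] = np.nan
        merged["n_z"] = np.nan

    records: list[HarmonizedRecord] = []
    prov_rows: list[dict] = []
    flip = merged["beta_x"] < 0
    zero = merged["beta_x"] == 0
    sign = np.where(flip, -1.0, 1.0)
    for i, row in enumerate(merged.itertuples(index=False)):
        prow = {
            "variant_id": row.variant_id,
            "status": "kept",
            "reason": "",
            "outcome_proxy": "",
            "outcome_r2": np.nan,
            "indicator_proxy": "",
            "indicator_r2": np.nan,
        }
        if zero.iloc[i]:
            prow.update(status="dropped", reason="zero-exposure-effect")
            prov_rows.append(prow)
            continue
        s = sign[i]
        flipped = s < 0
        has_z = not pd.isna(row.beta_z)
        if not has_z:
            prow["reason"] = "indicator-missing"
        eff = row.other_allele_x if flipped else row.effect_allele_x
        oth = row.effect_allele_x if flipped else row.other_allele_x
        eaf = row.eaf_x
        records.append(
            HarmonizedRecord(
                variant_id=str(row.variant_id),
                effect_allele=str(eff),
                other_allele=str(oth),
                eaf=None if pd.isna(eaf) else float(1 - eaf if flipped else eaf),
                beta_x=float(s * row.beta_x),
                se_x=float(row.se_x),
                p_x=float(row.pval_x),
                n_x=int(row.n_x),
                beta_z=float(s * row.beta_z) if has_z else None,
                se_z=float(row.se_z) if has_z else None,
                n_z=int(row.n_z) if has_z else None,
                beta_y=float(s * row.beta_y),
                se_y=float(row.se_y),
                n_y=int(row.n_y),
            )
        )
        prov_rows.append(prow)

    # instruments absent from the outcome table drop with no-proxy
    missing = set(sel["variant_id"]) - set(merged["variant_id"])
    for vid in sorted(missing):
        prov_rows.append(
            {
                "variant_id": vid,
                "status": "dropped",
                "reason": "no-proxy",
                "outcome_proxy": "",
                "outcome_r2": np.nan,
                "indicator_proxy": "",
                "indicator_r2": np.nan,
            }
        )
    provenance = pd.DataFrame(
        prov_rows,
        columns=[
            "variant_id", "status", "reason",
            "outcome_proxy", "outcome_r2", "indicator_proxy", "indicator_r2",
        ],
    )
    return HarmonizedSet(records=records, provenance=provenance)


# --- harmonized-set TSV round trip (pipeline plumbing) -----------------------

def write_harmonized(hset: HarmonizedSet, path: str | Path) -> Path:
    path = Path(path)
    df = hset.to_frame()
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            cells = []
            for col in df.columns:
                v = row[col]
                if isinstance(v, float):
                    cells.append("NA" if np.isnan(v) else repr(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")
    return path


def read_harmonized(path: str | Path) -> HarmonizedSet:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={"variant_id": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            HarmonizedRecord(
                variant_id=str(row.variant_id),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                beta_x=float(row.beta_x),
                se_x=float(row.se_x),
                p_x=float(row.p_x),
                n_x=int(row.n_x),
                beta_z=None if pd.isna(row.beta_z) else float(row.beta_z),
                se_z=None if pd.isna(row.se_z) else float(row.se_z),
                n_z=None if pd.isna(row.n_z) else int(row.n_z),
                beta_y=float(row.beta_y),
                se_y=float(row.se_y),
                n_y=int(row.n_y),
                proxy_of=None if (pd.isna(row.proxy_of) or row.proxy_of == "") else str(row.proxy_of),
                indicator_proxy=None
                if (pd.isna(row.indicator_proxy) or row.indicator_proxy == "")
                else str(row.indicator_proxy),
            )
        )
    return HarmonizedSet(records=records)


def write_provenance(hset: HarmonizedSet, path: str | Path) -> Path:
    path = Path(path)
    hset.provenance.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path
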