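"""GWAS summary-statistics tables and LD reference I/O.

The on-disk dialect is a tab-separated table with a header row and the
canonical columns

    variant_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

(positions 1-based; alleles single-nucleotide, upper case; ``eaf`` may be
missing and is serialized as ``NA``).  Other dialects are ingested through a
``column_map`` translating foreign header names onto the canonical ones.

The LD reference is consumed pre-computed, as a long-format pair table
``variant_id_a  variant_id_b  r2`` plus a positions table
``variant_id  chrom  pos``; lookups are symmetric and every variant has an
implied self-correlation of 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

VALID_ALLELES = frozenset({"A", "C", "G", "T"})

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: columns that must be present and non-missing in every row
MANDATORY_COLUMNS = [c for c in CANONICAL_COLUMNS if c != "eaf"]

MISSING_TOKEN = "NA"


@dataclass
class VariantAssociation:
    """One variant's association record with one trait.

    ``beta`` is in trait units per copy of ``effect_allele``; ``eaf`` is the
    effect-allele frequency and may be ``None`` when the source omits it.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.variant_id}: effect_allele {self.effect_allele!r} "
                f"not a single nucleotide in {sorted(VALID_ALLELES)}"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.variant_id}: other_allele {self.other_allele!r} "
                f"not a single nucleotide in {sorted(VALID_ALLELES)}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: alleles identical")
        if not self.se > 0:
            raise ValidationError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if self.pos < 1:
            raise ValidationError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if not (0 < self.pval <= 1):
            raise ValidationError(
                f"{self.variant_id}: pval must be in (0, 1], got {self.pval}"
            )
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.variant_id}: eaf must be in [0, 1], got {self.eaf}")
        if self.n <= 1:
            raise ValidationError(f"{self.variant_id}: n must be > 1, got {self.n}")


@dataclass
class SummaryStatsTable:
    """An ordered collection of :class:`VariantAssociation` for one trait.

    Backed by a :class:`pandas.DataFrame` in canonical column order;
    ``variant_id`` is unique and row order is stable under round-trip.
    """

    df: pd.DataFrame
    trait_name: str = ""
    trait_units: str = ""

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    @property
    def _index(self) -> pd.Index:
        return pd.Index(self.df["variant_id"])

    def get(self, variant_id: str) -> VariantAssociation | None:
        rows = self.df.loc[self.df["variant_id"] == variant_id]
        if rows.empty:
            return None
        return _row_to_record(rows.iloc[0])

    def records(self) -> Iterable[VariantAssociation]:
        for _, row in self.df.iterrows():
            yield _row_to_record(row)

    @classmethod
    def from_records(
        cls,
        records: Iterable[VariantAssociation],
        trait_name: str = "",
        trait_units: str = "",
    ) -> "SummaryStatsTable":
        rows = []
        for rec in records:
            rec.validate()
            rows.append(
                {
                    "variant_id": rec.variant_id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "effect_allele": rec.effect_allele,
                    "other_allele": rec.other_allele,
                    "eaf": math.nan if rec.eaf is None else rec.eaf,
                    "beta": rec.beta,
                    "se": rec.se,
                    "pval": rec.pval,
                    "n": rec.n,
                }
            )
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        df = _coerce_dtypes(df)
        if df["variant_id"].duplicated().any():
            dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValidationError(f"duplicate variant_id {dup!r}")
        return cls(df=df, trait_name=trait_name, trait_units=trait_units)


def _row_to_record(row: pd.Series) -> VariantAssociation:
    eaf = row["eaf"]
    return VariantAssociation(
        variant_id=str(row["variant_id"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        eaf=None if pd.isna(eaf) else float(eaf),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pval=float(row["pval"]),
        n=int(row["n"]),
    )


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = df[col].astype(float)
    df["n"] = df["n"].astype(np.int64)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    return df


def _validate_rows(df: pd.DataFrame) -> list[str]:
    """Return one diagnostic per invalid row (1-based data row numbers)."""
    problems: list[str] = []
    allele_ok = df["effect_allele"].isin(VALID_ALLELES) & df["other_allele"].isin(
        VALID_ALLELES
    )
    for i, (idx, row) in enumerate(df.iterrows(), start=1):
        if not allele_ok.loc[idx]:
            problems.append(
                f"row {i} ({row['variant_id']}): allele outside "
                f"{sorted(VALID_ALLELES)} (indels not supported)"
            )
        elif row["effect_allele"] == row["other_allele"]:
            problems.append(f"row {i} ({row['variant_id']}): identical alleles")
        elif not row["se"] > 0:
            problems.append(f"row {i} ({row['variant_id']}): se = {row['se']} is not > 0")
        elif row["pos"] < 1:
            problems.append(f"row {i} ({row['variant_id']}): pos = {row['pos']} < 1")
        elif not (0 < row["pval"] <= 1):
            problems.append(
                f"row {i} ({row['variant_id']}): pval = {row['pval']} outside (0, 1]"
            )
        elif not pd.isna(row["eaf"]) and not (0 <= row["eaf"] <= 1):
            problems.append(
                f"row {i} ({row['variant_id']}): eaf = {row['eaf']} outside [0, 1]"
            )
        elif row["n"] <= 1:
            problems.append(f"row {i} ({row['variant_id']}): n = {row['n']} is not > 1")
    return problems


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "",
    trait_units: str = "",
    on_invalid: str = "raise",
) -> SummaryStatsTable:
    """Read a tab-separated summary-statistics table.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional mapping of the file's column names onto the canonical names,
        e.g. ``{"SNP": "variant_id", "A1": "effect_allele"}``.  Canonical
        columns not covered by the map are looked up under their own name.
    on_invalid
        ``"raise"`` (default) aborts on the first invalid row; ``"drop"``
        removes invalid rows and records a diagnostic per dropped row in the
        returned table's ``df.attrs["diagnostics"]``.  Either way every input
        row is accounted for.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"variant_id": str, "chrom": str}, na_values=[MISSING_TOKEN]
    )
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"present: {list(df.columns)}"
        )
    if "eaf" not in df.columns:
        df["eaf"] = math.nan
    df = df[CANONICAL_COLUMNS]

    for col in MANDATORY_COLUMNS:
        if df[col].isna().any():
            i = int(df.index[df[col].isna()][0]) + 1
            raise ValidationError(f"{path}: row {i}: missing value in mandatory column {col!r}")

    df = _coerce_dtypes(df)
    problems = _validate_rows(df)
    if problems:
        if on_invalid == "raise":
            raise ValidationError(f"{path}: " + "; ".join(problems))
        bad_rows = {int(p.split()[1]) - 1 for p in problems}
        df = df.drop(df.index[sorted(bad_rows)]).reset_index(drop=True)
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate variant_id {dup!r}")
    table = SummaryStatsTable(
        df=df.reset_index(drop=True), trait_name=trait_name, trait_units=trait_units
    )
    table.df.attrs["diagnostics"] = problems if on_invalid == "drop" else []
    return table


def write_sumstats(table: SummaryStatsTable, path: str | Path) -> Path:
    """Write a table as TSV in canonical column order, round-trip safe.

    Reals are written with :func:`repr` precision, so ``read(write(T)) == T``
    bit-for-bit; missing ``eaf`` is serialized as ``NA``.
    """
    path = Path(path)
    df = table.df
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            eaf = MISSING_TOKEN if pd.isna(row.eaf) else repr(float(row.eaf))
            fh.write(
                "\t".join(
                    [
                        str(row.variant_id),
                        str(row.chrom),
                        str(int(row.pos)),
                        str(row.effect_allele),
                        str(row.other_allele),
                        eaf,
                        repr(float(row.beta)),
                        repr(float(row.se)),
                        repr(float(row.pval)),
                        str(int(row.n)),
                    ]
                )
                + "\n"
            )
    return path


@dataclass
class LDReference:
    """Symmetric pairwise-r² lookup plus variant positions.

    An absent pair means the correlation is *unknown*, not zero; the proxy
    search (harmonization) only considers pairs with known r².
    """

    _adj: dict[str, dict[str, float]] = field(default_factory=dict)
    _positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def add_pair(self, a: str, b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ValidationError(f"r2({a}, {b}) = {r2} outside [0, 1]")
        if a == b:
            return
        self._adj.setdefault(a, {})[b] = r2
        self._adj.setdefault(b, {})[a] = r2

    def add_position(self, variant_id: str, chrom: str, pos: int) -> None:
        self._positions[variant_id] = (str(chrom), int(pos))

    def r2(self, a: str, b: str) -> float | None:
        """Known pairwise r², 1 for a self-pair, ``None`` if unknown."""
        if a == b:
            return 1.0
        return self._adj.get(a, {}).get(b)

    def neighbors(self, variant_id: str) -> dict[str, float]:
        return dict(self._adj.get(variant_id, {}))

    def position(self, variant_id: str) -> tuple[str, int] | None:
        return self._positions.get(variant_id)

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    def __len__(self) -> int:
        return self.n_pairs


def read_ld_reference(pairs_path: str | Path, positions_path: str | Path) -> LDReference:
    """Load a long-format LD pair table and its positions table."""
    ld = LDReference()
    pairs = pd.read_csv(pairs_path, sep="\t", dtype={"variant_id_a": str, "variant_id_b": str})
    for col in ("variant_id_a", "variant_id_b", "r2"):
        if col not in pairs.columns:
            raise ConfigurationError(f"{pairs_path}: missing column {col!r}")
    for row in pairs.itertuples(index=False):
        ld.add_pair(row.variant_id_a, row.variant_id_b, float(row.r2))
    positions = pd.read_csv(positions_path, sep="\t", dtype={"variant_id": str, "chrom": str})
    for col in ("variant_id", "chrom", "pos"):
        if col not in positions.columns:
            raise ConfigurationError(f"{positions_path}: missing column {col!r}")
    for row in positions.itertuples(index=False):
        ld.add_position(row.variant_id, row.chrom, int(row.pos))
    return ld


def write_ld_reference(ld: LDReference, pairs_path: str | Path, positions_path: str | Path) -> None:
    seen = set()
    with open(pairs_path, "w") as fh:
        fh.write("variant_id_a\tvariant_id_b\tr2\n")
        for a in sorted(ld._adj):
            for b, r2 in sorted(ld._adj[a].items()):
                key = (min(a, b), max(a, b))
                if key in seen:
                    continue
                seen.add(key)
                fh.write(f"{key[0]}\t{key[1]}\t{repr(float(r2))}\n")
    with open(positions_path, "w") as fh:
        fh.write("variant_id\tchrom\tpos\n")
        for vid in sorted(ld._positions):
            chrom, pos = ld._positions[vid]
            fh.write(f"{vid}\t{chrom}\t{pos}\n")
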