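"""Reading, validating and writing phenotype tables and result sets.

The canonical in-memory representation is long format: one record per
(genotype, block, trait) observation. Wide spreadsheets as exported by
seed-imaging systems (one row per genotype x replicate, one column per
trait) are melted on read using a :class:`~seedpheno.traits.TraitSchema`.
Both decimal-point and decimal-comma CSV dialects are supported behind
an explicit flag, since exports from pt-BR locales commonly use commas.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from seedpheno.traits import DEFAULT_SCHEMA, TraitSchema

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["genotype", "block", "trait", "value"]


@dataclass
class PhenotypeTable:
    """Long-format genotype x replicate x trait observations.

    Invariants enforced on construction: every (genotype, block, trait)
    triple appears at most once and all values are finite.
    """

    data: pd.DataFrame
    balanced: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table is missing columns {missing}")
        df = df.loc[:, LONG_COLUMNS].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["block"] = df["block"].astype(str)
        df["trait"] = df["trait"].astype(str)
        values = pd.to_numeric(df["value"], errors="coerce")
        bad = df.index[values.isna() & df["value"].notna()]
        if len(bad):
            row = bad[0]
            raise ValueError(
                f"non-numeric value {df.loc[row, 'value']!r} at row {row} "
                f"({df.loc[row, 'genotype']}, {df.loc[row, 'block']}, {df.loc[row, 'trait']})"
            )
        df["value"] = values.astype(float)
        if not np.isfinite(df["value"].dropna()).all():
            raise ValueError("phenotype table contains non-finite values")
        dup = df.duplicated(subset=["genotype", "block", "trait"], keep=False)
        if dup.any():
            g, b, t = df.loc[dup.idxmax(), ["genotype", "block", "trait"]]
            raise ValueError(f"duplicate observation for triple ({g}, {b}, {t})")
        df = df.dropna(subset=["value"]).reset_index(drop=True)
        self.data = df
        g, r = len(self.genotypes), len(self.blocks)
        counts = df.groupby("trait").size()
        self.balanced = bool(len(counts) > 0 and (counts == g * r).all())

    # -- structure ---------------------------------------------------------
    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def blocks(self) -> list[str]:
        return sorted(self.data["block"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def __len__(self) -> int:
        return len(self.data)

    def is_balanced(self, trait_id: str) -> bool:
        sub = self.data[self.data["trait"] == trait_id]
        expected = {(g, b) for g in self.genotypes for b in self.blocks}
        return set(zip(sub["genotype"], sub["block"])) == expected

    def missing_cells(self, trait_id: str) -> list[tuple[str, str]]:
        sub = self.data[self.data["trait"] == trait_id]
        have = set(zip(sub["genotype"], sub["block"]))
        return sorted(
            (g, b) for g in self.genotypes for b in self.blocks if (g, b) not in have
        )

    # -- marginalizations --------------------------------------------------
    def plot_matrix(self, trait_id: str) -> pd.DataFrame:
        """Genotype x block matrix of observations for one trait."""
        sub = self.data[self.data["trait"] == trait_id]
        if sub.empty:
            raise KeyError(f"unknown trait {trait_id!r}")
        return sub.pivot(index="genotype", columns="block", values="value")

    def genotype_means(self, traits=None) -> pd.DataFrame:
        """Genotype x trait matrix of means over replicates (profiles)."""
        wide = self.data.pivot_table(
            index="genotype", columns="trait", values="value", aggfunc="mean"
        )
        if traits is not None:
            wide = wide.loc[:, list(traits)]
        return wide


def read_phenotype_table(
    source,
    *,
    sep: str = ",",
    decimal: str = ".",
    schema: TraitSchema | None = None,
) -> PhenotypeTable:
    """Read a phenotype CSV (long or wide) into a validated table.

    Long input has columns ``genotype, block, trait, value``; anything
    else is treated as wide (``genotype, block`` plus one column per
    trait) and melted using ``schema`` (display labels or trait ids are
    both accepted as column headers; unknown columns are skipped with a
    warning).
    """
    schema = schema or DEFAULT_SCHEMA
    df = pd.read_csv(source, sep=sep, decimal=decimal)
    df.columns = [str(c).strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    if all(c in lower for c in LONG_COLUMNS):
        df = df.rename(columns={lower[c]: c for c in LONG_COLUMNS})
        table = PhenotypeTable(df)
    else:
        for key in ("genotype", "block"):
            if key not in lower:
                raise ValueError(f"wide table must have a {key!r} column")
        df = df.rename(columns={lower["genotype"]: "genotype", lower["block"]: "block"})
        rename, drop = {}, []
        for col in df.columns:
            if col in ("genotype", "block"):
                continue
            if col in schema:
                rename[col] = col
            elif col in schema.labels:
                rename[col] = schema.labels[col]
            else:
                drop.append(col)
        if drop:
            warnings.warn(f"skipping unknown trait columns: {drop}", stacklevel=2)
            df = df.drop(columns=drop)
        df = df.rename(columns=rename)
        long = df.melt(id_vars=["genotype", "block"], var_name="trait", value_name="value")
        table = PhenotypeTable(long)
    g, r, t = len(table.genotypes), len(table.blocks), len(table.traits)
    logger.info("read phenotype table: %d genotypes, %d blocks, %d traits", g, r, t)
    return table


def write_phenotype_table(table: PhenotypeTable, path) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False)
    return path


def write_results(tables: dict, destination, summary: dict | None = None) -> list[Path]:
    """Write one CSV per result table plus a machine-readable run summary.

    ``tables`` maps name -> DataFrame (or PhenotypeTable). Column order
    is preserved as given, so writes are deterministic. Returns the list
    of files written (summary last).
    """
    destination = Path(destination)
    try:
        destination.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {destination}: {exc}") from exc
    if not destination.is_dir():
        raise OSError(f"destination {destination} is not a directory")
    written: list[Path] = []
    if not tables:
        warnings.warn("empty result collection: writing summary only", stacklevel=2)
    for name, obj in tables.items():
        df = obj.data if isinstance(obj, PhenotypeTable) else obj
        path = destination / f"{name}.csv"
        df.to_csv(path, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)
        written.append(path)
    summary = dict(summary or {})
    summary.setdefault("tables", [p.name for p in written])
    spath = destination / "run_summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    written.append(spath)
    return written
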