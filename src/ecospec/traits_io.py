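"""Reading, validating and partitioning binary species×trait tables.

A trait table holds one row per species and one binary (0/1) column per
trait; columns are grouped into named *bundles* (e.g. the nine diet
categories, the fifteen habitat categories).  One specialization index is
later computed per species per bundle, so the bundle structure is carried
alongside the matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "BundleConfig",
    "TraitTable",
    "ValidationIssue",
    "ValidationReport",
    "TraitTableError",
    "normalize_species_label",
    "read_trait_table",
    "write_trait_table",
    "validate_trait_table",
]


class TraitTableError(ValueError):
    """Raised for malformed trait tables or bundle configurations."""


def normalize_species_label(label: str) -> str:
    """Canonicalize a species label for matching against tree tip labels.

    Surrounding whitespace is trimmed and internal spaces are converted to
    underscores (the Newick convention used by birdtree-style tip labels),
    so ``" Parus major "`` and ``"Parus_major"`` compare equal.
    """
    return label.strip().replace(" ", "_")


@dataclass(frozen=True)
class BundleConfig:
    """Ordered mapping of bundle name -> list of trait column names."""

    entries: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise TraitTableError("bundle configuration is empty")
        seen: set[str] = set()
        for name, cols in self.entries.items():
            if not name:
                raise TraitTableError("empty bundle name")
            if len(cols) < 2:
                raise TraitTableError(
                    f"bundle {name!r} has {len(cols)} trait(s); at least 2 required"
                )
            for c in cols:
                if not c:
                    raise TraitTableError(f"bundle {name!r} contains an empty column name")
                if c in seen:
                    raise TraitTableError(f"trait column {c!r} appears in more than one bundle")
                seen.add(c)

    @property
    def bundle_names(self) -> list[str]:
        return list(self.entries)

    @property
    def all_columns(self) -> list[str]:
        return [c for cols in self.entries.values() for c in cols]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "BundleConfig":
        return cls({str(k): [str(c) for c in v] for k, v in mapping.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "BundleConfig":
        """Load from YAML or JSON (format inferred from the suffix)."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise TraitTableError(f"{path}: bundle config must be a mapping of bundle -> columns")
        return cls.from_mapping(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.entries, indent=1), encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(self.entries, sort_keys=False), encoding="utf-8")


@dataclass
class TraitTable:
    """Species×trait binary matrix partitioned into named bundles.

    ``values`` is a DataFrame indexed by species id with one 0/1 column per
    trait; ``bundles`` maps each bundle name to its ordered column list.
    """

    values: pd.DataFrame
    bundles: dict[str, list[str]]

    def __post_init__(self) -> None:
        idx = self.values.index
        if len(idx) == 0:
            raise TraitTableError("trait table has no species")
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise TraitTableError(f"duplicated species ids: {dupes}")
        for name, cols in self.bundles.items():
            missing = [c for c in cols if c not in self.values.columns]
            if missing:
                raise TraitTableError(f"bundle {name!r}: missing columns {missing}")
        bad = ~self.values.isin([0, 1]).to_numpy()
        if bad.any():
            i, j = map(int, next(zip(*bad.nonzero())))
            raise TraitTableError(
                f"non-binary cell at species {self.values.index[i]!r}, "
                f"column {self.values.columns[j]!r}: {self.values.iat[i, j]!r}"
            )

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def bundle_names(self) -> list[str]:
        return list(self.bundles)

    @property
    def n_species(self) -> int:
        return len(self.values.index)

    def bundle_matrix(self, bundle: str) -> pd.DataFrame:
        """The 0/1 sub-matrix of one bundle, column order per config."""
        if bundle not in self.bundles:
            raise TraitTableError(f"unknown bundle {bundle!r}")
        return self.values[self.bundles[bundle]]

    def restrict(self, bundles: Iterable[str]) -> "TraitTable":
        """A new table keeping only the named bundles (values untouched)."""
        keep = {b: self.bundles[b] for b in bundles}
        cols = [c for cs in keep.values() for c in cs]
        return TraitTable(self.values[cols].copy(), keep)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    where: str  # species or column identifier
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "issues": [
                    {"severity": i.severity, "where": i.where, "message": i.message}
                    for i in self.issues
                ],
            },
            indent=1,
        )

    def __str__(self) -> str:
        lines = [f"ok: {self.ok}"]
        lines += [f"{i.severity.upper()}: {i.where}: {i.message}" for i in self.issues]
        return "\n".join(lines)


def read_trait_table(path: str | Path, config: BundleConfig) -> TraitTable:
    """Read a CSV trait table and restrict it to the configured bundles.

    The first CSV column is the species identifier; remaining columns are
    traits.  Column order follows the bundle config, row order the file.
    Non-{0,1} cells, missing configured columns and duplicate species ids
    are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise TraitTableError(f"{path}: expected a species column plus trait columns")
    species_col = df.columns[0]
    df[species_col] = df[species_col].map(normalize_species_label)
    if df[species_col].duplicated().any():
        dupes = df.loc[df[species_col].duplicated(), species_col].tolist()
        raise TraitTableError(f"{path}: duplicated species ids: {dupes}")
    missing = [c for c in config.all_columns if c not in df.columns]
    if missing:
        raise TraitTableError(f"{path}: missing trait columns {missing}")
    values = df.set_index(species_col)[config.all_columns]
    arr = values.to_numpy()
    bad = ~values.isin([0, 1]).to_numpy()
    if bad.any():
        i, j = map(int, next(zip(*bad.nonzero())))
        raise TraitTableError(
            f"{path}: non-binary cell at row {i + 2} (species {values.index[i]!r}), "
            f"column {values.columns[j]!r}: value {arr[i, j]!r}"
        )
    values = values.astype(int)
    return TraitTable(values, dict(config.entries))


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Write the table back to CSV (species id in the first column)."""
    out = table.values.copy()
    out.index.name = out.index.name or "species"
    out.to_csv(path)


def validate_trait_table(table: TraitTable) -> ValidationReport:
    """Check a table for rows and columns that break the Gini contract.

    An all-zero row within a bundle is an *error*: the Gini denominator
    2n²x̄ is zero there, so the index is undefined.  A trait column that is
    zero for every species is only a *warning* (the index is defined, the
    column is just uninformative).
    """
    report = ValidationReport()
    for bundle, cols in table.bundles.items():
        sub = table.values[cols]
        zero_rows = sub.sum(axis=1) == 0
        for sp in sub.index[zero_rows]:
            report.issues.append(
                ValidationIssue(
                    "error",
                    f"{sp}/{bundle}",
                    "all-zero trait row: bundle mean is 0, Gini undefined",
                )
            )
        zero_cols = sub.sum(axis=0) == 0
        for col in sub.columns[zero_cols]:
            report.issues.append(
                ValidationIssue("warning", col, "trait column is zero for all species")
            )
    return report
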