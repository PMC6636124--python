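"""Readers and writers for the pipeline's plain-text formats.

All tabular data travel as :class:`pandas.DataFrame` with fixed schemas:

* **methylation matrix** — probes x samples, float beta values in [0, 1],
  ``NaN`` for missing; index = probe IDs, columns = sample IDs.  On disk:
  TSV with a leading probe-ID column and ``NA`` missing markers (the
  UCSC-Xena download dialect).
* **clinical table** — one row per sample, indexed by sample ID, with
  columns ``followup_days, event, T, N, M, stage, grade, age_years, sex``.
  Ordinal fields use integer codes (T1..T4 -> 1..4 etc.); missing entries
  are ``NA``.
* **probe manifest** — one row per probe, indexed by probe ID, with
  columns ``chromosome, position, genes, feature, cross_reactive,
  snp_overlap``.  ``genes`` is a semicolon-joined symbol list (may be
  empty = intergenic probe with no annotation).
* **gene sets** — standard GMT (set name, description, member genes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROMOTER_FEATURES = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})
FEATURE_VOCAB = frozenset(
    {"TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "intergenic"}
)
CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])

CLINICAL_COLUMNS = [
    "followup_days", "event", "T", "N", "M", "stage", "grade", "age_years", "sex",
]
_CLINICAL_RANGES = {
    "event": {0, 1},
    "T": {1, 2, 3, 4},
    "N": {0, 1},
    "M": {0, 1},
    "stage": {1, 2, 3, 4},
    "grade": {1, 2, 3, 4},
}
MANIFEST_COLUMNS = [
    "chromosome", "position", "genes", "feature", "cross_reactive", "snp_overlap",
]


class FormatError(ValueError):
    """A file violated the expected dialect or vocabulary."""


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise FormatError(f"{path}: duplicate {what} ID {dup!r}")


# ---------------------------------------------------------------------------
# methylation matrix

def read_methylation_tsv(path) -> pd.DataFrame:
    """Read a probes x samples beta-value matrix.

    Raises :class:`FormatError` (naming the offending row/column) on
    duplicate IDs, non-numeric cells, values outside [0, 1], or ragged rows.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      na_values=["NA"], keep_default_na=False,
                      on_bad_lines="error")
    _check_unique(raw.index, "probe", path)
    _check_unique(raw.columns, "sample", path)
    try:
        values = raw.astype(float)
    except ValueError:
        for probe, row in raw.iterrows():
            for sample, cell in row.items():
                if pd.isna(cell):
                    continue
                try:
                    float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at probe {probe!r},"
                        f" sample {sample!r}") from None
        raise
    bad = (values < 0) | (values > 1)
    if bad.any().any():
        probe = values.index[bad.any(axis=1)][0]
        sample = values.columns[bad.loc[probe]][0]
        raise FormatError(
            f"{path}: beta value {values.loc[probe, sample]} outside [0, 1] "
            f"at probe {probe!r}, sample {sample!r}")
    return values


def write_methylation_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="probe",
                  lineterminator="\n")


# ---------------------------------------------------------------------------
# clinical table

def read_clinical_tsv(path) -> pd.DataFrame:
    """Read a clinical table; validates ordinal vocabularies (e.g. T in 1..4)."""
    table = pd.read_csv(path, sep="\t", index_col=0,
                        na_values=["NA"], keep_default_na=False)
    _check_unique(table.index, "sample", path)
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing clinical columns {missing_cols}")
    table = table[CLINICAL_COLUMNS]
    return validate_clinical(table, where=str(path))


def validate_clinical(table: pd.DataFrame, where: str = "clinical table") -> pd.DataFrame:
    table = table.copy()
    for col, allowed in _CLINICAL_RANGES.items():
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table[col].notna() & ~vals.isin(list(allowed))
        if bad.any():
            sample = table.index[bad][0]
            raise FormatError(
                f"{where}: {col}={table.loc[sample, col]!r} for sample "
                f"{sample!r} outside vocabulary {sorted(allowed)}")
        table[col] = vals
    sex = table["sex"].astype("string").str.lower()
    bad = table["sex"].notna() & ~sex.isin(["male", "female"])
    if bad.any():
        sample = table.index[bad][0]
        raise FormatError(f"{where}: sex={table.loc[sample, 'sex']!r} for "
                          f"sample {sample!r} not male/female")
    table["sex"] = sex
    table["followup_days"] = pd.to_numeric(table["followup_days"])
    if (table["followup_days"] < 0).any():
        raise FormatError(f"{where}: negative follow-up time")
    table["age_years"] = pd.to_numeric(table["age_years"])
    return table


def write_clinical_tsv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    # integers rendered without trailing .0 where whole, missing as NA
    for col in ["event", "T", "N", "M", "stage", "grade"]:
        out[col] = out[col].astype("Int64")
    out.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id",
               lineterminator="\n")


# ---------------------------------------------------------------------------
# probe manifest

def read_manifest(path) -> pd.DataFrame:
    """Read the probe manifest CSV (chromosome, position, gene annotation,
    genomic feature class, cross-reactive and SNP-overlap flags)."""
    man = pd.read_csv(path, index_col=0, dtype=str,
                      na_values=["NA"], keep_default_na=False)
    _check_unique(man.index, "probe", path)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in man.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing manifest columns {missing_cols}")
    man = man[MANIFEST_COLUMNS].copy()
    chrom = man["chromosome"].str.replace("^chr", "", regex=True)
    bad = ~chrom.isin(CHROMOSOMES)
    if bad.any():
        probe = man.index[bad][0]
        raise FormatError(f"{path}: chromosome {man.loc[probe, 'chromosome']!r}"
                          f" for probe {probe!r} not in 1-22/X/Y")
    man["chromosome"] = chrom
    man["position"] = pd.to_numeric(man["position"]).astype(int)
    if (man["position"] < 1).any():
        probe = man.index[man["position"] < 1][0]
        raise FormatError(f"{path}: position < 1 for probe {probe!r}")
    bad = ~man["feature"].isin(FEATURE_VOCAB)
    if bad.any():
        probe = man.index[bad][0]
        raise FormatError(f"{path}: feature {man.loc[probe, 'feature']!r} for "
                          f"probe {probe!r} not in {sorted(FEATURE_VOCAB)}")
    man["genes"] = man["genes"].fillna("")
    for col in ("cross_reactive", "snp_overlap"):
        man[col] = pd.to_numeric(man[col]).astype(int).astype(bool)
    return man


def write_manifest(man: pd.DataFrame, path) -> None:
    out = man.copy()
    for col in ("cross_reactive", "snp_overlap"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index_label="probe_id", lineterminator="\n")


def manifest_genes(man: pd.DataFrame, probes=None) -> list[str]:
    """All gene symbols annotated on the manifest (or a probe subset)."""
    rows = man if probes is None else man.loc[probes]
    genes: set[str] = set()
    for cell in rows["genes"]:
        if cell:
            genes.update(g for g in str(cell).split(";") if g)
    return sorted(genes)


# ---------------------------------------------------------------------------
# gene sets (GMT)

@dataclass
class GeneSetCollection:
    """Named gene sets over a gene universe (for set enrichment)."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def restricted(self, universe) -> "GeneSetCollection":
        """Intersect every set with a new universe, dropping emptied sets."""
        universe = frozenset(universe)
        sets = {name: genes & universe for name, genes in self.sets.items()}
        sets = {name: genes for name, genes in sets.items() if genes}
        return GeneSetCollection(sets, universe, dict(self.descriptions))


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT file: tab-separated ``name<TAB>description<TAB>gene...``.

    Each line needs a name, a description, and at least one gene.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(fields)} fields)")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, frozenset(universe), descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# JSON helpers (deterministic: sorted keys, fixed float repr)

def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
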