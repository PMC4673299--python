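"""Domain types, file formats and pipeline configuration.

The pipeline exchanges five plain-text formats:

* expression TSV — header row of sample ids, first column ``probe_id``,
  log2 intensities; optional detection-flag columns named
  ``<sample>.flag`` holding P/A/M calls,
* design TSV — ``sample_id``, ``patient_id``, ``condition`` columns,
* BED-like annotation TSV — ``chrom  start  end  probe_id  gene_id
  biotype  strand`` with 0-based half-open coordinates,
* GMT — one gene set per line: ``set_id  description  member...``,
* qPCR Ct TSV — ``patient_id  condition  gene_id  ct_rep1..ct_repK``.

All readers validate their invariants eagerly and raise
:class:`FormatError` naming the offending row or column.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lncoexp")

VALID_FLAGS = frozenset({"P", "A", "M"})
VALID_BIOTYPES = ("lncRNA", "mRNA")
#: canonical condition labels; C/N aliases follow tumor/normal column naming
CONDITION_ALIASES = {
    "tumor": "tumor", "t": "tumor", "c": "tumor", "cancer": "tumor",
    "normal": "normal", "n": "normal", "nt": "normal",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2 intensities with per-cell detection flags (probes x samples)."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray          # float, shape (n_probes, n_samples)
    flags: np.ndarray           # unicode P/A/M, same shape

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.values.shape, "P", dtype="<U1")
        self.flags = np.asarray(self.flags, dtype="<U1")
        n_p, n_s = len(self.probe_ids), len(self.sample_ids)
        if self.values.shape != (n_p, n_s):
            raise ValueError(
                f"values shape {self.values.shape} != ({n_p}, {n_s})")
        if self.flags.shape != self.values.shape:
            raise ValueError("flags shape differs from values shape")
        if len(set(self.probe_ids)) != n_p:
            raise ValueError("duplicate probe_ids")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample_ids")
        if n_p and n_s and not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        bad = set(self.flags.ravel()) - VALID_FLAGS
        if bad:
            raise ValueError(f"invalid detection flags: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids,
                            columns=self.sample_ids)

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [idx[p] for p in probe_ids]
        return ExpressionMatrix(list(probe_ids), list(self.sample_ids),
                                self.values[rows], self.flags[rows])

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def equal(self, other: "ExpressionMatrix", rtol: float = 1e-6) -> bool:
        return (self.probe_ids == other.probe_ids
                and self.sample_ids == other.sample_ids
                and np.allclose(self.values, other.values, rtol=rtol)
                and bool(np.array_equal(self.flags, other.flags)))


@dataclass(frozen=True)
class DesignEntry:
    sample_id: str
    patient_id: str
    condition: str  # "tumor" | "normal"


@dataclass
class StudyDesign:
    """Sample -> (patient, condition) assignment for a paired cohort."""

    entries: list[DesignEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in design")
        for e in self.entries:
            if e.condition not in ("tumor", "normal"):
                raise ValueError(f"invalid condition {e.condition!r}")

    def samples(self, condition: str) -> list[str]:
        return [e.sample_id for e in self.entries if e.condition == condition]

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.patient_id)
        return list(seen)

    def condition_of(self, sample_id: str) -> str:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e.condition
        raise KeyError(sample_id)

    def pairs(self) -> list[tuple[str, str, str]]:
        """(patient_id, tumor_sample, normal_sample) triples.

        Raises ``ValueError`` unless every patient has exactly one tumor
        and one normal sample — the contract of paired operations.
        """
        by_patient: dict[str, dict[str, list[str]]] = {}
        for e in self.entries:
            by_patient.setdefault(e.patient_id, {}).setdefault(
                e.condition, []).append(e.sample_id)
        out = []
        for pat in self.patients:
            conds = by_patient[pat]
            if len(conds.get("tumor", [])) != 1 or len(conds.get("normal", [])) != 1:
                raise ValueError(
                    f"patient {pat!r} lacks a unique tumor/normal pair")
            out.append((pat, conds["tumor"][0], conds["normal"][0]))
        return out


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic location and biotype of one probe (0-based half-open)."""

    probe_id: str
    gene_id: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.probe_id}: start {self.start} >= end {self.end}")
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"{self.probe_id}: invalid biotype {self.biotype!r}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.probe_id}: invalid strand {self.strand!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets (GO/KEGG-like terms or TF regulatory targets)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        uni = frozenset(universe)
        kept = {sid: m & uni for sid, m in self.sets.items() if m & uni}
        return GeneSetCollection(kept, {s: self.descriptions.get(s, "")
                                        for s in kept})


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with published defaults.

    ``fc_threshold``/``p_threshold`` gate differential-expression calls,
    ``r_threshold`` gates co-expression edges, ``trans_distance_bp`` splits
    cis from trans pairs, ``enrich_p_cutoff`` gates term enrichment and
    ``tf_p_cutoff``/``tf_fdr_cutoff`` gate TF-lncRNA associations.
    """

    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    r_threshold: float = 0.99
    trans_distance_bp: int = 100_000
    enrich_p_cutoff: float = 0.05
    tf_p_cutoff: float = 0.01
    tf_fdr_cutoff: float = 0.01
    top_n_for_enrichment: int = 500
    t_test_mode: str = "pooled_unpaired"   # pooled_unpaired | welch | paired
    flag_min_fraction: float = 1.0
    correlation_signed: bool = False
    filter_before_normalize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "p_threshold", "r_threshold",
                     "trans_distance_bp", "enrich_p_cutoff", "tf_p_cutoff",
                     "tf_fdr_cutoff", "top_n_for_enrichment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.flag_min_fraction <= 1.0:
            raise ValueError("flag_min_fraction must lie in [0, 1]")
        if self.t_test_mode not in ("pooled_unpaired", "welch", "paired"):
            raise ValueError(f"unknown t_test_mode {self.t_test_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV into an :class:`ExpressionMatrix`.

    Columns suffixed ``.flag`` carry detection calls for the matching
    sample column; samples without a flag column default to all-present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "probe_id":
        raise FormatError(f"{path}: first column must be 'probe_id', "
                          f"got {df.columns[0]!r}")
    probe_ids = df["probe_id"].tolist()
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate probe_id {dup.iloc[0]!r}")
    sample_cols = [c for c in df.columns[1:] if not c.endswith(".flag")]
    flag_cols = {c[:-5]: c for c in df.columns[1:] if c.endswith(".flag")}
    unknown_flags = set(flag_cols) - set(sample_cols)
    if unknown_flags:
        raise FormatError(f"{path}: flag columns without sample columns: "
                          f"{sorted(unknown_flags)}")
    values = np.empty((len(probe_ids), len(sample_cols)))
    for j, col in enumerate(sample_cols):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = probe_ids[bad.index[0]] if not bad.empty else "?"
            raise FormatError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}")
    flags = np.full(values.shape, "P", dtype="<U1")
    for sample, col in flag_cols.items():
        j = sample_cols.index(sample)
        flags[:, j] = df[col].astype(str).str.strip().to_numpy()
    try:
        return ExpressionMatrix(probe_ids, sample_cols, values, flags)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_table(matrix: ExpressionMatrix, path: str | Path,
                           write_flags: bool = True) -> None:
    """Write a matrix so that :func:`read_expression_table` round-trips it."""
    df = pd.DataFrame({"probe_id": matrix.probe_ids})
    for j, sample in enumerate(matrix.sample_ids):
        df[sample] = matrix.values[:, j]
    if write_flags:
        for j, sample in enumerate(matrix.sample_ids):
            df[f"{sample}.flag"] = matrix.flags[:, j]
    # %.10g keeps >= 6 significant digits for lossless round trips
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_design(path: str | Path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing design columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        raw = str(row["condition"]).strip().lower()
        if raw not in CONDITION_ALIASES:
            raise FormatError(
                f"{path}: unknown condition {row['condition']!r} for sample "
                f"{row['sample_id']!r}")
        entries.append(DesignEntry(str(row["sample_id"]).strip(),
                                   str(row["patient_id"]).strip(),
                                   CONDITION_ALIASES[raw]))
    try:
        return StudyDesign(entries)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_design(design: StudyDesign, path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(e) for e in design.entries],
                 columns=["sample_id", "patient_id", "condition"]
                 ).to_csv(path, sep="\t", index=False)


def read_annotation_bed(path: str | Path) -> list[ProbeAnnotation]:
    """Read BED-like annotation: chrom start end probe_id gene_id biotype strand."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 fields, "
                                  f"got {len(parts)}")
            chrom, start, end, probe_id, gene_id, biotype = parts[:6]
            strand = parts[6] if len(parts) > 6 else "."
            try:
                rec = ProbeAnnotation(probe_id, gene_id, biotype, chrom,
                                      int(start), int(end), strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_annotation_bed(annotation: Sequence[ProbeAnnotation],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annotation:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.probe_id}\t"
                     f"{a.gene_id}\t{a.biotype}\t{a.strand}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file; duplicate members within a set are deduplicated."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields")
            sid, desc = parts[0], parts[1]
            if sid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: set {sid!r} is empty")
            sets[sid] = members
            descriptions[sid] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in collection.sets:
            members = "\t".join(sorted(collection.sets[sid]))
            fh.write(f"{sid}\t{collection.descriptions.get(sid, '')}\t{members}\n")


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table with columns patient_id, condition, gene_id, ct_rep*."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str,
                                            "condition": str, "gene_id": str})
    required = {"patient_id", "condition", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing qPCR columns {sorted(missing)}")
    rep_cols = [c for c in df.columns if c.startswith("ct_rep")]
    if not rep_cols:
        raise FormatError(f"{path}: no ct_rep* replicate columns")
    cond = df["condition"].str.strip().str.lower()
    unknown = set(cond) - set(CONDITION_ALIASES)
    if unknown:
        raise FormatError(f"{path}: unknown conditions {sorted(unknown)}")
    df = df.copy()
    df["condition"] = cond.map(CONDITION_ALIASES)
    return df


def write_qpcr_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
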