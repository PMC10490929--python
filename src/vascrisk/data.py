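"""Domain types and readers/writers for the drug-response database.

The in-memory model mirrors the experimental design of a two-cell-type
(endothelial / smooth-muscle) vascular co-culture screen: every compound is
profiled at one or more concentrations, and each treatment yields one
differential-expression contrast per cell type (treatment vs the atheroprone
vehicle control).  A :class:`Database` bundles the compound metadata, those
contrast tables, and the atheroprone-vs-atheroprotective baseline contrasts.

File formats are deliberately boring: tab-separated UTF-8 tables with a
mandatory header ("." or empty = missing) and standard GMT for pathway gene
sets.  Gene identifiers are opaque strings matched case-sensitively after
whitespace trimming; no identifier translation is attempted.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CellType",
    "CompoundRecord",
    "ContrastResult",
    "Pathway",
    "PathwayCollection",
    "Database",
    "DataError",
    "ParseError",
    "SchemaError",
    "ValidationError",
    "IntegrityError",
    "read_gmt",
    "write_gmt",
    "read_contrast_table",
    "write_contrast_table",
    "read_metadata",
    "write_metadata",
    "load_database",
    "write_database",
    "treatment_id",
    "split_treatment_id",
]


class DataError(Exception):
    """Base class for data-layer failures."""


class ParseError(DataError):
    """A file could not be parsed (malformed line / unparseable field)."""


class SchemaError(DataError):
    """A table is missing required columns."""


class ValidationError(DataError):
    """Values are out of their documented range or violate an invariant."""


class IntegrityError(DataError):
    """Cross-references between records do not resolve."""


class CellType(str, Enum):
    """The two co-cultured vascular cell types profiled separately."""

    EC = "EC"
    SMC = "SMC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_cell_type(value: "CellType | str") -> CellType:
    if isinstance(value, CellType):
        return value
    try:
        return CellType(str(value))
    except ValueError as exc:
        raise ValidationError(f"unknown cell type {value!r}; expected EC or SMC") from exc


SIDE_EFFECT_LABELS = ("positive", "negative", "unknown")

_CONC_FMT = "{:.6g}"


def treatment_id(compound_id: str, concentration: float) -> str:
    """Canonical treatment identifier: ``<compound_id>@<molar concentration>``."""
    return f"{compound_id}@{_CONC_FMT.format(concentration)}"


def split_treatment_id(tid: str) -> tuple[str, float]:
    """Invert :func:`treatment_id`."""
    compound_id, _, conc = tid.rpartition("@")
    if not compound_id:
        raise ValidationError(f"malformed treatment id {tid!r} (expected '<compound>@<conc>')")
    try:
        return compound_id, float(conc)
    except ValueError as exc:
        raise ValidationError(f"malformed concentration in treatment id {tid!r}") from exc


@dataclass(frozen=True)
class CompoundRecord:
    """One reference or query compound.

    ``cv_risk`` carries the FDA boxed-warning flag for cardiovascular risk;
    ``side_effects`` maps side-effect names to ``positive``/``negative``/
    ``unknown`` clinical labels.  Concentrations are molar.
    """

    compound_id: str
    name: str
    drug_class: str
    clinical_stage: bool
    cv_risk: bool
    side_effects: Mapping[str, str] = field(default_factory=dict)
    concentrations: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if not self.concentrations:
            raise ValidationError(f"{self.compound_id}: concentrations must be non-empty")
        if any(c <= 0 or not math.isfinite(c) for c in self.concentrations):
            raise ValidationError(f"{self.compound_id}: concentrations must be finite and > 0")
        for se, label in self.side_effects.items():
            if label not in SIDE_EFFECT_LABELS:
                raise ValidationError(
                    f"{self.compound_id}: side effect {se!r} has label {label!r}; "
                    f"expected one of {SIDE_EFFECT_LABELS}"
                )

    @property
    def designated_concentration(self) -> float:
        """The concentration used downstream (highest tested)."""
        return max(self.concentrations)

    @property
    def designated_treatment(self) -> str:
        return treatment_id(self.compound_id, self.designated_concentration)


CONTRAST_COLUMNS = ("gene_id", "log_fc", "p_value", "fdr", "mean_expr")


@dataclass
class ContrastResult:
    """Per-gene differential-expression summary for one treatment vs control.

    ``data`` holds one row per gene with columns ``gene_id`` (unique string),
    ``log_fc`` (log2 fold change), ``p_value``/``fdr`` in [0, 1], and
    ``mean_expr`` (CPM-scale mean expression, >= 0).
    """

    treatment_id: str
    cell_type: CellType
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.cell_type = _as_cell_type(self.cell_type)
        missing = [c for c in CONTRAST_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"contrast table missing column(s): {', '.join(missing)}")
        df = self.data.loc[:, list(CONTRAST_COLUMNS)].reset_index(drop=True).copy()
        df["gene_id"] = df["gene_id"].astype(str).str.strip()
        for col in ("log_fc", "p_value", "fdr", "mean_expr"):
            values = pd.to_numeric(df[col], errors="coerce")
            if values.isna().any():
                bad = df.loc[values.isna(), "gene_id"].iloc[0]
                raise ValidationError(f"non-numeric {col} for gene {bad!r}")
            df[col] = values.astype(float)
        for col in ("p_value", "fdr"):
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise ValidationError(f"{col} outside [0, 1] in contrast {self.treatment_id}")
        if (df["mean_expr"] < 0).any():
            raise ValidationError(f"negative mean_expr in contrast {self.treatment_id}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise IntegrityError(f"duplicate gene_id {dup!r} in contrast {self.treatment_id}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.data["gene_id"])

    def indexed(self) -> pd.DataFrame:
        """The table indexed by gene_id (cached)."""
        cached = getattr(self, "_indexed", None)
        if cached is None:
            cached = self.data.set_index("gene_id")
            object.__setattr__(self, "_indexed", cached)
        return cached


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"pathway {self.pathway_id!r} has an empty gene set")


class PathwayCollection:
    """Named gene sets (e.g. Reactome pathways) parsed from a GMT file."""

    def __init__(self, pathways: Iterable[Pathway]):
        self._pathways: dict[str, Pathway] = {}
        for pw in pathways:
            if pw.pathway_id in self._pathways:
                raise IntegrityError(f"duplicate pathway id {pw.pathway_id!r}")
            self._pathways[pw.pathway_id] = pw

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self._pathways.values())

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._pathways

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._pathways[pathway_id]

    @property
    def ids(self) -> list[str]:
        return list(self._pathways)

    def sorted_ids(self) -> list[str]:
        return sorted(self._pathways)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCollection):
            return NotImplemented
        return self._pathways == other._pathways


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT file: one pathway per line, ``id<TAB>description<TAB>gene...``.

    Duplicate genes within a line collapse silently; a duplicate pathway id is
    an :class:`IntegrityError`; a line with fewer than three fields is a
    :class:`ParseError` naming the line number.
    """
    path = Path(path)
    pathways: list[Pathway] = []
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} field(s); need >= 3")
            pw_id, description, *genes = fields
            gene_set = frozenset(g.strip() for g in genes if g.strip())
            if not gene_set:
                raise ParseError(f"{path}:{lineno}: pathway {pw_id!r} lists no genes")
            pathways.append(Pathway(pw_id.strip(), description.strip(), gene_set))
    return PathwayCollection(pathways)


def write_gmt(pathways: PathwayCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for pw in pathways:
            genes = "\t".join(sorted(pw.genes))
            handle.write(f"{pw.pathway_id}\t{pw.description}\t{genes}\n")


def read_contrast_table(
    path: str | Path,
    cell_type: CellType | str,
    treatment: str | None = None,
) -> ContrastResult:
    """Read one DE contrast TSV.  ``treatment`` defaults to the file stem."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["."], keep_default_na=True)
    missing = [c for c in CONTRAST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    if df[list(CONTRAST_COLUMNS[1:])].isna().any().any():
        raise ValidationError(f"{path}: missing/non-numeric statistics are not allowed")
    if treatment is None:
        treatment = path.stem.split("__")[0]
    return ContrastResult(treatment_id=treatment, cell_type=_as_cell_type(cell_type), data=df)


def write_contrast_table(contrast: ContrastResult, path: str | Path) -> None:
    # default pandas float formatting = shortest repr → exact round trip
    contrast.data.to_csv(path, sep="\t", index=False)


CONTROL_STEM = "control"  # reserved stem for the atheroprone-vs-atheroprotective baseline


@dataclass
class Database:
    """A drug-response database: compounds plus their DE contrasts.

    ``contrasts`` is keyed by ``(treatment_id, cell_type.value)``;
    ``control_contrasts`` (keyed by cell type value) hold the disease-model
    baseline (atheroprone vehicle vs atheroprotective control) per cell type.
    """

    compounds: list[CompoundRecord]
    contrasts: dict[tuple[str, str], ContrastResult] = field(default_factory=dict)
    control_contrasts: dict[str, ContrastResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.compound_id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise IntegrityError(f"duplicate compound_id {dup!r}")
        self.compounds = sorted(self.compounds, key=lambda c: c.compound_id)
        self._by_id = {c.compound_id: c for c in self.compounds}
        for (tid, ct), contrast in self.contrasts.items():
            compound_id, conc = split_treatment_id(tid)
            compound = self._by_id.get(compound_id)
            if compound is None:
                raise IntegrityError(f"contrast {tid!r} references unknown compound {compound_id!r}")
            if not any(math.isclose(conc, c, rel_tol=1e-4) for c in compound.concentrations):
                raise IntegrityError(
                    f"contrast {tid!r} references concentration {conc:g} not tested for "
                    f"{compound_id!r} (tested: {list(compound.concentrations)})"
                )
            _as_cell_type(ct)
            if contrast.treatment_id != tid:
                raise IntegrityError(f"contrast key {tid!r} != contrast.treatment_id {contrast.treatment_id!r}")

    # ---- summary counts -------------------------------------------------
    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_clinical(self) -> int:
        return sum(c.clinical_stage for c in self.compounds)

    @property
    def n_risk(self) -> int:
        return sum(c.cv_risk for c in self.compounds)

    def compound(self, compound_id: str) -> CompoundRecord:
        return self._by_id[compound_id]

    def risk_labels(self) -> dict[str, bool]:
        return {c.compound_id: c.cv_risk for c in self.compounds}

    def side_effect_names(self) -> list[str]:
        names: set[str] = set()
        for c in self.compounds:
            names.update(c.side_effects)
        return sorted(names)

    def references(self, cell_type: CellType | str) -> dict[str, ContrastResult]:
        """One designated contrast per compound (highest concentration) for a cell type.

        Compounds without a contrast for this cell type are omitted.
        """
        ct = _as_cell_type(cell_type).value
        out: dict[str, ContrastResult] = {}
        for compound in self.compounds:
            key = (compound.designated_treatment, ct)
            if key in self.contrasts:
                out[compound.compound_id] = self.contrasts[key]
        return out

    def missing_cell_types(self) -> list[tuple[str, str]]:
        """(treatment_id, cell_type) pairs absent for otherwise-present treatments."""
        tids = {tid for tid, _ in self.contrasts}
        missing = []
        for tid in sorted(tids):
            for ct in CellType:
                if (tid, ct.value) not in self.contrasts:
                    missing.append((tid, ct.value))
        return missing


# ---------------------------------------------------------------------------
# metadata TSV
# ---------------------------------------------------------------------------

_BOOL_TRUE = {"1", "true", "yes"}
_BOOL_FALSE = {"0", "false", "no"}
_SE_PREFIX = "se:"
META_COLUMNS = ("compound_id", "name", "drug_class", "clinical_stage", "cv_risk", "concentrations")


def _parse_bool(value: str, context: str) -> bool:
    v = str(value).strip().lower()
    if v in _BOOL_TRUE:
        return True
    if v in _BOOL_FALSE:
        return False
    raise ParseError(f"{context}: cannot parse boolean {value!r}")


def read_metadata(path: str | Path) -> list[CompoundRecord]:
    """Read compound metadata TSV.

    Required columns: compound_id, name, drug_class, clinical_stage, cv_risk,
    concentrations (semicolon-separated molar values).  Any column named
    ``se:<name>`` is a side-effect label column (positive/negative/unknown;
    "." or empty = unknown).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) <= 1:
        return []
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    se_cols = [c for c in df.columns if c.startswith(_SE_PREFIX)]
    records: list[CompoundRecord] = []
    for _, row in df.iterrows():
        cid = row["compound_id"].strip()
        concs = tuple(float(x) for x in re.split(r"[;,]", row["concentrations"]) if x.strip())
        side_effects = {}
        for col in se_cols:
            raw = row[col].strip()
            side_effects[col[len(_SE_PREFIX):]] = raw if raw and raw != "." else "unknown"
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=row["name"].strip(),
                drug_class=row["drug_class"].strip(),
                clinical_stage=_parse_bool(row["clinical_stage"], f"{path}:{cid}"),
                cv_risk=_parse_bool(row["cv_risk"], f"{path}:{cid}"),
                side_effects=side_effects,
                concentrations=concs,
            )
        )
    return records


def write_metadata(compounds: Iterable[CompoundRecord], path: str | Path) -> None:
    compounds = list(compounds)
    se_names = sorted({se for c in compounds for se in c.side_effects})
    rows = []
    for c in compounds:
        row = {
            "compound_id": c.compound_id,
            "name": c.name,
            "drug_class": c.drug_class,
            "clinical_stage": int(c.clinical_stage),
            "cv_risk": int(c.cv_risk),
            "concentrations": ";".join(_CONC_FMT.format(x) for x in c.concentrations),
        }
        for se in se_names:
            row[_SE_PREFIX + se] = c.side_effects.get(se, "unknown")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# database directory layout
# ---------------------------------------------------------------------------

def load_database(metadata_path: str | Path, contrasts_dir: str | Path) -> Database:
    """Assemble a :class:`Database` from a metadata TSV and a contrast directory.

    Contrast files are named ``<treatment_id>__<EC|SMC>.tsv``; the reserved
    stem ``control`` holds the atheroprone-vs-atheroprotective baseline.
    Loading is discovery-order independent (files are sorted).
    """
    compounds = read_metadata(metadata_path)
    contrasts: dict[tuple[str, str], ContrastResult] = {}
    controls: dict[str, ContrastResult] = {}
    contrasts_dir = Path(contrasts_dir)
    for path in sorted(contrasts_dir.glob("*.tsv")):
        stem, sep, ct_part = path.stem.rpartition("__")
        if not sep:
            raise ParseError(f"{path}: contrast filename must be '<treatment>__<cell_type>.tsv'")
        ct = _as_cell_type(ct_part)
        contrast = read_contrast_table(path, ct, treatment=stem)
        if stem == CONTROL_STEM:
            controls[ct.value] = contrast
        else:
            contrasts[(stem, ct.value)] = contrast
    db = Database(compounds=compounds, contrasts=contrasts, control_contrasts=controls)
    log.info(
        "loaded database: %d compounds (%d clinical-stage, %d cardiovascular-risk), %d contrasts",
        db.n_compounds, db.n_clinical, db.n_risk, len(db.contrasts),
    )
    return db


def write_database(db: Database, directory: str | Path) -> Path:
    """Write a database as ``metadata.tsv`` + ``contrasts/*.tsv`` under ``directory``."""
    directory = Path(directory)
    (directory / "contrasts").mkdir(parents=True, exist_ok=True)
    write_metadata(db.compounds, directory / "metadata.tsv")
    for (tid, ct), contrast in sorted(db.contrasts.items()):
        write_contrast_table(contrast, directory / "contrasts" / f"{tid}__{ct}.tsv")
    for ct, contrast in sorted(db.control_contrasts.items()):
        write_contrast_table(contrast, directory / "contrasts" / f"{CONTROL_STEM}__{ct}.tsv")
    return directory
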