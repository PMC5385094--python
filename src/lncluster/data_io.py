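"""Tabular I/O: expression matrices, clinical tables and GMT gene sets.

Canonical on-disk dialect is TSV (UTF-8, '.' decimal separator), the form
in which TCGA-style expression exports usually circulate.  Missing values
are encoded as an empty string or ``NA``.  Gene identifiers are opaque
strings; no identifier translation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

GENE_CLASSES = ("lncRNA", "PCG")
SAMPLE_ROLES = ("tumor", "normal")

_NA_TOKENS = ("", "NA")


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative RPKM-like expression values.

    Attributes
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns; entries
        are finite and >= 0.
    gene_class
        Per-gene tag, ``"lncRNA"`` or ``"PCG"``, aligned with the rows.
    sample_role
        Per-sample tag, ``"tumor"`` or ``"normal"``, aligned with columns.
    """

    values: pd.DataFrame
    gene_class: pd.Series
    sample_role: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value for gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        if arr.size and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative value for gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        if not self.gene_class.index.equals(idx):
            raise InputError("gene_class index does not match matrix rows")
        if not self.sample_role.index.equals(cols):
            raise InputError("sample_role index does not match matrix columns")
        bad_class = set(self.gene_class.unique()) - set(GENE_CLASSES)
        if bad_class:
            raise InputError(f"unknown gene class tags: {sorted(bad_class)}")
        bad_role = set(self.sample_role.unique()) - set(SAMPLE_ROLES)
        if bad_role:
            raise InputError(f"unknown sample role tags: {sorted(bad_role)}")

    # -- accessors --------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def log2(self) -> pd.DataFrame:
        """log2(RPKM + 1) transform, the working scale of all correlations."""
        return np.log2(self.values + 1.0)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = pd.Index(gene_ids)
        missing = gene_ids.difference(self.values.index)
        if len(missing):
            raise InputError(f"unknown gene ids: {list(missing[:5])}")
        return ExpressionMatrix(
            self.values.loc[gene_ids],
            self.gene_class.loc[gene_ids],
            self.sample_role,
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = pd.Index(sample_ids)
        missing = sample_ids.difference(self.values.columns)
        if len(missing):
            raise InputError(f"unknown sample ids: {list(missing[:5])}")
        return ExpressionMatrix(
            self.values[sample_ids],
            self.gene_class,
            self.sample_role.loc[sample_ids],
        )

    def select_class(self, gene_class: str) -> "ExpressionMatrix":
        keep = self.gene_class[self.gene_class == gene_class].index
        return self.subset_genes(keep)

    def select_role(self, role: str) -> "ExpressionMatrix":
        keep = self.sample_role[self.sample_role == role].index
        return self.subset_samples(keep)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample covariates plus survival endpoints.

    ``schema`` maps each column to one of ``categorical``, ``continuous``,
    ``time`` or ``event``.  A survival endpoint named ``X`` is stored as
    paired columns ``X_time`` / ``X_event``.
    """

    data: pd.DataFrame
    schema: dict[str, str]
    n_unparseable: int = 0

    _KINDS = ("categorical", "continuous", "time", "event")

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        unknown = set(self.schema.values()) - set(self._KINDS)
        if unknown:
            raise InputError(f"unknown schema kinds: {sorted(unknown)}")
        for col, kind in self.schema.items():
            if col not in self.data.columns:
                raise InputError(f"schema column {col!r} absent from table")
            if kind == "time":
                vals = self.data[col].dropna()
                if (vals < 0).any():
                    raise FormatError(f"negative time in column {col!r}")
            elif kind == "event":
                vals = self.data[col].dropna()
                if not vals.isin((0, 1)).all():
                    raise InputError(f"non-binary event in column {col!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def categorical(self, name: str) -> pd.Series:
        if self.schema.get(name) != "categorical":
            raise InputError(f"{name!r} is not a categorical column")
        return self.data[name]

    def continuous(self, name: str) -> pd.Series:
        if self.schema.get(name) != "continuous":
            raise InputError(f"{name!r} is not a continuous column")
        return self.data[name]

    def endpoints(self) -> list[str]:
        """Endpoint names having both a time and an event column."""
        names = []
        for col, kind in self.schema.items():
            if kind == "time" and col.endswith("_time"):
                stem = col[: -len("_time")]
                if self.schema.get(f"{stem}_event") == "event":
                    names.append(stem)
        return names

    def survival(self, endpoint: str) -> tuple[pd.Series, pd.Series]:
        """(time, event) for one endpoint, rows with either missing dropped."""
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        if self.schema.get(tcol) != "time" or self.schema.get(ecol) != "event":
            raise InputError(f"no survival endpoint {endpoint!r}")
        sub = self.data[[tcol, ecol]].dropna()
        return sub[tcol].astype(float), sub[ecol].astype(int)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str,
            keep_default_na=False, encoding="utf-8",
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged or malformed TSV ({exc})", path=str(path)) from exc
    return df


def read_expression(path, gene_class_column: str = "gene_class",
                    sample_role_map=None, default_role: str = "tumor",
                    default_class: str = "lncRNA") -> ExpressionMatrix:
    """Read a gene x sample expression TSV.

    First column holds gene ids; an optional ``gene_class_column`` tags each
    gene as lncRNA or PCG; remaining columns are samples.  ``sample_role_map``
    maps sample id to ``tumor``/``normal`` (default: every sample is
    ``default_role``).
    """
    df = _read_tsv(path)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r}", path=str(path))
    if gene_class_column in df.columns:
        gene_class = df[gene_class_column].copy()
        df = df.drop(columns=[gene_class_column])
    else:
        gene_class = pd.Series(default_class, index=df.index)
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        blank = raw.isin(_NA_TOKENS)
        if blank.any():
            gene = raw.index[blank][0]
            raise FormatError(
                "missing expression value", path=str(path),
                line=str(gene), field=col,
            )
        parsed = pd.to_numeric(raw, errors="coerce")
        if parsed.isna().any():
            gene = raw.index[parsed.isna()][0]
            raise FormatError(
                f"unparseable value {raw[gene]!r}", path=str(path),
                line=str(gene), field=col,
            )
        values[col] = parsed
    roles = pd.Series(default_role, index=values.columns)
    if sample_role_map is not None:
        for sid, role in sample_role_map.items():
            if sid in roles.index:
                roles[sid] = role
    return ExpressionMatrix(values, gene_class, roles)


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    out.insert(0, "gene_class", expr.gene_class)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g", encoding="utf-8")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format: name, description, members...

    Duplicate members within a line are stored once, order preserved;
    duplicate set names across lines are a format error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"expected >=3 tab-separated fields, got {len(parts)}",
                    path=str(path), line=lineno,
                )
            name, desc = parts[0], parts[1]
            if name in sets:
                raise FormatError(
                    f"duplicate gene set name {name!r}",
                    path=str(path), line=lineno,
                )
            members = list(dict.fromkeys(m for m in parts[2:] if m))
            if not members:
                raise FormatError(
                    f"gene set {name!r} has no members",
                    path=str(path), line=lineno,
                )
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_clinical(path, schema: dict[str, str]) -> ClinicalTable:
    """Read a per-sample clinical TSV with a declared column schema.

    Unparseable cells become missing (counted and logged) rather than
    failing the whole file; negative times are a hard format error, as is a
    missing sample-id column.
    """
    df = _read_tsv(path)
    if df.index.name is None or df.index.isin(_NA_TOKENS).any():
        raise FormatError("missing sample id", path=str(path))
    n_unparseable = 0
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.items():
        if col not in df.columns:
            raise FormatError(f"schema column {col!r} absent", path=str(path))
        raw = df[col]
        blank = raw.isin(_NA_TOKENS)
        if kind == "categorical":
            out[col] = raw.where(~blank, other=pd.NA)
        elif kind in ("continuous", "time"):
            parsed = pd.to_numeric(raw.where(~blank, other=pd.NA), errors="coerce")
            bad = parsed.isna() & ~blank
            n_unparseable += int(bad.sum())
            if kind == "time" and (parsed.dropna() < 0).any():
                sid = parsed.index[parsed < 0][0]
                raise FormatError(
                    "negative time", path=str(path), line=str(sid), field=col,
                )
            out[col] = parsed
        elif kind == "event":
            parsed = pd.to_numeric(raw.where(~blank, other=pd.NA), errors="coerce")
            bad = (parsed.isna() & ~blank) | ~parsed.isin((0, 1)) & parsed.notna()
            n_unparseable += int(bad.sum())
            out[col] = parsed.where(~bad, other=pd.NA)
        else:
            raise InputError(f"unknown schema kind {kind!r} for {col!r}")
    if n_unparseable:
        logger.warning("read_clinical: %d unparseable cells set to missing",
                       n_unparseable)
    return ClinicalTable(out, dict(schema), n_unparseable=n_unparseable)


def write_clinical(table: ClinicalTable, path) -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA",
               encoding="utf-8")
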