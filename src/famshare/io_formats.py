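"""Readers and writers for the classic microbiome file formats.

Four formats are supported, all plain text:

* classic tab-separated OTU tables (header line starting ``#OTU ID``,
  optional trailing ``taxonomy`` / ``Consensus Lineage`` column),
* BIOM-JSON tables (format version 1.0, dense or sparse),
* newick trees with branch lengths,
* tab-separated per-sample mapping files keyed by ``#SampleID``, and the
  labeled square distance-matrix format.

Everything read is validated against the type invariants (non-negative
integer counts, unique ids, symmetric hollow distance matrices, role/age
consistency) so downstream modules can assume clean inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "FormatError",
    "BODY_SITES",
    "HUMAN_SITES",
    "DOG_SITES",
    "ROLES",
    "read_otu_table",
    "write_otu_table",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "family_rank",
]

HUMAN_SITES = ("fecal", "oral", "forehead", "palm_L", "palm_R")
DOG_SITES = ("fecal", "oral", "forehead", "paw_BL", "paw_BR", "paw_FL", "paw_FR")
BODY_SITES = ("fecal", "oral", "forehead", "palm_L", "palm_R",
              "paw_BL", "paw_BR", "paw_FL", "paw_FR")
ROLES = ("adult_M", "adult_F", "child", "infant", "senior", "dog")

#: age bins (years) each role must fall in: infant 0-1, child 1-17,
#: adult 18-59, senior >= 60.  Dogs are unconstrained.
ROLE_AGE_BINS = {
    "infant": (0.0, 1.0),
    "child": (1.0, 18.0),
    "adult_M": (18.0, 60.0),
    "adult_F": (18.0, 60.0),
    "senior": (60.0, float("inf")),
}

METADATA_COLUMNS = ("host_id", "family_id", "body_site", "species", "role",
                    "age", "has_dog", "has_cat", "family_size")


class FormatError(ValueError):
    """Raised when a file violates its declared dialect or a type invariant."""


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Samples x phylotypes count matrix (stored OTUs x samples).

    Parameters
    ----------
    otu_ids, sample_ids
        Unique ordered labels.  Order is preserved as read; it never
        encodes meaning.
    counts
        Non-negative integer matrix of shape ``(n_otus, n_samples)``.
    taxonomy
        Optional greengenes-style 7-rank lineage string per OTU
        (``k__...; p__...; ...; s__...``).
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.otu_ids = list(map(str, self.otu_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {counts.shape} != ({len(self.otu_ids)}, {len(self.sample_ids)})")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise FormatError("counts must be integers")
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            raise FormatError("counts must be >= 0")
        self.counts = counts
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.taxonomy is not None:
            self.taxonomy = list(map(str, self.taxonomy))
            if len(self.taxonomy) != len(self.otu_ids):
                raise FormatError("taxonomy length != number of OTUs")

    # -- basic queries ------------------------------------------------------

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def depths(self) -> np.ndarray:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)

    def presence(self) -> np.ndarray:
        """Boolean (n_otus, n_samples) presence matrix (count >= 1)."""
        return self.counts >= 1

    def relative_abundance(self) -> np.ndarray:
        """Column-normalized proportions; empty samples give zero columns."""
        depths = self.depths().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(depths > 0, self.counts / depths, 0.0)
        return rel

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return OtuTable(list(self.otu_ids), [self.sample_ids[i] for i in idx],
                        self.counts[:, idx], None if self.taxonomy is None
                        else list(self.taxonomy))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (self.otu_ids == other.otu_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.counts, other.counts)
                and self.taxonomy == other.taxonomy)


def family_rank(lineage: str) -> Optional[str]:
    """Extract the family-rank name from a greengenes-style lineage string.

    ``"k__Bacteria; ...; f__Streptococcaceae; g__..."`` -> ``"Streptococcaceae"``.
    Returns ``None`` when the family rank is absent or empty.
    """
    for token in lineage.split(";"):
        token = token.strip()
        if token.startswith("f__"):
            name = token[3:].strip()
            return name or None
    return None


_TAXONOMY_HEADERS = {"taxonomy", "consensus lineage"}


def _read_classic_tsv(path: Path) -> OtuTable:
    with open(path) as fh:
        lines = fh.read().splitlines()
    # optional bare comment line(s) before the header
    i = 0
    while i < len(lines) and not lines[i].startswith("#OTU ID"):
        if not lines[i].startswith("#"):
            raise FormatError(f"{path}: line {i + 1}: expected '#OTU ID' header")
        i += 1
    if i == len(lines):
        raise FormatError(f"{path}: missing '#OTU ID' header line")
    header = lines[i].split("\t")
    has_tax = len(header) > 1 and header[-1].strip().lower() in _TAXONOMY_HEADERS
    sample_ids = header[1:-1] if has_tax else header[1:]
    otu_ids: list[str] = []
    taxonomy: list[str] = []
    rows: list[list[int]] = []
    for ln, line in enumerate(lines[i + 1:], start=i + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        expected = 1 + len(sample_ids) + (1 if has_tax else 0)
        if len(fields) != expected:
            raise FormatError(f"{path}: line {ln}: expected {expected} fields, got {len(fields)}")
        otu_ids.append(fields[0])
        vals = fields[1:1 + len(sample_ids)]
        row = []
        for j, v in enumerate(vals):
            try:
                x = float(v)
            except ValueError:
                raise FormatError(f"{path}: line {ln}, field {j + 2}: non-numeric count {v!r}")
            if x != int(x):
                raise FormatError(f"{path}: line {ln}, field {j + 2}: non-integer count {v!r}")
            if x < 0:
                raise FormatError(f"{path}: line {ln}, field {j + 2}: negative count {v!r}")
            row.append(int(x))
        rows.append(row)
        if has_tax:
            taxonomy.append(fields[-1])
    counts = np.array(rows, dtype=np.int64).reshape(len(otu_ids), len(sample_ids))
    return OtuTable(otu_ids, list(sample_ids), counts, taxonomy if has_tax else None)


def _read_biom_json(path: Path) -> OtuTable:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in doc:
            raise FormatError(f"{path}: BIOM document missing field {key!r}")
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_r, n_c = doc["shape"]
    if (n_r, n_c) != (len(otu_ids), len(sample_ids)):
        raise FormatError(f"{path}: shape field disagrees with rows/columns")
    counts = np.zeros((n_r, n_c), dtype=np.int64)
    if doc["matrix_type"] == "dense":
        arr = np.asarray(doc["data"])
        if arr.shape != (n_r, n_c):
            raise FormatError(f"{path}: dense data shape mismatch")
        if arr.size and not np.all(np.equal(np.mod(arr, 1), 0)):
            raise FormatError(f"{path}: non-integer count in data")
        counts = arr.astype(np.int64)
    elif doc["matrix_type"] == "sparse":
        for triple in doc["data"]:
            r, c, v = triple
            if v != int(v):
                raise FormatError(f"{path}: non-integer count {v!r}")
            counts[int(r), int(c)] = int(v)
    else:
        raise FormatError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    taxonomy = None
    if all(r.get("metadata") and "taxonomy" in r["metadata"] for r in doc["rows"]):
        taxonomy = []
        for r in doc["rows"]:
            tax = r["metadata"]["taxonomy"]
            taxonomy.append("; ".join(tax) if isinstance(tax, list) else str(tax))
    return OtuTable(otu_ids, sample_ids, counts, taxonomy)


def read_otu_table(path, format: str = "classic_tsv") -> OtuTable:
    """Read an OTU table in the classic TSV or BIOM-JSON (1.0) dialect."""
    path = Path(path)
    if format == "classic_tsv":
        return _read_classic_tsv(path)
    if format == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def write_otu_table(table: OtuTable, path, format: str = "classic_tsv") -> None:
    """Write ``table`` so that reading it back reproduces it exactly."""
    path = Path(path)
    if format == "classic_tsv":
        with open(path, "w") as fh:
            fh.write("# Constructed from OTU table\n")
            header = ["#OTU ID"] + table.sample_ids
            if table.taxonomy is not None:
                header.append("taxonomy")
            fh.write("\t".join(header) + "\n")
            for i, otu in enumerate(table.otu_ids):
                fields = [otu] + [str(int(v)) for v in table.counts[i]]
                if table.taxonomy is not None:
                    fields.append(table.taxonomy[i])
                fh.write("\t".join(fields) + "\n")
    elif format == "biom_json":
        rows = []
        for i, otu in enumerate(table.otu_ids):
            md = None
            if table.taxonomy is not None:
                md = {"taxonomy": [t.strip() for t in table.taxonomy[i].split(";")]}
            rows.append({"id": otu, "metadata": md})
        nz = np.nonzero(table.counts)
        data = [[int(r), int(c), int(table.counts[r, c])] for r, c in zip(*nz)]
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "famshare",
            "date": "1970-01-01T00:00:00",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [table.n_otus, table.n_samples],
            "rows": rows,
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths default to 0.

    Raises :class:`FormatError` on unparseable newick or duplicate tip
    names; warns when branch lengths are missing.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"{path}: newick parse error: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise FormatError(f"{path}: duplicate tip names")
    missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            missing += 1
        elif not np.isfinite(node.length) or node.length < 0:
            raise FormatError(f"{path}: invalid branch length {node.length!r}")
    if tree.length is None:
        tree.length = 0.0
    if missing:
        warnings.warn(f"{path}: {missing} branch length(s) missing, set to 0",
                      stacklevel=2)
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Sample metadata (mapping file)
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample host/family/site/role/age attributes.

    Wraps a DataFrame indexed by sample id with columns ``host_id,
    family_id, body_site, species, role, age, has_dog, has_cat,
    family_size``.  Validation enforces the site/species compatibility
    rules (paws only on dogs, palms only on humans) and the role/age
    bins (infant 0-1 y, child 1-17 y, adult 18-59 y, senior >= 60 y).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing required column(s): {missing}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample id(s): {dupes[:5]}")
        bad_site = sorted(set(df["body_site"]) - set(BODY_SITES))
        if bad_site:
            raise FormatError(f"unknown body_site value(s): {bad_site}")
        bad_role = sorted(set(df["role"]) - set(ROLES))
        if bad_role:
            raise FormatError(f"unknown role value(s): {bad_role}")
        bad_sp = sorted(set(df["species"]) - {"human", "dog"})
        if bad_sp:
            raise FormatError(f"unknown species value(s): {bad_sp}")
        for sid, row in df.iterrows():
            if row["species"] == "human":
                if row["body_site"] not in HUMAN_SITES:
                    raise FormatError(f"{sid}: site {row['body_site']} invalid for humans")
                if row["role"] == "dog":
                    raise FormatError(f"{sid}: role 'dog' on a human sample")
            else:
                if row["body_site"] not in DOG_SITES:
                    raise FormatError(f"{sid}: site {row['body_site']} invalid for dogs")
                if row["role"] != "dog":
                    raise FormatError(f"{sid}: dog sample must have role 'dog'")
            age = float(row["age"])
            if not np.isfinite(age) or age < 0:
                raise FormatError(f"{sid}: invalid age {row['age']!r}")
            bins = ROLE_AGE_BINS.get(row["role"])
            if bins is not None and not (bins[0] <= age < bins[1] or
                                         (age == bins[0] == 0.0)):
                raise FormatError(
                    f"{sid}: age {age} inconsistent with role {row['role']!r}")
            if int(row["family_size"]) < 1:
                raise FormatError(f"{sid}: family_size must be >= 1")

    # -- queries ------------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, mask) -> "SampleMetadata":
        return SampleMetadata(self.frame[mask])

    def at_site(self, body_site: str, species: Optional[str] = None) -> pd.DataFrame:
        df = self.frame[self.frame["body_site"] == body_site]
        if species is not None:
            df = df[df["species"] == species]
        return df

    def families(self) -> list[str]:
        return sorted(self.frame["family_id"].unique())

    def hosts(self) -> pd.DataFrame:
        """One row per host: family, species, role, age, pet flags."""
        cols = ["family_id", "species", "role", "age", "has_dog", "has_cat",
                "family_size"]
        return self.frame.groupby("host_id", sort=False)[cols].first()


_BOOL_TOKENS = {"yes": True, "no": False, "true": True, "false": False,
                "1": True, "0": False, "y": True, "n": False}


def _parse_bool(value, sid: str, col: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token not in _BOOL_TOKENS:
        raise FormatError(f"{sid}: cannot parse {col}={value!r} as boolean")
    return _BOOL_TOKENS[token]


def read_metadata(path) -> SampleMetadata:
    """Read a tab-separated mapping file whose first header field is #SampleID."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if not first.startswith("#SampleID"):
        raise FormatError(f"{path}: mapping file must start with '#SampleID'")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={"#SampleID": "sample_id"}).set_index("sample_id")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    out = pd.DataFrame(index=df.index.astype(str))
    out.index.name = "sample_id"
    for col in ("host_id", "family_id", "body_site", "species", "role"):
        out[col] = df[col].astype(str)
    try:
        out["age"] = df["age"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable age value: {exc}") from exc
    out["has_dog"] = [_parse_bool(v, s, "has_dog") for s, v in df["has_dog"].items()]
    out["has_cat"] = [_parse_bool(v, s, "has_cat") for s, v in df["has_cat"].items()]
    try:
        out["family_size"] = df["family_size"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable family_size: {exc}") from exc
    return SampleMetadata(out)


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.frame.copy()
    df["has_dog"] = df["has_dog"].map({True: "yes", False: "no"})
    df["has_cat"] = df["has_cat"].map({True: "yes", False: "no"})
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Distance matrices (labeled square TSV)
# ---------------------------------------------------------------------------

def read_distance_matrix(path) -> DistanceMatrix:
    """Read a labeled square TSV distance matrix.

    Symmetry is enforced: asymmetries beyond 1e-8 are an error, smaller
    ones are symmetrized away.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise FormatError(f"{path}: row and column labels disagree")
    values = df.to_numpy(dtype=float)
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > 1e-8:
        raise FormatError(f"{path}: matrix asymmetric (max |d_ij - d_ji| = {asym:.3g})")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    if values.size and values.min() < 0:
        raise FormatError(f"{path}: negative distance")
    return DistanceMatrix(values, ids)


def write_distance_matrix(matrix: DistanceMatrix, path) -> None:
    df = pd.DataFrame(matrix.data, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, sep="\t", float_format="%.12g")
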