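"""Readers, writers and in-memory containers for the pipeline's file formats.

Three kinds of input feed the pipeline: gene-set collections in GMT
(one set per line: name, description, members, tab-separated), expression
matrices as TSV (rows = probes, columns = samples, log2-scale intensities,
with a ``probe_id`` and a ``gene`` column up front), and a dataset manifest
TSV listing one row per study with its case/control sample counts.

All readers reject malformed input instead of repairing it; errors name the
file and (where meaningful) the line or cell of the offender.  Gene
identifiers are opaque symbols throughout — there is no ID-translation
layer; the probe-to-gene assignment travels in the matrix itself.
"""

from __future__ import annotations

import dataclasses
import os
from collections.abc import Iterable, Iterator, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "ExpressionDataset",
    "Manifest",
    "ManifestRow",
    "FormatError",
    "read_gmt",
    "write_gmt",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_manifest",
    "write_manifest",
    "summarize_manifest",
    "load_manifest_datasets",
    "CASE",
    "CONTROL",
    "GROUP_TOKENS",
]

CASE = "case"
CONTROL = "control"
GROUP_TOKENS = (CASE, CONTROL)


class FormatError(ValueError):
    """A file violated the expected dialect; message carries file/line."""


@dataclasses.dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set must have a non-empty name")
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


class GeneSetCollection:
    """Ordered collection of named gene sets over a symbol universe.

    Set names are unique; members are unique within a set (duplicates in the
    constructor input are collapsed keeping first occurrence, matching the
    GMT de-duplication rule); empty sets are rejected.
    """

    def __init__(self, sets: Iterable[GeneSet | tuple[str, str, Sequence[str]]]):
        self._sets: dict[str, GeneSet] = {}
        for item in sets:
            if not isinstance(item, GeneSet):
                name, description, members = item
                deduped = tuple(dict.fromkeys(members))
                item = GeneSet(name, description, deduped)
            if item.name in self._sets:
                raise ValueError(f"duplicate gene set name {item.name!r}")
            self._sets[item.name] = item
        self._universe = frozenset(
            g for s in self._sets.values() for g in s.members
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._sets)

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member genes across sets."""
        return self._universe

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def members(self, name: str) -> tuple[str, ...]:
        return self._sets[name].members

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets, {len(self._universe)} genes)"


@dataclasses.dataclass
class ExpressionDataset:
    """One study's probe-by-sample log2 expression matrix with labels.

    ``values`` rows are probes, columns samples; ``gene_of_probe`` maps each
    probe to a gene symbol (a sentinel such as ``"unmapped"`` is allowed);
    ``group_of_sample`` maps each sample to ``"case"`` or ``"control"``.
    After probe collapse the row index holds gene symbols and
    ``gene_of_probe`` is the identity on them.
    """

    dataset_id: str
    values: pd.DataFrame
    gene_of_probe: pd.Series
    group_of_sample: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate probe ids")
        if v.columns.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate sample ids")
        if not v.index.equals(self.gene_of_probe.index):
            raise ValueError(
                f"{self.dataset_id}: gene_of_probe index does not match probe ids"
            )
        if set(v.columns) != set(self.group_of_sample.index):
            raise ValueError(
                f"{self.dataset_id}: sample labels do not cover the matrix columns"
            )
        bad = set(self.group_of_sample) - set(GROUP_TOKENS)
        if bad:
            raise ValueError(
                f"{self.dataset_id}: unknown group label(s) {sorted(bad)}; "
                f"allowed: {list(GROUP_TOKENS)}"
            )
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError(
                f"{self.dataset_id}: need >=2 case and >=2 control samples "
                f"(got {self.n_case} case / {self.n_control} control)"
            )
        if v.isna().any().any():
            r, c = np.argwhere(v.isna().to_numpy())[0]
            raise ValueError(
                f"{self.dataset_id}: missing value at probe {v.index[r]!r}, "
                f"sample {v.columns[c]!r}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.group_of_sample[s] == CASE]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.group_of_sample[s] == CONTROL]

    @property
    def n_case(self) -> int:
        return len(self.case_samples)

    @property
    def n_control(self) -> int:
        return len(self.control_samples)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(pd.unique(self.gene_of_probe))

    def case_mask(self) -> np.ndarray:
        """Boolean array over columns, True for case samples."""
        return np.array(
            [self.group_of_sample[s] == CASE for s in self.values.columns]
        )

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionDataset":
        idx = pd.Index(probes)
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            values=self.values.loc[idx],
            gene_of_probe=self.gene_of_probe.loc[idx],
            group_of_sample=self.group_of_sample,
        )


@dataclasses.dataclass(frozen=True)
class ManifestRow:
    dataset_id: str
    matrix_path: str
    n_case: int
    n_control: int
    labels_path: str | None = None

    def resolved_labels_path(self) -> str:
        if self.labels_path:
            return self.labels_path
        stem, _ = os.path.splitext(self.matrix_path)
        return stem + ".labels.tsv"


@dataclasses.dataclass(frozen=True)
class Manifest:
    rows: tuple[ManifestRow, ...]

    def __post_init__(self) -> None:
        ids = [r.dataset_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate dataset_id(s) in manifest: {dup}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[ManifestRow]:
        return iter(self.rows)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (MSigDB dialect): name TAB description TAB member...

    Blank lines are skipped.  Duplicate members within a line are collapsed
    keeping first occurrence; a duplicate set name or a line with fewer than
    three fields is an error naming the line.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                    f"(name, description, members...), got {len(fields)}"
                )
            name, description, *members = fields
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            members = [m for m in members if m != ""]
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets.append(GeneSet(name, description, tuple(dict.fromkeys(members))))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; round-trips losslessly through read_gmt."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for s in collection:
            for token in (s.name, s.description, *s.members):
                if "\t" in token or "\n" in token:
                    raise FormatError(
                        f"cannot write GMT: field {token!r} in set {s.name!r} "
                        "contains a tab or newline"
                    )
            fh.write("\t".join((s.name, s.description, *s.members)) + "\n")


# ---------------------------------------------------------------------------
# Expression matrix + labels
# ---------------------------------------------------------------------------

def read_expression_matrix(
    matrix_path: str | Path,
    labels_path: str | Path,
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Load a probe x sample TSV plus its two-column sample-label TSV.

    Matrix dialect: header row; first column ``probe_id``, second ``gene``,
    remaining columns are sample ids with numeric log2 intensities.  Labels
    dialect: header ``sample_id``, ``group``; group tokens are ``case`` or
    ``control``.  Any non-numeric cell, unknown label token, or matrix
    sample missing from the labels file is an error naming the offender.
    """
    matrix_path = Path(matrix_path)
    labels_path = Path(labels_path)
    df = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["probe_id", "gene"]:
        raise FormatError(
            f"{matrix_path}: first two columns must be 'probe_id' and 'gene', "
            f"got {list(df.columns[:2])}"
        )
    sample_cols = list(df.columns[2:])
    if not sample_cols:
        raise FormatError(f"{matrix_path}: no sample columns")
    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        cell = df.iloc[r][sample_cols[c]]
        raise FormatError(
            f"{matrix_path}: non-numeric or missing value {cell!r} at "
            f"row {r + 2} (probe {df.iloc[r]['probe_id']!r}), "
            f"column {sample_cols[c]!r}"
        )
    values.index = pd.Index(df["probe_id"], name="probe_id")
    gene_of_probe = pd.Series(
        df["gene"].to_numpy(), index=values.index, name="gene"
    )

    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if list(labels.columns) != ["sample_id", "group"]:
        raise FormatError(
            f"{labels_path}: columns must be 'sample_id' and 'group', "
            f"got {list(labels.columns)}"
        )
    bad = sorted(set(labels["group"]) - set(GROUP_TOKENS))
    if bad:
        raise FormatError(
            f"{labels_path}: unknown group token(s) {bad}; "
            f"allowed tokens: {list(GROUP_TOKENS)}"
        )
    group = pd.Series(
        labels["group"].to_numpy(), index=pd.Index(labels["sample_id"]), name="group"
    )
    missing = [s for s in sample_cols if s not in group.index]
    if missing:
        raise FormatError(
            f"{matrix_path}: sample(s) {missing} absent from labels file "
            f"{labels_path}"
        )
    group = group.loc[sample_cols]
    return ExpressionDataset(
        dataset_id=dataset_id or matrix_path.stem,
        values=values.astype(float),
        gene_of_probe=gene_of_probe,
        group_of_sample=group,
    )


def write_expression_matrix(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    """Write the TSV pair that read_expression_matrix consumes."""
    matrix_path = Path(matrix_path)
    if labels_path is None:
        stem, _ = os.path.splitext(str(matrix_path))
        labels_path = Path(stem + ".labels.tsv")
    out = dataset.values.copy()
    out.insert(0, "gene", dataset.gene_of_probe)
    out.index.name = "probe_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.10g", lineterminator="\n")
    lab = pd.DataFrame(
        {"sample_id": dataset.values.columns, "group": dataset.group_of_sample.loc[dataset.values.columns].to_numpy()}
    )
    lab.to_csv(labels_path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

_MANIFEST_REQUIRED = ["dataset_id", "matrix_path", "n_case", "n_control"]


def read_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {missing}")
    rows = []
    for i, rec in df.iterrows():
        try:
            n_case = int(rec["n_case"])
            n_control = int(rec["n_control"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: line {i + 2}: n_case/n_control must be integers"
            ) from None
        rows.append(
            ManifestRow(
                dataset_id=rec["dataset_id"],
                matrix_path=rec["matrix_path"],
                n_case=n_case,
                n_control=n_control,
                labels_path=rec.get("labels_path") if "labels_path" in df.columns else None,
            )
        )
    return Manifest(tuple(rows))


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "dataset_id": [r.dataset_id for r in manifest],
            "matrix_path": [r.matrix_path for r in manifest],
            "labels_path": [r.resolved_labels_path() for r in manifest],
            "n_case": [r.n_case for r in manifest],
            "n_control": [r.n_control for r in manifest],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def summarize_manifest(manifest: Manifest) -> tuple[int, int, pd.DataFrame]:
    """Total case/control counts plus a per-dataset table."""
    table = pd.DataFrame(
        {
            "dataset_id": [r.dataset_id for r in manifest],
            "n_case": [r.n_case for r in manifest],
            "n_control": [r.n_control for r in manifest],
        }
    )
    total_case = int(table["n_case"].sum()) if len(table) else 0
    total_control = int(table["n_control"].sum()) if len(table) else 0
    return total_case, total_control, table


def load_manifest_datasets(
    manifest: Manifest, base_dir: str | Path | None = None
) -> list[ExpressionDataset]:
    """Load every dataset a manifest references, checking its counts.

    Relative paths are resolved against ``base_dir`` (default: cwd).  A
    mismatch between the manifest's n_case/n_control and the labels actually
    found in the matrix is an error.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    out = []
    for row in manifest:
        mpath = Path(row.matrix_path)
        lpath = Path(row.resolved_labels_path())
        if not mpath.is_absolute():
            mpath = base / mpath
        if not lpath.is_absolute():
            lpath = base / lpath
        ds = read_expression_matrix(mpath, lpath, dataset_id=row.dataset_id)
        if ds.n_case != row.n_case or ds.n_control != row.n_control:
            raise FormatError(
                f"{row.dataset_id}: manifest declares {row.n_case} case / "
                f"{row.n_control} control but matrix has {ds.n_case} / {ds.n_control}"
            )
        out.append(ds)
    return out
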