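"""Typed containers for block-structured data and delimited-format IO.

Data are an ``n x p`` predictor matrix ``X`` (e.g. SNP dosages in {0,1,2})
and an ``n x q`` outcome matrix ``Y``, together with two partitions:
observation sets (samples grouped by study/source) and variable groups
(SNPs grouped by gene, genes by pathway).  Variables are kept in a
canonical order in which group members are contiguous; user-facing files
always use string identifiers, internal indices are 0-based and never
serialized.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import DataFormatError, IdentifierError, PartitionError


def _as_labels(values) -> list[str]:
    return [str(v) for v in values]


@dataclass(frozen=True)
class ObservationSets:
    """Partition of samples into M studies (observation sets)."""

    labels: tuple[str, ...]  # study labels, canonical order
    index: np.ndarray        # shape (n,), study index per sample

    @property
    def M(self) -> int:
        return len(self.labels)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.index, minlength=self.M)

    def rows(self, m: int) -> np.ndarray:
        return np.flatnonzero(self.index == m)

    def blocks(self) -> Iterator[tuple[str, np.ndarray]]:
        for m, label in enumerate(self.labels):
            yield label, self.rows(m)

    def validate(self, n: int) -> list[str]:
        problems = []
        if len(self.index) != n:
            problems.append(f"study assignments cover {len(self.index)} samples, expected {n}")
        if self.index.min(initial=0) < 0 or self.index.max(initial=-1) >= self.M:
            problems.append("study index out of range")
        sizes = self.sizes
        for label, size in zip(self.labels, sizes):
            if size < 2:
                problems.append(f"study '{label}' has {size} sample(s); at least 2 required")
        return problems


@dataclass(frozen=True)
class VariableGroups:
    """Disjoint partition of variables into K groups."""

    labels: tuple[str, ...]  # group labels, canonical order
    index: np.ndarray        # shape (p,), group index per variable

    @property
    def K(self) -> int:
        return len(self.labels)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.index, minlength=self.K)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.index == k)

    def blocks(self) -> Iterator[tuple[str, np.ndarray]]:
        for k, label in enumerate(self.labels):
            yield label, self.members(k)

    def validate(self, p: int) -> list[str]:
        problems = []
        if len(self.index) != p:
            problems.append(f"group assignments cover {len(self.index)} variables, expected {p}")
        if self.K and int(self.sizes.sum()) != len(self.index):
            problems.append("group sizes do not sum to p")
        if any(s == 0 for s in self.sizes):
            empty = [self.labels[k] for k in range(self.K) if self.sizes[k] == 0]
            problems.append(f"empty group(s): {empty}")
        return problems


@dataclass(frozen=True)
class PenaltyParams:
    """Sparse-group penalty: overall strength lambda and mixing alpha.

    ``alpha = 1`` is pure per-variable shrinkage, ``alpha = 0`` pure
    per-group shrinkage.  ``n_groups_kept`` is the group-count surrogate
    for lambda: when set, lambda is resolved on the calibration input so
    that exactly that many groups survive.
    """

    lam: float = 0.0
    alpha: float = 1.0
    n_groups_kept: Optional[int] = None

    def __post_init__(self):
        from .errors import ParameterError

        if self.lam < 0:
            raise ParameterError(f"lambda must be nonnegative, got {self.lam}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_groups_kept is not None and self.n_groups_kept < 0:
            raise ParameterError("n_groups_kept must be >= 0")


@dataclass
class LoadingSet:
    """Per-component stacked loadings U (p x M) and V (q x M)."""

    components: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    mode: str = "regression"

    def __len__(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class SelectionResult:
    """Identifiers selected at the variable and group level."""

    variables: tuple[str, ...]
    groups: tuple[str, ...]
    variable_mask: np.ndarray
    group_mask: np.ndarray


@dataclass
class StructuredDataset:
    """X, Y and the two partitions, with string labels throughout."""

    X: np.ndarray
    Y: np.ndarray
    obs_sets: ObservationSets
    var_groups: VariableGroups
    sample_ids: tuple[str, ...]
    variable_ids: tuple[str, ...]
    outcome_ids: tuple[str, ...]
    user_variable_order: Optional[np.ndarray] = None  # canonical -> user position
    standardized: bool = False
    study_stats: Optional[dict] = None   # per-study means/scales used
    zero_variance_flags: Optional[dict] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if self.X.shape[0] != self.Y.shape[0]:
            raise DataFormatError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )

    # -- basic dimensions -------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    @property
    def M(self) -> int:
        return self.obs_sets.M

    @property
    def K(self) -> int:
        return self.var_groups.K

    def study_rows(self, label: str) -> np.ndarray:
        try:
            m = self.obs_sets.labels.index(label)
        except ValueError:
            raise IdentifierError(f"unknown study id '{label}'")
        return self.obs_sets.rows(m)

    def subset_rows(self, rows: np.ndarray) -> "StructuredDataset":
        rows = np.asarray(rows)
        return StructuredDataset(
            X=self.X[rows].copy(),
            Y=self.Y[rows].copy(),
            obs_sets=ObservationSets(self.obs_sets.labels, self.obs_sets.index[rows].copy()),
            var_groups=self.var_groups,
            sample_ids=tuple(self.sample_ids[i] for i in rows),
            variable_ids=self.variable_ids,
            outcome_ids=self.outcome_ids,
            user_variable_order=self.user_variable_order,
            standardized=self.standardized,
            study_stats=self.study_stats,
        )

    def copy(self) -> "StructuredDataset":
        return replace(
            self,
            X=self.X.copy(),
            Y=self.Y.copy(),
        )


# ---------------------------------------------------------------------------
# Delimited IO
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> pd.DataFrame:
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["", "NA"])
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise DataFormatError(f"duplicate sample id(s) in {path}: {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise DataFormatError(f"duplicate column id(s) in {path}: {dup}")
    return df


def _read_two_col_map(path: Path, kind: str) -> "pd.DataFrame":
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise DataFormatError(f"{kind} map {path} must have exactly 2 tab-separated columns")
    # tolerate an optional header row
    first = tuple(df.iloc[0])
    if first in {("variable_id", "group_id"), ("sample_id", "study_id")}:
        df = df.iloc[1:].reset_index(drop=True)
    if df[0].duplicated().any():
        dup = df[0][df[0].duplicated()].tolist()
        raise DataFormatError(f"duplicate id(s) in {kind} map: {dup}")
    return df


def load_dataset(genotype_path, phenotype_path, group_map_path, study_map_path) -> StructuredDataset:
    """Load a dataset bundle from delimited files.

    Variables are reordered so that group members are contiguous (groups in
    order of first appearance in the group map, variables within a group in
    their original file order); the permutation back to user order is kept
    on the returned dataset.
    """
    geno = _read_matrix(Path(genotype_path))
    pheno = _read_matrix(Path(phenotype_path))
    gmap = _read_two_col_map(Path(group_map_path), "group")
    smap = _read_two_col_map(Path(study_map_path), "study")

    if list(geno.index) != list(pheno.index):
        if set(geno.index) != set(pheno.index):
            missing = sorted(set(geno.index) ^ set(pheno.index))
            raise PartitionError(f"genotype/phenotype sample mismatch: {missing}")
        pheno = pheno.loc[geno.index]

    var_to_group = dict(zip(gmap[0], gmap[1]))
    unknown = sorted(set(var_to_group) - set(geno.columns))
    if unknown:
        raise IdentifierError(f"group map references unknown variable id(s): {unknown}")
    uncovered = sorted(set(geno.columns) - set(var_to_group))
    if uncovered:
        raise PartitionError(f"variable(s) missing from group map: {uncovered}")

    sample_to_study = dict(zip(smap[0], smap[1]))
    unknown = sorted(set(sample_to_study) - set(geno.index))
    if unknown:
        raise IdentifierError(f"study map references unknown sample id(s): {unknown}")
    uncovered = sorted(set(geno.index) - set(sample_to_study))
    if uncovered:
        raise PartitionError(f"sample(s) missing from study map: {uncovered}")

    # canonical variable order: group-contiguous
    group_labels: list[str] = []
    for gid in gmap[1]:
        if gid not in group_labels:
            group_labels.append(gid)
    order = []
    for gid in group_labels:
        order.extend(j for j, v in enumerate(geno.columns) if var_to_group[v] == gid)
    order = np.asarray(order, dtype=int)
    variable_ids = tuple(geno.columns[j] for j in order)
    group_index = np.asarray(
        [group_labels.index(var_to_group[v]) for v in variable_ids], dtype=int
    )

    study_labels: list[str] = []
    for sid in geno.index:
        st = sample_to_study[sid]
        if st not in study_labels:
            study_labels.append(st)
    study_index = np.asarray([study_labels.index(sample_to_study[s]) for s in geno.index])

    return StructuredDataset(
        X=geno.to_numpy(dtype=float)[:, order],
        Y=pheno.to_numpy(dtype=float),
        obs_sets=ObservationSets(tuple(study_labels), study_index),
        var_groups=VariableGroups(tuple(group_labels), group_index),
        sample_ids=tuple(_as_labels(geno.index)),
        variable_ids=variable_ids,
        outcome_ids=tuple(_as_labels(pheno.columns)),
        user_variable_order=order,
    )


def write_dataset(dataset: StructuredDataset, out_dir, fmt: str = "csv") -> dict:
    """Write the dataset bundle plus a JSON manifest with per-file checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sep = "\t" if fmt == "tsv" else ","
    ext = "tsv" if fmt == "tsv" else "csv"

    geno = pd.DataFrame(dataset.X, index=list(dataset.sample_ids), columns=list(dataset.variable_ids))
    pheno = pd.DataFrame(dataset.Y, index=list(dataset.sample_ids), columns=list(dataset.outcome_ids))
    paths = {
        "genotype": out / f"genotype.{ext}",
        "phenotype": out / f"phenotype.{ext}",
        "group_map": out / "groups.tsv",
        "study_map": out / "studies.tsv",
    }
    geno.index.name = "sample_id"
    pheno.index.name = "sample_id"
    geno.to_csv(paths["genotype"], sep=sep)
    pheno.to_csv(paths["phenotype"], sep=sep)
    with open(paths["group_map"], "w") as fh:
        for v, k in zip(dataset.variable_ids, dataset.var_groups.index):
            fh.write(f"{v}\t{dataset.var_groups.labels[k]}\n")
    with open(paths["study_map"], "w") as fh:
        for s, m in zip(dataset.sample_ids, dataset.obs_sets.index):
            fh.write(f"{s}\t{dataset.obs_sets.labels[m]}\n")

    manifest = {"files": {}}
    for key, path in paths.items():
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][key] = {"path": path.name, "sha256": digest}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_bundle(bundle_dir) -> StructuredDataset:
    """Load a dataset written by :func:`write_dataset` via its manifest."""
    bundle = Path(bundle_dir)
    with open(bundle / "manifest.json") as fh:
        manifest = json.load(fh)
    files = manifest["files"]
    return load_dataset(
        bundle / files["genotype"]["path"],
        bundle / files["phenotype"]["path"],
        bundle / files["group_map"]["path"],
        bundle / files["study_map"]["path"],
    )


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[tuple[str, bool, str], ...]

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[str]:
        return [f"{name}: {detail}" for name, ok, detail in self.checks if not ok]


def validate_partitions(dataset: StructuredDataset) -> ValidationReport:
    """Check every partition invariant and report pass/fail per check."""
    checks = []

    obs_problems = dataset.obs_sets.validate(dataset.n)
    checks.append(("observation_sets_partition", not obs_problems, "; ".join(obs_problems) or "ok"))

    var_problems = dataset.var_groups.validate(dataset.p)
    checks.append(("variable_groups_partition", not var_problems, "; ".join(var_problems) or "ok"))

    shape_ok = dataset.X.shape[0] == dataset.Y.shape[0] == dataset.n
    checks.append(("row_counts_match", shape_ok, "ok" if shape_ok else "X/Y row mismatch"))

    nan_free = not (np.isnan(dataset.X).any() or np.isnan(dataset.Y).any())
    checks.append(("no_missing_values", nan_free, "ok" if nan_free else "missing values present"))

    label_ok = (
        len(set(dataset.sample_ids)) == dataset.n
        and len(set(dataset.variable_ids)) == dataset.p
    )
    checks.append(("unique_labels", label_ok, "ok" if label_ok else "duplicate labels"))

    return ValidationReport(tuple(checks))
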