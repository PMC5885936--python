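"""Cohort assembly and tabular I/O.

The pipeline's sole input object is a :class:`ThicknessCohort`: a subjects ×
regions matrix of cortical thickness (mm), a numeric covariate matrix, and a
per-subject group label, all row-aligned on subject id.  Readers accept
delimited text (TSV/CSV, delimiter auto-detected) with a header row; writers
emit edge lists (TSV + GraphML) and per-group-pair node reports.

Missing covariate values are a hard error: the pipeline refuses rather than
imputes, so users must pre-impute or drop subjects explicitly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class CohortError(ValueError):
    """Raised for malformed or inconsistent cohort inputs."""


@dataclass(frozen=True)
class RegionSet:
    """Ordered cortical region labels with hemisphere tags and a-priori flags.

    Region order is fixed at construction and preserved through every
    downstream artifact (matrices, networks, reports).
    """

    labels: tuple[str, ...]
    hemisphere: tuple[str, ...] = ()
    a_priori: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if len(labels) != len(set(labels)):
            raise CohortError("duplicate region name in region set")
        if any(not lab for lab in labels):
            raise CohortError("empty region name")
        hemi = tuple(self.hemisphere) or tuple(
            _infer_hemisphere(lab) for lab in labels
        )
        apr = tuple(self.a_priori) or (False,) * len(labels)
        if len(hemi) != len(labels) or len(apr) != len(labels):
            raise CohortError("hemisphere/a_priori length mismatch")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "hemisphere", hemi)
        object.__setattr__(self, "a_priori", apr)

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def with_a_priori(self, names: Sequence[str]) -> "RegionSet":
        """Return a copy with the a-priori flag set for ``names``."""
        unknown = set(names) - set(self.labels)
        if unknown:
            raise CohortError(f"unknown a-priori region(s): {sorted(unknown)}")
        flags = tuple(lab in set(names) for lab in self.labels)
        return RegionSet(self.labels, self.hemisphere, flags)

    def subset(self, keep: Sequence[int]) -> "RegionSet":
        keep = list(keep)
        return RegionSet(
            tuple(self.labels[i] for i in keep),
            tuple(self.hemisphere[i] for i in keep),
            tuple(self.a_priori[i] for i in keep),
        )


def _infer_hemisphere(label: str) -> str:
    low = label.lower()
    if low.startswith(("l ", "l_", "lh", "left")):
        return "L"
    if low.startswith(("r ", "r_", "rh", "right")):
        return "R"
    return "?"


@dataclass(frozen=True)
class ThicknessCohort:
    """Row-aligned thickness, covariates, and group labels for all subjects."""

    subject_ids: tuple[str, ...]
    thickness: np.ndarray  # subjects x regions, mm
    covariates: np.ndarray  # subjects x k
    covariate_names: tuple[str, ...]
    group: tuple[str, ...]
    regions: RegionSet

    def __post_init__(self) -> None:
        thick = np.asarray(self.thickness, dtype=float)
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov.reshape(len(thick), -1)
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise CohortError("duplicate subject id")
        if thick.shape[0] != n or cov.shape[0] != n or len(self.group) != n:
            raise CohortError("row counts of thickness, covariates, group differ")
        if thick.shape[1] != len(self.regions):
            raise CohortError("thickness column count does not match region set")
        if cov.shape[1] != len(self.covariate_names):
            raise CohortError("covariate column count does not match names")
        if not np.all(np.isfinite(thick)):
            raise CohortError("non-finite thickness value")
        if np.any(thick <= 0):
            raise CohortError("non-positive thickness value")
        if not np.all(np.isfinite(cov)):
            raise CohortError("missing or non-finite covariate value")
        k = cov.shape[1]
        for g, cnt in zip(*np.unique(self.group, return_counts=True)):
            if cnt < k + 3:
                raise CohortError(
                    f"insufficient degrees of freedom: group {g!r} has n={cnt} "
                    f"subjects but k={k} covariates requires n >= {k + 3}"
                )
        object.__setattr__(self, "thickness", thick)
        object.__setattr__(self, "covariates", cov)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def group_labels(self) -> tuple[str, ...]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(g, None)
        return tuple(seen)

    def group_mask(self, label: str) -> np.ndarray:
        return np.asarray([g == label for g in self.group], dtype=bool)

    def group_slice(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """Thickness and covariate rows for one group."""
        m = self.group_mask(label)
        if not m.any():
            raise CohortError(f"unknown group {label!r}")
        return self.thickness[m], self.covariates[m]

    def drop_regions(self, labels: Sequence[str]) -> "ThicknessCohort":
        """Cohort view with the named regions removed everywhere."""
        drop = set(labels)
        keep = [i for i, lab in enumerate(self.regions.labels) if lab not in drop]
        return ThicknessCohort(
            self.subject_ids,
            self.thickness[:, keep],
            self.covariates,
            self.covariate_names,
            self.group,
            self.regions.subset(keep),
        )

    def select_covariates(self, names: Sequence[str]) -> "ThicknessCohort":
        idx = [self.covariate_names.index(n) for n in names]
        return ThicknessCohort(
            self.subject_ids,
            self.thickness,
            self.covariates[:, idx],
            tuple(names),
            self.group,
            self.regions,
        )


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table; delimiter sniffed from the header line."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
    try:
        delim = csv.Sniffer().sniff(head, delimiters="\t,;").delimiter
    except csv.Error:
        delim = "\t"
    return pd.read_csv(path, sep=delim, dtype=str, index_col=0)


def read_thickness_table(
    path: str | Path, region_set: RegionSet | None = None
) -> tuple[np.ndarray, tuple[str, ...], RegionSet]:
    """Read a subject × region thickness table.

    First column holds subject ids; remaining header names are region labels.
    Returns ``(matrix, subject_ids, regions)`` with region order taken from
    the header, or validated against ``region_set`` when provided.
    """
    df = _read_table(path)
    subject_ids = tuple(str(s) for s in df.index)
    if len(set(subject_ids)) != len(subject_ids):
        dup = df.index[df.index.duplicated()].tolist()
        raise CohortError(f"duplicate subject id: {dup[0]}")
    labels = tuple(str(c) for c in df.columns)
    if len(set(labels)) != len(labels):
        raise CohortError("duplicate region name in header")
    if region_set is not None:
        if tuple(region_set.labels) != labels:
            raise CohortError("region labels do not match provided region set")
        regions = region_set
    else:
        regions = RegionSet(labels)
    matrix = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise CohortError(
                f"non-numeric thickness for subject {subject_ids[bad[0]]!r}, "
                f"region {col!r}: {df[col].iloc[bad[0]]!r}"
            )
        if np.any(vals <= 0):
            i = int(np.flatnonzero(vals <= 0)[0])
            raise CohortError(
                f"non-positive thickness for subject {subject_ids[i]!r}, "
                f"region {col!r}"
            )
        matrix[:, j] = vals
    return matrix, subject_ids, regions


def read_covariate_table(
    path: str | Path, coding: Mapping[str, Mapping[str, float]] | None = None
) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Read a subject × covariate table.

    ``coding`` maps a categorical column name to a level→number map (e.g.
    ``{"sex": {"M": 1, "F": 0}}``); every other column must parse as numeric.
    Missing values are rejected — no imputation is performed.
    Returns ``(matrix, subject_ids, covariate_names)``.
    """
    coding = dict(coding or {})
    df = _read_table(path)
    subject_ids = tuple(str(s) for s in df.index)
    if len(set(subject_ids)) != len(subject_ids):
        raise CohortError("duplicate subject id in covariate table")
    names = tuple(str(c) for c in df.columns)
    matrix = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col]
        missing = raw.isna() | (raw.astype(str).str.strip() == "")
        if missing.any():
            sid = subject_ids[int(np.flatnonzero(missing.to_numpy())[0])]
            raise CohortError(f"missing value in covariate {col!r} for subject {sid!r}")
        if col in coding:
            levels = coding[col]
            unknown = set(raw) - set(levels)
            if unknown:
                raise CohortError(
                    f"unknown category level {sorted(unknown)[0]!r} in covariate {col!r}"
                )
            matrix[:, j] = [float(levels[v]) for v in raw]
        else:
            vals = pd.to_numeric(raw, errors="coerce").to_numpy()
            bad = np.flatnonzero(~np.isfinite(vals))
            if bad.size:
                raise CohortError(
                    f"non-numeric covariate {col!r} for subject "
                    f"{subject_ids[bad[0]]!r}: {raw.iloc[bad[0]]!r} "
                    f"(declare a coding for categorical columns)"
                )
            matrix[:, j] = vals
    return matrix, subject_ids, names


def read_group_table(path: str | Path) -> dict[str, str]:
    """Read a two-column subject → group assignment table."""
    df = _read_table(path)
    if df.shape[1] < 1:
        raise CohortError("group table needs a subject and a group column")
    col = df.columns[0]
    return {str(s): str(g) for s, g in zip(df.index, df[col])}


def assemble_cohort(
    thickness: tuple[np.ndarray, Sequence[str], RegionSet],
    covariates: tuple[np.ndarray, Sequence[str], Sequence[str]],
    groups: Mapping[str, str],
) -> ThicknessCohort:
    """Align thickness, covariates, and group labels on subject id.

    Rows are the intersection of the three id sets, ordered as in the
    thickness table; extra subjects in the covariate or group tables are
    dropped with a logged warning.
    """
    t_mat, t_ids, regions = thickness
    c_mat, c_ids, c_names = covariates
    t_ids = tuple(str(s) for s in t_ids)
    c_index = {str(s): i for i, s in enumerate(c_ids)}
    common = [s for s in t_ids if s in c_index and s in groups]
    if not common:
        raise CohortError("no subjects common to thickness, covariates, and groups")
    dropped = (set(t_ids) | set(c_index) | set(groups)) - set(common)
    if dropped:
        logger.warning(
            "dropping %d subject(s) absent from some input table: %s",
            len(dropped),
            sorted(dropped)[:10],
        )
    t_rows = [t_ids.index(s) for s in common]
    c_rows = [c_index[s] for s in common]
    return ThicknessCohort(
        tuple(common),
        np.asarray(t_mat, dtype=float)[t_rows],
        np.asarray(c_mat, dtype=float)[c_rows],
        tuple(c_names),
        tuple(groups[s] for s in common),
        regions,
    )


# ---------------------------------------------------------------------------
# writers


def write_edge_list(network, path: str | Path) -> None:
    """Write a network as a TSV edge list plus a GraphML sibling.

    One ``region_i<TAB>region_j`` line per edge with i < j in node-index
    order; a ``.graphml`` file with the same stem is written alongside for
    graph viewers.  Reading the TSV back reproduces the adjacency exactly.
    """
    path = Path(path)
    labels = network.labels
    ii, jj = np.nonzero(np.triu(network.adjacency, k=1))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("region_i\tregion_j\n")
        for i, j in zip(ii, jj):
            fh.write(f"{labels[i]}\t{labels[j]}\n")
    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from((labels[i], labels[j]) for i, j in zip(ii, jj))
    nx.write_graphml(g, path.with_suffix(".graphml"))


def read_edge_list(path: str | Path, labels: Sequence[str]) -> np.ndarray:
    """Read a TSV edge list back into an adjacency matrix over ``labels``."""
    idx = {lab: i for i, lab in enumerate(labels)}
    adj = np.zeros((len(labels), len(labels)), dtype=int)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("region_i"):
            raise CohortError("not an edge-list file")
        for line in fh:
            a, b = line.rstrip("\n").split("\t")
            adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1
    return adj


_MEASURES = ("degree", "betweenness", "closeness", "eigenvector")
_FMT = {"degree": "{:.0f}", "betweenness": "{:.1f}",
        "closeness": "{:.3f}", "eigenvector": "{:.3f}"}


def write_node_report(report, path: str | Path) -> None:
    """Write one TSV per group pair mirroring the published table layout.

    Columns: node, a_priori, then per measure a paired ``x/y`` value column
    (first group / second group, in the fixed order degree, betweenness,
    closeness, eigenvector), the four permutation p-values, the number of
    measures passing, the significance decision, and the direction.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for comp in report.comparisons:
        ga, gb = comp.group_pair
        ta = report.centralities[ga]
        tb = report.centralities[gb]
        out = path / f"nodes_{ga}_vs_{gb}.tsv"
        with open(out, "w", encoding="utf-8") as fh:
            cols = ["node", "a_priori"]
            cols += [f"{m}_{ga}/{gb}" for m in _MEASURES]
            cols += [f"p_{m}" for m in _MEASURES]
            cols += ["measures_passing", "significant", "direction"]
            fh.write("\t".join(cols) + "\n")
            for i, node in enumerate(report.regions.labels):
                dec = report.decisions[(ga, gb)][i]
                row = [node, str(report.regions.a_priori[i]).lower()]
                for m in _MEASURES:
                    fmt = _FMT[m]
                    row.append(
                        fmt.format(ta.measure(m)[i]) + "/" + fmt.format(tb.measure(m)[i])
                    )
                row += [f"{comp.p_values[m][i]:.6g}" for m in _MEASURES]
                row += [str(dec.measures_passing), str(dec.significant).lower(),
                        dec.direction]
                fh.write("\t".join(row) + "\n")
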