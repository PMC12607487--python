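"""Core containers for GC/MS relative-abundance profiling data.

An :class:`AbundanceTable` is a features x samples matrix of relative
abundances (percent of total identified peak area per sample), a
:class:`SampleClasses` object maps sample identifiers to one of two
cultivar classes (with an optional extract-type annotation), and
:class:`BioactivityRecord` / :class:`DockingRecord` hold enzyme-inhibition
and docking readouts for single compounds and two-compound combinations.
All tabular I/O is plain UTF-8 CSV through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Relative abundances of identified peaks: per-sample sums may fall short of
# 100% (unidentified peaks are excluded) but must not meaningfully exceed it.
COLUMN_SUM_TOLERANCE = 0.5

_MISSING_TOKENS = {"", "-", "na", "nd", "n.d.", "not founded", "not found"}


def _check_unique(ids, kind: str) -> None:
    seen, dup = set(), []
    for x in ids:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    if dup:
        raise ValueError(f"duplicate {kind} identifier(s): {', '.join(map(str, dup))}")


@dataclass
class AbundanceTable:
    """Features x samples matrix of relative abundances.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by metabolite (feature) name, columns by sample ID.
    units : {"percent", "zscore"}
        ``"percent"`` enforces non-negative values with per-sample column
        sums <= 100 (+ tolerance); ``"zscore"`` marks a standardized table
        where those range checks do not apply.
    """

    data: pd.DataFrame
    units: str = "percent"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(list(self.data.index), "feature")
        _check_unique(list(self.data.columns), "sample")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("abundance table body must be numeric")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at feature {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if self.units == "percent":
            if (values < 0).any():
                bad = np.argwhere(values < 0)[0]
                raise ValueError(
                    f"negative abundance at feature {self.data.index[bad[0]]!r}, "
                    f"sample {self.data.columns[bad[1]]!r}"
                )
            sums = values.sum(axis=0)
            if values.size and (sums > 100 + COLUMN_SUM_TOLERANCE).any():
                j = int(np.argmax(sums))
                raise ValueError(
                    f"sample {self.data.columns[j]!r} abundances sum to "
                    f"{sums[j]:.3f} > 100"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Matrix [n_features x n_samples]."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, feature_ids) -> "AbundanceTable":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"unknown feature(s): {', '.join(missing)}")
        return AbundanceTable(self.data.loc[list(feature_ids)], units=self.units)

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


def _parse_cell(raw, i, j, index, columns) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return 0.0
    if isinstance(raw, str):
        token = raw.strip()
        if token.lower() in _MISSING_TOKENS:
            return 0.0
        try:
            return float(token)
        except ValueError:
            raise ValueError(
                f"non-numeric cell {raw!r} at row {index[i]!r}, column {columns[j]!r}"
            ) from None
    return float(raw)


def read_abundance_table(path, orientation: str = "features_in_rows") -> AbundanceTable:
    """Read a feature table from CSV and validate it.

    The first column holds identifiers; the header row holds the other axis.
    Missing cells (empty, ``-``) are treated as 0: the compound was not
    detected in that extract.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, index_col=0, dtype=object)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty abundance table in {path}")
    index, columns = list(df.index), list(df.columns)
    body = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            body[i, j] = _parse_cell(raw[i, j], i, j, index, columns)
    parsed = pd.DataFrame(body, index=index, columns=columns)
    if orientation == "samples_in_rows":
        parsed = parsed.T
    return AbundanceTable(parsed)


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.to_csv(path)


@dataclass
class SampleClasses:
    """Binary class labels (0/1) per sample, with display names.

    ``class_names`` records which display name maps to which code so that
    PLS-DA sign conventions are reproducible; ``extract_type`` optionally
    annotates each sample with its extract (e.g. O, M-H, M-E).
    """

    labels: dict[str, int]
    class_names: dict[int, str]
    extract_type: dict[str, str] | None = None

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {0, 1}
        if bad:
            raise ValueError(f"class labels must be 0/1, got {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    def label_vector(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise ValueError(f"unlabeled sample(s): {', '.join(missing)}")
        return np.array([self.labels[s] for s in sample_ids], dtype=int)

    def class_sizes(self) -> dict[int, int]:
        sizes = {0: 0, 1: 0}
        for v in self.labels.values():
            sizes[v] += 1
        return sizes

    def name_of(self, code: int) -> str:
        return self.class_names.get(code, str(code))

    def to_csv(self, path) -> None:
        rows = {"sample_id": list(self.labels), "class": [self.name_of(v) for v in self.labels.values()]}
        if self.extract_type is not None:
            rows["extract_type"] = [self.extract_type.get(s, "") for s in self.labels]
        pd.DataFrame(rows).to_csv(path, index=False)


def read_classes(path) -> SampleClasses:
    """Read a sample_id,class[,extract_type] CSV.

    Class names are mapped to {0, 1} in lexicographic order (recorded in
    ``class_names``), so the coding does not depend on row order.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"no samples in {path}")
    if df.shape[1] < 2:
        raise ValueError("classes CSV needs at least sample_id and class columns")
    sample_col, class_col = df.columns[0], df.columns[1]
    names = sorted(df[class_col].unique())
    if len(names) > 2:
        raise ValueError(f"more than two class names: {', '.join(names)}")
    code = {name: i for i, name in enumerate(names)}
    _check_unique(list(df[sample_col]), "sample")
    labels = {row[sample_col]: code[row[class_col]] for _, row in df.iterrows()}
    extract = None
    if df.shape[1] >= 3:
        extract = dict(zip(df[sample_col], df[df.columns[2]]))
    return SampleClasses(labels=labels, class_names={v: k for k, v in code.items()}, extract_type=extract)


def align(table: AbundanceTable, classes: SampleClasses):
    """Join a table with its labels; column order of the table is preserved.

    Returns
    -------
    (AbundanceTable, numpy.ndarray)
        The table unchanged and the 0/1 label vector in column order.
    """
    y = classes.label_vector(table.sample_ids)
    return table, y


@dataclass
class BioactivityRecord:
    """Percent-inhibition readout for one compound or a two-compound mix."""

    agent_ids: tuple[str, ...]
    inhibition_pct: float
    concentration: float | None = None
    inhibition_sd: float | None = None
    n_replicates: int | None = None

    def __post_init__(self) -> None:
        self.agent_ids = tuple(self.agent_ids)
        if not 1 <= len(self.agent_ids) <= 2:
            raise ValueError("a record holds one or two agents")
        if self.inhibition_pct > 100:
            raise ValueError(f"inhibition {self.inhibition_pct} exceeds 100%")


@dataclass
class DockingRecord:
    """Docking score (kcal/mol, sign as printed) for one or two ligands."""

    ligand_ids: tuple[str, ...]
    score: float

    def __post_init__(self) -> None:
        self.ligand_ids = tuple(self.ligand_ids)
        if not 1 <= len(self.ligand_ids) <= 2:
            raise ValueError("a record holds one or two ligands")
        if not np.isfinite(self.score):
            raise ValueError("docking score must be finite")
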