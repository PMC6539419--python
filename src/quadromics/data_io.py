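"""Typed data model and tab-separated I/O for abundance tables.

The pipeline operates on features-by-samples matrices of non-negative
measurements (metabolite peak areas or gene expression units) together
with a staged, replicated sample design.  All tables are UTF-8,
tab-separated, with a header row; sample columns are matched to the
design by ``sample_id``, never by position.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_STAGES = ("NEC", "PEC", "GE")

__all__ = [
    "DEFAULT_STAGES",
    "SampleDesign",
    "FeatureAnnotation",
    "AbundanceMatrix",
    "ComparisonSpec",
    "load_design",
    "load_abundance",
    "load_annotations",
    "load_pathway_map",
    "write_table",
    "write_pathway_map",
]


class DataValidationError(ValueError):
    """Raised when an input table violates the data model."""


@dataclasses.dataclass(frozen=True)
class ComparisonSpec:
    """A two-stage contrast: *test_stage* over *ref_stage* (FC numerator/denominator)."""

    test_stage: str
    ref_stage: str

    def __post_init__(self) -> None:
        if self.test_stage == self.ref_stage:
            raise DataValidationError(
                f"comparison stages must differ, got {self.test_stage!r} twice"
            )

    @classmethod
    def parse(cls, text: str) -> "ComparisonSpec":
        """Parse ``"TEST:REF"`` (e.g. ``"PEC:NEC"``)."""
        parts = text.split(":")
        if len(parts) != 2 or not all(parts):
            raise DataValidationError(f"expected 'TEST:REF', got {text!r}")
        return cls(parts[0], parts[1])

    @property
    def label(self) -> str:
        return f"{self.test_stage}_vs_{self.ref_stage}"

    def validate(self, design: "SampleDesign") -> None:
        for stage in (self.test_stage, self.ref_stage):
            if stage not in design.stages:
                raise DataValidationError(
                    f"stage {stage!r} not in design stages {design.stages}"
                )


class SampleDesign:
    """Ordered staged/replicated sample layout.

    Parameters
    ----------
    samples : iterable of (sample_id, stage, replicate)
    stages : ordered stage labels; defaults to the stages in first-seen order.
    """

    def __init__(
        self,
        samples: Iterable[tuple[str, str, int]],
        stages: Sequence[str] | None = None,
    ) -> None:
        rows = [(str(s), str(g), int(r)) for s, g, r in samples]
        if not rows:
            raise DataValidationError("sample design is empty")
        ids = [r[0] for r in rows]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise DataValidationError(f"duplicate sample ids: {sorted(dup)}")
        seen_stages = list(dict.fromkeys(r[1] for r in rows))
        if stages is None:
            stages = seen_stages
        else:
            stages = [str(s) for s in stages]
            unknown = set(seen_stages) - set(stages)
            if unknown:
                raise DataValidationError(f"samples reference unknown stages: {sorted(unknown)}")
        if not stages:
            raise DataValidationError("stage set is empty")
        for _, _, rep in rows:
            if rep < 1:
                raise DataValidationError("replicate numbers must be positive")
        self._rows = rows
        self.stages: tuple[str, ...] = tuple(stages)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, stages: Sequence[str] | None = None) -> "SampleDesign":
        required = {"sample_id", "stage", "replicate"}
        missing = required - set(frame.columns)
        if missing:
            raise DataValidationError(f"design table missing columns: {sorted(missing)}")
        return cls(
            zip(frame["sample_id"], frame["stage"], frame["replicate"]),
            stages=stages,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=["sample_id", "stage", "replicate"])

    @property
    def sample_ids(self) -> list[str]:
        return [r[0] for r in self._rows]

    def samples_for_stage(self, stage: str) -> list[str]:
        if stage not in self.stages:
            raise DataValidationError(f"unknown stage {stage!r}")
        return [r[0] for r in self._rows if r[1] == stage]

    def require_replicates(self, minimum: int = 2) -> None:
        """Ensure every stage has at least *minimum* replicates (for within-group stats)."""
        for stage in self.stages:
            n = len(self.samples_for_stage(stage))
            if 0 < n < minimum:
                raise DataValidationError(
                    f"stage {stage!r} has {n} replicate(s); at least {minimum} required"
                )

    def __len__(self) -> int:
        return len(self._rows)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SampleDesign)
            and self._rows == other._rows
            and self.stages == other.stages
        )

    def __repr__(self) -> str:
        return f"SampleDesign({len(self)} samples, stages={list(self.stages)})"


@dataclasses.dataclass(frozen=True)
class FeatureAnnotation:
    """Per-feature metadata: display name, compound class, KEGG-style pathway ids."""

    feature_id: str
    name: str = ""
    feature_class: str = ""
    pathway_ids: frozenset[str] = frozenset()


class AbundanceMatrix:
    """Features-by-samples matrix of non-negative measurements.

    ``values`` is a pandas DataFrame indexed by feature id with one column
    per sample, stored in design order.  ``annotations`` maps feature id to
    :class:`FeatureAnnotation`.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        design: SampleDesign,
        annotations: Mapping[str, FeatureAnnotation] | None = None,
    ) -> None:
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate feature ids: {dup}")
        missing = set(design.sample_ids) - set(values.columns)
        if missing:
            raise DataValidationError(f"design samples missing from table: {sorted(missing)}")
        # align by identifier, never by column position
        values = values.loc[:, design.sample_ids].copy()
        arr = values.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise DataValidationError(
                f"non-finite value at feature {values.index[bad[0]]!r}, "
                f"sample {values.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise DataValidationError(
                f"negative value at feature {values.index[bad[0]]!r}, "
                f"sample {values.columns[bad[1]]!r}"
            )
        self.values = values
        self.design = design
        if annotations is None:
            annotations = {}
        self.annotations: dict[str, FeatureAnnotation] = {
            fid: annotations.get(fid, FeatureAnnotation(feature_id=fid))
            for fid in values.index
        }

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def stage_values(self, stage: str) -> pd.DataFrame:
        return self.values.loc[:, self.design.samples_for_stage(stage)]

    def stage_means(self) -> pd.DataFrame:
        """Per-feature mean within each stage (columns ordered as design stages)."""
        return pd.DataFrame(
            {stage: self.stage_values(stage).mean(axis=1) for stage in self.design.stages}
        )

    def pathway_map(self) -> dict[str, frozenset[str]]:
        return {fid: ann.pathway_ids for fid, ann in self.annotations.items()}

    def subset(self, feature_ids: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.loc[list(feature_ids)],
            self.design,
            self.annotations,
        )

    def equals(self, other: "AbundanceMatrix") -> bool:
        return (
            self.design == other.design
            and self.values.equals(other.values)
            and self.annotations == other.annotations
        )

    def __repr__(self) -> str:
        return f"AbundanceMatrix({self.n_features} features x {self.n_samples} samples)"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_design(path: str | Path, stages: Sequence[str] | None = None) -> SampleDesign:
    """Read a sample-design table (columns sample_id, stage, replicate)."""
    frame = _read_tsv(path)
    try:
        frame["replicate"] = frame["replicate"].astype(int)
    except (KeyError, ValueError) as exc:
        raise DataValidationError(f"bad design table {path}: {exc}") from exc
    return SampleDesign.from_frame(frame, stages=stages)


def load_annotations(path: str | Path) -> dict[str, FeatureAnnotation]:
    """Read a feature-annotation table.

    Expected columns: ``feature_id``, ``name``, ``feature_class``,
    ``pathway_ids`` (semicolon-separated, possibly empty).
    """
    frame = _read_tsv(path)
    required = {"feature_id", "name", "feature_class", "pathway_ids"}
    missing = required - set(frame.columns)
    if missing:
        raise DataValidationError(f"annotation table missing columns: {sorted(missing)}")
    out: dict[str, FeatureAnnotation] = {}
    for row in frame.itertuples(index=False):
        fid = row.feature_id
        if fid in out:
            raise DataValidationError(f"duplicate feature id in annotations: {fid!r}")
        pids = frozenset(p for p in str(row.pathway_ids).split(";") if p)
        out[fid] = FeatureAnnotation(fid, row.name, row.feature_class, pids)
    return out


def load_abundance(
    path: str | Path,
    design: SampleDesign,
    annotations: Mapping[str, FeatureAnnotation] | None = None,
    feature_column: str = "feature_id",
) -> AbundanceMatrix:
    """Read an abundance table: one feature-id column then sample columns.

    Sample columns are aligned to ``design`` by identifier; extra columns
    (e.g. embedded annotation columns) are ignored.  Non-numeric or negative
    cells raise :class:`DataValidationError` naming the offending cell.
    """
    frame = _read_tsv(path)
    if feature_column not in frame.columns:
        raise DataValidationError(f"missing feature id column {feature_column!r} in {path}")
    dup = frame[feature_column][frame[feature_column].duplicated()].unique().tolist()
    if dup:
        raise DataValidationError(f"duplicate feature ids in {path}: {dup}")
    frame = frame.set_index(feature_column)
    missing = set(design.sample_ids) - set(frame.columns)
    if missing:
        raise DataValidationError(f"sample columns missing from {path}: {sorted(missing)}")
    values = frame.loc[:, design.sample_ids]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"non-numeric cell at feature {values.index[i]!r}, sample {values.columns[j]!r}"
        )
    return AbundanceMatrix(numeric.astype(float), design, annotations)


def load_pathway_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column (feature_id, pathway_id) map into a multimap."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["feature_id", "pathway_id"]:
                continue  # optional header
            if len(parts) != 2 or not all(parts):
                raise DataValidationError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            out.setdefault(parts[0], set()).add(parts[1])
    return {fid: frozenset(p) for fid, p in out.items()}


def write_pathway_map(pathway_map: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("feature_id\tpathway_id\n")
        for fid in sorted(pathway_map):
            for pid in sorted(pathway_map[fid]):
                handle.write(f"{fid}\t{pid}\n")


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a stable column order (as given)."""
    records.to_csv(path, sep="\t", index=False)


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.insert(0, "feature_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def write_annotations(annotations: Mapping[str, FeatureAnnotation], path: str | Path) -> None:
    rows = [
        {
            "feature_id": ann.feature_id,
            "name": ann.name,
            "feature_class": ann.feature_class,
            "pathway_ids": ";".join(sorted(ann.pathway_ids)),
        }
        for ann in annotations.values()
    ]
    pd.DataFrame(rows, columns=["feature_id", "name", "feature_class", "pathway_ids"]).to_csv(
        path, sep="\t", index=False
    )


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)
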