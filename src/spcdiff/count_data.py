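"""Spectral-count matrices, group designs, pooling and group summaries.

The central object is the :class:`CountMatrix`: a non-negative integer
matrix of spectral counts with rows indexed by proteins and columns by
(biological sample, technical replicate) pairs, plus a :class:`GroupDesign`
mapping every column to one of two comparison groups.  Technical
replicates are pooled by summation before any statistics; per-protein
sufficient statistics live in :class:`ProteinGroupSummary`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DesignError,
    FormatError,
    ParameterError,
    ReconciliationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

META_COLUMNS = ["entry_name", "gene_id", "description", "length_aa"]


@dataclass(frozen=True)
class ProteinMeta:
    """Identity and annotation of one protein row.

    ``entry_name`` is the primary key (UniProtKB entry-name stem style,
    e.g. ``TXND5``); ``length_aa`` is the sequence length in amino acids
    and may be ``None`` when unknown.
    """

    entry_name: str
    gene_id: str = ""
    description: str = ""
    length_aa: int | None = None

    def __post_init__(self) -> None:
        if not self.entry_name:
            raise ValidationError("protein entry_name must be non-empty")
        if self.length_aa is not None and self.length_aa < 1:
            raise ValidationError(
                f"{self.entry_name}: length_aa must be >= 1, got {self.length_aa}"
            )


@dataclass(frozen=True)
class DesignColumn:
    """One column of the count matrix: a single injection of one sample."""

    column_id: str
    sample_id: str
    replicate: int
    group: str

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"column {self.column_id}: replicate index must be >= 1"
            )


@dataclass(frozen=True)
class GroupDesign:
    """Mapping of matrix columns to samples and to the two groups.

    ``control_label`` designates the control group (A); the other label is
    the case group (B).  ``n_control``/``n_case`` count distinct biological
    samples, not columns.
    """

    columns: tuple[DesignColumn, ...]
    control_label: str

    def __post_init__(self) -> None:
        labels = sorted({c.group for c in self.columns})
        if len(labels) != 2:
            raise DesignError(f"exactly two group labels required, got {labels}")
        if self.control_label not in labels:
            raise DesignError(
                f"control label {self.control_label!r} not among groups {labels}"
            )
        ids = [c.column_id for c in self.columns]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate column_id in design")
        sample_group: dict[str, str] = {}
        for c in self.columns:
            prev = sample_group.setdefault(c.sample_id, c.group)
            if prev != c.group:
                raise DesignError(
                    f"sample {c.sample_id} assigned to both {prev} and {c.group}"
                )

    @property
    def case_label(self) -> str:
        (other,) = {c.group for c in self.columns} - {self.control_label}
        return other

    @property
    def column_ids(self) -> list[str]:
        return [c.column_id for c in self.columns]

    def samples(self, group: str) -> list[str]:
        """Distinct sample ids of one group, in lexicographic order."""
        return sorted({c.sample_id for c in self.columns if c.group == group})

    @property
    def n_control(self) -> int:
        return len(self.samples(self.control_label))

    @property
    def n_case(self) -> int:
        return len(self.samples(self.case_label))

    def canonical_order(self) -> list[int]:
        """Column permutation: control samples first, then case, each by
        sample_id then replicate index."""
        rank = {self.control_label: 0, self.case_label: 1}
        idx = sorted(
            range(len(self.columns)),
            key=lambda i: (
                rank[self.columns[i].group],
                self.columns[i].sample_id,
                self.columns[i].replicate,
            ),
        )
        return idx


@dataclass(frozen=True)
class CountMatrix:
    """Protein x column spectral-count matrix with its design."""

    proteins: tuple[ProteinMeta, ...]
    design: GroupDesign
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.shape != (len(self.proteins), len(self.design.columns)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.proteins)} proteins x {len(self.design.columns)} columns"
            )
        if counts.size and counts.min() < 0:
            r, c = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at protein {self.proteins[r].entry_name!r}, "
                f"column {self.design.columns[c].column_id!r}"
            )
        names = [p.entry_name for p in self.proteins]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate protein entry_name")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def entry_names(self) -> list[str]:
        return [p.entry_name for p in self.proteins]

    def canonicalized(self) -> "CountMatrix":
        """Columns reordered to (control samples, case samples)."""
        order = self.design.canonical_order()
        cols = tuple(self.design.columns[i] for i in order)
        return CountMatrix(
            proteins=self.proteins,
            design=replace(self.design, columns=cols),
            counts=self.counts[:, order],
        )


@dataclass(frozen=True)
class ProteinGroupSummary:
    """Sufficient statistics of one protein for the two-group tests.

    ``n_a``/``n_b`` are pooled spectral counts (summed over samples and
    replicates) in the control/case group; ``d_a``/``d_b`` the number of
    biological samples in which the protein is detected; ``t_a``/``t_b``
    the comparison-wide group count totals over all proteins; ``cap_n_a``/
    ``cap_n_b`` the biological sample sizes.
    """

    entry_name: str
    n_a: int
    n_b: int
    d_a: int
    d_b: int
    t_a: int
    t_b: int
    cap_n_a: int
    cap_n_b: int

    def __post_init__(self) -> None:
        if not (0 <= self.d_a <= self.cap_n_a and 0 <= self.d_b <= self.cap_n_b):
            raise ValidationError(
                f"{self.entry_name}: detection counts outside [0, N]"
            )
        if self.n_a > self.t_a or self.n_b > self.t_b:
            raise ValidationError(
                f"{self.entry_name}: pooled count exceeds group total"
            )
        for d, n, g in ((self.d_a, self.n_a, "A"), (self.d_b, self.n_b, "B")):
            if (d == 0) != (n == 0):
                raise ValidationError(
                    f"{self.entry_name}: group {g} has d={d} but n={n}"
                )

    @property
    def observed(self) -> bool:
        return self.n_a + self.n_b > 0


# ---------------------------------------------------------------------------
# I/O: counts TSV + design TSV
# ---------------------------------------------------------------------------

def read_count_matrix(
    counts_path: str | Path,
    design_path: str | Path,
    control_label: str,
) -> CountMatrix:
    """Read a counts TSV and its companion design TSV.

    The counts file has header ``entry_name  gene_id  description
    length_aa  <column_id>...`` (tab-separated); the design file has header
    ``column_id  sample_id  replicate  group``.  Column order of the
    returned matrix follows the design file.  Missing cells are rejected.
    """
    counts_path, design_path = Path(counts_path), Path(design_path)
    design_df = pd.read_csv(design_path, sep="\t", dtype=str)
    expected = ["column_id", "sample_id", "replicate", "group"]
    if list(design_df.columns) != expected:
        raise FormatError(
            f"{design_path}: design header must be {expected}, "
            f"got {list(design_df.columns)}"
        )
    try:
        reps = design_df["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{design_path}: non-integer replicate index") from exc
    columns = tuple(
        DesignColumn(row.column_id, row.sample_id, rep, row.group)
        for row, rep in zip(design_df.itertuples(index=False), reps)
    )
    design = GroupDesign(columns=columns, control_label=control_label)

    df = pd.read_csv(counts_path, sep="\t", dtype=str)
    if list(df.columns[:4]) != META_COLUMNS:
        raise FormatError(
            f"{counts_path}: first four header fields must be {META_COLUMNS}, "
            f"got {list(df.columns[:4])}"
        )
    file_cols = list(df.columns[4:])
    want = design.column_ids
    missing = [c for c in want if c not in file_cols]
    extra = [c for c in file_cols if c not in want]
    if missing or extra:
        raise ReconciliationError(
            f"column mismatch between {counts_path} and {design_path}: "
            f"missing from counts file {missing}, not in design {extra}"
        )

    proteins = []
    for row in df.itertuples(index=False):
        length = None
        raw_len = getattr(row, "length_aa")
        if isinstance(raw_len, str) and raw_len != "":
            try:
                length = int(raw_len)
            except ValueError as exc:
                raise ValidationError(
                    f"{counts_path}: non-integer length_aa for {row.entry_name!r}"
                ) from exc
        proteins.append(
            ProteinMeta(
                entry_name=row.entry_name,
                gene_id="" if pd.isna(row.gene_id) else str(row.gene_id),
                description="" if pd.isna(row.description) else str(row.description),
                length_aa=length,
            )
        )

    raw = df[want]
    if raw.isna().any().any():
        r, c = next(zip(*np.where(raw.isna().to_numpy())))
        raise ValidationError(
            f"{counts_path}: missing count at row {proteins[r].entry_name!r}, "
            f"column {want[c]!r} (no imputation)"
        )
    try:
        counts = raw.astype(np.int64).to_numpy()
    except ValueError:
        for c in want:
            for i, v in enumerate(raw[c]):
                try:
                    int(v)
                except ValueError:
                    raise ValidationError(
                        f"{counts_path}: non-integer count {v!r} at row "
                        f"{proteins[i].entry_name!r}, column {c!r}"
                    ) from None
        raise
    if counts.size and counts.min() < 0:
        r, c = np.argwhere(counts < 0)[0]
        raise ValidationError(
            f"{counts_path}: negative count at row {proteins[r].entry_name!r}, "
            f"column {want[c]!r}"
        )
    return CountMatrix(proteins=tuple(proteins), design=design, counts=counts)


def write_count_matrix(
    matrix: CountMatrix,
    counts_path: str | Path,
    design_path: str | Path,
) -> None:
    """Write the counts/design TSV pair; ``read_count_matrix`` of the
    output reproduces the matrix exactly."""
    if matrix.n_proteins == 0:
        raise ValidationError("refusing to write an empty matrix")
    counts_path, design_path = Path(counts_path), Path(design_path)

    with open(design_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("column_id\tsample_id\treplicate\tgroup\n")
        for c in matrix.design.columns:
            fh.write(f"{c.column_id}\t{c.sample_id}\t{c.replicate}\t{c.group}\n")

    with open(counts_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(META_COLUMNS + matrix.design.column_ids) + "\n")
        for p, row in zip(matrix.proteins, matrix.counts):
            length = "" if p.length_aa is None else str(p.length_aa)
            cells = [p.entry_name, p.gene_id, p.description, length]
            cells += [str(int(v)) for v in row]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Pooling, summaries, Venn partition
# ---------------------------------------------------------------------------

def pool_replicates(matrix: CountMatrix) -> CountMatrix:
    """Sum technical-replicate columns within each biological sample.

    Returns a matrix with one column per sample (replicate index 1),
    columns in canonical order (control samples first).  Total counts are
    conserved exactly.
    """
    canon = matrix.canonicalized()
    design = canon.design
    pooled_cols: list[DesignColumn] = []
    pooled_counts: list[np.ndarray] = []
    for group in (design.control_label, design.case_label):
        for sample in design.samples(group):
            idx = [
                i
                for i, c in enumerate(design.columns)
                if c.sample_id == sample
            ]
            pooled_cols.append(
                DesignColumn(
                    column_id=sample, sample_id=sample, replicate=1, group=group
                )
            )
            pooled_counts.append(canon.counts[:, idx].sum(axis=1))
    return CountMatrix(
        proteins=canon.proteins,
        design=GroupDesign(
            columns=tuple(pooled_cols), control_label=design.control_label
        ),
        counts=np.column_stack(pooled_counts),
    )


def summarize_groups(
    pooled: CountMatrix, detection_threshold: int = 1
) -> list[ProteinGroupSummary]:
    """Per-protein pooled counts, detection counts and group totals.

    ``pooled`` must have one column per biological sample (run
    :func:`pool_replicates` first).  A protein is detected in a sample when
    its pooled count there is >= ``detection_threshold``.
    """
    if detection_threshold < 1:
        raise ParameterError(
            f"detection_threshold must be >= 1, got {detection_threshold}"
        )
    design = pooled.design
    sample_ids = [c.sample_id for c in design.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(
            "matrix has replicate columns; pool_replicates must run first"
        )
    mask_a = np.array([c.group == design.control_label for c in design.columns])
    mask_b = ~mask_a
    counts = pooled.counts
    n_a = counts[:, mask_a].sum(axis=1)
    n_b = counts[:, mask_b].sum(axis=1)
    d_a = (counts[:, mask_a] >= detection_threshold).sum(axis=1)
    d_b = (counts[:, mask_b] >= detection_threshold).sum(axis=1)
    t_a, t_b = int(n_a.sum()), int(n_b.sum())
    return [
        ProteinGroupSummary(
            entry_name=p.entry_name,
            n_a=int(na),
            n_b=int(nb),
            d_a=int(da),
            d_b=int(db),
            t_a=t_a,
            t_b=t_b,
            cap_n_a=design.n_control,
            cap_n_b=design.n_case,
        )
        for p, na, nb, da, db in zip(pooled.proteins, n_a, n_b, d_a, d_b)
    ]


@dataclass(frozen=True)
class VennPartition:
    """Group-presence partition of the observed proteins."""

    unique_to_a: tuple[str, ...]
    shared: tuple[str, ...]
    unique_to_b: tuple[str, ...]
    never_observed: tuple[str, ...]

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "unique_to_a": len(self.unique_to_a),
            "shared": len(self.shared),
            "unique_to_b": len(self.unique_to_b),
        }


def venn_partition(summaries: Sequence[ProteinGroupSummary]) -> VennPartition:
    """Partition proteins by group presence: observed only in the control
    group (A), only in the case group (B), or in both.

    Never-observed proteins (zero counts in both groups) are excluded from
    the three sets and reported separately (with a log message).
    """
    only_a, shared, only_b, never = [], [], [], []
    for s in summaries:
        if s.n_a > 0 and s.n_b > 0:
            shared.append(s.entry_name)
        elif s.n_a > 0:
            only_a.append(s.entry_name)
        elif s.n_b > 0:
            only_b.append(s.entry_name)
        else:
            never.append(s.entry_name)
    if never:
        logger.info(
            "%d protein(s) never observed in either group; excluded from "
            "the presence partition",
            len(never),
        )
    return VennPartition(
        unique_to_a=tuple(only_a),
        shared=tuple(shared),
        unique_to_b=tuple(only_b),
        never_observed=tuple(never),
    )
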