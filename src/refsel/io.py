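"""Reading, normalizing and annotating expression matrices.

An expression matrix is held as a :class:`pandas.DataFrame` with one row per
gene (unique gene or probe identifiers as the index) and one column per
sample.  Cohort membership is carried separately in :class:`CohortLabels`:
every sample belongs to one of three groups (``responder``, ``nonresponder``,
``control``) and the binary class vector ``y`` — non-responder = 0,
responder = 1 — is defined over the patient samples only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, FormatError

GROUP_RESPONDER = "responder"
GROUP_NONRESPONDER = "nonresponder"
GROUP_CONTROL = "control"
VALID_GROUPS = (GROUP_RESPONDER, GROUP_NONRESPONDER, GROUP_CONTROL)

#: Fixed class encoding for the binary response problem.
CLASS_ENCODING = {GROUP_NONRESPONDER: 0, GROUP_RESPONDER: 1}

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


@dataclass(frozen=True)
class CohortLabels:
    """Per-sample group membership plus the binary patient class vector.

    Attributes
    ----------
    groups:
        Series mapping sample identifier -> group token, in sample order.
    y:
        Series of 0/1 class labels over the patient (non-control) samples
        only, in the same relative order as ``groups``.
    """

    groups: pd.Series
    y: pd.Series = field(init=False, compare=False)

    def __post_init__(self):
        bad = sorted(set(self.groups) - set(VALID_GROUPS))
        if bad:
            raise FormatError(f"unknown group token(s): {bad}; expected one of {VALID_GROUPS}")
        patients = self.groups[self.groups != GROUP_CONTROL]
        y = patients.map(CLASS_ENCODING).astype(int)
        object.__setattr__(self, "y", y)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.y.index)

    @property
    def control_ids(self) -> list[str]:
        return list(self.groups.index[self.groups == GROUP_CONTROL])


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples expression table.

    Parameters
    ----------
    path:
        Tab-separated file; first column gene identifiers, header row of
        sample identifiers.
    dialect:
        ``"tsv"`` for a plain table, or ``"series_matrix"`` for the GEO
        series-matrix layout where metadata lines are prefixed with ``!``
        and the expression table sits between the table-begin/end markers.
    """
    if dialect not in ("tsv", "series_matrix"):
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    raw = path.read_text().splitlines()

    if dialect == "series_matrix":
        numbered = _series_matrix_table_lines(raw)
    else:
        numbered = [(i, ln) for i, ln in enumerate(raw, start=1) if ln.strip()]
    if not numbered:
        raise FormatError(f"{path}: no table content found")

    header_no, header = numbered[0]
    cols = _split_fields(header, dialect)
    sample_ids = cols[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample identifiers: {dupes}")

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in numbered[1:]:
        fields = _split_fields(line, dialect)
        if len(fields) != len(cols):
            raise FormatError(
                f"{path}: ragged row at line {lineno}: expected {len(cols)} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0])
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value at line {lineno}: {exc}") from None

    seen: dict[str, int] = {}
    dupes = []
    for g in gene_ids:
        seen[g] = seen.get(g, 0) + 1
        if seen[g] == 2:
            dupes.append(g)
    if dupes:
        raise FormatError(f"{path}: duplicate gene identifiers: {sorted(dupes)}")

    return pd.DataFrame(np.asarray(rows, dtype=float), index=gene_ids, columns=sample_ids)


def _series_matrix_table_lines(raw: list[str]) -> list[tuple[int, str]]:
    """Select the expression-table lines of a series-matrix file.

    Lines between the begin/end markers are used when the markers are
    present; otherwise all non-metadata (non-``!``) lines are taken.
    """
    lines = [(i, ln) for i, ln in enumerate(raw, start=1)]
    begins = [i for i, (_, ln) in enumerate(lines) if ln.strip().lower() == _TABLE_BEGIN]
    ends = [i for i, (_, ln) in enumerate(lines) if ln.strip().lower() == _TABLE_END]
    if begins and ends:
        lines = lines[begins[0] + 1 : ends[0]]
    return [(n, ln) for n, ln in lines if ln.strip() and not ln.startswith("!")]


def _split_fields(line: str, dialect: str) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if dialect == "series_matrix":
        # GEO series-matrix tables quote identifiers.
        fields = [f.strip('"') for f in fields]
    return fields


def read_labels(path: str | Path) -> CohortLabels:
    """Read a two-column (sample_id, group) tab-separated label table."""
    path = Path(path)
    ids: list[str] = []
    groups: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].lower() in ("sample_id", "sample"):
            continue
        if len(fields) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
        ids.append(fields[0])
        groups.append(fields[1])
    return encode_labels(dict(zip(ids, groups)), ids)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (probe_id, gene_id) tab-separated mapping table."""
    path = Path(path)
    pm: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].lower() in ("probe_id", "probe"):
            continue
        if len(fields) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
        if fields[0] in pm:
            raise FormatError(f"{path}: duplicate probe identifier {fields[0]!r} at line {lineno}")
        pm[fields[0]] = fields[1]
    return pm


def zscore_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene row: mean 0, population (n-denominator) sd 1.

    Constant rows carry no between-sample information; they are mapped to
    all-zeros (rather than dropped, so feature indices stay stable) and a
    warning lists how many were affected.
    """
    if matrix.shape[1] < 2:
        raise ConsistencyError("z-score normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0.0
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    out = (values - mean) / safe_sd
    if constant.any():
        ids = list(matrix.index[constant])
        shown = ids[:10] + (["..."] if len(ids) > 10 else [])
        warnings.warn(
            f"{constant.sum()} constant gene row(s) zeroed during z-scoring: {shown}",
            UserWarning,
            stacklevel=2,
        )
        out[constant] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def encode_labels(groups: Mapping[str, str] | pd.Series, sample_ids: Iterable[str]) -> CohortLabels:
    """Build :class:`CohortLabels` for ``sample_ids`` from a group mapping.

    Controls are retained in ``groups`` but excluded from the class vector
    ``y``, which follows the fixed encoding non-responder = 0, responder = 1.
    """
    sample_ids = list(sample_ids)
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ConsistencyError(f"samples missing from the label table: {missing}")
    ordered = pd.Series([groups[s] for s in sample_ids], index=sample_ids, name="group")
    return CohortLabels(groups=ordered)


def map_probes(
    matrix: pd.DataFrame, pm: Mapping[str, str], unmapped_policy: str = "keep"
) -> pd.DataFrame:
    """Replace probe row identifiers with gene identifiers.

    Unmapped rows are kept under their original identifier or dropped,
    depending on ``unmapped_policy``.  When two rows map to the same gene
    both are kept, disambiguated with ``.1``, ``.2`` ... suffixes in row
    order, and the collision is reported as a warning.  Values are never
    reordered or altered.
    """
    if unmapped_policy not in ("keep", "drop"):
        raise ConsistencyError(f"unmapped_policy must be 'keep' or 'drop', got {unmapped_policy!r}")
    if unmapped_policy == "drop":
        keep_mask = [g in pm for g in matrix.index]
        matrix = matrix.loc[keep_mask]
    new_ids = [pm.get(g, g) for g in matrix.index]

    counts: dict[str, int] = {}
    for g in new_ids:
        counts[g] = counts.get(g, 0) + 1
    collisions = sorted(g for g, c in counts.items() if c > 1)
    if collisions:
        warnings.warn(
            f"probe mapping collisions for gene(s) {collisions}; rows kept with numeric suffixes",
            UserWarning,
            stacklevel=2,
        )
        running: dict[str, int] = {}
        disambiguated = []
        for g in new_ids:
            if counts[g] > 1:
                running[g] = running.get(g, 0) + 1
                disambiguated.append(f"{g}.{running[g]}")
            else:
                disambiguated.append(g)
        new_ids = disambiguated

    out = matrix.copy()
    out.index = new_ids
    return out
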