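"""Expression-study containers, table IO, comparison selection and quantile normalization.

The experimental unit is a bilateral (two-arm) human study: each subject
contributes a pair of muscle samples, one from the exercised arm and one from
the resting control arm, taken at a single recovery time point (4 h or 24 h
post-exercise).  Expression values are log2-scale probe intensities from a
pre-summarized array matrix.  This module owns

* :class:`ExpressionStudy` — the probes x samples matrix plus per-sample
  design annotations (subject, sex, arm, time);
* :class:`Comparison` — a named paired or unpaired two-group contrast defined
  by predicates over the design columns;
* TSV readers/writers for the expression matrix and the design table;
* :func:`quantile_normalize` — forces every column onto the common
  distribution of across-column mean order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

SEXES = ("M", "F")
ARMS = ("exercised", "control")
TIMES = ("baseline", "4h", "24h")
DESIGN_COLUMNS = ("subject_id", "sex", "arm", "time")

__all__ = [
    "ExpressionStudy",
    "Comparison",
    "FormatError",
    "ConsistencyError",
    "DEFAULT_COMPARISONS",
    "read_expression_table",
    "write_expression_table",
    "read_design_table",
    "write_design_table",
    "quantile_normalize",
    "log2p1",
]


class FormatError(ValueError):
    """A file violates the declared tabular format."""


class ConsistencyError(ValueError):
    """Expression matrix and design table disagree, or a design invariant fails."""


def _check_selector(selector: Mapping[str, object]) -> dict[str, tuple[str, ...]]:
    out = {}
    for key, allowed in selector.items():
        if key not in DESIGN_COLUMNS:
            raise KeyError(f"unknown design column in selector: {key!r}")
        if isinstance(allowed, str):
            allowed = (allowed,)
        out[key] = tuple(allowed)
    return out


def _selector_mask(design: pd.DataFrame, selector: Mapping[str, object]) -> pd.Series:
    mask = pd.Series(True, index=design.index)
    for key, allowed in _check_selector(selector).items():
        mask &= design[key].isin(allowed)
    return mask


@dataclass
class ExpressionStudy:
    """log2 expression matrix (probes x samples) plus per-sample design records.

    ``values``: DataFrame indexed by probe id with one column per sample id.
    ``design``: DataFrame indexed by sample id with columns
    ``subject_id, sex, arm, time``.  Invariants (checked at construction):
    unique probe and sample ids, finite values, every sample annotated, and
    at most one sample per (subject, arm, time).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        v, d = self.values, self.design
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate probe id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if d.index.has_duplicates:
            dup = d.index[d.index.duplicated()][0]
            raise ConsistencyError(f"duplicate sample id in design: {dup!r}")
        arr = v.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            raise FormatError("expression matrix contains non-finite values")
        missing = [s for s in v.columns if s not in d.index]
        if missing:
            raise ConsistencyError(
                f"samples present in expression but absent from design: {missing[:5]}"
            )
        for col in DESIGN_COLUMNS:
            if col not in d.columns:
                raise FormatError(f"design table missing column {col!r}")
        bad_sex = set(d["sex"]) - set(SEXES)
        if bad_sex:
            raise FormatError(f"invalid sex value(s) {sorted(bad_sex)}; allowed: {SEXES}")
        bad_arm = set(d["arm"]) - set(ARMS)
        if bad_arm:
            raise FormatError(f"invalid arm value(s) {sorted(bad_arm)}; allowed: {ARMS}")
        bad_time = set(d["time"]) - set(TIMES)
        if bad_time:
            raise FormatError(f"invalid time value(s) {sorted(bad_time)}; allowed: {TIMES}")
        counts = d.groupby(["subject_id", "arm", "time"], sort=False).size()
        clashes = counts[counts > 1]
        if len(clashes):
            subj, arm, time = clashes.index[0]
            raise ConsistencyError(
                f"subject {subj!r} has {clashes.iloc[0]} samples for arm={arm!r}, time={time!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_matching(self, selector: Mapping[str, object]) -> list[str]:
        """Sample ids whose design record satisfies every selector predicate."""
        d = self.design.loc[list(self.values.columns)]
        return list(d.index[_selector_mask(d, selector)])


@dataclass(frozen=True)
class Comparison:
    """A named two-group contrast over the design.

    ``mode`` is ``"paired"`` (within-subject case minus reference, e.g.
    exercised vs control arm) or ``"unpaired"`` (two independent groups, e.g.
    male vs female control arms).  Selectors are mappings from design columns
    to an allowed value or collection of values; case and reference selections
    must be disjoint.
    """

    name: str
    mode: str
    case_selector: Mapping[str, object]
    reference_selector: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.mode not in ("paired", "unpaired"):
            raise ValueError(f"mode must be 'paired' or 'unpaired', got {self.mode!r}")
        _check_selector(self.case_selector)
        _check_selector(self.reference_selector)

    def select(self, study: ExpressionStudy) -> tuple[list[str], list[str]]:
        """Case and reference sample ids, validated for this mode."""
        case = study.samples_matching(self.case_selector)
        ref = study.samples_matching(self.reference_selector)
        overlap = set(case) & set(ref)
        if overlap:
            raise ConsistencyError(
                f"comparison {self.name!r}: selectors overlap on {sorted(overlap)[:5]}"
            )
        if self.mode == "paired":
            pairs = self.paired_samples(study)
            if len(pairs) < 2:
                raise ConsistencyError(
                    f"comparison {self.name!r}: paired mode requires >=2 complete "
                    f"subject pairs, found {len(pairs)}"
                )
        else:
            if len(case) < 2 or len(ref) < 2:
                raise ConsistencyError(
                    f"comparison {self.name!r}: unpaired mode requires >=2 samples "
                    f"per group, found {len(case)} vs {len(ref)}"
                )
        return case, ref

    def paired_samples(self, study: ExpressionStudy) -> list[tuple[str, str]]:
        """(case_sample, reference_sample) per subject with both sides present.

        Subjects missing either side (e.g. a failed array) are silently
        dropped; asymmetry is expressed by omission from the design.
        """
        if self.mode != "paired":
            raise ValueError("paired_samples is only defined for paired comparisons")
        d = study.design
        case = study.samples_matching(self.case_selector)
        ref = study.samples_matching(self.reference_selector)
        by_subject_case = {d.loc[s, "subject_id"]: s for s in case}
        by_subject_ref = {d.loc[s, "subject_id"]: s for s in ref}
        subjects = sorted(set(by_subject_case) & set(by_subject_ref))
        return [(by_subject_case[s], by_subject_ref[s]) for s in subjects]


#: The five-contrast template of the bilateral study: a resting-state
#: male-vs-female comparison on control arms (all biopsy times pooled) and
#: four within-subject exercised-vs-control comparisons, one per sex x time.
DEFAULT_COMPARISONS: tuple[Comparison, ...] = (
    Comparison(
        "baseline_m_vs_f",
        "unpaired",
        {"sex": "M", "arm": "control"},
        {"sex": "F", "arm": "control"},
    ),
    Comparison(
        "male_4h", "paired",
        {"sex": "M", "time": "4h", "arm": "exercised"},
        {"sex": "M", "time": "4h", "arm": "control"},
    ),
    Comparison(
        "male_24h", "paired",
        {"sex": "M", "time": "24h", "arm": "exercised"},
        {"sex": "M", "time": "24h", "arm": "control"},
    ),
    Comparison(
        "female_4h", "paired",
        {"sex": "F", "time": "4h", "arm": "exercised"},
        {"sex": "F", "time": "4h", "arm": "control"},
    ),
    Comparison(
        "female_24h", "paired",
        {"sex": "F", "time": "24h", "arm": "exercised"},
        {"sex": "F", "time": "24h", "arm": "control"},
    ),
)


# ---------------------------------------------------------------------------
# Table IO (TSV, UTF-8, LF, full double precision)
# ---------------------------------------------------------------------------

def read_expression_table(path) -> pd.DataFrame:
    """Read a probes x samples TSV: first column probe ids, header sample ids."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expression table needs a probe-id column and >=1 sample")
    sample_ids = header[1:]
    dup = pd.Index(sample_ids)
    if dup.has_duplicates:
        raise FormatError(f"{path}: duplicate sample id {dup[dup.duplicated()][0]!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, encoding="utf-8",
                     float_precision="round_trip")
    df.columns = sample_ids
    if df.index.has_duplicates:
        bad = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe id {bad!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[coerced.isna()]
            probe = bad_rows[0]
            raise FormatError(
                f"{path}: non-numeric value {df.loc[probe, col]!r} at "
                f"row (probe) {probe!r}, column (sample) {col!r}"
            )
    return df.astype(float)


def write_expression_table(values: pd.DataFrame, path) -> None:
    values.to_csv(
        path, sep="\t", index_label="probe_id",
        float_format="%.17g", lineterminator="\n", encoding="utf-8",
    )


def read_design_table(path, expression: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read the per-sample design TSV (sample_id, subject_id, sex, arm, time).

    When ``expression`` is given, every expression sample must be annotated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    required = ("sample_id",) + DESIGN_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: design table missing column(s) {missing}")
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate sample id {df.index[df.index.duplicated()][0]!r}")
    for col, allowed in (("sex", SEXES), ("arm", ARMS), ("time", TIMES)):
        bad = set(df[col]) - set(allowed)
        if bad:
            raise FormatError(
                f"{path}: invalid {col} value(s) {sorted(bad)}; allowed: {allowed}"
            )
    if expression is not None:
        absent = [s for s in expression.columns if s not in df.index]
        if absent:
            raise ConsistencyError(
                f"{path}: sample(s) in expression but absent from design: {absent[:5]}"
            )
    counts = df.groupby(["subject_id", "arm", "time"], sort=False).size()
    clashes = counts[counts > 1]
    if len(clashes):
        subj, arm, time = clashes.index[0]
        raise ConsistencyError(
            f"{path}: subject {subj!r} has multiple samples for arm={arm!r}, time={time!r}"
        )
    return df[list(DESIGN_COLUMNS)]


def write_design_table(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id",
                  lineterminator="\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean of the across-column order statistics.

    Every output column holds the same multiset of values: position i of the
    sorted column becomes the across-column mean of the i-th order statistics.
    Ties within a column receive the mean of the target order statistics over
    their rank span (average-rank convention), which makes the map
    deterministic; on tie-free input the operation is idempotent and the
    column distributions are exactly equal.
    """
    if values.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("quantile normalization requires finite values")
    sorted_vals = np.sort(arr, axis=0)
    mu = sorted_vals.mean(axis=1)
    # rows whose order statistics already agree across columns keep their
    # value exactly (mean of identical floats is that float), which makes
    # the operation exactly idempotent
    same = (sorted_vals == sorted_vals[:, :1]).all(axis=1)
    mu[same] = sorted_vals[same, 0]
    csum = np.concatenate(([0.0], np.cumsum(mu)))
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        rmin = rankdata(col, method="min").astype(np.intp)   # 1-based
        rmax = rankdata(col, method="max").astype(np.intp)
        out[:, j] = mu[rmin - 1]
        span = rmax > rmin
        if span.any():
            out[span, j] = (csum[rmax[span]] - csum[rmin[span] - 1]) / (
                rmax[span] - rmin[span] + 1
            )
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log2p1(values: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) transform for raw-scale input matrices."""
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("log2p1 requires non-negative input")
    return pd.DataFrame(np.log2(arr + 1.0), index=values.index, columns=values.columns)
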