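"""Delimited-text input/output and analysis configuration.

Input tables are CSV/TSV with a header, one row per observational unit
(a ``--transpose`` option accommodates loci-by-samples methylation
matrices), one column holding the two-level group label and the
remaining selected columns holding numeric coordinates such as
methylation beta-values.  Results are written as tidy delimited tables
that round-trip through ``pandas`` losslessly to 12 significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .closure import ClosedTestResult
from .ranks import TwoGroupSample
from .wald import TestResult

__all__ = ["DataError", "AnalysisConfig", "read_table", "write_results"]

logger = logging.getLogger("releff")


class DataError(ValueError):
    """A problem with user-supplied data (file contents, labels, shapes)."""


@dataclass
class AnalysisConfig:
    """Everything needed to turn a delimited file into a TwoGroupSample.

    ``group_a`` names the label mapped to group A — the reference of the
    relative effect p_AB; swapping it flips p_hat around 1/2, so the
    mapping is logged explicitly.
    """

    group_column: str = "group"
    group_a: str | None = None
    coordinates: list[str] = field(default_factory=list)
    sep: str = ","
    transpose: bool = False


def read_table(path, cfg: AnalysisConfig) -> TwoGroupSample:
    """Parse and validate a delimited file into a TwoGroupSample.

    Rows with missing values in the selected coordinates are dropped
    with a logged count; fewer than two units per group, more than two
    group levels or non-numeric coordinates raise :class:`DataError`
    naming the offending column or labels.
    """
    frame = pd.read_csv(path, sep=cfg.sep)
    if cfg.transpose:
        frame = frame.set_index(frame.columns[0]).T.reset_index(names="unit")
    if cfg.group_column not in frame.columns:
        raise DataError(f"group column {cfg.group_column!r} not found in {path}")
    raw_groups = frame[cfg.group_column].astype(str)
    levels = sorted(raw_groups.unique())
    if len(levels) != 2:
        raise DataError(
            f"group column {cfg.group_column!r} must have exactly 2 levels, got {levels}"
        )
    label_a = cfg.group_a if cfg.group_a is not None else levels[0]
    if label_a not in levels:
        raise DataError(f"group-A label {label_a!r} not among levels {levels}")
    logger.info("group A (reference of p_AB) = %r; group B = %r", label_a,
                [l for l in levels if l != label_a][0])

    coords = cfg.coordinates or [
        c for c in frame.columns if c not in (cfg.group_column, "unit")
    ]
    missing_cols = [c for c in coords if c not in frame.columns]
    if missing_cols:
        raise DataError(f"selected coordinates not in file: {missing_cols}")
    values = frame[coords].apply(pd.to_numeric, errors="coerce")
    bad = values.columns[values.isna().all(axis=0)]
    if len(bad):
        raise DataError(f"non-numeric coordinate columns: {list(bad)}")
    keep = values.notna().all(axis=1)
    if (~keep).any():
        logger.warning("dropping %d row(s) with missing values", int((~keep).sum()))
    values = values[keep]
    group = np.where(raw_groups[keep] == label_a, "A", "B")
    if min((group == "A").sum(), (group == "B").sum()) < 2:
        raise DataError("fewer than 2 complete units in a group after filtering")
    return TwoGroupSample(values.to_numpy(float), group, tuple(coords))


def results_frame(result) -> pd.DataFrame:
    """Tidy DataFrame view of a test result (single-row or per-coordinate)."""
    if isinstance(result, ClosedTestResult):
        names = result.coord_names or tuple(f"c{j+1}" for j in range(len(result.adjusted_p)))
        raw = [result.subset_p[(j,)] for j in range(len(names))]
        return pd.DataFrame(
            {
                "coordinate": names,
                "p_raw": raw,
                "p_adjusted": result.adjusted_p,
                "rejected": result.rejected,
            }
        )
    if isinstance(result, TestResult):
        return pd.DataFrame(
            [
                {
                    "statistic": result.statistic,
                    "effective_df": result.effective_df,
                    "p_asymptotic": result.p_asymptotic,
                    "p_permutation": result.p_permutation,
                    "stat_family": result.stat_family,
                    "calibration": result.calibration,
                }
            ]
        )
    if isinstance(result, (list, pd.DataFrame)):  # experiment grid rows
        return pd.DataFrame(result)
    raise DataError(f"cannot serialize result of type {type(result).__name__}")


def write_results(result, path, sep: str = ",") -> None:
    """Write a result table as delimited text, 12 significant digits."""
    results_frame(result).to_csv(path, sep=sep, index=False, float_format="%.12g")
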