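"""Linked-cohort data structures, validation and delimited-text I/O.

The central object is :class:`LinkedCohort`: one row per census record,
carrying the exposure/covariate pair, the age at census ``w``, the age at
the analysis date ``v``, the record-linkage outcome ``r`` with its
probabilistic match score ``p_match``, and — when a death record was
linked — the matched event age ``t_star``.  Simulated cohorts additionally
carry the latent truth (``t_true``, ``delta_true``) so that methods can be
benchmarked against a fully-observed gold standard.

All ages are continuous years since birth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for cohort files
COHORT_COLUMNS = ["id", "x", "z", "w", "v", "r", "p_match", "t_star"]
TRUTH_COLUMNS = ["t_true", "delta_true"]


class CohortSchemaError(ValueError):
    """A required column is missing or unparseable."""


class CohortValidationError(ValueError):
    """One or more rows violate the cohort invariants.

    Attributes
    ----------
    report : pandas.DataFrame
        One row per offending record with columns ``id`` and ``problem``.
    """

    def __init__(self, report: pd.DataFrame):
        self.report = report
        ids = report["id"].tolist()
        shown = ", ".join(str(i) for i in ids[:10])
        more = "" if len(ids) <= 10 else f" (+{len(ids) - 10} more)"
        super().__init__(
            f"{len(ids)} record(s) violate cohort invariants "
            f"[ids: {shown}{more}]:\n{report.head(20).to_string(index=False)}"
        )


def _validation_report(df: pd.DataFrame, has_truth: bool) -> pd.DataFrame:
    """Collect per-row invariant violations; empty frame means valid."""
    problems: list[tuple[object, str]] = []

    def flag(mask: pd.Series, msg: str) -> None:
        for rid in df.loc[mask.fillna(True), "id"]:
            problems.append((rid, msg))

    flag(~df["x"].isin([0, 1]), "x must be 0/1")
    flag(~df["z"].isin([0, 1]), "z must be 0/1")
    flag(~(df["w"] > 0), "w must be > 0")
    flag(~(df["v"] > df["w"]), "v must exceed w")
    flag(~df["r"].isin([0, 1]), "r must be 0/1")
    flag(~((df["p_match"] >= 0) & (df["p_match"] <= 1)), "p_match outside [0,1]")

    nomatch = df["r"] == 0
    match = df["r"] == 1
    flag(nomatch & (df["p_match"] != 0), "r=0 requires p_match=0")
    flag(nomatch & df["t_star"].notna(), "r=0 requires t_star absent")
    flag(match & ~(df["p_match"] > 0), "r=1 requires p_match in (0,1]")
    flag(match & df["t_star"].isna(), "r=1 requires t_star present")

    if has_truth:
        flag(~(df["t_true"] > 0), "t_true must be > 0")
        flag(
            df["delta_true"] != (df["t_true"] < df["v"]).astype(int),
            "delta_true must equal I(t_true < v)",
        )
        flag(match & (df["delta_true"] != 1), "matched records must have delta_true=1")

    return pd.DataFrame(problems, columns=["id", "problem"])


@dataclass
class LinkedCohort:
    """A validated cohort of census records with linkage outcomes.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``id, x, z, w, v, r, p_match, t_star`` and optionally
        ``t_true, delta_true`` (simulation only).  ``t_star`` is NaN for
        unmatched records.
    validate : bool
        Check all invariants on construction (default True).
    """

    data: pd.DataFrame
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.data.columns]
        if missing:
            raise CohortSchemaError(f"missing required column(s): {missing}")
        truth_present = [c for c in TRUTH_COLUMNS if c in self.data.columns]
        if truth_present and len(truth_present) != len(TRUTH_COLUMNS):
            raise CohortSchemaError(
                "simulation truth columns must appear together: "
                f"have {truth_present}, need {TRUTH_COLUMNS}"
            )
        cols = COHORT_COLUMNS + (TRUTH_COLUMNS if truth_present else [])
        df = self.data[cols].reset_index(drop=True).copy()
        for c in cols:
            if c == "id":
                continue
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError) as exc:
                raise CohortSchemaError(f"column {c!r} is not numeric: {exc}") from exc
        if df["id"].duplicated().any():
            raise CohortValidationError(
                pd.DataFrame(
                    {"id": df.loc[df["id"].duplicated(), "id"], "problem": "duplicate id"}
                )
            )
        self.data = df
        if self.validate:
            report = _validation_report(df, bool(truth_present))
            if len(report):
                raise CohortValidationError(report)
        # the measurement-error model can push a matched age below w;
        # accepted, but downstream methods should know it happens
        below = (df["r"] == 1) & (df["t_star"] < df["w"])
        if below.any():
            logger.info("%d matched event age(s) fall below the census age w", int(below.sum()))
        fc = df["v"] - df["w"]
        if len(df) > 1 and not np.allclose(fc, fc.iloc[0]):
            logger.warning("follow-up v - w is not constant across records")

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_truth(self) -> bool:
        return "t_true" in self.data.columns

    @property
    def followup(self) -> float:
        """Median follow-up v - w (constant by design in simulated data)."""
        return float((self.data["v"] - self.data["w"]).median())

    def matched(self, threshold: float | None = None) -> pd.DataFrame:
        """Rows with r=1; if ``threshold`` given, only unequivocal matches
        (p_match >= threshold)."""
        df = self.data[self.data["r"] == 1]
        if threshold is not None:
            df = df[df["p_match"] >= threshold]
        return df

    def equals(self, other: "LinkedCohort") -> bool:
        return self.data.equals(other.data)


def read_cohort(path, dialect: dict[str, str] | None = None) -> LinkedCohort:
    """Read a cohort from a delimited text file.

    Parameters
    ----------
    path : str or pathlib.Path
    dialect : dict, optional
        Mapping from the file's column names to the canonical names
        (``{"file_col": "canonical"}``), for files that do not use the
        canonical header.
    """
    # round_trip float parsing: the default fast parser is off by 1 ulp
    df = pd.read_csv(path, float_precision="round_trip")
    if dialect:
        df = df.rename(columns=dialect)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(
            f"file {path} is missing required column(s): {missing}"
        )
    return LinkedCohort(df)


def write_cohort(cohort: LinkedCohort, path) -> None:
    """Write a cohort as UTF-8 CSV; round-trips through :func:`read_cohort`
    to full float precision (shortest-repr float formatting, which the
    CSV parser reads back bit-exactly)."""
    cohort.data.to_csv(path, index=False, encoding="utf-8")
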