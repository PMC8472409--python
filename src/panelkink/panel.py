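"""Panel containers, the kink transform, first differencing, sample filters and CSV I/O.

The in-memory container is a long-format :class:`pandas.DataFrame` (one row per
individual per period) wrapped by :class:`PanelDataset`, which validates the
panel invariants once at construction.  Two survey waves are encoded as
``period`` 1 and 2; calendar years and ages are metadata, not data, so the
machinery applies to any two-wave panel with a continuous threshold variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError, ParseError, SchemaError

logger = logging.getLogger(__name__)

#: mandatory non-covariate columns of a panel table, in canonical order
PANEL_BASE_COLUMNS = ["id", "period", "hours", "bmi"]
PANEL_LABEL_COLUMNS = ["gender", "skill", "employment_status", "pregnant"]

#: columns of an instrument table: one row per individual, all time-invariant
INSTRUMENT_COLUMNS = ["id", "birth_weight", "bmi_age10", "mother_bmi", "father_bmi"]

GENDERS = ("female", "male")
SKILLS = ("high", "low")
EMPLOYMENT_STATUSES = ("employee", "self_employed", "not_working")


# ---------------------------------------------------------------------------
# containers


@dataclass
class PanelDataset:
    """A validated long-format two-period panel.

    Parameters
    ----------
    df : pandas.DataFrame
        Long-format table with columns ``id, period, hours, bmi``, the
        covariate columns named in ``covariate_names``, and the label columns
        ``gender, skill, employment_status, pregnant``.
    covariate_names : list of str
        Ordered covariate labels (the x-variables of the outcome equation).
    """

    df: pd.DataFrame
    covariate_names: list[str]

    def __post_init__(self) -> None:
        required = PANEL_BASE_COLUMNS + list(self.covariate_names) + PANEL_LABEL_COLUMNS
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"panel table is missing column(s): {missing}")
        df = self.df.loc[:, required].reset_index(drop=True).copy()
        if not set(np.unique(df["period"])) <= {1, 2}:
            raise DataIntegrityError("period must take values in {1, 2}")
        dup = df.duplicated(subset=["id", "period"])
        if dup.any():
            bad = df.loc[dup, "id"].iloc[0]
            raise DataIntegrityError(f"individual {bad!r} appears more than once in a period")
        for col in ["hours", "bmi"] + list(self.covariate_names):
            values = pd.to_numeric(df[col], errors="coerce")
            if values.isna().any():
                row = int(values.index[values.isna()][0])
                raise ParseError(f"non-numeric or missing value in column {col!r} at row {row}")
            df[col] = values.astype(float)
        if (df["bmi"] <= 0).any() or not np.isfinite(df["bmi"]).all():
            raise DataIntegrityError("bmi must be finite and positive")
        if not np.isfinite(df["hours"]).all():
            raise DataIntegrityError("hours must be finite")
        self.df = df

    # -- views -----------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def n_individuals(self) -> int:
        return self.df["id"].nunique()

    def balanced_view(self) -> "PanelDataset":
        """Subset of individuals observed in both periods (estimation sample)."""
        counts = self.df.groupby("id")["period"].nunique()
        keep = counts.index[counts == 2]
        sub = self.df[self.df["id"].isin(keep)]
        return PanelDataset(sub.reset_index(drop=True), list(self.covariate_names))

    def subset(self, mask) -> "PanelDataset":
        return PanelDataset(self.df.loc[mask].reset_index(drop=True), list(self.covariate_names))


@dataclass
class InstrumentTable:
    """Per-individual time-invariant excluded instruments.

    Columns: ``id`` plus the four childhood anthropometry variables —
    birth weight (kg), own BMI at age 10, mother's and father's BMI when the
    respondent was 10 (kg/m^2).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in INSTRUMENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"instrument table is missing column(s): {missing}")
        df = self.df.loc[:, INSTRUMENT_COLUMNS].reset_index(drop=True).copy()
        if df["id"].duplicated().any():
            raise DataIntegrityError("instrument table must have one row per individual")
        for col in INSTRUMENT_COLUMNS[1:]:
            values = pd.to_numeric(df[col], errors="coerce")
            if values.isna().any():
                row = int(values.index[values.isna()][0])
                raise ParseError(f"non-numeric or missing value in column {col!r} at row {row}")
            df[col] = values.astype(float)
            if (df[col] <= 0).any() or not np.isfinite(df[col]).all():
                raise DataIntegrityError(f"instrument column {col!r} must be finite and positive")
        self.df = df

    @property
    def instrument_names(self) -> list[str]:
        return INSTRUMENT_COLUMNS[1:]


@dataclass
class FilterAudit:
    """Ordered record of sample-selection rules: (rule, n_before, n_excluded, n_after)."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, rule: str, n_before: int, n_after: int) -> None:
        self.steps.append((rule, n_before, n_before - n_after, n_after))
        self.validate()

    def validate(self) -> None:
        for rule, nb, nx, na in self.steps:
            if na != nb - nx:
                raise DataIntegrityError(f"audit step {rule!r} counts are inconsistent")
        for (r1, *_, na), (r2, nb, *_) in zip(self.steps, self.steps[1:]):
            if na != nb:
                raise DataIntegrityError(f"audit chain broken between {r1!r} and {r2!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "n_before", "n_excluded", "n_after"])


# ---------------------------------------------------------------------------
# the kink transform and first differencing


def kink_transform(q, gamma):
    """Continuous threshold (kink) basis: ``max(q - gamma, 0)``.

    The term ``delta * kink_transform(q, gamma)`` bends the regression slope at
    the threshold ``gamma`` without introducing a jump: the function is
    continuous and piecewise linear in both arguments, and 1-Lipschitz in ``q``.
    Accepts scalars or arrays.
    """
    q = np.asarray(q, dtype=float)
    g = np.asarray(gamma, dtype=float)
    if not (np.isfinite(q).all() and np.isfinite(g).all()):
        raise ValueError("kink_transform requires finite inputs")
    out = np.maximum(q - g, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def first_difference(data: PanelDataset) -> pd.DataFrame:
    """Within-individual period-2 minus period-1 differences.

    Returns one row per balanced individual with columns ``id``, ``d_hours``,
    ``d_bmi``, ``d_<covariate>`` for every covariate, and the *level* BMIs
    ``bmi_1`` and ``bmi_2``; the levels are retained because the differenced
    kink term must be re-evaluated at every candidate threshold.
    """
    df = data.df
    counts = df.groupby("id")["period"].nunique()
    if (counts < df.groupby("id")["period"].size()).any():
        raise DataIntegrityError("duplicated period within individual")
    if (counts != 2).any():
        raise DataIntegrityError(
            "first_difference requires the balanced view (every individual in both periods)"
        )
    p1 = df[df["period"] == 1].set_index("id")
    p2 = df[df["period"] == 2].set_index("id").loc[p1.index]
    out = pd.DataFrame(index=p1.index)
    out["d_hours"] = p2["hours"] - p1["hours"]
    out["d_bmi"] = p2["bmi"] - p1["bmi"]
    for cov in data.covariate_names:
        out[f"d_{cov}"] = p2[cov] - p1[cov]
    out["bmi_1"] = p1["bmi"]
    out["bmi_2"] = p2["bmi"]
    return out.reset_index()


# ---------------------------------------------------------------------------
# sample-selection filters


def apply_sample_filters(data: PanelDataset) -> tuple[PanelDataset, FilterAudit]:
    """Apply the study's sample-selection rules and return the audit trail.

    Rules, in order (all evaluated per individual, dropping both records):

    0. keep individuals observed in both periods (balanced panel);
    1. keep individuals working (employee or self-employed) in both periods
       and *not* self-employed in period 1;
    2. drop women pregnant in either survey year;
    3. keep individuals whose weekly hours lie in [10, 70] in both periods
       (bounds inclusive).
    """
    audit = FilterAudit()
    df = data.df

    n0 = df["id"].nunique()
    balanced = data.balanced_view()
    audit.add("balanced_panel", n0, balanced.n_individuals)
    df = balanced.df

    by_id = df.groupby("id")
    working_both = by_id["employment_status"].agg(lambda s: (s != "not_working").all())
    p1 = df[df["period"] == 1].set_index("id")
    not_self_emp_p1 = p1["employment_status"] != "self_employed"
    keep = working_both & not_self_emp_p1.reindex(working_both.index, fill_value=False)
    df = df[df["id"].isin(keep.index[keep])]
    audit.add("working_both_periods_not_self_employed_p1", balanced.n_individuals, df["id"].nunique())

    n_before = df["id"].nunique()
    preg = df.groupby("id").apply(
        lambda g: (g["gender"].iloc[0] == "female") and bool(np.asarray(g["pregnant"], dtype=bool).any()),
        include_groups=False,
    )
    df = df[df["id"].isin(preg.index[~preg])]
    audit.add("pregnancy_exclusion", n_before, df["id"].nunique())

    n_before = df["id"].nunique()
    ok_hours = df.groupby("id")["hours"].agg(lambda h: bool(((h >= 10) & (h <= 70)).all()))
    df = df[df["id"].isin(ok_hours.index[ok_hours])]
    audit.add("hours_in_10_to_70", n_before, df["id"].nunique())

    filtered = PanelDataset(df.reset_index(drop=True), list(data.covariate_names))
    return filtered, audit


# ---------------------------------------------------------------------------
# CSV I/O


def _read_csv_checked(path, mandatory: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    for col in numeric:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header line, one for 0-based indexing
            row = int(bad.index[bad][0]) + 2
            raise ParseError(f"{path}: cannot parse value {df.loc[row - 2, col]!r} "
                             f"in column {col!r} at file line {row}")
        df[col] = values
    return df


def read_panel_csv(path, covariate_names: list[str]) -> PanelDataset:
    """Read a long-format panel CSV.

    Expected columns: ``id, period, hours, bmi``, the covariates listed in
    ``covariate_names``, then ``gender, skill, employment_status, pregnant``.
    Unknown columns are ignored with a logged warning; records with missing
    numeric values are dropped with a logged count (complete-case analysis).
    """
    numeric = ["period", "hours", "bmi"] + list(covariate_names)
    df = _read_csv_checked(path, PANEL_BASE_COLUMNS + list(covariate_names) + PANEL_LABEL_COLUMNS,
                           numeric)
    known = set(PANEL_BASE_COLUMNS + list(covariate_names) + PANEL_LABEL_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("ignoring unknown column(s) %s in %s", extra, path)
        df = df.drop(columns=extra)
    incomplete = df[numeric].isna().any(axis=1)
    if incomplete.any():
        logger.warning("dropping %d record(s) with missing values from %s", int(incomplete.sum()), path)
        df = df[~incomplete]
    df = df.copy()
    df["period"] = df["period"].astype(int)
    df["pregnant"] = df["pregnant"].astype(bool)
    return PanelDataset(df.reset_index(drop=True), list(covariate_names))


def write_panel_csv(data: PanelDataset, path) -> None:
    data.df.to_csv(path, index=False)


def read_instruments_csv(path) -> InstrumentTable:
    df = _read_csv_checked(path, INSTRUMENT_COLUMNS, INSTRUMENT_COLUMNS[1:])
    return InstrumentTable(df)


def write_instruments_csv(table: InstrumentTable, path) -> None:
    table.df.to_csv(path, index=False)
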