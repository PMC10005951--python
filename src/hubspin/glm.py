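"""Mass-univariate general linear models on parcellated cortical thickness.

Four model families are supported, matching the two clinical-cohort and
two general-population analyses:

* ``abide_group``:        T = intercept + Site + Group + Age
* ``abide_age_by_group``: T = intercept + Site + Group + Age + Age:Group
* ``ping_prs``:           T = intercept + Age + PRS + PCs + Scanner + Sex
* ``ping_age_by_prs``:    same + Age:PRS

Age is mean-centered before any interaction product is formed;
categoricals are one-hot coded against the first level in sort order;
the group indicator is 1 for ASD, so a positive Group beta means
ASD > CTL.  Each parcel is fitted by ordinary least squares and the
per-parcel beta, t and two-sided p for the coefficient of interest form
the "alteration map" consumed by the overlap and epicenter analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlignmentError,
    CollinearityError,
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
)

__all__ = [
    "ModelSpec",
    "MODEL_FAMILIES",
    "make_design_matrix",
    "ParcelwiseGLM",
    "ParcelwiseGLMResults",
    "fit_parcelwise_glm",
]


@dataclass(frozen=True)
class ModelSpec:
    """Ordered covariate list plus the coefficient the map reports."""

    family: str
    terms: tuple
    coefficient_of_interest: str

    def __post_init__(self):
        if self.coefficient_of_interest not in self.terms:
            raise InvalidArgumentError(
                f"coefficient of interest {self.coefficient_of_interest!r} "
                "must appear in the term list"
            )


MODEL_FAMILIES = {
    "abide_group": ModelSpec(
        "abide_group", ("Intercept", "Site", "Group", "Age"), "Group"
    ),
    "abide_age_by_group": ModelSpec(
        "abide_age_by_group",
        ("Intercept", "Site", "Group", "Age", "Age:Group"),
        "Age:Group",
    ),
    "ping_prs": ModelSpec(
        "ping_prs", ("Intercept", "Age", "PRS", "PC", "Scanner", "Sex"), "PRS"
    ),
    "ping_age_by_prs": ModelSpec(
        "ping_age_by_prs",
        ("Intercept", "Age", "PRS", "PC", "Scanner", "Sex", "Age:PRS"),
        "Age:PRS",
    ),
}

# subject-table column that backs each model term
_TERM_COLUMN = {"Site": "site", "Scanner": "site", "Group": "group", "Sex": "sex",
                "Age": "age", "PRS": "prs"}


def resolve_spec(spec) -> ModelSpec:
    if isinstance(spec, ModelSpec):
        return spec
    try:
        return MODEL_FAMILIES[spec]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown model family {spec!r}; choose from {sorted(MODEL_FAMILIES)}"
        ) from None


def _onehot(values: pd.Series, term: str):
    levels = sorted(values.unique())
    if len(levels) < 2:
        raise DegenerateDesignError(
            f"categorical term {term!r} has a single level ({levels[0]!r})"
        )
    cols = [(f"{term}[{lev}]", (values == lev).to_numpy(float)) for lev in levels[1:]]
    return cols


def make_design_matrix(subjects: pd.DataFrame, spec) -> tuple:
    """Build the design matrix for a model spec.

    Returns ``(X, column_names, column_map)`` where ``column_map`` maps
    each term to the list of column indices it occupies.

    Raises
    ------
    DegenerateDesignError
        if a categorical term in the model has fewer than two levels.
    CollinearityError
        if the design is rank deficient (names the offending columns).
    """
    spec = resolve_spec(spec)
    n = len(subjects)
    age_c = None
    if "Age" in spec.terms or any(":" in t for t in spec.terms):
        age = subjects["age"].to_numpy(float)
        age_c = age - age.mean()

    columns: list = []
    colmap: dict = {}
    for term in spec.terms:
        start = len(columns)
        if term == "Intercept":
            columns.append(("Intercept", np.ones(n)))
        elif term in ("Site", "Scanner", "Sex"):
            columns.extend(_onehot(subjects[_TERM_COLUMN[term]].astype(str), term))
        elif term == "Group":
            levels = sorted(subjects["group"].astype(str).unique())
            if len(levels) < 2:
                raise DegenerateDesignError("Group has a single level")
            # ASD coded 1 so positive beta = ASD > CTL
            columns.append(("Group[ASD]", (subjects["group"] == "ASD").to_numpy(float)))
        elif term == "Age":
            columns.append(("Age", age_c))
        elif term == "PRS":
            columns.append(("PRS", subjects["prs"].to_numpy(float)))
        elif term == "PC":
            pc_cols = [c for c in subjects.columns if c.startswith("pc") and c[2:].isdigit()]
            pc_cols = sorted(pc_cols, key=lambda c: int(c[2:]))
            if not pc_cols:
                raise DegenerateDesignError("PC block requested but no pc columns present")
            for c in pc_cols:
                columns.append((c.upper(), subjects[c].to_numpy(float)))
        elif term == "Age:Group":
            columns.append(("Age:Group[ASD]", age_c * (subjects["group"] == "ASD").to_numpy(float)))
        elif term == "Age:PRS":
            columns.append(("Age:PRS", age_c * subjects["prs"].to_numpy(float)))
        else:
            raise InvalidArgumentError(f"unknown model term {term!r}")
        colmap[term] = list(range(start, len(columns)))

    names = [name for name, _ in columns]
    X = np.column_stack([col for _, col in columns])

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: columns past the rank are the linearly dependent ones
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        offending = sorted(names[j] for j in piv[rank:])
        raise CollinearityError(offending)
    return X, names, colmap


@dataclass(frozen=True)
class ParcelwiseGLMResults:
    """Per-parcel OLS estimates for one model.

    ``beta``/``t``/``p`` are term x parcel DataFrames over all design
    columns; ``stat_map`` restricts them to the coefficient of interest.
    """

    spec: ModelSpec
    parcel_id: tuple
    beta: pd.DataFrame
    t: pd.DataFrame
    p: pd.DataFrame
    df_resid: int
    coef_column: str

    @property
    def stat_map(self) -> pd.DataFrame:
        """Columns ``parcel_id, beta, t, p, df`` for the coefficient of interest."""
        return pd.DataFrame(
            {
                "parcel_id": list(self.parcel_id),
                "beta": self.beta.loc[self.coef_column].to_numpy(),
                "t": self.t.loc[self.coef_column].to_numpy(),
                "p": self.p.loc[self.coef_column].to_numpy(),
                "df": self.df_resid,
            }
        )

    def alteration_map(self, statistic: str = "t") -> np.ndarray:
        """Per-parcel map passed downstream; ``statistic`` is 't' or 'beta'."""
        if statistic not in ("t", "beta"):
            raise InvalidArgumentError("statistic must be 't' or 'beta'")
        frame = self.t if statistic == "t" else self.beta
        return frame.loc[self.coef_column].to_numpy().copy()

    def to_tsv(self, path) -> None:
        self.stat_map.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        sm = self.stat_map
        lines = [
            f"Parcelwise GLM [{self.spec.family}] — coefficient: {self.coef_column}",
            f"parcels: {len(self.parcel_id)}   residual df: {self.df_resid}",
            f"beta: mean {sm['beta'].mean():+.4f}  range [{sm['beta'].min():+.4f}, {sm['beta'].max():+.4f}]",
            f"t:    mean {sm['t'].mean():+.3f}  range [{sm['t'].min():+.3f}, {sm['t'].max():+.3f}]",
            f"parcels with p < 0.05: {(sm['p'] < 0.05).sum()} / {len(sm)}",
        ]
        return "\n".join(lines)


class ParcelwiseGLM:
    """Mass-univariate OLS of thickness on a model family.

    Parameters
    ----------
    thickness : pandas.DataFrame
        Subjects x parcels matrix; the index must match
        ``subjects['subject_id']`` in the same order.
    subjects : pandas.DataFrame
        Phenotype table with the covariates the family requires.
    spec : str or ModelSpec
        One of the named families or an explicit spec.
    """

    def __init__(self, thickness: pd.DataFrame, subjects: pd.DataFrame, spec):
        self.spec = resolve_spec(spec)
        if len(thickness) != len(subjects):
            raise AlignmentError("thickness and subject table differ in length")
        if not np.array_equal(
            thickness.index.to_numpy().astype(str),
            subjects["subject_id"].to_numpy().astype(str),
        ):
            raise AlignmentError("thickness rows are not aligned with subject_id order")
        self.thickness = thickness
        self.subjects = subjects
        self.X, self.column_names, self.column_map = make_design_matrix(subjects, self.spec)

    def fit(self) -> ParcelwiseGLMResults:
        X = self.X
        Y = self.thickness.to_numpy(float)
        n, k = X.shape
        df = n - k
        if df < 10:
            raise InsufficientDataError(f"residual df = {df} < 10")

        beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        sigma2 = (resid**2).sum(axis=0) / df
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)

        parcels = tuple(str(c) for c in self.thickness.columns)
        idx = self.column_map[self.spec.coefficient_of_interest]
        # interactions / simple terms occupy one column; the coefficient of
        # interest is never a multi-column block in the supported families
        coef_column = self.column_names[idx[0]]
        mk = lambda a: pd.DataFrame(a, index=self.column_names, columns=list(parcels))
        return ParcelwiseGLMResults(
            spec=self.spec,
            parcel_id=parcels,
            beta=mk(beta),
            t=mk(t),
            p=mk(p),
            df_resid=int(df),
            coef_column=coef_column,
        )


def fit_parcelwise_glm(thickness: pd.DataFrame, subjects: pd.DataFrame, spec) -> ParcelwiseGLMResults:
    """Convenience wrapper: build and fit a :class:`ParcelwiseGLM`."""
    return ParcelwiseGLM(thickness, subjects, spec).fit()
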