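"""Univariate/bivariate tables and model-screening diagnostics.

Crosstab percentages follow the source table's convention: category
percentages are percent of the grand total, and the traditional/modern
columns are also percent of the grand total (so the two outcome columns sum
to the category's share).  Pearson chi-square is computed without
continuity correction by default (a Yates flag exists for 2x2 tables).
Variance inflation factors screen the dummy-coded design at the
conventional threshold of 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, McprError

__all__ = [
    "CATEGORY_ORDER",
    "REFERENCE_LEVELS",
    "CrossTab",
    "crosstab",
    "chi_square_test",
    "build_design",
    "vif_screen",
    "select_variables",
]

#: category display order per variable (mirrors the published table order)
CATEGORY_ORDER: dict[str, list[str]] = {
    "age_group": ["15-19", "20-29", "30-39", "40+"],
    "marital": ["single", "married", "living_together", "previously_married"],
    "head_sex": ["male", "female"],
    "parity": ["1", "2", "3", "4+"],
    "ever_terminated": ["no", "yes"],
    "education": ["none", "primary", "secondary+"],
    "media_exposure": ["low", "medium", "high"],
    "wanted_last": ["then", "later", "no_more"],
    "wealth": ["poor", "middle", "rich"],
    "religion": ["anglican", "catholic", "muslim", "other"],
    "employed": ["no", "yes"],
    "residence_majority": ["urban", "rural"],
    "community_age": ["young", "old"],
    "community_ses": ["low", "high"],
    "community_media_fp": ["low", "high"],
    "community_education": ["low", "high"],
    "community_facility_access": ["low", "high"],
}

#: reference level of each covariate (the table's "(Ref)" rows)
REFERENCE_LEVELS: dict[str, str] = {v: order[0] for v, order in CATEGORY_ORDER.items()}


@dataclass
class CrossTab:
    """One background variable crossed with the binary outcome."""

    variable: str
    categories: list[str]
    counts: np.ndarray            # per category
    pct_total: np.ndarray         # per category, % of grand total
    traditional_pct: np.ndarray   # % of grand total
    modern_pct: np.ndarray        # % of grand total
    n: int
    chi_square: float
    df: int
    p_value: float
    table: np.ndarray = field(repr=False, default=None)  # categories x (trad, modern)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.categories,
                "n": self.counts,
                "pct": np.round(self.pct_total, 1),
                "traditional_pct": np.round(self.traditional_pct, 1),
                "modern_pct": np.round(self.modern_pct, 1),
            }
        )


def chi_square_test(table: np.ndarray, yates: bool = False):
    """Pearson chi-square on an r x c contingency table.

    X^2 = sum (O - E)^2 / E with E from the product of margins;
    df = (r-1)(c-1); p from the upper tail of chi-square(df).

    Raises
    ------
    DegenerateTableError
        If any expected count is zero (an empty row or column margin).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError("need at least a 2x2 table")
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if np.any(expected == 0):
        raise DegenerateTableError("zero expected cell count")
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def crosstab(records: pd.DataFrame, variable: str, outcome: str = "outcome_modern",
             yates: bool = False, percent: str = "total") -> CrossTab:
    """Cross-tabulate one coded variable against the binary outcome.

    ``percent="total"`` reports the outcome columns as percent of the
    grand total (the published convention, where the two outcome columns
    sum to the category's overall share); ``percent="row"`` reports
    within-category row percentages instead.
    """
    if percent not in ("total", "row"):
        raise McprError(f"percent must be 'total' or 'row', got {percent!r}")
    if variable not in records.columns:
        raise McprError(f"unknown variable: {variable!r}")
    sub = records.loc[records[outcome].notna(), [variable, outcome]]
    order = CATEGORY_ORDER.get(variable)
    if order is None:
        order = sorted(sub[variable].astype(str).unique())
    order = [c for c in order if c in set(sub[variable].astype(str))]
    n = len(sub)
    counts, trad, modern = [], [], []
    for cat in order:
        mask = sub[variable].astype(str) == cat
        counts.append(int(mask.sum()))
        modern.append(int((sub.loc[mask, outcome] == 1).sum()))
        trad.append(int((sub.loc[mask, outcome] == 0).sum()))
    counts = np.array(counts)
    trad = np.array(trad)
    modern = np.array(modern)
    table = np.column_stack([trad, modern])
    if len(order) >= 2 and table.sum(axis=0).min() > 0:
        stat, df, p = chi_square_test(table, yates=yates)
    else:
        stat, df, p = np.nan, 0, np.nan
    denom = counts if percent == "row" else np.full_like(counts, n)
    denom = np.where(denom == 0, 1, denom)
    return CrossTab(
        variable=variable,
        categories=order,
        counts=counts,
        pct_total=100.0 * counts / n,
        traditional_pct=100.0 * trad / denom,
        modern_pct=100.0 * modern / denom,
        n=n,
        chi_square=stat,
        df=df,
        p_value=p,
        table=table,
    )


def build_design(
    records: pd.DataFrame,
    terms: list[str],
    references: dict[str, str] | None = None,
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Dummy-code ``terms`` dropping each variable's reference level.

    Columns are named ``variable:category`` in the documented category
    order, so output layout is bit-reproducible.
    """
    references = REFERENCE_LEVELS if references is None else references
    cols = {}
    if add_intercept:
        cols["intercept"] = np.ones(len(records))
    for term in terms:
        if term not in records.columns:
            raise McprError(f"unknown model term: {term!r}")
        order = CATEGORY_ORDER.get(term) or sorted(records[term].astype(str).unique())
        ref = references.get(term, order[0])
        vals = records[term].astype(str)
        for cat in order:
            if cat == ref:
                continue
            cols[f"{term}:{cat}"] = (vals == cat).to_numpy(float)
    return pd.DataFrame(cols, index=records.index)


def vif_screen(design: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor per predictor column.

    VIF_k = 1 / (1 - R^2_k), with R^2_k from the least-squares regression
    of predictor k on all the others (plus a constant).  Exact collinearity
    is reported as ``inf`` with the flag set, never raised.  The design
    must not contain the constant column itself.
    """
    X = design.to_numpy(float)
    names = list(design.columns)
    if "intercept" in names:
        raise McprError("drop the intercept column before VIF screening")
    n, p = X.shape
    rows = []
    ones = np.ones((n, 1))
    for k in range(p):
        yk = X[:, k]
        others = np.hstack([ones, np.delete(X, k, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yk, rcond=None)
        resid = yk - others @ beta
        tss = float(np.sum((yk - yk.mean()) ** 2))
        if tss == 0:
            vif = np.inf
        else:
            r2 = 1.0 - float(np.sum(resid**2)) / tss
            vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"predictor": names[k], "vif": vif, "flagged": bool(vif > 10)})
    out = pd.DataFrame(rows)
    finite = out["vif"].replace(np.inf, np.nan)
    out.attrs["mean_vif"] = float(finite.mean())
    out.attrs["min_vif"] = float(finite.min())
    out.attrs["max_vif"] = float(out["vif"].max())
    return out


def select_variables(
    crosstabs: dict[str, CrossTab],
    records: pd.DataFrame,
    alpha: float = 0.05,
    vif_max: float = 10.0,
):
    """Bivariate screen then multicollinearity screen.

    Keeps variables whose chi-square p-value is below ``alpha``, builds the
    joint dummy design for the survivors, and drops any variable with a
    predictor VIF above ``vif_max``.  Returns ``(kept, log)`` where ``log``
    records every drop and its reason, in deterministic order.
    """
    log: list[str] = []
    screened = []
    for var, ct in crosstabs.items():
        if np.isnan(ct.p_value):
            log.append(f"{var}: dropped (degenerate bivariate table)")
        elif ct.p_value < alpha:
            screened.append(var)
        else:
            log.append(f"{var}: dropped (chi-square p={ct.p_value:.3g} >= {alpha})")
    if not screened:
        return [], log
    design = build_design(records, screened, add_intercept=False)
    vif = vif_screen(design)
    dropped = set()
    for _, row in vif.iterrows():
        if row["flagged"]:
            var = row["predictor"].split(":")[0]
            if var not in dropped:
                dropped.add(var)
                log.append(f"{var}: dropped (VIF {row['vif']:.2f} > {vif_max})")
    kept = [v for v in screened if v not in dropped]
    return kept, log
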