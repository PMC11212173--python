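"""Survey-variable construction.

Recodes raw women's-record survey variables into the analysis categories:
the modern/traditional outcome, the three-item media-exposure composite,
collapsed education and wealth, and district-level ("community") aggregates
dichotomised at the median of the district proportion distribution.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import AggregationError, ClassificationError, CodingError

__all__ = [
    "load_method_vocab",
    "classify_method",
    "media_composite",
    "code_records",
    "apply_sample_filter",
    "aggregate_community",
    "attach_community",
    "COMMUNITY_COLUMNS",
]

#: community-level columns produced by :func:`aggregate_community`
COMMUNITY_COLUMNS = [
    "community_age",
    "community_ses",
    "community_media_fp",
    "community_education",
    "community_facility_access",
    "residence_majority",
]


def load_method_vocab(path: str | None = None) -> dict[str, str]:
    """Load the method-code vocabulary as a flat ``code -> class`` map.

    By default reads the packaged YAML file, which pins the mapping
    bit-exactly; pass ``path`` to substitute a custom vocabulary.
    """
    if path is None:
        text = resources.files("mcpr.data").joinpath("method_vocab.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    vocab: dict[str, str] = {}
    for cls in ("modern", "traditional"):
        for code in raw[cls]:
            vocab[str(code).strip().lower()] = cls
    return vocab


_DEFAULT_VOCAB = load_method_vocab()


def classify_method(method_code: str, vocab: dict[str, str] | None = None) -> str:
    """Classify one contraceptive method code as ``modern`` or ``traditional``.

    Modern methods: female/male sterilization, IUD, injectables, implants,
    pill, male/female condom, emergency contraception, other modern.
    Traditional: rhythm, withdrawal, lactational amenorrhea, other traditional.

    Raises
    ------
    ClassificationError
        If the code is not in the controlled vocabulary; the message names
        the offending code.
    """
    vocab = _DEFAULT_VOCAB if vocab is None else vocab
    key = str(method_code).strip().lower()
    try:
        return vocab[key]
    except KeyError:
        raise ClassificationError(
            f"unknown contraceptive method code: {method_code!r}"
        ) from None


def media_composite(items) -> str:
    """Collapse three media-frequency items into low/medium/high exposure.

    Each item is coded 0 (not at all), 1 (less than once a week) or
    2 (at least once a week).  Items are first recoded to binary access
    (0 -> no access, 1-2 -> access); the number of accessed sources S in
    0..3 is then split at the median: S=0 low, S=1 medium, S in {2,3} high.
    """
    items = list(items)
    if len(items) != 3:
        raise CodingError(f"expected 3 media items, got {len(items)}")
    for it in items:
        if it not in (0, 1, 2):
            raise CodingError(f"media item outside {{0,1,2}}: {it!r}")
    s = sum(1 for it in items if it in (1, 2))
    if s == 0:
        return "low"
    if s == 1:
        return "medium"
    return "high"


_EDU_MAP = {"none": "none", "primary": "primary", "secondary": "secondary+", "higher": "secondary+"}
_WEALTH_MAP = {
    "poorest": "poor",
    "poorer": "poor",
    "middle": "middle",
    "richer": "rich",
    "richest": "rich",
}


def apply_sample_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Restrict to the analytic sample: users of any method, not pregnant.

    Keeps exactly the rows with ``used_any_method == 'yes'`` and
    ``pregnant_now == 'no'``, preserving order.  This mirrors the two-stage
    screening of the source survey (non-users excluded first, pregnant
    users second).
    """
    keep = (records["used_any_method"] == "yes") & (records["pregnant_now"] == "no")
    return records.loc[keep].copy()


def code_records(records: pd.DataFrame, vocab: dict[str, str] | None = None) -> pd.DataFrame:
    """Derive the analysis variables from raw record columns.

    Adds ``education`` (secondary and higher collapsed), ``wealth``
    (poorest+poorer -> poor, richer+richest -> rich), ``media_exposure``
    (three-item composite) and ``outcome_modern`` (1 if the reported method
    classifies as modern, 0 if traditional, missing for non-users).
    """
    out = records.copy()
    out["education"] = out["education_raw"].map(_EDU_MAP)
    if out["education"].isna().any() and out["education_raw"].notna().any():
        bad = out.loc[out["education"].isna() & out["education_raw"].notna(), "education_raw"]
        raise CodingError(f"unknown education codes: {sorted(bad.unique())}")
    out["wealth"] = out["wealth_raw"].map(_WEALTH_MAP)
    if out["wealth"].isna().any() and out["wealth_raw"].notna().any():
        bad = out.loc[out["wealth"].isna() & out["wealth_raw"].notna(), "wealth_raw"]
        raise CodingError(f"unknown wealth codes: {sorted(bad.unique())}")
    media = np.column_stack(
        [out["media_newspaper"], out["media_radio"], out["media_tv"]]
    )
    out["media_exposure"] = [media_composite(row) for row in media]
    used = out["used_any_method"] == "yes"
    outcome = pd.Series(np.nan, index=out.index, dtype=float)
    codes = out.loc[used, "method_code"]
    outcome.loc[used] = [1.0 if classify_method(c, vocab) == "modern" else 0.0 for c in codes]
    out["outcome_modern"] = outcome
    return out


def _dichotomize(props: pd.Series) -> pd.Series:
    """Median split of district proportions; ties (p == median) go high."""
    med = props.median()
    return pd.Series(np.where(props >= med, "high", "low"), index=props.index)


def aggregate_community(
    coded: pd.DataFrame,
    fp_media_column: str = "fp_media_source",
) -> pd.DataFrame:
    """Build district-level community variables from coded records.

    Per district the following proportions are computed and each is
    dichotomised at the median of the across-district distribution
    (proportion >= median -> ``high``):

    - share of women aged 15-29 (community age; high share -> "young"
      reported via ``community_age`` using young/old labels)
    - share with middle or rich wealth (community socioeconomic status)
    - share with at least one family-planning media source
    - share with secondary+ education
    - share who visited a health facility in the last 12 months

    ``residence_majority`` is the district majority vote (ties -> urban);
    ``prevalence_modern`` is the percent of the district's method users on
    a modern method, and ``share_national_modern`` the district's percent
    of all modern users nationally (the quantity mapped in choropleths,
    which is why district values are single-digit percentages even when
    within-district prevalence is ~50%).
    """
    if len(coded) == 0 or coded["district_id"].nunique() == 0:
        raise AggregationError("no districts to aggregate")
    g = coded.groupby("district_id")
    summary = pd.DataFrame(index=g.size().index)
    summary["n_women"] = g.size()
    young = coded["age_group"].isin(["15-19", "20-29"])
    summary["prop_young"] = young.groupby(coded["district_id"]).mean()
    ses = coded["wealth"].isin(["middle", "rich"])
    summary["prop_ses_high"] = ses.groupby(coded["district_id"]).mean()
    fp = coded[fp_media_column].astype(float) > 0
    summary["prop_media_fp"] = fp.groupby(coded["district_id"]).mean()
    edu = coded["education"] == "secondary+"
    summary["prop_education_high"] = edu.groupby(coded["district_id"]).mean()
    fac = coded["visited_facility_12m"] == "yes"
    summary["prop_facility_access"] = fac.groupby(coded["district_id"]).mean()
    urban = coded["residence"] == "urban"
    prop_urban = urban.groupby(coded["district_id"]).mean()

    age_hl = _dichotomize(summary["prop_young"])
    summary["community_age"] = np.where(age_hl == "high", "young", "old")
    summary["community_ses"] = _dichotomize(summary["prop_ses_high"])
    summary["community_media_fp"] = _dichotomize(summary["prop_media_fp"])
    summary["community_education"] = _dichotomize(summary["prop_education_high"])
    summary["community_facility_access"] = _dichotomize(summary["prop_facility_access"])
    summary["residence_majority"] = np.where(prop_urban >= 0.5, "urban", "rural")

    users = coded["outcome_modern"].notna()
    n_users = users.groupby(coded["district_id"]).sum()
    n_modern = (coded["outcome_modern"] == 1).groupby(coded["district_id"]).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        summary["prevalence_modern"] = 100.0 * n_modern / n_users.replace(0, np.nan)
    total_modern = n_modern.sum()
    summary["share_national_modern"] = (
        100.0 * n_modern / total_modern if total_modern > 0 else np.nan
    )
    summary.index.name = "district_id"
    return summary.reset_index()


def attach_community(coded: pd.DataFrame, summary: pd.DataFrame) -> pd.DataFrame:
    """Merge the district-level community labels onto women-level records."""
    cols = ["district_id"] + COMMUNITY_COLUMNS
    return coded.merge(summary[cols], on="district_id", how="left", validate="m:1")
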