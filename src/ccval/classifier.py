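"""Administrative chronicity classification (CC) of back pain from claims.

The rule set (after Freytag et al.) assigns each insured person with at
least two back-pain diagnoses (ICD-10 M40-M54) in a 12-month lookback
window one of three chronicity classes:

* **CC 3** - evidence of chronicity: >= 6 weeks (42 days) of incapacity to
  work attributed to an M40-M54 diagnosis, or at least two strong-opioid
  prescriptions (ATC N02A) within six months of each other;
* **CC 2** - evidence of risk of chronicity: fewer than two qualifying
  opioid prescriptions, and either 1-41 attributed sick-leave days or at
  least two psychiatric F-diagnoses from a fixed code list;
* **CC 1** - without evidence of chronicity: neither of the above.

Classes are evaluated with precedence CC3 -> CC2 -> CC1. A person with
fewer than two M40-M54 diagnosis records is not classifiable (below the
invitation threshold). CC3 alone counts as "severe" in the dichotomous
comparison with the Graded Chronic Pain Scale.

The lookback window is closed on both ends and anchored at the invitation
date; records dated exactly on either boundary count. Diagnosis *records*
are counted, not distinct codes or dates (claims extracts legitimately
repeat codes); an optional deduplication by (code, date) can be switched on.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ClaimsHistory

#: default psychiatric risk-marker codes; a trailing ``*`` matches any child code
DEFAULT_F_CODES = (
    "F32*", "F33*", "F34.1", "F34.8", "F34.9", "F38*", "F41.2", "F45.4",
    "F48.0", "F43.20", "F43.21", "F43.22", "F54*", "F62.80",
)

CC_LEVELS = (1, 2, 3)
NOT_CLASSIFIABLE = "not_classifiable"


@dataclass(frozen=True)
class CcConfig:
    """Tunable constants of the chronicity rules.

    Defaults are the published rule set: 365-day lookback, M40-M54 back-pain
    block, N02A opioids with a 183-day ("within six months") pair window and
    42 sick-leave days ("six weeks") as the chronicity threshold.
    """

    lookback_days: int = 365
    bp_code_low: str = "M40"
    bp_code_high: str = "M54"
    f_code_list: tuple[str, ...] = DEFAULT_F_CODES
    opioid_atc_prefix: str = "N02A"
    opioid_window_days: int = 183
    sickleave_chronic_days: int = 42
    dedupe_diagnoses: bool = False

    def __post_init__(self) -> None:
        if min(self.lookback_days, self.opioid_window_days,
               self.sickleave_chronic_days) <= 0:
            raise ValueError("all window/threshold lengths must be positive")

    def f_exact_codes(self) -> frozenset[str]:
        return frozenset(c for c in self.f_code_list if not c.endswith("*"))

    def f_prefixes(self) -> tuple[str, ...]:
        return tuple(c[:-1] for c in self.f_code_list if c.endswith("*"))


@dataclass(frozen=True)
class CcFeatures:
    """Lookback-window feature summary feeding the classification rules."""

    m_diag_count: int
    f_diag_count: int
    opioid_rx_pair_within_window: bool
    opioid_rx_count: int
    bp_sickleave_days: int

    def __post_init__(self) -> None:
        if min(self.m_diag_count, self.f_diag_count,
               self.opioid_rx_count, self.bp_sickleave_days) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.opioid_rx_pair_within_window and self.opioid_rx_count < 2:
            raise ValueError("an opioid pair implies at least two prescriptions")


@dataclass(frozen=True)
class ChronicityClass:
    """The assigned class (1, 2, 3 or 'not_classifiable') and its severity."""

    cc: int | str
    severe: bool

    def __post_init__(self) -> None:
        if self.cc not in (*CC_LEVELS, NOT_CLASSIFIABLE):
            raise ValueError(f"invalid chronicity class {self.cc!r}")
        if self.severe != (self.cc == 3):
            raise ValueError("severe must hold exactly for CC 3")


def is_bp_code(code: str, config: CcConfig = CcConfig()) -> bool:
    """Whether an ICD-10 code's 3-character root falls in the back-pain block."""
    root = code[:3]
    return config.bp_code_low <= root <= config.bp_code_high


def is_f_code(code: str, config: CcConfig = CcConfig()) -> bool:
    """Whether a code matches the psychiatric risk-marker list."""
    return code in config.f_exact_codes() or code.startswith(config.f_prefixes())


def extract_features(
    history: ClaimsHistory, index_date: dt.date, config: CcConfig = CcConfig()
) -> CcFeatures:
    """Summarise one claims history over the lookback window ending at
    ``index_date`` (closed interval of ``lookback_days`` days)."""
    win_start = index_date - dt.timedelta(days=config.lookback_days - 1)
    in_window = lambda d: win_start <= d <= index_date  # noqa: E731

    m_count = sum(
        1 for rec in history.diagnoses
        if in_window(rec.date) and is_bp_code(rec.code, config)
    )
    f_count = sum(
        1 for rec in history.diagnoses
        if in_window(rec.date) and is_f_code(rec.code, config)
    )

    opioid_dates = sorted(
        rec.date for rec in history.prescriptions
        if in_window(rec.date) and rec.atc_code.startswith(config.opioid_atc_prefix)
    )
    pair = any(
        (b - a).days <= config.opioid_window_days
        for a, b in zip(opioid_dates, opioid_dates[1:])
    )

    sickleave_days = 0
    for ep in history.sick_leave:
        if not is_bp_code(ep.attributed_code, config):
            continue
        overlap = (min(ep.end, index_date) - max(ep.start, win_start)).days + 1
        sickleave_days += max(0, overlap)

    return CcFeatures(
        m_diag_count=m_count,
        f_diag_count=f_count,
        opioid_rx_pair_within_window=pair,
        opioid_rx_count=len(opioid_dates),
        bp_sickleave_days=sickleave_days,
    )


def classify(features: CcFeatures, config: CcConfig = CcConfig()) -> ChronicityClass:
    """Apply the chronicity rules to a feature summary.

    Precedence is CC3 -> CC2 -> CC1; a person with fewer than two back-pain
    diagnosis records is not classifiable.
    """
    if features.m_diag_count < 2:
        return ChronicityClass(NOT_CLASSIFIABLE, False)
    if (features.bp_sickleave_days >= config.sickleave_chronic_days
            or features.opioid_rx_pair_within_window):
        return ChronicityClass(3, True)
    if 1 <= features.bp_sickleave_days or features.f_diag_count >= 2:
        return ChronicityClass(2, False)
    return ChronicityClass(1, False)


def dichotomize_cc(cc: int) -> bool:
    """True for severe back pain, i.e. CC 3; CC 1 and CC 2 are non-severe."""
    if cc not in CC_LEVELS:
        raise ValueError(
            f"cannot dichotomise chronicity class {cc!r}; "
            "not-classifiable persons must be filtered upstream"
        )
    return cc == 3


def classify_person(
    history: ClaimsHistory, index_date: dt.date, config: CcConfig = CcConfig()
) -> ChronicityClass:
    """Convenience composition of :func:`extract_features` and :func:`classify`."""
    return classify(extract_features(history, index_date, config), config)


# ---------------------------------------------------------------------------
# vectorised table route


def _date_ordinals(series: pd.Series) -> np.ndarray:
    return pd.to_datetime(series).to_numpy(dtype="datetime64[D]").astype("int64")


def classify_table(
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    sick_leave: pd.DataFrame,
    index_dates: pd.Series,
    config: CcConfig = CcConfig(),
) -> pd.DataFrame:
    """Classify every person in ``index_dates`` (person_id -> index date).

    Vectorised equivalent of :func:`classify_person` over interchange
    tables; returns one row per person with the feature columns and the
    class, in ``index_dates`` order.
    """
    persons = index_dates.index.astype(str)
    idx = pd.Series(
        pd.to_datetime(index_dates.to_numpy()).to_numpy(dtype="datetime64[D]")
        .astype("int64"),
        index=persons,
    )

    def window_mask(df: pd.DataFrame, date_col: str) -> tuple[pd.Series, np.ndarray]:
        pid = df["person_id"].astype(str)
        anchor = pid.map(idx).to_numpy(dtype=float)
        days = _date_ordinals(df[date_col]).astype(float)
        known = ~np.isnan(anchor)
        inside = known & (days <= anchor) & (days >= anchor - (config.lookback_days - 1))
        return pid, inside

    zeros = pd.Series(0, index=persons)

    if len(diagnoses):
        pid, inside = window_mask(diagnoses, "date")
        roots = diagnoses["code"].astype(str).str[:3]
        is_m = (roots >= config.bp_code_low) & (roots <= config.bp_code_high)
        codes = diagnoses["code"].astype(str)
        is_f = codes.isin(config.f_exact_codes())
        prefixes = config.f_prefixes()
        if prefixes:
            is_f |= codes.str.startswith(prefixes)
        keep_m = inside & is_m.to_numpy()
        if config.dedupe_diagnoses:
            sub = diagnoses.loc[keep_m, ["person_id", "code", "date"]].drop_duplicates()
            m_count = sub.groupby(sub["person_id"].astype(str)).size()
        else:
            m_count = pid[keep_m].value_counts()
        f_count = pid[inside & is_f.to_numpy()].value_counts()
    else:
        m_count = f_count = zeros

    if len(prescriptions):
        pid, inside = window_mask(prescriptions, "date")
        is_op = prescriptions["atc_code"].astype(str).str.startswith(
            config.opioid_atc_prefix
        )
        keep = inside & is_op.to_numpy()
        sub = pd.DataFrame(
            {"person_id": pid[keep].to_numpy(),
             "day": _date_ordinals(prescriptions["date"])[keep]}
        ).sort_values(["person_id", "day"], kind="mergesort")
        rx_count = sub["person_id"].value_counts()
        same = sub["person_id"].to_numpy()[1:] == sub["person_id"].to_numpy()[:-1]
        gap = np.diff(sub["day"].to_numpy())
        pair_rows = same & (gap <= config.opioid_window_days)
        pair = pd.Series(pair_rows, index=sub.index[1:]).groupby(
            sub["person_id"].iloc[1:]
        ).any() if len(sub) > 1 else pd.Series(dtype=bool)
    else:
        rx_count = zeros
        pair = pd.Series(dtype=bool)

    if len(sick_leave):
        pid = sick_leave["person_id"].astype(str)
        anchor = pid.map(idx).to_numpy(dtype=float)
        start = _date_ordinals(sick_leave["start"]).astype(float)
        end = _date_ordinals(sick_leave["end"]).astype(float)
        win_start = anchor - (config.lookback_days - 1)
        overlap = np.minimum(end, anchor) - np.maximum(start, win_start) + 1
        overlap = np.where(np.isnan(anchor), 0, np.clip(overlap, 0, None))
        roots = sick_leave["attributed_code"].astype(str).str[:3]
        is_m = ((roots >= config.bp_code_low) & (roots <= config.bp_code_high)).to_numpy()
        sl_days = pd.Series(overlap * is_m, index=pid.index).groupby(pid).sum()
    else:
        sl_days = zeros

    out = pd.DataFrame(index=persons)
    out["m_diag_count"] = m_count.reindex(persons).fillna(0).astype(int)
    out["f_diag_count"] = f_count.reindex(persons).fillna(0).astype(int)
    out["opioid_rx_count"] = rx_count.reindex(persons).fillna(0).astype(int)
    out["opioid_rx_pair_within_window"] = (
        pair.reindex(persons, fill_value=False).astype(bool)
    )
    out["bp_sickleave_days"] = sl_days.reindex(persons).fillna(0).astype(int)

    cc3 = (out["bp_sickleave_days"] >= config.sickleave_chronic_days) | out[
        "opioid_rx_pair_within_window"
    ]
    cc2 = (out["bp_sickleave_days"] >= 1) | (out["f_diag_count"] >= 2)
    classifiable = out["m_diag_count"] >= 2
    cc = np.select([~classifiable, cc3, cc2], [0, 3, 2], default=1)
    cc_obj = np.array([int(v) if v else NOT_CLASSIFIABLE for v in cc], dtype=object)
    out["cc"] = cc_obj
    out["severe"] = cc == 3
    out.index.name = "person_id"
    return out.reset_index()
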