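"""Cohort construction: the data-preparation cascade of the study.

Three nested analysis populations are derived from the enrolment and
invoice tables:

1. **cost cohort** - everyone who submitted at least one invoice in the
   12 months before enrolment (persons with no invoices are excluded to
   limit deductible-driven under-reporting bias);
2. **validation cohort** - the subset who were invited by the insurer and
   enrolled within 90 days of the invitation (the chronicity class is only
   valid at invitation, so slow enrollers are dropped);
3. **sick-leave subgroup** - the further subset holding daily sickness
   benefit insurance with this insurer, for whom incapacity-to-work data
   are reliable (sensitivity analysis).

Both windows are closed intervals: "within 90 days" includes day 90, and
the invoice window is the 365 days ending at (and including) the
enrolment date. The two anchors differ by design: invoices are anchored
at enrolment, the classifier's lookback at invitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INVOICE_WINDOW_DAYS = 365
ENROLMENT_WINDOW_DAYS = 90


@dataclass
class Cohorts:
    """The three nested person-id sets and the cascade ledger."""

    cost_cohort: list[str]
    validation_cohort: list[str]
    sickleave_subgroup: list[str]
    ledger: dict[str, int]


def flag_invoice_availability(
    invoices: pd.DataFrame, enrolment_dates: pd.Series
) -> pd.Series:
    """True per person iff >= 1 invoice falls in the closed 365-day window
    ending at that person's enrolment date."""
    persons = enrolment_dates.index.astype(str)
    if not len(invoices):
        return pd.Series(False, index=persons)
    anchor = pd.Series(
        pd.to_datetime(enrolment_dates.to_numpy())
        .to_numpy(dtype="datetime64[D]").astype("int64"),
        index=persons,
    )
    pid = invoices["person_id"].astype(str)
    inv_day = (
        pd.to_datetime(invoices["date"]).to_numpy(dtype="datetime64[D]").astype("int64")
    ).astype(float)
    a = pid.map(anchor).to_numpy(dtype=float)
    inside = (~np.isnan(a)) & (inv_day <= a) & (inv_day >= a - (INVOICE_WINDOW_DAYS - 1))
    has = pid[inside].value_counts() > 0
    return has.reindex(persons, fill_value=False).astype(bool)


def flag_enrolment_window(enrolment: pd.DataFrame) -> pd.Series:
    """True per person iff invited and enrolled at most 90 days after the
    invitation; self-selected persons are always False."""
    persons = enrolment["person_id"].astype(str)
    invited = (enrolment["path"] == "invited").to_numpy()
    gap = (
        pd.to_datetime(enrolment["enrolment_date"])
        - pd.to_datetime(enrolment["invitation_date"])
    ).dt.days.to_numpy(dtype=float)
    ok = invited & (gap <= ENROLMENT_WINDOW_DAYS) & (gap >= 0)
    return pd.Series(ok, index=persons.to_numpy())


def build_flags(enrolment: pd.DataFrame, invoices: pd.DataFrame) -> pd.DataFrame:
    """One row per enrolled person with the cascade flags."""
    persons = enrolment["person_id"].astype(str).to_numpy()
    enrol_dates = pd.Series(
        pd.to_datetime(enrolment["enrolment_date"]).to_numpy(), index=persons
    )
    flags = pd.DataFrame(
        {
            "person_id": persons,
            "has_any_invoice_12mo": flag_invoice_availability(
                invoices, enrol_dates
            ).to_numpy(),
            "invited": (enrolment["path"] == "invited").to_numpy(),
            "enrolled_within_90d": flag_enrolment_window(enrolment).to_numpy(),
            "sick_leave_insured": enrolment["sick_leave_insured"].astype(bool).to_numpy(),
        }
    )
    return flags


def select_cohorts(flags: pd.DataFrame) -> Cohorts:
    """Apply the cascade and return the nested cohorts with a counts ledger.

    The ledger mirrors the study-population preparation table: overall
    size, invoice exclusion, invited restriction, 90-day window, and the
    sick-leave-insured subgroup.
    """
    f = flags.set_index(flags["person_id"].astype(str))
    cost = f["has_any_invoice_12mo"]
    invited = cost & f["invited"]
    within = invited & f["enrolled_within_90d"]
    sick = within & f["sick_leave_insured"]

    ledger = {
        "study_size": int(len(f)),
        "with_invoice_12mo": int(cost.sum()),
        "invited": int(invited.sum()),
        "enrolled_within_90d": int(within.sum()),
        "plus_sick_leave_insured": int(sick.sum()),
    }
    return Cohorts(
        cost_cohort=sorted(f.index[cost]),
        validation_cohort=sorted(f.index[within]),
        sickleave_subgroup=sorted(f.index[sick]),
        ledger=ledger,
    )
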