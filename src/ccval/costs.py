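"""Direct health-care cost aggregation and outlier-robust summaries.

Costs are the billed amounts of submitted invoices in the 12 months
before enrolment, summed per person into four categories: total health,
back-pain (BP) inpatient, BP outpatient, and the derived BP total
(inpatient + outpatient). Nominal amounts are converted to base-year
euros with consumer price indices (amount * cpi[base] / cpi[year]).

Because health-care costs are heavily right-skewed, each category is
summarised both raw and truncated:

* **high-cost cases** lie above the Tukey upper fence Q3 + 1.5 * IQR
  (upper outliers only), with quartiles by linear interpolation between
  order statistics (the "type 7" convention) computed over the whole
  analysis cohort so that per-group outlier percentages share one fence;
* **low-cost cases** submitted no invoice of that category in the window
  (presence, not amount: a single 1-cent invoice is not low-cost);
* the **truncated mean** averages the values with neither flag;
* **skewness** is the adjusted Fisher-Pearson standardised third moment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COST_CATEGORIES = ("total_health", "bp_total", "bp_inpatient", "bp_outpatient")
COST_WINDOW_DAYS = 365

#: German consumer price index, 2020 = 100 (editable placeholders).
DEFAULT_CPI = {
    2013: 92.2, 2014: 93.1, 2015: 93.6, 2016: 94.0, 2017: 95.4,
    2018: 97.1, 2019: 98.5, 2020: 100.0, 2021: 103.1,
}
DEFAULT_BASE_YEAR = 2020


@dataclass(frozen=True)
class CostVector:
    """Per-person 12-month sums, in base-year euros."""

    person_id: str
    total_health: float
    bp_inpatient: float
    bp_outpatient: float

    @property
    def bp_total(self) -> float:
        return self.bp_inpatient + self.bp_outpatient


@dataclass
class CostSummary:
    """One group x category row of the cost table."""

    group: str
    category: str
    n: int
    mean: float
    sd: float
    q1: float
    q3: float
    iqr: float
    upper_fence: float
    n_high_cost: int
    pct_high_cost: float
    n_low_cost: int
    pct_low_cost: float
    truncated_mean: float | None
    truncated_sd: float | None
    skew: float
    skew_truncated: float | None


def cpi_adjust(
    amount: float | np.ndarray,
    invoice_year: int | np.ndarray,
    cpi_table: dict[int, float] | None = None,
    base_year: int = DEFAULT_BASE_YEAR,
) -> float | np.ndarray:
    """Convert nominal euros of ``invoice_year`` to base-year euros."""
    cpi = DEFAULT_CPI if cpi_table is None else cpi_table
    if not cpi:
        raise KeyError("empty CPI table")
    if base_year not in cpi:
        raise KeyError(f"base year {base_year} missing from CPI table")
    if np.isscalar(invoice_year):
        if invoice_year not in cpi:
            raise KeyError(f"invoice year {invoice_year} missing from CPI table")
        return amount * cpi[base_year] / cpi[invoice_year]
    years = np.asarray(invoice_year)
    missing = set(np.unique(years)) - set(cpi)
    if missing:
        raise KeyError(f"invoice years missing from CPI table: {sorted(missing)}")
    factors = np.vectorize(lambda y: cpi[base_year] / cpi[int(y)])(years)
    return np.asarray(amount, dtype=float) * factors


def aggregate_costs(
    invoices: pd.DataFrame,
    enrolment_dates: pd.Series,
    cpi_table: dict[int, float] | None = None,
    base_year: int = DEFAULT_BASE_YEAR,
) -> pd.DataFrame:
    """Per-person CPI-adjusted category sums over the closed 365-day window
    ending at each person's enrolment date.

    Returns one row per person in ``enrolment_dates`` (persons with no
    invoices get zeros) with columns for all four categories plus
    per-category invoice counts used by the low-cost flags.
    """
    persons = enrolment_dates.index.astype(str)
    base_cats = ("total_health", "bp_inpatient", "bp_outpatient")
    out = pd.DataFrame(index=persons)
    if len(invoices):
        anchor = pd.Series(
            pd.to_datetime(enrolment_dates.to_numpy())
            .to_numpy(dtype="datetime64[D]").astype("int64"),
            index=persons,
        )
        pid = invoices["person_id"].astype(str)
        day = (
            pd.to_datetime(invoices["date"]).to_numpy(dtype="datetime64[D]")
            .astype("int64").astype(float)
        )
        a = pid.map(anchor).to_numpy(dtype=float)
        inside = (~np.isnan(a)) & (day <= a) & (day >= a - (COST_WINDOW_DAYS - 1))
        adj = cpi_adjust(
            invoices["amount"].to_numpy(dtype=float),
            invoices["year"].to_numpy(dtype=int),
            cpi_table, base_year,
        )
        sub = pd.DataFrame(
            {"person_id": pid.to_numpy(), "category": invoices["category"].to_numpy(),
             "amount": adj}
        ).loc[inside]
        sums = sub.pivot_table(
            index="person_id", columns="category", values="amount", aggfunc="sum"
        )
        counts = sub.pivot_table(
            index="person_id", columns="category", values="amount", aggfunc="size"
        )
    else:
        sums = counts = pd.DataFrame()
    for cat in base_cats:
        s = sums[cat] if cat in sums else pd.Series(dtype=float)
        c = counts[cat] if cat in counts else pd.Series(dtype=float)
        out[cat] = s.reindex(persons).fillna(0.0)
        out[f"n_invoices_{cat}"] = c.reindex(persons).fillna(0).astype(int)
    out["bp_total"] = out["bp_inpatient"] + out["bp_outpatient"]
    out["n_invoices_bp_total"] = (
        out["n_invoices_bp_inpatient"] + out["n_invoices_bp_outpatient"]
    )
    out.index.name = "person_id"
    return out.reset_index()


def tukey_upper_fence(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Upper Tukey fence Q3 + 1.5 * IQR and the above-fence flags.

    Only the upper fence is applied (costs are bounded below by zero and
    interest lies in high-cost outliers).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least four values for quartile fences")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear ("type 7") interpolation
    fence = q3 + 1.5 * (q3 - q1)
    return float(fence), values > fence


def flag_low_cost(invoice_counts: np.ndarray) -> np.ndarray:
    """Low-cost flag: no invoice of the category in the window."""
    return np.asarray(invoice_counts) == 0


def truncated_mean(
    values: np.ndarray, high_flags: np.ndarray, low_flags: np.ndarray
) -> float:
    """Mean over values that are neither high-cost nor low-cost cases."""
    values = np.asarray(values, dtype=float)
    keep = ~(np.asarray(high_flags, bool) | np.asarray(low_flags, bool))
    if not keep.any():
        raise ValueError("no values survive truncation")
    return float(values[keep].mean())


def skewness(values: np.ndarray) -> float:
    """Adjusted Fisher-Pearson sample skewness; NaN for constant input."""
    values = np.asarray(values, dtype=float)
    if values.size < 3 or np.ptp(values) == 0:
        return float("nan")
    return float(stats.skew(values, bias=False))


def cost_table_by_group(
    cost_vectors: pd.DataFrame,
    group_labels: pd.Series,
    categories: tuple[str, ...] = COST_CATEGORIES,
) -> pd.DataFrame:
    """Per-(group, category) cost summaries plus an overall row per category.

    ``cost_vectors`` is the output of :func:`aggregate_costs`;
    ``group_labels`` maps person_id -> group (e.g. GCPS grade). High-cost
    fences are computed once per category over the whole cohort, so group
    percentages are shares of globally flagged cases.
    """
    df = cost_vectors.set_index(cost_vectors["person_id"].astype(str))
    groups = group_labels.astype(str)
    df = df.loc[df.index.intersection(groups.index)]
    rows: list[CostSummary] = []
    for cat in categories:
        values = df[cat].to_numpy(dtype=float)
        fence, high = tukey_upper_fence(values)
        low = flag_low_cost(df[f"n_invoices_{cat}"].to_numpy())
        if cat == "total_health" and low.any():
            warnings.warn(
                "zero-invoice persons present in the total-health category; "
                "upstream cohort selection normally removes them",
                stacklevel=2,
            )
        labels = groups.reindex(df.index)
        for group in ["overall", *sorted(labels.unique())]:
            mask = np.ones(len(df), bool) if group == "overall" \
                else (labels == group).to_numpy()
            rows.append(_summarise(group, cat, values[mask], high[mask], low[mask],
                                   fence))
    out = pd.DataFrame([vars(r) for r in rows])
    return out


def _summarise(
    group: str, cat: str, values: np.ndarray, high: np.ndarray, low: np.ndarray,
    fence: float,
) -> CostSummary:
    n = len(values)
    q1, q3 = (np.quantile(values, [0.25, 0.75]) if n else (float("nan"),) * 2)
    keep = ~(high | low)
    trunc = values[keep]
    return CostSummary(
        group=group,
        category=cat,
        n=n,
        mean=float(values.mean()) if n else float("nan"),
        sd=float(values.std(ddof=1)) if n > 1 else float("nan"),
        q1=float(q1),
        q3=float(q3),
        iqr=float(q3 - q1),
        upper_fence=fence,
        n_high_cost=int(high.sum()),
        pct_high_cost=float(high.mean() * 100) if n else float("nan"),
        n_low_cost=int(low.sum()),
        pct_low_cost=float(low.mean() * 100) if n else float("nan"),
        truncated_mean=float(trunc.mean()) if len(trunc) else None,
        truncated_sd=float(trunc.std(ddof=1)) if len(trunc) > 1 else None,
        skew=skewness(values),
        skew_truncated=skewness(trunc) if len(trunc) else None,
    )
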