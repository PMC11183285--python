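"""Summary artifacts: subtype shares, ROI atrophy flags, conversion and
APOE reports, cognitive trajectories, and baseline group comparisons.

All percentages are rounded half-up to one decimal, the convention that
reproduces standard clinical-table arithmetic such as 103/396 -> 26.0%.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .longitudinal_screen import PERIODS, ScreenResult

COGNITIVE_SCALES = (
    "MMSE", "CDRSB", "ADAS13", "FAQ", "ADNI_MEM", "ADNI_EF", "ADNI_LAN", "ADNI_VS",
)
CONTINUOUS_VARS = ("age", "education_years") + COGNITIVE_SCALES


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """100 * count / total, rounded half-up to ``ndigits`` decimals."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


def _merge_assignments(assignments: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    sub = subjects.copy()
    sub["subject_id"] = sub["subject_id"].astype(str)
    merged = assignments.merge(sub, on="subject_id", how="left", validate="one_to_one")
    missing = merged.loc[merged["diagnosis"].isna(), "subject_id"]
    if len(missing):
        raise KeyError(
            "assigned subjects missing from the subject table: "
            + ", ".join(missing.astype(str).head(5))
        )
    return merged


def is_carrier(subjects: pd.DataFrame, allele: str) -> pd.Series:
    """Carrier = at least one copy of the allele; NaN when genotype missing."""
    a1, a2 = subjects["apoe_a1"], subjects["apoe_a2"]
    missing = a1.isna() | a2.isna()
    carrier = (a1 == allele) | (a2 == allele)
    return carrier.mask(missing)


def subtype_share_table(
    assignments: pd.DataFrame, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Counts, percentage shares and covariate/cognitive means per subtype."""
    merged = _merge_assignments(assignments, subjects)
    total = len(merged)
    rows = []
    for label, grp in merged.groupby("subtype_label", sort=False):
        row: dict = {"subtype": label, "n": len(grp), "share_pct": percent(len(grp), total)}
        for var in CONTINUOUS_VARS:
            if var in grp.columns:
                row[f"{var}_mean"] = float(grp[var].mean())
                row[f"{var}_sd"] = float(grp[var].std(ddof=1)) if len(grp) > 1 else float("nan")
        if {"apoe_a1", "apoe_a2"}.issubset(grp.columns):
            for allele in ("e4", "e2"):
                carriers = is_carrier(grp, allele)
                n_known = int(carriers.notna().sum())
                n_car = int((carriers == True).sum())  # noqa: E712 -- NaN-safe
                row[f"apoe_{allele}_n"] = n_car
                row[f"apoe_{allele}_pct"] = (
                    percent(n_car, n_known) if n_known else float("nan")
                )
        rows.append(row)
    return pd.DataFrame(rows)


def roi_atrophy_flags(
    features: pd.DataFrame,
    groups: pd.Series,
    reference: str = "CN",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-ROI Welch comparison of each group against the reference group.

    Flags an ROI when the two-sided p-value is below ``alpha``; the effect
    direction records the sign of (group mean - reference mean). Identical
    degenerate samples (zero variance, equal means) short-circuit to an
    unflagged p = 1. Requires at least two subjects per compared group.
    """
    groups = groups.loc[features.index]
    ref = features[groups == reference].to_numpy(float)
    if ref.shape[0] < 2:
        raise ValueError(f"reference group {reference!r} needs >= 2 subjects")
    rows = []
    for label in [g for g in groups.unique() if g != reference]:
        grp = features[groups == label].to_numpy(float)
        if grp.shape[0] < 2:
            raise ValueError(f"group {label!r} needs >= 2 subjects")
        for j, roi in enumerate(features.columns):
            a, b = grp[:, j], ref[:, j]
            if a.std() == 0.0 and b.std() == 0.0:
                p = 1.0 if a.mean() == b.mean() else 0.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            diff = float(a.mean() - b.mean())
            rows.append({
                "group": label, "roi": roi, "p_value": p,
                "flag": bool(p < alpha),
                "direction": int(np.sign(diff)), "mean_diff": diff,
            })
    return pd.DataFrame(rows)


def conversion_counts(
    events: pd.DataFrame, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Per-subtype per-period converter counts from screened event lists."""
    conv = events[events["to"] == "AD"].copy()
    conv["subject_id"] = conv["subject_id"].astype(str)
    lab = assignments.set_index("subject_id")["subtype_label"]
    conv["subtype"] = conv["subject_id"].map(lab).fillna("unknown")
    table = (
        conv.groupby(["subtype", "visit"]).size().unstack(fill_value=0)
        .reindex(columns=list(PERIODS), fill_value=0)
    )
    table.columns.name = None
    return table.reset_index()


def cumulative_conversions(per_period: pd.DataFrame) -> pd.DataFrame:
    """Sum per-period converter counts into cumulative totals per subtype."""
    counts = per_period.set_index("subtype")[list(PERIODS)]
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative converter counts")
    out = counts.copy()
    out["total"] = counts.sum(axis=1)
    return out.reset_index()


def conversion_rate_series(
    events: pd.DataFrame, assignments: pd.DataFrame, at_risk_by_subtype: dict[str, dict[str, int]]
) -> pd.DataFrame:
    """Per-subtype per-period conversion rates with at-risk denominators."""
    counts = conversion_counts(events, assignments).set_index("subtype")
    rows = []
    for subtype, row in counts.iterrows():
        for period in PERIODS:
            n_risk = at_risk_by_subtype.get(str(subtype), {}).get(period, 0)
            n_conv = int(row[period])
            rate = n_conv / n_risk if n_risk else float("nan")
            rows.append((subtype, period, n_risk, n_conv, rate))
    return pd.DataFrame(rows, columns=["subtype", "period", "n_at_risk", "n_convert", "rate"])


def apoe_carrier_stats(
    events: pd.DataFrame, assignments: pd.DataFrame, subjects: pd.DataFrame
) -> pd.DataFrame:
    """APOE e4/e2 carrier counts and percentages among converters per subtype.

    Subjects with missing genotype are counted in an explicit ``apoe_missing``
    column, never silently dropped; percentages use the genotyped converters
    as denominator.
    """
    conv = events[events["to"] == "AD"].copy()
    conv["subject_id"] = conv["subject_id"].astype(str)
    lab = assignments.set_index("subject_id")["subtype_label"]
    conv["subtype"] = conv["subject_id"].map(lab).fillna("unknown")
    sub = subjects.copy()
    sub["subject_id"] = sub["subject_id"].astype(str)
    merged = conv.merge(sub, on="subject_id", how="left")
    rows = []
    for subtype, grp in merged.groupby("subtype", sort=False):
        e4 = is_carrier(grp, "e4")
        e2 = is_carrier(grp, "e2")
        n_known = int(e4.notna().sum())
        row = {
            "subtype": subtype,
            "n_converters": len(grp),
            "apoe_missing": len(grp) - n_known,
        }
        for name, series in (("e4", e4), ("e2", e2)):
            n_car = int((series == True).sum())  # noqa: E712 -- NaN-safe
            row[f"{name}_carriers"] = n_car
            row[f"{name}_pct"] = percent(n_car, n_known) if n_known else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def trajectory_means(
    scores: pd.DataFrame,
    assignments: pd.DataFrame,
    result: ScreenResult,
    scales: tuple[str, ...] = COGNITIVE_SCALES,
) -> pd.DataFrame:
    """Mean +/- sd per subtype per visit over subjects retained at that visit.

    ``scores`` is a long table (subject_id, visit, one column per scale).
    Baseline uses the full screened baseline set; each follow-up period uses
    its at-risk set (no carry-forward of dropped subjects).
    """
    retained = {"bl": set(result.baseline)}
    retained.update({p: set(ids) for p, ids in result.at_risk.items()})
    lab = assignments.set_index("subject_id")["subtype_label"]
    sc = scores.copy()
    sc["subject_id"] = sc["subject_id"].astype(str)
    sc["subtype"] = sc["subject_id"].map(lab)
    rows = []
    for visit, ids in retained.items():
        frame = sc[(sc["visit"] == visit) & sc["subject_id"].isin(ids)]
        for subtype, grp in frame.groupby("subtype", sort=False):
            for scale in scales:
                if scale not in grp.columns:
                    continue
                vals = grp[scale].dropna()
                rows.append({
                    "subtype": subtype, "visit": visit, "scale": scale,
                    "n": len(vals),
                    "mean": float(vals.mean()) if len(vals) else float("nan"),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                })
    return pd.DataFrame(rows)


def group_comparison_table(
    assignments: pd.DataFrame,
    subjects: pd.DataFrame,
    continuous: tuple[str, ...] = CONTINUOUS_VARS,
    dunnett_alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA across subtypes per continuous variable, chi-square for
    APOE carrier proportions; Dunnett-style post-hoc p-values (vs the first
    subtype) are reported only when the ANOVA is significant.

    Groups with fewer than two subjects cause the variable to be skipped with
    a note rather than an error.
    """
    merged = _merge_assignments(assignments, subjects)
    grouped = [g for _, g in merged.groupby("subtype_label", sort=False)]
    labels = [str(g["subtype_label"].iloc[0]) for g in grouped]
    rows = []
    for var in continuous:
        if var not in merged.columns:
            continue
        samples = [g[var].dropna().to_numpy(float) for g in grouped]
        if any(len(s) < 2 for s in samples) or len(samples) < 2:
            rows.append({"variable": var, "test": "anova", "p_value": float("nan"),
                         "note": "group with n < 2; skipped"})
            continue
        p = float(stats.f_oneway(*samples).pvalue)
        note = ""
        if p < dunnett_alpha and len(samples) > 2:
            post = stats.dunnett(*samples[1:], control=samples[0])
            note = "dunnett_vs_" + labels[0] + ": " + ", ".join(
                f"{lab}={pv:.3g}" for lab, pv in zip(labels[1:], post.pvalue)
            )
        rows.append({"variable": var, "test": "anova", "p_value": p, "note": note})
    if {"apoe_a1", "apoe_a2"}.issubset(merged.columns):
        for allele in ("e4", "e2"):
            table = []
            for g in grouped:
                car = is_carrier(g, allele).dropna()
                table.append([int(car.sum()), int((~car.astype(bool)).sum())])
            arr = np.array(table)
            if arr.sum(axis=1).min() == 0 or arr.shape[0] < 2:
                continue
            if arr.sum(axis=0).min() == 0:  # no carriers (or all) anywhere
                rows.append({"variable": f"apoe_{allele}_carrier", "test": "chi2",
                             "p_value": float("nan"),
                             "note": "degenerate contingency table; skipped"})
                continue
            p = float(stats.chi2_contingency(arr).pvalue)
            rows.append({"variable": f"apoe_{allele}_carrier", "test": "chi2",
                         "p_value": p, "note": ""})
    return pd.DataFrame(rows)
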