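"""Visit screening for longitudinal MCI follow-up with a 24-month cut-off.

Subjects enter at baseline with an MCI diagnosis and a baseline scan. The
follow-up grid (m06, m12, m18, m24, plus m36 as a recovery visit) is
screened in two coupled passes:

* a scan-pattern rule decides, per period, whether a subject is followable:
  a subject with an M24 scan is retained at every period; one without an
  M24 scan is retained at a period only if it has both that period's scan
  and an M36 scan (the M36 visit substitutes for the missing cut-off);
* a forward diagnostic sweep over m06 -> m24 records the first visit at
  which a retained subject is observed AD (conversion) or CN (reversion);
  the event is terminal and the subject leaves every later at-risk set.

A subject with no M24 scan who stays MCI is kept for the M24 period only
when all of m06-m18 and m36 were scanned and the m36 diagnosis is still
MCI (status ``imputed_from_m36``); if the m36 state is AD or CN the
conversion time is indeterminable and the subject is excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PERIODS: tuple[str, ...] = ("m06", "m12", "m18", "m24")
ALL_VISITS: tuple[str, ...] = ("bl", "m06", "m12", "m18", "m24", "m36")

REASON_NO_BASELINE = "no_baseline_mci"
REASON_INDETERMINATE = "missing_followup_indeterminate"
REASON_CONVERTED = "converted_prior_period"
REASON_REVERTED = "reverted_prior_period"
STATUS_IMPUTED = "imputed_from_m36"

M24_OBSERVED = "observed"
M24_IMPUTED = "imputed_mci_from_m36"
M24_EXCLUDED = "excluded_indeterminate"


class DataConsistencyError(ValueError):
    """A diagnosis is recorded at a visit without a scan (strict mode)."""


@dataclass
class ScreenResult:
    """Retained sets, reason-coded exclusions and terminal events."""

    baseline: list[str]
    at_risk: dict[str, list[str]]                 # period -> subject ids
    events: pd.DataFrame                          # subject_id, visit, to
    exclusions: pd.DataFrame                      # subject_id, reason (one each)
    period_removals: pd.DataFrame = field(default_factory=pd.DataFrame)
    m24_status: dict[str, str] = field(default_factory=dict)


def _subject_grids(visits: pd.DataFrame) -> tuple[dict, dict]:
    """Per subject: visit -> scan flag and visit -> diagnosis."""
    scans: dict[str, dict[str, bool]] = {}
    diags: dict[str, dict[str, str]] = {}
    for row in visits.itertuples(index=False):
        sid = str(row.subject_id)
        scans.setdefault(sid, {})[row.visit] = bool(row.scan_present)
        dx = getattr(row, "diagnosis", None)
        if isinstance(dx, str) and dx and dx.lower() != "missing":
            diags.setdefault(sid, {})[row.visit] = dx
    return scans, diags


def screen_baseline(visits: pd.DataFrame) -> tuple[list[str], pd.DataFrame]:
    """Subjects with baseline diagnosis MCI and a baseline scan.

    Returns (retained ids, exclusions with reason ``no_baseline_mci``).
    """
    scans, diags = _subject_grids(visits)
    kept, excluded = [], []
    for sid in sorted(scans):
        if scans[sid].get("bl", False) and diags.get(sid, {}).get("bl") == "MCI":
            kept.append(sid)
        else:
            excluded.append((sid, REASON_NO_BASELINE))
    return kept, pd.DataFrame(excluded, columns=["subject_id", "reason"])


def retained_by_scan_pattern(has_scan: dict[str, bool], period: str) -> bool:
    """The cut-off scan rule, isolated so alternative readings can be swapped.

    Retained at a period iff the subject has an M24 scan, or has this
    period's scan together with an M36 scan despite the missing M24.
    """
    if has_scan.get("m24", False):
        return True
    return has_scan.get(period, False) and has_scan.get("m36", False)


def resolve_m24(has_scan: dict[str, bool], diagnosis: dict[str, str]) -> str:
    """Classify a non-event subject's standing at the M24 cut-off."""
    if has_scan.get("m24", False):
        return M24_OBSERVED
    full_track = all(has_scan.get(v, False) for v in ("m06", "m12", "m18", "m36"))
    if full_track and diagnosis.get("m36") == "MCI":
        return M24_IMPUTED
    return M24_EXCLUDED


def screen_periods(
    visits: pd.DataFrame,
    baseline: list[str] | None = None,
    require_scan: bool = True,
    strict: bool = False,
) -> ScreenResult:
    """Forward sweep m06 -> m24 producing at-risk sets and terminal events.

    ``require_scan`` (default) honors a diagnosis for event detection only
    at visits with a scan; with ``require_scan=False`` scan-less clinical
    diagnoses also trigger events (each is warned about, or raises when
    ``strict``). Conversion and reversion are absorbing: an event at period
    p removes the subject from every later at-risk set (removal reason
    ``converted_prior_period`` / ``reverted_prior_period``).
    """
    scans, diags = _subject_grids(visits)
    if baseline is None:
        baseline, base_excl = screen_baseline(visits)
    else:
        baseline = [str(s) for s in baseline]
        base_excl = pd.DataFrame(columns=["subject_id", "reason"])

    _audit_scanless(visits, strict)

    alive = list(baseline)
    at_risk: dict[str, list[str]] = {}
    events, removals, exclusions = [], [], []
    m24_status: dict[str, str] = {}
    for period in PERIODS:
        if period == "m24":
            # at the cut-off period the resolution itself decides membership
            current = []
            for sid in alive:
                status = resolve_m24(scans[sid], diags.get(sid, {}))
                m24_status[sid] = status
                if status == M24_EXCLUDED:
                    exclusions.append((sid, REASON_INDETERMINATE))
                else:
                    current.append(sid)
            alive = current
            risk = list(alive)
        else:
            # sequential screening: a subject failing the retention rule at
            # one period is out of every later set as well, so at-risk
            # counts are monotone non-increasing
            risk = [s for s in alive if retained_by_scan_pattern(scans[s], period)]
            for sid in set(alive) - set(risk):
                m24_status[sid] = resolve_m24(scans[sid], diags.get(sid, {}))
                exclusions.append((sid, REASON_INDETERMINATE))
            alive = list(risk)
        at_risk[period] = risk
        for sid in risk:
            observed = scans[sid].get(period, False) or not require_scan
            dx = diags.get(sid, {}).get(period)
            if not observed or dx is None:
                continue
            if dx == "AD":
                events.append((sid, period, "AD"))
            elif dx == "CN":
                events.append((sid, period, "CN"))
            else:
                continue
            alive = [s for s in alive if s != sid]
            reason = REASON_CONVERTED if dx == "AD" else REASON_REVERTED
            for later in PERIODS[PERIODS.index(period) + 1 :]:
                removals.append((sid, later, reason))
    excl = pd.concat(
        [base_excl, pd.DataFrame(exclusions, columns=["subject_id", "reason"])],
        ignore_index=True,
    )
    return ScreenResult(
        baseline=baseline,
        at_risk=at_risk,
        events=pd.DataFrame(events, columns=["subject_id", "visit", "to"]),
        exclusions=excl,
        period_removals=pd.DataFrame(removals, columns=["subject_id", "period", "reason"]),
        m24_status=m24_status,
    )


def _audit_scanless(visits: pd.DataFrame, strict: bool) -> None:
    mask = (visits["scan_present"].astype(int) == 0) & visits["diagnosis"].isin(
        ["CN", "AD"]
    ) & visits["visit"].isin(PERIODS)
    if mask.any():
        msg = (
            f"{int(mask.sum())} period rows carry a diagnosis without a scan; "
            "event detection honors scans only (require_scan=True)"
        )
        if strict:
            raise DataConsistencyError(msg)
        warnings.warn(msg, stacklevel=3)


def at_risk_series(result: ScreenResult) -> pd.DataFrame:
    """Per-period at-risk counts, converters, reverters and conversion rate.

    The rate is converters / at-risk for the period; a period with an empty
    at-risk set reports NaN (not applicable). A nonzero event count with an
    empty at-risk set is an impossible state and raises.
    """
    rows = []
    for period in PERIODS:
        n_risk = len(result.at_risk.get(period, []))
        ev = result.events[result.events["visit"] == period]
        n_conv = int((ev["to"] == "AD").sum())
        n_rev = int((ev["to"] == "CN").sum())
        if n_risk == 0 and (n_conv or n_rev):
            raise ValueError(f"period {period}: events recorded with empty at-risk set")
        rate = n_conv / n_risk if n_risk else float("nan")
        rows.append((period, n_risk, n_conv, n_rev, rate))
    return pd.DataFrame(
        rows, columns=["period", "n_at_risk", "n_convert", "n_revert", "rate"]
    )
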