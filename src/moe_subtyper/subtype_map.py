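"""Severity naming of experts and min-distance mapping of MCI subjects.

AD subjects carry fuzzy memberships, so their subtype is the argmax
membership expert. MCI subjects have no memberships; each is assigned to
the expert whose hyperplane lies closest to its residualized features,
using the unsigned geometric distance |w.x + b| / ||w||_2. Converters are
re-assigned at their conversion visit with the same rule to build the
baseline-to-conversion transition table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .moe_core import MOEModel
from .synth_cohort import VISIT_MONTHS

K3_LABELS = ("MIN", "MID", "DIF")


class DegenerateExpertError(ValueError):
    """An expert has a zero weight vector; distances are undefined."""


def hyperplane_distances(
    model: MOEModel, X: np.ndarray, signed: bool = False
) -> np.ndarray:
    """Per-expert distance of each row to the expert hyperplane.

    Unsigned geometric distance by default; ``signed=True`` keeps the sign of
    the decision value (positive toward the AD side), for sensitivity
    analyses. Invariant under joint rescaling of (w, b).
    """
    X = np.atleast_2d(np.asarray(X, float))
    cols = []
    for k, e in enumerate(model.experts):
        norm = float(np.linalg.norm(e.w))
        if norm == 0.0:
            raise DegenerateExpertError(f"expert {k} has a zero weight vector")
        val = e.decision(X) / norm
        cols.append(val if signed else np.abs(val))
    return np.column_stack(cols)


def assign_min_distance(
    model: MOEModel,
    residuals: pd.DataFrame,
    labels: dict[int, str] | None = None,
    signed: bool = False,
) -> pd.DataFrame:
    """Assign each subject (row of ``residuals``) to its nearest hyperplane.

    Ties resolve to the lowest expert index. Returns a table with the full
    distance vector, ``d_min`` and, when a label map is given, the subtype
    label.
    """
    D = hyperplane_distances(model, residuals.to_numpy(float), signed=signed)
    k_star = D.argmin(axis=1)
    out = pd.DataFrame({"subject_id": residuals.index.astype(str), "expert_index": k_star})
    if labels is not None:
        out["subtype_label"] = [labels[int(k)] for k in k_star]
    for k in range(model.K):
        out[f"d_{k + 1}"] = D[:, k]
    out["d_min"] = D[np.arange(len(D)), k_star]
    return out


def assign_ad_by_membership(
    model: MOEModel, labels: dict[int, str] | None = None
) -> pd.DataFrame:
    """AD subjects' subtype = argmax membership (lowest index on ties)."""
    k_star = model.memberships.argmax(axis=1)
    out = pd.DataFrame({"subject_id": list(model.ad_ids), "expert_index": k_star})
    if labels is not None:
        out["subtype_label"] = [labels[int(k)] for k in k_star]
    return out


def rank_and_name_subtypes(model: MOEModel, residuals: pd.DataFrame) -> dict[int, str]:
    """Name experts by atrophy severity of their argmax-membership AD members.

    Severity = mean over members of the subject-mean ROI residual; more
    negative means more atrophy. For K = 3 the labels are MIN (least
    atrophy), MID, DIF; otherwise S1 (mildest) ... SK (severest). Ties rank
    by expert index.
    """
    ad_ids = [i for i in model.ad_ids if i in residuals.index]
    if len(ad_ids) != len(model.ad_ids):
        missing = set(model.ad_ids) - set(map(str, residuals.index))
        raise ValueError(f"residuals missing AD subjects: {sorted(missing)[:5]}")
    member_of = model.memberships.argmax(axis=1)
    mean_resid = residuals.loc[list(model.ad_ids)].to_numpy(float).mean(axis=1)
    severity = np.empty(model.K)
    for k in range(model.K):
        members = member_of == k
        if not members.any():
            raise ValueError(f"expert {k} has no argmax-membership AD members")
        severity[k] = mean_resid[members].mean()
    # least negative residual = least atrophy; stable sort keeps index order on ties
    order = np.argsort(-severity, kind="stable")
    names = K3_LABELS if model.K == 3 else tuple(f"S{i + 1}" for i in range(model.K))
    return {int(k): names[rank] for rank, k in enumerate(order)}


def attribute_converters(
    model: MOEModel,
    glm_fit,
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    thickness_by_visit: dict[str, pd.DataFrame],
    baseline_assignments: pd.DataFrame,
    labels: dict[int, str] | None = None,
    use_visit_age: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign converters to AD subtypes at their conversion visit.

    ``events`` must hold columns (subject_id, visit, to) with to == 'AD' for
    conversions; conversion-visit thickness is residualized with the baseline
    CN GLM fit before the min-distance rule. Converters whose conversion
    visit lacks a scan table entry are reported with subtype 'unattributable'
    rather than dropped. Returns (per-converter assignments, transition
    counts baseline_subtype x ad_subtype_at_conversion).
    """
    from .harmonize import residualize

    conv = events[events["to"] == "AD"]
    base = baseline_assignments.set_index("subject_id")
    rows = []
    for _, ev in conv.iterrows():
        sid, visit = str(ev["subject_id"]), str(ev["visit"])
        table = thickness_by_visit.get(visit)
        base_label = (
            str(base.loc[sid, "subtype_label"]) if sid in base.index else "unknown"
        )
        if table is None or sid not in table.index:
            rows.append((sid, visit, base_label, None, "unattributable"))
            continue
        feats = table.loc[[sid]]
        sub_v = subjects
        if use_visit_age and "age" in subjects.columns:
            sub_v = subjects.copy()
            sub_v["age"] = sub_v["age"] + VISIT_MONTHS.get(visit, 0) / 12.0
        resid = residualize(feats, sub_v, glm_fit)
        assign = assign_min_distance(model, resid, labels=labels)
        k = int(assign["expert_index"].iloc[0])
        lab = labels[k] if labels is not None else f"expert_{k}"
        rows.append((sid, visit, base_label, k, lab))
    result = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "conversion_visit", "baseline_subtype",
            "expert_index", "ad_subtype_at_conversion",
        ],
    )
    transition = (
        result.groupby(["baseline_subtype", "ad_subtype_at_conversion"])
        .size()
        .reset_index(name="count")
    )
    return result, transition
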