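"""Seeded synthetic ADNI-like cohort generator.

Builds cross-sectional and longitudinal tables of Desikan-Killiany cortical
thickness with planted atrophy subtypes, covariate effects, APOE genotypes,
visit missingness and MCI-to-AD conversion events, so that every downstream
stage of the subtyping pipeline is testable without access to restricted
clinical data.

The generative model per subject and ROI is

    thickness = baseline + beta_age*age + beta_sex*sex + beta_edu*edu
                + beta_icv*icv - scale * template_weight + N(0, noise_sd)

where ``scale`` is 1 for AD, ``mci_scale`` for MCI and 0 for CN, and
``template_weight`` is the subtype's per-ROI atrophy magnitude in mm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# ROI naming: the 34 Desikan-Killiany cortical parcels per hemisphere.
# Column order is fixed and identical across every table emitted in a run.
# ---------------------------------------------------------------------------

DK_REGIONS: tuple[str, ...] = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)

ROI_NAMES: tuple[str, ...] = tuple(
    f"{hemi}_{region}_thickness" for hemi in ("lh", "rh") for region in DK_REGIONS
)
N_ROIS = len(ROI_NAMES)  # 68

TEMPORAL_REGIONS = frozenset({
    "bankssts", "entorhinal", "fusiform", "inferiortemporal",
    "middletemporal", "parahippocampal", "superiortemporal", "temporalpole",
    "transversetemporal",
})
FRONTAL_REGIONS = frozenset({
    "caudalmiddlefrontal", "frontalpole", "lateralorbitofrontal",
    "medialorbitofrontal", "paracentral", "parsopercularis", "parsorbitalis",
    "parstriangularis", "precentral", "rostralmiddlefrontal",
    "superiorfrontal",
})
MEDIAL_TEMPORAL_REGIONS = frozenset({"entorhinal", "parahippocampal", "temporalpole"})
POSTERIOR_REGIONS = frozenset({
    "caudalanteriorcingulate", "cuneus", "inferiorparietal", "insula",
    "isthmuscingulate", "lateraloccipital", "lingual", "paracentral",
    "pericalcarine", "postcentral", "posteriorcingulate", "precuneus",
    "superiorparietal", "supramarginal",
})

VISITS: tuple[str, ...] = ("bl", "m06", "m12", "m18", "m24", "m36")
VISIT_MONTHS: dict[str, int] = {"bl": 0, "m06": 6, "m12": 12, "m18": 18, "m24": 24, "m36": 36}

COGNITIVE_SCALES: tuple[str, ...] = (
    "MMSE", "CDRSB", "ADAS13", "FAQ", "ADNI_MEM", "ADNI_EF", "ADNI_LAN", "ADNI_VS",
)

SUBJECT_COLUMNS = (
    "subject_id", "diagnosis", "age", "sex", "education_years", "icv_mm3",
    "apoe_a1", "apoe_a2", "latent_subtype",
) + COGNITIVE_SCALES


def _roi_mask(regions: frozenset[str]) -> np.ndarray:
    return np.array(
        [name.split("_", 1)[1].rsplit("_", 1)[0] in regions for name in ROI_NAMES]
    )


class CohortSpecError(ValueError):
    """Raised when a cohort specification violates its invariants."""


# ---------------------------------------------------------------------------
# Specification dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubtypeTemplate:
    """One planted atrophy pattern.

    ``roi_weights`` holds per-ROI atrophy magnitudes in mm (>= 0); AD subjects
    drawn from the template lose the full weight, MCI subjects lose
    ``mci_scale`` times the weight.
    """

    label: str
    roi_weights: np.ndarray
    prevalence: float
    mci_scale: float = 0.5
    # per-period increase of the atrophy-burden driving cognitive decline
    # (mm of mean cortical loss per 6-month period)
    decline_rate: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.roi_weights, dtype=float)
        object.__setattr__(self, "roi_weights", w)
        if np.any(w < 0):
            raise CohortSpecError(f"roi_weights for {self.label!r} must be >= 0")
        if not 0.0 <= self.mci_scale <= 1.0:
            raise CohortSpecError(f"mci_scale for {self.label!r} must lie in [0, 1]")
        if not 0.0 <= self.prevalence <= 1.0:
            raise CohortSpecError(f"prevalence for {self.label!r} must lie in [0, 1]")

    @property
    def mean_burden(self) -> float:
        """Mean per-ROI cortical loss (mm) at full AD expression."""
        return float(np.mean(self.roi_weights))


def default_templates(effect: float = 0.4, n_rois: int = N_ROIS) -> list[SubtypeTemplate]:
    """Three atrophy patterns ordered by severity.

    The patterns follow the canonical neuropathological AD variants rather
    than strictly nested ROI sets: MIN plants the focal deficit on the
    temporal lobe (limbic-predominant-like), MID on the frontal cortex while
    sparing the medial temporal lobe (hippocampal-sparing-like), and DIF is
    genuinely diffuse -- nonzero on every ROI -- with posterior predominance
    (the full deficit on parieto-occipital/cingulate/insular cortex, 0.375x
    elsewhere), so its total burden is the largest. Mean atrophy burden
    rises MIN < MID < DIF, every full-expression (AD) pattern is separable
    from CN and from the other patterns, and -- because the patterns are not
    nested with equal magnitudes -- the half-scale MCI expressions are not
    equidistant from the expert hyperplanes. Prevalences follow the observed
    subtype shares of a typical amnestic-MCI cohort (roughly 26/34/40
    percent).
    """
    if n_rois != N_ROIS:
        # reduced feature spaces (tests): first quarter / second quarter /
        # diffuse with predominance on the back half
        q = max(1, n_rois // 4)
        w_min = np.zeros(n_rois)
        w_min[:q] = effect
        w_mid = np.zeros(n_rois)
        w_mid[q : 2 * q] = effect
        w_dif = np.full(n_rois, 0.375 * effect)
        w_dif[2 * q :] = effect
    else:
        w_min = np.where(_roi_mask(TEMPORAL_REGIONS), effect, 0.0)
        w_mid = np.where(_roi_mask(FRONTAL_REGIONS), effect, 0.0)
        w_dif = np.where(_roi_mask(POSTERIOR_REGIONS), effect, 0.375 * effect)
    return [
        SubtypeTemplate("MIN", w_min, prevalence=0.26, mci_scale=0.5, decline_rate=0.005),
        SubtypeTemplate("MID", w_mid, prevalence=0.34, mci_scale=0.5, decline_rate=0.090),
        SubtypeTemplate("DIF", w_dif, prevalence=0.40, mci_scale=0.5, decline_rate=0.080),
    ]


def default_apoe_rates() -> dict[str, tuple[float, float]]:
    """Per group/template (e4, e2) allele frequencies.

    Carrier probability is 1 - (1 - f)^2 under two independent allele draws;
    frequencies are set so carrier rates resemble an amnestic-MCI cohort
    (roughly half of MCI carrying at least one e4 allele, CN near 26%).
    """
    return {
        "CN": (0.14, 0.050),
        "MIN": (0.27, 0.056),
        "MID": (0.34, 0.034),
        "DIF": (0.33, 0.030),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cross-sectional cohort."""

    n_cn: int = 228
    n_ad: int = 192
    n_mci: int = 396
    n_rois: int = N_ROIS
    roi_baseline_mean: np.ndarray | float = 2.5
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": -0.008, "sex": 0.02, "education": 0.002, "icv": 0.0}
    )
    noise_sd: float = 0.1
    templates: list[SubtypeTemplate] = field(default_factory=default_templates)
    apoe_rates: dict[str, tuple[float, float]] = field(default_factory=default_apoe_rates)
    age_range: tuple[float, float] = (55.0, 90.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cn", "n_ad", "n_mci"):
            if getattr(self, name) <= 0:
                raise CohortSpecError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.noise_sd < 0:
            raise CohortSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not self.templates:
            raise CohortSpecError("templates must be non-empty")
        total = sum(t.prevalence for t in self.templates)
        if abs(total - 1.0) > 1e-8:
            raise CohortSpecError(
                f"template prevalences must sum to 1, got {total:.6f}"
            )
        for t in self.templates:
            if t.roi_weights.shape != (self.n_rois,):
                raise CohortSpecError(
                    f"roi_weights for template {t.label!r} has length "
                    f"{t.roi_weights.size}, expected n_rois={self.n_rois}"
                )
        base = np.broadcast_to(
            np.asarray(self.roi_baseline_mean, dtype=float), (self.n_rois,)
        )
        object.__setattr__(self, "roi_baseline_mean", np.array(base))

    @property
    def roi_names(self) -> list[str]:
        if self.n_rois == N_ROIS:
            return list(ROI_NAMES)
        return [f"roi_{i:02d}_thickness" for i in range(self.n_rois)]


@dataclass(frozen=True)
class VisitSchedule:
    """Longitudinal acquisition pattern and diagnostic transition model."""

    visits: tuple[str, ...] = VISITS
    missingness: dict[str, float] = field(
        default_factory=lambda: {
            "bl": 0.0, "m06": 0.08, "m12": 0.10, "m18": 0.12, "m24": 0.15, "m36": 0.25,
        }
    )
    conversion_prob: dict[str, float] = field(
        default_factory=lambda: {"MIN": 0.033, "MID": 0.055, "DIF": 0.060}
    )
    reversion_prob: float = 0.01
    # hazard multiplier on the per-period conversion probability for APOE e4
    # carriers; ~2.5 reproduces the strong carrier enrichment among converters
    # seen in amnestic-MCI cohorts
    apoe_e4_risk: float = 2.5
    # post-conversion atrophy ramps from mci_scale toward full AD expression
    # by this amount per 6-month period (freshly converted subjects are early
    # AD, not end-stage)
    conversion_ramp: float = 0.1

    def __post_init__(self) -> None:
        months = [VISIT_MONTHS.get(v) for v in self.visits]
        if any(m is None for m in months) or months != sorted(months):
            raise CohortSpecError(f"visits must be ordered in time, got {self.visits}")
        probs = list(self.missingness.values()) + list(self.conversion_prob.values())
        probs.append(self.reversion_prob)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise CohortSpecError("all schedule probabilities must lie in [0, 1]")
        if self.apoe_e4_risk < 0 or self.conversion_ramp < 0:
            raise CohortSpecError("apoe_e4_risk and conversion_ramp must be >= 0")


@dataclass
class Cohort:
    """Generated cross-sectional cohort: subject table plus baseline thickness."""

    spec: CohortSpec
    subjects: pd.DataFrame           # one row per subject, SUBJECT_COLUMNS
    thickness: pd.DataFrame          # subject_id index, ROI columns (mm)


@dataclass
class LongitudinalData:
    """Generated visit grid with per-visit thickness and ground truth."""

    visits: pd.DataFrame                       # subject_id, visit, scan_present, diagnosis
    thickness_by_visit: dict[str, pd.DataFrame]
    true_conversion_visit: dict[str, str]      # subject_id -> visit of MCI->AD conversion
    true_reversion_visit: dict[str, str]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _covariate_design(sub: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "age": sub["age"].to_numpy(float),
        "sex": (sub["sex"] == "F").to_numpy(float),
        "education": sub["education_years"].to_numpy(float),
        "icv": sub["icv_mm3"].to_numpy(float),
    }


def _covariate_shift(spec: CohortSpec, sub: pd.DataFrame) -> np.ndarray:
    """Per-subject additive covariate contribution to every ROI (mm)."""
    design = _covariate_design(sub)
    shift = np.zeros(len(sub))
    for name, slope in spec.covariate_effects.items():
        shift += slope * design[name]
    return shift


def _draw_apoe(rng: np.random.Generator, rates: tuple[float, float], n: int) -> np.ndarray:
    f4, f2 = rates
    f3 = 1.0 - f4 - f2
    if f3 < 0:
        raise CohortSpecError("APOE e4 + e2 allele frequencies exceed 1")
    alleles = rng.choice(["e4", "e2", "e3"], size=(n, 2), p=[f4, f2, f3])
    alleles.sort(axis=1)  # unordered pair, canonical order
    return alleles


_SCORE_MODEL = {
    # scale -> (healthy mean, slope per mm of mean cortical loss, noise sd, clip)
    "MMSE": (29.1, -14.5, 1.0, (0.0, 30.0)),
    "CDRSB": (0.03, 11.0, 0.4, (0.0, 18.0)),
    "ADAS13": (9.5, 24.0, 3.0, (0.0, 85.0)),
    "FAQ": (0.14, 11.0, 1.5, (0.0, 30.0)),
    "ADNI_MEM": (0.97, -2.6, 0.5, None),
    "ADNI_EF": (0.64, -1.7, 0.7, None),
    "ADNI_LAN": (0.78, -2.0, 0.7, None),
    "ADNI_VS": (0.23, -1.1, 0.6, None),
}


def _cognitive_scores(rng: np.random.Generator, burden: np.ndarray) -> dict[str, np.ndarray]:
    """Scores as linear functions of atrophy burden (mm mean loss) + noise."""
    out = {}
    for scale, (mean, slope, sd, clip) in _SCORE_MODEL.items():
        vals = mean + slope * burden + rng.normal(0.0, sd, size=burden.size)
        if clip is not None:
            vals = np.clip(vals, *clip)
        out[scale] = np.round(vals, 2)
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full cross-sectional cohort from ``spec``.

    Deterministic given ``spec.seed``: independent random streams are spawned
    per concern (demographics, subtype draws, APOE, noise, scores) so that
    changing one count does not perturb unrelated draws.
    """
    master = np.random.SeedSequence(spec.seed)
    rng_demo, rng_subtype, rng_apoe, rng_noise, rng_score = (
        np.random.default_rng(s) for s in master.spawn(5)
    )

    groups = (["CN"] * spec.n_cn) + (["AD"] * spec.n_ad) + (["MCI"] * spec.n_mci)
    n = len(groups)
    subject_ids = [f"SUB{i:04d}" for i in range(n)]

    lo, hi = spec.age_range
    age = np.clip(rng_demo.normal(75.0, 6.5, n), lo, hi)
    sex = np.where(rng_demo.random(n) < 0.45, "F", "M")
    edu = np.clip(np.round(rng_demo.normal(15.8, 3.0, n)), 6, 20)
    icv = rng_demo.normal(1.5e6, 1.5e5, n)

    # latent subtype per AD/MCI subject by template prevalence
    labels = [t.label for t in spec.templates]
    prev = np.array([t.prevalence for t in spec.templates])
    prev = prev / prev.sum()
    latent = np.array(["none"] * n, dtype=object)
    is_patient = np.array([g != "CN" for g in groups])
    latent[is_patient] = rng_subtype.choice(labels, size=int(is_patient.sum()), p=prev)

    apoe = np.empty((n, 2), dtype=object)
    for key, mask in _apoe_strata(groups, latent):
        rates = spec.apoe_rates.get(key, spec.apoe_rates.get("CN", (0.14, 0.05)))
        apoe[mask] = _draw_apoe(rng_apoe, rates, int(mask.sum()))

    sub = pd.DataFrame({
        "subject_id": subject_ids,
        "diagnosis": groups,
        "age": np.round(age, 1),
        "sex": sex,
        "education_years": edu.astype(int),
        "icv_mm3": np.round(icv, 0),
        "apoe_a1": apoe[:, 0],
        "apoe_a2": apoe[:, 1],
        "latent_subtype": latent,
    })

    template_by_label = {t.label: t for t in spec.templates}
    scale = np.zeros(n)
    weights = np.zeros((n, spec.n_rois))
    for i, (g, lab) in enumerate(zip(groups, latent)):
        if g == "CN":
            continue
        t = template_by_label[str(lab)]
        scale[i] = 1.0 if g == "AD" else t.mci_scale
        weights[i] = t.roi_weights

    shift = _covariate_shift(spec, sub)
    thickness = (
        spec.roi_baseline_mean[None, :]
        + shift[:, None]
        - scale[:, None] * weights
        + rng_noise.normal(0.0, spec.noise_sd, size=(n, spec.n_rois))
    )
    thickness_df = pd.DataFrame(thickness, index=pd.Index(subject_ids, name="subject_id"),
                                columns=spec.roi_names)

    burden = scale * weights.mean(axis=1)
    for name, vals in _cognitive_scores(rng_score, burden).items():
        sub[name] = vals

    return Cohort(spec=spec, subjects=sub, thickness=thickness_df)


def _apoe_strata(groups: list[str], latent: np.ndarray):
    """Yield (rate key, boolean mask) per CN group and per patient subtype."""
    garr = np.asarray(groups)
    yield "CN", garr == "CN"
    for lab in sorted(set(latent[garr != "CN"])):
        yield str(lab), (garr != "CN") & (latent == lab)


def generate_longitudinal(
    cohort: Cohort, schedule: VisitSchedule = VisitSchedule(), seed: int | None = None
) -> LongitudinalData:
    """Simulate visit attendance, diagnostic transitions and follow-up scans.

    Conversion (MCI -> AD) is absorbing, as is reversion (MCI -> CN); a
    converted subject's later thickness continues the full AD-level atrophy
    trajectory of its latent template. The true conversion visit is recorded
    for recovery testing.
    """
    spec = cohort.spec
    if seed is None:
        seed = spec.seed + 1
    master = np.random.SeedSequence(seed)
    rng_miss, rng_conv, rng_noise = (np.random.default_rng(s) for s in master.spawn(3))

    sub = cohort.subjects
    template_by_label = {t.label: t for t in spec.templates}
    followups = [v for v in schedule.visits if v != "bl"]

    rows = []
    conv_visit: dict[str, str] = {}
    rev_visit: dict[str, str] = {}
    diag_paths: dict[str, dict[str, str]] = {}
    for _, s in sub.iterrows():
        sid, dx0 = s["subject_id"], s["diagnosis"]
        carrier = "e4" in (s["apoe_a1"], s["apoe_a2"])
        path = {"bl": dx0}
        state = dx0
        for v in followups:
            if state == "MCI":
                t = template_by_label[str(s["latent_subtype"])]
                p_conv = schedule.conversion_prob.get(t.label, 0.0)
                if carrier:
                    p_conv = min(1.0, p_conv * schedule.apoe_e4_risk)
                u = rng_conv.random()
                if u < p_conv:
                    state = "AD"
                    conv_visit[sid] = v
                elif u < p_conv + schedule.reversion_prob:
                    state = "CN"
                    rev_visit[sid] = v
            path[v] = state
        diag_paths[sid] = path
        for v in schedule.visits:
            present = 1 if v == "bl" else int(
                rng_miss.random() >= schedule.missingness.get(v, 0.0)
            )
            rows.append((sid, v, present, path[v]))

    visits = pd.DataFrame(rows, columns=["subject_id", "visit", "scan_present", "diagnosis"])

    # per-visit thickness: baseline covariates re-evaluated at visit age,
    # atrophy scale follows the diagnosis path, fresh measurement noise
    thickness_by_visit = {"bl": cohort.thickness.copy()}
    base_shift = _covariate_shift(spec, sub)
    age_slope = spec.covariate_effects.get("age", 0.0)
    sids = sub["subject_id"].to_numpy()
    for v in followups:
        dt_years = VISIT_MONTHS[v] / 12.0
        scale = np.zeros(len(sub))
        weights = np.zeros((len(sub), spec.n_rois))
        for i, s in enumerate(sub.itertuples(index=False)):
            lab = str(s.latent_subtype)
            if lab == "none":
                continue
            t = template_by_label[lab]
            dx_v = diag_paths[s.subject_id][v]
            weights[i] = t.roi_weights
            if s.diagnosis == "AD":
                scale[i] = 1.0
            elif dx_v == "AD":
                # early-AD converter: atrophy ramps up from the MCI level
                periods_since = (VISIT_MONTHS[v] - VISIT_MONTHS[conv_visit[s.subject_id]]) // 6
                scale[i] = min(
                    1.0,
                    t.mci_scale + schedule.conversion_ramp * (periods_since + 1),
                )
            elif dx_v == "MCI":
                scale[i] = t.mci_scale
            else:  # reverted to CN
                scale[i] = 0.0
        thick = (
            spec.roi_baseline_mean[None, :]
            + (base_shift + age_slope * dt_years)[:, None]
            - scale[:, None] * weights
            + rng_noise.normal(0.0, spec.noise_sd, size=(len(sub), spec.n_rois))
        )
        thickness_by_visit[v] = pd.DataFrame(
            thick, index=pd.Index(sids, name="subject_id"), columns=spec.roi_names
        )

    return LongitudinalData(visits, thickness_by_visit, conv_visit, rev_visit)


def longitudinal_scores(
    cohort: Cohort, long_data: LongitudinalData, seed: int | None = None
) -> pd.DataFrame:
    """Per-visit cognitive scores driven by a growing atrophy burden.

    Each subject's burden increases by its template's ``decline_rate`` per
    6-month period (doubled after conversion to AD), and the baseline linear
    score maps are re-applied with fresh noise. Returns a long table
    (subject_id, visit, one column per scale).
    """
    spec = cohort.spec
    if seed is None:
        seed = spec.seed + 2
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    template_by_label = {t.label: t for t in spec.templates}
    sub = cohort.subjects.set_index("subject_id")
    visits_order = list(long_data.thickness_by_visit)

    frames = []
    for v in visits_order:
        period = max(0, VISIT_MONTHS[v] // 6)
        burden = np.zeros(len(sub))
        for i, (sid, s) in enumerate(sub.iterrows()):
            lab = str(s["latent_subtype"])
            if lab == "none":
                continue
            t = template_by_label[lab]
            base = t.mean_burden * (1.0 if s["diagnosis"] == "AD" else t.mci_scale)
            rate = t.decline_rate
            conv = long_data.true_conversion_visit.get(sid)
            if conv is not None and VISIT_MONTHS[v] >= VISIT_MONTHS[conv]:
                rate = 2.0 * rate
            burden[i] = base + rate * period
        frame = pd.DataFrame({"subject_id": sub.index, "visit": v})
        for name, vals in _cognitive_scores(rng, burden).items():
            frame[name] = vals
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Plain-text I/O (tab-separated; round-trips losslessly through the readers)
# ---------------------------------------------------------------------------

def emit_tables(
    cohort: Cohort, path: str | Path, long_data: LongitudinalData | None = None
) -> list[Path]:
    """Write subjects.tsv, thickness_<visit>.tsv and visits.tsv under ``path``."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    f = out / "subjects.tsv"
    cohort.subjects.to_csv(f, sep="\t", index=False)
    written.append(f)

    by_visit = long_data.thickness_by_visit if long_data else {"bl": cohort.thickness}
    for visit, table in by_visit.items():
        f = out / f"thickness_{visit}.tsv"
        table.to_csv(f, sep="\t")
        written.append(f)

    if long_data is not None:
        f = out / "visits.tsv"
        long_data.visits.to_csv(f, sep="\t", index=False)
        written.append(f)
    return written


def read_subjects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str})


def read_thickness(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")


def read_visits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str, "visit": str})
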