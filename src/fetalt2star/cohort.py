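"""Scan-level cohort bookkeeping: inclusion filters and stratification.

A manifest lists one row per fetal scan with the attributes that drive the
study flow chart: availability of the structural and multi-echo sequences,
gestational age at scan, whether the brain was inside the field of view,
whether motion could be corrected, and the control/pathology group
assigned from birth outcome. Inclusion applies the rules in the fixed
order sequences -> GA -> FOV -> motion so the exclusion log is
deterministic (each excluded scan is logged under the first failing rule).

``flowchart_manifest`` builds a fully synthetic manifest that reproduces
every box of the study's recruitment flow: 193 scans from 145 pregnant
individuals, 150 scans (114 individuals) with both sequences, exclusions
of 8 scans below 20 weeks, 1 without the brain in the FOV and 6 with
uncorrectable motion, leaving 135 scans from 107 individuals — 92 control
scans (71 individuals) and 43 pathology scans (36 individuals).

``synthesize_control_cohort`` draws per-scan regional T2* (and volume)
values from the normative reference table: GA values match the per-bin
control counts, and each regional value is Gaussian around the
midpoint-interpolated bin mean with sd = (p95 - p5) / 3.29.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import BIN_EDGES, BIN_N, REGIONS, lookup_reference_t2star, reference_sd

__all__ = [
    "ScanRecord",
    "MANIFEST_COLUMNS",
    "apply_inclusion_filters",
    "stratify",
    "flowchart_manifest",
    "synthesize_control_cohort",
]

MANIFEST_COLUMNS = [
    "scan_id",
    "subject_id",
    "ga_at_scan_weeks",
    "has_structural",
    "has_multiecho",
    "brain_in_fov",
    "motion_correctable",
    "group",
    "outcome",
]

MIN_GA_WEEKS = 20.0


@dataclass
class ScanRecord:
    scan_id: str
    subject_id: str
    ga_at_scan_weeks: float
    has_structural: bool
    has_multiecho: bool
    brain_in_fov: bool
    motion_correctable: bool
    group: str  # 'control' or 'pathology'
    outcome: str = ""

    def __post_init__(self):
        if not self.scan_id or not self.subject_id:
            raise ValueError("scan_id and subject_id must be nonempty")
        if self.ga_at_scan_weeks <= 0:
            raise ValueError("ga_at_scan_weeks must be positive")


def _as_dataframe(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records], columns=MANIFEST_COLUMNS)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "outcome"]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def apply_inclusion_filters(records):
    """Split a manifest into included scans and an exclusion log.

    Keep rows with both sequences AND GA >= 20 weeks AND brain in FOV AND
    correctable motion. The log records scan_id, subject_id and the first
    failing rule, evaluated in the order sequences -> GA -> FOV -> motion.
    Returns (included DataFrame, exclusion-log DataFrame).
    """
    df = _as_dataframe(records)
    if df.empty:
        return df, pd.DataFrame(columns=["scan_id", "subject_id", "reason"])

    reasons = []
    for _, row in df.iterrows():
        if not (bool(row["has_structural"]) and bool(row["has_multiecho"])):
            reasons.append("missing_sequence")
        elif float(row["ga_at_scan_weeks"]) < MIN_GA_WEEKS:
            reasons.append("ga_below_20_weeks")
        elif not bool(row["brain_in_fov"]):
            reasons.append("brain_not_in_fov")
        elif not bool(row["motion_correctable"]):
            reasons.append("excessive_motion")
        else:
            reasons.append("")
    reasons = np.asarray(reasons, dtype=object)
    keep = reasons == ""
    included = df.loc[keep].reset_index(drop=True)
    log = df.loc[~keep, ["scan_id", "subject_id"]].reset_index(drop=True)
    log["reason"] = reasons[~keep]
    return included, log


def stratify(records) -> dict:
    """Scan and distinct-subject counts per group and per outcome label."""
    df = _as_dataframe(records)
    out = {
        "n_scans": int(len(df)),
        "n_subjects": int(df["subject_id"].nunique()) if len(df) else 0,
        "groups": {},
        "outcomes": {},
    }
    for group, sub in df.groupby("group"):
        out["groups"][group] = {
            "n_scans": int(len(sub)),
            "n_subjects": int(sub["subject_id"].nunique()),
        }
    if "outcome" in df.columns:
        for outcome, sub in df.groupby("outcome"):
            if outcome:
                out["outcomes"][str(outcome)] = int(len(sub))
    return out


# ---------------------------------------------------------------------------
# synthetic manifest reproducing the recruitment flow chart

_PATHOLOGY_OUTCOMES = (
    ["ventriculomegaly"] * 12
    + ["hypertension"] * 8
    + ["gestational_diabetes"] * 7
    + ["preterm_birth"] * 5
    + ["pre_eclampsia"] * 4
    + ["cytomegalovirus"] * 2
    + ["pprom"] * 2
    + ["agenesis_corpus_callosum"] * 1
    + ["head_circumference_below_1st"] * 1
    + ["hypoplastic_left_heart"] * 1
)  # 43 labels


def _control_ga_values() -> np.ndarray:
    """92 GA values matching the per-bin control counts, spread within bins."""
    vals = []
    for b, n in enumerate(BIN_N):
        lo, hi = BIN_EDGES[b], BIN_EDGES[b + 1]
        vals.extend(lo + (np.arange(n) + 0.5) / n * (hi - lo))
    return np.asarray(vals)


def flowchart_manifest() -> pd.DataFrame:
    """Deterministic synthetic manifest reproducing the recruitment flow.

    193 scans / 145 subjects in total; applying the inclusion filters
    yields 135 scans / 107 subjects (92 control scans from 71 subjects,
    43 pathology scans from 36 subjects), with 43 scans excluded for a
    missing sequence, 8 for GA < 20 weeks, 1 for brain outside the FOV
    and 6 for uncorrectable motion.
    """
    rows = []

    def add(scan_id, subject_id, ga, structural=True, multiecho=True, fov=True,
            motion=True, group="control", outcome=""):
        rows.append(
            dict(scan_id=scan_id, subject_id=subject_id, ga_at_scan_weeks=round(float(ga), 2),
                 has_structural=structural, has_multiecho=multiecho, brain_in_fov=fov,
                 motion_correctable=motion, group=group, outcome=outcome or group)
        )

    # included control scans: subjects C001..C071; C001-C021 scanned twice
    ga_control = _control_ga_values()
    subject_of_scan = [f"C{i + 1:03d}" for i in range(71)] + [f"C{i + 1:03d}" for i in range(21)]
    for i, (subj, ga) in enumerate(zip(subject_of_scan, ga_control)):
        add(f"SC{i + 1:03d}", subj, ga, group="control", outcome="control")

    # included pathology scans: subjects P001..P036; P001-P007 scanned twice
    subject_of_scan = [f"P{i + 1:03d}" for i in range(36)] + [f"P{i + 1:03d}" for i in range(7)]
    ga_path = 20.0 + (np.arange(43) + 0.5) / 43 * 20.0
    for i, (subj, ga) in enumerate(zip(subject_of_scan, ga_path)):
        add(f"SP{i + 1:03d}", subj, ga, group="pathology", outcome=_PATHOLOGY_OUTCOMES[i])

    # sequence-complete exclusions: 8 below 20 weeks (4 from otherwise-included
    # control subjects, 4 from subjects seen only here), 1 brain outside FOV,
    # 6 uncorrectable motion (4 from included subjects, 2 new)
    early_subjects = ["C022", "C023", "C024", "C025", "X001", "X002", "X003", "X004"]
    for i, subj in enumerate(early_subjects):
        add(f"SE{i + 1:03d}", subj, 17.5 + 0.3 * i, group="control")
    add("SF001", "X005", 28.0, fov=False, group="control")
    motion_subjects = ["C026", "C027", "C028", "C029", "X006", "X007"]
    for i, subj in enumerate(motion_subjects):
        add(f"SM{i + 1:03d}", subj, 24.0 + 2.0 * i, motion=False, group="control")

    # scans lacking one of the two sequences: 43 scans, 31 subjects seen
    # only here (S001..S031) plus 12 repeat scans of included subjects
    seq_subjects = [f"S{i + 1:03d}" for i in range(31)] + [f"C{i + 30:03d}" for i in range(12)]
    for i, subj in enumerate(seq_subjects):
        add(
            f"SQ{i + 1:03d}", subj, 22.0 + (i % 16),
            structural=(i % 2 == 0), multiecho=(i % 2 == 1), group="control",
        )

    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


# ---------------------------------------------------------------------------
# tabular synthetic control cohort


def synthesize_control_cohort(
    seed: int = 0,
    bin_counts=None,
    include_volumes: bool = True,
    volume_noise_sd: float = 0.08,
) -> pd.DataFrame:
    """Draw a synthetic control cohort from the normative parameterization.

    GA values follow the per-bin control counts (uniform within each
    2-week bin); each scan's regional T2* is Gaussian around the
    midpoint-interpolated reference mean with sd = (p95 - p5)/3.29 of the
    scan's bin. Regional volumes, when requested, follow a monotone
    growth model (ellipsoid-compartment proportions of the digital
    phantom) with multiplicative log-normal noise.

    Returns a long-format DataFrame: scan_id, ga, region, t2star[, volume].
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(bin_counts if bin_counts is not None else BIN_N)
    ga_vals = np.concatenate(
        [rng.uniform(BIN_EDGES[b], BIN_EDGES[b + 1], size=n) for b, n in enumerate(counts)]
    )

    vol_interp = _phantom_volume_interpolators() if include_volumes else None

    rows = []
    for i, ga in enumerate(ga_vals):
        for region in REGIONS:
            mean = lookup_reference_t2star(region, ga)
            sd = reference_sd(region, ga)
            row = dict(
                scan_id=f"SYN{i + 1:03d}", ga=float(ga), region=region,
                t2star=float(rng.normal(mean, sd)),
            )
            if include_volumes:
                vol = vol_interp[region](ga) * np.exp(rng.normal(0.0, volume_noise_sd))
                row["volume"] = float(vol)
            rows.append(row)
    return pd.DataFrame(rows)


def _phantom_volume_interpolators():
    """Per-region volume-vs-GA interpolators from the phantom geometry."""
    from .phantom import PhantomSpec, build_label_volume
    from .regional import regional_volume

    ga_grid = np.arange(21.0, 40.0, 3.0)
    vols = {r: [] for r in REGIONS}
    for ga in ga_grid:
        labels = build_label_volume(PhantomSpec(gestational_age=float(ga), grid_shape=(48, 48, 48)))
        for stats in regional_volume(labels):
            vols[stats.region].append(stats.volume_ml)
    return {
        r: (lambda ga, v=np.asarray(vols[r]): float(np.interp(ga, ga_grid, v)))
        for r in REGIONS
    }
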