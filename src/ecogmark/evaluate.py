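"""Ground-truth evaluation: pooled comparisons, thresholds, detection.

The reference for "normal tissue" is derived from post-resection recordings
of cured patients (seizure-free off medication one year after surgery): if
the operation cured the patient, whatever tissue is left cannot trigger
seizures, so its biomarker values bound the normal range. The per-biomarker
threshold is the maximum over all post-resection channel values of all cured
patients in scope; a patient's epileptogenic tissue counts as detected when
any pre-resection value on an eventually-resected channel exceeds that
threshold strictly.

Group-level effects are tested with a one-sided two-sample
Kolmogorov-Smirnov test of "pre-resection resected values stochastically
larger than post-resection values", at alpha = 0.01 with no
multiple-comparison correction. Bipolar channels straddling the resection
border ("cut") and unlabelled channels never enter the pre-resection pools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import PatientMeta

logger = logging.getLogger(__name__)

SCOPES = ("all", "T", "E")


def _scope_patients(patients: dict[str, PatientMeta], scope: str) -> set[str]:
    if scope == "all":
        return set(patients)
    return {pid for pid, p in patients.items() if p.epilepsy_type == scope}


@dataclass
class ValuePools:
    """Per-biomarker pre/post value pools for one scope."""

    scope: str
    pre: dict[str, np.ndarray]
    post: dict[str, np.ndarray]
    n_pre_patients: int = 0
    n_post_patients: int = 0


def build_pools(table: pd.DataFrame, patients: dict[str, PatientMeta],
                scope: str = "all") -> ValuePools:
    """Pre-resection-resected vs cured-post value pools.

    Pre pool: all values of resected derived channels in pre-resection
    situations of in-scope patients (every patient is Engel 1A "improved";
    cured patients are a subset and contribute too). Post pool: all channel
    values of post-resection situations of in-scope *cured* patients.
    """
    in_scope = _scope_patients(patients, scope)
    cured = {pid for pid in in_scope if patients[pid].outcome == "cured"}
    if not cured:
        raise ValueError(f"no cured patients in scope {scope!r}: "
                         "cannot build a normal-tissue reference")
    t = table[table["patient"].isin(in_scope)]
    pre = t[(t["phase"] == "pre") & (t["resected"] == "resected")]
    post = t[(t["phase"] == "post") & t["patient"].isin(cured)]
    pools = ValuePools(
        scope=scope,
        pre={bm: g["value"].to_numpy() for bm, g in pre.groupby("biomarker")},
        post={bm: g["value"].to_numpy() for bm, g in post.groupby("biomarker")},
        n_pre_patients=pre["patient"].nunique(),
        n_post_patients=post["patient"].nunique(),
    )
    return pools


def ks_one_sided(pre: np.ndarray, post: np.ndarray,
                 method: str = "auto") -> tuple[float, float]:
    """One-sided two-sample KS test of "pre stochastically larger".

    The statistic is D+ = sup_x [F_post(x) - F_pre(x)]; small p-values
    indicate the pre-resection distribution is shifted towards larger
    values. Exact small-sample p-values when ``method='auto'`` and the
    pools are small, asymptotic otherwise.
    """
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    if pre.size < 2 or post.size < 2:
        raise ValueError("KS test needs at least 2 values per sample")
    res = stats.ks_2samp(pre, post, alternative="less", method=method)
    return float(res.statistic), float(res.pvalue)


def max_per_patient(table: pd.DataFrame, patients: dict[str, PatientMeta],
                    scope: str = "all") -> dict[str, dict[str, dict[str, float]]]:
    """Per-patient maxima: pre over resected channels of every in-scope
    patient, post over all channels of in-scope cured patients.

    Returns {biomarker: {"pre": {patient: max}, "post": {patient: max}}}.
    Patients without eligible channels are simply absent.
    """
    in_scope = _scope_patients(patients, scope)
    cured = {pid for pid in in_scope if patients[pid].outcome == "cured"}
    t = table[table["patient"].isin(in_scope)]
    pre = t[(t["phase"] == "pre") & (t["resected"] == "resected")]
    post = t[(t["phase"] == "post") & t["patient"].isin(cured)]
    out: dict[str, dict[str, dict[str, float]]] = {}
    for bm in sorted(t["biomarker"].unique()):
        out[bm] = {
            "pre": pre[pre["biomarker"] == bm].groupby("patient")["value"]
            .max().to_dict(),
            "post": post[post["biomarker"] == bm].groupby("patient")["value"]
            .max().to_dict(),
        }
    return out


def compute_thresholds(pools: ValuePools) -> dict[str, float]:
    """Per-biomarker normal-tissue reference: max of the cured post pool."""
    thr = {}
    for bm, vals in pools.post.items():
        if vals.size == 0:
            raise ValueError(f"empty post pool for biomarker {bm}")
        thr[bm] = float(vals.max())
    return thr


def detect(values: pd.DataFrame, threshold: float
           ) -> tuple[bool, int, str | None, float]:
    """Detection for one patient and biomarker.

    ``values`` holds the patient's pre-resection resected rows for that
    biomarker. A value strictly above the threshold flags detection; returns
    (flag, n channels above, argmax channel, max value).
    """
    if values.empty:
        raise ValueError("no eligible pre-resection resected values")
    v = values["value"].to_numpy()
    n_above = int((v > threshold).sum())
    imax = int(np.argmax(v))
    return bool(n_above > 0), n_above, str(values.iloc[imax]["channel"]), \
        float(v[imax])


@dataclass
class DetectionReport:
    """Full evaluation of one scope: thresholds, detections, KS results."""

    scope: str
    alpha: float
    thresholds: dict[str, float]
    detections: pd.DataFrame  # patient x biomarker rows
    patient_summary: pd.DataFrame  # per patient: count + cumulative flag
    ks_pooled: dict[str, dict] = field(default_factory=dict)
    ks_max: dict[str, dict] = field(default_factory=dict)
    pool_sizes: dict[str, dict] = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return len(self.patient_summary)

    @property
    def n_cumulative_detected(self) -> int:
        return int(self.patient_summary["cumulative"].sum())

    def n_detected(self, biomarker: str) -> int:
        d = self.detections
        return int(d[d["biomarker"] == biomarker]["detected"].sum())

    def to_json_dict(self) -> dict:
        return {
            "scope": self.scope,
            "alpha": self.alpha,
            "thresholds": self.thresholds,
            "pool_sizes": self.pool_sizes,
            "ks_pooled": self.ks_pooled,
            "ks_max_per_patient": self.ks_max,
            "n_patients": self.n_patients,
            "n_detected_per_biomarker": {
                bm: self.n_detected(bm)
                for bm in sorted(self.detections["biomarker"].unique())
            },
            "n_cumulative_detected": self.n_cumulative_detected,
        }


def evaluate_scope(table: pd.DataFrame, patients: dict[str, PatientMeta],
                   scope: str = "all", alpha: float = 0.01,
                   leave_one_out: bool = False) -> DetectionReport:
    """Thresholds, per-patient detection and KS statistics for one scope.

    With ``leave_one_out`` a cured patient's own post-resection values are
    withheld from the threshold applied to their pre-resection data (a
    sensitivity analysis; the default keeps them in, which is the
    conservative, worst-case reference).
    """
    pools = build_pools(table, patients, scope)
    thresholds = compute_thresholds(pools)
    in_scope = _scope_patients(patients, scope)
    cured = {pid for pid in in_scope if patients[pid].outcome == "cured"}
    t = table[table["patient"].isin(in_scope)]
    pre = t[(t["phase"] == "pre") & (t["resected"] == "resected")]
    post = t[(t["phase"] == "post") & t["patient"].isin(cured)]

    rows = []
    for (pid, bm), g in pre.groupby(["patient", "biomarker"]):
        thr = thresholds[bm]
        if leave_one_out and pid in cured:
            others = post[(post["biomarker"] == bm) & (post["patient"] != pid)]
            if others.empty:
                raise ValueError(
                    f"leave-one-out leaves no post values for {bm} in scope "
                    f"{scope!r}")
            thr = float(others["value"].max())
        flag, n_above, argmax_ch, vmax = detect(g, thr)
        rows.append({"scope": scope, "patient": pid, "biomarker": bm,
                     "detected": flag, "n_above": n_above,
                     "argmax_channel": argmax_ch, "max_value": vmax,
                     "threshold": thr})
    detections = pd.DataFrame(rows)
    if detections.empty:
        raise ValueError(f"no pre-resection resected values in scope {scope!r}")
    summary = (
        detections.groupby("patient")["detected"].sum().rename("n_biomarkers")
        .to_frame()
    )
    summary["cumulative"] = summary["n_biomarkers"] > 0
    summary = summary.reset_index()

    ks_pooled, ks_max, sizes = {}, {}, {}
    maxima = max_per_patient(table, patients, scope)
    for bm in sorted(pre["biomarker"].unique()):
        a = pools.pre.get(bm, np.empty(0))
        b = pools.post.get(bm, np.empty(0))
        sizes[bm] = {"pre": int(a.size), "post": int(b.size)}
        if a.size >= 2 and b.size >= 2:
            d, p = ks_one_sided(a, b)
            ks_pooled[bm] = {"D": d, "p": p, "significant": bool(p < alpha)}
        am = np.array(list(maxima[bm]["pre"].values()))
        bmx = np.array(list(maxima[bm]["post"].values()))
        if am.size >= 2 and bmx.size >= 2:
            d, p = ks_one_sided(am, bmx)
            ks_max[bm] = {"D": d, "p": p, "significant": bool(p < alpha),
                          "n_pre_patients": int(am.size),
                          "n_post_patients": int(bmx.size)}
    return DetectionReport(scope=scope, alpha=alpha, thresholds=thresholds,
                           detections=detections, patient_summary=summary,
                           ks_pooled=ks_pooled, ks_max=ks_max,
                           pool_sizes=sizes)


def mesiotemporal_contrast(table: pd.DataFrame,
                           patients: dict[str, PatientMeta],
                           alpha: float = 0.01) -> dict[str, dict]:
    """Mesiotemporal vs neocortical channel values in temporal patients.

    One-sided KS per biomarker, alternative "mesiotemporal values larger",
    on all pre-resection channel values of temporal patients. The
    mesiotemporal flag propagates to a derived channel only when all its
    parent electrodes carry it.
    """
    temporal = {pid for pid, p in patients.items() if p.epilepsy_type == "T"}
    t = table[table["patient"].isin(temporal) & (table["phase"] == "pre")]
    if t.empty or not t["mesiotemporal"].any():
        raise ValueError("no mesiotemporal channels among temporal patients")
    out = {}
    for bm, g in t.groupby("biomarker"):
        mesio = g[g["mesiotemporal"]]["value"].to_numpy()
        neo = g[~g["mesiotemporal"]]["value"].to_numpy()
        if mesio.size < 2 or neo.size < 2:
            continue
        d, p = ks_one_sided(mesio, neo)
        out[bm] = {"D": d, "p": p, "significant": bool(p < alpha),
                   "n_mesiotemporal": int(mesio.size),
                   "n_neocortical": int(neo.size)}
    return out


def evaluate_cohort(table: pd.DataFrame, patients: dict[str, PatientMeta],
                    scopes: tuple[str, ...] = SCOPES, alpha: float = 0.01,
                    leave_one_out: bool = False
                    ) -> dict[str, DetectionReport]:
    """Evaluate every requested scope, recomputing thresholds per scope."""
    reports: dict[str, DetectionReport] = {}
    errors = []
    for scope in scopes:
        try:
            reports[scope] = evaluate_scope(table, patients, scope, alpha,
                                            leave_one_out)
        except ValueError as e:
            logger.warning("scope %r skipped: %s", scope, e)
            errors.append(f"{scope}: {e}")
    if not reports:
        raise ValueError("no scope could be evaluated: " + "; ".join(errors))
    return reports
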