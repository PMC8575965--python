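"""Biomarker screening: treatment-by-gene interaction tests (predictive
markers) and treatment-adjusted main-effect tests (prognostic markers).

For each binary gene feature g the predictive screen fits

    h_i(t) = h0(t) * exp(psi1*r_i + psi2*g_i + psi3*r_i*g_i)

with r_i = 1 for the TKI arm and 0 for chemotherapy, and reads off the Wald
summary of the interaction term psi3.  A negative interaction z means the
alteration shifts relative benefit toward the TKI arm.  The prognostic test
drops the interaction term and reads off the gene main effect from a
treatment-adjusted model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, MinervaError
from .io import ClinicalRecord, FeatureMatrix
from .survival import fit_cox, wald_summary

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionResult",
    "PrognosticResult",
    "cohort_frame",
    "survival_frame",
    "screen_interactions",
    "adjusted_interaction",
    "prognostic_test",
    "results_to_frame",
]

CLINICAL_COVARIATES = ("age", "sex", "smoking", "stage", "n_stage")

#: non-reference levels used when expanding categorical covariates
_DUMMY_LEVELS = {
    "sex": ("F",),
    "smoking": ("never", "unknown"),
    "stage": ("IIIA",),
    "n_stage": ("N2",),
}


@dataclass
class InteractionResult:
    feature_id: str
    n_altered: int
    events_altered: int
    ihr: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    converged: bool
    adjusted: bool = False
    status: str = "OK"  # OK | SKIPPED | FAILED
    p_adjusted: float | None = None
    message: str | None = None


@dataclass
class PrognosticResult:
    feature_id: str
    hr: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    adjusted: bool = False


# ---------------------------------------------------------------------------
# cohort marshalling
# ---------------------------------------------------------------------------


def cohort_frame(clinical) -> pd.DataFrame:
    """Typed per-patient clinical frame indexed by patient_id.

    ``arm`` is coded numerically: TKI = 1, CHEMO = 0.
    """
    if isinstance(clinical, pd.DataFrame):
        frame = clinical.copy()
        if frame.index.name != "patient_id":
            frame = frame.set_index("patient_id")
        frame["arm"] = (
            frame["arm"].map({"TKI": 1, "CHEMO": 0, 1: 1, 0: 0}).astype(int)
        )
        return frame
    rows = []
    for r in clinical:
        if not isinstance(r, ClinicalRecord):
            raise TypeError(f"expected ClinicalRecord, got {type(r)}")
        rows.append(
            {
                "patient_id": r.patient_id,
                "arm": 1 if r.arm == "TKI" else 0,
                "dfs_months": r.dfs_months,
                "dfs_event": r.dfs_event,
                "os_months": np.nan if r.os_months is None else r.os_months,
                "os_event": np.nan if r.os_event is None else r.os_event,
                "age": np.nan if r.age is None else r.age,
                "sex": r.sex,
                "smoking": r.smoking,
                "stage": r.stage,
                "n_stage": r.n_stage,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def survival_frame(clinical, endpoint: str = "dfs") -> pd.DataFrame:
    """(time, event, arm) frame for the requested endpoint, indexed by patient."""
    endpoint = endpoint.lower()
    cf = cohort_frame(clinical)
    # PFS cohorts reuse the dfs_* columns; the label is cosmetic
    col = "os" if endpoint == "os" else "dfs"
    if endpoint not in ("dfs", "os", "pfs"):
        raise ValueError(f"endpoint must be dfs, os or pfs, got {endpoint!r}")
    out = pd.DataFrame(
        {
            "time": cf[f"{col}_months"].astype(float),
            "event": cf[f"{col}_event"].astype(float),
            "arm": cf["arm"].astype(float),
        },
        index=cf.index,
    )
    if out["time"].isna().any() or out["event"].isna().any():
        missing = out.index[out["time"].isna() | out["event"].isna()].tolist()
        raise DegenerateDataError(
            f"endpoint {endpoint!r} missing for patients {missing[:5]}"
        )
    out["event"] = out["event"].astype(bool)
    return out


def _aligned_feature(fm: FeatureMatrix, feature_id: str, index) -> pd.Series:
    col = fm.to_frame()[feature_id]
    col = col.reindex(index)
    if col.isna().any():
        raise DegenerateDataError(
            f"feature matrix missing patients {col.index[col.isna()].tolist()[:5]}"
        )
    return col.astype(float)


def covariate_design(cf: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Expand clinical covariates to numeric model columns.

    Categorical covariates become indicator columns for their non-reference
    levels; covariates constant across the cohort are dropped with a warning.
    """
    cols = {}
    for cov in covariates:
        if cov not in cf.columns:
            raise KeyError(f"unknown covariate {cov!r}")
        if cov in _DUMMY_LEVELS:
            for level in _DUMMY_LEVELS[cov]:
                cols[f"{cov}_{level}"] = (cf[cov] == level).astype(float)
        else:
            cols[cov] = cf[cov].astype(float)
    design = pd.DataFrame(cols, index=cf.index)
    keep = []
    for c in design.columns:
        if design[c].isna().any():
            logger.warning("covariate %s has missing values; dropped", c)
        elif design[c].nunique() <= 1:
            logger.warning("covariate %s is constant; dropped", c)
        else:
            keep.append(c)
    return design[keep]


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def _check_two_arms(sf: pd.DataFrame) -> None:
    if sf["arm"].nunique() < 2:
        raise DegenerateDataError(
            "interaction screening requires both treatment arms in the cohort"
        )


def _interaction_fit(
    feature_id, gene, sf, extra: pd.DataFrame | None, ties: str
) -> tuple:
    model = sf.assign(gene=gene, arm_gene=sf["arm"] * gene)
    covs = ["arm", "gene", "arm_gene"]
    if extra is not None and extra.shape[1]:
        model = model.join(extra)
        covs += list(extra.columns)
    fit = fit_cox(model, covariates=covs, ties=ties)
    return fit, wald_summary(fit, "arm_gene")


def screen_interactions(
    fm: FeatureMatrix,
    clinical,
    endpoint: str = "dfs",
    alpha: float = 0.05,
    min_altered: int = 10,
    ties: str = "efron",
    correction: str | None = None,
) -> tuple:
    """Screen every feature for a treatment interaction.

    Features altered in fewer than ``min_altered`` patients are reported with
    status SKIPPED and never fitted.  Returns ``(results, selected)`` where
    ``selected`` are the converged features with interaction p < alpha
    (on Benjamini-Hochberg-adjusted p if ``correction="bh"``), and results
    are sorted by p ascending with SKIPPED/FAILED rows last.
    """
    sf = survival_frame(clinical, endpoint)
    _check_two_arms(sf)
    fmat = fm.to_frame().reindex(sf.index)
    if fmat.isna().any().any():
        raise DegenerateDataError("feature matrix does not cover the clinical cohort")

    results = []
    for feature_id in fm.feature_ids:
        gene = fmat[feature_id].astype(float)
        n_altered = int(gene.sum())
        events_altered = int(sf.loc[gene > 0, "event"].sum())
        if n_altered < min_altered:
            results.append(
                InteractionResult(
                    feature_id, n_altered, events_altered,
                    math.nan, math.nan, math.nan, math.nan, math.nan,
                    converged=False, status="SKIPPED",
                    message=f"n_altered {n_altered} < min_altered {min_altered}",
                )
            )
            continue
        try:
            fit, w = _interaction_fit(feature_id, gene, sf, None, ties)
        except MinervaError as exc:
            results.append(
                InteractionResult(
                    feature_id, n_altered, events_altered,
                    math.nan, math.nan, math.nan, math.nan, math.nan,
                    converged=False, status="FAILED", message=str(exc),
                )
            )
            continue
        results.append(
            InteractionResult(
                feature_id, n_altered, events_altered,
                w.hr, w.ci_low, w.ci_high, w.z, w.p,
                converged=fit.converged,
            )
        )

    tested = [r for r in results if r.status == "OK"]
    if correction == "bh" and tested:
        _, q, _, _ = multipletests([r.p for r in tested], method="fdr_bh")
        for r, qv in zip(tested, q):
            r.p_adjusted = float(qv)
    elif correction not in (None, "bh"):
        raise ValueError(f"unknown correction {correction!r}")

    def effective_p(r):
        return r.p_adjusted if correction == "bh" else r.p

    selected = [r for r in tested if r.converged and effective_p(r) < alpha]
    results.sort(
        key=lambda r: (r.status != "OK", r.p if not math.isnan(r.p) else math.inf)
    )
    selected.sort(key=lambda r: r.p)
    return results, selected


def adjusted_interaction(
    feature_id: str,
    fm: FeatureMatrix,
    clinical,
    endpoint: str = "dfs",
    covariates: Sequence[str] = CLINICAL_COVARIATES,
    ties: str = "efron",
) -> InteractionResult:
    """Interaction test with clinical covariates controlled
    (age, sex, smoking history, clinical stage and nodal stage by default)."""
    sf = survival_frame(clinical, endpoint)
    _check_two_arms(sf)
    cf = cohort_frame(clinical)
    extra = covariate_design(cf, covariates)
    gene = _aligned_feature(fm, feature_id, sf.index)
    fit, w = _interaction_fit(feature_id, gene, sf, extra, ties)
    return InteractionResult(
        feature_id=feature_id,
        n_altered=int(gene.sum()),
        events_altered=int(sf.loc[gene > 0, "event"].sum()),
        ihr=w.hr, ci_low=w.ci_low, ci_high=w.ci_high, z=w.z, p=w.p,
        converged=fit.converged, adjusted=True,
    )


def prognostic_test(
    feature_id: str,
    fm: FeatureMatrix,
    clinical,
    endpoint: str = "dfs",
    covariates: Sequence[str] = (),
    ties: str = "efron",
) -> PrognosticResult:
    """Treatment-adjusted gene main effect, without the interaction term."""
    sf = survival_frame(clinical, endpoint)
    _check_two_arms(sf)
    gene = _aligned_feature(fm, feature_id, sf.index)
    model = sf.assign(gene=gene)
    covs = ["arm", "gene"]
    if covariates:
        extra = covariate_design(cohort_frame(clinical), covariates)
        model = model.join(extra)
        covs += list(extra.columns)
    fit = fit_cox(model, covariates=covs, ties=ties)
    w = wald_summary(fit, "gene")
    return PrognosticResult(
        feature_id=feature_id,
        hr=w.hr, ci_low=w.ci_low, ci_high=w.ci_high, z=w.z, p=w.p,
        adjusted=bool(covariates),
    )


def results_to_frame(results: Sequence[InteractionResult]) -> pd.DataFrame:
    """Screening table with formatted events/altered and iHR (CI) columns."""

    def fmt(r):
        if r.status != "OK":
            return {"iHR (95% CI)": "", "z": "", "p": ""}
        return {
            "iHR (95% CI)": f"{r.ihr:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})",
            "z": round(r.z, 2),
            "p": round(r.p, 4),
        }

    return pd.DataFrame(
        [
            {
                "feature": r.feature_id,
                "events/altered": f"{r.events_altered}/{r.n_altered}",
                **fmt(r),
                "status": r.status,
            }
            for r in results
        ]
    )
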