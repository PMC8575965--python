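"""The composite MINERVA score: a per-patient linear combination of binary
alteration indicators weighted by treatment-interaction z-scores,

    score_i = sum_{g in G} z_g * p_{i,g}

where G is the selected feature set, z_g the interaction Wald z of feature g
and p_{i,g} the patient's 0/1 alteration status.  Lower scores mean greater
relative benefit from adjuvant TKI.  Patients are stratified at fixed score
cutoffs into Highly TKI-Preferable (HTP, score <= low), TKI-Preferable (TP)
and Chemo-Preferable (CP, score >= high) subgroups, and within-subgroup
relative benefit is summarised by the 2-year survival-rate ratio and the
median survival difference between arms.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError, MinervaError
from .io import FeatureMatrix, SIGNATURE_FEATURES
from .screen import InteractionResult, survival_frame
from .survival import fit_cox, km_estimate, km_summary, logrank_test, wald_summary

logger = logging.getLogger(__name__)

__all__ = [
    "PUBLISHED_WEIGHTS",
    "MinervaWeights",
    "ScoreResult",
    "SubgroupBenefit",
    "published_weights",
    "refit_weights",
    "compute_score",
    "classify",
    "evaluate_cutoffs",
    "benefit_summary",
    "attainable_scores",
]

SUBGROUPS = ("HTP", "TP", "CP")

#: interaction z-scores of the five published signature features
PUBLISHED_WEIGHTS = {
    "RB1_alt": 2.88,
    "NKX2-1_gain": -2.72,
    "CDK4_gain": -2.26,
    "TP53_e45_mis": -2.11,
    "MYC_gain": -1.98,
}


@dataclass
class MinervaWeights:
    """feature_id -> interaction-z weight map."""

    weights: dict
    source: str = "refit"  # published | refit | custom

    def __post_init__(self):
        if not self.weights:
            raise ConfigError("empty signature: no weighted features")
        bad = {k: v for k, v in self.weights.items() if not math.isfinite(v)}
        if bad:
            raise ConfigError(f"non-finite weights: {bad}")


@dataclass
class ScoreResult:
    """Per-patient scores and (after classification) subgroup labels."""

    scores: pd.Series
    subgroups: pd.Series | None = None
    cutoffs: tuple | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"score": self.scores})
        frame["subgroup"] = self.subgroups if self.subgroups is not None else ""
        frame.index.name = "patient_id"
        return frame


@dataclass
class SubgroupBenefit:
    subgroup: str
    n: int
    n_tki: int
    n_chemo: int
    defined: bool = True
    rate_tki: float = math.nan      # KM survival at the horizon, TKI arm
    rate_chemo: float = math.nan
    rate_ratio: float = math.nan    # TKI / chemo
    median_tki: float | None = None  # None = not reached
    median_chemo: float | None = None
    median_diff: float | None = None
    hr: float = math.nan            # within-subgroup treatment HR (TKI vs chemo)
    hr_ci_low: float = math.nan
    hr_ci_high: float = math.nan
    logrank_p: float = math.nan
    message: str | None = None


def published_weights() -> MinervaWeights:
    """The five-feature signature with its published interaction z weights."""
    return MinervaWeights(dict(PUBLISHED_WEIGHTS), source="published")


def refit_weights(selected: Sequence[InteractionResult]) -> MinervaWeights:
    """Signature weights from a screen's selected features (weight = z)."""
    if not selected:
        raise ConfigError("empty signature: no features selected")
    bad = [r.feature_id for r in selected if not r.converged]
    if bad:
        raise ConfigError(f"non-converged interaction fit(s) in selection: {bad}")
    return MinervaWeights({r.feature_id: float(r.z) for r in selected}, source="refit")


def compute_score(weights: MinervaWeights, fm: FeatureMatrix) -> ScoreResult:
    """Linear score over the weighted features.

    Weighted features absent from the matrix are treated as all-wild-type
    (contribute 0) with a warning; an all-wild-type patient scores exactly 0.
    """
    frame = fm.to_frame()
    missing = [f for f in weights.weights if f not in frame.columns]
    if missing:
        logger.warning(
            "compute_score: feature(s) %s absent from matrix; treated wild-type",
            missing,
        )
    present = [f for f in weights.weights if f in frame.columns]
    w = np.array([weights.weights[f] for f in present])
    values = frame[present].to_numpy(dtype=float) if present else np.zeros((len(frame), 0))
    scores = pd.Series(values @ w if present else np.zeros(len(frame)),
                       index=frame.index, name="score")
    return ScoreResult(scores=scores)


def _classify_values(scores: pd.Series, low: float, high: float) -> pd.Series:
    labels = np.where(
        scores <= low, "HTP", np.where(scores >= high, "CP", "TP")
    )
    return pd.Series(labels, index=scores.index, name="subgroup")


def classify(result: ScoreResult, cutoffs: tuple = (-0.5, 0.5)) -> ScoreResult:
    """Assign HTP (score <= low) / TP / CP (score >= high) subgroup labels.

    Both boundaries are inclusive toward the outer groups.
    """
    low, high = cutoffs
    if not low < high:
        raise ConfigError(f"cutoffs must satisfy low < high, got {cutoffs}")
    return ScoreResult(
        scores=result.scores,
        subgroups=_classify_values(result.scores, low, high),
        cutoffs=(float(low), float(high)),
    )


def _arm_series(clinical, index) -> pd.Series:
    sf = survival_frame(clinical, "dfs")
    return sf["arm"].reindex(index)


def benefit_summary(
    result: ScoreResult,
    clinical,
    endpoint: str = "dfs",
    horizon: float = 24.0,
    ties: str = "efron",
) -> list:
    """Within-subgroup arm-vs-arm benefit metrics.

    For each subgroup: Kaplan-Meier survival at the horizon per arm and their
    TKI/chemo ratio, median survival per arm and their difference (None
    propagates when a median is not reached), the treatment hazard ratio from
    a treatment-only Cox fit, and the two-group log-rank p.  Subgroups with an
    empty arm yield a row with ``defined=False``.
    """
    if result.subgroups is None:
        raise ConfigError("benefit_summary requires classified scores")
    sf = survival_frame(clinical, endpoint).reindex(result.scores.index)
    out = []
    for sub in SUBGROUPS:
        mask = (result.subgroups == sub).to_numpy()
        grp = sf[mask]
        tki = grp[grp["arm"] == 1]
        chemo = grp[grp["arm"] == 0]
        row = SubgroupBenefit(sub, len(grp), len(tki), len(chemo))
        if len(tki) == 0 or len(chemo) == 0:
            row.defined = False
            row.message = "empty arm within subgroup"
            out.append(row)
            continue
        km_t = km_summary(km_estimate(tki["time"], tki["event"]), [horizon])
        km_c = km_summary(km_estimate(chemo["time"], chemo["event"]), [horizon])
        row.rate_tki = km_t.horizons[0][1]
        row.rate_chemo = km_c.horizons[0][1]
        if row.rate_chemo > 0:
            row.rate_ratio = row.rate_tki / row.rate_chemo
        elif row.rate_tki > 0:
            row.rate_ratio = math.inf  # every chemo patient failed by the horizon
        else:
            row.rate_ratio = math.nan
        row.median_tki, row.median_chemo = km_t.median, km_c.median
        if row.median_tki is not None and row.median_chemo is not None:
            row.median_diff = row.median_tki - row.median_chemo
        try:
            fit = fit_cox(grp, covariates=["arm"], ties=ties)
            w = wald_summary(fit, "arm")
            row.hr, row.hr_ci_low, row.hr_ci_high = w.hr, w.ci_low, w.ci_high
        except MinervaError as exc:
            row.message = f"treatment Cox fit failed: {exc}"
        try:
            _, row.logrank_p = logrank_test(
                tki["time"], tki["event"], chemo["time"], chemo["event"]
            )
        except DegenerateDataError as exc:
            row.message = f"log-rank failed: {exc}"
        out.append(row)
    return out


def benefit_to_frame(benefits: Sequence[SubgroupBenefit]) -> pd.DataFrame:
    def nr(v):
        return "NOT_REACHED" if v is None else v

    return pd.DataFrame(
        [
            {
                "subgroup": b.subgroup,
                "n": b.n,
                "n_tki": b.n_tki,
                "n_chemo": b.n_chemo,
                "rate_tki": b.rate_tki,
                "rate_chemo": b.rate_chemo,
                "rate_ratio": b.rate_ratio,
                "median_tki": nr(b.median_tki) if b.defined else "",
                "median_chemo": nr(b.median_chemo) if b.defined else "",
                "median_diff": nr(b.median_diff) if b.defined else "",
                "hr": b.hr,
                "hr_ci_low": b.hr_ci_low,
                "hr_ci_high": b.hr_ci_high,
                "logrank_p": b.logrank_p,
                "defined": b.defined,
            }
            for b in benefits
        ]
    )


def evaluate_cutoffs(
    result: ScoreResult,
    clinical,
    endpoint: str = "dfs",
    candidates: Sequence[tuple] = ((-1.0, 1.0), (-0.5, 0.5), (0.0, 0.0)),
    ties: str = "efron",
) -> pd.DataFrame:
    """Report-only comparison of candidate cutoff pairs.

    For each candidate: subgroup sizes, within-subgroup treatment log-rank
    statistics, and a separation statistic (the subgroup-size-weighted sum of
    |within-subgroup log treatment HR|).  Candidates producing empty or
    single-arm subgroups are flagged, never excluded; no winner is chosen.
    A degenerate equal pair (c, c) splits at the single cutoff
    (HTP: score <= c, CP: score > c) leaving TP empty.
    """
    if result.scores.nunique() <= 1:
        raise DegenerateDataError("constant scores: cutoffs cannot separate patients")
    sf = survival_frame(clinical, endpoint).reindex(result.scores.index)
    rows = []
    for low, high in candidates:
        if low > high:
            raise ConfigError(f"cutoff pair ({low}, {high}) has low > high")
        labels = _classify_values(result.scores, low, high)
        flags = []
        if low == high:
            flags.append("degenerate pair: TP empty")
        sizes = {s: int((labels == s).sum()) for s in SUBGROUPS}
        separation = 0.0
        sep_weight = 0
        stats_cols = {}
        for sub in SUBGROUPS:
            grp = sf[(labels == sub).to_numpy()]
            tki, chemo = grp[grp["arm"] == 1], grp[grp["arm"] == 0]
            if len(grp) == 0:
                flags.append(f"{sub} empty")
                stats_cols[f"logrank_chi2_{sub}"] = math.nan
                continue
            if len(tki) == 0 or len(chemo) == 0:
                flags.append(f"{sub} single-arm")
                stats_cols[f"logrank_chi2_{sub}"] = math.nan
                continue
            try:
                chi2, _ = logrank_test(
                    tki["time"], tki["event"], chemo["time"], chemo["event"]
                )
            except DegenerateDataError:
                chi2 = math.nan
                flags.append(f"{sub} log-rank degenerate")
            stats_cols[f"logrank_chi2_{sub}"] = chi2
            try:
                fit = fit_cox(grp, covariates=["arm"], ties=ties)
                separation += len(grp) * abs(fit.coef("arm"))
                sep_weight += len(grp)
            except MinervaError:
                flags.append(f"{sub} Cox degenerate")
        rows.append(
            {
                "low": low,
                "high": high,
                **{f"n_{s}": sizes[s] for s in SUBGROUPS},
                **stats_cols,
                "separation": separation / sep_weight if sep_weight else math.nan,
                "flags": "; ".join(flags),
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values("separation", ascending=False, ignore_index=True)


def attainable_scores(weights: MinervaWeights | None = None) -> list:
    """All subset sums of the weight set (the reachable score values)."""
    if weights is None:
        weights = published_weights()
    values = list(weights.weights.values())
    sums = set()
    for r in range(len(values) + 1):
        for combo in itertools.combinations(values, r):
            sums.add(round(sum(combo), 10))
    return sorted(sums)
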