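"""Internal validation of the composite signature: repeated stratified
10-fold cross-validation with in-fold marker reselection, leave-one-out
cross-validation, the score-as-continuous-covariate interaction test, and
application of a fixed signature to an external cohort.

The CV contract: within each repeat, patients are partitioned into folds
stratified by treatment arm; the interaction screen runs on the training 90%
only, the held-out 10% are scored with the in-fold weights (a "mock" score),
and after all folds every patient carries exactly one mock score.  A held-out
patient's own alterations therefore never influence their own score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError, MinervaError
from .io import FeatureMatrix
from .score import (
    MinervaWeights,
    ScoreResult,
    SubgroupBenefit,
    SUBGROUPS,
    benefit_summary,
    classify,
    compute_score,
    refit_weights,
)
from .screen import cohort_frame, screen_interactions, survival_frame
from .survival import WaldSummary, fit_cox, wald_summary

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "RepeatResult",
    "CVResult",
    "ten_fold_cv",
    "loocv",
    "score_interaction_test",
    "apply_signature",
    "SignatureApplication",
]


@dataclass
class CVConfig:
    n_folds: int = 10
    n_repeats: int = 100
    alpha: float = 0.05
    min_altered: int = 10
    cutoffs: tuple = (-0.5, 0.5)
    endpoint: str = "dfs"
    horizon: float = 24.0
    ties: str = "efron"
    seed: int = 0
    max_resample: int = 20

    def __post_init__(self):
        if self.n_folds < 2:
            raise ConfigError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_repeats < 1:
            raise ConfigError(f"n_repeats must be >= 1, got {self.n_repeats}")
        low, high = self.cutoffs
        if not low < high:
            raise ConfigError(f"cutoffs must satisfy low < high, got {self.cutoffs}")


@dataclass
class RepeatResult:
    repeat: int
    scores: pd.Series
    subgroups: pd.Series
    benefits: list
    interaction: WaldSummary | None
    folds: np.ndarray | None = None
    flags: list = field(default_factory=list)


@dataclass
class CVResult:
    config: CVConfig
    repeats: list
    aggregate: dict

    def scores_frame(self) -> pd.DataFrame:
        """Per-repeat mock scores as a patients x repeats audit table."""
        return pd.DataFrame(
            {f"repeat_{r.repeat}": r.scores for r in self.repeats}
        )


def _stratified_folds(arm: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Fold label per patient, arm-stratified round-robin after shuffling."""
    fold = np.empty(len(arm), dtype=int)
    for value in np.unique(arm):
        idx = np.flatnonzero(arm == value)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def _train_split_ok(sf: pd.DataFrame, train_mask: np.ndarray) -> bool:
    sub = sf[train_mask]
    for a in (0, 1):
        grp = sub[sub["arm"] == a]
        if len(grp) == 0 or grp["event"].sum() == 0:
            return False
    return True


def _mock_scores_for_folds(
    fm: FeatureMatrix, cf: pd.DataFrame, sf: pd.DataFrame, fold: np.ndarray, cfg: CVConfig
):
    """Screen on each training split, score the held-out fold; returns
    (scores Series over all patients, flags)."""
    pids = np.asarray(fm.patient_ids)
    scores = pd.Series(np.nan, index=pids, name="score")
    flags = []
    for k in range(cfg.n_folds):
        held = fold == k
        if not held.any():
            continue
        train_ids = pids[~held]
        _, selected = screen_interactions(
            fm.subset(train_ids),
            cf.loc[train_ids].reset_index(),
            endpoint=cfg.endpoint,
            alpha=cfg.alpha,
            min_altered=cfg.min_altered,
            ties=cfg.ties,
        )
        held_fm = fm.subset(pids[held])
        if not selected:
            flags.append(f"fold {k}: empty in-fold selection; held-out scored 0")
            scores[pids[held]] = 0.0
            continue
        weights = refit_weights(selected)
        scores[pids[held]] = compute_score(weights, held_fm).scores
    return scores, flags


def ten_fold_cv(fm: FeatureMatrix, clinical, cfg: CVConfig | None = None) -> CVResult:
    """Repeated stratified k-fold CV with in-fold marker reselection.

    Per repeat: partition patients into ``cfg.n_folds`` folds stratified by
    arm (resampling the partition, with a flag, if a training split has an
    event-free arm); screen the training split, score the held-out fold with
    the in-fold interaction z weights (0 if nothing selected); then classify
    all patients, compute per-subgroup benefit metrics and the continuous
    mock-score-by-treatment interaction p.  Aggregates report means and
    standard errors over repeats and the fraction of repeats with interaction
    p < 0.05 and < 0.1.
    """
    if cfg is None:
        cfg = CVConfig()
    cf = cohort_frame(clinical)
    sf = survival_frame(clinical, cfg.endpoint)
    if sf["arm"].nunique() < 2:
        raise DegenerateDataError("cross-validation requires both treatment arms")
    arm = sf["arm"].to_numpy()

    repeats = []
    for rep in range(cfg.n_repeats):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(rep,))
        )
        flags = []
        fold = None
        for attempt in range(cfg.max_resample):
            cand = _stratified_folds(arm, cfg.n_folds, rng)
            if all(_train_split_ok(sf, cand != k) for k in range(cfg.n_folds)):
                fold = cand
                break
            flags.append(f"attempt {attempt}: event-free arm in a training split; resampled")
        if fold is None:
            raise DegenerateDataError(
                f"repeat {rep}: could not draw folds with events in every "
                f"training arm after {cfg.max_resample} attempts"
            )
        scores, fold_flags = _mock_scores_for_folds(fm, cf, sf, fold, cfg)
        flags.extend(fold_flags)
        assert not scores.isna().any()
        classified = classify(ScoreResult(scores=scores), cfg.cutoffs)
        benefits = benefit_summary(
            classified, clinical, endpoint=cfg.endpoint,
            horizon=cfg.horizon, ties=cfg.ties,
        )
        try:
            interaction = score_interaction_test(
                classified, clinical, endpoint=cfg.endpoint, ties=cfg.ties
            )
        except MinervaError as exc:
            interaction = None
            flags.append(f"score interaction test degenerate: {exc}")
        repeats.append(
            RepeatResult(
                rep, scores, classified.subgroups, benefits, interaction,
                folds=fold, flags=flags,
            )
        )
    return CVResult(config=cfg, repeats=repeats, aggregate=_aggregate(repeats))


def _mean_se(values: list) -> dict:
    arr = np.array([v for v in values if v is not None and math.isfinite(v)], float)
    if arr.size == 0:
        return {"mean": math.nan, "se": math.nan, "n_defined": 0}
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else math.nan
    return {"mean": float(arr.mean()), "se": se, "n_defined": int(arr.size)}


def _aggregate(repeats: Sequence[RepeatResult]) -> dict:
    agg = {"n_repeats": len(repeats), "subgroups": {}}
    for sub in SUBGROUPS:
        ratios, diffs, sizes = [], [], []
        for r in repeats:
            b = next(x for x in r.benefits if x.subgroup == sub)
            sizes.append(b.n)
            if b.defined:
                ratios.append(b.rate_ratio)
                diffs.append(b.median_diff)
        rr = _mean_se(ratios)
        rr["n_infinite"] = sum(1 for v in ratios if v is not None and math.isinf(v))
        agg["subgroups"][sub] = {
            "rate_ratio": rr,
            "median_diff": _mean_se(diffs),
            "mean_size": float(np.mean(sizes)) if sizes else math.nan,
        }
    pvals = [r.interaction.p for r in repeats if r.interaction is not None]
    agg["interaction"] = {
        "n_defined": len(pvals),
        "frac_p_lt_0.05": float(np.mean([p < 0.05 for p in pvals])) if pvals else math.nan,
        "frac_p_lt_0.1": float(np.mean([p < 0.1 for p in pvals])) if pvals else math.nan,
    }
    agg["n_flagged_repeats"] = sum(1 for r in repeats if r.flags)
    return agg


def loocv(fm: FeatureMatrix, clinical, cfg: CVConfig | None = None) -> ScoreResult:
    """Leave-one-out CV: each patient is scored by a signature selected and
    weighted on the remaining patients, then classified by the cutoffs.

    Deterministic: no randomness is involved.  Downstream KM and benefit
    summaries reuse :func:`~minerva_nsclc.score.benefit_summary`.
    """
    if cfg is None:
        cfg = CVConfig()
    pids = np.asarray(fm.patient_ids)
    if len(pids) < 3:
        raise DegenerateDataError(f"LOOCV requires n >= 3, got {len(pids)}")
    cf = cohort_frame(clinical)
    scores = pd.Series(np.nan, index=pids, name="score")
    n_empty = 0
    for i, pid in enumerate(pids):
        train_ids = np.delete(pids, i)
        try:
            _, selected = screen_interactions(
                fm.subset(train_ids),
                cf.loc[train_ids].reset_index(),
                endpoint=cfg.endpoint,
                alpha=cfg.alpha,
                min_altered=cfg.min_altered,
                ties=cfg.ties,
            )
        except DegenerateDataError as exc:
            # e.g. the left-out patient was an arm's sole member
            logger.warning("loocv: training set for %s degenerate (%s); scored 0",
                           pid, exc)
            selected = []
        if not selected:
            scores[pid] = 0.0
            n_empty += 1
            continue
        weights = refit_weights(selected)
        scores[pid] = compute_score(weights, fm.subset([pid])).scores.iloc[0]
    if n_empty:
        logger.info("loocv: %d patients scored 0 (empty selection)", n_empty)
    return classify(ScoreResult(scores=scores), cfg.cutoffs)


def score_interaction_test(
    scores: ScoreResult | pd.Series, clinical, endpoint: str = "dfs", ties: str = "efron"
) -> WaldSummary:
    """Treatment interaction of the score as a continuous covariate:
    Cox fit on {arm, score, arm x score}; returns the interaction Wald summary."""
    s = scores.scores if isinstance(scores, ScoreResult) else scores
    sf = survival_frame(clinical, endpoint)
    s = s.reindex(sf.index)
    if s.isna().any():
        raise DegenerateDataError("scores do not cover the clinical cohort")
    if s.nunique() <= 1:
        raise DegenerateDataError("constant score: interaction not identifiable")
    model = sf.assign(score=s.astype(float), arm_score=sf["arm"] * s.astype(float))
    fit = fit_cox(model, covariates=["arm", "score", "arm_score"], ties=ties)
    return wald_summary(fit, "arm_score")


@dataclass
class SignatureApplication:
    scores: ScoreResult
    benefits: list
    interaction: WaldSummary | None
    flags: list = field(default_factory=list)


def apply_signature(
    weights: MinervaWeights,
    fm: FeatureMatrix,
    clinical,
    cutoffs: tuple = (-0.5, 0.5),
    endpoint: str = "pfs",
    horizon: float = 24.0,
    ties: str = "efron",
) -> SignatureApplication:
    """Pure application of a fixed signature to an external cohort: no
    refitting.  Missing weighted features score as wild-type (warned in
    :func:`compute_score`); endpoint label is configurable (e.g. PFS)."""
    classified = classify(compute_score(weights, fm), cutoffs)
    benefits = benefit_summary(
        classified, clinical, endpoint=endpoint, horizon=horizon, ties=ties
    )
    flags = []
    try:
        interaction = score_interaction_test(classified, clinical, endpoint, ties)
    except MinervaError as exc:
        interaction = None
        flags.append(f"score interaction test degenerate: {exc}")
    return SignatureApplication(classified, benefits, interaction, flags)
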