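"""The APF2 ensemble score.

Five re-parametrized component predictors each cast a binary
functionality vote (1 = functional/neutral, 0 = deleterious) at their
optimized cutoff.  The ensemble score is the weight-normalized sum of
the available votes, so it lives in [0, 1]: 0 when every component calls
the variant deleterious, 1 when every component calls it functional.
Variants with a score at or below the fixed cutoff 0.367 are classified
deleterious; above it, functionally neutral.

Component weights default to each component's cross-validated mean
validation-fold informedness (Youden's J), normalized to sum to one, so
components that generalize better carry more of the vote; uniform or
user-supplied weights are also supported and the scheme is recorded in
the serialized model.

Because the binary votes order variants on a coarse [0, 1] scale, the
score also carries quantitative information: binned mean in-vitro
activity is close to linear in the score, and :func:`fit_activity_map`
exposes that regression for activity prediction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    AlgorithmSpec,
    Direction,
    LabeledVariantSet,
    ScoreTable,
    Strictness,
    VariantKey,
)
from .threshold_opt import CrossValidationResult, ThresholdFit

__all__ = [
    "DEFAULT_CUTOFF",
    "DEFAULT_MIN_COMPONENTS",
    "EnsembleModel",
    "Apf2Result",
    "ActivityMap",
    "default_model",
    "fit_ensemble",
    "apf2_score",
    "score_table",
    "classify",
    "fit_activity_map",
    "predict_activity",
]

#: Fixed deleterious cutoff of the shipped model: score <= 0.367 is
#: classified deleterious, > 0.367 functionally neutral.
DEFAULT_CUTOFF = 0.367

#: Minimum number of non-missing component votes for a valid call.
DEFAULT_MIN_COMPONENTS = 3

_H, _L = Direction.DELETERIOUS_IF_HIGH, Direction.DELETERIOUS_IF_LOW
_S, _NS = Strictness.STRICT, Strictness.NON_STRICT

# Re-parametrized cutoffs of the five shipped components and their
# combined-set optimized informedness, from which the default weights
# derive (J-proportional, normalized to sum 1).
_DEFAULT_COMPONENTS: tuple[tuple[AlgorithmSpec, float], ...] = (
    (AlgorithmSpec("AlphaMissense", _H, _NS, 0.152), 0.46),
    (AlgorithmSpec("PROVEAN", _L, _S, -3.2925), 0.44),
    (AlgorithmSpec("MutationAssessor", _H, _S, 2.08), 0.38),
    (AlgorithmSpec("PolyPhen-2", _H, _S, 0.42), 0.42),
    (AlgorithmSpec("VEST4", _H, _S, 0.2905, family="VEST"), 0.37),
)


@dataclass(frozen=True)
class EnsembleModel:
    """Component specs (at optimized cutoffs), weights, and the cutoff."""

    components: tuple[tuple[AlgorithmSpec, float], ...]
    cutoff: float = DEFAULT_CUTOFF
    min_components: int = DEFAULT_MIN_COMPONENTS
    weighting: str = "cv_j"

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")
        weights = np.array([w for _, w in self.components], dtype=float)
        if len(weights) == 0 or (weights <= 0).any():
            raise ValueError("component weights must be positive")
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError("component weights must sum to 1")
        if not 1 <= self.min_components <= len(self.components):
            raise ValueError("min_components must be in [1, n_components]")
        names = [s.name for s, _ in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component algorithms")

    @property
    def algorithms(self) -> list[str]:
        return [s.name for s, _ in self.components]

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "min_components": self.min_components,
            "weighting": self.weighting,
            "components": [
                {
                    "name": s.name,
                    "family": s.family,
                    "direction": s.direction.value,
                    "strictness": s.strictness.value,
                    "threshold": s.threshold,
                    "weight": w,
                }
                for s, w in self.components
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "EnsembleModel":
        comps = tuple(
            (
                AlgorithmSpec(
                    name=c["name"],
                    direction=Direction(c["direction"]),
                    strictness=Strictness(c["strictness"]),
                    threshold=float(c["threshold"]),
                    family=c.get("family", ""),
                ),
                float(c["weight"]),
            )
            for c in d["components"]
        )
        return cls(
            components=comps,
            cutoff=float(d.get("cutoff", DEFAULT_CUTOFF)),
            min_components=int(d.get("min_components", DEFAULT_MIN_COMPONENTS)),
            weighting=str(d.get("weighting", "cv_j")),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_model() -> EnsembleModel:
    """The shipped five-component model.

    AlphaMissense >= 0.152, PROVEAN < -3.2925, MutationAssessor > 2.08,
    PolyPhen-2 > 0.42 and VEST4 > 0.2905, weighted in proportion to
    their combined-set optimized informedness, with the fixed 0.367
    deleterious cutoff.
    """
    total = sum(j for _, j in _DEFAULT_COMPONENTS)
    comps = tuple((spec, j / total) for spec, j in _DEFAULT_COMPONENTS)
    return EnsembleModel(components=comps, weighting="j")


@dataclass(frozen=True)
class Apf2Result:
    """Ensemble score and call for one variant.

    ``score`` is ``None`` (NO_CALL) when fewer than ``min_components``
    components could vote.
    """

    variant: str
    score: float | None
    call: str  # deleterious | neutral | no_call
    n_components_used: int
    votes: Mapping[str, float | None] = None  # 1 functional, 0 deleterious


def classify(score: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Binary call from an ensemble score: deleterious iff score <= cutoff."""
    if not 0 <= score <= 1:
        raise ValueError("ensemble score must lie in [0, 1]")
    return "deleterious" if score <= cutoff else "neutral"


def apf2_score(
    variant_scores: Mapping[str, float] | pd.Series,
    model: EnsembleModel,
) -> Apf2Result:
    """Ensemble score for one variant from its per-algorithm raw scores.

    Each component with a non-missing score votes 1 (functional) or 0
    (deleterious) at its optimized cutoff; the score is the vote sum
    under weights renormalized over the available components.  Fewer
    than ``model.min_components`` available votes yields NO_CALL.
    """
    if isinstance(variant_scores, pd.Series):
        name = variant_scores.name
        getter = variant_scores.get
    else:
        name = variant_scores.get("variant", "")
        getter = variant_scores.get
    votes: dict[str, float | None] = {}
    weights: list[float] = []
    values: list[float] = []
    for spec, w in model.components:
        raw = getter(spec.name)
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            votes[spec.name] = None
            continue
        v = 0.0 if spec.calls_deleterious(float(raw)) else 1.0
        votes[spec.name] = v
        weights.append(w)
        values.append(v)
    n_used = len(values)
    if n_used < model.min_components:
        return Apf2Result(
            variant=str(name or ""), score=None, call="no_call",
            n_components_used=n_used, votes=votes,
        )
    w = np.array(weights) / np.sum(weights)
    score = float(np.clip(np.dot(w, values), 0.0, 1.0))
    return Apf2Result(
        variant=str(name or ""),
        score=score,
        call=classify(score, model.cutoff),
        n_components_used=n_used,
        votes=votes,
    )


def score_table(table: ScoreTable, model: EnsembleModel) -> pd.DataFrame:
    """Score every variant of a table; one row per variant.

    Columns: apf2_score (NaN for NO_CALL), call, n_components_used, and
    one ``vote_<algorithm>`` column per component.
    """
    rows = []
    for vid in table.scores.index:
        res = apf2_score(table.scores.loc[vid], model)
        row = {
            "variant": vid,
            "apf2_score": np.nan if res.score is None else res.score,
            "call": res.call,
            "n_components_used": res.n_components_used,
        }
        for algo in model.algorithms:
            v = res.votes.get(algo)
            row[f"vote_{algo}"] = np.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")


def fit_ensemble(
    table: ScoreTable | None,
    labels: LabeledVariantSet | None,
    fits: Sequence[ThresholdFit | CrossValidationResult],
    weighting: str = "cv_j",
    weights: Sequence[float] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    min_components: int | None = None,
) -> EnsembleModel:
    """Assemble an ensemble model from per-component threshold fits.

    ``fits`` may mix :class:`CrossValidationResult` (preferred — the
    weight uses the mean validation-fold J) and plain
    :class:`ThresholdFit` (weight falls back to the full-set optimized
    J).  Weighting schemes: ``cv_j`` (J-proportional, default),
    ``uniform``, or ``user`` with explicit ``weights``.  Components with
    non-positive J are excluded with a warning; at least two must
    remain.  ``table``/``labels`` are accepted for signature symmetry
    with the rest of the pipeline and may be ``None``.
    """
    specs: list[AlgorithmSpec] = []
    js: list[float] = []
    for f in fits:
        if isinstance(f, CrossValidationResult):
            fit, j = f.final_fit, f.mean_validation_J
        else:
            fit, j = f, f.J_optimized
        spec = AlgorithmSpec(
            name=fit.algorithm,
            direction=fit.direction,
            strictness=Strictness.NON_STRICT
            if fit.direction is Direction.DELETERIOUS_IF_LOW
            else Strictness.STRICT,
            threshold=fit.optimized_threshold,
        )
        # midpoints never coincide with observed scores, so strictness
        # is irrelevant for fitted cutoffs; keep the registry's operator
        # when the component is a known algorithm
        from .io_model import _REGISTRY_BY_NAME

        base = _REGISTRY_BY_NAME.get(fit.algorithm)
        if base is not None:
            spec = base.with_threshold(fit.optimized_threshold)
        specs.append(spec)
        js.append(float(j))

    keep = [i for i, j in enumerate(js) if j > 0]
    dropped = [specs[i].name for i in range(len(js)) if i not in keep]
    if dropped:
        warnings.warn(
            f"excluding components with non-positive informedness: {dropped}",
            stacklevel=2,
        )
    if len(keep) < 2:
        raise ValueError("fewer than 2 informative components remain")
    specs = [specs[i] for i in keep]
    js = [js[i] for i in keep]

    if weighting == "uniform":
        w = np.full(len(specs), 1 / len(specs))
    elif weighting in ("cv_j", "j"):
        w = np.array(js) / np.sum(js)
    elif weighting == "user":
        if weights is None or len(weights) != len(fits):
            raise ValueError("weighting='user' needs one weight per fit")
        w = np.array([weights[i] for i in keep], dtype=float)
        w = w / w.sum()
    else:
        raise ValueError(f"unknown weighting scheme {weighting!r}")

    if min_components is None:
        min_components = min(DEFAULT_MIN_COMPONENTS, len(specs))
    return EnsembleModel(
        components=tuple(zip(specs, (float(x) for x in w))),
        cutoff=cutoff,
        min_components=min_components,
        weighting=weighting,
    )


@dataclass(frozen=True)
class ActivityMap:
    """Linear map from ensemble score to in-vitro activity (% wild type).

    Fitted by ordinary least squares of bin-mean activity on bin
    midpoint over equal-width score bins; predictions are clamped to
    [0, max activity observed at fit time].
    """

    bin_edges: np.ndarray
    bin_midpoints: np.ndarray
    bin_mean_activity: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    max_activity: float

    def to_dict(self) -> dict:
        return {
            "bin_edges": list(self.bin_edges),
            "bin_midpoints": list(self.bin_midpoints),
            "bin_mean_activity": list(self.bin_mean_activity),
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "max_activity": self.max_activity,
        }


def fit_activity_map(
    results: Sequence[Apf2Result] | Mapping[str, float] | pd.Series,
    activities: Mapping[str, float] | pd.Series,
    n_bins: int = 7,
) -> ActivityMap:
    """Regress binned mean activity on the ensemble score.

    Scores are binned into ``n_bins`` equal-width bins over [0, 1]; an
    OLS line of bin-mean activity on bin midpoint is fitted over the
    non-empty bins (at least 3 required), reporting R-squared and the
    two-sided p-value of the slope.
    """
    if isinstance(results, (pd.Series, Mapping)):
        score_by_id = dict(pd.Series(results).dropna())
    else:
        score_by_id = {
            r.variant: r.score for r in results if r.score is not None
        }
    act = pd.Series(activities).dropna()
    common = [vid for vid in score_by_id if vid in act.index]
    if len(common) < 3:
        raise ValueError("need >=3 variants with both a score and an activity")
    scores = np.array([score_by_id[v] for v in common], dtype=float)
    activity = act.loc[common].to_numpy(dtype=float)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    mids, means = [], []
    for b in range(n_bins):
        in_bin = idx == b
        if in_bin.any():
            mids.append((edges[b] + edges[b + 1]) / 2)
            means.append(float(activity[in_bin].mean()))
    if len(mids) < 3:
        raise ValueError("need >=3 non-empty score bins for the activity fit")
    mids_arr, means_arr = np.array(mids), np.array(means)
    if np.allclose(means_arr, means_arr[0]):
        slope, intercept, r2, p = 0.0, float(means_arr[0]), 0.0, 1.0
    else:
        fit = stats.linregress(mids_arr, means_arr)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2, p = float(fit.rvalue**2), float(fit.pvalue)
    return ActivityMap(
        bin_edges=edges,
        bin_midpoints=mids_arr,
        bin_mean_activity=means_arr,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        p_value=p,
        max_activity=float(activity.max()),
    )


def predict_activity(score: float, activity_map: ActivityMap) -> float:
    """Predicted activity (% wild type) at an ensemble score, clamped to
    [0, max activity seen during fitting]."""
    raw = activity_map.intercept + activity_map.slope * float(score)
    return float(np.clip(raw, 0.0, activity_map.max_activity))
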