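"""Estimator front-end over the evidence-summary and drug-ranking pipeline.

Both classes follow the scikit-learn estimator protocol: constructor
parameters mirror :class:`~ttdrank.evidence.SummaryConfig`, ``fit`` consumes
a curated record table, fitted state lives in trailing-underscore
attributes, and ``get_params``/``set_params`` (inherited from
``sklearn.base.BaseEstimator``) make them composable with sklearn model
selection.  The module-level functions in :mod:`ttdrank.evidence` and
:mod:`ttdrank.ranking` remain the computational core; the estimators
orchestrate them.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .evidence import (
    EvidenceSummary,
    PredictorEntry,
    SummaryConfig,
    build_predictor_set,
    summaries_to_frame,
    summarize_corpus,
)
from .ranking import (
    DrugScore,
    PatientProfile,
    RankResult,
    StatePairLexicon,
    overall_score,
    rank_drugs,
    signed_percentages,
)
from .schema import RelationshipClass, TTDRecord, validate_table

__all__ = ["DrugRanker", "EvidenceSummarizer"]


class EvidenceSummarizer(BaseEstimator):
    """Summarize a curated evidence table into prevalent-hypothesis verdicts.

    Parameters
    ----------
    threshold : float, default 0.5
        Decision-rule value; a hypothesis must hold strictly more than this
        fraction of the group's evidence score.
    confidence_level : float, default 0.95
        Level of the Agresti-Coull interval (and of the Z-test criterion).
    criterion : {"ci_lower_bound", "z_test"}, default "ci_lower_bound"
        Uncertainty check confronting the score percentage with the
        threshold.
    size_combination : {"multiplicative", "additive"}, default "multiplicative"
        How the size score n/10 adjusts the tier model score.
    base_score : int, default 6
        Evidence score of the lowest (animal in vitro) tier.
    alias_map : mapping or None
        Optional normalized-alias -> canonical-name map merging molecule
        synonyms before grouping.

    Attributes
    ----------
    summaries_ : list of EvidenceSummary
        One verdict per evidence group, sorted by group key.
    n_records_ : int
        Number of records summarized.
    issues_ : list of RecordIssue
        Validation issues of the fitted table (errors raise in ``fit``).

    Examples
    --------
    >>> summarizer = EvidenceSummarizer().fit(records)
    >>> summarizer.summary_frame().head()
    """

    def __init__(
        self,
        threshold: float = 0.5,
        confidence_level: float = 0.95,
        criterion: str = "ci_lower_bound",
        size_combination: str = "multiplicative",
        base_score: int = 6,
        alias_map: Mapping[str, str] | None = None,
    ) -> None:
        self.threshold = threshold
        self.confidence_level = confidence_level
        self.criterion = criterion
        self.size_combination = size_combination
        self.base_score = base_score
        self.alias_map = alias_map

    def _config(self) -> SummaryConfig:
        return SummaryConfig(
            confidence_level=self.confidence_level,
            threshold=self.threshold,
            criterion=self.criterion,
            size_combination=self.size_combination,
            base_score=self.base_score,
        )

    def fit(self, X: Iterable[TTDRecord], y=None) -> "EvidenceSummarizer":
        """Validate the record table and compute all group summaries."""
        records = list(X)
        issues = validate_table(records)
        errors = [i for i in issues if i.severity == "error"]
        if errors:
            raise ValueError(
                "record table has validation errors: "
                + "; ".join(i.message for i in errors[:5])
            )
        self.config_ = self._config()
        self.issues_ = issues
        self.summaries_ = summarize_corpus(records, self.config_, self.alias_map)
        self.n_records_ = len(records)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "summaries_"):
            raise AttributeError("this EvidenceSummarizer is not fitted yet")

    def transform(self, X=None):
        """Return the summary table as a pandas DataFrame (one row per
        group-direction).  ``X`` is ignored; present for pipeline duck
        typing."""
        self._check_fitted()
        return summaries_to_frame(self.summaries_)

    def fit_transform(self, X: Iterable[TTDRecord], y=None):
        return self.fit(X).transform()

    def summary_frame(self):
        return self.transform()

    def predictor_set(
        self,
        drug: str,
        relationship_class: RelationshipClass = RelationshipClass.EFFICACY,
    ) -> list[PredictorEntry]:
        """Informative molecules (prevalent positive/negative groups) for a
        drug."""
        self._check_fitted()
        return build_predictor_set(self.summaries_, drug, relationship_class)


class DrugRanker(BaseEstimator):
    """Match patient molecular profiles to summarized evidence and rank drugs.

    ``fit`` consumes the curated record table (delegating to
    :class:`EvidenceSummarizer`); ``rank`` produces a full
    :class:`~ttdrank.ranking.RankResult` for one profile and ``decision_function``
    returns overall scores for many profiles against one drug, which is the
    shape response-simulation and ROC analysis consume.

    Parameters are those of :class:`EvidenceSummarizer` plus the state-pair
    ``lexicon`` used to resolve concordance and the ``relationship_class``
    ranked (efficacy by default; synergism is never ranked at patient level).
    """

    def __init__(
        self,
        threshold: float = 0.5,
        confidence_level: float = 0.95,
        criterion: str = "ci_lower_bound",
        size_combination: str = "multiplicative",
        base_score: int = 6,
        alias_map: Mapping[str, str] | None = None,
        lexicon: StatePairLexicon | None = None,
        relationship_class: RelationshipClass = RelationshipClass.EFFICACY,
    ) -> None:
        self.threshold = threshold
        self.confidence_level = confidence_level
        self.criterion = criterion
        self.size_combination = size_combination
        self.base_score = base_score
        self.alias_map = alias_map
        self.lexicon = lexicon
        self.relationship_class = relationship_class

    def fit(self, X: Iterable[TTDRecord], y=None) -> "DrugRanker":
        summarizer = EvidenceSummarizer(
            threshold=self.threshold,
            confidence_level=self.confidence_level,
            criterion=self.criterion,
            size_combination=self.size_combination,
            base_score=self.base_score,
            alias_map=self.alias_map,
        ).fit(X)
        self.summarizer_ = summarizer
        self.summaries_ = summarizer.summaries_
        self.config_ = summarizer.config_
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "summaries_"):
            raise AttributeError("this DrugRanker is not fitted yet")

    def rank(
        self, profile: PatientProfile, drugs: Sequence[str] | None = None
    ) -> RankResult:
        """Rank drugs for one profile by descending overall score."""
        self._check_fitted()
        return rank_drugs(
            profile,
            self.summaries_,
            drugs,
            self.config_,
            self.lexicon,
            self.relationship_class,
        )

    def score_profile(self, profile: PatientProfile, drug: str) -> DrugScore:
        """Full scored verdict of one drug against one profile."""
        self._check_fitted()
        predictor_set = build_predictor_set(
            self.summaries_, drug, self.relationship_class
        )
        if not predictor_set:
            raise ValueError(f"no informative molecules for drug {drug!r}")
        evidence, excluded = signed_percentages(predictor_set, profile, self.lexicon)
        if not evidence:
            raise ValueError("no informative molecules")
        return overall_score(drug, evidence, self.config_, excluded)

    def decision_function(
        self, X: Sequence[PatientProfile], drug: str
    ) -> np.ndarray:
        """Overall score of ``drug`` for each profile in ``X``; NaN where no
        informative molecule is resolvable."""
        self._check_fitted()
        out = np.full(len(X), np.nan)
        for i, profile in enumerate(X):
            try:
                out[i] = self.score_profile(profile, drug).os
            except ValueError:
                pass
        return out

    def predict(self, X: Sequence[PatientProfile], drug: str) -> list[str]:
        """Sensitive/resistant/indeterminate classification per profile."""
        self._check_fitted()
        labels = []
        for profile in X:
            try:
                labels.append(self.score_profile(profile, drug).classification)
            except ValueError:
                labels.append("indeterminate")
        return labels
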