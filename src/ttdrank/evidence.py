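"""Evidence synthesis: scores, score percentages, Agresti-Coull intervals
and prevalent-hypothesis verdicts.

Each curated study carries an evidence score that rates its experimental
model: the seven model tiers form a doubling ladder starting at
``base_score`` (default 6) for the animal-in-vitro tier, so a randomized
controlled trial weighs ``6 * 2**5 = 192`` evidence-score units.  The score
is further adjusted by a size score ``n/10`` when the study's case count
``n`` is known.  Within a group of studies that address the same
(molecule, state, drug, relationship) hypothesis, the score percentage
``SP_i = ES_i / sum(ES)`` measures the fraction of the published evidence
supporting each direction (+1, -1, 0).

A direction is the *prevalent hypothesis* when its SP exceeds the decision
threshold (default 0.5) and the lower bound of the Agresti-Coull confidence
interval of that proportion stays above the threshold as well (default
criterion), or alternatively when a Z-test of the corrected proportion
against the threshold is significant.  Evidence scores enter the binomial
formulas as pseudo-counts; they need not be integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

from .schema import (
    Direction,
    ModelTier,
    RelationshipClass,
    TTDRecord,
    normalize_text,
)

__all__ = [
    "DIRECTIONS",
    "EvidenceGroupKey",
    "EvidenceSummary",
    "HypothesisTally",
    "PredictorEntry",
    "ProportionEstimate",
    "SummaryConfig",
    "agresti_coull_interval",
    "build_predictor_set",
    "determine_prevalent",
    "minimal_base_score",
    "model_score",
    "record_weight",
    "score_percentages",
    "size_score",
    "summaries_to_frame",
    "summarize_corpus",
    "tally_group",
    "z_test_proportion",
]

#: Hypothesis directions in reporting order.
DIRECTIONS = (Direction.POSITIVE, Direction.NEGATIVE, Direction.NULL)


@dataclass(frozen=True)
class SummaryConfig:
    """Tunable constants of the evidence-summary procedure.

    Parameters
    ----------
    confidence_level : float
        Two-sided confidence level of the Agresti-Coull interval
        (0.95 gives z = 1.959964).
    threshold : float
        Decision-rule value theta; a hypothesis must hold *more* than this
        fraction of the evidence score (strict inequality).
    criterion : {"ci_lower_bound", "z_test"}
        How the uncertainty of SP is confronted with the threshold:
        the lower CI bound must exceed theta, or a Z-test of the corrected
        proportion against theta must be significant at 1 - confidence_level.
    size_combination : {"multiplicative", "additive"}
        How the size score n/10 adjusts the model score:
        ``model * (1 + n/10)`` (default) or ``model + n/10``.
    base_score : int
        Evidence score of the lowest tier (animal in vitro).
    """

    confidence_level: float = 0.95
    threshold: float = 0.5
    criterion: str = "ci_lower_bound"
    size_combination: str = "multiplicative"
    base_score: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence_level < 1.0:
            raise ValueError("confidence_level must be in (0, 1)")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.criterion not in ("ci_lower_bound", "z_test"):
            raise ValueError(f"unknown criterion: {self.criterion!r}")
        if self.size_combination not in ("multiplicative", "additive"):
            raise ValueError(f"unknown size_combination: {self.size_combination!r}")
        if self.base_score < 1:
            raise ValueError("base_score must be >= 1")

    @property
    def z_value(self) -> float:
        """Standard-normal quantile for the two-sided confidence level."""
        return float(norm.ppf(0.5 + self.confidence_level / 2.0))

    @property
    def alpha(self) -> float:
        return 1.0 - self.confidence_level


@dataclass(frozen=True)
class EvidenceGroupKey:
    """Normalized identity of one evidence group.  Synergism groups are keyed
    additionally on the modifier compound."""

    molecule: str
    state: str
    drug: str
    relationship_class: RelationshipClass
    modifier: str | None = None

    def sort_key(self) -> tuple:
        return (
            self.molecule,
            self.state,
            self.drug,
            self.relationship_class.value,
            self.modifier or "",
        )


@dataclass
class HypothesisTally:
    """Per-direction evidence-score totals and record counts for one group."""

    es: dict[Direction, float]
    n_records: dict[Direction, int]

    @property
    def total(self) -> float:
        return sum(self.es.values())


@dataclass
class ProportionEstimate:
    """Score percentage of one direction with its Agresti-Coull correction.

    ``sp`` is the raw proportion ES_i / sum(ES); ``sp_corrected`` the
    add-z^2 corrected proportion; the CI is clipped to [0, 1].  ``z`` and
    ``p`` are filled by the threshold test.
    """

    sp: float
    sp_corrected: float
    se: float
    ci_low: float
    ci_high: float
    z: float | None = None
    p: float | None = None

    @property
    def variance(self) -> float:
        """V = SPc * (1 - SPc), the variance measure used as inverse-variance
        weight in profile ranking."""
        return self.sp_corrected * (1.0 - self.sp_corrected)


@dataclass
class EvidenceSummary:
    """Verdict for one evidence group: tallies, per-direction estimates and
    the prevalent hypothesis ('positive', 'negative', 'null' or
    'undetermined')."""

    key: EvidenceGroupKey
    tally: HypothesisTally
    estimates: dict[Direction, ProportionEstimate]
    prevalent: str
    config_used: SummaryConfig
    flags: list[str] = field(default_factory=list)


_PREVALENT_NAME = {
    Direction.POSITIVE: "positive",
    Direction.NEGATIVE: "negative",
    Direction.NULL: "null",
}


def model_score(tier: ModelTier, config: SummaryConfig = SummaryConfig()) -> float:
    """Evidence score of a model tier: base_score doubled per tier step."""
    return float(config.base_score * 2 ** int(tier))


def size_score(cases: int | None) -> float:
    """Size score n/10; an absent case count contributes nothing."""
    if cases is None:
        return 0.0
    if cases < 0:
        raise ValueError("cases must be >= 0")
    return cases / 10.0


def record_weight(record: TTDRecord, config: SummaryConfig = SummaryConfig()) -> float:
    """Evidence score of one record: model score adjusted by the size score.

    Multiplicative mode scales the tier score by ``1 + n/10`` so an unknown
    case count leaves the ladder value untouched; additive mode adds ``n/10``.
    """
    ms = model_score(record.model, config)
    ss = size_score(record.cases)
    if config.size_combination == "multiplicative":
        return ms * (1.0 + ss)
    return ms + ss


def tally_group(
    records: Sequence[TTDRecord], config: SummaryConfig = SummaryConfig()
) -> HypothesisTally:
    """Sum record weights per hypothesis direction for one evidence group."""
    if not records:
        raise ValueError("cannot tally an empty record group")
    es = {d: 0.0 for d in DIRECTIONS}
    n = {d: 0 for d in DIRECTIONS}
    for rec in records:
        d = Direction(rec.hypothesis)
        es[d] += record_weight(rec, config)
        n[d] += 1
    return HypothesisTally(es=es, n_records=n)


def score_percentages(tally: HypothesisTally) -> dict[Direction, float]:
    """SP_i = ES_i / sum(ES); raises on a zero-total (undetermined) group."""
    total = tally.total
    if total <= 0:
        raise ValueError("undetermined group: total evidence score is zero")
    return {d: tally.es[d] / total for d in DIRECTIONS}


def agresti_coull_interval(
    es_i: float, es_total: float, confidence_level: float = 0.95
) -> ProportionEstimate:
    """Agresti-Coull interval for the proportion es_i / es_total.

    Evidence scores play the role of binomial pseudo-counts (es_i the
    successes, es_total the trials); non-integer values are allowed.  The
    corrected proportion is ``(es_i + z^2/2) / (es_total + z^2)``, its
    standard error ``sqrt(p~ (1 - p~) / n~)``, and the interval
    ``p~ +/- z * se`` clipped to [0, 1].
    """
    if es_total <= 0:
        raise ValueError("total evidence score must be positive")
    if not 0 <= es_i <= es_total:
        raise ValueError("es_i must lie in [0, es_total]")
    z = float(norm.ppf(0.5 + confidence_level / 2.0))
    n_tilde = es_total + z * z
    p_tilde = (es_i + z * z / 2.0) / n_tilde
    se = math.sqrt(p_tilde * (1.0 - p_tilde) / n_tilde)
    return ProportionEstimate(
        sp=es_i / es_total,
        sp_corrected=p_tilde,
        se=se,
        ci_low=max(0.0, p_tilde - z * se),
        ci_high=min(1.0, p_tilde + z * se),
    )


def z_test_proportion(
    estimate: ProportionEstimate, threshold: float = 0.5
) -> tuple[float, float]:
    """Z-test of the corrected score percentage against the decision rule:
    ``Z = (SPc - theta) / SE`` with two-tailed ``p = 2 (1 - Phi(|Z|))``."""
    if estimate.se <= 0:
        raise ValueError("standard error must be positive for the Z-test")
    z = (estimate.sp_corrected - threshold) / estimate.se
    p = 2.0 * (1.0 - float(norm.cdf(abs(z))))
    return z, p


def _qualifies(sp: float, est: ProportionEstimate, config: SummaryConfig) -> bool:
    # strict inequalities: a tie at exactly theta fails ("more than 50%")
    if sp <= config.threshold:
        return False
    if config.criterion == "ci_lower_bound":
        return est.ci_low > config.threshold
    z, p = z_test_proportion(est, config.threshold)
    return z > 0 and p < config.alpha


def determine_prevalent(
    tally: HypothesisTally,
    config: SummaryConfig = SummaryConfig(),
    key: EvidenceGroupKey | None = None,
) -> EvidenceSummary:
    """Apply the decision rule to a tally and return the full summary.

    With ``threshold >= 0.5`` at most one direction can qualify, since the
    score percentages sum to one.
    """
    if key is None:
        key = EvidenceGroupKey("", "", "", RelationshipClass.EFFICACY)
    flags: list[str] = []
    if tally.total <= 0:
        return EvidenceSummary(
            key=key,
            tally=tally,
            estimates={},
            prevalent="undetermined",
            config_used=config,
            flags=["zero total evidence score"],
        )
    sps = score_percentages(tally)
    estimates: dict[Direction, ProportionEstimate] = {}
    prevalent = "undetermined"
    for d in DIRECTIONS:
        est = agresti_coull_interval(tally.es[d], tally.total, config.confidence_level)
        est.z, est.p = z_test_proportion(est, config.threshold)
        estimates[d] = est
        if _qualifies(sps[d], est, config):
            if prevalent != "undetermined":  # pragma: no cover - theta < 0.5 only
                flags.append("multiple qualifying directions")
            prevalent = _PREVALENT_NAME[d]
    return EvidenceSummary(
        key=key,
        tally=tally,
        estimates=estimates,
        prevalent=prevalent,
        config_used=config,
        flags=flags,
    )


def _group_key(rec: TTDRecord, alias_map: Mapping[str, str] | None) -> EvidenceGroupKey:
    molecule = normalize_text(rec.molecule)
    if alias_map:
        molecule = alias_map.get(molecule, molecule)
    return EvidenceGroupKey(
        molecule=molecule,
        state=normalize_text(rec.state),
        drug=normalize_text(rec.drug),
        relationship_class=rec.relationship_class,
        modifier=(
            normalize_text(rec.modifier or "")
            if rec.relationship_class is RelationshipClass.SYNERGISM
            else None
        ),
    )


def summarize_corpus(
    records: Iterable[TTDRecord],
    config: SummaryConfig = SummaryConfig(),
    alias_map: Mapping[str, str] | None = None,
) -> list[EvidenceSummary]:
    """Group records by (molecule, state, drug, relationship[, modifier]) and
    apply tally -> SP -> CI -> verdict to each group.

    ``alias_map`` optionally merges molecule synonyms (normalized alias ->
    normalized canonical name) before grouping.  Output is sorted by group
    key, so the result is invariant to input row order.
    """
    groups: dict[EvidenceGroupKey, list[TTDRecord]] = {}
    for rec in records:
        groups.setdefault(_group_key(rec, alias_map), []).append(rec)
    return [
        determine_prevalent(tally_group(recs, config), config, key=key)
        for key, recs in sorted(groups.items(), key=lambda kv: kv[0].sort_key())
    ]


@dataclass(frozen=True)
class PredictorEntry:
    """One informative molecule for a drug: its state, prevalent direction
    and the proportion estimate of that direction."""

    molecule: str
    state: str
    direction: Direction
    estimate: ProportionEstimate
    modifier: str | None = None


def build_predictor_set(
    summaries: Iterable[EvidenceSummary],
    drug: str,
    relationship_class: RelationshipClass = RelationshipClass.EFFICACY,
) -> list[PredictorEntry]:
    """Molecules informative for predicting response to ``drug``.

    Groups whose prevalent hypothesis is positive or negative are included;
    null verdicts (the molecule does not modulate the drug) and undetermined
    groups (not enough evidence) are eliminated.
    """
    drug_norm = normalize_text(drug)
    out: list[PredictorEntry] = []
    for s in summaries:
        if s.key.drug != drug_norm or s.key.relationship_class is not relationship_class:
            continue
        if s.prevalent == "positive":
            d = Direction.POSITIVE
        elif s.prevalent == "negative":
            d = Direction.NEGATIVE
        else:
            continue
        out.append(
            PredictorEntry(
                molecule=s.key.molecule,
                state=s.key.state,
                direction=d,
                estimate=s.estimates[d],
                modifier=s.key.modifier,
            )
        )
    return out


def minimal_base_score(
    confidence_level: float = 0.95,
    threshold: float = 0.5,
    criterion: str = "ci_lower_bound",
    max_scan: int = 10_000,
) -> int:
    """Smallest integer base score at which a *single* lowest-tier study
    already yields a prevalent verdict.

    This audits the choice of the default base score: the scan is a linear
    search over b = 1, 2, ... where the whole evidence score b sits on one
    direction.  Besides the two summary criteria, ``criterion="z_test_null"``
    evaluates the Z-test with the null-hypothesis standard error
    ``sqrt(theta (1 - theta) / n~)`` for comparison.
    """
    if criterion not in ("ci_lower_bound", "z_test", "z_test_null"):
        raise ValueError(f"unknown criterion: {criterion!r}")
    z = float(norm.ppf(0.5 + confidence_level / 2.0))
    alpha = 1.0 - confidence_level
    for b in range(1, max_scan + 1):
        est = agresti_coull_interval(float(b), float(b), confidence_level)
        if criterion == "ci_lower_bound":
            ok = est.ci_low > threshold
        elif criterion == "z_test":
            zstat, p = z_test_proportion(est, threshold)
            ok = zstat > 0 and p < alpha
        else:
            se0 = math.sqrt(threshold * (1.0 - threshold) / (b + z * z))
            zstat = (est.sp_corrected - threshold) / se0
            ok = zstat > 0 and 2.0 * (1.0 - float(norm.cdf(abs(zstat)))) < alpha
        if ok:
            return b
    raise RuntimeError(f"no qualifying base score found up to {max_scan}")


def summaries_to_frame(summaries: Sequence[EvidenceSummary]):
    """Flatten summaries to a pandas DataFrame, one row per group-direction."""
    import pandas as pd

    rows = []
    for s in summaries:
        for d in DIRECTIONS:
            est = s.estimates.get(d)
            rows.append(
                {
                    "molecule": s.key.molecule,
                    "state": s.key.state,
                    "drug": s.key.drug,
                    "relationship": s.key.relationship_class.value,
                    "modifier": s.key.modifier or "",
                    "direction": int(d),
                    "n_records": s.tally.n_records.get(d, 0),
                    "es": s.tally.es.get(d, 0.0),
                    "sp": est.sp if est else float("nan"),
                    "sp_corrected": est.sp_corrected if est else float("nan"),
                    "se": est.se if est else float("nan"),
                    "ci_low": est.ci_low if est else float("nan"),
                    "ci_high": est.ci_high if est else float("nan"),
                    "z": est.z if est else float("nan"),
                    "p": est.p if est else float("nan"),
                    "prevalent": s.prevalent,
                    "flags": "; ".join(s.flags),
                }
            )
    return pd.DataFrame(rows)
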