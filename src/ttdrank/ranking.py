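"""Patient-profile matching and inverse-variance drug ranking.

Given the informative molecules for a drug (prevalent positive/negative
evidence groups), each molecule's score percentage receives a sign: ``+``
when the prevalent evidence favours treatment benefit (sensitivity,
synergism, decreased toxicity), ``-`` when it favours resistance,
antagonism or increased toxicity.  The sign is flipped when the patient
carries the *opposite* molecular state to the literature state (as declared
by a state-pair lexicon, e.g. "mut V600E" <-> "wt"); a patient state that is
neither the literature state nor its declared opposite is unresolvable and
excluded with a reason, never imputed.

The overall score for a drug is the inverse-variance weighted mean of the
signed score percentages, ``OS = sum(W_i SP_i) / sum(W_i)`` with
``W_i = 1 / V_i`` and ``V_i = SPc (1 - SPc)``; its variance is
``OV = 1 / sum(W_i)``.  An OS beyond +/- theta whose confidence interval
does not cross the threshold classifies the profile as sensitive or
resistant; anything else is indeterminate.  Two drugs are compared with
``Z = (OS_a - OS_b) / sqrt(OV_a + OV_b)``.

All outputs are hypothesis-generating research summaries of published
evidence; they are not clinical recommendations.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

from .evidence import (
    EvidenceSummary,
    PredictorEntry,
    SummaryConfig,
    build_predictor_set,
)
from .schema import Direction, RelationshipClass, normalize_text

__all__ = [
    "DrugScore",
    "PatientProfile",
    "PatientProfileEntry",
    "RankResult",
    "SignedEvidence",
    "StatePairLexicon",
    "compare_drugs",
    "overall_score",
    "rank_drugs",
    "resolve_concordance",
    "signed_percentages",
]

RESEARCH_USE_DISCLAIMER = (
    "Research use only: these scores summarize published evidence to generate "
    "hypotheses; they must not be used for clinical decision making."
)


class StatePairLexicon:
    """Symmetric map of opposite molecular states per molecule.

    Declaring ``("BRAF", "mut V600E", "wt")`` makes each state the opposite
    of the other; a state has at most one declared opposite.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, str]] = ()) -> None:
        self._opposite: dict[tuple[str, str], str] = {}
        for molecule, state_a, state_b in pairs:
            self.add(molecule, state_a, state_b)

    def add(self, molecule: str, state_a: str, state_b: str) -> None:
        mol = normalize_text(molecule)
        a, b = normalize_text(state_a), normalize_text(state_b)
        if a == b:
            raise ValueError("a state cannot be its own opposite")
        for s, o in ((a, b), (b, a)):
            existing = self._opposite.get((mol, s))
            if existing is not None and existing != o:
                raise ValueError(
                    f"state {s!r} of {mol!r} already has opposite {existing!r}"
                )
            self._opposite[(mol, s)] = o

    def opposite(self, molecule: str, state: str) -> str | None:
        return self._opposite.get((normalize_text(molecule), normalize_text(state)))

    def __len__(self) -> int:
        return len(self._opposite) // 2

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StatePairLexicon):
            return NotImplemented
        return self._opposite == other._opposite

    @classmethod
    def from_csv(cls, path) -> "StatePairLexicon":
        """Read a lexicon from CSV with columns Molecule, StateA, StateB."""
        lex = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                lex.add(row["Molecule"], row["StateA"], row["StateB"])
        return lex


@dataclass(frozen=True)
class PatientProfileEntry:
    """One molecular assay result: the observed state of one molecule."""

    molecule: str
    observed_state: str
    assay_note: str = ""

    def __post_init__(self) -> None:
        if not self.molecule.strip() or not self.observed_state.strip():
            raise ValueError("molecule and observed_state must be non-empty")


@dataclass
class PatientProfile:
    """A set of (molecule, observed state) assertions for one patient."""

    entries: list[PatientProfileEntry] = field(default_factory=list)
    patient_id: str = ""

    def lookup(self, molecule: str) -> PatientProfileEntry | None:
        mol = normalize_text(molecule)
        for e in self.entries:
            if normalize_text(e.molecule) == mol:
                return e
        return None

    @classmethod
    def from_csv(cls, path, patient_id: str = "") -> "PatientProfile":
        """Read a profile from CSV with columns Molecule, ObservedState
        (optional AssayNote)."""
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    PatientProfileEntry(
                        molecule=row["Molecule"],
                        observed_state=row["ObservedState"],
                        assay_note=row.get("AssayNote", "") or "",
                    )
                )
        return cls(entries=entries, patient_id=patient_id)


@dataclass
class SignedEvidence:
    """One informative molecule's signed contribution to a drug's score."""

    molecule: str
    state: str
    sp_signed: float
    variance: float
    weight: float
    concordance: str  # "concordant" | "discordant"


@dataclass
class DrugScore:
    """Signed overall score for one drug against one patient profile."""

    drug: str
    os: float
    ov: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    classification: str  # "sensitive" | "resistant" | "indeterminate"
    n_informative: int
    contributions: list[SignedEvidence] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class RankResult:
    """Drugs ranked by descending overall score, with the pairwise Z-test
    matrix; drugs without informative molecules are listed unranked."""

    scores: list[DrugScore]
    pairwise: dict[tuple[str, str], tuple[float, float]]
    unranked: list[tuple[str, str]] = field(default_factory=list)
    disclaimer: str = RESEARCH_USE_DISCLAIMER


def resolve_concordance(
    entry: PatientProfileEntry,
    literature_state: str,
    lexicon: StatePairLexicon | None = None,
) -> str:
    """Concordance of an observed patient state with a literature state.

    'concordant' when they match (sign kept), 'discordant' when the observed
    state is the lexicon-declared opposite (sign flipped), 'unresolvable'
    otherwise.
    """
    observed = normalize_text(entry.observed_state)
    literature = normalize_text(literature_state)
    if observed == literature:
        return "concordant"
    if lexicon is not None and lexicon.opposite(entry.molecule, literature_state) == observed:
        return "discordant"
    return "unresolvable"


def signed_percentages(
    predictor_set: Sequence[PredictorEntry],
    profile: PatientProfile,
    lexicon: StatePairLexicon | None = None,
) -> tuple[list[SignedEvidence], list[tuple[str, str]]]:
    """Assign signs to the predictor SPs for one drug against one profile.

    The initial sign comes from the prevalent direction (+ for positive, -
    for negative); it is flipped when the patient's state is discordant.
    Untested and unresolvable molecules are excluded with a reason.
    """
    evidence: list[SignedEvidence] = []
    excluded: list[tuple[str, str]] = []
    for pred in predictor_set:
        entry = profile.lookup(pred.molecule)
        if entry is None:
            excluded.append((pred.molecule, "untested"))
            continue
        concordance = resolve_concordance(entry, pred.state, lexicon)
        if concordance == "unresolvable":
            excluded.append(
                (
                    pred.molecule,
                    f"unresolvable state {entry.observed_state!r} vs "
                    f"literature {pred.state!r}",
                )
            )
            continue
        sign = 1.0 if pred.direction is Direction.POSITIVE else -1.0
        if concordance == "discordant":
            sign = -sign
        variance = pred.estimate.variance
        evidence.append(
            SignedEvidence(
                molecule=pred.molecule,
                state=pred.state,
                sp_signed=sign * pred.estimate.sp,
                variance=variance,
                weight=1.0 / variance,
                concordance=concordance,
            )
        )
    return evidence, excluded


def overall_score(
    drug: str,
    evidence: Sequence[SignedEvidence],
    config: SummaryConfig = SummaryConfig(),
    excluded: Sequence[tuple[str, str]] = (),
) -> DrugScore:
    """Inverse-variance pooled overall score for one drug.

    The Z-test compares |OS| with the threshold (the decision rule is
    symmetric for sensitivity and resistance); classification additionally
    requires the CI bound nearer zero to stay beyond sign(OS) * theta.
    """
    if not evidence:
        raise ValueError("no informative molecules")
    sum_w = sum(e.weight for e in evidence)
    os_value = sum(e.weight * e.sp_signed for e in evidence) / sum_w
    ov = 1.0 / sum_w
    se = math.sqrt(ov)
    zq = config.z_value
    ci_low = max(-1.0, os_value - zq * se)
    ci_high = min(1.0, os_value + zq * se)
    z = (abs(os_value) - config.threshold) / se
    p = 2.0 * (1.0 - float(norm.cdf(abs(z))))
    theta = config.threshold
    if os_value > theta and ci_low > theta:
        classification = "sensitive"
    elif os_value < -theta and ci_high < -theta:
        classification = "resistant"
    else:
        classification = "indeterminate"
    return DrugScore(
        drug=drug,
        os=os_value,
        ov=ov,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        z=z,
        p=p,
        classification=classification,
        n_informative=len(evidence),
        contributions=list(evidence),
        excluded=list(excluded),
    )


def compare_drugs(a: DrugScore, b: DrugScore) -> tuple[float, float]:
    """Z-test between two overall scores for the same profile:
    ``Z = (OS_a - OS_b) / sqrt(OV_a + OV_b)``, two-tailed p."""
    denom = a.ov + b.ov
    if denom <= 0:
        raise ValueError("sum of overall variances must be positive")
    z = (a.os - b.os) / math.sqrt(denom)
    p = 2.0 * (1.0 - float(norm.cdf(abs(z))))
    return z, p


def rank_drugs(
    profile: PatientProfile,
    summaries: Iterable[EvidenceSummary],
    drugs: Sequence[str] | None = None,
    config: SummaryConfig = SummaryConfig(),
    lexicon: StatePairLexicon | None = None,
    relationship_class: RelationshipClass = RelationshipClass.EFFICACY,
) -> RankResult:
    """Score every requested drug against the profile and rank by OS.

    ``drugs=None`` ranks every drug present in the summaries.  Drugs whose
    predictor set is empty or fully excluded are reported unranked.  By
    default only efficacy evidence enters the rank; toxicity ranking uses
    the same machinery with ``relationship_class=RelationshipClass.TOXICITY``
    (synergism concerns drug pairs and is excluded from patient-level
    ranking).
    """
    summaries = list(summaries)
    if drugs is None:
        drugs = sorted(
            {s.key.drug for s in summaries if s.key.relationship_class is relationship_class}
        )
    scores: list[DrugScore] = []
    unranked: list[tuple[str, str]] = []
    for drug in drugs:
        predictor_set = build_predictor_set(summaries, drug, relationship_class)
        if not predictor_set:
            unranked.append((drug, "no informative molecules in the evidence"))
            continue
        evidence, excluded = signed_percentages(predictor_set, profile, lexicon)
        if not evidence:
            unranked.append((drug, "no informative molecule resolvable in the profile"))
            continue
        scores.append(overall_score(drug, evidence, config, excluded))
    scores.sort(key=lambda s: (-s.os, s.drug))
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for a in scores:
        for b in scores:
            if a.drug == b.drug:
                pairwise[(a.drug, b.drug)] = (0.0, 1.0)
            else:
                pairwise[(a.drug, b.drug)] = compare_drugs(a, b)
    return RankResult(scores=scores, pairwise=pairwise, unranked=unranked)


def rank_to_frame(result: RankResult):
    """Flatten a RankResult to a pandas DataFrame, one row per ranked drug."""
    import pandas as pd

    rows = [
        {
            "rank": i + 1,
            "drug": s.drug,
            "os": s.os,
            "ov": s.ov,
            "se": s.se,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
            "z": s.z,
            "p": s.p,
            "classification": s.classification,
            "n_informative": s.n_informative,
            "n_excluded": len(s.excluded),
        }
        for i, s in enumerate(result.scores)
    ]
    return pd.DataFrame(rows)
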