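"""Synthetic curated-literature corpora, patient profiles and simulated
treatment outcomes with known ground truth.

No public corpus ships with the package: every study of the pipeline's
operating characteristics runs on generated data.  A :class:`TruthTable`
fixes, per (molecule, state, drug, relationship) group, the *true*
hypothesis direction and the probability ``support_prob`` that a generated
study's conclusion agrees with it; disagreeing studies split evenly between
the two other directions.  Model tiers are drawn from a configurable mix
and clinical-tier studies receive case counts.  A single integer seed feeds
named substreams (corpus / profiles / responses) so each stage is
independently reproducible.

The generator emulates the record-level structure of a curated table
(keys, hypothesis labels, tiers, counts); it makes no attempt to imitate
real literature text or publication-bias structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ranking import PatientProfile, PatientProfileEntry, StatePairLexicon
from .schema import Direction, ModelTier, RelationshipClass, TTDRecord

__all__ = [
    "CorpusConfig",
    "ResponseSimConfig",
    "TruthEntry",
    "TruthTable",
    "default_truth_table",
    "generate_corpus",
    "generate_profiles",
    "simulate_responses",
    "truth_lexicon",
]

# named substreams derived from the one user-facing seed
_STREAM_CORPUS = 101
_STREAM_PROFILES = 202
_STREAM_RESPONSES = 303

#: Default tier mix, weighted toward preclinical literature the way curated
#: oncology corpora are: human-in-vitro studies dominate, meta-analyses are
#: rare.  Order follows the seven tiers.
DEFAULT_TIER_MIX = (0.10, 0.08, 0.40, 0.12, 0.22, 0.06, 0.02)

_OTHER_DIRECTIONS = {
    Direction.POSITIVE: (Direction.NEGATIVE, Direction.NULL),
    Direction.NEGATIVE: (Direction.POSITIVE, Direction.NULL),
    Direction.NULL: (Direction.POSITIVE, Direction.NEGATIVE),
}


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one evidence group."""

    molecule: str
    state: str
    drug: str
    true_direction: Direction
    support_prob: float = 0.8
    relationship_class: RelationshipClass = RelationshipClass.EFFICACY
    modifier: str | None = None
    #: how disagreeing studies split between the two non-true directions
    disagree_split: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.support_prob <= 1.0:
            raise ValueError("support_prob must be in [0, 1]")
        if abs(sum(self.disagree_split) - 1.0) > 1e-12:
            raise ValueError("disagree_split fractions must sum to 1")


@dataclass
class TruthTable:
    entries: list[TruthEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def default_truth_table(
    n_molecules: int = 4,
    drugs: Sequence[str] = ("DRUG_A", "DRUG_B"),
    support_prob: float = 0.8,
    direction_cycle: Sequence[Direction] = (
        Direction.POSITIVE,
        Direction.NEGATIVE,
        Direction.POSITIVE,
        Direction.NULL,
    ),
) -> TruthTable:
    """A small readable truth table: molecules MOL001.. with a mutant state,
    true directions cycling through the given pattern per (molecule, drug)."""
    entries = []
    i = 0
    for m in range(n_molecules):
        for drug in drugs:
            entries.append(
                TruthEntry(
                    molecule=f"MOL{m + 1:03d}",
                    state=f"mut M{m + 1}",
                    drug=drug,
                    true_direction=direction_cycle[i % len(direction_cycle)],
                    support_prob=support_prob,
                )
            )
            i += 1
    return TruthTable(entries)


def truth_lexicon(truth: TruthTable) -> StatePairLexicon:
    """Lexicon pairing each literature state in the truth table with the
    wild-type state ``"wt"``."""
    lex = StatePairLexicon()
    seen = set()
    for e in truth:
        key = (e.molecule, e.state)
        if key not in seen:
            lex.add(e.molecule, e.state, "wt")
            seen.add(key)
    return lex


@dataclass
class CorpusConfig:
    """Generative specification for one synthetic corpus.

    ``studies_per_group`` is either a fixed integer or a callable
    ``rng -> int``; ``cases_distribution`` draws case counts for clinical
    tiers (default DiscreteUniform(50, 500)); preclinical records carry no
    case count, matching curated-table practice.
    """

    truth: TruthTable
    studies_per_group: int = 10
    tier_mix: Sequence[float] = DEFAULT_TIER_MIX
    cases_low: int = 50
    cases_high: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.tier_mix, dtype=float)
        if mix.shape != (7,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("tier_mix must be 7 non-negative probabilities summing to 1")
        if not callable(self.studies_per_group) and self.studies_per_group < 0:
            raise ValueError("studies_per_group must be >= 0")


@dataclass
class ResponseSimConfig:
    """Binary response model: P(response) = logistic(intercept + slope * OS)."""

    link_intercept: float = 0.0
    link_slope: float = 3.0
    n_patients: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def _draw_direction(entry: TruthEntry, rng: np.random.Generator) -> Direction:
    u = rng.random()
    if u < entry.support_prob:
        return entry.true_direction
    other = _OTHER_DIRECTIONS[entry.true_direction]
    frac = entry.disagree_split[0]
    rest = (u - entry.support_prob) / max(1.0 - entry.support_prob, 1e-300)
    return other[0] if rest < frac else other[1]


def generate_corpus(config: CorpusConfig) -> list[TTDRecord]:
    """Generate a TTD-format record list realizing the truth table.

    Records satisfy all schema invariants (H matches the relationship
    direction, cases only on clinical tiers, synergism rows carry their
    modifier); an identical seed yields an identical corpus.
    """
    rng = np.random.default_rng([config.seed, _STREAM_CORPUS])
    tiers = [ModelTier(i) for i in range(7)]
    mix = np.asarray(config.tier_mix, dtype=float)
    records: list[TTDRecord] = []
    next_id = 1
    for entry in config.truth:
        n_studies = (
            config.studies_per_group(rng)
            if callable(config.studies_per_group)
            else config.studies_per_group
        )
        for _ in range(n_studies):
            direction = _draw_direction(entry, rng)
            tier = tiers[int(rng.choice(7, p=mix))]
            cases = (
                int(rng.integers(config.cases_low, config.cases_high + 1))
                if tier.is_clinical
                else None
            )
            records.append(
                TTDRecord(
                    id=next_id,
                    source="melanoma specimen",
                    molecule=entry.molecule,
                    state=entry.state,
                    modifier=entry.modifier
                    or (
                        "MODIFIER_X"
                        if entry.relationship_class is RelationshipClass.SYNERGISM
                        else None
                    ),
                    relationship_class=entry.relationship_class,
                    direction=direction,
                    drug=entry.drug,
                    model=tier,
                    hypothesis=int(direction),
                    cases=cases,
                    reference=f"SYNTH-{next_id:05d}",
                    notes="synthetic record",
                )
            )
            next_id += 1
    return records


def generate_profiles(
    pairs: Sequence[tuple[str, str]],
    match_prob: float,
    n: int,
    seed: int = 0,
    lexicon: StatePairLexicon | None = None,
) -> list[PatientProfile]:
    """Generate ``n`` patient profiles over the given (molecule, literature
    state) pairs.

    Each entry takes the literature state with probability ``match_prob``
    and otherwise the lexicon-declared opposite state (``"wt"`` when no
    lexicon is supplied).
    """
    if not 0.0 <= match_prob <= 1.0:
        raise ValueError("match_prob must be in [0, 1]")
    rng = np.random.default_rng([seed, _STREAM_PROFILES])
    profiles = []
    for i in range(n):
        entries = []
        for molecule, state in pairs:
            if rng.random() < match_prob:
                observed = state
            else:
                observed = (lexicon.opposite(molecule, state) if lexicon else None) or "wt"
            entries.append(PatientProfileEntry(molecule=molecule, observed_state=observed))
        profiles.append(PatientProfile(entries=entries, patient_id=f"P{i + 1:04d}"))
    return profiles


def simulate_responses(
    os_values: Sequence[float], config: ResponseSimConfig
) -> np.ndarray:
    """Draw binary treatment responses from the logistic link on the overall
    score; one outcome per profile OS."""
    os_arr = np.asarray(os_values, dtype=float)
    rng = np.random.default_rng([config.seed, _STREAM_RESPONSES])
    prob = 1.0 / (1.0 + np.exp(-(config.link_intercept + config.link_slope * os_arr)))
    return (rng.random(os_arr.shape) < prob).astype(int)
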