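"""The majority-voting antigen predictor (three-member ensemble).

The deployed bacterial immunogenicity predictor trains the three best
families — random-subspace 1-NN, gradient boosting, and random forest with
feature selection — on the full labeled set and classifies a new protein by
majority voting: each member casts a binary vote, and a protein is a
"probable antigen" when at least two of three vote positive.  The reported
probability is the vote fraction (0, 1/3, 2/3 or 1), displayed as a whole
percentage (0/33/67/100).  With three voters no tie is possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np

from .data import LabeledDataset, ProteinRecord
from .encoding import (DescriptorTable, EncodingError, SequenceLengthError,
                       acc_transform, build_feature_matrix,
                       default_descriptor_table, encode_sequence, ordering_tag)
from .models import (FeatureContractError, ModelConfig, TrainedModel,
                     predict_scores, train_model)

__all__ = [
    "BUNDLE_MEMBERS",
    "VotingResult",
    "VaxiJenBundle",
    "fit_vaxijen_predictor",
    "tally_votes",
    "majority_vote",
    "predict_batch",
    "save_bundle",
    "load_bundle",
]

#: The three member families, in vote order; seeds fan out as seed, seed+1, seed+2.
BUNDLE_MEMBERS = ("rsm_knn", "xgboost", "rf")


@dataclass
class VotingResult:
    """Majority-vote outcome for one protein."""

    record_id: str
    per_model_votes: dict[str, int]
    positive_votes: int
    probability: float
    verdict: str
    mean_score: float  # diagnostic: mean member score, not used for the verdict

    @property
    def probability_percent(self) -> int:
        """Display rounding of the vote fraction to a whole percent."""
        return round(self.probability * 100)


@dataclass
class VaxiJenBundle:
    """Three trained member models plus the encoding context they expect."""

    members: dict[str, TrainedModel]
    table: DescriptorTable
    lag_max: int
    feature_ordering_tag: str
    metadata_json: str

    def __post_init__(self) -> None:
        if tuple(self.members) != BUNDLE_MEMBERS:
            raise ValueError(f"bundle must contain exactly the members {BUNDLE_MEMBERS}")
        for name, model in self.members.items():
            if model.feature_ordering_tag != self.feature_ordering_tag:
                raise FeatureContractError(
                    f"member {name} ordering tag {model.feature_ordering_tag!r} "
                    f"does not match bundle tag {self.feature_ordering_tag!r}")


def fit_vaxijen_predictor(dataset: LabeledDataset, seed: int = 0,
                          table: DescriptorTable | None = None,
                          lag_max: int = 8) -> VaxiJenBundle:
    """Train the three-member bundle on the full labeled dataset.

    Members use their default configurations (random forest with feature
    selection on); member seeds are seed, seed+1, seed+2 in vote order.  Any
    member's training failure aborts the whole bundle.
    """
    table = table or default_descriptor_table()
    expected_tag = ordering_tag(table, lag_max)
    if dataset.feature_ordering_tag != expected_tag:
        raise FeatureContractError(
            f"dataset ordering tag {dataset.feature_ordering_tag!r} does not match "
            f"the bundle's encoding context {expected_tag!r}")

    members: dict[str, TrainedModel] = {}
    for offset, algorithm in enumerate(BUNDLE_MEMBERS):
        config = ModelConfig(algorithm=algorithm, seed=seed + offset)
        members[algorithm] = train_model(config, dataset)

    metadata = {
        "members": {name: model.metadata() for name, model in members.items()},
        "lag_max": lag_max,
        "table_name": table.name,
        "feature_ordering_tag": expected_tag,
        "seed": seed,
    }
    return VaxiJenBundle(
        members=members,
        table=table,
        lag_max=lag_max,
        feature_ordering_tag=expected_tag,
        metadata_json=json.dumps(metadata, sort_keys=True),
    )


def _vote_matrix(bundle: VaxiJenBundle, features: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """(records x members) vote and score matrices, members in vote order."""
    votes = np.empty((features.shape[0], len(BUNDLE_MEMBERS)), dtype=int)
    scores = np.empty_like(votes, dtype=float)
    for col, name in enumerate(BUNDLE_MEMBERS):
        member_scores, member_labels = predict_scores(bundle.members[name], features)
        votes[:, col] = member_labels
        scores[:, col] = member_scores
    return votes, scores


def tally_votes(record_id: str, votes: np.ndarray | list[int],
                scores: np.ndarray | list[float]) -> VotingResult:
    """Turn the three member votes (in :data:`BUNDLE_MEMBERS` order) into a result.

    The verdict is "probable antigen" iff at least two votes are positive;
    the probability is the vote fraction (0, 1/3, 2/3 or 1).
    """
    votes = np.asarray(votes, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if votes.shape != (len(BUNDLE_MEMBERS),):
        raise ValueError(f"expected {len(BUNDLE_MEMBERS)} member votes")
    if not np.isin(votes, (0, 1)).all():
        raise ValueError("votes must be binary")
    positive = int(votes.sum())
    return VotingResult(
        record_id=record_id,
        per_model_votes={name: int(v) for name, v in zip(BUNDLE_MEMBERS, votes)},
        positive_votes=positive,
        probability=positive / 3.0,
        verdict="probable antigen" if positive >= 2 else "probable non-antigen",
        mean_score=float(scores.mean()),
    )


def majority_vote(bundle: VaxiJenBundle, features: np.ndarray,
                  record_id: str = "") -> VotingResult:
    """Classify one ACC feature vector by majority voting of the members."""
    row = np.asarray(features, dtype=float).reshape(1, -1)
    votes, scores = _vote_matrix(bundle, row)
    return tally_votes(record_id, votes[0], scores[0])


def predict_batch(bundle: VaxiJenBundle, records: list[ProteinRecord],
                  policy: str = "strict",
                  ) -> tuple[list[VotingResult], list[tuple[str, str]]]:
    """Majority-vote every admissible record; report the rest with reasons.

    Records failing encoding (non-standard residues under strict policy) or
    the minimum-length rule are returned in the skip report, never silently
    scored or dropped; result order follows input order.  An input with no
    admissible record at all is an error.
    """
    admissible: list[ProteinRecord] = []
    skipped: list[tuple[str, str]] = []
    for rec in records:
        try:
            encoded = encode_sequence(rec.sequence, bundle.table, policy)
            acc_transform(encoded, bundle.lag_max)
        except (EncodingError, SequenceLengthError) as exc:
            skipped.append((rec.id, str(exc)))
            continue
        admissible.append(rec)
    if not admissible:
        raise ValueError("no admissible records to classify "
                         f"({len(skipped)} skipped)")

    unlabeled = [ProteinRecord(r.id, r.sequence, r.description, None) for r in admissible]
    dataset = build_feature_matrix(unlabeled, bundle.table, bundle.lag_max, policy)
    votes, scores = _vote_matrix(bundle, dataset.features)
    results = [tally_votes(rec.id, votes[i], scores[i])
               for i, rec in enumerate(admissible)]
    return results, skipped


# ---------------------------------------------------------------------------
# Bundle persistence
# ---------------------------------------------------------------------------

_BUNDLE_FORMAT = "accvax-bundle-v1"


def save_bundle(bundle: VaxiJenBundle, path: str | Path) -> None:
    """Persist the three-member bundle as one versioned joblib archive."""
    payload = {
        "format": _BUNDLE_FORMAT,
        "metadata_json": bundle.metadata_json,
        "members": bundle.members,
        "table_values": dict(bundle.table.values),
        "table_name": bundle.table.name,
        "lag_max": bundle.lag_max,
        "feature_ordering_tag": bundle.feature_ordering_tag,
    }
    joblib.dump(payload, path)


def load_bundle(path: str | Path) -> VaxiJenBundle:
    """Load a persisted bundle, verifying format and ordering-tag coherence."""
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != _BUNDLE_FORMAT:
        raise ValueError(f"{path}: not an {_BUNDLE_FORMAT} archive")
    table = DescriptorTable(values=payload["table_values"], name=payload["table_name"])
    return VaxiJenBundle(
        members=payload["members"],
        table=table,
        lag_max=int(payload["lag_max"]),
        feature_ordering_tag=payload["feature_ordering_tag"],
        metadata_json=payload["metadata_json"],
    )
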