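"""Dataset curation: quality filters, pocket labeling, redundancy removal, splitting.

The pipeline mirrors common practice for building site-prediction training
sets from protein-modulator complexes:

1. resolution filter (keep X-ray structures better than ``resolution_max``);
2. modulator multiplicity (exactly one modulator instance per entry);
3. distance labeling (the pocket whose center of mass is closest to the
   modulator center becomes the single positive; entries whose closest pocket
   is farther than ``distance_max`` are dropped as unreliable);
4. sequence-redundancy removal at ``identity_max`` global identity, keeping
   the entry with the shorter modulator-pocket distance (finer labeling);
5. a protein-level random train/test split.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .structures import FEATURE_NAMES, ProteinEntry

__all__ = [
    "CurationConfig",
    "CurationReport",
    "label_pockets",
    "pairwise_identity",
    "redundancy_filter",
    "filter_resolution",
    "split_train_test",
    "curate",
    "entries_to_table",
    "read_feature_table",
    "table_fingerprint",
]


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds and split settings for the curation pipeline.

    resolution_max : keep entries with resolution strictly below this (A).
    identity_max   : maximum allowed pairwise global sequence identity.
    distance_max   : maximum modulator-to-closest-pocket distance (A).
    train_fraction : protein-level fraction assigned to the training split.
    split_seed     : RNG seed for the split; required for reproducibility.
    """

    resolution_max: float = 3.0
    identity_max: float = 0.30
    distance_max: float = 10.0
    train_fraction: float = 0.8
    split_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if min(self.resolution_max, self.identity_max, self.distance_max) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class CurationReport:
    """Per-stage drop counts plus a per-entry drop-reason log."""

    input_count: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)
    retained: int = 0

    def record_drop(self, protein_id: str, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1
        self.reasons[protein_id] = reason

    def check_conserved(self) -> None:
        if sum(self.dropped.values()) + self.retained != self.input_count:
            raise AssertionError("curation counts not conserved")

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_count": self.input_count,
                "dropped": self.dropped,
                "retained": self.retained,
                "reasons": self.reasons,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Labeling


def label_pockets(
    entry: ProteinEntry, distance_max: float = 10.0
) -> tuple[ProteinEntry | None, str | None]:
    """Label the pocket closest to the modulator positive; or drop the entry.

    Returns ``(labeled_entry, None)`` on success and ``(None, reason)`` when
    the entry must be dropped: ``"modulator_multiplicity"`` unless exactly one
    modulator instance is present, ``"no_pockets"`` without pockets, and
    ``"distance"`` when the closest pocket center is farther than
    ``distance_max`` from the modulator center.  Distance ties go to the
    lower pocket index (deterministic).
    """
    if entry.modulator_count != 1 or entry.modulator_center is None:
        return None, "modulator_multiplicity"
    if not entry.pockets:
        return None, "no_pockets"
    if any(p.center is None for p in entry.pockets):
        raise ValueError(f"{entry.protein_id}: pocket centers must be set before labeling")

    centers = np.array([p.center for p in entry.pockets], dtype=float)
    dists = np.linalg.norm(centers - np.asarray(entry.modulator_center, dtype=float), axis=1)
    # argmin on (distance, pocket_index) resolves exact ties deterministically
    order = sorted(range(len(dists)), key=lambda i: (dists[i], entry.pockets[i].pocket_index))
    best = order[0]
    if dists[best] > distance_max:
        return None, "distance"
    labels = tuple(1 if i == best else 0 for i in range(len(entry.pockets)))
    return (
        replace(entry, labels=labels, min_modulator_distance=float(dists[best])),
        None,
    )


# ---------------------------------------------------------------------------
# Sequence identity

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=-1.0,
    extend_gap_score=-1.0,
)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Needleman-Wunsch with match +1, mismatch 0, linear gap -1; identity is
    identical aligned pairs over the full alignment length (gaps included).
    The argument pair is canonicalized before aligning so the result is
    exactly symmetric even when co-optimal alignments exist.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a, b = sorted((seq_a, seq_b))
    alignment = _aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / alignment.length


# ---------------------------------------------------------------------------
# Filters


def filter_resolution(
    entries: Sequence[ProteinEntry],
    resolution_max: float = 3.0,
    report: CurationReport | None = None,
) -> list[ProteinEntry]:
    """Keep entries with a known resolution strictly below ``resolution_max``.

    Entries without a recorded resolution (e.g. NMR structures) fail the
    filter: only demonstrably high-resolution structures pass.
    """
    kept = []
    for e in entries:
        if e.resolution is not None and e.resolution < resolution_max:
            kept.append(e)
        elif report is not None:
            report.record_drop(e.protein_id, "resolution")
    return kept


def redundancy_filter(
    entries: Sequence[ProteinEntry],
    identity_max: float = 0.30,
    report: CurationReport | None = None,
) -> list[ProteinEntry]:
    """Greedy sequence-redundancy removal in input order.

    Each candidate is compared against all previously retained entries; if its
    identity to any of them exceeds ``identity_max``, the entry with the
    shorter minimum modulator-pocket distance survives (finer labeling wins).
    A candidate only displaces conflicting survivors if it beats every one of
    them.  The result contains no pair above the threshold and the pass is
    idempotent.
    """
    for e in entries:
        if e.min_modulator_distance is None:
            raise ValueError(f"{e.protein_id}: entries must be labeled before redundancy_filter")
    retained: list[ProteinEntry] = []
    for cand in entries:
        conflicts = [
            r for r in retained if pairwise_identity(cand.sequence, r.sequence) > identity_max
        ]
        if not conflicts:
            retained.append(cand)
        elif all(cand.min_modulator_distance < r.min_modulator_distance for r in conflicts):
            for r in conflicts:
                retained.remove(r)
                if report is not None:
                    report.record_drop(r.protein_id, "identity")
            retained.append(cand)
        elif report is not None:
            report.record_drop(cand.protein_id, "identity")
    return retained


def split_train_test(
    entries: Sequence[ProteinEntry],
    train_fraction: float = 0.8,
    split_seed: int = 0,
) -> tuple[list[ProteinEntry], list[ProteinEntry]]:
    """Random protein-level split into ``round(n*f)`` train and the rest test."""
    n = len(entries)
    if n < 2:
        raise ValueError("need at least 2 entries to split")
    n_train = int(round(n * train_fraction))
    perm = np.random.default_rng(split_seed).permutation(n)
    train = [entries[i] for i in sorted(perm[:n_train])]
    test = [entries[i] for i in sorted(perm[n_train:])]
    return train, test


# ---------------------------------------------------------------------------
# Full pipeline


def curate(
    entries: Sequence[ProteinEntry], config: CurationConfig
) -> tuple[list[ProteinEntry], list[ProteinEntry], CurationReport]:
    """Run the full pipeline: resolution -> labeling -> redundancy -> split."""
    report = CurationReport(input_count=len(entries))
    kept = filter_resolution(entries, config.resolution_max, report)
    labeled = []
    for e in kept:
        lab, reason = label_pockets(e, config.distance_max)
        if lab is not None:
            labeled.append(lab)
        else:
            report.record_drop(e.protein_id, reason)
    unique = redundancy_filter(labeled, config.identity_max, report)
    report.retained = len(unique)
    report.check_conserved()
    train, test = split_train_test(unique, config.train_fraction, config.split_seed)
    return train, test, report


# ---------------------------------------------------------------------------
# Feature tables

TABLE_COLUMNS = ["protein_id", "pocket_index", *FEATURE_NAMES, "label"]


def entries_to_table(entries: Sequence[ProteinEntry]) -> pd.DataFrame:
    """One row per pocket: protein_id, pocket_index, 19 descriptors, label."""
    rows = []
    for e in entries:
        if e.labels is None:
            raise ValueError(f"{e.protein_id}: entry is not labeled")
        for pocket, label in zip(e.pockets, e.labels):
            rows.append(
                [e.protein_id, pocket.pocket_index, *pocket.features.as_vector(), label]
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns and c != "label"]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return df


def table_fingerprint(df: pd.DataFrame) -> str:
    """Row count plus a content hash, for provenance lines in reports."""
    digest = hashlib.sha256(
        df.to_csv(index=False).encode()
    ).hexdigest()[:16]
    return f"{len(df)}:{digest}"
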