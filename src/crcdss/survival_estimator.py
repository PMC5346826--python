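"""Similarity-based survival estimation over a screening registry.

Each living patient's survival percent is derived from the deceased members of
the registry: under the default ``deceased-distance`` mode the estimate is

    percent = 100 × (1 − mean cosine similarity to the k most similar deceased
    patients)

— a patient whose coded profile closely resembles people who died gets a low
estimated survival.  References are drawn from the patient's own risk subgroup
when it holds at least ``k`` deceased members, otherwise registry-wide; ties
are broken by patient_id ascending for determinism.

The alternative ``outcome-weighted`` mode is a similarity-weighted k-NN vote
over patients of known vital status: percent = 100 × Σ(sim·alive) / Σ(sim).

Similarity is computed over the coded minimum-data-set slots excluding the
outcome fields (vital status, survival quality), so the estimate never reads
the answer off the reference's own outcome coding.  Each slot is min-max
scaled to [0, 1] first (registry option ``normalize_features``, on by
default): unnormalised codes would let a single wide-coded field dominate the
distance, defeating the similarity comparison.

Per-subgroup mean survival is maintained as plain arithmetic means over the
current estimates of living members and carries a monotone revision counter;
every registry change triggers a refresh whose result is guaranteed identical
to recomputing everything from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import InsufficientReferenceError
from .similarity import batch_similarity

DECEASED_DISTANCE = "deceased-distance"
OUTCOME_WEIGHTED = "outcome-weighted"

DEFAULT_K = 5


@dataclass(frozen=True)
class SurvivalEstimate:
    patient_id: str
    percent: float
    neighbors: Tuple[Tuple[str, float], ...]  # (deceased/reference id, similarity), sim desc
    k_used: int
    estimator_mode: str

    def __post_init__(self):
        if not 0.0 <= self.percent <= 100.0:
            raise ValueError(f"percent {self.percent} outside [0, 100]")
        if self.k_used != len(self.neighbors):
            raise ValueError("k_used must equal the number of neighbors")


@dataclass(frozen=True)
class GroupStats:
    subgroup: str
    mean_percent: Optional[float]  # None when the group has no estimated members
    n: int
    last_updated: int  # registry revision counter


def rank_neighbors(query_codes: Sequence[int],
                   refs: Sequence[Tuple[str, Sequence[int]]],
                   k: int,
                   feature_slots: Optional[Sequence[int]] = None,
                   similarity_mode: str = "faithful") -> List[Tuple[str, float]]:
    """Top-k references by similarity to the query (ties: patient_id ascending)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not refs:
        return []
    q = np.asarray(query_codes, dtype=float)
    mat = np.asarray([codes for _, codes in refs], dtype=float)
    if feature_slots is not None:
        slots = list(feature_slots)
        q = q[slots]
        mat = mat[:, slots]
    sims = batch_similarity(q, mat, mode=similarity_mode)
    scored = [(refs[i][0], float(sims[i])) for i in range(len(refs))
              if np.isfinite(sims[i])]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]


def estimate_survival(query, registry, k: int = DEFAULT_K,
                      mode: str = DECEASED_DISTANCE) -> SurvivalEstimate:
    """Estimate the survival percent of one patient against the registry.

    ``query`` is an :class:`~crcdss.mds_schema.EncodedVector`; the registry
    supplies the reference pool, the feature slots, and (when the query is a
    registry member) its risk subgroup for subgroup-restricted lookup.
    """
    entry = registry.entries.get(query.patient_id)
    subgroup = entry.group_key if entry is not None else None
    slots = registry.feature_slots
    query_features = (entry.features if entry is not None
                      else registry.scaled_codes(query.codes))

    if mode == DECEASED_DISTANCE:
        deceased = [(pid, e.features) for pid, e in registry.entries.items()
                    if e.record.is_deceased() and pid != query.patient_id]
        if not deceased:
            raise InsufficientReferenceError(
                "deceased-distance mode needs at least one deceased registry member")
        if subgroup is not None and getattr(registry, "subgroup_restricted", True):
            within = [(pid, c) for pid, c in deceased
                      if registry.entries[pid].group_key == subgroup]
            if len(within) >= k:
                deceased = within
        neighbors = rank_neighbors(query_features, deceased, k, slots)
        if not neighbors:
            raise InsufficientReferenceError(
                f"no deceased reference shares coded slots with {query.patient_id!r}")
        mean_sim = float(np.mean([s for _, s in neighbors]))
        percent = 100.0 * (1.0 - mean_sim)
    elif mode == OUTCOME_WEIGHTED:
        known = [(pid, e.features) for pid, e in registry.entries.items()
                 if e.record.vital_status is not None and pid != query.patient_id]
        if not known:
            raise InsufficientReferenceError(
                "outcome-weighted mode needs at least one patient of known vital status")
        neighbors = rank_neighbors(query_features, known, k, slots)
        if not neighbors:
            raise InsufficientReferenceError(
                f"no reference shares coded slots with {query.patient_id!r}")
        alive = {pid: 0.0 if registry.entries[pid].record.is_deceased() else 1.0
                 for pid, _ in neighbors}
        total = sum(s for _, s in neighbors)
        if total > 0:
            percent = 100.0 * sum(s * alive[pid] for pid, s in neighbors) / total
        else:  # all-zero similarities: fall back to the unweighted alive fraction
            percent = 100.0 * float(np.mean([alive[pid] for pid, _ in neighbors]))
    else:
        raise ValueError(f"unknown estimator mode {mode!r}")

    # 6-decimal rounding removes binary float residue (e.g. 99.999999999 for an
    # all-alive neighborhood) without affecting any displayed precision
    percent = round(float(min(100.0, max(0.0, percent))), 6)
    return SurvivalEstimate(query.patient_id, percent, tuple(neighbors),
                            len(neighbors), mode)


def group_mean_survival(registry, subgroup: str) -> GroupStats:
    """Arithmetic mean of current estimates over living members of ``subgroup``.

    An empty or estimate-less subgroup yields ``mean_percent=None`` with
    ``n=0`` — a signal, not an exception.
    """
    # summation in patient-id order so the mean is independent of insertion order
    values = [e.estimate.percent for _, e in sorted(registry.entries.items())
              if e.group_key == subgroup and not e.record.is_deceased()
              and e.estimate is not None]
    mean = float(np.mean(values)) if values else None
    return GroupStats(subgroup, mean, len(values), registry.revision)


def update_on_change(registry, changed_patient_id: str) -> Tuple[Set[str], Dict[str, GroupStats]]:
    """Refresh every estimate and statistic the changed patient can influence.

    Delegates to the registry's refresh machinery; the post-state is
    guaranteed identical to a full recomputation from scratch (the affected
    set is over-approximated whenever the change touches a reference pool).
    Returns the ids whose estimates changed and the refreshed per-group stats.
    """
    return registry.update_on_change(changed_patient_id)
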