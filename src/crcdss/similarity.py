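"""Cosine similarity with the registry system's fixed rounding contract.

The deployed screening system computes patient-to-patient similarity as

    cos(x, y) = round( dot(x, y) / (round(|x|, 3) * round(|y|, 3)), 3 )

i.e. each Euclidean norm is rounded to three decimals *before* the product, and
the quotient is rounded again.  The two-stage rounding is part of the contract
(the system's own worked example, ``cosine_similarity([3,45,7,2],
[2,54,13,15]) == 0.972``, is only reproducible this way), so ``faithful`` mode
preserves it bit-for-bit; ``unrounded`` mode gives the plain high-precision
cosine.  Rounding is Python's ``round`` (round-half-even on floats).

Feature vectors come from encoded minimum-data-set records; missing slots are
handled by :func:`prepare_pair` before any similarity call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .derived_features import MISSING
from .errors import AlignmentError, EmptyOverlapError, UndefinedSimilarityError

PAIRWISE_COMPLETE = "pairwise-complete"
UNKNOWN_AS_CODED = "unknown-as-coded"


@dataclass(frozen=True)
class FeatureVector:
    """An ordered run of nonnegative feature values plus the codebook slots they occupy."""

    values: Tuple[float, ...]
    feature_mask: Tuple[int, ...] = field(default=())

    def __post_init__(self):
        if len(self.values) < 1:
            raise ValueError("FeatureVector must hold at least one value")
        arr = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("FeatureVector values must be finite")
        if self.feature_mask and len(self.feature_mask) != len(self.values):
            raise ValueError("feature_mask length must match values length")


def _values(x) -> Sequence[float]:
    return x.values if isinstance(x, FeatureVector) else x


def rounded_norm(x) -> float:
    """Euclidean norm rounded to 3 decimals, exactly as the deployed helper."""
    vals = _values(x)
    if len(vals) == 0:
        raise ValueError("empty vector has no norm")
    return round(sqrt(sum(a * a for a in vals)), 3)


def cosine_similarity(x, y, mode: str = "faithful") -> float:
    """Cosine similarity under the two-stage 3-decimal rounding contract.

    Accepts :class:`FeatureVector` or plain sequences.  When both arguments are
    FeatureVectors their masks must match.  Raises
    :class:`~crcdss.errors.UndefinedSimilarityError` when both norms are zero.
    """
    if isinstance(x, FeatureVector) and isinstance(y, FeatureVector):
        if x.feature_mask != y.feature_mask:
            raise AlignmentError("feature masks differ; vectors are not comparable")
    xv, yv = _values(x), _values(y)
    if len(xv) != len(yv):
        raise AlignmentError(f"length mismatch: {len(xv)} vs {len(yv)}")
    numerator = sum(a * b for a, b in zip(xv, yv))
    if mode == "faithful":
        denominator = rounded_norm(xv) * rounded_norm(yv)
        if denominator == 0:
            raise UndefinedSimilarityError("both vectors have zero rounded norm")
        return round(numerator / float(denominator), 3)
    elif mode == "unrounded":
        denominator = sqrt(sum(a * a for a in xv)) * sqrt(sum(a * a for a in yv))
        if denominator == 0:
            raise UndefinedSimilarityError("both vectors have zero norm")
        return numerator / denominator
    raise ValueError(f"unknown mode {mode!r}")


def prepare_pair(a, b, policy: str = PAIRWISE_COMPLETE) -> Tuple[FeatureVector, FeatureVector]:
    """Align two encoded vectors into comparable FeatureVectors.

    ``pairwise-complete`` drops every slot missing in either vector and records
    the shared slot indices in the mask.  ``unknown-as-coded`` behaves the same
    for truly missing slots but, being applied to encoded vectors, keeps the
    codebook's coded "Unknown" (code 3) entries as ordinary values — they are
    codes, not missing markers, so no extra handling is needed beyond the name
    documenting the intent.
    """
    if policy not in (PAIRWISE_COMPLETE, UNKNOWN_AS_CODED):
        raise ValueError(f"unknown policy {policy!r}")
    ca, cb = a.codes, b.codes
    if len(ca) != len(cb):
        raise AlignmentError("encoded vectors come from different codebooks")
    mask = tuple(i for i in range(len(ca)) if ca[i] != MISSING and cb[i] != MISSING)
    if not mask:
        raise EmptyOverlapError(
            f"no shared non-missing slots between {a.patient_id!r} and {b.patient_id!r}")
    fa = FeatureVector(tuple(float(ca[i]) for i in mask), mask)
    fb = FeatureVector(tuple(float(cb[i]) for i in mask), mask)
    return fa, fb


def pairwise_similarity(a, b, policy: str = PAIRWISE_COMPLETE, mode: str = "faithful") -> float:
    fa, fb = prepare_pair(a, b, policy)
    return cosine_similarity(fa, fb, mode=mode)


def batch_similarity(query_codes: np.ndarray, ref_codes: np.ndarray,
                     mode: str = "faithful") -> np.ndarray:
    """Similarity of one query against many references, missing-aware, vectorised.

    ``query_codes``: shape (d,), ``ref_codes``: shape (m, d); entries equal to
    the missing sentinel are dropped pairwise per reference.  Numerically
    identical to the per-pair scalar path (numpy's ``round`` is also
    half-even); rows with no overlap or an undefined quotient yield NaN.
    """
    q = np.asarray(query_codes, dtype=float)
    r = np.atleast_2d(np.asarray(ref_codes, dtype=float))
    valid = (q != MISSING) & (r != MISSING)
    qm = np.where(valid, q, 0.0)
    rm = np.where(valid, r, 0.0)
    dots = np.einsum("ij,ij->i", qm, rm)
    qn = np.round(np.sqrt(np.einsum("ij,ij->i", qm, qm)), 3)
    rn = np.round(np.sqrt(np.einsum("ij,ij->i", rm, rm)), 3)
    denom = qn * rn
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "faithful":
            out = np.round(dots / denom, 3)
        elif mode == "unrounded":
            qn2 = np.sqrt(np.einsum("ij,ij->i", qm, qm))
            rn2 = np.sqrt(np.einsum("ij,ij->i", rm, rm))
            out = dots / (qn2 * rn2)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    out[~valid.any(axis=1)] = np.nan
    out[denom == 0] = np.nan
    return out


def codebook_scaler(book) -> Tuple[np.ndarray, np.ndarray]:
    """Per-slot (min, range) of a codebook's live codes, for min-max feature scaling.

    Similarity over coded records normalises every slot to [0, 1] so that no
    single wide-coded field dominates the distance; slots whose field has a
    single code get range 1 (they scale to 0).
    """
    mins = np.array([min(c for _, c in f.codes) for f in book], dtype=float)
    maxs = np.array([max(c for _, c in f.codes) for f in book], dtype=float)
    rng = np.where(maxs > mins, maxs - mins, 1.0)
    return mins, rng


def normalize_codes(codes, mins: np.ndarray, rng: np.ndarray) -> np.ndarray:
    """Min-max scale a coded vector, preserving the missing sentinel."""
    arr = np.asarray(codes, dtype=float)
    out = (arr - mins) / rng
    out[arr == MISSING] = MISSING
    return out


def similarity_matrix(vectors: Iterable, policy: str = PAIRWISE_COMPLETE,
                      mode: str = "faithful") -> pd.DataFrame:
    """Symmetric patient-by-patient similarity matrix (diagonal fixed at 1.0).

    Pairs whose similarity is undefined (zero norms or empty overlap) are left
    as NaN and logged.
    """
    import logging

    vecs: List = list(vectors)
    if len(vecs) < 2:
        raise ValueError("similarity_matrix needs at least two vectors")
    ids = [v.patient_id for v in vecs]
    n = len(vecs)
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    log = logging.getLogger(__name__)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                out[i, j] = out[j, i] = pairwise_similarity(vecs[i], vecs[j], policy, mode)
            except (EmptyOverlapError, UndefinedSimilarityError) as exc:
                log.warning("similarity undefined for (%s, %s): %s", ids[i], ids[j], exc)
    return pd.DataFrame(out, index=ids, columns=ids)
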